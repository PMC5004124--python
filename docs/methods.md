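# Methods

## The decoding problem

Hippocampal CA1 place cells fire selectively at particular locations.
During quiet wakefulness and slow-wave sleep the same cells re-express
run-like firing sequences ("replay") inside sharp-wave-ripple events,
but the data look nothing like run data: epochs are short (tens to
hundreds of milliseconds), only a small fraction of cells participates
in any one event, and the sequences play out ~10-20x faster than
behavior.  `popdecode` implements two Bayesian population decoders for
this regime, a synthetic data generator that reproduces the sleep-like
structure with known ground truth, and a shuffle-based significance
test for replay.

Throughout, spike counts are binned at width Δ and, conditional on the
latent position/state `S_t`, are independent Poisson across cells:

    p(y_t | S_t) = prod_c Poisson(y_tc ; lambda_c(S_t) * Δ)

The posterior over `S_t` follows Bayes' rule with either no temporal
prior (per-bin decoding) or a first-order Markov prior.

## Receptive-field decoder (supervised)

Place fields `lambda_c(S)` are estimated from behavior as
occupancy-normalized rate maps on 10-cm track bins or 15x15-cm (or
5x5-cm) open-field bins, then smoothed with a small Gaussian template
(5x1 in 1-D, 3x3 in 2-D, SD = 0.5 bins).  Smoothing is applied to the
spike-count and occupancy-time maps separately using a kernel whose
weights are renormalized per *source* bin over the visited bins it can
reach.  This makes smoothing exactly mass-preserving (total spikes and
total time are conserved, which the test suite asserts to 1e-9) and
positivity-preserving, and it removes edge attenuation.  Bins never
visited are masked and excluded from the decoding support rather than
set to zero rate.

Decoding maximizes the per-bin posterior (MAP).  Numerical choices:

* log-domain likelihoods with per-row max subtraction;
* a rate floor of ε = 0.01 Hz added to the field before taking logs, so
  a finite-sample empty field bin cannot produce a -inf likelihood;
* MAP ties broken toward the lowest support index (deterministic);
* accuracy is the median over time bins of the distance between the MAP
  bin center and the true position — linear distance on linear tracks,
  wrap-around distance on circular tracks, Euclidean in 2-D.

Because per-bin decoding ignores temporal context, the median error is
*exactly* invariant to how the recording is cut into epochs, reversed,
or reordered (the decoded multiset of bins is unchanged); the suite
checks bit-identity across epoch lengths.

## Spatial information

Per cell, `I_c = sum_S p(S) lambda_c(S) log2(lambda_c(S)/mean_c)` in
bits/s with `mean_c = sum_S p(S) lambda_c(S)`, `0 log 0 := 0`, and the
normalized rate `I_c / mean_c` in bits/spike (log base 2 throughout).
Cells are median-split on bits/spike for the information experiments;
the extra cell of an odd population goes to the low group and ties are
broken by cell index, so the split is deterministic.

## Receptive-field-free decoder (HDP-HMM)

Without behavior, position is modeled as a latent discrete state with a
stationary transition matrix P and a state-by-cell rate matrix Λ.  The
state count m is inferred with a hierarchical-Dirichlet-process prior
over transition rows, sampled by a weak-limit blocked Gibbs sampler at
truncation L (default 100):

1. state sequences per epoch by forward-filter/backward-sample, epochs
   treated as independent chains sharing P and Λ, each initialized at
   the stationary distribution of the current P;
2. conjugate gamma-Poisson updates for Λ (shape 1, rate matched so the
   prior mean equals the grand mean firing rate of the data);
3. HDP stick weights via the usual auxiliary table counts, with an
   optional sticky self-transition mass κ (default 0).

Concentrations default to γ = α = 1 (weakly informative); they were
fixed by parameter-recovery oracles on synthetic K-state data.

**Reported sample.**  One posterior sample is reported (not an average,
so P and Λ stay mutually coherent).  The sample is chosen, after
burn-in, to maximize the *collapsed* joint p(y, z | β, hyperparameters)
with Λ and P integrated out (gamma-Poisson and Dirichlet-multinomial
marginals).  Selecting instead by the complete-data likelihood
p(y, z | P, Λ) measurably inflates the state count — an extra near-
duplicate state always fits noise slightly better — while the collapsed
score carries the Bayesian Occam penalty and recovers the true m on
oracle data.  The effective state count m is the number of states
occupying at least 0.5% of time bins in the selected sample; raw
truncation occupancy would overstate m.

Mixing caveat: merging two redundant states is a slow move for a Gibbs
sampler.  On weakly structured data (few states, iid-like counts) a few
hundred sweeps are needed before the occupancy collapses; the
diagnostics include the collapsed log-joint trace and a crude
convergence flag comparing early and late post-burn-in segments.

**Evaluation only:** a state-space map assigns each state the centroid
(circular mean on circular tracks) of the positions of its
Viterbi-assigned bins.  Positions enter nowhere else.  Decoding error
is then the same median-distance statistic as for the supervised
decoder; bins whose state has no mapped position are excluded and the
excluded fraction reported.  The state graph (edge weight
`P_ij + P_ji`, force-directed Fruchterman-Reingold layout with a fixed
seed, coordinates normalized to the unit bounding box) is exposed for
qualitative topology inspection.

## Replay significance

Candidate events are screened from the smoothed multi-unit activity
(and, if supplied, ripple-band power) at mean + 3 SD, expanded to the
nearest sub-mean crossings, and kept only if at least
max(6, 10% of cells) are active.  Each event's posterior is summarized
by the weighted correlation R: the Pearson correlation between time-bin
index and support position with the posterior mass as weights.  R is
computed with exactly rounded summation (math.fsum) on a centered time
index, which makes `R(time-reversed event) = -R(event)` hold bit-exactly
and the statistic independent of summation order.

The null is built from (default) 1000 joint shuffles of the event's
spike-count matrix — whole time bins permuted together, then cell
identities permuted — each re-decoded with the same decoder.  The
Z-score standardizes |R| by the signed null's mean and SD,
`Z = (|R| - mean R_shuffle)/SD(R_shuffle)`; |R| is used so forward and
reverse events score alike, with the signed R kept for the direction
call.  If the null passes a Shapiro-Wilk normality check (alpha = 0.05,
n <= 5000) the p-value is the one-sided normal tail; otherwise the
Monte-Carlo add-one estimator `(1 + #{|R_s| >= |R|})/(n + 1)` is used,
which also avoids p = 0.

An event is significant iff all of: |R| > 0.5; length >= 5 bins (100 ms
at the 20-ms ripple timescale) with a MAP probability score above the
5/n_support chance level; and Z > 1.65 (or Monte-Carlo p < 0.05 on the
non-normal branch).

## Synthetic data: what it emulates and what it does not

The generator is the exact generative twin of the Poisson likelihood:
Gaussian-bump tuning curves evaluated along a simulated trajectory
(smooth random walk with reflecting walls in the open field; laps on
tracks; 60-Hz position sampling; lognormal speed with the target mean).
Cell heterogeneity is deliberate and matches the strongly skewed rates
of real CA1 populations: lognormal peak rates (median 10 Hz, log-SD
0.6, clipped to 2-40 Hz) and lognormal out-of-field baselines (median
0.15 Hz, log-SD 1.0).  Defaults give session rates near 1-1.5 Hz with a
wide spread and bits/spike spanning roughly 0.2-3.  This heterogeneity
is what gives the information-split experiment its direction: a
homogeneous population (equal peaks, shared baseline) shows no
advantage for the "information-rich" half, because the median split
then only separates narrow from wide fields.

Sleep-like structure is imposed by transforms with conserved
quantities: a 15-cm/s speed filter; even splitting into T0-bin epochs
with per-epoch time reversal (probability 0.5) and order shuffling
(trailing partial epochs are dropped); fixed or per-epoch random cell
subsampling with `max(round(rho*C), 10)` active cells (round-half-up);
clip-to-one spike thinning (a binomial variant is exposed);
zeroing of randomly chosen time bins; flattening selected cells into
non-place cells by redistributing their exact spike total over time
bins in proportion to spatial occupancy; and compressed replay events —
a path resampled to `round(duration/Δ)` bins at Δ = 20 ms with a rate
gain, embedded in a Poisson MUA baseline for detector tests.

Not emulated: theta-phase precession and theta sequences, real LFP
waveforms (only a band-power-like MUA trace), interneurons, rate
remapping, and behavioral stereotypy (a given position is approached
from random directions).  Consequently the tests demonstrate internal
consistency and statistical calibration of the methods, not their
performance on real recordings; in particular the bin-size effects
driven by theta sequences in real data are absent here.

## Experiment harness and problem sizes

Monte-Carlo runs are paired: run i is seeded with `base_seed + i` and
all grid cells within a run share the same synthetic substrate.
Summaries are mean ± SEM (SD/sqrt(n)) over runs of the per-run median
decoding error, or of |R| and Z for detection experiments.  Default
sizes follow the published convention (n = 50 runs; 100 for detection);
the shipped acceptance checks use n = 20 runs on 36-cell, 300-s
sessions with the woRF sampler at L = 25 and 40 sweeps, and 500 null
events at 1000 shuffles each — sizes chosen so the whole suite runs on
a laptop-class single core in minutes while leaving every assertion's
direction unchanged at larger scale.

## Known limitations

* The weak-limit Gibbs sampler has no split-merge moves; state counts
  from a single short chain are noisy (hence modal-m reporting across
  chains, mirroring the run-to-run variability of any MCMC decoder).
* The MAP state sequence is taken from one selected sample; posterior
  uncertainty about P is not propagated into the replay statistics.
* The candidate-event detector assumes a uniformly sampled MUA trace
  and a single threshold pair; it is a screening tool, not a ripple
  detector for raw LFP.
* 2-D replay scoring requires an ordered 1-D support (track position or
  mapped state positions); cursive 2-D trajectories are out of scope.
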