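# Methods

## The model

A dense multi-electrode array records the extracellular potential
`V(i, t)` on a rectangular grid of electrodes. The sorter assumes each
recorded firing event is a linear superposition of stereotyped unit
waveforms plus correlated Gaussian noise:

    V = sum_k  lambda_k * T_{c_k}(t - t_k)  +  noise,

where `T_c` is the spatiotemporal template of unit `c` (defined on the 3x3
electrode neighborhood of its leader electrode), `t_k` the spike time, and
`lambda_k > 0` a per-spike amplitude scale. The only intrinsic waveform
variability modeled is this multiplicative rescaling; it is given a Gaussian
prior `lambda ~ N(mu_c, sigma_c^2)` per unit (kept Gaussian for analytic
tractability even though lambda is positive — the mass at negative values is
negligible for the concentrations seen in practice). Firing is a priori
Poisson with rate `r_c`, deliberately unstructured: no refractory period or
cross-unit correlation enters the prior, so the refractory hole observed in
the output is a genuine check, not an assumption.

## Noise model

After spatial whitening the noise is modeled as independent across channels
and AR(1) in time:

    Cov[n_i(t), n_j(t')] = delta_ij * sigma^2 * exp(-|t - t'| / tau).

The inverse of an AR(1) covariance is tridiagonal, so every quadratic form
`x' C^-1 y` costs O(channels x samples); no empirical covariance matrix is
ever inverted. `sigma^2` is the pooled lag-0 autocovariance of noise clips;
`tau` comes from a log-linear least-squares fit of autocovariance against
lag over lags 1..10 per channel, averaged. Lags whose autocovariance does
not clear four standard errors of the estimator are dropped from the fit —
the log of a noisy near-zero estimate is badly biased and would otherwise
drag `tau` around (this matters for white or short-memory noise).

`gaussianity_check` decorrelates clips with the innovations filter
`e_t = (x_t - a x_{t-1}) / (sigma sqrt(1-a^2))` and compares the pooled
one-point marginal against N(0,1) on a quantile grid, reporting the mass
beyond four standard deviations. The model is deliberately light-tailed; the
check is how a user discovers when their data is not.

## Preprocessing

* High-pass: zero-phase (forward-backward) windowed-sinc FIR, default cutoff
  200 Hz, order chosen so a single pass attenuates >= 20 dB at half the
  cutoff (>= 40 dB for the two passes).
* Clip extraction uses two negative thresholds expressed in multiples of the
  pooled noise sd: spike threshold 4 sigma, noise-exclusion threshold
  3.5 sigma. Windows whose deepest excursion lies between the two are used
  for nothing — too shallow to be a trusted spike, too deep to be clean
  noise. The 3.5 sigma default is deliberate: the probability that a
  30-channel x 32-sample window stays above 2 sigma everywhere is
  essentially zero for Gaussian noise, so a 2 sigma exclusion would starve
  the noise estimator; at 3.5 sigma about 80% of genuinely clean windows
  qualify. Both knobs are configurable.
* Spatial whitening applies the symmetric inverse square root of the
  noise-clip channel covariance (regularized by 1e-6 x mean diagonal),
  rescaled so the pooled per-channel noise sd is preserved — thresholds keep
  their familiar units. Whitening uses the symmetric root rather than a
  Cholesky factor so the transform treats channels symmetrically.
* Segmentation thresholds the whitened data into stixels (channel, sample)
  and groups them into connected components, connecting nearest grid
  neighbors (4-connectivity) and adjacent samples. Each component yields one
  cropped event: a 32-sample, 3x3-channel region centered on the component's
  deepest stixel (ties: earliest time, then lowest channel), zero-padded
  with a validity mask at array edges. Peak stixel tie-breaks and 0-based
  indexing make segmentation bit-reproducible.

## Clustering

Only events sharing a leader electrode are directly compared. Within a
batch, events are cubic-spline upsampled x5, aligned so the leader-row
trough sits at the window center, and downsampled again. Alignment uses the
leader row, not the global deepest sample: a deeper spike from a
neighboring unit inside the crop would otherwise hijack the alignment. The
correction is clamped to +-2 samples because crops are already centered to
the sample by construction.

Masking zeroes samples less negative than 2 sigma. The distance between two
masked events is

    d(x, y) = (1/N) * sum_{i active} (x_i - y_i)^2 / s_i,

where the active set is stixels nonzero in either event, N its size, and
`s_i = max(|x_i|, |y_i|, sigma)` a local amplitude scale that partially
compensates the higher variability of high-voltage traces (set `s_i = 1` to
disable). Pairs with disjoint masks get a large sentinel distance.

OPTICS is implemented in-package on the precomputed distance matrix:
expansion starts at index 0 and the next point is always the unprocessed
point of smallest reachability, ties broken by event index, making the
ordering deterministic. Clusters are cut from the ordering either from an
explicit band list (the programmatic replacement for the interactive
band-cutting step) or automatically: the ordering is split at positions
whose reachability reaches 3x the median reachability, each split position
starting the next band, and bands shorter than `min_pts` (default 10) stay
unassigned. The split-at-peaks rule replaces a band rule that kept "runs
below a threshold": with any threshold near the median, roughly half the
within-cluster reachability values sit above it by definition and even a
single clean cluster would shatter.

Composite clusters are detected by projecting the *unmasked* aligned
waveforms of a band onto their first three principal components and testing
each projection for multimodality (masked events quantize into discrete
stixel patterns that fake multimodal projections). Multimodality is a
2-component Gaussian mixture that beats one component on BIC, with Ashman's
D > 2 and both weights above 3% — overlapping components describe a skewed
bump, not two modes. A genuinely multimodal projection is cut at the
histogram valley between the two component means, recursing once; a split
that strands fewer than `min_pts` events on one side is rejected, which
also disarms outlier-driven mixture fits. The mixture/BIC test stands in
for a dip-style unimodality test, which no installed library provides.

Duplicate clusters (one unit heard on two leader electrodes, or split
bands) are merged transitively when the peak normalized cross-correlation
of their median waveforms over time shifts reaches 0.95.

## Templates and priors

A cluster's template is the pointwise median of its aligned upsampled
events, refined once: each event is re-aligned to the draft median by
maximizing normalized cross-correlation over +-1 ms of shifts, events whose
best correlation stays below 0.5 are dropped as outliers, and the median is
recomputed. Medians make the template robust to the contaminated events in
which a second unit fired nearby. The per-event scale
`lambda = <event, T> / <T, T>` (ordinary inner product, the same closed
form used later for subtraction) gives the amplitude prior (mu_c, sigma_c);
the template is renormalized so mu_c = 1. The rate prior is the cluster's
event count over the clustered duration. Clusters need 20 events to produce
a template. The five reading frames are the downsampled versions of the
upsampled template at each sub-sample shift; fitting phase k at integer
sample m represents a spike at m - k/5 samples.

## Fitting

For a candidate "unit c at sample t, phase k", the amplitude is integrated
out analytically. With `A = T'C^-1 T + 1/sigma_c^2` and
`b = T'C^-1 V + mu_c/sigma_c^2`, the log posterior ratio against "no
additional spike" is

    log R = log(r_c dt) + b^2/(2A) - mu_c^2/(2 sigma_c^2)
            - (1/2) log(sigma_c^2 A).

The closed form is certified against direct numerical quadrature of the
defining integral in the test suite (relative tolerance 1e-6). The
`log(r_c dt)` factor is tiny (a per-sample firing probability), so a
candidate must explain substantial signal energy to be accepted; the tight
amplitude prior additionally punishes templates that must stretch far from
their typical scale — both effects counteract overfitting without any
explicit penalty term.

The greedy (matching-pursuit) loop: find the clip's absolute negative peak;
evaluate the ratio for every template whose leader is within one grid step
of the peak channel, every reading frame, and every sample within +-1 ms;
if no template's ratio summed over candidate times exceeds one
(log-sum-exp in log space), stop; otherwise accept the argmax (ties: higher
prior mean, then lower unit id), subtract the least-squares fit (scale
`<V,T>/<T,T>`, shift searched over +-2 samples and all five phases; a
non-positive scale rejects the candidate), and repeat, up to 20 spikes per
event. The reported spike time is the posterior argmax, not the subtraction
optimum. Because templates vanish outside their 3x3 neighborhood, computing
the quadratic forms over the template support is exact at clip scale — the
spatiotemporal-neighborhood restriction that motivates it on large arrays
introduces no approximation here.

Spike clips may overlap when a burst outlasts the clip window, so one spike
can be fitted from two clips; after each pass, fits of one unit closer than
0.25 ms collapse onto the one with the higher posterior ratio. (Planted
refractory periods are 2 ms, so no legitimate pair is ever that close.)

A residual still crossing the 4 sigma detection threshold after the loop
terminates is an "incomplete fit": the residual clip is archived,
re-segmented, re-clustered, and turned into new templates (discarding any
whose waveform duplicates an existing template at xcorr >= 0.95). Priors
are refreshed from pass-1 fits (rates from counts over the full duration;
amplitude priors from accepted scales above the unit's amplitude cutoff)
and a second pass refits every event with the extended bank.

## Validation

Per unit: (1) residuals of single-spike events should be flat in the mean
and match the noise sd pointwise and pooled (tolerance 25% on the pooled
ratio); (2) the amplitude histogram should be unimodal — a well-separated
low mode (valley below half the minor mode's height) is treated as noise
fits and cut away at the valley, while discernible-but-overlapping modes
flag the unit unreliable; (3) the ISI distribution must show a refractory
hole (violation fraction below 0.5% at a 2 ms refractory window); and the
amplitude histogram must stay clear of the detection floor — a unit with
more than 5% of fitted amplitudes below the 4 sigma trigger level is
missing true spikes and is excluded. Pairwise cross-correlograms are
scanned for central holes (mass in +-1.5 ms below half the flanking
expectation, Poisson-tested at p < 0.01): distinct units need no mutual
refractoriness, so a hole marks probable duplicates, which are merged when
their templates also agree (xcorr >= 0.95).

## Synthetic study conditions

The generator emulates the recording conditions the sorter targets: a 5x6
grid (30 channels) at 100 µm pitch, 10 kHz sampling; biphasic unit
waveforms (negative lobe about 0.5 ms, slower positive rebound about 1 ms
later) with exponential spatial falloff (length scale 0.4–1 electrode
pitch) from a continuous soma position near an interior electrode; per-spike
amplitudes N(1, 0.1^2) truncated at zero (10% jitter); noise that is AR(1)
in time (tau = 0.3 ms) and exponentially correlated in space (length 40 µm),
sd 10 µV. Peak amplitudes span 5–10 noise sd by default. Two planting
modes: per-unit Poisson trains with a refractory dead time, and the
planted-overlap clip design (a fixed number of distinct units per clip at
random times with edge margins). Ground truth records every planted spike.

Distinct templates must satisfy two separation rules: normalized waveform
cross-correlation < 0.95 and masked-metric distance >= 2.5 noise sd on
shared support. The second rule is what "well separated" means here: a
template pair whose waveform difference is below the metric's noise floor
is statistically indistinguishable event-by-event, and no clustering method
could meet an agreement criterion on it. Both bounds are configurable.

What the generator does not emulate: spike-width variation, electrode
drift, axonal (triphasic, propagating) signals, bursting amplitude decay
correlated in time, non-Gaussian noise tails, and stimulus-locked firing.
Tests passing on these conditions therefore demonstrate correctness of the
algorithmic machinery under the model's own assumptions, not robustness to
every departure from them seen in tissue.

Scoring matches fitted to true spikes greedily by |Δt| within +-0.5 ms
(each spike used once); a false negative is an unmatched true spike, a
false positive an unmatched fit. Fitted units map to true units by greedy
template cross-correlation.

## Numerical and determinism notes

* All randomness flows from explicit seeds; the generator derives
  independent sub-streams for templates, noise, and spike placement, so the
  spike realization is identical with and without noise.
* Ratio sums over candidate times use log-sum-exp.
* The AR(1) quadratic form uses exact boundary coefficients; embedded
  (interior) waveforms use the interior coefficient shortcut, which is
  exact when the support is strictly inside the window.
* OPTICS ties and peak-stixel ties are broken by index, making every stage
  order-deterministic; two runs of the full pipeline with the same
  configuration produce identical spike tables.
* Degenerate inputs: zero amplitude-prior sd falls back to a plug-in ratio
  at lambda = mu_c with a warning; clusters below the event floor are
  dropped with a warning; an all-zero event has no barycenter and raises.

## Problem sizes in the tests

The acceptance checks run on desk-scale versions of the study conditions:
5,000 32-sample clips per noise-model replicate (20 replicates), 400 events
for template recovery, 10 units / 30 s for clustering, 1,000 single-spike
trials and 500 three-spike overlap clips for fitting error rates, 40 s for
second-pass recycling, and 12–24 s recordings for the end-to-end pipeline
runs. These sizes were chosen so each check's sampling error is small
relative to its acceptance margin.
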