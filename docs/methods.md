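# Methods

`voxnorm` implements individual-level abnormality mapping for
co-registered scalar brain maps (white-matter fractional anisotropy FA,
mean diffusivity MD, grey-matter cerebral blood flow CBF): a per-voxel
normative model is fit to an uninjured control cohort, and a single
subject's map is converted into a thresholded binary map of voxels where
that subject is statistically extreme relative to the controls.

## The normative model

At each masked voxel, the control values X_1 .. X_N (N controls) define
a weighted Gaussian kernel density

    f(x) = sum_n w_n * phi((x - X_n) / h) / h .

**Bandwidth.** h is chosen per voxel by least-squares leave-one-out
cross-validation,

    CV(h) = Int f^2(x) dx - (2/N) sum_n f_{-n}(X_n),

evaluated in closed form for Gaussian kernels (the squared-density
integral is a pairwise Gaussian of center differences at variance 2h^2;
the leave-one-out density renormalizes the remaining N-1 kernels) over
50 log-spaced candidates between 0.01 and 10 times the sample SD.
CV(h) diverges to -inf as h -> 0 whenever the sample contains
near-duplicate values — the classical LSCV degeneracy — so the selector
takes the **largest interior local minimizer** of the CV curve (the
standard remedy), falling back to the global argmin when the curve has
no interior local minimum; exact ties resolve to the smallest h.  Even
so, LSCV retains its well-documented selection variance: on clean
Gaussian samples of N = 44 about one voxel in five selects h below
0.4 SD, which measurably thickens the far-tail error of the plug-in
p-values (see "Known limitations").

**Robust weights.** The kernel weights w_n down-weight outlying control
points (e.g. corrupted scans) so they do not inflate the normative
tails.  Following the robust-KDE construction, each point's distance to
the current mixture is computed in the Gaussian-kernel feature space,

    d_n^2 = k(x_n, x_n) - 2 sum_m w_m k(x_n, x_m) + sum_jk w_j w_k k(x_j, x_k),

and weights are updated as w_n ∝ psi(d_n)/d_n for the Hampel
redescending influence function (linear to a, flat to b, tapering to
zero at c), iterating to a 1e-6 max-weight-change tolerance (at most
100 iterations; non-convergence returns the last iterate with a
warning, recorded in the model provenance).  The breakpoints are set
once, from the distance distribution at the uniform-weight
initialization:

    a = median(d),  b = max(d),  c = 2 max(d) - median(d).

This placement is a deliberate design choice.  Because the feature-space
distance saturates (every far-away point approaches the same limiting
distance), quantile breakpoints *inside* the observed range — e.g.
b at the 95th percentile with c at the maximum — zero out the most
extreme control points even when the sample is perfectly clean, which
lightens the normative tails and inflates far-tail false positives by
an order of magnitude (measured: P(P' <= 0.001) ~ 0.03 instead of
~0.004 for N = 44 Gaussian controls).  With the zero of the influence
function placed *beyond* the initial distance range, clean extreme
points keep at least a/max(d) (~ 70%) of the bulk weight (max/min
weight spread below ~2), the flag rate on clean data matches the
unweighted estimator, and gross outliers — which always sit at the
largest distances — still receive the smallest weights and redescend
toward zero as the mixture migrates away from them during the
iteration.  Contamination experiments (10% of controls displaced by
~8 SD) confirm the outlier weight falls below every inlier weight and
the robust fit's flag rate on clean test values stays closer to the
nominal level than the unweighted fit's.  Note the direction of that
comparison: one-sided contamination *widens* an unweighted KDE, so the
corrupted model flags fewer clean values, not more; deviation from the
nominal rate is the meaningful robustness measure.

Voxels with zero control variance cannot support a density and are
flagged invalid; their probabilities propagate as missing and they are
excluded from every downstream count, never silently filled.

## Scoring, thresholding, direction

A subject's value (cross-sectional analysis, CS: the post-injury value
against control baselines) or change (longitudinal analysis, LNG: the
post-minus-baseline change against control post-season-minus-baseline
changes) is scored by the mixture CDF P = sum_n w_n Phi((x - X_n)/h)
and folded to a two-tailed probability P' = 2 min(P, 1 - P).  Each
single map is thresholded by the Benjamini-Hochberg step-up at FDR
q = 0.05 over its valid masked voxels (one BH run per subject, modality,
analysis and timepoint — maps are not pooled), then connected abnormal
components smaller than 3 voxels are removed (26-neighbourhood by
default; the neighbourhood and minimum size are configurable).
Surviving voxels are classified positive (P >= 0.975) or negative
(P <= 0.025); an abnormal voxel with mid-range P cannot have survived
FDR <= 0.05 and raises a consistency error.  Tissue masks use strict
thresholds: mean FA > 0.25 (white matter), mean control CBF > 20
mL/100 g/min (grey matter); MD is analysed inside the FA-derived mask,
which the caller supplies.

Overlap of two binary maps is the Jaccard index |X n Y| / |X u Y|;
when both maps are empty the value is recorded as missing rather than
0 or 1, and excluded from pooled medians (an empty pair is "no
abnormality anywhere", not disagreement).  Paired contrasts of overlap
values use the Wilcoxon signed-rank test (zero differences dropped,
exact null for n <= 25 without ties; an all-zero contrast returns
p = 1).  Threshold sweeps re-threshold the retained P' maps under
three schemes — BH at q in [0.005, 0.10], uncorrected P' <= alpha in
[0.005, 0.05], and per-map percentile cutoffs from the 95th to 99.9th
percentile (each map's own P' distribution; 7 grid points per scheme)
— with the cluster filter re-applied in every scheme.  Regional
localization parcellates each binary map into connected clusters (same
neighbourhood as the filter), assigns every cluster the set of atlas
regions it overlaps, and assigns background-only clusters to the
region with the nearest center of mass (Euclidean, voxel coordinates;
ties to the lowest region id), so no abnormal voxel is dropped.
Regional frequency counts *maps*, not clusters.  CS/LNG concordance of
regional frequencies is a Spearman correlation with a percentile 95%
bootstrap CI over 10,000 resamples of regions (the correlated units).

## The synthetic cohort generator

Individual-level athlete imaging data are rarely shareable, so every
experiment runs on a generator that emulates the statistical structure
the analysis assumes.  For subject s, voxel v and session:

    X = mu(v) * (1 + s_off(v) * delta_s(v) + s_noise(v) * eps + is_post * drift)

* `delta_s` — a unit-variance **stable offset field**, drawn once per
  subject and shared by all of that subject's sessions.  This is the
  trait-like component (anatomy, physiology) that makes an individual
  consistently high or low at particular voxels.
* `eps` — unit-variance session noise, fresh per session.
* Both fields are spatially smoothed (Gaussian, 1.5 voxels by default,
  periodic boundaries so the per-voxel variance renormalization is
  exact) and, at a designated fraction of voxels (default 15%,
  matching the published 5-21% non-normal voxel fractions), pushed
  through a standardized log-normal transform (shape 0.8) to emulate
  non-Gaussian voxels.
* `drift` — the modality's median longitudinal percent change.

The split of the baseline across-subject CoV field c(v) into offset and
noise shares is governed by one parameter, the relative change scale
g = sd(post - baseline)/baseline:

    s_noise = g / sqrt(2),    s_off(v) = sqrt(c(v)^2 - g^2 / 2),

so that, by construction, (i) baseline CoV across subjects equals c(v),
(ii) the SD of control change maps is g * mu, and (iii) the CoV of
change values is g / |drift|.  Defaults are calibrated to the published
control summaries:

| modality | c median | drift (%) | change CoV | implied g |
|----------|----------|-----------|------------|-----------|
| FA       | 0.0586   | -0.12     | 7.47       | 0.0090    |
| MD       | 0.0423   | +1.41     | 2.26       | 0.0319    |
| CBF      | 0.443    | -1.87     | 2.99       | 0.0559    |

Note what the calibration implies: for FA and CBF the stable offset
carries ~99% of baseline variance.  That asymmetry is the engine of the
headline phenomenon — cross-sectional scoring sees trait deviations
that longitudinal scoring cancels — and here it is reproducible by
construction.  The offset must be a *field*, not a
per-subject scalar: a scalar offset couples every voxel to one shared
random draw, so cohort-level summaries (median CoV) inherit its +-11%
fluctuation, and a subject two offset-SDs from zero shifts *all* voxels
past P' = 0.05 at once, which makes the BH step-up flag entire maps.

Injected abnormalities are voxel clusters (Euclidean balls, or exactly
n nearest mask voxels when an exact size is needed) shifted by
sign x effect x SD(v).  Two modes define the ground truth for the two
analyses: **value** mode adds the offset to the subject's baseline and
the affected post-injury sessions (a stable deviation, in units of the
baseline value SD c(v) mu(v)) — detectable by CS, invisible to LNG
because it subtracts out; **change** mode adds the offset only to the
post-injury sessions, in units of the control change SD g mu(v) —
detectable by LNG, and small in value units wherever stable offsets
dominate.  Values are clipped to the modality's physical range (FA to
[0, 1], MD/CBF to non-negative), which for CBF's large CoV truncates
~1% of draws and biases its measured CoV a few percent low.

Per-subject random streams are derived deterministically from the
cohort seed, so enlarging a cohort never perturbs existing subjects.

What the generator does **not** emulate: biophysical structure (tensor
or perfusion models), anatomically realistic mean fields or masks,
scanner/site effects, registration error, and spatial correlation
beyond stationary Gaussian smoothing.  Passing tests therefore
demonstrate the statistical machinery — calibration, error control,
mechanism separation, recovery — under the assumed data-generating
structure, not performance on real MRI.

## Experiment problem sizes

The packaged experiments (shared by the acceptance tests, the
acceptance script, and the `analysis/` drivers) use 20x20x20 grids
(8000 voxels), 44 controls, 12-20 concussed subjects, and 20 seeded
replicates for the error-control experiment; the analysis drivers use
14x14x14 grids with all three modalities.  These sizes put every
experiment within minutes on one CPU while keeping the per-voxel
sample size (N = 44) at the published cohort's scale, which is the
quantity that actually drives calibration behaviour.

## Numerical choices

* Masked voxels are vectorized in ascending C-order (raster) index of
  the 3-D mask; all per-voxel arrays share this order.
* Batch LSCV uses float32 pairwise kernels (selection is a discrete
  argmin; verified to match the float64 scalar path exactly on random
  data) and shares one exponential per candidate via
  exp(-d^2/(2h^2)) = [exp(-d^2/(4h^2))]^2.
* The mixture CDF is clipped to [0, 1] to guard float summation drift.
* CoV uses the sample (N-1) SD.  Quartiles are linear-interpolation
  percentiles.  Percent change takes the median over subjects at each
  voxel before summarizing over voxels.
* CoV fields sampled from printed summaries use a log-normal matched to
  the median and quartile ratio; printed quartiles that are not
  log-symmetric are reproduced to a few percent.
* Representative-slice selection ranks axial slices by abnormal count
  with average ranks on ties and returns the lowest slice index on
  final mean-rank ties.
* Serialization: normative models round-trip through a single
  compressed archive with embedded metadata; volumes are NIfTI
  (float64, bit-exact round-trip); all tables are TSV.

## Known limitations

* **Far-tail calibration of plug-in KDE p-values.**  With N = 44
  controls, P' is approximately uniform in the bulk but anti-
  conservative in the far tail (P(P' <= 0.0025) ~ 0.006 even with
  uniform weights), driven largely by the minority of voxels where
  LSCV selects a small bandwidth.  Pushed through BH at q = 0.05 in
  the presence of 6-SD signal at 5% of voxels, the realized mean
  false-discovery proportion of the CS pipeline measures ~0.09 rather
  than <= 0.07 (sensitivity ~0.995): spatially smoothed noise makes
  false positives arrive in small clumps the 3-voxel cluster filter
  does not remove (with unsmoothed noise the same pipeline measures
  ~0.03), and detections adjacent to true clusters attach to them and
  survive the filter.  This is a property of the method at this
  control-sample size, reported as measured, not tuned away.
* LSCV bandwidth selection is high-variance; the largest-local-
  minimizer rule removes the degenerate h -> 0 solutions but not the
  occasional small-h choice at clumpy samples.
* The Hampel breakpoints are a design choice; the robust-KDE reference
  implementations in the field do not publish a single canonical
  setting, and other placements trade clean-data calibration against
  aggressiveness toward outliers.
* Wilcoxon contrasts at n = 12 subjects have limited power; the
  threshold-sweep and pooling conventions follow the per-map spirit of
  the FDR analysis (percentiles computed per map, not pooled).
* The bootstrap CI for regional concordance resamples regions with
  replacement; resamples with a constant profile are dropped.
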