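# Methods

## The threshold model

The segmentation method delineates a lesion as the set of voxels at or
above a percentage of its SUVmax, with the percentage predicted from
SUVmax itself:

    Th_opt(%) = A · ln(1/SUVmax) + B  =  A·X + B,   X = ln(1/SUVmax)

The logarithmic form captures two regimes in one line: at low uptake the
lesion barely exceeds background and only a high relative threshold
separates it; at high uptake the apparent boundary of a blurred lesion sits
near half of the (background-inflated) maximum, so the relative threshold
falls slowly towards ~40–50 %. Because `Th_opt` is linear in X, (A, B) are
fitted by ordinary least squares of gold-standard thresholds on X, with R²
and the residual SD (n−2 degrees of freedom) reported as diagnostics.

Constants are per lesion type — primary lung tumours sit in aerated lung
(low background), mediastinal nodes in blood-pool background — and are
deliberately *not* per scanner generation: the line-comparison test below
exists to verify that independence on a given dataset. The packaged
defaults (primaries A = 13.29, B = 74.24; nodes A = 18.71, B = 88.55) are
coarse two-point constructions through characteristic operating points of
per-radiotherapy NSCLC delineation — (SUVmax 6.2, 50 %) and (10.5, 43 %)
for primaries, (4.6, 60 %) and (5.4, 57 %) for nodes. They are starting
values, not fitted calibrations; `fit_threshold_model` replaces them
whenever (SUVmax, gold threshold) pairs are available. Predictions are
clipped to [1, 100] % because the line is unbounded in SUVmax.

SUVmax is the single hottest voxel in the VOI (no neighbourhood-averaged
SUVpeak), ties resolving to the lowest lexicographic index. Volumes are
assumed SUV-calibrated on input; activity-to-SUV conversion is explicitly
out of scope.

## Segmentation mechanics

All methods reduce to one primitive: inclusive thresholding (SUV ≥ t)
inside a half-open VOI, followed by keeping only the 26-connected
component containing the SUVmax voxel. Inclusiveness guarantees the
SUVmax voxel survives a 100 % relative threshold; the component filter
reflects that a single lesion is being delineated, so disconnected
physiological uptake inside the VOI cannot inflate the volume. Volume in
cc is plain voxel counting times voxel volume — no sub-voxel interpolation
of the isocontour.

Comparators:

- **Fixed SUV** (2 / 2.5 / 3 / 3.5) and **fixed %SUVmax** (40 / 50 / 60 / 70).
- **AOV**: absolute threshold at 1.5 × the mean SUV of a 1 cc aortic
  blood-pool sample, supplied by the caller.
- **COA**: absolute threshold `c1·m70 + c2·BG` where `m70` is the mean SUV
  inside the 70 %-of-SUVmax isocontour and BG the background mean.
- **ADT**: fixed-point iteration of the relative threshold,
  `T ← a0 + a1·(BG / contour mean)`, started at 40 %, stopped when
  successive thresholds differ by < `adt_tol` (default 0.005). The voxel
  lattice quantises the contour, so the map can enter a cycle with no
  fixed point in between; cycles are detected (repeated iterate) and the
  run is flagged non-convergent with the last iterate returned and a
  `ConvergenceWarning` raised — these flags propagate into study reports.

COA/ADT coefficient values are scanner-specific calibrations that must be
configured; the shipped defaults (COA 0.5/0.5, ADT 0.39/0.45) are
physically plausible placeholders so the code paths run, and are labelled
as such rather than presented as published calibrations.

## Gold-standard threshold search

The reference ("gold standard") contour for a lesion is the relative
threshold whose isocontour volume matches an expert target volume.
Segmented volume is a non-increasing step function of the threshold, so
the search is a boundary bisection: first locate the highest threshold
whose volume still reaches the target, then, if the plateau just below the
target is at least as close, a second bisection finds the top of that
plateau. Ties therefore resolve toward the higher threshold, matching an
exhaustive fine sweep's convention. Budget: 40 volume evaluations, volume
tolerance half a voxel. Targets above the volume achievable at the minimum
threshold raise an error naming the achievable range.

## Statistics

- **Line comparison** (old vs new scanners, or primaries vs nodes):
  sequential nested-OLS F-tests. Slopes first (separate-slopes vs
  common-slope model); if p < α (default 0.05) the lines differ and
  intercepts are not compared; otherwise intercepts (common-slope
  separate-intercepts vs single line). Assumes homoscedastic Gaussian
  residuals — exact under the simulation model, approximate on real data.
- **Method comparison**: the design is paired (every lesion scored by
  every method), so the omnibus is Friedman's test; with only two methods
  it degrades to a Wilcoxon signed-rank test. Pairwise tests are Wilcoxon
  signed-rank of the reference against each comparator with Bonferroni
  adjustment (raw p × number of comparisons, capped at 1). Identical
  paired vectors short-circuit to p = 1 rather than a degenerate rank
  test.
- **Dice**: the standard Sørensen–Dice `2|X∩Y|/(|X|+|Y|)`. Two empty
  masks score 1 (agreement on absence), one empty scores 0. Summaries use
  linear-interpolation quantiles (numpy's default), so R and Python
  implementations agree; the SD of a single value is defined as 0.
- **Agreement bands**: DSC is rounded to 2 decimals and then binned —
  ≤ 0.20 poor, ≤ 0.40 fair, ≤ 0.60 moderate, ≤ 0.80 good, ≤ 1.00 very
  good. Rounding first closes the printed gaps between band edges
  (0.204 → poor, 0.206 → fair).

A note on the intercept: B is the threshold at SUVmax = 1, which lies at
or beyond the edge of any realistic lesion population (X̄ ≈ −2), so
intercept estimates are extrapolations and their sampling error is several
times the slope's. Recovery of B to within a couple of percent-units needs
either large n or threshold scatter well below ~2 points; this is a
property of the model parameterisation, not of the fitting code.

## Phantoms

A phantom is an ellipsoid of uniform uptake in a uniform background on a
voxel lattice, convolved with an isotropic Gaussian PSF and degraded with
additive Gaussian noise (seeded, clipped at 0). The truth mask is the
*pre-blur* support: the "real" tumour, against which partial-volume
effects genuinely degrade every segmentation. This is the mechanism that
separates adaptive from fixed thresholds — the optimal relative threshold
of a blurred lesion rises as contrast and size fall, and only an adaptive
method can track it.

Defaults, chosen once as typical whole-body FDG PET values: 4 mm isotropic
voxels, PSF FWHM 6.5 mm, image noise SD 0.05 SUV, background 0.8 SUV for
lung lesions and 1.8 SUV for nodes (blood pool), giving nodes their
characteristically lower contrast. Lesions are centred on a voxel centre
so the hottest voxel samples the lesion centre; on 4 mm grids a
corner-centred lesion would under-read SUVmax by up to ~25 % for small
lesions. The pre-blur peak needed to realise a target SUVmax is obtained
in closed form from the centre amplitude of a blurred ball
(`erf(t/√2) − t·√(2/π)·e^(−t²/2)`, t = r/σ), so generated lesions hit
their target uptake to within ~15 % once their diameter exceeds ~3 FWHM.

Cohorts draw lesion type (default half primaries, half nodes), SUVmax and
volume from clipped lognormal distributions (primaries: SUVmax median 6.5
on [2.5, 36.5], volume median 8 cc on [0.26, 140]; nodes: median 4.6 on
[2.4, 9.3], median 2 cc on [0.26, 25]) matching the observed
per-radiotherapy NSCLC population; a uniform SUVmax option exists for
designed calibration experiments. Each lesion's gold-standard threshold is
drawn from the generating (A, B) line plus Gaussian scatter (default SD
3 percent-units; optionally relative, as a fraction of the threshold),
clipped to (0, 100] — emulating expert thresholds that follow the model
with biological and reader scatter. Study evaluation scores methods
against the gold-standard isocontour mask, mirroring how expert
threshold-matched contours serve as the reference in practice; the
pre-blur truth mask remains available for physics-level checks.

What the phantoms do **not** emulate: Poisson counting noise and
reconstruction texture, non-uniform uptake and necrosis, irregular lesion
shapes, respiratory motion, and neighbouring avid structures. Passing the
synthetic experiments therefore demonstrates correctness of the machinery
and the structural advantage of adaptive thresholding under partial-volume
blur — not clinical performance on patient images.

## Study driver and problem sizes

`run_study` simulates a cohort (default 60 lesions on per-lesion grids of
roughly 24–40³ voxels), optionally refits (A, B) per lesion type on the
cohort's own gold thresholds (the default, mirroring how the method is
calibrated in practice), segments with all twelve methods, and evaluates.
Per-lesion failures are logged and skipped; non-converged ADT runs carry a
`converged=False` flag into the output tables. All outputs are plain
CSV/JSON, carry seed and package version per row, and are byte-identical
across reruns of the same configuration. These cohort sizes keep a full
study under a few seconds while leaving every statistic well-determined;
larger cohorts are a matter of `n_lesions`.

## Known limitations

- Uniform-uptake spheres are the easiest case for threshold methods; DSC
  values on phantoms are optimistic relative to patient data.
- Voxel counting without partial-volume interpolation biases small-lesion
  volumes; below ~8 voxels the discretisation error dominates.
- The placeholder COA/ADT coefficients make those comparators plausible
  but not faithful to any specific scanner calibration.
- The F-tests and the Gaussian threshold-scatter model are exact only
  under the simulation's assumptions.
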