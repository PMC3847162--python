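# Methods

## The null model and its oracle

The simulator (`popsim`) implements selection on a heritable growth-rate
phenotype in an asexual population. Founder *i* draws a rate
*rᵢ* ~ N(μ₀, (cv·μ₀)²) once; every descendant inherits it unchanged
("stable" mode). Between protocol events lineage sizes evolve as exact
exponentials, nᵢ(t) = nᵢ(0)·e^{rᵢt}, so for the protocol-free case the
only randomness is the founder draw. This hybrid representation — expected
lineage sizes, with stochasticity confined to dilution sampling and
switching events — reaches chemostat scales (10⁹–10¹⁰ cells) without
per-cell bookkeeping. A per-cell agent mode (1 + Poisson(e^{rΔ}−1)
offspring per step, matching the exponential expectation; survival
probability e^{rΔ} for negative rates) exists for cross-validation at
N ≲ 10⁴, and the two modes are required by the test suite to agree within
replicate standard error.

Exponential reweighting of a Gaussian is again Gaussian (complete the
square): weighting N(μ₀, σ₀²) by e^{rt} gives N(μ₀+σ₀²t, σ₀²). Hence the
population-mean rate grows **linearly** at slope σ₀² with unchanged SD —
the Gaussian specialization of Fisher's fundamental theorem,
d⟨r⟩/dt = Var(r). `closed_form_gaussian_mean` exposes this law; a
quadrature of ∫r·e^{rt}φ(r)dr/∫e^{rt}φ(r)dr verifies it independently in
the tests, and the `deterministic` simulator mode evaluates trajectories
from it directly. The closed form holds for the continuum; a finite
founder sample saturates once σ₀²t approaches the sample maximum, so
oracle-equivalence tests stay at σ₀t ≤ 0.6 where the finite-sample
deviation is within replicate noise at 1000 founders.

Generations are counted as log₂ of the cumulative *gross* growth factor
(dilution losses excluded); chemostat runs additionally report
t·D/ln 2. With 1000 founders at cv = 0.3 the mean rate gains ≈ 27–30%
(seed-dependent) by five doublings — the monotone takeover benchmark.
Takeover is operationalized as the first (interpolated) checkpoint at
which descendants of the fastest `top_fraction` founders exceed half the
population; it is finite for any cv > 0 and decreases with cv.

"Switching" mode breaks stable inheritance: cells re-draw their rate at
exponentially distributed waiting times (rate `switch_rate`), by default
from the founder distribution, which pins the mean near μ₀ and lets it
plateau and decrease — the qualitative signature stable inheritance
cannot produce. In the lineage representation switching uses
tau-leaping: Poisson event counts per class per step, with at most
`max_new_classes_per_step` (default 200) new rate classes created per
step and switchers distributed evenly among them. This approximates the
per-cell process at high switching flux; the agent mode applies the
per-cell redraw exactly and is the reference at small N. An
Ornstein–Uhlenbeck drift of class rates is available (`redraw="ou"`) as a
clearly-labelled extension beyond the null model.

Serial dilution draws a uniform factor from `dilution_range` (default
1:10–1:50 every 12 h) and samples survivors multinomially over lineages,
leaving expected lineage frequencies unchanged; a transfer below
`min_transfer` (default 10⁵ cells) aborts the run with
`protocol_violation` status rather than silently bottlenecking.

## The microcolony pipeline

`growthfit` mirrors a time-lapse assay in which wells are imaged hourly
for 12–24 h and each microcolony's pixel area is fitted to
y = A·exp(B·x); B (1/hour) is the instantaneous growth rate.

*Segmentation* ("filtered raw images" left unspecified upstream) defaults
to Gaussian smoothing (σ = 1 px), Otsu threshold, connected components,
minimum area 20 px and a minimum foreground/background contrast of 10
intensity units — the contrast floor stops Otsu from shattering blank
noisy frames. The backend is deliberately thin and pluggable; the
pipeline equally accepts pre-extracted area tables, since everything of
scientific interest happens downstream of areas.

*Tracking* is greedy nearest-centroid matching under a maximum
displacement of one mean colony radius per frame (default from the first
populated frame); exactly equidistant candidates are resolved by smallest
area difference and logged. An active track whose nearest region was
claimed by another track is deemed merged into it and both carry the
`merged` flag; tracks coming within `edge_margin` (10 px) of the field
border are `edge_proximal`; unmatched tracks are `lost`.

*Fitting* is two-parameter least squares on the **area scale** (matching
the reported model form), initialized by log-OLS; `method="log"` keeps
the log-OLS estimate instead. Rsq = 1 − SS_res/SS_tot is always computed
on the area scale. Constant-area tracks (SS_tot = 0) are `non_growing`
with B = 0 and undefined Rsq. Because B is meant to be an *instantaneous*
rate, fits longer than ~3 doublings of the fitted rate are windowed from
the start and refitted (up to three iterations).

*Gating* is a pure function of (Rsq, flags): flagged tracks are
`rejected_exclusion` regardless of fit quality; Rsq strictly greater than
0.95 accepts; the boundary rejects.

*Automated review.* A hard Rsq > 0.95 gate at realistic noise is biased:
with 5% multiplicative area noise and 13 hourly frames, a colony growing
2.7-fold sits near Rsq ≈ 0.97 but one growing 1.9-fold sits near the
gate, so strict auto-rejection truncates the slow tail and shrinks both
the mean and the CV of the accepted rates (measurably: CV ≈ 0.24
recovered from a CV = 0.30 fixture). Assays of this kind therefore
re-examine sub-gate fits by eye for "exponential growth despite
outliers". `review_rejected` automates that judgement reproducibly: a
rejected track is rescued iff its log-area regression has (i) a slope
significantly positive, (ii) no significant quadratic curvature, and
(iii) no significant lag-1 residual autocorrelation, all at α = 0.01.
Noisy exponentials pass (restoring unbiased recovery); constant tracks
fail (i); saturating or otherwise non-exponential tracks fail (ii)/(iii).
Rescued fits get the distinct status `accepted_review` — so `accepted`
still guarantees Rsq > 0.95 — and every review decision is written to a
queue file for audit. Review can be disabled (`review=False`) to obtain
the strict-gate behaviour.

*Summary.* The accepted-rate histogram carries per-bin bootstrap SDs
(200 resamples); the mean is reported with SEM = SD/√n and the CV with
its bootstrap SE. Samples under 100 accepted colonies warn rather than
fail. A subsample-convergence diagnostic averages the mean of 20 random
subsets at each of several sizes and checks the half-sample value agrees
with the full mean within one SEM. `fraction_exponential` is
accepted / (accepted + non_growing + rejected_rsq), with positional
exclusions removed from the denominator.

Known estimator property: with multiplicative noise the fitted-rate
spread adds the per-track fit error in quadrature,
E[ĉv²] ≈ cv² + (SE_B/μ)², so the measured CV sits slightly above the
generating value (≈ +0.005 at the wild-type fixture settings). The
area-scale fit effectively upweights late frames, which makes SE_B
somewhat larger than the log-OLS value.

## Scaling analyses

`standardize` subtracts the mean and divides by the population SD
(ddof = 0), so output moments are exactly (0, 1); it is idempotent and
affine-invariant, and degenerate (zero-SD) inputs raise. Collapse is
quantified by pairwise two-sample Kolmogorov–Smirnov statistics between
standardized snapshots (distribution-free null; Cramér–von Mises
selectable), summarized by the maximum pairwise distance.
`fit_variance_mean` is unweighted OLS of variance on (1, μ, μ²) — exact
on exact quadratic input — with an optional linear-only constraint for
model comparison; rank-deficient designs raise. `windowed_cv` reports
σ/μ over non-overlapping complete windows of positive series.
`autocorrelation_time` returns the linearly interpolated first lag at
which the autocorrelation of the mean-removed series falls below 1/e
(≥ 50 uniform samples required), optionally also in generations.

## Plating statistics

`fraction_adapted` divides the mean selective-plate colony count by the
mean rich-plate count. Counts are modelled Poisson, so each plate-type
mean has relative variance 1/(n_plates·mean) and the ratio's relative SE
adds the two in quadrature. The estimator is intentionally unclipped:
independent sampling of the two plate types can push it above 1. It is
scale-invariant in the counts and unbiased for
frac_adapted × (selective/rich plating efficiency), which the tests check
over 1000 replicate plate draws.

## Synthetic data: what it emulates, and what it does not

Defaults encode the measured study conditions: growing-cell rates
Gaussian with σ/μ = 0.3 (adapted rewired phase) or 0.1 (wild type); mean
division time 8.4 h for the adapted fixture; hourly frames for 12 h
(13 points); single-cell area 45 px; 5% multiplicative log-normal area
noise (measurement error scales with colony size); designated
non-growers at exactly zero rate; Gaussian draws ≤ 0 reclassified as
non-growers rather than resampled, preserving the Gaussian growing tail.
The wild-type fixture uses a 4 h division time so the hourly 12 h movie
spans the full ~3-generation instantaneous-rate window — the same
duration-matching logic as the assay itself — keeping the fit-noise
inflation of the measured CV below sampling error. Fluorescence snapshot
families rescale one fixed standardized base shape (a standardized
log-normal, shape parameter 0.6 — right-skewed like measured
distributions, with no analytic form implied) to requested means and to
variances on a quadratic law, with sample moments pinned exactly;
`exact_family=True` shares base draws across snapshots for bitwise
collapse, while the default draws fresh samples so two-sample distances
sit at the KS sampling floor. Image fixtures render colonies as filled
disks with additive Gaussian pixel noise on a uniform background.

Not emulated: real colony morphology and bright-field optics (halos,
focus drift), cell debris, colony motion, segmentation over- and
under-splitting, day-scale drifts of illumination, and any real temporal
autocorrelation of growth within lineages. Passing tests therefore
demonstrate correctness of the estimators and their statistical
calibration on the stated noise model — not robustness to every
real-microscopy artefact; the pluggable segmentation backend and the
area-table entry point are the intended path for real data.

Problem sizes in the test and acceptance runs (300–1000 colonies,
500–10⁴ founders, 20 replicate seeds, 40 000-cell snapshots) are the
package's chosen desk-scale defaults; all estimators are O(n) or O(n log n)
and scale to larger inputs unchanged.

## Numerical choices and degenerate inputs

- Rasterized disks quantize area (a radius-10 disk covers 305 px vs
  π·100 ≈ 314), so the image path recovers rates to ~1%, while the
  table path is exact to solver tolerance; tests assert each at its own
  level.
- All randomness flows from a single integer seed through named CRC32
  sub-streams (`phenodyn._random.substream`); generators are pure
  functions of (config, seed) and byte-identical on repeat.
- JSON outputs are written with sorted keys and no timestamps so reruns
  are byte-identical; CSV floats are written/parsed in round-trip
  precision.
- Degenerate inputs raise typed errors: zero-SD standardization,
  zero-denominator plate ratios, rank-deficient variance–mean designs,
  constant series autocorrelation, sub-minimum dilution transfers,
  invalid configurations.

## Limitations

- The review stage's α = 0.01 trades a ~0.5% false rejection of genuine
  exponentials against a ~1% false acceptance of noisy non-growers; both
  are below the binomial noise of the fixtures but matter at much larger
  sample sizes.
- The lineage-mode switching approximation caps new rate classes per
  step; at extreme switching rates use agent mode.
- The tracker is greedy and single-hypothesis; it flags rather than
  resolves merges, and does not re-identify lost colonies.
- Agent mode matches the lineage representation in expectation but not
  in offspring-number variance (Poisson vs Yule), which is invisible to
  mean-trajectory comparisons but would matter for fixation-probability
  questions the package does not address.
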