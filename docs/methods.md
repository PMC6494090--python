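# Methods

This note records the models, conventions and numerical choices behind
`macula`, in the order the pipeline runs them.

## Lateral scale correction

Fixed-optics SD-OCT devices assume one axial length (24.46 mm for the
Cirrus HD-OCT) when mapping scan angle to millimetres. The correction is
the linear ratio `actual_extent = nominal · AL / 24.46`; thickness is an
axial quantity and is left untouched, so the correction rescales only
the pixel pitch (`apply_scale`). Both constants are parameters with
device defaults. The correction composes multiplicatively, which the
tests assert. Axial lengths outside [15, 35] mm are rejected as unit
mistakes rather than extrapolated.

## Fovea localisation

The device's onboard fovea finder is proprietary; `locate_fovea` uses a
transparent re-specification: Gaussian-smooth the map (FWHM 0.25 mm, a
scale that suppresses pixel noise without displacing a ~2 mm-wide pit),
take the discrete minimum within the central half of the field (the
fovea is always near fixation in a macular cube), and refine to
sub-pixel accuracy with a separable 3-point quadratic fit. A flat
smoothed field, or a minimum on the search boundary, is an error rather
than a guess. On noiseless synthetic eyes the detection error is well
under 0.02 mm.

## ETDRS sectorisation

Diameters are the standard 1 / 3 / 6 mm. Pixels are assigned by the
physical distance of their centre from the fovea with half-open ring
intervals (centre d ≤ 0.5, inner 0.5 < d ≤ 1.5, outer 1.5 < d ≤ 3.0 mm)
and half-open diagonal quadrant boundaries ([45°, 135°) superior, etc.,
with row 0 = superior; both conventions are documented because devices
are silent about ties). For OD the nasal quadrant defaults to the left
column side (`od_nasal_side`), mirrored for OS, so a column flip plus
laterality swap is an exact identity — asserted in the tests.

Pixel-centre assignment (not area weighting) keeps sector membership
exact and bit-reproducible; at ≥ 128×128 the discretisation error of a
sector mean is below 1 µm, which the 256×256 quadrature-oracle test
bounds directly. Short eyes necessarily truncate the corrected 6 mm
ring; truncated sectors are averaged over available pixels and each
sector's `coverage` (sampled pixel area / geometric sector area) is
reported, with a warning below 0.25 and NaN for empty sectors. How the
original device handles sub-6 mm corrected scans is not documented
anywhere we know of; coverage reporting makes our choice explicit.

## Difference-of-Gaussians pit model

The radial profile is built by binning pixels by distance from the
fovea (default bin width = pixel pitch). Each bin's abscissa is the
*mean radius of its pixels* rather than the geometric bin centre — this
removes the leading-order bias of annulus averaging and is why noiseless
parameter recovery reaches 10⁻³ relative error at 128×128.

The DoG model `t(r) = base + a₁·e^(−r²/2s₁²) − a₂·e^(−r²/2s₂²)` is
fitted by count-weighted bounded least squares (trust-region reflective)
over (base, a₁, s₁, a₂, s₂) with a₁, a₂ ≥ 0 and 0.05 ≤ widths ≤ 3 mm.
The width ordering s₂ ≤ s₁ is enforced by a soft penalty residual
(weight 10³), which handles the degenerate flat-profile case gracefully
(both amplitudes cancel at equal widths) without the sign pathologies of
post-hoc Gaussian swapping. Eight multi-starts are derived from the
data (baseline = outer 20% mean, pit amplitude = rim − centre) with
seeded jitter; the best converged residual wins, so fits are
deterministic given (profile, seed).

Metrics are read off the fitted curve in mm units (µm/1000):
rim radius r\* = interior argmax on (0, 3] mm by a 3001-point grid plus
bounded scalar refinement; depth = f(r\*) − f(0); diameter = 2r\*;
slope = max of arctan f′ on (0, r\*) in degrees using the analytic
derivative (the *maximum* wall slope — some authors report a mean slope;
ours is labelled); volume = ∫₀^{r\*} (f(r\*) − f(r))·2πr dr by adaptive
quadrature. Profiles with no interior maximum (a₂ ≈ 0) return all-zero
metrics flagged `no_pit`. Every metric is validated against an
independent dense-grid (10⁻⁴ mm) brute-force oracle to four significant
figures.

## Interocular statistics

Bland-Altman differences are fixed as OD − OS. Limits of agreement are
bias ± 1.96·SD (sample SD, n−1); the bias CI is `t₀.₉₇₅,ₙ₋₁·SD/√n` and
each LOA's CI the classical large-sample `t·SD·√(3/n)`. Normality is
screened with the D'Agostino-Pearson K² omnibus test (n ≥ 20 required;
non-normal metrics proceed with a logged warning rather than a hard
stop). Group comparisons use the pooled-variance two-sample t-test with
df = n₁ + n₂ − 2.

## Logistic disease models

`LogisticModel.fit()` is a Newton-Raphson / IRLS maximum-likelihood fit:
convergence when the largest coefficient update < 10⁻⁸ (≤ 100
iterations), standard errors from the inverse observed information.
Quasi-complete separation is flagged when any standardised coefficient
exceeds 15; such fits carry `converged=False` and refuse odds-ratio
computation. Rank-deficient designs fail fast, naming the collinear
columns. The implementation is cross-checked against an independent
reference fit in the test suite, and against the 2×2 contingency closed
form `β = ln(ad/bc)`.

Forward selection starts from the forced covariates (or intercept
only), adds the AIC-minimising candidate each step, and stops when no
addition lowers AIC; ties break deterministically by name order, and
candidates whose fit errors are skipped with a note. The analysis unit
is one row per eye carrying the subject's outcome, but LOOCV always
leaves out whole subjects so correlated fellow eyes cannot leak across
folds (a subject-level averaging mode is a straightforward aggregation
of the design table). By default the selected predictor set is held
fixed across folds and only coefficients are re-estimated;
`reselect_per_fold=True` re-runs the selection inside every fold for a
stricter (and noisier) protocol. The C-statistic is the trapezoidal
area under the threshold-sweep ROC, identical to the concordant-pair
fraction with ties counted ½ (asserted against exhaustive pair counting
over 1,000 random instances). The optional CI for the cross-validated C
is a seeded cluster bootstrap over subjects (default 2,000 resamples)
on the pooled out-of-fold predictions. The interaction screen refits
the base model plus one product term per pair and reports the term's
Wald p without multiplicity correction — a screening convention, so
small p-values are hypotheses, not discoveries.

## Synthetic cohort generator

The generator defines the study conditions for all tests: 33 PD + 40
control subjects, paired eyes, axial lengths from a normal(23.9, 1.2)
truncated to [21, 28] mm (the observed clinical range rounded outward),
female fractions 0.39 (PD) / 0.70 (HC) matching the cohort composition,
and 2 µm i.i.d. pixel noise. Pit parameters are drawn per subject from
a population whose means (base 276 µm, a₁ 48 µm, s₁ 0.92 mm, a₂ 138 µm,
s₂ 0.37 mm) were chosen once, by forward computation, so that a typical
eye's metrics (depth 0.113 mm, diameter 1.94 mm, slope 11.7°, volume
0.074 mm³) sit inside published adult ranges; the tests treat those
ranges only as a sanity envelope.

Realism choices that matter:

* **Mis-scaled metadata.** Eyes are sampled on the true physical grid
  (extent 6·AL/24.46 mm) while the sidecar records 6.0 mm, reproducing
  the device error the scale correction undoes; tests assert the
  corrected pitch equals the true sampling pitch to machine precision.
* **Correlated, mirrored fellow eyes.** OS parameters are OD parameters
  plus N(0, `interocular_sd_um`) jitter, and the fovea decentration is
  drawn per subject and mirrored across the vertical midline, so with
  zero jitter and noise the fellow eyes are exact mirror images and all
  interocular metric differences vanish — the degenerate case the
  Bland-Altman identities require.
* **Regional anatomical variability.** Each subject receives
  idiosyncratic per-sector thickness offsets (`regional_sd_um`, default
  4 µm) shared by both eyes. Without them, sector *contrasts* would be
  deterministic functions of the planted offsets and any group effect
  would be linearly separable — an artefact no real cohort shows.
* **Planted effects.** Disease effects are additive per-sector offsets
  (default −5 µm uniform; no effect sizes are published for this
  contrast, so defaults are configurable rather than calibrated) and a
  −8 µm female offset on the baseline, consistent with reports that
  female retinas are thinner.

What the generator does **not** emulate: speckle, segmentation
failures, motion artefacts, layer-resolved anatomy, or asymmetric pit
shapes. Passing tests therefore demonstrate correctness of the
measurement and modelling chain under the stated forward model, not
robustness to device artefacts.

## Problem sizes used in the test suite

Grids default to 128×128 (256×256 for the quadrature oracle), the DoG
recovery suite uses 50 noiseless + 50 noisy eyes, the ROC oracle 1,000
random instances, and the end-to-end selection study nine seeded
73-subject cohorts with majority voting; these sizes make the whole
suite run in a few minutes on one core while leaving the statistical
assertions comfortably powered.
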