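# macula

Axial-length-corrected macular OCT structure analysis: ETDRS thickness
grids, foveal pit morphometry, interocular agreement, and logistic
disease models with leave-one-subject-out validation.

## The problem

Spectral-domain OCT devices convert scan angles to lateral millimetres
assuming a fixed eye size, so the nominal 6 mm macular cube actually
covers `6 · AL / 24.46` mm in an eye of axial length `AL` (24.46 mm is
the Cirrus HD-OCT's assumed axial length). Across a realistic cohort
(AL ≈ 21–28 mm) the true extent ranges from about 5.25 to 6.84 mm, which
shifts every distance-based measurement — ETDRS sector boundaries, pit
diameter, pit volume. `macula` implements the corrected analysis chain
used to evaluate retinal structure as a candidate biomarker for
Parkinson's disease (PD):

1. **Scale correction** — pixel pitch is rescaled by `AL / 24.46`;
   thickness values (axial measurements) are untouched.
2. **ETDRS grids** — the fovea is localised as the minimum of the
   smoothed map, and mean thickness is computed over the standard nine
   sectors (1 mm centre disc, 1–3 mm and 3–6 mm rings split into
   superior / inferior / nasal / temporal quadrants, nasal–temporal
   mirrored between OD and OS).
3. **Foveal pit morphometry** — the radial profile is fitted with a
   difference of Gaussians, `t(r) = base + a₁·e^(−r²/2s₁²) −
   a₂·e^(−r²/2s₂²)`, and pit depth, diameter, maximum wall slope and
   volume are derived from the fitted curve.
4. **Interocular symmetry** — Bland-Altman bias and 95% limits of
   agreement of OD − OS metric differences, with D'Agostino-Pearson
   normality screening and pooled t-tests for group comparisons.
5. **Disease models** — logistic regression of PD status on sector
   means, foveal metrics and sex (coded 1 = female), with forward AIC
   selection, Wald odds ratios, a two-way interaction screen, and ROC /
   C-statistic both apparent and leave-one-*subject*-out cross-validated
   (both eyes of a subject always stay on the same side of a fold).

Because clinical OCT cohorts of this kind are not publicly deposited,
the package ships a synthetic-cohort generator (`macula.simulate`) that
reproduces the study design — paired eyes, truncated-normal axial
lengths, deliberately mis-scaled scan metadata, correlated fellow eyes,
planted group and sex effects — so every stage is testable against known
ground truth.

## Worked example

```bash
macula simulate --out demo --seed 7            # 33 PD + 40 HC subjects, 146 eyes
macula fovea    --cohort demo/cohort.csv --maps demo/maps --out fovea.csv
macula symmetry --metrics fovea.csv --out symmetry.csv
macula model    --cohort demo/cohort.csv --maps demo/maps --out model_out
```

The `model` step prints the selected logistic model and its validation:

```
term                    coef        se         p
intercept            19.7971    5.4819    0.0003
sex_female           -2.4760    0.5188    0.0000
outer_superior       -0.1527    0.0482    0.0015
inner_nasal           0.0998    0.0419    0.0172
outer_temporal       -0.1002    0.0485    0.0389
outer_nasal           0.0797    0.0464    0.0861
C (apparent) = 0.823, C (LOOCV) = 0.747
```

Sex enters with a strongly negative coefficient (females are simulated
with thinner retinas and are over-represented among controls, so female
sex predicts lower PD odds here), thinner outer-temporal/outer-superior
retina raises PD odds, and the cross-validated C-statistic of ≈ 0.75
shows the apparent discrimination survives subject-level validation.
`symmetry.csv` summarises interocular agreement; for pit depth the bias
is −8.4 × 10⁻⁵ mm with limits of agreement of ± 0.0045 mm — fellow eyes
are highly symmetric, as expected from correlated anatomy.

The same analyses are available as a library:

```python
from macula import (SimConfig, generate_cohort, eye_table,
                    forward_select, loocv_roc, actual_scan_length)

actual_scan_length(21.40)          # 5.249... mm true extent of a "6 mm" scan
cohort, truth = generate_cohort(SimConfig(seed=7))
table = eye_table(cohort, fit_pit=False)
fit, trace = forward_select(table, candidates=[c for c in table
                            if c.startswith(("center", "inner", "outer"))],
                            forced=["sex_female"])
print(fit.summary())
roc = loocv_roc(table, list(fit.params.index[1:]))
```

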