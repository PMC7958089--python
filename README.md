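# bscore

Shape-based scoring of knee osteoarthritis (OA) severity from corresponded
3D femur bone surfaces, with repeatability analysis and logistic
clinical-risk modelling.

Radiographic OA staging with the Kellgren–Lawrence grade (KLG, 0–4) is
coarse and ordinal: knees sharing a grade differ widely in structural
severity, and the grade itself is read with only moderate reliability.
This package implements a continuous alternative for researchers working
with statistical shape models of the femur: the **B-score**, a scalar
measure of how far a knee's bone shape has travelled along the population
direction of OA change.

## The method

Every femur surface is a corresponded point set (vertex *i* is the same
anatomical location on every knee), flattened to a vector
$\mathbf{x} \in \mathbb{R}^{3m}$ after mirroring left knees to the
right-knee convention and rigid generalized Procrustes alignment (no
scaling — OA shape change includes real size increase).

From a non-OA reference group and an OA group (selected by KLG), per sex:

$$b(\mathbf{x}) \;=\; \frac{(\mathbf{x}-\bar{\mathbf{x}}_{\text{non-OA}})\cdot \hat{\mathbf{d}}}{\sigma},
\qquad
\hat{\mathbf{d}} = \frac{\bar{\mathbf{x}}_{\text{OA}}-\bar{\mathbf{x}}_{\text{non-OA}}}{\lVert\bar{\mathbf{x}}_{\text{OA}}-\bar{\mathbf{x}}_{\text{non-OA}}\rVert}$$

where $\sigma$ is the sample SD of the non-OA group's own projections onto
$\hat{\mathbf{d}}$ (the **OA vector**). By construction the non-OA mean
shape scores 0, the defining non-OA sample has B-score SD exactly 1, and
its central 95% reference range is ±1.96. Around this core the package
provides:

- **Repeatability** — Bland–Altman limits of agreement on repeat-scan
  B-score pairs; the smallest detectable difference (SDD) is
  $1.96\,\mathrm{SD}(d_i)$, and dividing the working score range by the
  SDD gives the number of measurement-distinguishable grades.
- **Clinical risk** — logistic regression of pain (NRS ≥ 4 moderate / ≥ 8
  severe), WOMAC function (≥ 20 / ≥ 35) and total knee replacement against
  B-score or KLG; risk curves with delta-method CIs, within-KLG B-score
  quartile odds ratios, nested-model AUC comparison and covariate
  adjustment. All thresholds are overridable for sensitivity analysis.
- **Synthetic cohorts** — a fully seeded generator of condyle-like
  corresponded surfaces whose deformation grows with a latent severity
  (concentrated on a cartilage-plate "rim" band), with per-sex offsets,
  individual variation, scan noise, KLG as a noisy discretisation of
  severity and outcomes drawn from logistic models of severity — so the
  entire pipeline runs and is tested without any imaging data.

The core classes follow scikit-learn conventions (`fit` / `transform`,
fitted attributes with trailing underscores): `GeneralizedProcrustes`,
`ShapePCA` and `BScoreModel` compose with sklearn pipelines; module-level
functions (`build_oa_vector`, `compute_bscore`, `bland_altman_sdd`, ...)
are thin wrappers.

## Worked example

```python
import numpy as np
from bscore import (SimulationConfig, generate_cohort, build_oa_vector,
                    mirror_to_reference_side, nonoa_limits, OutcomeSpec,
                    fit_logistic, risk_curve, outcome_vector,
                    bland_altman_sdd, distinguishable_grades)
from bscore.simulate import oa_group_labels, simulate_score_pairs

cohort = generate_cohort(SimulationConfig(n_subjects=250, seed=1))
labels = oa_group_labels(cohort.records)          # KLG 0 vs KLG >= 2
shapes = [mirror_to_reference_side(s) for s in cohort.shapes]
nonoa = [s for s in shapes if labels.get(s.shape_id) == 0]
oa = [s for s in shapes if labels.get(s.shape_id) == 1]

model = build_oa_vector(nonoa, oa)                # per-sex OA vectors
scores = dict(zip([s.shape_id for s in shapes], model.transform(shapes)))

spec = OutcomeSpec(scale="nrs_pain", severity="moderate", timing="current")
idx, y = outcome_vector(cohort.records, spec)
x = np.array([scores[cohort.records[i].knee_id] for i in idx])
fit = fit_logistic(y, x.reshape(-1, 1), names=["bscore"])
print(risk_curve(fit, np.array([0.0, 2.0, 6.0])))

pairs = simulate_score_pairs(10_000, error_sd=0.0906, seed=41)
rep = bland_altman_sdd(pairs)
print(rep.sdd, distinguishable_grades(-3, 7, rep.sdd))
```

Output (trimmed):

```
cohort: 500 knees; 96 non-OA, 280 OA
non-OA female B-scores: mean 1.60e-15, SD 1.000000
non-OA 95% range: (-1.96, 1.96)
risk(moderate pain | B=0) = 13.6% (9.9 to 18.5)
risk(moderate pain | B=2) = 21.8% (18.0 to 26.1)
risk(moderate pain | B=6) = 46.5% (38.9 to 54.3)
SDD = 0.252 B-score units -> 40 distinguishable grades over (-3, 7)
```

The non-OA group scores mean 0 / SD 1 by construction; risk of a
moderately painful knee rises smoothly and roughly threefold across the
B-score range; and a per-measurement error SD of 0.0906 B-score units
yields an SDD of ≈ 0.25 ($1.96\sqrt{2}\,\sigma_e$), i.e. 40
distinguishable grades over a working range of −3 to +7 — a far finer
scale than the five KLG grades.

## Command line

```sh
bscore simulate --seed 42 --n-subjects 250 --out-dir cohort/
bscore build-vector --shapes 'cohort/shapes/*.ply' --clinical cohort/clinical.csv --out model.json
bscore score --model model.json --shapes 'cohort/shapes/*.ply' --out bscores.csv
bscore risk --clinical cohort/clinical.csv --bscores bscores.csv \
       --outcome pain:moderate:current --out curve.csv
bscore quartiles --clinical cohort/clinical.csv --bscores bscores.csv \
       --outcome tkr --out quartiles.csv
bscore heatmap --model model.json --topology cohort/topology.csv --b 2 --out heatmap.csv
```

## Layout

- `src/bscore/shapes.py` — corresponded shapes, mirroring, Procrustes, PCA
- `src/bscore/oa_vector.py` — OA vector, B-score, area-change maps
- `src/bscore/repeatability.py` — Bland–Altman SDD, distinguishable grades
- `src/bscore/outcomes.py` — outcome definitions, logistic risk modelling
- `src/bscore/simulate.py` — synthetic cohort generator
- `src/bscore/io.py`, `src/bscore/cli.py` — formats and command line
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
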