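# ctrsa

Simulation and analysis of radiostereometric implant-migration studies
in total hip arthroplasty (THA).

After a THA, the femoral stem and acetabular cup may migrate slightly
within the host bone during the first months; continuous migration
predicts later loosening. Radiostereometric analysis (RSA) and its
CT-based successor (CT-RSA) measure this micromotion — tenths of a
millimetre and fractions of a degree — by rigidly registering the bone
(tantalum beads or a bone segmentation) between a baseline and a
follow-up examination and expressing the implant's relative pose change
in six degrees of freedom. `ctrsa` is a desk-scale, fully testable
implementation of that measurement chain plus the statistics such a
follow-up study reports, driven by a synthetic-scene generator with
known ground truth. It is aimed at people developing or validating
migration-measurement pipelines and at anyone who wants the study
statistics reproducible from code.

## What it computes

**Measurement.** Migration of a rigid body between examinations:

- least-squares rigid superposition (Kabsch) of labelled marker sets,
  with the standard RSA quality gates — condition number of the marker
  configuration (< 120) and mean error of rigid-body fitting
  (< 0.35 mm);
- ICP fitting of an implant surface model (a CAD-model stand-in) to the
  observed implant cloud, seeded from named landmarks;
- decomposition of the relative implant motion, in an implant-based
  frame for the stem (y along the stem axis, x in the stem/neck plane)
  and the scanner-table frame for the cup, into translations Tx, Ty, Tz
  (medial, superior, anterior positive) and Cardan rotations
  Rx, Ry, Rz, with Euclidean totals
  `Ttot = sqrt(Tx^2 + Ty^2 + Tz^2)` (likewise Rtot) and left hips
  mirrored to right-hip sign convention.

**Statistics.**

- double-examination precision: `SD(differences) x t_crit` (two-sided,
  5%, df = n−1 by default);
- Bland–Altman limits of agreement `bias ± 1.96 SD` between two
  measurement methods, plus model-based least-square means per
  timepoint;
- piecewise linear mixed-effects migration curves
  `y = b0 + b1*t + b2*max(0, t−3) + u_subject + e` with a breakpoint at
  3 months (REML);
- planned-vs-used implant size concordance with exact
  (Clopper–Pearson) binomial confidence intervals.

**Simulation.** `StudyConfig`/`generate_study` build complete virtual
studies: 9–10 bone markers per segment, parametric stem/cup models,
piecewise-linear per-subject migration truths, two methods with
different per-DOF noise, double examinations with repositioning, left
and right hips, and a plan table — serialized as CSV/PLY/JSON/YAML.

## Worked example

```python
from ctrsa import (StudyConfig, generate_study, analyze_study, double_exam_diffs,
                   precision_table, fit_piecewise_lme, plan_vs_actual, bland_altman)

cfg = StudyConfig(seed=1)                      # 26 subjects, 0/3/12/24 months
exams, truths, plan = generate_study(cfg)
table = analyze_study(exams)                   # tidy 6-DOF migration table

dbl = table[table.timepoint_months == cfg.double_exam_timepoint]
for method in ("ctrsa", "mbrsa"):
    rows = {(r.segment, r.dof): r for r in
            precision_table(double_exam_diffs(dbl[dbl.method == method]))}
    p = rows[("stem", "Ty")]
    print(f"{method} stem Ty precision: {p.precision:.2f} mm (SD {p.sd_diff:.2f}, n={p.n_pairs})")

fit = fit_piecewise_lme(table[(table.method == "ctrsa") & (table.segment == "stem")], "Ty")
print(f"stem Ty slope 0-3 mo: {fit.beta1:.4f} mm/mo (p={fit.p_early:.2g})")
print(f"2-year stem subsidence: {-fit.predict([24.0])[0]:.2f} mm")

ba = bland_altman(table, "mbrsa", "ctrsa")["stem/Ty"]
print(f"stem Ty method agreement: bias {ba.bias:.3f} mm, LoA {ba.loa_low:.2f} to {ba.loa_high:.2f} mm")

for r in plan_vs_actual(plan):
    pct, lo, hi = r.rounded()
    print(f"{r.category}: {r.k}/{r.n} = {pct}% (95% CI {lo}-{hi})")
```

prints

```
ctrsa stem Ty precision: 0.08 mm (SD 0.04, n=26)
mbrsa stem Ty precision: 0.25 mm (SD 0.11, n=10)
stem Ty slope 0-3 mo: -0.0130 mm/mo (p=0.0011)
2-year stem subsidence: 0.12 mm
stem Ty method agreement: bias -0.021 mm, LoA -0.26 to 0.22 mm
cup_size: 25/26 = 96% (95% CI 80-100)
stem_size: 25/26 = 96% (95% CI 80-100)
stem_exact: 18/26 = 69% (95% CI 48-86)
```

Read: the CT-based method resolves stem subsidence to 0.08 mm
(precision), three times tighter than the marker-based method; the
simulated stem settles 0.12 mm over two years, almost all of it before
3 months (the early slope is significant); the two methods agree within
about a quarter millimetre; and the planning concordance reproduces the
exact binomial machinery on categorical draws.

The same pipeline is available from the shell:

```sh
ctrsa run-all --out run/ --seed 1          # simulate + all analysis stages
ctrsa simulate --out study/ --seed 1       # or stage by stage
ctrsa migrate --study study/ --out run/
ctrsa precision --table run/migration.csv --out run/ --df-rule n-1
```

## Layout

| module | contents |
| --- | --- |
| `ctrsa.synthetic` | study configuration, implant models, scene/exam generator, ground truth |
| `ctrsa.registration` | rigid transforms, Kabsch fit, CN/ME quality gates, ICP |
| `ctrsa.kinematics` | anatomic frames, Cardan 6-DOF decomposition, mirroring, `analyze_pair` |
| `ctrsa.precision` | double-exam precision, Bland–Altman, LS means |
| `ctrsa.longitudinal` | piecewise linear mixed-effects model |
| `ctrsa.concordance` | Clopper–Pearson intervals, plan-vs-used table |
| `ctrsa.pipeline`, `ctrsa.io`, `ctrsa.cli`, `ctrsa.config` | orchestration, serialization, CLI |

See `docs/methods.md` for the model conventions, noise model, and the
design decisions behind them.
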