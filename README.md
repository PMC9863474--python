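# papvrscore

Preoperative decision support for **right partial anomalous pulmonary venous
return (PAPVR)**. In this congenital defect one or more right pulmonary veins
drain into the superior vena cava or right atrium, usually alongside a sinus
venosus defect (SVD). The repair is chosen between baffling the veins through
the defect (**single/double patch**) and the **Warden procedure** (caval
transection and reimplantation) — and the further the anomalous vein lies from
the defect, the more a Warden repair is favoured.

This package implements the morphometric score behind that decision, for
surgeons and imaging scientists who annotate landmarks on 3D-reconstructed
heart models:

```
              d(PV, SVD)
ratio = ─────────────────────────
        d(PV, SVD) + d(PV, azygos)
```

where `d(PV, SVD)` is the straight-line distance (mm) from the superior rim of
the most cranial anomalous pulmonary vein to the superior rim of the SVD, and
`d(PV, azygos)` the distance from the same vein to the inferior rim of the
azygos vein. The ratio is dimensionless, confined to [0, 1], and invariant
under uniform scaling of the anatomy, so it applies across patient sizes
without body-surface-area correction. The decision rule is **WARDEN iff
ratio > 0.68** (strictly), the cutoff selected by maximising Youden's
J = sensitivity + specificity − 1 on the empirical ROC curve.

The package provides:

- **geometry** — landmark annotation files, optional nearest-vertex snapping
  onto STL surface models, and the two distance measurements;
- **scoring** — the ratio, the binary Warden-vs-patch classifier, and the
  cohort-table format;
- **roc** — empirical ROC over midpoint thresholds, Youden-optimal cutoff
  with specificity-first tie-breaking, AUC, confusion matrices;
- **cohort_stats** — per-procedure summaries (n, mean, SD) and the
  conventional between-group tests (Welch t / Kruskal–Wallis, Fisher /
  chi-square);
- **synthetic** — a calibrated synthetic-anatomy generator (no patient data
  are distributed) whose per-group ratio distributions default to the
  published single-patch 0.51 ± 0.08, double-patch 0.62 ± 0.09 and Warden
  0.85 ± 0.10;
- **cli** — a `papvr` command with `simulate`, `score`, `study` and
  `fixture` subcommands.

## Worked example

Simulate a 30-patient cohort (7 single patch / 8 double patch / 15 Warden)
and run the full analysis:

```bash
papvr study --simulate --seed 1 --out-dir demo
```

prints

```
Mean PAPVR ratio by surgical procedure

procedure        n   mean     sd
SINGLE_PATCH     7   0.51   0.04
DOUBLE_PATCH     8   0.64   0.10
WARDEN          15   0.79   0.08

omnibus test: kruskal_wallis p = 5.34e-05
Warden vs patch: welch_t p = 1.27e-06
optimal cutoff (Youden): 0.68 (sens 0.93, spec 0.87, auc 0.93)
confusion at cutoff 0.68: TP=14 FP=2 TN=13 FN=1
```

Reading this: the three procedure groups separate cleanly on the ratio
(patch repairs low, Warden high; both between-group tests far below 0.001),
and the Youden-optimal threshold for this cohort lands at 0.68 — a Warden
patient is called correctly 14 times out of 15 (sensitivity 0.93) at that
cutoff. `demo/report.json` holds the same numbers at full precision, plus
the ROC threshold table and per-group-vs-rest tests.

Scoring a measured cohort instead of a simulated one:

```bash
papvr score --table cohort.csv --cutoff 0.68 --out-dir out
```

where `cohort.csv` has the strict header
`patient_id,d_pv_svd_mm,d_pv_azygos_mm,actual_procedure`. Landmark
annotation files (`*.landmarks.txt`, one `landmark NAME x y z` line per
point, coordinates in mm) can be scored directly with `--anatomy-dir`, with
`--snap` snapping each landmark to the nearest vertex of the matching STL.

## Caveats

- Distances are point-to-point Euclidean, not geodesic along the vessel
  wall; landmark placement upstream must resolve which vein is "most
  cranial".
- The synthetic generator emulates the published group-level ratio
  distributions, not realistic heart geometry; see `docs/methods.md` for
  what that does and does not validate.
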