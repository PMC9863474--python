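# Methods

## The score

For one patient, three landmarks are annotated on a 3D surface
reconstruction of the heart (millimetre coordinates, right-handed
Cartesian): the superior rim of the most cranial anomalous pulmonary vein
(PV), the superior rim of the sinus venosus defect (SVD), and the inferior
rim of the azygos vein. Two Euclidean distances are measured from the PV
landmark, and the score is

    ratio = d_pv_svd / (d_pv_svd + d_pv_azygos)   ∈ [0, 1].

The azygos distance is a per-patient normaliser: the ratio is exactly
invariant under uniform scaling of the anatomy, which is the reason it can
be applied across patient sizes without body-surface-area adjustment. It is
strictly increasing in `d_pv_svd` and strictly decreasing in `d_pv_azygos`.

**Distance convention.** Distances are straight-line point-to-point, not
geodesic along the vessel wall. The published description says only
"distance … in mm" measured on 3D models; the Euclidean reading is the
simplest reproducible one, and a geodesic would require the full
segmentation, which is out of scope here. This is a documented assumption,
not an established equivalence.

**Classification direction.** The decision rule is WARDEN iff ratio >
cutoff, strictly; a ratio exactly at the cutoff is called PATCH. The source
literature is internally inconsistent about the direction (its abstract
states the opposite inequality), but the group means (Warden 0.85 vs patch
0.51/0.62), the prospective Warden ratios (0.99/0.82/0.88, described as
"> 0.68") and the discussion all place Warden at high ratios; this package
follows that numerically self-consistent direction.

## Landmark handling

Annotations are parsed from a strict one-dialect key-value text file
(`patient_id` plus exactly one `landmark NAME x y z` line per landmark).
Coordinates must be finite; landmarks must be pairwise separated by more
than 1e-6 mm. Optionally, landmarks are snapped to the nearest vertex of a
triangulated STL surface (k-d tree nearest neighbour); snapping is off by
default, reports the per-landmark displacement, and fails loudly if two
landmarks collapse onto coincident vertices — that indicates an annotation
coarser than the mesh resolution.

## Cutoff selection

The empirical ROC is swept over the midpoints between consecutive distinct
observed ratios, plus one sentinel 0.01 below the minimum (everyone called
Warden) and one 0.01 above the maximum (no one called Warden). Midpoints
make the strict rule unambiguous: a reported cutoff can never collide with
an observed score. Sensitivity is the fraction of Warden patients with
ratio above the threshold; specificity the fraction of patch patients at or
below it.

The optimal cutoff maximises Youden's J = sensitivity + specificity − 1.
Ties are broken first towards **higher specificity**, then towards the
lower threshold. The specificity preference is a clinical judgement:
over-calling Warden commits an adult patient to a prosthetic caval conduit
and anticoagulation, so when two thresholds discriminate equally well the
conservative one (fewer Warden calls) is chosen. A corollary is that in the
fully degenerate case — all ratios identical, J = 0 everywhere — selection
lands on the upper sentinel (nobody called Warden) and a
`DegenerateRocWarning` is emitted.

AUC is the trapezoidal area over the (1 − specificity, sensitivity) points
in lexicographic order, which for an empirical ROC equals the normalised
Mann–Whitney U statistic (probability a random Warden ratio exceeds a
random patch ratio, ties counted half); the test suite asserts this
equality and cross-checks against an independent ROC implementation. No
smoothed/binormal fitting and no bootstrap confidence intervals are
provided.

## Cohort statistics

Per-procedure summaries report n, mean and sample SD (n − 1 denominator; SD
undefined for singleton groups). Group values are accumulated in sorted
order so the summary is bit-identical under cohort permutation. Between-group
comparison in `auto` mode uses Welch's unequal-variance t-test when there
are exactly two groups and both pass a Shapiro–Wilk screen at α = 0.05
(n ≥ 3 required per group, constant samples fail the screen), and the
Kruskal–Wallis rank-sum test otherwise. All tests are two-sided; no
multiple-testing correction is applied. Because the published per-group
p-values do not state their comparison, reports carry the omnibus test, the
Warden-vs-pooled-patch test and each group-vs-rest test, explicitly
labelled. Nominal associations use Fisher's exact test for 2×2 tables with
any expected cell below 5 and Pearson's chi-square otherwise, with the
sample odds ratio (ad/bc) reported for 2×2 tables.

## Synthetic cohorts

No imaging data are distributed, so cohorts are simulated ratio-first:

1. a surgical label is drawn (either from preset weights or from fixed
   group counts, shuffled);
2. a target ratio is drawn from that group's normal distribution truncated
   to (0.01, 0.99) — truncation by exact rejection sampling, which keeps
   both distances strictly positive and degenerates gracefully to the mean
   at SD 0;
3. a total span S = d_pv_svd + d_pv_azygos is drawn uniformly from
   20–60 mm (plausible caval segment lengths from pediatric to adult; the
   span provably never affects the ratio, and a test asserts this);
4. the three landmarks are placed collinearly along a randomly oriented,
   randomly positioned axis so the Euclidean distances equal ratio·S and
   (1 − ratio)·S exactly. With zero jitter the full pipeline recovers the
   drawn ratio to machine precision; optional perpendicular Gaussian jitter
   (SD in mm) breaks collinearity to probe robustness.

Defaults are the published group distributions — single patch 0.51 ± 0.08,
double patch 0.62 ± 0.09, Warden 0.85 ± 0.10 — with a 7/8/15 group split at
n = 30. The split is an assumption (the study never prints it): 15 Warden
patients is the only simple split consistent with the reported sensitivity
0.93 ≈ 14/15 at n = 30. Everything is driven by one integer seed through
`numpy.random.default_rng`; identical spec + seed gives byte-identical
cohorts.

**Truncation bias.** For the Warden preset the upper truncation bound at
0.99 sits only 1.4 SD above the mean, so the sampled mean is biased low by
≈ 0.016 (measured sample mean ≈ 0.83 at n = 1000 rather than 0.85). The
patch presets sit far from both bounds and are essentially unbiased. This
bias propagates to the recovered cutoff: the median Youden-optimal cutoff
over repeated 30-patient cohorts is ≈ 0.72 rather than exactly 0.68. Both
quantities remain within the package's stated recovery tolerances (±0.02
for group means, ±0.07 for the cutoff), and the bias is reported here
rather than compensated, because the truncated-normal target is the
generator's definition, not an estimate.

**What passing tests show.** The generator emulates the *statistical*
structure of the study cohort (group ratio distributions and sizes), not
anatomy: landmarks are collinear, meshes are tubes, and no imaging noise,
annotation error or reader variability is modelled. Pipeline correctness
and cutoff-recovery results on synthetic cohorts therefore validate the
computation, not the clinical performance of the score on real patients.

The mesh fixture used to exercise snapping is a cylindrical tube whose
centreline is the landmark axis displaced radially by the tube radius, so
the wall passes exactly through the landmark line and ring vertices are
placed at each landmark — mirroring the fact that rim landmarks lie on a
vessel wall, and making snap-then-measure agree with authored distances to
numerical precision for collinear anatomies.

The six-patient prospective fixture carries the three published Warden
ratios (0.99, 0.82, 0.88) exactly; the three patch-side ratios were never
published, so the fixture uses synthetic stand-ins (0.50, 0.55, 0.62) below
the cutoff, flagged with a `-synthetic` suffix in their patient ids.

## Numerical choices and edge cases

- Ratios are never rounded internally; human-readable reports round to two
  decimals (the precision of the published tables), JSON keeps full
  precision.
- Sentinel thresholds sit 0.01 outside the observed ratio range.
- A measurement with d_pv_svd = 0 is valid (vein at the defect, ratio 0);
  both distances zero is rejected as an undefined score.
- Kruskal–Wallis on completely constant data (which scipy rejects) is
  reported directly as statistic 0, p = 1.
- Cohort tables are strict: exact header, non-negative finite distances,
  known procedure labels; strict mode aborts on the first malformed row
  with its line number, lenient mode skips and logs.
- Problem sizes used by the reproduction script — n = 1000 per group for
  calibration means, 500 cohorts of 30 for cutoff recovery — were chosen so
  that Monte-Carlo error (SE ≈ 0.003 for means) is an order of magnitude
  below the recovery tolerances.

## Known limitations

- Euclidean (not geodesic) distances; see above.
- The score is binary (Warden vs patch); no attempt is made to separate
  single- from double-patch repairs.
- The 7/8/15 split and the patch-side prospective ratios are assumptions,
  configurable and flagged, never to be mistaken for study data.
- No DICOM/MRI ingestion, segmentation, mesh repair or centerline
  extraction; landmark coordinates are taken as given.
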