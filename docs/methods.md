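# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic generators do and
do not establish.

## The mismatch statistic

All volumes are carried internally as decimal millilitres; only reports
round (0.1 ml for single-patient output, 1 ml in cohort tables). For one
patient with DWI lesion volume `V_dwi` and perfusion lesion volume `V_pwi`:

1. **Union rule.** DWI voxels not covered by the perfusion lesion are added
   to the total perfusion volume: `V_total = vol(PWI ∪ DWI)`. With masks
   this is computed voxel-wise; with scalars only, the tightest consistent
   value `V_total = max(V_pwi, V_dwi)` is used — either way the absolute
   mismatch below is identical.
2. **Zero floor.** `mismatch = max(V_total − V_dwi, 0)`: a perfusion lesion
   smaller than the infarct means no salvageable penumbra, not a negative
   one.
3. **Relative mismatch.** `100 · mismatch / V_dwi` percent. Undefined at
   `V_dwi = 0` exactly; the scalar operation refuses it. Printed tables
   avoid the case because a "0 ml" row hides a sub-ml decimal; simulations
   may substitute a configured cap (`zero_dwi_pct_cap`, default 10 000 %).
4. **Classification.** Both boundaries are inclusive: `V_dwi ≤ 70 ml`
   (or 100 ml for the secondary cutoff) counts as a small lesion, and
   relative mismatch `≥ 100 %` counts as a large mismatch.

The ABC/2 ellipsoid approximation (`a·b·c/2` from the three longest
orthogonal diameters in cm) is provided for bedside estimation; it is 3/π ≈
0.955 of the exact ellipsoid volume.

## Cohort tables and row validation

The packaged tables transcribe the per-patient printed values (hours from
onset, DWI volume, MTT or TTP lesion volume, mismatch volume, mismatch %)
at whole-ml precision. `validate_records` re-derives each row's mismatch
from its printed volumes and checks

* `|recomputed − printed mismatch| ≤ 1.5 ml` (two ±0.5 ml roundings plus
  slack), and
* printed percentage inside the interval propagated from ±0.5 ml on both
  volumes (unbounded when the printed DWI volume is 0, i.e. sub-ml).

Exactly one row per cohort cannot be reconciled with the rules at any
rounding; both are flagged `inconsistent_flag=1` in the fixtures and are
excluded from tolerance checks. They classify identically under their
printed values, so no count-based result depends on them. Fixture files
carry pinned SHA-256 checksums; edits without a checksum update fail tests.

## Statistics

* **Fisher's exact test** (two-tailed) uses the point-probability (Irwin)
  rule: with margins fixed, sum the hypergeometric probabilities of every
  table whose point probability does not exceed the observed one (relative
  tolerance 1e-7 when comparing probabilities, to keep ties that float
  rounding would split). Log-pmf accumulation keeps the evaluation exact to
  float precision at any counts. Degenerate margins give p = 1. This is the
  convention of the major statistics packages; the unit tests cross-check
  it against an exact-rational enumeration and against an independent
  library implementation.
* **Spearman rank correlation** is the Pearson correlation of midranks
  (tie-corrected). The two-tailed p uses the full permutation distribution
  for n ≤ 9 (vectorised enumeration of all n! permutations) and the
  t-approximation `t = ρ·√((n−2)/(1−ρ²))` with n−2 d.f. above; |ρ| = 1
  always takes the permutation route so p stays positive.
* **Summaries.** Quartiles use linear (type-7) interpolation — the source
  convention for the printed IQRs is unknown, so those are reproduced only
  approximately and are not asserted. Means come with SEM = s/√n using the
  n−1 standard deviation. Group comparisons use the rank-sum test for
  continuous variables; the 0.05 two-tailed significance convention is kept.

## Forward DSC model (phantoms)

Geometric phantoms only — labelled regions (normal tissue per hemisphere,
core, penumbra, arterial block) on a rectangular grid; no anatomy. The
territory is the set of in-hemisphere voxels nearest a centre in physical
mm, so its voxel-count volume hits the target within one voxel; the core is
its innermost fraction.

Per tissue region with delay d, mean transit time m and relative blood
volume v:

* AIF: gamma variate `A(t) = a (t−t₀)^α exp(−(t−t₀)/β)` with α = 3,
  β = 1.5 s, onset t₀ = injection delay + 2 s, peak-normalised. A standard
  literature form — the measured-artery AIF of a real acquisition is not
  modelled; arterial voxels emit A(t) itself, which is what an AIF ROI
  measures.
* Tissue: `C(t) = (v/m) · (A ⊛ e^{−t/m})(t − d)`, evaluated on a grid
  oversampled 20× relative to TR and resampled at frame times, keeping
  quadrature error well below the 2 % checked by the area-ratio test.
* Signal: `S(t) = S₀ · exp(−k·TE·C(t))` with k = 1 (arbitrary concentration
  units — TTP and MTT are invariant to k and no absolute quantification is
  claimed), plus optional additive Gaussian noise on the signal scale.
  Gaussian rather than Rician noise is a documented simplification,
  adequate at the SNR regimes tested.

Acquisition defaults: TR 1.5 s, TE 40 ms, 46 frames, injection 10 s after
acquisition start, 6 baseline frames. Geometry defaults follow a 22-cm FOV:
0.859 mm in-plane on a 256 matrix, 6 mm slice spacing (5 mm + 1 mm gap).
Phantom work uses a 64×64×16 grid at 220/64 = 3.4375 mm in-plane — the same
FOV on a 64 matrix — because a 200-ml territory must fit inside one
hemisphere, which the fine spacing on a 64-voxel grid cannot hold (the
generator raises "territory does not fit" in that case).

## Perfusion mapping conventions

* Concentration conversion requires ≥ 3 baseline frames; voxels outside the
  brain mask or with non-positive baseline are zeroed and flagged.
* TTP is computed on concentration (not the raw-signal minimum); for the
  monotone signal model the two coincide, and the concentration route is
  robust to S₀ variation. TTP values lie on the frame grid, ties break to
  the earliest frame; an off-grid bolus delay therefore quantises to ±TR/2
  per region, and a *difference* of two region TTPs can be off by up to TR.
* The TTP-delay reference is the mean over a contralateral ROI with at
  least 10 valid voxels. The 4-s lesion threshold is strict (`> 4.0 s`).
* Invalid voxels carry NaN and are excluded from every ROI statistic —
  never coerced to zero.
* SVD deconvolution builds the lower-triangular Toeplitz convolution matrix
  `A[i,j] = TR · AIF[i−j]`, zeroes singular values below `truncation_frac ×
  s_max`, and per voxel takes CBF = max of the estimated residue, CBV = the
  trapezoid area ratio to the AIF, MTT = CBV/CBF. No block-circulant delay
  correction: the standard formulation's delay sensitivity is accepted
  because TTP carries the delay signal, and MTT accuracy is only claimed
  for delay-free curves.
* The MTT lesion mask (MTT > 1.5 × contralateral mean) is a reproducible
  surrogate for visual outlining, not a validated reproduction of it.

### Truncation and the MTT bias

`truncation_frac` defaults to 0.20, the conventional choice for clinical
noise levels. That choice is *not* appropriate for noiseless data: cutting
20 % of the spectrum of this smooth gamma-variate kernel smooths the
residue, underestimates its maximum (CBF) and biases MTT high by ~25–55 %
over the 4–10 s range — an intrinsic property of truncated SVD, not an
implementation defect (it persists even when the data are generated by the
same discrete convolution matrix). Accuracy claims are therefore stated at
regularisation matched to the noise level: at `truncation_frac = 0.01` on
noiseless phantoms, MTT ∈ {4, 6, 8, 10} s recovers within 13 % (worst case
+12.7 % at 4 s, where the residue is narrowest relative to TR) and CBV
within 1 %. The unit suite asserts the 15 % tolerance at 0.01 and documents
the high bias at 0.20.

## Cohort simulator

A stated world, fixed once: territory T ~ Normal(220, 40) ml truncated at
20 ml (the at-risk territory is "well over 200 ml"; the spread is a
placeholder, no published distribution exists); collateral grade
f ~ Beta(2, 2) on (0, 1); core = (1−f)·T·u and hypoperfused = T·v with
lognormal measurement noise u, v (CV 10 %); onset uniform on 0.5–24 h;
volumes rounded to 1 ml to mirror clinical tables. Mismatch fields are
computed from the rounded volumes by the volumetry rules — never
independently — so every record satisfies the internal-consistency
identity.

What a green test establishes: the inverse core–mismatch coupling and the
small-lesion → large-mismatch association emerge from the collateral model
and survive rounding and measurement noise. What it does not: anything
about real lesion geometry, reader variability in manual outlining,
perfusion-map artifacts, or the true distribution of territory volumes.

## Known limitations

* No motion correction, coregistration, leakage correction, or absolute
  CBF/CBV quantification; inputs must share one grid.
* Gaussian (not Rician) signal noise; no partial-volume or arterial
  dispersion modelling.
* The MTT-lesion threshold surrogate is not claimed to reproduce visual
  outlines; the printed IQRs' quartile convention is unknown.
* Standard (non-circulant) SVD is delay-sensitive; MTT accuracy is claimed
  only for delay-free curves.
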