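# Methods

This note records the models, conventions and design decisions behind
`mpmtools`, in the spirit of a package methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic
validation does and does not demonstrate.

## Signal model

The spoiled-gradient-echo (SPGR/FLASH) steady state is modelled as

S = A·sin α·(1 − E)/(1 − E·(1 − δ)·cos α)·exp(−TE·R2\*), E = exp(−TR·R1)

with A ≥ 0 (a.u.), α ∈ (0, π/2) rad, TR > 0 s, R1, R2\* ≥ 0 s⁻¹ and
δ ≥ 0 the fractional saturation of longitudinal magnetization applied once
per TR by the off-resonance MT pulse. The (1 − δ) factor is the package's
exact counterpart of the standard small-angle rational form

S ≈ A·α·(TR·R1)/(α²/2 + TR·R1 + δ)·exp(−TE·R2\*),

to which it reduces by series expansion; at δ = 0 it is the plain Ernst
equation. Ideal spoiling is assumed — residual-coherence effects enter
only through the pluggable flip-angle correction below. All internal units
are SI (seconds, radians, s⁻¹); file metadata uses milliseconds and
degrees, converted at parse time.

**Simulator vs estimator.** The simulator's default forward model is the
exact steady state, while the estimator always inverts the rational form.
This deliberately reproduces the real-world model mismatch: at the
protocol's 4°/25° angles and TR 18 ms it biases R1 by about −1.7 % and A
by < 0.4 % (bounded at 5 % over R1 ∈ [0.5, 1.5] s⁻¹ by tests), and MT
saturation by about −4 %. Simulating with the rational forward model
instead makes the whole chain an algebraic identity, recovered to ≤ 1e−10
relative — that is the regression test for the inversion formulas, not a
statement about accuracy on real data.

**Flip-angle optimisation.** The PDw/T1w excitation angles sit at c·α_E
with c the roots of c² − 2√2·c + 1 = 0, i.e. √2 ∓ 1 ≈ 0.4142 and 2.4142:
the two angles at which the rational signal falls to 1/√2 of its maximum
over flip angle, which minimises noise propagation into dual-angle
R1/PD estimates. The identity is independent of TR·R1.

**Effective flip angle.** α_eff = P(f_T·α_nominal), where f_T is the
relative transmit (B1+) field and P an optional polynomial in the angle
keyed by (RF-spoiling phase increment, TR). The polynomial coefficients
are sequence-specific calibration data supplied via configuration and
disabled by default (an empty table is the identity); synthetic round
trips inject known polynomials. Whether the correction should also apply
to the MT-weighted scan is genuinely uncertain in practice, so it is a
config switch (`correct_mtw_spoiling`, default on). No additional
empirical B1+ bias correction is applied to MT maps beyond using α_eff
inside the δ formula; MT saturation is largely insensitive to residual
B1+/R1 variation by construction of the semi-quantitative measure.

## Estimation chain

1. **ESTATICS.** Unweighted ordinary least squares on log-signal over all
   echoes of all three contrasts, one shared slope −R2\* and one intercept
   ln S0 per contrast. The design matrix is voxel-independent, so the fit
   is a single precomputed pseudoinverse applied to all voxels. Voxels
   with any non-positive echo are masked (log undefined); unweighted OLS
   is used because no weighting scheme is canonical. The TE = 0 intercepts
   are the extrapolated signals used downstream, which removes
   R2\*-weighting bias from PD.
2. **Dual-angle inversion.** R1 = (S_T1·α_T1/TR_T1 − S_PD·α_PD/TR_PD) /
   (2(S_PD/α_PD − S_T1/α_T1)) and the matching closed form for A; both are
   exact inverses of the rational model. Near-zero denominators (contrast
   collapse), negative R1 and non-positive A are masked.
3. **MT saturation.** δ = (A·α_MT/S_MT − 1)·R1·TR_MT − α_MT²/2, reported
   as 100·δ p.u. Values with |p.u.| ≥ `mt_threshold` are masked. Default
   thresholds follow the dynamic-range settings needed for the second
   vendor's data dialect: `mt_threshold = 15`, `a_threshold = 1e8`; both
   are configuration, and per-step masking counts (in = valid + masked)
   are logged and asserted by tests.
4. **Receive sensitivity.** Precedence: a measured field if supplied; else
   the smoothed head/body-coil ratio (Gaussian σ = 2 voxels, mean-1
   normalised over the brain mask) when the calibration pair is usable;
   else a data-driven fall-back that fits a low-order 3-D polynomial
   (default order 2) to log A inside the brain mask — a deliberately
   simple stand-in for segmentation-based bias-field estimation that
   captures smooth multiplicative trends but not anatomy. A calibration
   pair is rejected when its recorded flip angle is not the expected 6°
   (re-enacting how a miscalibrated acquisition is excluded), which is
   what routes the faulty-calibration scenario to the fall-back.
5. **PD calibration.** PD = (A/s)·k with k set so the mean over WM voxels
   with tissue probability > 0.95 equals exactly 69 p.u. The calibration
   is idempotent and makes PD a relative measure: global receive-field
   scale errors cancel, smooth shape errors do not.

## Synthetic traveling-heads study

The generator emulates the study conditions the statistics are meant for:
five subjects, six sites (four reference-vendor, two second-vendor), two
scans per site, all on one 48³ grid at 3 mm (a protocol-faithful
176×256×256 at 1 mm is supported but the desk-scale default keeps a full
study run around 20 s; all reported problem sizes in tests use 48³ or
32³).

- **Anatomy**: concentric ellipsoidal CSF–GM–WM shells plus two embedded
  deep-GM spheres and one CSF "ventricle", with per-subject positional
  jitter. Tissue values are literature-typical 3 T defaults (WM: R1 1.1
  s⁻¹, MT 2 p.u., PD 69 p.u., R2\* 21 s⁻¹; GM: 0.7, 1.0, 83, 16; CSF:
  0.25, 0, 100, 1) — configuration, not measured ground truth. Subjects
  differ by a 2 % multiplicative value jitter; within GM/WM a smooth
  texture field (amplitude 0.15, normalised to tissue mean 1) emulates
  regional biological variation, which also gives the harmonization fit a
  realistic continuous MT spread. Tissue probabilities are smoothed
  one-hot labels renormalised to sum to 1 inside the head, so
  probability-thresholded masks erode boundaries as real segmentations
  do.
- **Site effects**: smooth mean-1 transmit (amplitude 0.10, correlation
  length 16 voxels) and receive fields (0.15, 12 voxels), drawn per
  site × subject and shared by the scan-rescan pair. The second vendor's
  MT pulse difference is modelled as the exact inverse of the linear
  harmonization transform, δ_acq = (δ_true − b)/a with defaults
  (a, b) = (0.7895, −0.0807), making the harmonization problem
  identifiable with known truth.
- **Noise**: Gaussian by default, with σ set from SNR 50 on the TE = 0
  PDw amplitude in WM; a Rician option (magnitude of complex Gaussian)
  exists for bias studies, and both coincide as σ → 0. The Gaussian
  default is what the recovery tests pin down; Rician magnitude bias is a
  known, second-order omission at this SNR.
- **Determinism**: every stream derives from the master seed through
  tagged child seeds (ground truth / fields / noise / calibration), so a
  study regenerates identically — including byte-identical .nii.gz files,
  which are gzipped with a fixed mtime.
- **Protocol deviations**: a study design can inject faults (e.g. echo
  times scaled by 1.04, calibration flip angle set to 23°) that change
  the actual simulated acquisition; sidecars truthfully record the
  deviated settings, which is what the QC checker compares against the
  reference protocol (relative tolerance, default 1 %).

What passing tests on this phantom does **not** show: performance on real
anatomy (no atlas geometry, no partial-volume mixtures beyond smoothed
probabilities), motion or registration error (all sessions share one grid
by construction), k-space or parallel-imaging artifacts, Rician-noise
estimator bias, or the physics of specific vendor MT pulses (the linear
vendor effect is an assumption made exact here, an approximation in
reality).

## Harmonization

Per session, ordinary least squares of the reference-site map (mean of its
scan-rescan pair per subject) on the source map over the combined GM+WM
probability > 0.99 mask, CSF excluded; fits with fewer than 100 voxels or
zero source variance are errors. Per-scan fits are pooled across subjects,
sites and scans by the componentwise median. OLS (rather than orthogonal
regression) is the documented choice; with noise on the predictor the
slope attenuates by var_signal/(var_signal + var_noise), a property the
test suite checks against the errors-in-variables closed form. At the
default study's SNR this attenuation is ~0.6 % of the slope — visible but
inside the recovery tolerance; the fixed constants shipped in
configuration, (0.7895, −0.0807), are applied, never re-derived, when no
study data is available.

## Reproducibility statistics

Sample SDs use the n−1 denominator throughout (for the scan-rescan pair,
σ = |x₁ − x₂|/√2 — pinned by the 90/110 → CoV 14.14 % example); the
inter-site CoV uses **all** scans of a subject (both scan and rescan at
every site — 12 maps in the default design), with the per-site-means
alternative available by calling `cov_inter` on per-site means directly.
Voxels enter a statistic only where every contributing map is valid
(intersection masking), preventing masked zeros from contaminating CoVs.
Analysis masks threshold the averaged tissue probabilities strictly at
0.95 (harmonization masks at 0.99). ROI, site and subject summaries are
root-mean-square aggregates; subgroup tables (e.g. per vendor) take the
RMS over the subset's sites with per-site bias kept relative to the
full-study mean, so subgroup RMS² compose exactly to the full-study value
with count weights. Reports serialise as tidy long-format TSV.

## Numerical choices and degenerate inputs

- Near-zero denominators are masked at a relative 1e−12 of the largest
  denominator magnitude rather than raising.
- The smooth-field generator scales centred filtered noise by its peak, so
  bounds [1 − a, 1 + a] and an exact mean of 1 hold by construction.
- `receive_sensitivity_from_ratio` smooths NaN-aware (value and weight
  filtered separately) and masks voxels where the body-coil signal is
  ≲ 1e−6 of its maximum.
- Empty masks, single-echo contrasts, missing contrasts, grid and affine
  mismatches, unknown sites/fields and non-increasing echo times all fail
  fast with named errors; an all-masked fit aborts rather than returning
  empty maps.
- Voxel grids are 0-based with world coordinates only via the NIfTI
  affine; no resampling happens anywhere in the estimation chain.

## Known limitations

Beyond the phantom realism caveats above: the data-driven receive
fall-back confounds anatomy with bias at low polynomial orders and is
honest only for smooth fields; the QC checker compares metadata, not image
content; harmonization is global and linear (no spatially varying or
nonlinear variant) and applies to MT only; and no statistical inference
(confidence intervals or tests) is attached to CoV differences.
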