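# mpmtools

Quantitative MRI **multiparameter mapping (MPM)** for multicenter
reproducibility studies: a forward simulator of multi-site, dual-vendor,
multi-echo spoiled-gradient-echo brain acquisitions; the MT / PD / R1 / R2\*
map-estimation chain; linear cross-vendor MT harmonization; and the
scan-rescan coefficient-of-variation and inter-site bias statistics used to
qualify an MPM protocol for clinical multicenter trials.

The intended users are quantitative-MRI methods researchers who want a
tested, scriptable reference implementation of the MPM analysis chain and a
seeded synthetic "traveling heads" study (the same subjects scanned twice
at every site) on which every step of that chain can be validated against
known ground truth.

## The model

Each of the three weighted scans (MT-, PD- and T1-weighted) is a multi-echo
spoiled gradient echo. The steady-state signal at flip angle α, repetition
time TR and echo time TE is

```
S = A sin α · (1 − E) / (1 − E (1 − δ) cos α) · exp(−TE · R2*),   E = exp(−TR · R1)
```

where A is the effective amplitude (proton density × receive sensitivity),
R1 and R2\* the longitudinal and effective transverse relaxation rates, and
δ the per-TR magnetization-transfer saturation imparted by the
off-resonance MT pulse (δ = 0 for the PDw/T1w scans). Estimation inverts
the small-angle rational approximation

```
S ≈ A α · TR·R1 / (α²/2 + TR·R1 + δ) · exp(−TE · R2*)
```

in four steps:

1. **ESTATICS** — one joint log-linear least-squares fit of all echoes of
   all three contrasts with a single shared R2\* slope and one TE = 0
   intercept per contrast;
2. **dual-angle inversion** — closed-form R1 and A from the PDw/T1w
   intercepts at their effective (transmit-corrected, optionally
   RF-spoiling-corrected) flip angles α_PD, α_T1;
3. **MT saturation** — δ = (A α_MT / S_MT − 1) · R1 · TR_MT − α_MT²/2,
   reported in percent units (100 δ);
4. **PD calibration** — receive-sensitivity correction of A (measured map,
   head/body-coil ratio, or a data-driven polynomial bias fit, in that
   precedence), then scaling so white matter averages 69 p.u.

The PDw/T1w flip angles follow the noise-propagation optimum: 0.4142 and
2.4142 times the Ernst angle `α_E = arccos(exp(−TR·R1))`, the two angles
at which the rational signal drops to 1/√2 of its maximum.

Because vendors' MT pulses differ, MT maps from the second vendor are
harmonized against a reference site by voxel-wise ordinary least squares of
`MT_scaled = a · MT_orig + b` over combined GM+WM masks (probability
> 0.99, CSF excluded), pooled across sessions by the median.

Reproducibility is summarised by the scan-rescan (intra-site) CoV
σ_intra/μ_intra, the inter-site CoV across all scans of a subject, the
per-site relative bias Δ = μ_intra,site / mean_sites(μ_intra) − 1, and
root-mean-square aggregation over ROI voxels, sites and subjects (sample
SDs use the n−1 convention throughout).

## Worked example

```python
from mpmtools import StudyDesign, run_pipeline

result = run_pipeline(StudyDesign(seed=1))   # 5 subjects x 6 sites x 2 scans
a, b = result.scaling_constants
print(f"pooled MT scaling: a={a:.4f}, b={b:.4f}")
print(f"MT inter-site bias RMS: {result.rms_bias_mt_before:.3f} -> "
      f"{result.rms_bias_mt_after:.3f}")
```

prints

```
pooled MT scaling: a=0.7845, b=-0.0631
MT inter-site bias RMS: 0.147 -> 0.026
```

The default design puts the same five digital heads through six sites —
four on the reference vendor preset and two on the second vendor, whose
generative MT effect is the inverse of `(a, b) = (0.7895, −0.0807)`. The
pooled fit recovers that effect (the residual 0.6 % slope shrinkage is the
classic errors-in-variables attenuation of OLS at SNR 50, with per-session
R² ≈ 0.98), and applying it cuts the RMS inter-site MT bias from ~15 % to
~3 %. `result.roi_table` holds the tidy per-ROI CoV/bias table and
`result.qc_table` the protocol-deviation findings (empty for a clean
study).

The same run is available from the shell:

```sh
mpm run --out study_report --seed 1
mpm simulate --out study_tree --seed 1          # NIfTI + JSON study tree
mpm fit --session study_tree/sub-01/site-ZH/scan-1 \
        --wm-prob study_tree/sub-01/ground_truth/prob_WM.nii.gz --out maps
mpm qc --session study_tree/sub-01/site-ZH/scan-1 --protocol ref.json
```

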