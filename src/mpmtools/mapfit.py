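"""MT/PD/R1/R2* map estimation from one session's multi-echo contrasts.

The estimation chain mirrors the standard multiparameter-mapping recipe:

1. joint log-linear fit of all echoes of all three contrasts with one
   shared R2* decay rate and one TE=0 intercept per contrast (ESTATICS);
2. dual-angle inversion of the small-angle rational SPGR signal
   approximation for R1 and the signal amplitude A, using effective
   (transmit-corrected, optionally spoiling-corrected) flip angles;
3. MT saturation from the MT-weighted TE=0 intercept, A and R1;
4. receive-sensitivity correction of A (measured map, head/body-coil
   ratio, or a data-driven polynomial bias fit, in that precedence);
5. proton-density calibration so white matter averages 69 percent units.

All steps are voxel-wise, vectorised, and propagate a validity mask with
per-step masking counts.

The statsmodels-style entry point is :class:`MPMModel` (built from a
session, ``fit()`` returns :class:`MPMResults`); the individual steps are
module functions usable on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .protocols import CONTRASTS
from .signal import SpoilingModel, effective_flip_angle
from .volumes import AcquisitionVolume, FieldMaps, ParameterMaps

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "estatics_fit",
    "estimate_r1",
    "estimate_a",
    "estimate_mt",
    "receive_sensitivity_from_ratio",
    "receive_bias_datadriven",
    "calibrate_pd",
    "fit_mpm",
    "MPMModel",
    "MPMResults",
]

#: calibration value of the mean white-matter proton density, percent units
WM_PD_PU = 69.0


@dataclass
class FitConfig:
    """Tunables of the estimation chain.

    ``mt_threshold`` masks implausible MT saturation (|p.u.| >= threshold)
    and ``a_threshold`` masks runaway amplitudes (A >= threshold); the
    defaults are the dynamic-range settings used for the second vendor's
    data dialect. ``sens_smooth_vox`` is the smoothing applied to the
    head/body coil ratio; ``bias_poly_order`` the polynomial order of the
    data-driven receive-bias fall-back.
    """

    mt_threshold: float = 15.0      # p.u.
    a_threshold: float = 1e8        # a.u.
    wm_pd_pu: float = WM_PD_PU
    wm_prob_threshold: float = 0.95
    sens_smooth_vox: float = 2.0
    bias_poly_order: int = 2
    spoiling: SpoilingModel | None = None
    correct_mtw_spoiling: bool = True
    calib_flip_expected_deg: float = 6.0


# ---------------------------------------------------------------------------
# step 1: ESTATICS
# ---------------------------------------------------------------------------

def estatics_fit(
    volumes: Mapping[str, AcquisitionVolume] | Sequence[AcquisitionVolume],
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Joint log-linear multi-echo fit with one shared R2* across contrasts.

    Ordinary least squares on the log signal: for contrast c and echo time
    TE, ``ln S = ln S0_c - R2* * TE``, with one intercept per contrast and
    a single common slope. Solved for all voxels at once via the
    pseudoinverse of the shared design matrix. Voxels with any non-positive
    signal are masked out entirely (log undefined).

    Returns
    -------
    s0 : dict of contrast -> TE=0 intercept field (a.u.)
    r2s : shared R2* field (1/s)
    residual : root-mean-square log-domain residual field
    mask : boolean validity field
    """
    if not isinstance(volumes, Mapping):
        volumes = {v.protocol.contrast: v for v in volumes}
    contrasts = list(volumes)
    if not contrasts:
        raise ValueError("no volumes supplied")
    grids = {volumes[c].grid for c in contrasts}
    if len(grids) != 1:
        raise ValueError(f"volumes on inconsistent grids: {grids}")
    grid = grids.pop()

    rows, te_all = [], []
    for ci, c in enumerate(contrasts):
        v = volumes[c]
        if v.protocol.n_echoes < 2:
            raise ValueError(f"contrast {c} has fewer than 2 echoes")
        for te in v.protocol.te_s:
            row = np.zeros(len(contrasts) + 1)
            row[ci] = 1.0
            row[-1] = -te
            rows.append(row)
            te_all.append(te)
    design = np.asarray(rows)                       # (n_obs, n_contrasts+1)

    data = np.concatenate(
        [volumes[c].data.reshape(-1, volumes[c].protocol.n_echoes) for c in contrasts],
        axis=1,
    )                                               # (n_vox, n_obs)
    mask = np.all(data > 0, axis=1)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.info("estatics_fit: masked %d voxels with non-positive signal", n_bad)

    coef = np.full((data.shape[0], design.shape[1]), np.nan)
    if mask.any():
        logs = np.log(data[mask])
        coef[mask] = logs @ np.linalg.pinv(design).T

    fitted = np.full_like(data, np.nan)
    residual = np.full(data.shape[0], np.nan)
    if mask.any():
        fitted[mask] = coef[mask] @ design.T
        residual[mask] = np.sqrt(
            np.mean((np.log(data[mask]) - fitted[mask]) ** 2, axis=1)
        )

    s0 = {
        c: np.exp(coef[:, ci]).reshape(grid) for ci, c in enumerate(contrasts)
    }
    r2s = coef[:, -1].reshape(grid)
    return s0, r2s, residual.reshape(grid), mask.reshape(grid)


# ---------------------------------------------------------------------------
# steps 2-3: rational-approximation inversion
# ---------------------------------------------------------------------------

def _masked_divide(num, den, rel_eps=1e-12):
    """Elementwise num/den; near-zero or non-finite denominators give NaN."""
    num, den = np.broadcast_arrays(
        np.asarray(num, dtype=float), np.asarray(den, dtype=float)
    )
    scale = np.nanmax(np.abs(den), initial=0.0)
    ok = np.isfinite(num) & np.isfinite(den) & (np.abs(den) > rel_eps * max(scale, 1e-300))
    out = np.full(den.shape, np.nan)
    out[ok] = num[ok] / den[ok]
    return out


def estimate_r1(s0_pd, s0_t1, alpha_pd, alpha_t1, tr_pd: float, tr_t1: float):
    """Longitudinal relaxation rate from the dual-angle signal pair.

    Inverts the small-angle rational SPGR approximation for the PDw/T1w
    intercepts (TE=0-extrapolated) at their effective flip angles:

    ``R1 = (S_T1 a_T1 / TR_T1 - S_PD a_PD / TR_PD)
           / (2 (S_PD / a_PD - S_T1 / a_T1))``

    Negative and non-finite results (contrast collapse, noise) are NaN.
    """
    num = s0_t1 * alpha_t1 / tr_t1 - s0_pd * alpha_pd / tr_pd
    den = 2.0 * (s0_pd / alpha_pd - s0_t1 / alpha_t1)
    r1 = _masked_divide(num, den)
    return np.where(np.isfinite(r1) & (r1 >= 0), r1, np.nan)


def estimate_a(s0_pd, s0_t1, alpha_pd, alpha_t1, tr_pd: float, tr_t1: float):
    """Signal amplitude A (proton-density precursor) from the dual-angle pair.

    ``A = S_PD S_T1 (TR_PD a_T1/a_PD - TR_T1 a_PD/a_T1)
          / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD)``

    Homogeneous of degree 1 in the signals; non-positive results are NaN.
    """
    num = s0_pd * s0_t1 * (tr_pd * alpha_t1 / alpha_pd - tr_t1 * alpha_pd / alpha_t1)
    den = s0_t1 * tr_pd * alpha_t1 - s0_pd * tr_t1 * alpha_pd
    a = _masked_divide(num, den)
    return np.where(np.isfinite(a) & (a > 0), a, np.nan)


def estimate_mt(amplitude, r1, s0_mt, alpha_mt, tr_mt: float,
                mt_threshold: float = FitConfig.mt_threshold):
    """MT saturation (percent units) from the MT-weighted TE=0 intercept.

    ``delta = (A a_MT / S_MT - 1) R1 TR_MT - a_MT^2 / 2``, reported as
    100*delta p.u. The per-TR saturation delta absorbs what the
    off-resonance pulse strips from longitudinal magnetization each
    repetition. Values with |p.u.| >= ``mt_threshold`` (implausible, driven
    by noise or fit failure) and voxels with S_MT <= 0 are NaN.
    """
    s0_mt = np.asarray(s0_mt, dtype=float)
    ratio = _masked_divide(np.asarray(amplitude, dtype=float) * alpha_mt, s0_mt)
    ratio = np.where(s0_mt > 0, ratio, np.nan)
    delta = (ratio - 1.0) * np.asarray(r1, dtype=float) * tr_mt \
        - np.asarray(alpha_mt, dtype=float) ** 2 / 2.0
    with np.errstate(invalid="ignore"):
        mt_pu = 100.0 * delta
        return np.where(np.isfinite(mt_pu) & (np.abs(mt_pu) < mt_threshold),
                        mt_pu, np.nan)


# ---------------------------------------------------------------------------
# step 4: receive sensitivity
# ---------------------------------------------------------------------------

def receive_sensitivity_from_ratio(
    head: np.ndarray,
    body: np.ndarray,
    smooth_vox: float = FitConfig.sens_smooth_vox,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Receive sensitivity from the head/body-coil calibration pair.

    The body coil is assumed uniformly sensitive, so the smoothed ratio
    head/body estimates the head coil's relative net receive field,
    normalised to mean 1 over the mask (whole grid when None). Voxels where
    the body-coil signal is ~0 are NaN.
    """
    head = np.asarray(head, dtype=float)
    body = np.asarray(body, dtype=float)
    if head.shape != body.shape:
        raise ValueError("head and body volumes must share a grid")
    floor = 1e-6 * np.nanmax(np.abs(body))
    ratio = np.where(np.abs(body) > floor, head / np.where(body == 0, 1, body), np.nan)
    if smooth_vox > 0:
        # NaN-aware smoothing: filter values and weights separately
        w = np.isfinite(ratio).astype(float)
        v = np.where(np.isfinite(ratio), ratio, 0.0)
        num = ndimage.gaussian_filter(v, smooth_vox)
        den = ndimage.gaussian_filter(w, smooth_vox)
        ratio = np.where(den > 1e-3, num / np.where(den == 0, 1, den), np.nan)
    m = np.ones(ratio.shape, bool) if mask is None else np.asarray(mask, bool)
    scale = np.nanmean(ratio[m])
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("degenerate calibration pair: no usable ratio voxels")
    return ratio / scale


def _poly_design(shape, order: int) -> np.ndarray:
    """Monomial design x^i y^j z^k, i+j+k <= order, coords scaled to [-1,1]."""
    axes = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    cols = [
        (x**i * y**j * z**k).ravel()
        for i in range(order + 1)
        for j in range(order + 1 - i)
        for k in range(order + 1 - i - j)
    ]
    return np.column_stack(cols)


def receive_bias_datadriven(
    amplitude: np.ndarray,
    mask: np.ndarray,
    order: int = FitConfig.bias_poly_order,
) -> np.ndarray:
    """Data-driven multiplicative receive-bias field (fall-back estimator).

    When no usable calibration pair exists, a low-order 3-D polynomial is
    fitted by least squares to the log amplitude inside the brain mask; the
    exponentiated fit, normalised to mean 1 over the mask, is the bias
    estimate. Order 0 returns the constant field 1. This stands in for a
    segmentation-based bias-field correction: it captures smooth
    multiplicative trends but not anatomy.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    mask = np.asarray(mask, bool) & np.isfinite(amplitude) & (amplitude > 0)
    if not mask.any():
        raise ValueError("empty mask for data-driven bias estimation")
    design = _poly_design(amplitude.shape, order)
    dm = design[mask.ravel()]
    if dm.shape[0] < dm.shape[1]:
        raise ValueError(
            f"mask too small ({dm.shape[0]} voxels) for polynomial order {order}"
        )
    coef, *_ = np.linalg.lstsq(dm, np.log(amplitude[mask]), rcond=None)
    bias = np.exp(design @ coef).reshape(amplitude.shape)
    return bias / bias[mask].mean()


# ---------------------------------------------------------------------------
# step 5: PD calibration
# ---------------------------------------------------------------------------

def calibrate_pd(
    amplitude: np.ndarray,
    receive: np.ndarray,
    wm_probability: np.ndarray,
    wm_pd_pu: float = WM_PD_PU,
    wm_prob_threshold: float = FitConfig.wm_prob_threshold,
) -> np.ndarray:
    """Calibrate the receive-corrected amplitude to proton density in p.u.

    ``PD = (A / s) * k`` with k chosen so the mean over white-matter voxels
    (tissue probability > threshold) equals exactly ``wm_pd_pu`` (69 p.u.
    by convention). Idempotent by construction.
    """
    wm = np.asarray(wm_probability) > wm_prob_threshold
    corrected = np.asarray(amplitude, dtype=float) / np.asarray(receive, dtype=float)
    wm_vals = corrected[wm & np.isfinite(corrected)]
    if wm_vals.size == 0:
        raise ValueError(
            f"no white-matter voxels above probability {wm_prob_threshold}"
        )
    return corrected * (wm_pd_pu / wm_vals.mean())


# ---------------------------------------------------------------------------
# orchestration: Model / Results
# ---------------------------------------------------------------------------

@dataclass
class MPMResults:
    """Estimated parameter maps plus fit diagnostics.

    Attributes
    ----------
    maps : ParameterMaps
        MT (p.u.), PD (p.u.), R1 (1/s), R2* (1/s), amplitude A (a.u.) and
        the joint validity mask.
    receive : ndarray
        Receive-sensitivity field used for the PD correction.
    receive_source : str
        Which estimator produced it (measured | ratio-derived |
        data-driven | unity).
    masking_log : list of dict
        Per-step voxel accounting: name, voxels in, valid, masked.
    residual : ndarray
        Log-domain RMS residual of the ESTATICS fit.
    """

    maps: ParameterMaps
    receive: np.ndarray
    receive_source: str
    masking_log: list[dict]
    residual: np.ndarray
    config: FitConfig

    def summary(self, tissue_masks: Mapping[str, np.ndarray] | None = None):
        """Per-map summary table (optionally per tissue ROI) as a DataFrame."""
        import pandas as pd

        rows = []
        regions = tissue_masks or {"all": self.maps.mask}
        for region, rmask in regions.items():
            rmask = np.asarray(rmask, bool) & self.maps.mask
            for name, arr in self.maps.as_dict().items():
                vals = arr[rmask]
                vals = vals[np.isfinite(vals)]
                rows.append({
                    "region": region, "map": name, "n_voxels": vals.size,
                    "mean": vals.mean() if vals.size else np.nan,
                    "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                })
        return pd.DataFrame(rows)

    def plot_maps(self, axis: int = 2, index: int | None = None):
        """Show the central slice of each map (matplotlib figure)."""
        import matplotlib.pyplot as plt

        maps = self.maps.as_dict()
        index = index if index is not None else self.maps.mt.shape[axis] // 2
        fig, axes = plt.subplots(1, len(maps), figsize=(3 * len(maps), 3))
        for ax, (name, arr) in zip(np.atleast_1d(axes), maps.items()):
            sl = np.take(arr, index, axis=axis)
            im = ax.imshow(sl.T, origin="lower")
            ax.set_title(name)
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
        return fig


class MPMModel:
    """Multiparameter-mapping estimation model for one session.

    Parameters
    ----------
    volumes : mapping or sequence of AcquisitionVolume
        The MTw/PDw/T1w multi-echo acquisitions on one grid.
    f_transmit : ndarray, optional
        Relative transmit field (B1+ ratio); 1 when absent.
    receive : ndarray, optional
        Measured receive-sensitivity field; takes precedence over the
        calibration pair and the data-driven fall-back.
    calibration : (head, body) pair of AcquisitionVolume, optional
        Head/body-coil volumes for the ratio-derived receive field. The
        pair is rejected (fall-back engaged) when its recorded flip angle
        deviates from the expected low-angle setting — re-enacting how a
        miscalibrated acquisition is excluded in practice.
    wm_probability, brain_mask : ndarray, optional
        White-matter probability (for PD calibration) and brain mask (for
        normalisations and the data-driven bias fit).
    config : FitConfig
    """

    def __init__(
        self,
        volumes,
        f_transmit: np.ndarray | None = None,
        receive: np.ndarray | None = None,
        calibration: tuple[AcquisitionVolume, AcquisitionVolume] | None = None,
        wm_probability: np.ndarray | None = None,
        brain_mask: np.ndarray | None = None,
        config: FitConfig | None = None,
    ):
        if not isinstance(volumes, Mapping):
            volumes = {v.protocol.contrast: v for v in volumes}
        missing = set(CONTRASTS) - set(volumes)
        if missing:
            raise ValueError(f"missing contrasts: {sorted(missing)}")
        grids = {volumes[c].grid for c in CONTRASTS}
        if len(grids) != 1:
            raise ValueError(f"session volumes on inconsistent grids: {grids}")
        self.volumes = volumes
        self.grid = grids.pop()
        self.f_transmit = (np.ones(self.grid) if f_transmit is None
                           else np.asarray(f_transmit, dtype=float))
        self.receive_measured = receive
        self.calibration = calibration
        self.wm_probability = wm_probability
        self.brain_mask = (np.asarray(brain_mask, bool) if brain_mask is not None
                           else None)
        self.config = config or FitConfig()

    @classmethod
    def from_session(cls, session, use_true_fields: bool = False,
                     config: FitConfig | None = None,
                     wm_probability: np.ndarray | None = None,
                     brain_mask: np.ndarray | None = None) -> "MPMModel":
        """Build from a simulated :class:`~mpmtools.phantom.SessionData`.

        ``use_true_fields`` hands the generator's exact transmit and
        receive fields to the estimator (the measured-field-maps scenario);
        otherwise only the transmit field and the calibration pair are
        used, as for real acquisitions.
        """
        return cls(
            session.volumes,
            f_transmit=session.fields.f_transmit,
            receive=session.fields.receive if use_true_fields else None,
            calibration=(session.calib_head, session.calib_body),
            wm_probability=wm_probability,
            brain_mask=brain_mask,
            config=config,
        )

    # -- receive-field precedence ---------------------------------------
    def _calibration_usable(self) -> bool:
        if self.calibration is None:
            return False
        head, _ = self.calibration
        expected = self.config.calib_flip_expected_deg
        found = head.meta.get("flip_deg", head.protocol.flip_deg)
        if abs(found - expected) > 0.5:
            logger.warning(
                "calibration pair unusable: flip angle %.1f deg, expected %.1f; "
                "falling back to data-driven receive-bias estimation",
                found, expected,
            )
            return False
        return True

    def _receive_field(self, amplitude, mask):
        cfg = self.config
        if self.receive_measured is not None:
            return np.asarray(self.receive_measured, dtype=float), "measured"
        if self._calibration_usable():
            head, body = self.calibration
            s = receive_sensitivity_from_ratio(
                head.data[..., 0], body.data[..., 0],
                smooth_vox=cfg.sens_smooth_vox,
                mask=self.brain_mask if self.brain_mask is not None else mask,
            )
            return s, "ratio-derived"
        bias_mask = mask if self.brain_mask is None else (mask & self.brain_mask)
        try:
            s = receive_bias_datadriven(amplitude, bias_mask, cfg.bias_poly_order)
            return s, "data-driven"
        except ValueError:
            return np.ones(self.grid), "unity"

    # -- the chain -------------------------------------------------------
    def fit(self) -> MPMResults:
        cfg = self.config
        log: list[dict] = []

        def account(step, valid, previous):
            n_in = int(previous.sum())
            n_valid = int(valid.sum())
            log.append({"step": step, "n_in": n_in, "n_valid": n_valid,
                        "n_masked": n_in - n_valid})
            logger.info("%s: %d in, %d valid, %d masked",
                        step, n_in, n_valid, n_in - n_valid)

        all_vox = np.ones(self.grid, bool)
        s0, r2s, residual, mask = estatics_fit(self.volumes)
        r2s_clean = r2s.copy()
        neg_r2s = mask & (r2s_clean < 0)
        r2s_clean[~mask] = np.nan
        mask = mask & ~neg_r2s
        r2s_clean[neg_r2s] = np.nan
        account("estatics", mask, all_vox)

        def alpha_eff(contrast):
            proto = self.volumes[contrast].protocol
            spoil = cfg.spoiling
            if contrast == "MTw" and not cfg.correct_mtw_spoiling:
                spoil = None
            return effective_flip_angle(
                proto.flip_rad, self.f_transmit, spoil, proto.tr_s
            )

        a_pd, a_t1, a_mt = (alpha_eff(c) for c in ("PDw", "T1w", "MTw"))
        tr_pd = self.volumes["PDw"].protocol.tr_s
        tr_t1 = self.volumes["T1w"].protocol.tr_s
        tr_mt = self.volumes["MTw"].protocol.tr_s

        r1 = estimate_r1(s0["PDw"], s0["T1w"], a_pd, a_t1, tr_pd, tr_t1)
        amplitude = estimate_a(s0["PDw"], s0["T1w"], a_pd, a_t1, tr_pd, tr_t1)
        with np.errstate(invalid="ignore"):
            amplitude = np.where(amplitude < cfg.a_threshold, amplitude, np.nan)
        valid = mask & np.isfinite(r1) & np.isfinite(amplitude)
        account("dual_angle_r1_a", valid, mask)
        mask = valid

        mt = estimate_mt(amplitude, r1, s0["MTw"], a_mt, tr_mt, cfg.mt_threshold)
        valid = mask & np.isfinite(mt)
        account("mt_saturation", valid, mask)
        mask = valid

        receive, source = self._receive_field(amplitude, mask)
        pd_map = calibrate_pd(
            amplitude, receive,
            self.wm_probability if self.wm_probability is not None
            else np.ones(self.grid),
            cfg.wm_pd_pu, cfg.wm_prob_threshold,
        ) if self.wm_probability is not None else (
            amplitude / receive
        )
        valid = mask & np.isfinite(pd_map) & (pd_map > 0)
        account("pd_calibration", valid, mask)
        mask = valid

        if not mask.any():
            raise ValueError("all voxels masked; nothing to report")

        def cleaned(arr):
            out = np.asarray(arr, dtype=float).copy()
            out[~mask] = np.nan
            return out

        maps = ParameterMaps(
            mt=cleaned(mt), pd=cleaned(pd_map), r1=cleaned(r1),
            r2s=cleaned(r2s_clean), amplitude=cleaned(amplitude), mask=mask,
        )
        return MPMResults(maps, receive, source, log, residual, cfg)


def fit_mpm(
    volumes,
    field_maps: FieldMaps | None = None,
    calibration=None,
    wm_probability=None,
    brain_mask=None,
    config: FitConfig | None = None,
) -> MPMResults:
    """Functional wrapper around :class:`MPMModel` for one session."""
    model = MPMModel(
        volumes,
        f_transmit=None if field_maps is None else field_maps.f_transmit,
        receive=(field_maps.receive
                 if field_maps is not None and field_maps.source == "measured"
                 else None),
        calibration=calibration,
        wm_probability=wm_probability,
        brain_mask=brain_mask,
        config=config,
    )
    return model.fit()
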