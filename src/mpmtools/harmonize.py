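"""Cross-vendor MT harmonization.

MT saturation maps depend on the vendor's MT pulse (shape, power, offset),
so maps from different scanner platforms live on different scales. The
remedy is a linear rescaling ``MT_scaled = a * MT_orig + b`` fitted
voxel-wise against a reference site over brain tissue: per-session ordinary
least squares on the combined GM+WM mask (probability > 0.99, CSF excluded
because its direct-saturation offset differs from tissue), then pooling of
the per-session estimates by the componentwise median into fixed study
constants, which are applied to every map of the affected vendor.

The statsmodels-style surface is :class:`MTScalingModel` (``fit()`` returns
:class:`MTScalingResults`); :func:`fit_mt_scaling`, :func:`pool_models` and
:func:`apply_mt_scaling` are the functional equivalents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from typing import Sequence

import numpy as np

__all__ = [
    "MTScalingModel",
    "MTScalingResults",
    "fit_mt_scaling",
    "pool_models",
    "apply_mt_scaling",
    "STUDY_DEFAULT_SCALING",
]

#: Fixed scaling constants shipped as configuration defaults for the
#: second-vendor preset (median slope/offset of the pooled per-session
#: fits of the original six-site study). Provided as constants, not
#: recomputed from data.
STUDY_DEFAULT_SCALING: tuple[float, float] = (0.7895, -0.0807)

MIN_MASK_VOXELS = 100


@dataclass
class MTScalingResults:
    """Fitted linear MT harmonization model.

    ``a`` (slope, dimensionless) and ``b`` (offset, p.u.) map source-vendor
    MT values onto the reference scale; ``rsquared`` and ``n_voxels``
    qualify the fit; ``bse`` are the OLS standard errors of (b, a).
    """

    a: float
    b: float
    rsquared: float
    n_voxels: int
    bse: tuple[float, float] = (np.nan, np.nan)
    provenance: dict = dfield(default_factory=dict)

    def apply(self, mt: np.ndarray) -> np.ndarray:
        return apply_mt_scaling(mt, self.a, self.b)

    def summary(self) -> str:
        lines = [
            "MT harmonization fit (OLS, target ~ a * source + b)",
            f"  slope a       {self.a:10.4f}  (se {self.bse[1]:.4f})",
            f"  offset b      {self.b:10.4f}  p.u.  (se {self.bse[0]:.4f})",
            f"  R-squared     {self.rsquared:10.4f}",
            f"  mask voxels   {self.n_voxels:10d}",
        ]
        if self.provenance:
            lines.append(f"  provenance    {self.provenance}")
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "rsquared": self.rsquared,
            "n_voxels": self.n_voxels, "bse": list(self.bse),
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MTScalingResults":
        return cls(a=d["a"], b=d["b"], rsquared=d["rsquared"],
                   n_voxels=d["n_voxels"], bse=tuple(d.get("bse", (np.nan, np.nan))),
                   provenance=d.get("provenance", {}))

    @classmethod
    def from_json(cls, path) -> "MTScalingResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class MTScalingModel:
    """Linear harmonization of one source MT map against a reference map.

    Parameters
    ----------
    mt_source : ndarray
        MT map (p.u.) from the vendor to be harmonized.
    mt_target : ndarray
        Reference-site MT map (p.u.) of the same subject on the same grid.
    mask : ndarray of bool
        Combined GM+WM probability > 0.99 brain-tissue mask (CSF excluded).
    """

    def __init__(self, mt_source: np.ndarray, mt_target: np.ndarray,
                 mask: np.ndarray, provenance: dict | None = None):
        src = np.asarray(mt_source, dtype=float)
        tgt = np.asarray(mt_target, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if not (src.shape == tgt.shape == mask.shape):
            raise ValueError("source, target and mask must share a grid")
        keep = mask & np.isfinite(src) & np.isfinite(tgt)
        self.source = src[keep]
        self.target = tgt[keep]
        self.provenance = dict(provenance or {})
        if self.source.size < MIN_MASK_VOXELS:
            raise ValueError(
                f"only {self.source.size} usable mask voxels "
                f"(need >= {MIN_MASK_VOXELS})"
            )
        if np.ptp(self.source) == 0 or self.source.std() == 0:
            raise ValueError("zero variance in source MT values; cannot fit")

    def fit(self) -> MTScalingResults:
        """OLS of target on source: returns slope a, offset b, R^2, n."""
        import statsmodels.api as sm

        exog = sm.add_constant(self.source)
        res = sm.OLS(self.target, exog).fit()
        b, a = res.params
        return MTScalingResults(
            a=float(a), b=float(b), rsquared=float(res.rsquared),
            n_voxels=int(self.source.size),
            bse=(float(res.bse[0]), float(res.bse[1])),
            provenance=self.provenance,
        )


def fit_mt_scaling(mt_source, mt_target, gmwm_mask,
                   provenance: dict | None = None) -> MTScalingResults:
    """Fit the per-session linear MT rescaling (see :class:`MTScalingModel`)."""
    return MTScalingModel(mt_source, mt_target, gmwm_mask, provenance).fit()


def pool_models(models: Sequence[MTScalingResults]) -> tuple[float, float]:
    """Fixed scaling constants: componentwise median of per-session fits."""
    if len(models) == 0:
        raise ValueError("no harmonization models to pool")
    a = float(np.median([m.a for m in models]))
    b = float(np.median([m.b for m in models]))
    return a, b


def apply_mt_scaling(mt: np.ndarray, a: float, b: float):
    """Apply ``MT_scaled = a * MT + b`` voxel-wise; NaN mask is preserved."""
    if not a > 0:
        raise ValueError("slope a must be > 0")
    out = a * np.asarray(mt, dtype=float) + b
    return float(out) if np.ndim(out) == 0 else out
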