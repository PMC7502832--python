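"""In-memory containers for volumes, field maps and parameter maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import ProtocolSpec


def _check_finite_grid(shape) -> None:
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"expected a 3-D grid, got shape {shape}")


@dataclass
class AcquisitionVolume:
    """One weighted multi-echo magnitude acquisition.

    ``data`` is 4-D, (x, y, z, echo), in arbitrary scanner units; echo
    times and the rest of the acquisition parameters live in ``protocol``.
    """

    data: np.ndarray
    protocol: ProtocolSpec
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("AcquisitionVolume data must be 4-D (x, y, z, echo)")
        _check_finite_grid(self.data.shape[:3])
        if self.data.shape[3] != self.protocol.n_echoes:
            raise ValueError(
                f"echo count mismatch: data has {self.data.shape[3]} echoes, "
                f"protocol lists {self.protocol.n_echoes}"
            )

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class FieldMaps:
    """Transmit ratio field f_T (B1+) and receive sensitivity s (B1-).

    Both are dimensionless with nominal value 1; ``source`` records where
    the receive field came from (measured | ratio-derived | data-driven |
    unity).
    """

    f_transmit: np.ndarray
    receive: np.ndarray
    source: str = "unity"

    def __post_init__(self) -> None:
        self.f_transmit = np.asarray(self.f_transmit, dtype=float)
        self.receive = np.asarray(self.receive, dtype=float)
        for name, arr in (("f_transmit", self.f_transmit), ("receive", self.receive)):
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise ValueError(f"{name} must be strictly positive where defined")

    @classmethod
    def unity(cls, grid: tuple[int, int, int]) -> "FieldMaps":
        return cls(np.ones(grid), np.ones(grid), source="unity")


@dataclass
class ParameterMaps:
    """Estimated quantitative maps of one session.

    MT saturation in percent units (100 * delta), PD in percent units
    (white matter calibrated to 69 p.u.), R1 and R2* in 1/s, plus the
    pre-calibration amplitude A (a.u.) and the validity mask. Voxels
    outside the mask hold NaN.
    """

    mt: np.ndarray
    pd: np.ndarray
    r1: np.ndarray
    r2s: np.ndarray
    amplitude: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        grids = {m.shape for m in (self.mt, self.pd, self.r1, self.r2s,
                                   self.amplitude, self.mask)}
        if len(grids) != 1:
            raise ValueError(f"parameter maps on inconsistent grids: {grids}")
        self.mask = np.asarray(self.mask, dtype=bool)
        m = self.mask
        for name in ("r1", "r2s", "pd"):
            arr = getattr(self, name)
            if np.any(arr[m] < 0) if name != "pd" else np.any(arr[m] <= 0):
                raise ValueError(f"{name} violates positivity inside the mask")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"MT": self.mt, "PD": self.pd, "R1": self.r1, "R2s": self.r2s}
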