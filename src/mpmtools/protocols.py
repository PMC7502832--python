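"""Acquisition protocol descriptions and vendor presets.

The multiparameter-mapping (MPM) protocol acquires three multi-echo spoiled
gradient-echo scans with magnetization-transfer (MTw), proton-density (PDw)
and T1 (T1w) weighting. TR, echo trains, flip angles and RF-spoiling phase
increments differ between the two vendor product sequences; the presets here
carry those per-vendor defaults. Angles are stored in degrees and times in
milliseconds, matching the metadata convention; SI accessors convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONTRASTS = ("MTw", "PDw", "T1w")


@dataclass(frozen=True)
class MTPulse:
    """Off-resonance MT saturation pulse descriptor (metadata only)."""

    angle_deg: float
    duration_ms: float
    offset_khz: float
    shape: str


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition parameters of one weighted multi-echo SPGR scan."""

    contrast: str
    vendor: str
    tr_ms: float
    flip_deg: float
    te_ms: tuple[float, ...]
    spoil_phase_deg: float
    mt_pulse: MTPulse | None = None

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be > 0")
        te = np.asarray(self.te_ms)
        if len(te) and (np.any(np.diff(te) <= 0) or te[0] <= 0):
            raise ValueError("te_ms must be strictly increasing and positive")
        if len(te) and te[-1] >= self.tr_ms:
            raise ValueError("echo times must not exceed TR")

    # SI accessors -------------------------------------------------------
    @property
    def tr_s(self) -> float:
        return self.tr_ms * 1e-3

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))

    @property
    def te_s(self) -> np.ndarray:
        return np.asarray(self.te_ms) * 1e-3

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)


def _echoes(first_ms: float, last_ms: float, n: int = 6) -> tuple[float, ...]:
    return tuple(np.round(np.linspace(first_ms, last_ms, n), 2))


# Vendor presets: common flips 6/4/25 deg and TR 18 ms for PDw/T1w; the
# MT-weighted TR and the echo grid differ between product sequences, as do
# the RF-spoiling phase increments and the (unchangeable) MT pulse shapes.
VENDOR_PRESETS: dict[str, dict[str, ProtocolSpec]] = {
    "siemens": {
        "MTw": ProtocolSpec(
            "MTw", "siemens", 37.0, 6.0, _echoes(2.46, 14.76), 50.0,
            MTPulse(500.0, 10.0, 1.2, "gaussian"),
        ),
        "PDw": ProtocolSpec("PDw", "siemens", 18.0, 4.0, _echoes(2.46, 14.76), 50.0),
        "T1w": ProtocolSpec("T1w", "siemens", 18.0, 25.0, _echoes(2.46, 14.76), 50.0),
    },
    "philips": {
        "MTw": ProtocolSpec(
            "MTw", "philips", 48.0, 6.0, _echoes(2.40, 14.40), 150.0,
            MTPulse(220.0, 8.0, 1.0, "gauss-filtered sinc"),
        ),
        "PDw": ProtocolSpec("PDw", "philips", 18.0, 4.0, _echoes(2.40, 14.40), 150.0),
        "T1w": ProtocolSpec("T1w", "philips", 18.0, 25.0, _echoes(2.40, 14.40), 150.0),
    },
}


def vendor_protocols(vendor: str) -> dict[str, ProtocolSpec]:
    """Return the MTw/PDw/T1w protocol set for a vendor preset."""
    try:
        return dict(VENDOR_PRESETS[vendor])
    except KeyError:
        raise KeyError(
            f"unknown vendor preset {vendor!r}; available: {sorted(VENDOR_PRESETS)}"
        ) from None


def with_deviation(spec: ProtocolSpec, **changes) -> ProtocolSpec:
    """Copy a protocol with some fields changed (used to model faults)."""
    return replace(spec, **changes)
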