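"""Spoiled-gradient-echo (SPGR/FLASH) steady-state signal models.

Closed-form signal equations shared by the phantom simulator and the map
estimator: the exact Ernst-equation steady state (optionally extended with a
per-TR magnetization-transfer saturation factor), the small-angle rational
approximation used for parameter estimation, Ernst-angle utilities, the
noise-optimal dual flip-angle factors, and the effective-flip-angle
correction chain (transmit-field scaling plus an optional RF-spoiling
polynomial).

All functions are vectorised over numpy arrays and use SI units internally:
seconds, radians, 1/s. Conversion from the MRI metadata convention
(milliseconds, degrees) happens at the I/O boundary, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalParams",
    "SpoilingModel",
    "ernst_angle",
    "spgr_signal_exact",
    "spgr_signal_rational",
    "optimal_flip_factors",
    "effective_flip_angle",
]


@dataclass(frozen=True)
class SignalParams:
    """Parameters of one SPGR steady-state signal evaluation.

    Attributes
    ----------
    amplitude : float or ndarray
        Effective equilibrium signal amplitude ``A`` (a.u., >= 0); proportional
        to proton density times receive sensitivity.
    flip_angle : float or ndarray
        Excitation flip angle (radians, 0 < alpha < pi/2).
    tr : float
        Repetition time (seconds, > 0).
    r1 : float or ndarray
        Longitudinal relaxation rate (1/s, >= 0).
    r2s : float or ndarray
        Effective transverse relaxation rate R2* (1/s, >= 0).
    te : float or ndarray
        Echo time (seconds, >= 0).
    mt_delta : float or ndarray
        Magnetization-transfer saturation per TR (dimensionless fraction,
        >= 0; reported externally as percent units = 100 * delta). Zero
        reduces the MT-weighted model to the plain SPGR model.
    """

    amplitude: float | np.ndarray
    flip_angle: float | np.ndarray
    tr: float
    r1: float | np.ndarray
    r2s: float | np.ndarray = 0.0
    te: float | np.ndarray = 0.0
    mt_delta: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitude must be >= 0")
        fa = np.asarray(self.flip_angle)
        if np.any(fa < 0) or np.any(fa >= np.pi / 2):
            raise ValueError("flip_angle must lie in [0, pi/2)")
        if not self.tr > 0:
            raise ValueError("tr must be > 0")
        for name in ("r1", "r2s", "te", "mt_delta"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SpoilingModel:
    """Imperfect-RF-spoiling flip-angle correction.

    RF spoiling with a finite quadratic phase increment leaves residual
    transverse coherences that bias the apparent flip angle. The standard
    remedy is a polynomial correction, in the transmit-corrected nominal
    flip angle, whose coefficients depend on the spoiling phase increment
    and TR. Those coefficients are sequence-specific and supplied via
    configuration; with an empty table (or ``enabled=False``) the
    correction is the identity.

    ``table`` maps ``(phase_increment_deg, tr_ms)`` keys (both rounded to
    2 decimals) to polynomial coefficients ``[c0, c1, c2, ...]`` applied as
    ``alpha_eff = c0 + c1*alpha + c2*alpha**2 + ...`` with alpha in radians.
    """

    phase_increment_deg: float = 50.0
    table: dict[tuple[float, float], tuple[float, ...]] = field(default_factory=dict)
    enabled: bool = False

    @staticmethod
    def _key(phase_increment_deg: float, tr_s: float) -> tuple[float, float]:
        return (round(float(phase_increment_deg), 2), round(float(tr_s) * 1e3, 2))

    def coefficients(self, tr_s: float) -> tuple[float, ...] | None:
        """Polynomial coefficients for this model's phase increment at TR.

        Returns None when the correction is disabled or the table is empty;
        raises KeyError naming the missing key when enabled with a non-empty
        table that lacks the requested entry.
        """
        if not self.enabled or not self.table:
            return None
        key = self._key(self.phase_increment_deg, tr_s)
        if key not in self.table:
            raise KeyError(
                f"no spoiling-correction coefficients for (phase_increment_deg, "
                f"tr_ms) = {key}; available: {sorted(self.table)}"
            )
        return self.table[key]


def ernst_angle(tr: float, r1: float | np.ndarray) -> float | np.ndarray:
    """Flip angle maximising the SPGR steady-state signal.

    ``alpha_E = arccos(exp(-TR * R1))``; 0 when R1 = 0 (no relaxation, no
    optimum tilt).

    Parameters
    ----------
    tr : float
        Repetition time in seconds (> 0).
    r1 : float or ndarray
        Longitudinal relaxation rate in 1/s (>= 0).
    """
    if not tr > 0:
        raise ValueError("tr must be > 0")
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 < 0):
        raise ValueError("r1 must be >= 0")
    out = np.arccos(np.exp(-tr * r1))
    return float(out) if out.ndim == 0 else out


def spgr_signal_exact(p: SignalParams) -> float | np.ndarray:
    """Exact SPGR steady-state signal (Ernst equation), with optional MT term.

    .. math::

        S = A \\sin\\alpha \\frac{1 - E}{1 - E (1 - \\delta) \\cos\\alpha}
            e^{-TE \\cdot R_2^*}, \\qquad E = e^{-TR \\cdot R_1}

    The factor ``(1 - delta)`` models the fractional saturation of
    longitudinal magnetization imparted once per TR by an off-resonance MT
    pulse; with ``delta = 0`` this is the plain spoiled Ernst equation. Its
    small-angle expansion reproduces :func:`spgr_signal_rational`.
    """
    e1 = np.exp(-p.tr * np.asarray(p.r1, dtype=float))
    ca = np.cos(p.flip_angle)
    s = (
        p.amplitude
        * np.sin(p.flip_angle)
        * (1.0 - e1)
        / (1.0 - e1 * (1.0 - np.asarray(p.mt_delta)) * ca)
        * np.exp(-np.asarray(p.te) * np.asarray(p.r2s))
    )
    return float(s) if np.ndim(s) == 0 else s


def spgr_signal_rational(p: SignalParams) -> float | np.ndarray:
    """Small-angle rational approximation of the SPGR signal.

    .. math::

        S = A \\alpha \\frac{TR \\cdot R_1}
            {\\alpha^2/2 + TR \\cdot R_1 + \\delta} e^{-TE \\cdot R_2^*}

    Valid in the small-angle, short-TR regime (alpha <~ 30 deg,
    TR*R1 << 1); with ``delta = 0`` it approximates
    :func:`spgr_signal_exact` to ~1% at protocol flip angles. This is the
    model the map estimator inverts; applicability is the caller's call.
    """
    a = np.asarray(p.flip_angle, dtype=float)
    trr1 = p.tr * np.asarray(p.r1, dtype=float)
    s = (
        p.amplitude
        * a
        * trr1
        / (a**2 / 2.0 + trr1 + np.asarray(p.mt_delta))
        * np.exp(-np.asarray(p.te) * np.asarray(p.r2s))
    )
    return float(s) if np.ndim(s) == 0 else s


def optimal_flip_factors() -> tuple[float, float]:
    """Noise-optimal dual flip angles as ratios to the Ernst angle.

    For the rational signal ``S(alpha) ~ alpha * t / (alpha^2/2 + t)`` with
    ``t = TR*R1`` fixed, the signal peaks at the (small-angle) Ernst angle
    ``alpha_E = sqrt(2 t)``. Noise propagation into dual-angle R1/PD
    estimates is minimised by the two flip angles at which the signal drops
    to ``1/sqrt(2)`` of that maximum. Writing ``alpha = c * alpha_E``, the
    half-power condition reduces to the TR*R1-independent quadratic

    .. math:: c^2 - 2\\sqrt{2}\\, c + 1 = 0

    whose roots this function returns, ``(sqrt(2)-1, sqrt(2)+1) ~
    (0.4142, 2.4142)``.

    Returns
    -------
    (low, high) : tuple of float
        Ratios of the low (PD-weighted) and high (T1-weighted) optimal flip
        angles to the Ernst angle; their product is exactly 1.
    """
    roots = np.sort(np.roots([1.0, -2.0 * np.sqrt(2.0), 1.0]).real)
    return float(roots[0]), float(roots[1])


def effective_flip_angle(
    alpha_nominal: float | np.ndarray,
    f_transmit: float | np.ndarray,
    spoiling: SpoilingModel | None = None,
    tr: float | None = None,
) -> float | np.ndarray:
    """Local effective flip angle after transmit-field and spoiling correction.

    The nominal angle is first scaled by the relative transmit field
    ``f_T`` (B1+ ratio, nominal 1), then optionally passed through the
    RF-spoiling correction polynomial for the sequence's phase increment
    and TR.

    Parameters
    ----------
    alpha_nominal : float or ndarray
        Prescribed flip angle, radians.
    f_transmit : float or ndarray
        Relative transmit field; values outside (0.5, 1.5) trigger a warning
        (plausible B1+ deviations at 3 T stay well within that band).
    spoiling : SpoilingModel, optional
        Correction model; identity when None, disabled, or empty table.
    tr : float, optional
        Repetition time (seconds), required only when the spoiling
        correction is enabled.
    """
    ft = np.asarray(f_transmit, dtype=float)
    if np.any((ft <= 0.5) | (ft >= 1.5)):
        warnings.warn(
            "transmit field outside plausible range (0.5, 1.5)", stacklevel=2
        )
    alpha = np.asarray(alpha_nominal, dtype=float) * ft
    if spoiling is not None:
        if spoiling.enabled and spoiling.table and tr is None:
            raise ValueError("tr is required when spoiling correction is enabled")
        coeffs = spoiling.coefficients(tr) if tr is not None else (
            spoiling.coefficients(0.0) if spoiling.enabled and spoiling.table else None
        )
        if coeffs is not None:
            # numpy.polyval wants highest order first
            alpha = np.polyval(list(coeffs)[::-1], alpha)
    return float(alpha) if np.ndim(alpha) == 0 else alpha
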