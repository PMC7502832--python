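"""Synthetic traveling-heads study generator.

Builds digital head phantoms (piecewise-constant CSF/GM/WM geometry with a
few embedded spherical structures), site-specific smooth transmit/receive
fields, a linear vendor effect on MT saturation, and noisy multi-echo
spoiled-gradient-echo acquisitions plus head/body-coil calibration volume
pairs — emulating a multicenter scan-rescan reproducibility study in which
the same subjects travel to every site.

Everything is deterministic given the design and master seed; scans of the
same session differ only in their noise realization.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dfield
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage

from .protocols import CONTRASTS, ProtocolSpec, vendor_protocols, with_deviation
from .signal import SignalParams, SpoilingModel, spgr_signal_exact, spgr_signal_rational
from .volumes import AcquisitionVolume, FieldMaps

LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3}

#: Literature-typical 3 T tissue values used as the phantom default. These
#: are configuration, not measured ground truth of any particular cohort.
DEFAULT_TISSUES: dict[str, dict[str, float]] = {
    "WM":  {"r1": 1.10, "pd_pu": 69.0,  "mt_pu": 2.0, "r2s": 21.0},
    "GM":  {"r1": 0.70, "pd_pu": 83.0,  "mt_pu": 1.0, "r2s": 16.0},
    "CSF": {"r1": 0.25, "pd_pu": 100.0, "mt_pu": 0.0, "r2s": 1.0},
}


def _rng(master_seed: int, *tags: int) -> np.random.Generator:
    """Deterministic child generator from a master seed plus integer tags."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *tags]))


# tag codes for the seeding tree (arbitrary but frozen)
_TAG_GT, _TAG_FIELDS, _TAG_NOISE, _TAG_CAL = 11, 22, 33, 44


@dataclass
class GroundTruth:
    """Per-voxel ground-truth parameter maps of one synthetic subject."""

    shape: tuple[int, int, int]
    voxel_mm: float
    labels: np.ndarray                       # int codes per LABELS
    mt_delta: np.ndarray                     # dimensionless fraction
    pd: np.ndarray                           # percent units
    r1: np.ndarray                           # 1/s
    r2s: np.ndarray                          # 1/s
    probabilities: dict[str, np.ndarray]     # CSF/GM/WM, each in [0, 1]
    rois: dict[str, np.ndarray] = dfield(default_factory=dict)
    tissue_table: dict = dfield(default_factory=lambda: copy.deepcopy(DEFAULT_TISSUES))

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class SiteEffect:
    """Scanner-site characteristics applied on top of the ground truth.

    The MT vendor effect is linear on the percent-unit scale: the map a
    scanner of this site produces is ``delta_acq = (delta_true - b) / a``,
    the inverse of the harmonization transform, so harmonizing with
    ``(a, b)`` restores the reference scale. The reference vendor has
    a=1, b=0.
    """

    site_id: str
    vendor: str = "siemens"
    mt_a: float = 1.0
    mt_b: float = 0.0                       # p.u.
    snr: float = 50.0                       # WM PDw TE=0 amplitude over sigma
    noise_sigma: float | None = None        # a.u. override of the SNR rule
    noise: str = "gaussian"                 # or "rician"
    ft_amplitude: float = 0.10
    ft_lengthscale: float = 16.0            # voxels
    s_amplitude: float = 0.15
    s_lengthscale: float = 12.0
    spoiling: SpoilingModel | None = None

    def __post_init__(self) -> None:
        if self.mt_a <= 0:
            raise ValueError("mt_a must be > 0")
        if self.noise not in ("gaussian", "rician"):
            raise ValueError("noise must be 'gaussian' or 'rician'")


def default_sites() -> list[SiteEffect]:
    """Six-site dual-vendor layout: four reference-vendor sites and two
    sites whose MT pulse differs, expressed as the linear vendor effect."""
    siemens = [SiteEffect(s, "siemens") for s in ("ZH", "BCN", "HD", "BSL")]
    philips = [
        SiteEffect(s, "philips", mt_a=0.7895, mt_b=-0.0807) for s in ("NOT", "SNS")
    ]
    return siemens + philips


@dataclass
class StudyDesign:
    """Traveling-heads study layout: subjects x sites x scan-rescan."""

    n_subjects: int = 5
    sites: list[SiteEffect] = dfield(default_factory=default_sites)
    scans_per_site: int = 2
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 3.0
    seed: int = 0
    subject_jitter: float = 0.02       # relative SD of per-subject tissue values
    texture_amplitude: float = 0.15    # within-tissue smooth variation, MT/R1/R2*
    forward: str = "exact"             # forward signal model: exact | rational
    deviations: list[dict] = dfield(default_factory=list)

    def site(self, site_id: str) -> SiteEffect:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"unknown site id {site_id!r}")


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_smooth_field(
    shape: tuple[int, int, int],
    amplitude: float,
    lengthscale: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smooth positive random field with mean exactly 1.

    Gaussian-filtered white noise, centred and scaled so the field lies
    within [1 - amplitude, 1 + amplitude] by construction. ``lengthscale``
    is the filter sigma in voxels and sets the spatial correlation length.
    Used for both the transmit ratio f_T and the receive sensitivity s.
    """
    if not 0 <= amplitude < 0.5:
        raise ValueError("amplitude must lie in [0, 0.5)")
    if amplitude == 0:
        return np.ones(shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=lengthscale)
    g -= g.mean()
    peak = np.max(np.abs(g))
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * g / peak


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    """Boolean ellipsoid in normalised [-1, 1] coordinates."""
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    return (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def make_ground_truth(
    shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    voxel_mm: float = 3.0,
    tissue_table: Mapping[str, Mapping[str, float]] | None = None,
    value_jitter: float = 0.0,
    texture_amplitude: float = 0.0,
    texture_lengthscale: float = 6.0,
    prob_smooth_sigma: float = 0.6,
) -> GroundTruth:
    """Build a digital head phantom.

    Concentric ellipsoidal CSF-GM-WM geometry with two embedded deep-GM
    spheres and a CSF "ventricle" sphere, recorded as named ROIs. Parameter
    values are piecewise constant per tissue (from ``tissue_table``),
    optionally jittered per subject (``value_jitter``, multiplicative,
    one draw per tissue/parameter) and modulated by smooth within-tissue
    texture fields normalised to mean 1 within each tissue, so tissue-mean
    values stay exactly at the table values.

    Tissue probability maps are smoothed one-hot label fields renormalised
    to sum to 1 inside the head and 0 outside, emulating the soft
    boundaries of a real segmentation.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("shape must be 3-D with every dimension >= 16")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    head = _ellipsoid(shape, (0, 0, 0), (0.88, 0.82, 0.85))
    gm_outer = _ellipsoid(shape, (0, 0, 0), (0.76, 0.70, 0.73))
    wm_core = _ellipsoid(shape, (0, 0, 0), (0.55, 0.48, 0.52))

    labels = np.zeros(shape, dtype=np.int8)
    labels[head] = LABELS["CSF"]
    labels[gm_outer] = LABELS["GM"]
    labels[wm_core] = LABELS["WM"]

    # embedded spherical structures (jittered positions per subject)
    jit = lambda s: rng.uniform(-0.02, 0.02, 3) * s  # noqa: E731
    rois: dict[str, np.ndarray] = {}
    for name, center, radius, lab in (
        ("deep_gm_left", (-0.20, 0.10, 0.0), 0.11, "GM"),
        ("deep_gm_right", (0.20, 0.10, 0.0), 0.11, "GM"),
        ("ventricle", (0.0, -0.16, 0.05), 0.09, "CSF"),
    ):
        c = np.asarray(center) + jit(1.0)
        sph = _ellipsoid(shape, c, (radius,) * 3)
        labels[sph] = LABELS[lab]
        rois[name] = sph

    table = copy.deepcopy(tissue_table if tissue_table is not None else DEFAULT_TISSUES)
    if value_jitter > 0:
        for tis in table.values():
            for key in tis:
                tis[key] *= float(1.0 + value_jitter * rng.standard_normal())
    # CSF carries no bound pool: MT saturation stays 0 regardless of jitter
    table["CSF"]["mt_pu"] = 0.0

    maps = {k: np.zeros(shape) for k in ("mt_delta", "pd", "r1", "r2s")}
    for name in ("CSF", "GM", "WM"):
        m = labels == LABELS[name]
        maps["mt_delta"][m] = table[name]["mt_pu"] / 100.0
        maps["pd"][m] = table[name]["pd_pu"]
        maps["r1"][m] = table[name]["r1"]
        maps["r2s"][m] = table[name]["r2s"]

    if texture_amplitude > 0:
        for key, amp in (("mt_delta", texture_amplitude),
                         ("r1", texture_amplitude),
                         ("r2s", texture_amplitude),
                         ("pd", texture_amplitude / 3.0)):
            tex = make_smooth_field(shape, amp, texture_lengthscale, rng)
            for name in ("GM", "WM"):
                m = labels == LABELS[name]
                local = tex[m]
                mean = local.mean()
                if mean > 0:
                    maps[key][m] *= local / mean

    # soft tissue probabilities: smooth one-hot fields, renormalised in-head
    probs: dict[str, np.ndarray] = {}
    for name in ("CSF", "GM", "WM"):
        probs[name] = ndimage.gaussian_filter(
            (labels == LABELS[name]).astype(float), sigma=prob_smooth_sigma
        )
    total = sum(probs.values())
    inside = head & (total > 0)
    for name, p in probs.items():
        out = np.zeros(shape)
        out[inside] = p[inside] / total[inside]
        probs[name] = out

    return GroundTruth(
        shape=shape, voxel_mm=voxel_mm, labels=labels,
        mt_delta=maps["mt_delta"], pd=maps["pd"], r1=maps["r1"], r2s=maps["r2s"],
        probabilities=probs, rois=rois, tissue_table=table,
    )


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """One simulated scanning session: three weighted multi-echo volumes,
    the true field maps, the head/body calibration pair, and metadata."""

    volumes: dict[str, AcquisitionVolume]
    fields: FieldMaps
    calib_head: AcquisitionVolume
    calib_body: AcquisitionVolume
    meta: dict


def _forward_signal(gt, protocol, alpha_eff, delta, model, te):
    fn = spgr_signal_exact if model == "exact" else spgr_signal_rational
    p = SignalParams(
        amplitude=gt.pd, flip_angle=alpha_eff, tr=protocol.tr_s,
        r1=gt.r1, r2s=gt.r2s, te=te, mt_delta=delta,
    )
    return fn(p)


def _add_noise(signal, sigma, kind, rng):
    if sigma == 0:
        return signal.copy()
    if kind == "gaussian":
        return signal + sigma * rng.standard_normal(signal.shape)
    # Rician: magnitude of a complex Gaussian centred on the signal
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def noise_sigma_for_snr(gt: GroundTruth, snr: float) -> float:
    """Noise level giving the requested SNR on the TE=0 PDw amplitude in WM."""
    wm = gt.tissue_mask("WM")
    proto = vendor_protocols("siemens")["PDw"]
    s = _forward_signal(gt, proto, proto.flip_rad, 0.0, "exact", 0.0)
    return float(s[wm].mean() / snr)


def simulate_session(
    gt: GroundTruth,
    site: SiteEffect,
    protocols: Mapping[str, ProtocolSpec] | None = None,
    seed: int = 0,
    field_maps: FieldMaps | None = None,
    forward: str = "exact",
    cal_flip_deg: float = 6.0,
    meta_extra: Mapping | None = None,
) -> SessionData:
    """Simulate one session of one subject at one site.

    Per echo and contrast the voxel signal is the steady-state SPGR model
    (exact Ernst equation by default; the MT-weighted contrast carries the
    per-TR saturation term) evaluated at the transmit-scaled flip angle,
    multiplied by the receive sensitivity, plus noise. The calibration pair
    renders the PDw-like TE~2.2 ms image once with uniform (body-coil) and
    once with the site's head-coil sensitivity, low-pass filtered to mimic
    the low-resolution acquisition.
    """
    protocols = dict(protocols) if protocols else vendor_protocols(site.vendor)
    missing = set(CONTRASTS) - set(protocols)
    if missing:
        raise ValueError(f"protocol set incomplete, missing {sorted(missing)}")

    if field_maps is None:
        frng = _rng(seed, _TAG_FIELDS)
        field_maps = FieldMaps(
            make_smooth_field(gt.shape, site.ft_amplitude, site.ft_lengthscale, frng),
            make_smooth_field(gt.shape, site.s_amplitude, site.s_lengthscale, frng),
            source="simulated-truth",
        )
    sigma = (site.noise_sigma if site.noise_sigma is not None
             else noise_sigma_for_snr(gt, site.snr))
    nrng = _rng(seed, _TAG_NOISE)

    # vendor effect on the acquired MT saturation, percent-unit scale
    delta_acq = ((100.0 * gt.mt_delta) - site.mt_b) / site.mt_a / 100.0

    volumes: dict[str, AcquisitionVolume] = {}
    for contrast in CONTRASTS:
        proto = protocols[contrast]
        alpha = proto.flip_rad * field_maps.f_transmit
        if site.spoiling is not None:
            coeffs = site.spoiling.coefficients(proto.tr_s)
            if coeffs is not None:
                alpha = np.polyval(list(coeffs)[::-1], alpha)
        delta = delta_acq if contrast == "MTw" else 0.0
        echoes = np.empty(gt.shape + (proto.n_echoes,))
        for e, te in enumerate(proto.te_s):
            clean = _forward_signal(gt, proto, alpha, delta, forward, te)
            echoes[..., e] = _add_noise(clean * field_maps.receive,
                                        sigma, site.noise, nrng)
        volumes[contrast] = AcquisitionVolume(echoes, proto)

    # head/body-coil calibration pair (PDw-like, TE ~2.2 ms, flip 6 deg
    # unless a fault injects another setting)
    cal_proto = with_deviation(protocols["PDw"], contrast="PDw",
                               flip_deg=cal_flip_deg, te_ms=(2.2,))
    crng = _rng(seed, _TAG_CAL)
    clean = _forward_signal(gt, cal_proto, cal_proto.flip_rad * field_maps.f_transmit,
                            0.0, forward, cal_proto.te_s[0])
    lowres = lambda v: ndimage.gaussian_filter(v, sigma=1.0)  # noqa: E731
    body = _add_noise(lowres(clean), sigma, site.noise, crng)
    head = _add_noise(lowres(clean * field_maps.receive), sigma, site.noise, crng)
    cal_meta = {"flip_deg": cal_proto.flip_deg, "te_ms": list(cal_proto.te_ms)}
    calib_body = AcquisitionVolume(body[..., None], cal_proto, meta=dict(cal_meta))
    calib_head = AcquisitionVolume(head[..., None], cal_proto, meta=dict(cal_meta))

    meta = {
        "site": site.site_id, "vendor": site.vendor, "seed": int(seed),
        "noise": site.noise, "noise_sigma": sigma, "forward": forward,
        "mt_a_true": site.mt_a, "mt_b_true": site.mt_b,
        "protocols": {c: _protocol_meta(protocols[c]) for c in CONTRASTS},
        "calibration": dict(cal_meta),
        "deviations": [],
    }
    if meta_extra:
        meta.update(meta_extra)
    return SessionData(volumes, field_maps, calib_head, calib_body, meta)


def _protocol_meta(p: ProtocolSpec) -> dict:
    d = {
        "contrast": p.contrast, "vendor": p.vendor, "tr_ms": p.tr_ms,
        "flip_deg": p.flip_deg, "te_ms": list(p.te_ms),
        "spoil_phase_deg": p.spoil_phase_deg,
    }
    if p.mt_pulse is not None:
        d["mt_pulse"] = {
            "angle_deg": p.mt_pulse.angle_deg, "duration_ms": p.mt_pulse.duration_ms,
            "offset_khz": p.mt_pulse.offset_khz, "shape": p.mt_pulse.shape,
        }
    return d


# ---------------------------------------------------------------------------
# protocol deviations
# ---------------------------------------------------------------------------

def _resolve(meta: dict, dotted: str):
    """Walk a dotted path into nested dicts; return (parent, leaf key)."""
    parts = dotted.split(".")
    node = meta
    for p in parts[:-1]:
        if not isinstance(node, dict) or p not in node:
            raise KeyError(f"unknown metadata field {dotted!r}")
        node = node[p]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise KeyError(f"unknown metadata field {dotted!r}")
    return node, parts[-1]


def inject_protocol_deviation(meta: dict, deviation: Mapping[str, tuple] | None) -> dict:
    """Return a copy of session metadata with the stated perturbations.

    ``deviation`` maps dotted field paths (e.g. ``protocols.PDw.te_ms``,
    ``calibration.flip_deg``) to ``("scale", factor)`` or ``("set", value)``
    actions. An empty or None deviation is the identity. Every applied
    perturbation is recorded under ``meta["deviations"]`` so the study
    manifest can flag the session for QC tests.
    """
    out = copy.deepcopy(meta)
    if not deviation:
        return out
    for dotted, (op, value) in deviation.items():
        parent, key = _resolve(out, dotted)
        if op == "scale":
            old = parent[key]
            parent[key] = (
                [v * value for v in old] if isinstance(old, (list, tuple)) else old * value
            )
        elif op == "set":
            parent[key] = value
        else:
            raise ValueError(f"unknown deviation op {op!r}")
        out.setdefault("deviations", []).append(
            {"field": dotted, "op": op, "value": value}
        )
    return out


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------

class Study:
    """Handle to a (re)generatable synthetic study.

    Sessions are produced lazily and deterministically from the design's
    master seed, so a 60-session study never needs to sit in memory at
    once. Ground truths are cached per subject.
    """

    def __init__(self, design: StudyDesign):
        self.design = design
        self._gt: dict[int, GroundTruth] = {}

    def ground_truth(self, subject: int) -> GroundTruth:
        if subject not in self._gt:
            d = self.design
            self._gt[subject] = make_ground_truth(
                d.shape, seed=_rng(d.seed, _TAG_GT, subject),
                voxel_mm=d.voxel_mm,
                value_jitter=d.subject_jitter,
                texture_amplitude=d.texture_amplitude,
            )
        return self._gt[subject]

    def _session_deviation(self, subject, site_id, scan) -> dict | None:
        dev = {}
        for d in self.design.deviations:
            if (d.get("subject", subject) == subject
                    and d.get("site", site_id) == site_id
                    and d.get("scan", scan) == scan):
                dev[d["field"]] = (d["op"], d["value"])
        return dev or None

    def session(self, subject: int, site_id: str, scan: int) -> SessionData:
        d = self.design
        site = d.site(site_id)
        site_idx = [s.site_id for s in d.sites].index(site_id)
        gt = self.ground_truth(subject)

        # site x subject fields: fixed across the scan-rescan pair
        frng = _rng(d.seed, _TAG_FIELDS, subject, site_idx)
        fields = FieldMaps(
            make_smooth_field(d.shape, site.ft_amplitude, site.ft_lengthscale, frng),
            make_smooth_field(d.shape, site.s_amplitude, site.s_lengthscale, frng),
            source="simulated-truth",
        )
        protocols = vendor_protocols(site.vendor)
        cal_flip = 6.0
        deviation = self._session_deviation(subject, site_id, scan)
        if deviation:
            protocols, cal_changes = _apply_protocol_deviation(protocols, deviation)
            if "flip_deg" in cal_changes:
                op, value = cal_changes["flip_deg"]
                cal_flip = cal_flip * value if op == "scale" else value
        # scan-specific noise stream: fields are shared, noise is not
        sess = simulate_session(
            gt, site, protocols,
            seed=int(_rng(d.seed, _TAG_NOISE, subject, site_idx, scan).integers(2**31)),
            field_maps=fields, forward=d.forward, cal_flip_deg=cal_flip,
            meta_extra={"subject": subject, "scan": scan},
        )
        if deviation:
            # the sidecar already reflects the deviated acquisition; only
            # record what was injected so the manifest can flag the session
            sess.meta["deviations"] = [
                {"field": f, "op": op, "value": v}
                for f, (op, v) in sorted(deviation.items())
            ]
        return sess

    def iter_index(self) -> Iterator[tuple[int, str, int]]:
        d = self.design
        for subject in range(1, d.n_subjects + 1):
            for site in d.sites:
                for scan in range(1, d.scans_per_site + 1):
                    yield subject, site.site_id, scan

    def manifest(self) -> "pd.DataFrame":  # noqa: F821 (lazy import)
        import pandas as pd

        rows = []
        for subject, site_id, scan in self.iter_index():
            site = self.design.site(site_id)
            dev = self._session_deviation(subject, site_id, scan)
            rows.append({
                "subject": subject, "site": site_id, "scan": scan,
                "vendor": site.vendor, "seed": self.design.seed,
                "deviations": ";".join(sorted(dev)) if dev else "",
            })
        return pd.DataFrame(rows)


def _apply_protocol_deviation(protocols, deviation):
    """Apply deviations that change the actual acquisition (not just the
    sidecar): echo-time scalings and flip-angle changes of the weighted
    scans. Calibration-volume deviations are handled separately."""
    protocols = dict(protocols)
    cal = {}
    for dotted, (op, value) in deviation.items():
        parts = dotted.split(".")
        if parts[0] == "protocols" and len(parts) == 3:
            c, fld = parts[1], parts[2]
            p = protocols[c]
            if fld == "te_ms":
                new = tuple(t * value for t in p.te_ms) if op == "scale" else tuple(value)
                protocols[c] = with_deviation(p, te_ms=new)
            elif fld in ("flip_deg", "tr_ms", "spoil_phase_deg"):
                new = getattr(p, fld) * value if op == "scale" else value
                protocols[c] = with_deviation(p, **{fld: new})
        elif parts[0] == "calibration":
            cal[parts[-1]] = (op, value)
    return protocols, cal


def simulate_study(design: StudyDesign, out_dir=None) -> Study:
    """Materialise a study; optionally write the NIfTI/JSON/TSV tree.

    With ``out_dir`` given, writes one directory per session containing the
    three weighted volumes with JSON sidecars, the field maps, the
    calibration pair, per-subject ground-truth maps and tissue
    probabilities, and a top-level TSV manifest. Regeneration from the same
    design and seed is byte-identical.
    """
    study = Study(design)
    if out_dir is not None:
        from . import io as mio

        mio.write_study(study, out_dir)
    return study
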