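"""File formats, metadata validation and study trees.

Volumes travel as NIfTI-1 (.nii or .nii.gz) with one JSON sidecar each
(BIDS-like naming: ``<stem>.json`` next to ``<stem>.nii.gz``; documented,
not claimed BIDS-compliant). Angles are stored in degrees and times in
milliseconds, the MRI metadata convention; parsing converts to SI.
Sidecars validate against a pydantic schema; the JSON-Schema document is
exported by :func:`sidecar_schema`. Gzip members are written with a fixed
mtime, so regenerating a study from the same seed is byte-identical.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .phantom import SessionData, SiteEffect, Study, StudyDesign
from .protocols import CONTRASTS, MTPulse, ProtocolSpec
from .volumes import AcquisitionVolume, FieldMaps

__all__ = [
    "SidecarMetadata",
    "sidecar_schema",
    "read_volume",
    "write_volume",
    "write_study",
    "load_session",
    "load_design",
    "dump_design",
]


class MTPulseMeta(BaseModel):
    angle_deg: float
    duration_ms: float
    offset_khz: float
    shape: str


class SidecarMetadata(BaseModel):
    """Per-volume acquisition metadata (the JSON sidecar contract)."""

    contrast: str
    vendor: str
    site: str = ""
    subject: int = 0
    scan: int = 0
    tr_ms: float = Field(gt=0)
    flip_deg: float = Field(gt=0, lt=90)
    te_ms: list[float]
    spoil_phase_deg: float = 0.0
    mt_pulse: MTPulseMeta | None = None
    seed: int = 0

    @field_validator("te_ms")
    @classmethod
    def _te_increasing(cls, v):
        if not v or any(b <= a for a, b in zip(v, v[1:])) or v[0] <= 0:
            raise ValueError("te_ms must be positive and strictly increasing")
        return v

    def to_protocol(self) -> ProtocolSpec:
        pulse = None
        if self.mt_pulse is not None:
            pulse = MTPulse(self.mt_pulse.angle_deg, self.mt_pulse.duration_ms,
                            self.mt_pulse.offset_khz, self.mt_pulse.shape)
        return ProtocolSpec(
            contrast=self.contrast, vendor=self.vendor, tr_ms=self.tr_ms,
            flip_deg=self.flip_deg, te_ms=tuple(self.te_ms),
            spoil_phase_deg=self.spoil_phase_deg, mt_pulse=pulse,
        )


def sidecar_schema() -> dict:
    """JSON-Schema document for the sidecar contract."""
    return SidecarMetadata.model_json_schema()


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    raise ValueError(f"not a NIfTI path: {path}")


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None,
                 sidecar: dict | None = None) -> Path:
    """Write a NIfTI volume (deterministic gzip) and optional JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)
    img.set_data_dtype(np.asarray(data).dtype)
    raw = img.to_bytes()
    if path.name.endswith(".nii.gz"):
        path.write_bytes(gzip.compress(raw, mtime=0))
    else:
        path.write_bytes(raw)
    if sidecar is not None:
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_volume(path, require_sidecar: bool = False):
    """Read a NIfTI volume; returns (data, affine, sidecar-dict-or-None)."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    sc_path = _sidecar_path(path)
    sidecar = None
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    elif require_sidecar:
        raise FileNotFoundError(f"missing sidecar {sc_path}")
    return data, img.affine, sidecar


def _volume_sidecar(vol: AcquisitionVolume, meta: dict) -> dict:
    p = vol.protocol
    sc = SidecarMetadata(
        contrast=p.contrast, vendor=p.vendor,
        site=meta.get("site", ""), subject=meta.get("subject", 0),
        scan=meta.get("scan", 0),
        tr_ms=p.tr_ms, flip_deg=vol.meta.get("flip_deg", p.flip_deg),
        te_ms=list(vol.meta.get("te_ms", p.te_ms)),
        spoil_phase_deg=p.spoil_phase_deg,
        mt_pulse=None if p.mt_pulse is None else MTPulseMeta(
            angle_deg=p.mt_pulse.angle_deg, duration_ms=p.mt_pulse.duration_ms,
            offset_khz=p.mt_pulse.offset_khz, shape=p.mt_pulse.shape,
        ),
        seed=meta.get("seed", 0),
    )
    return sc.model_dump()


# ---------------------------------------------------------------------------
# study trees
# ---------------------------------------------------------------------------

def _session_dir(root: Path, subject: int, site: str, scan: int) -> Path:
    return root / f"sub-{subject:02d}" / f"site-{site}" / f"scan-{scan}"


def write_session(out_dir, session: SessionData, affine: np.ndarray) -> None:
    out_dir = Path(out_dir)
    names = {"MTw": "mtw", "PDw": "pdw", "T1w": "t1w"}
    for contrast, vol in session.volumes.items():
        write_volume(out_dir / f"{names[contrast]}.nii.gz", vol.data, affine,
                     _volume_sidecar(vol, session.meta))
    write_volume(out_dir / "b1map.nii.gz", session.fields.f_transmit, affine)
    write_volume(out_dir / "sens_body.nii.gz", session.calib_body.data[..., 0],
                 affine, _volume_sidecar(session.calib_body, session.meta))
    write_volume(out_dir / "sens_head.nii.gz", session.calib_head.data[..., 0],
                 affine, _volume_sidecar(session.calib_head, session.meta))
    write_volume(out_dir / "receive_truth.nii.gz", session.fields.receive, affine)
    (out_dir / "session.json").write_text(
        json.dumps(session.meta, indent=1, sort_keys=True)
    )


def write_study(study: Study, out_dir) -> Path:
    """Write the full subject/site/scan NIfTI+JSON tree plus TSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = study.design
    affine = np.diag([d.voxel_mm] * 3 + [1.0])

    for subject in range(1, d.n_subjects + 1):
        gt = study.ground_truth(subject)
        gdir = out_dir / f"sub-{subject:02d}" / "ground_truth"
        write_volume(gdir / "mt_pu.nii.gz", 100.0 * gt.mt_delta, affine)
        write_volume(gdir / "pd_pu.nii.gz", gt.pd, affine)
        write_volume(gdir / "r1.nii.gz", gt.r1, affine)
        write_volume(gdir / "r2s.nii.gz", gt.r2s, affine)
        write_volume(gdir / "labels.nii.gz", gt.labels.astype(np.int16), affine)
        for tissue, prob in gt.probabilities.items():
            write_volume(gdir / f"prob_{tissue}.nii.gz", prob, affine)

    for subject, site, scan in study.iter_index():
        sess = study.session(subject, site, scan)
        write_session(_session_dir(out_dir, subject, site, scan), sess, affine)

    study.manifest().to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    (out_dir / "sidecar.schema.json").write_text(
        json.dumps(sidecar_schema(), indent=1)
    )
    dump_design(d, out_dir / "study.yaml")
    return out_dir


def load_session(session_dir):
    """Load one written session back into volumes + fields + metadata.

    Returns (volumes dict, f_transmit, (calib_head, calib_body), meta).
    All volumes of a session must share the affine (strict check).
    """
    session_dir = Path(session_dir)
    names = {"MTw": "mtw", "PDw": "pdw", "T1w": "t1w"}
    volumes: dict[str, AcquisitionVolume] = {}
    affines = []
    for contrast, stem in names.items():
        data, affine, sidecar = read_volume(
            session_dir / f"{stem}.nii.gz", require_sidecar=True
        )
        meta = SidecarMetadata(**sidecar)
        volumes[contrast] = AcquisitionVolume(data, meta.to_protocol(),
                                              affine, dict(sidecar))
        affines.append(affine)
    ft, affine, _ = read_volume(session_dir / "b1map.nii.gz")
    affines.append(affine)
    calib = []
    for stem in ("sens_head", "sens_body"):
        data, affine, sidecar = read_volume(session_dir / f"{stem}.nii.gz")
        affines.append(affine)
        proto = SidecarMetadata(**sidecar).to_protocol() if sidecar else \
            volumes["PDw"].protocol
        calib.append(AcquisitionVolume(data[..., None], proto,
                                       affine, dict(sidecar or {})))
    for a in affines[1:]:
        if not np.allclose(a, affines[0]):
            raise ValueError(f"affine mismatch within session {session_dir}")
    meta = json.loads((session_dir / "session.json").read_text()) \
        if (session_dir / "session.json").exists() else {}
    return volumes, ft, tuple(calib), meta


# ---------------------------------------------------------------------------
# study design (YAML round trip)
# ---------------------------------------------------------------------------

def dump_design(design: StudyDesign, path) -> None:
    doc = {
        "n_subjects": design.n_subjects,
        "scans_per_site": design.scans_per_site,
        "shape": list(design.shape),
        "voxel_mm": design.voxel_mm,
        "seed": design.seed,
        "subject_jitter": design.subject_jitter,
        "texture_amplitude": design.texture_amplitude,
        "forward": design.forward,
        "deviations": design.deviations,
        "sites": [
            {
                "site_id": s.site_id, "vendor": s.vendor,
                "mt_a": s.mt_a, "mt_b": s.mt_b, "snr": s.snr,
                "noise_sigma": s.noise_sigma, "noise": s.noise,
                "ft_amplitude": s.ft_amplitude, "ft_lengthscale": s.ft_lengthscale,
                "s_amplitude": s.s_amplitude, "s_lengthscale": s.s_lengthscale,
            }
            for s in design.sites
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_design(path) -> StudyDesign:
    doc = yaml.safe_load(Path(path).read_text())
    sites = [SiteEffect(**s) for s in doc.pop("sites", [])]
    doc["shape"] = tuple(doc.get("shape", (48, 48, 48)))
    kwargs = {k: v for k, v in doc.items() if k in StudyDesign.__dataclass_fields__}
    if sites:
        kwargs["sites"] = sites
    return StudyDesign(**kwargs)
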