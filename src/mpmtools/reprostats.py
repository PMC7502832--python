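"""Scan-rescan and cross-site reproducibility statistics.

Voxel-wise coefficients of variation (CoV) quantify precision: the
intra-site CoV is the sample SD of the scan-rescan pair over its mean, the
inter-site CoV the sample SD over all scans of one subject across all
sites over their mean. The site-specific relative bias compares each
site's scan-rescan mean against the across-site mean. ROI and study-level
summaries aggregate these voxel fields by their root-mean-square (RMS),
and a subgroup table regroups sites (e.g. by vendor). Sample SDs use the
n-1 denominator throughout, so a 90/110 scan-rescan pair gives
CoV = 14.14%.

A protocol QC checker compares session metadata field-by-field against the
reference protocol, mirroring the post-hoc acquisition-parameter
consistency check of multicenter studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cov_intra",
    "cov_inter",
    "site_bias",
    "rms_aggregate",
    "build_tissue_masks",
    "RoiSet",
    "ReproReport",
    "compute_report",
    "subgroup_summary",
    "qc_check",
    "Deviation",
]


def _common_mask(*fields) -> np.ndarray:
    """Voxels where every contributing map is valid (intersection masking)."""
    mask = np.ones(np.asarray(fields[0]).shape, bool)
    for f in fields:
        mask &= np.isfinite(np.asarray(f))
    return mask


def cov_intra(map_scan, map_rescan):
    """Voxel-wise scan-rescan coefficient of variation.

    mu = (x1 + x2)/2, sigma = sample SD with the n-1 denominator
    (= |x1 - x2|/sqrt(2)), CoV = sigma/mu. Voxels with mu <= 0 or any
    invalid input are NaN. Returns (cov, sigma, mu).
    """
    x1 = np.asarray(map_scan, dtype=float)
    x2 = np.asarray(map_rescan, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("scan and rescan maps must share a grid")
    ok = _common_mask(x1, x2)
    mu = np.where(ok, (x1 + x2) / 2.0, np.nan)
    sigma = np.where(ok, np.abs(x1 - x2) / np.sqrt(2.0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(ok & (mu > 0), sigma / mu, np.nan)
    return cov, sigma, mu


def cov_inter(maps: Sequence[np.ndarray]):
    """Voxel-wise CoV across all scans of one subject (all sites).

    Sample SD (n-1) over the provided maps divided by their mean; with two
    maps this equals :func:`cov_intra` on the pair. Returns
    (cov, sigma, mu).
    """
    if len(maps) < 2:
        raise ValueError("cov_inter needs at least 2 maps")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    ok = np.all(np.isfinite(stack), axis=0)
    mu = np.where(ok, stack.mean(axis=0), np.nan)
    sigma = np.where(ok, stack.std(axis=0, ddof=1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(ok & (mu > 0), sigma / mu, np.nan)
    return cov, sigma, mu


def site_bias(mu_by_site: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Site-specific relative bias fields.

    Delta_site = mu_intra(site) / mean-over-sites(mu_intra) - 1; the mean
    over sites of Delta is 0 at every voxel by construction. Voxels where
    the across-site mean is ~0 or any site is invalid are NaN.
    """
    if len(mu_by_site) < 2:
        raise ValueError("site_bias needs at least 2 sites")
    stack = np.stack([np.asarray(m, dtype=float) for m in mu_by_site.values()])
    ok = np.all(np.isfinite(stack), axis=0)
    grand = stack.mean(axis=0)
    ok &= np.abs(grand) > 1e-12 * np.nanmax(np.abs(grand), initial=1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            site: np.where(ok, np.asarray(m, dtype=float) / grand - 1.0, np.nan)
            for site, m in mu_by_site.items()
        }


def rms_aggregate(field: np.ndarray, roi_mask: np.ndarray | None = None) -> float:
    """Root-mean-square of a voxel field over an ROI (NaN voxels excluded)."""
    field = np.asarray(field, dtype=float)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, bool)
        if field.shape != roi_mask.shape:
            raise ValueError("field and ROI mask must share a grid")
        if not roi_mask.any():
            raise ValueError("empty ROI mask")
        field = field[roi_mask]
    vals = field[np.isfinite(field)]
    if vals.size == 0:
        raise ValueError("no finite voxels to aggregate")
    return float(np.sqrt(np.mean(vals**2)))


@dataclass
class RoiSet:
    """Named binary region masks on the common grid."""

    masks: dict[str, np.ndarray]
    source: str = "supplied"

    def __post_init__(self) -> None:
        self.masks = {k: np.asarray(v, bool) for k, v in self.masks.items()}
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")

    def items(self):
        return self.masks.items()

    def __getitem__(self, name):
        return self.masks[name]


def build_tissue_masks(
    probability_maps: Mapping[str, Sequence[np.ndarray]],
    threshold: float = 0.95,
) -> RoiSet:
    """Average tissue probabilities across scans/sites, then binarise.

    For each tissue, the supplied probability maps (e.g. one per site and
    scan) are averaged and thresholded strictly (> threshold), yielding a
    unified conservative mask. 0.95 is the convention for analysis masks,
    0.99 for harmonization masks.
    """
    masks = {}
    for tissue, maps in probability_maps.items():
        stack = np.stack([np.asarray(m, dtype=float) for m in maps])
        if stack.min() < 0 or stack.max() > 1:
            raise ValueError(f"{tissue}: probabilities must lie in [0, 1]")
        mask = stack.mean(axis=0) > threshold
        if not mask.any():
            raise ValueError(
                f"tissue {tissue!r}: no voxels above threshold {threshold}"
            )
        masks[tissue] = mask
    return RoiSet(masks, source="tissue-threshold")


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

@dataclass
class ReproReport:
    """Voxel-level reproducibility fields plus aggregation helpers.

    Fields are keyed by (metric, subject, site) for the intra-site CoV and
    bias, and (metric, subject) for the inter-site CoV. ``roi_table``
    aggregates each field by its RMS over ROI voxels into a tidy
    long-format frame (one row per metric x subject x site x ROI x
    statistic).
    """

    metrics: list[str]
    subjects: list[int]
    sites: list[str]
    cov_intra_fields: dict = dfield(default_factory=dict)
    cov_inter_fields: dict = dfield(default_factory=dict)
    bias_fields: dict = dfield(default_factory=dict)

    def roi_table(self, rois) -> pd.DataFrame:
        """RMS aggregation per ROI; ``rois`` is a RoiSet shared by all
        subjects or a mapping subject -> RoiSet (per-subject anatomy)."""
        rows = []

        def roi_items(subject):
            return (rois[subject] if isinstance(rois, Mapping) else rois).items()

        def add(metric, subject, site, roi, stat, field, mask):
            sel = np.asarray(field)[mask]
            sel = sel[np.isfinite(sel)]
            if sel.size:
                rows.append({
                    "metric": metric, "subject": subject, "site": site,
                    "roi": roi, "statistic": stat,
                    "value": float(np.sqrt(np.mean(sel**2))),
                    "n_voxels": int(sel.size),
                })

        for (metric, subject, site), f in self.cov_intra_fields.items():
            for roi, mask in roi_items(subject):
                add(metric, subject, site, roi, "cov_intra", f, mask)
        for (metric, subject, site), f in self.bias_fields.items():
            for roi, mask in roi_items(subject):
                add(metric, subject, site, roi, "bias", f, mask)
        for (metric, subject), f in self.cov_inter_fields.items():
            for roi, mask in roi_items(subject):
                add(metric, subject, "", roi, "cov_inter", f, mask)
        return pd.DataFrame(rows)

    def summary(self, rois) -> pd.DataFrame:
        """Study-level RMS across ROIs, subjects and sites per statistic."""
        table = self.roi_table(rois)
        return (
            table.groupby(["metric", "statistic"])["value"]
            .apply(lambda v: float(np.sqrt(np.mean(np.square(v)))))
            .reset_index(name="rms")
        )


def compute_report(
    maps: Mapping[tuple[str, int, str, int], np.ndarray],
    metrics: Sequence[str],
    subjects: Sequence[int],
    sites: Sequence[str],
    scans: Sequence[int] = (1, 2),
) -> ReproReport:
    """Build the full reproducibility report from per-session maps.

    ``maps`` is keyed by (metric, subject, site, scan). For every metric
    and subject: the intra-site CoV per site from its scan-rescan pair,
    the inter-site CoV across all scans of all sites, and the per-site
    bias from the scan-rescan means. Inter-site quantities use
    intersection masking across everything they combine.
    """
    report = ReproReport(list(metrics), list(subjects), list(sites))
    scans = list(scans)
    for metric in metrics:
        for subject in subjects:
            mu_by_site = {}
            all_scans = []
            for site in sites:
                pair = [maps[(metric, subject, site, s)] for s in scans]
                all_scans.extend(pair)
                if len(pair) == 2:
                    cov, _, mu = cov_intra(*pair)
                else:
                    cov, _, mu = cov_inter(pair)
                report.cov_intra_fields[(metric, subject, site)] = cov
                mu_by_site[site] = mu
            cov, _, _ = cov_inter(all_scans)
            report.cov_inter_fields[(metric, subject)] = cov
            for site, delta in site_bias(mu_by_site).items():
                report.bias_fields[(metric, subject, site)] = delta
    return report


def subgroup_summary(
    report: ReproReport,
    grouping: Mapping[str, Sequence[str]],
    rois: RoiSet,
) -> pd.DataFrame:
    """Summaries per site subgroup (e.g. per vendor).

    For each named subset of sites, the RMS of CoV_intra, CoV_inter and
    bias over the ROI masks, subjects, and the subset's sites. Per-site
    bias stays relative to the full-study across-site mean. The inter-site
    CoV has no site index, so it is the same for any grouping and is
    reported for context.
    """
    for name, subset in grouping.items():
        unknown = set(subset) - set(report.sites)
        if unknown:
            raise KeyError(f"group {name!r} references unknown sites {sorted(unknown)}")
        if not subset:
            raise ValueError(f"group {name!r} is empty")
    table = report.roi_table(rois)
    rows = []
    for name, subset in grouping.items():
        sub = table[
            table["site"].isin(list(subset)) | (table["statistic"] == "cov_inter")
        ]
        for (metric, stat), grp in sub.groupby(["metric", "statistic"]):
            rows.append({
                "group": name, "metric": metric, "statistic": stat,
                "rms": float(np.sqrt(np.mean(np.square(grp["value"])))),
                "n": int(len(grp)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protocol QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deviation:
    """One detected protocol deviation."""

    field: str
    expected: object
    found: object
    relative: float


def _iter_leaves(node, prefix=""):
    if isinstance(node, Mapping):
        for k, v in node.items():
            yield from _iter_leaves(v, f"{prefix}{k}." if prefix else f"{k}.")
    else:
        yield prefix[:-1], node


def qc_check(
    session_meta: Mapping,
    reference: Mapping,
    tolerance: float = 0.01,
) -> list[Deviation]:
    """Field-by-field comparison of session metadata against the reference.

    Every leaf of the reference document is looked up in the session
    metadata (dotted paths); numeric values are compared with a relative
    tolerance, sequences elementwise, strings exactly. Returns the list of
    deviations exceeding tolerance; an identical session yields [].
    """
    session_leaves = dict(_iter_leaves(session_meta))
    deviations = []
    for path, expected in _iter_leaves(reference):
        if path not in session_leaves:
            deviations.append(Deviation(path, expected, None, np.inf))
            continue
        found = session_leaves[path]
        if isinstance(expected, (int, float)) and not isinstance(expected, bool):
            if not isinstance(found, (int, float)):
                deviations.append(Deviation(path, expected, found, np.inf))
                continue
            denom = abs(expected) if expected != 0 else 1.0
            rel = abs(found - expected) / denom
            if rel > tolerance:
                deviations.append(Deviation(path, expected, found, float(rel)))
        elif isinstance(expected, (list, tuple)):
            f = list(found) if isinstance(found, (list, tuple)) else [found]
            e = list(expected)
            if len(f) != len(e):
                deviations.append(Deviation(path, expected, found, np.inf))
                continue
            rels = [
                abs(fv - ev) / (abs(ev) if ev else 1.0)
                for fv, ev in zip(f, e)
                if isinstance(ev, (int, float)) and isinstance(fv, (int, float))
            ]
            rel = max(rels, default=0.0)
            if rel > tolerance or f != e and not rels:
                deviations.append(Deviation(path, expected, found, float(rel)))
        else:
            if found != expected:
                deviations.append(Deviation(path, expected, found, np.inf))
    return deviations
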