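"""Consistency and accuracy statistics built on pairwise ΔE00.

Two comparison protocols recur throughout card validation:

* *pairwise within a set* — k replicate measurements of the same physical
  patches (phone-sensor repeatability, sticker-to-sticker printing
  consistency, intra-site capture stability) are compared patch-by-patch
  over all k(k−1)/2 unordered pairs;
* *versus ground truth* — measured patch means are compared to the
  palette's reference CIELAB values.

Aggregates are flat means over all patches and pairs jointly, so a
10-image set over 26 patches yields 45 pairs per patch and 1170 ΔE00
values in total.
"""

from __future__ import annotations

import enum
import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .card_model import Palette, PatchMeasurements
from .colorspace import delta_e_2000

__all__ = [
    "ComparisonKind",
    "DeltaEReport",
    "Site",
    "SiteStudy",
    "pairwise_report",
    "ground_truth_report",
    "site_consistency",
]


class ComparisonKind(str, enum.Enum):
    PAIRWISE_WITHIN_SET = "pairwise_within_set"
    VS_GROUND_TRUTH = "vs_ground_truth"


@dataclass
class DeltaEReport:
    """Per-patch ΔE00 values and their flat aggregates."""

    per_patch: dict[int, list[float]]
    comparison_kind: ComparisonKind

    @property
    def values(self) -> np.ndarray:
        if not self.per_patch:
            return np.array([])
        return np.concatenate([np.asarray(v, dtype=float) for v in self.per_patch.values()])

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": pid, "pair_index": i, "delta_e00": v}
            for pid, vals in sorted(self.per_patch.items())
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "comparison_kind": self.comparison_kind.value,
            "mean": self.mean,
            "max": self.max,
            "sd": self.sd,
            "n_values": self.n_values,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


@dataclass
class Site:
    label: str
    color_temp_K: int
    images: list[PatchMeasurements]


@dataclass
class SiteStudy:
    """A multi-location capture study (several replicate images per site)."""

    sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        for site in self.sites:
            if len(site.images) < 2:
                raise ValueError(
                    f"site {site.label!r} needs >= 2 images for intra-site statistics"
                )


def _common_ids(sets: list[PatchMeasurements]) -> list[int]:
    ids = sets[0].ids
    for m in sets[1:]:
        if m.ids != ids:
            raise ValueError("patch id coverage differs between measurement sets")
    return ids


def pairwise_report(sets: list[PatchMeasurements]) -> DeltaEReport:
    """ΔE00 between every unordered pair of measurement sets, per patch.

    k sets produce k(k−1)/2 values per patch id.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 measurement sets for pairwise comparison")
    ids = _common_ids(sets)
    labs = np.stack([m.lab_array(ids) for m in sets])  # k × P × 3
    per_patch: dict[int, list[float]] = {pid: [] for pid in ids}
    for i, j in itertools.combinations(range(len(sets)), 2):
        d = delta_e_2000(labs[i], labs[j])
        for pid, v in zip(ids, np.atleast_1d(d)):
            per_patch[pid].append(float(v))
    return DeltaEReport(per_patch=per_patch, comparison_kind=ComparisonKind.PAIRWISE_WITHIN_SET)


def ground_truth_report(
    sets: list[PatchMeasurements] | PatchMeasurements, palette: Palette
) -> DeltaEReport:
    """ΔE00 of each measured patch mean against its palette reference."""
    if isinstance(sets, PatchMeasurements):
        sets = [sets]
    if not sets:
        raise ValueError("no measurement sets given")
    ids = _common_ids(sets)
    missing = set(ids) - set(palette.ids)
    if missing:
        raise ValueError(f"palette has no reference for patch ids {sorted(missing)}")
    refs = palette.ref_lab_array(ids)
    per_patch: dict[int, list[float]] = {pid: [] for pid in ids}
    for m in sets:
        d = delta_e_2000(m.lab_array(ids), refs)
        for pid, v in zip(ids, np.atleast_1d(d)):
            per_patch[pid].append(float(v))
    return DeltaEReport(per_patch=per_patch, comparison_kind=ComparisonKind.VS_GROUND_TRUTH)


def _mean_measurements(images: list[PatchMeasurements], label: str) -> PatchMeasurements:
    """Average the replicate images of one site into a site-level measurement."""
    from .colorspace import LabColor

    ids = _common_ids(images)
    labs = np.stack([m.lab_array(ids) for m in images]).mean(axis=0)
    return PatchMeasurements(
        mean_lab={pid: LabColor(*map(float, labs[k])) for k, pid in enumerate(ids)},
        pixel_count={pid: sum(m.pixel_count[pid] for m in images) for pid in ids},
        channel_sd={pid: np.zeros(3) for pid in ids},
        instance_means={pid: [] for pid in ids},
        source_image_id=label,
    )


@dataclass
class SiteConsistencyResult:
    intra_site: dict[str, DeltaEReport]
    intra_site_grand_mean: float
    inter_site: DeltaEReport
    vs_truth: dict[str, DeltaEReport]

    def table(self) -> pd.DataFrame:
        """Per-site summary: intra-site mean, mean/max from ground truth, SD."""
        rows = []
        for label in self.intra_site:
            gt = self.vs_truth[label]
            rows.append(
                {
                    "site": label,
                    "intra_site_mean": self.intra_site[label].mean,
                    "gt_mean": gt.mean,
                    "gt_max": gt.max,
                    "gt_sd": gt.sd,
                }
            )
        return pd.DataFrame(rows)


def site_consistency(
    study: SiteStudy,
    palette: Palette,
    inter_site_on_site_means: bool = True,
) -> SiteConsistencyResult:
    """Intra-site, inter-site and versus-ground-truth consistency statistics.

    Intra-site: pairwise ΔE00 within each site's replicate images (the
    grand mean averages the per-site means).  Inter-site: pairwise ΔE00
    across sites; by default each site is first collapsed to its mean
    patch colors (``inter_site_on_site_means=False`` pairs individual
    images across sites instead).  vs_truth: each site's images against
    the palette references.
    """
    if len(study.sites) < 2:
        raise ValueError("inter-site statistics require >= 2 sites")
    intra = {s.label: pairwise_report(s.images) for s in study.sites}
    grand = float(np.mean([r.mean for r in intra.values()]))
    if inter_site_on_site_means:
        site_means = [_mean_measurements(s.images, s.label) for s in study.sites]
        inter = pairwise_report(site_means)
    else:
        all_images = [m for s in study.sites for m in s.images]
        within = set()
        offset = 0
        for s in study.sites:
            k = len(s.images)
            within.update(
                (offset + i, offset + j) for i, j in itertools.combinations(range(k), 2)
            )
            offset += k
        ids = _common_ids(all_images)
        labs = np.stack([m.lab_array(ids) for m in all_images])
        per_patch: dict[int, list[float]] = {pid: [] for pid in ids}
        for i, j in itertools.combinations(range(len(all_images)), 2):
            if (i, j) in within:
                continue
            d = delta_e_2000(labs[i], labs[j])
            for pid, v in zip(ids, np.atleast_1d(d)):
                per_patch[pid].append(float(v))
        inter = DeltaEReport(per_patch=per_patch, comparison_kind=ComparisonKind.PAIRWISE_WITHIN_SET)
    vs_truth = {s.label: ground_truth_report(s.images, palette) for s in study.sites}
    return SiteConsistencyResult(
        intra_site=intra,
        intra_site_grand_mean=grand,
        inter_site=inter,
        vs_truth=vs_truth,
    )
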