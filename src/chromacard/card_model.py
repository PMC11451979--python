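"""Reference card model: palette, layout geometry, patch extraction, mirror QC.

The card carries 26 logical reference colors: 24 chromatic/grayscale
patches spanning the print gamut plus a black and a white reference that
extend the brightness range.  Each of the 24 colors is printed twice, at
positions that are mirror images across both card axes (equivalently a
180° rotation about the center), so that a local illumination fault —
glare or shadow hitting one corner — shows up as a color divergence
between the two instances of the same ink.  The black/white references
are printed once each, giving 50 physical patches.

The palette's published CIELAB values are defined under the D50 print
illuminant.  The bundled default palette is a synthetic stand-in built
from the classic 24-patch ColorChecker chart values plus pure black and
white extremes; real deployments supply their measured palette as JSON.
"""

from __future__ import annotations

import enum
import json
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .colorspace import (
    Encoding,
    ImageF32,
    LabColor,
    WhitePoint,
    delta_e_2000,
    linear_rgb_array_to_lab,
    srgb_to_linear,
)

__all__ = [
    "PatchRole",
    "PaletteEntry",
    "Palette",
    "Rect",
    "CardLayout",
    "PatchMeasurements",
    "ValidationError",
    "load_palette",
    "load_layout",
    "default_palette",
    "default_layout",
    "extract_patches",
    "patch_mask",
    "mirror_divergence",
]

N_PATCHES = 26


class PatchRole(str, enum.Enum):
    CHROMATIC = "chromatic"
    GRAYSCALE = "grayscale"
    BLACK_REF = "black_ref"
    WHITE_REF = "white_ref"


class ValidationError(ValueError):
    """Schema/invariant violations; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class PaletteEntry:
    id: int
    name: str
    lab_ref: LabColor
    role: PatchRole


@dataclass
class Palette:
    """The 26 logical reference colors and the mirrored-duplication map."""

    patches: list[PaletteEntry]
    mirrored_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        problems = []
        if len(self.patches) != N_PATCHES:
            problems.append(f"palette must have {N_PATCHES} patches, got {len(self.patches)}")
        ids = [p.id for p in self.patches]
        if len(set(ids)) != len(ids):
            problems.append("duplicate patch ids")
        for role in (PatchRole.BLACK_REF, PatchRole.WHITE_REF):
            n = sum(1 for p in self.patches if p.role is role)
            if n != 1:
                problems.append(f"palette must have exactly one {role.value}, got {n}")
        bad = set(self.mirrored_ids) - set(ids)
        if bad:
            problems.append(f"mirrored_ids reference unknown ids {sorted(bad)}")
        if problems:
            raise ValidationError(problems)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.patches]

    @property
    def mirror_pairs(self) -> list[tuple[int, int]]:
        """Each mirrored logical color paired with itself (its two instances)."""
        return [(i, i) for i in self.mirrored_ids]

    def entry(self, patch_id: int) -> PaletteEntry:
        for p in self.patches:
            if p.id == patch_id:
                return p
        raise KeyError(patch_id)

    def ref_lab_array(self, ids: list[int] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else ids
        return np.array([self.entry(i).lab_ref.as_array() for i in ids])

    def white_id(self) -> int:
        return next(p.id for p in self.patches if p.role is PatchRole.WHITE_REF)

    def black_id(self) -> int:
        return next(p.id for p in self.patches if p.role is PatchRole.BLACK_REF)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in normalized card coordinates, half-open."""

    x0: float
    y0: float
    x1: float
    y1: float

    def rotate180(self) -> "Rect":
        return Rect(1.0 - self.x1, 1.0 - self.y1, 1.0 - self.x0, 1.0 - self.y0)

    def shrunk(self, frac: float) -> "Rect":
        dx = (self.x1 - self.x0) * frac
        dy = (self.y1 - self.y0) * frac
        return Rect(self.x0 + dx, self.y0 + dy, self.x1 - dx, self.y1 - dy)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def in_unit_square(self) -> bool:
        return 0.0 <= self.x0 < self.x1 <= 1.0 and 0.0 <= self.y0 < self.y1 <= 1.0


@dataclass
class CardLayout:
    """Normalized geometry of the card's patch regions and sample wells.

    ``patch_regions`` holds the primary instance of each logical patch;
    ids listed in ``mirrored_ids`` additionally have a second instance at
    the 180°-rotated position (exact reflection across both axes).
    """

    patch_regions: dict[int, Rect]
    well_regions: list[Rect]
    card_aspect: float
    mirrored_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        problems = []
        rects = []
        for pid, rect in sorted(self.patch_regions.items()):
            for inst in self.instance_rects(pid):
                if not inst.in_unit_square():
                    problems.append(f"patch {pid} region outside unit square")
                rects.append((pid, inst))
        for w, rect in enumerate(self.well_regions):
            if not rect.in_unit_square():
                problems.append(f"well {w} region outside unit square")
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if rects[i][1].overlaps(rects[j][1]):
                    problems.append(
                        f"patch regions {rects[i][0]} and {rects[j][0]} overlap"
                    )
        if len(self.well_regions) != 6:
            problems.append(f"layout must have 6 well regions, got {len(self.well_regions)}")
        if self.card_aspect <= 0:
            problems.append("card_aspect must be positive")
        if problems:
            raise ValidationError(problems)

    def instance_rects(self, patch_id: int) -> list[Rect]:
        rect = self.patch_regions[patch_id]
        if patch_id in self.mirrored_ids:
            return [rect, rect.rotate180()]
        return [rect]


@dataclass
class PatchMeasurements:
    """Per-patch CIELAB statistics measured from one card image."""

    mean_lab: dict[int, LabColor]
    pixel_count: dict[int, int]
    channel_sd: dict[int, np.ndarray]
    instance_means: dict[int, list[np.ndarray]]
    source_image_id: str = ""

    @property
    def ids(self) -> list[int]:
        return sorted(self.mean_lab)

    def lab_array(self, ids: list[int] | None = None) -> np.ndarray:
        ids = self.ids if ids is None else ids
        return np.array([self.mean_lab[i].as_array() for i in ids])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid in self.ids:
            lab = self.mean_lab[pid]
            sd = self.channel_sd[pid]
            rows.append(
                {
                    "id": pid,
                    "L": lab.L,
                    "a": lab.a,
                    "b": lab.b,
                    "n": self.pixel_count[pid],
                    "sdL": sd[0],
                    "sda": sd[1],
                    "sdb": sd[2],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON schemas


def _palette_from_dict(doc: dict) -> Palette:
    problems = []
    patches = []
    for raw in doc.get("patches", []):
        try:
            lab = raw["lab_ref"]
            patches.append(
                PaletteEntry(
                    id=int(raw["id"]),
                    name=str(raw.get("name", f"patch-{raw['id']}")),
                    lab_ref=LabColor(float(lab[0]), float(lab[1]), float(lab[2])),
                    role=PatchRole(raw["role"]),
                )
            )
        except (KeyError, ValueError, TypeError, IndexError) as exc:
            problems.append(f"malformed patch entry {raw!r}: {exc}")
    if problems:
        raise ValidationError(problems)
    return Palette(patches=patches, mirrored_ids=[int(i) for i in doc.get("mirrored_ids", [])])


def load_palette(path: str | os.PathLike) -> Palette:
    """Load and validate a palette JSON file."""
    with open(path) as fh:
        return _palette_from_dict(json.load(fh))


def save_palette(palette: Palette, path: str | os.PathLike) -> None:
    doc = {
        "patches": [
            {
                "id": p.id,
                "name": p.name,
                "lab_ref": [p.lab_ref.L, p.lab_ref.a, p.lab_ref.b],
                "role": p.role.value,
            }
            for p in palette.patches
        ],
        "mirrored_ids": palette.mirrored_ids,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _rect_from_list(v) -> Rect:
    return Rect(float(v[0]), float(v[1]), float(v[2]), float(v[3]))


def _layout_from_dict(doc: dict) -> CardLayout:
    problems = []
    regions = {}
    for key, v in doc.get("patch_regions", {}).items():
        try:
            regions[int(key)] = _rect_from_list(v)
        except (ValueError, TypeError, IndexError) as exc:
            problems.append(f"malformed patch region {key}: {exc}")
    wells = []
    for v in doc.get("well_regions", []):
        try:
            wells.append(_rect_from_list(v))
        except (ValueError, TypeError, IndexError) as exc:
            problems.append(f"malformed well region {v!r}: {exc}")
    if problems:
        raise ValidationError(problems)
    return CardLayout(
        patch_regions=regions,
        well_regions=wells,
        card_aspect=float(doc.get("card_aspect", 0.6)),
        mirrored_ids=[int(i) for i in doc.get("mirrored_ids", [])],
    )


def load_layout(path: str | os.PathLike) -> CardLayout:
    """Load and validate a card layout JSON file."""
    with open(path) as fh:
        return _layout_from_dict(json.load(fh))


def save_layout(layout: CardLayout, path: str | os.PathLike) -> None:
    doc = {
        "patch_regions": {
            str(pid): [r.x0, r.y0, r.x1, r.y1]
            for pid, r in layout.patch_regions.items()
        },
        "well_regions": [[r.x0, r.y0, r.x1, r.y1] for r in layout.well_regions],
        "card_aspect": layout.card_aspect,
        "mirrored_ids": layout.mirrored_ids,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def default_palette() -> Palette:
    """The bundled stand-in palette (ColorChecker gamut + black/white extremes)."""
    text = resources.files("chromacard.data").joinpath("palette_default.json").read_text()
    return _palette_from_dict(json.loads(text))


def default_layout() -> CardLayout:
    """The bundled symmetric 4-column layout with 6 central sample wells."""
    text = resources.files("chromacard.data").joinpath("layout_default.json").read_text()
    return _layout_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Patch extraction


def _rect_to_slices(rect: Rect, shape: tuple[int, int]) -> tuple[slice, slice]:
    h, w = shape
    r0 = int(round(rect.y0 * h))
    r1 = int(round(rect.y1 * h))
    c0 = int(round(rect.x0 * w))
    c1 = int(round(rect.x1 * w))
    return slice(r0, r1), slice(c0, c1)


def patch_mask(
    layout: CardLayout,
    shape: tuple[int, int],
    shrink: float = 0.2,
    ids: list[int] | None = None,
) -> np.ndarray:
    """Boolean H×W mask covering the (shrunken) patch instances."""
    mask = np.zeros(shape, dtype=bool)
    for pid in ids if ids is not None else sorted(layout.patch_regions):
        for inst in layout.instance_rects(pid):
            rs, cs = _rect_to_slices(inst.shrunk(shrink), shape)
            mask[rs, cs] = True
    return mask


def _to_lab_pixels(img: ImageF32) -> np.ndarray:
    if img.encoding is Encoding.CIELAB:
        return np.asarray(img.pixels, dtype=np.float64)
    if img.encoding is Encoding.SRGB_ENCODED:
        img = srgb_to_linear(img)
    return linear_rgb_array_to_lab(img.pixels, WhitePoint.D50)


def extract_patches(
    img: ImageF32,
    layout: CardLayout,
    shrink: float = 0.2,
    pool_mirrored: bool = True,
    source_image_id: str = "",
) -> PatchMeasurements:
    """Measure per-patch CIELAB mean/SD from a rectified card image.

    Each patch rectangle is shrunk toward its center by ``shrink`` per
    side to avoid edge bleed before pixels are pooled.  With
    ``pool_mirrored`` (default) the two physical instances of a mirrored
    color are pooled into one measurement; per-instance means are always
    retained for divergence QC.
    """
    if not 0.0 <= shrink < 0.5:
        raise ValueError("shrink must be in [0, 0.5)")
    lab = _to_lab_pixels(img)
    h, w = lab.shape[:2]
    mean_lab, pixel_count, channel_sd, instance_means = {}, {}, {}, {}
    for pid in sorted(layout.patch_regions):
        chunks = []
        means = []
        for inst in layout.instance_rects(pid):
            rs, cs = _rect_to_slices(inst.shrunk(shrink), (h, w))
            pix = lab[rs, cs].reshape(-1, 3)
            if pix.shape[0] == 0:
                raise ValueError(
                    f"patch {pid}: region empty after shrink={shrink} "
                    f"at image size {w}×{h}"
                )
            chunks.append(pix)
            means.append(pix.mean(axis=0))
        pooled = (
            np.concatenate(chunks, axis=0) if pool_mirrored else chunks[0]
        )
        m = pooled.mean(axis=0)
        mean_lab[pid] = LabColor(float(m[0]), float(m[1]), float(m[2]))
        pixel_count[pid] = int(pooled.shape[0])
        channel_sd[pid] = pooled.std(axis=0, ddof=0)
        instance_means[pid] = means
    return PatchMeasurements(
        mean_lab=mean_lab,
        pixel_count=pixel_count,
        channel_sd=channel_sd,
        instance_means=instance_means,
        source_image_id=source_image_id,
    )


# ---------------------------------------------------------------------------
# Mirror divergence QC


@dataclass
class MirrorDivergenceReport:
    pair_delta_e: dict[int, float]
    flagged: list[int]
    flag_threshold: float

    @property
    def uncorrectable(self) -> bool:
        """Any flagged pair signals a local illumination fault (glare or
        shadow) that color transfer alone cannot repair."""
        return len(self.flagged) > 0


def mirror_divergence(
    m: PatchMeasurements,
    palette: Palette,
    flag_threshold: float = 3.0,
) -> MirrorDivergenceReport:
    """ΔE00 between the two mirrored instances of each duplicated color.

    Under uniform illumination both prints of an ink measure alike; a
    divergence above ``flag_threshold`` (default 3.0, the close-examination
    perceptibility bound) at any pair flags the image as suffering a local
    illumination fault.
    """
    pair_delta_e = {}
    flagged = []
    for pid in palette.mirrored_ids:
        if pid not in m.instance_means:
            raise ValueError(f"mirrored patch {pid} not measured")
        insts = m.instance_means[pid]
        if len(insts) < 2:
            raise ValueError(f"patch {pid} has a single measured instance")
        d = float(delta_e_2000(insts[0], insts[1]))
        pair_delta_e[pid] = d
        if d > flag_threshold:
            flagged.append(pid)
    return MirrorDivergenceReport(
        pair_delta_e=pair_delta_e, flagged=flagged, flag_threshold=flag_threshold
    )
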