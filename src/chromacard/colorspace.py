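"""Color encodings, conversions and the CIEDE2000 color difference.

Images are carried through the toolkit as :class:`ImageF32`: an H×W×3
float32 array tagged with its encoding (``srgb_encoded``, ``linear_rgb``
or ``cielab``) and reference white point.  Encoding transitions happen
only through the explicit conversion functions here, so a stage can never
silently reinterpret gamma-encoded values as linear ones.

The RGB↔Lab path is sRGB primaries → XYZ (D65) → Bradford chromatic
adaptation to the stated white point → CIELAB.  The card palettes used by
the rest of the package are defined under D50 (the print-industry design
illuminant), so D50 is the default white point throughout.

All per-pixel math is float32 with float64 accumulations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Encoding",
    "WhitePoint",
    "ImageF32",
    "LabColor",
    "DeltaEThresholds",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "lab_array_to_linear_rgb",
    "linear_rgb_array_to_lab",
    "delta_e_2000",
]


class Encoding(str, enum.Enum):
    SRGB_ENCODED = "srgb_encoded"
    LINEAR_RGB = "linear_rgb"
    CIELAB = "cielab"


class WhitePoint(str, enum.Enum):
    D50 = "D50"
    D65 = "D65"


# CIE XYZ of the standard illuminants (2° observer, Y normalized to 1).
WHITE_XYZ = {
    WhitePoint.D50: np.array([0.96422, 1.0, 0.82521]),
    WhitePoint.D65: np.array([0.95047, 1.0, 1.08883]),
}

# Linear sRGB (D65 primaries) -> XYZ.
_RGB_TO_XYZ_D65 = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Bradford cone response matrix for chromatic adaptation.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)


class EncodingError(ValueError):
    """Raised when an operation receives an image with the wrong encoding tag."""


@dataclass
class ImageF32:
    """A float32 RGB (or CIELAB-plane) image with an explicit encoding tag."""

    pixels: np.ndarray
    encoding: Encoding
    white_point: WhitePoint = WhitePoint.D50

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {self.pixels.shape}")
        self.encoding = Encoding(self.encoding)
        self.white_point = WhitePoint(self.white_point)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def require(self, encoding: Encoding) -> None:
        if self.encoding is not Encoding(encoding):
            raise EncodingError(
                f"operation requires {Encoding(encoding).value} image, "
                f"got {self.encoding.value}"
            )

    def copy(self) -> "ImageF32":
        return ImageF32(self.pixels.copy(), self.encoding, self.white_point)


@dataclass(frozen=True)
class LabColor:
    """A single CIELAB color with its reference white point."""

    L: float
    a: float
    b: float
    white_point: WhitePoint = WhitePoint.D50

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class DeltaEThresholds:
    """Conventional perceptibility bands for ΔE00 scores.

    ``imperceptible``: no perceptible difference; ``close_exam``: visible
    only under close examination; ``small``: small differences, the usual
    print-industry bound for solid ink patches; ``casual``: noticeable at
    a casual glance.
    """

    imperceptible: float = 1.0
    close_exam: float = 3.0
    small: float = 5.0
    casual: float = 8.0

    def __post_init__(self) -> None:
        seq = (self.imperceptible, self.close_exam, self.small, self.casual)
        if not all(x < y for x, y in zip(seq, seq[1:])):
            raise ValueError("thresholds must be strictly increasing")


# ---------------------------------------------------------------------------
# sRGB transfer function


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float32)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4).astype(
        np.float32
    )


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float32)
    return np.where(
        v <= 0.0031308, v * 12.92, 1.055 * np.maximum(v, 0.0) ** (1 / 2.4) - 0.055
    ).astype(np.float32)


def srgb_to_linear(img: ImageF32) -> ImageF32:
    """Decode an sRGB gamma-encoded image to linear RGB (the sRGB EOTF)."""
    img.require(Encoding.SRGB_ENCODED)
    return ImageF32(_srgb_decode(img.pixels), Encoding.LINEAR_RGB, img.white_point)


def linear_to_srgb(img: ImageF32) -> ImageF32:
    """Gamma-encode a linear RGB image with the sRGB OETF."""
    img.require(Encoding.LINEAR_RGB)
    return ImageF32(_srgb_encode(img.pixels), Encoding.SRGB_ENCODED, img.white_point)


# ---------------------------------------------------------------------------
# RGB <-> Lab


def _bradford_adaptation(src_white: np.ndarray, dst_white: np.ndarray) -> np.ndarray:
    """3×3 XYZ-space matrix adapting colors from src_white to dst_white."""
    rho_src = _BRADFORD @ src_white
    rho_dst = _BRADFORD @ dst_white
    return np.linalg.inv(_BRADFORD) @ np.diag(rho_dst / rho_src) @ _BRADFORD


def _rgb_to_xyz_matrix(white_point: WhitePoint) -> np.ndarray:
    m = _RGB_TO_XYZ_D65
    if white_point is not WhitePoint.D65:
        m = _bradford_adaptation(WHITE_XYZ[WhitePoint.D65], WHITE_XYZ[white_point]) @ m
    return m


_LAB_DELTA = 6.0 / 29.0


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(
        t > _LAB_DELTA**3, np.cbrt(t), t / (3 * _LAB_DELTA**2) + 4.0 / 29.0
    )


def _lab_f_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(
        ft > _LAB_DELTA, ft**3, 3 * _LAB_DELTA**2 * (ft - 4.0 / 29.0)
    )


def _xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def _lab_to_xyz(lab: np.ndarray, white: np.ndarray) -> np.ndarray:
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack([_lab_f_inv(fx), _lab_f_inv(fy), _lab_f_inv(fz)], axis=-1) * white


def linear_rgb_array_to_lab(
    rgb: np.ndarray, white_point: WhitePoint = WhitePoint.D50
) -> np.ndarray:
    """Convert an (...,3) array of linear sRGB values to CIELAB under white_point."""
    white_point = WhitePoint(white_point)
    m = _rgb_to_xyz_matrix(white_point)
    xyz = np.asarray(rgb, dtype=np.float64) @ m.T
    return _xyz_to_lab(xyz, WHITE_XYZ[white_point])


def lab_array_to_linear_rgb(
    lab: np.ndarray, white_point: WhitePoint = WhitePoint.D50, clip: bool = True
) -> tuple[np.ndarray, int]:
    """Convert (...,3) CIELAB values back to linear sRGB.

    Returns the RGB array and the number of out-of-gamut components that
    were clipped to [0, 1] (0 when ``clip`` is False, in which case values
    are returned unclipped).
    """
    white_point = WhitePoint(white_point)
    xyz = _lab_to_xyz(np.asarray(lab, dtype=np.float64), WHITE_XYZ[white_point])
    m_inv = np.linalg.inv(_rgb_to_xyz_matrix(white_point))
    rgb = xyz @ m_inv.T
    n_clipped = 0
    if clip:
        oob = (rgb < 0.0) | (rgb > 1.0)
        n_clipped = int(np.count_nonzero(oob))
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb, n_clipped


def rgb_to_lab(img: ImageF32, white_point: WhitePoint = WhitePoint.D50) -> ImageF32:
    """Linear RGB image → CIELAB planes under the stated white point."""
    img.require(Encoding.LINEAR_RGB)
    lab = linear_rgb_array_to_lab(img.pixels, white_point)
    return ImageF32(lab.astype(np.float32), Encoding.CIELAB, WhitePoint(white_point))


def lab_to_rgb(img: ImageF32) -> tuple[ImageF32, int]:
    """CIELAB image → linear RGB; out-of-gamut components clipped and counted."""
    img.require(Encoding.CIELAB)
    rgb, n_clipped = lab_array_to_linear_rgb(img.pixels, img.white_point)
    return (
        ImageF32(rgb.astype(np.float32), Encoding.LINEAR_RGB, img.white_point),
        n_clipped,
    )


# ---------------------------------------------------------------------------
# CIEDE2000


def delta_e_2000(c1, c2) -> np.ndarray | float:
    """CIEDE2000 color difference (kL = kC = kH = 1).

    Accepts :class:`LabColor` pairs (white points must match) or
    broadcastable (...,3) Lab arrays; returns a scalar or array of ΔE00.
    The hue-angle conventions for degenerate chroma (h := 0 when C' = 0)
    follow the CIE technical report.
    """
    if isinstance(c1, LabColor) or isinstance(c2, LabColor):
        if not (isinstance(c1, LabColor) and isinstance(c2, LabColor)):
            raise TypeError("mix of LabColor and array arguments")
        if c1.white_point is not c2.white_point:
            raise ValueError(
                "white point mismatch: "
                f"{c1.white_point.value} vs {c2.white_point.value}"
            )
        return float(_ciede2000(c1.as_array(), c2.as_array()))
    return _ciede2000(np.asarray(c1, dtype=np.float64), np.asarray(c2, dtype=np.float64))


def _ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0.0, 0.0, h1p)
    h2p = np.where(C2p == 0.0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    out = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    if out.ndim == 0:
        return float(out)
    return out
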