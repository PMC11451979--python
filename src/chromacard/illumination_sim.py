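"""Synthetic card renderer and illumination degradation model.

Renders an ideal card image (every patch at its reference color under the
D50 design illuminant) and then degrades it the way a smartphone capture
under an uncontrolled light source would be degraded:

* a chromatic cast, modeled as a von Kries diagonal adaptation in linear
  RGB from the D50 white toward the Planckian white of the requested
  correlated color temperature (CCT);
* a global brightness scale (dim rooms);
* an optional linear shading ramp across the card (a window on one side);
* per-channel Gaussian sensor noise, seeded for reproducibility.

Planckian whites are computed by direct integration of Planck's law
against the CIE 1931 2° color-matching functions on a 5 nm grid over
380–780 nm.  The CMF table is built at import from the multi-lobe
piecewise-Gaussian analytic fit of Wyman, Sloan & Shirley (JCGT 2013),
which reproduces published Planckian-locus chromaticities to within
0.0011 over 3000–6500 K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .card_model import CardLayout, Palette, _rect_to_slices, extract_patches
from .colorspace import (
    Encoding,
    ImageF32,
    WhitePoint,
    lab_array_to_linear_rgb,
    linear_to_srgb,
    srgb_to_linear,
)
from .metrics_qc import SiteStudy, Site

__all__ = [
    "IlluminantSpec",
    "RenderSpec",
    "render_card",
    "cct_to_white",
    "cct_from_xy_mccamy",
    "simulate_illumination",
    "make_site_study",
    "DEFAULT_SITE_CCTS",
]

# The five-site study design: noon daylight, bright LED, halogen,
# incandescent and dim warm lighting.
DEFAULT_SITE_CCTS = (5800, 5000, 4000, 3000, 2700)

_WAVELENGTHS_NM = np.arange(380.0, 780.0 + 1e-9, 5.0)


def _piecewise_gauss(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def _cmf_1931(lam: np.ndarray) -> np.ndarray:
    """CIE 1931 2° color-matching functions (analytic multi-lobe fit)."""
    x = (
        1.056 * _piecewise_gauss(lam, 599.8, 37.9, 31.0)
        + 0.362 * _piecewise_gauss(lam, 442.0, 16.0, 26.7)
        - 0.065 * _piecewise_gauss(lam, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _piecewise_gauss(lam, 568.8, 46.9, 40.5) + 0.286 * _piecewise_gauss(
        lam, 530.9, 16.3, 31.1
    )
    z = 1.217 * _piecewise_gauss(lam, 437.0, 11.8, 36.0) + 0.681 * _piecewise_gauss(
        lam, 459.0, 26.0, 13.8
    )
    return np.stack([x, y, z], axis=-1)


_CMF_TABLE = _cmf_1931(_WAVELENGTHS_NM)  # static 81×3 table on the 5 nm grid


@dataclass(frozen=True)
class IlluminantSpec:
    """Parameters of one simulated capture condition."""

    cct_K: int = 5000
    brightness: float = 1.0
    noise_sd: float = 0.0
    gradient_axis: str = "x"
    gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1000 <= self.cct_K <= 20000:
            raise ValueError("cct_K must lie in [1000, 20000]")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")
        if self.noise_sd < 0 or self.gradient_amplitude < 0:
            raise ValueError("noise_sd and gradient_amplitude must be >= 0")
        if self.gradient_axis not in ("x", "y"):
            raise ValueError("gradient_axis must be 'x' or 'y'")


@dataclass(frozen=True)
class RenderSpec:
    """Pixel dimensions of the rendered card fixture."""

    width: int = 180
    height: int = 300
    background_gray: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("dimensions must be positive")


def render_card(
    palette: Palette, layout: CardLayout, spec: RenderSpec = RenderSpec()
) -> ImageF32:
    """Render the ideal card: every patch instance at its D50 reference color.

    The output is an sRGB-encoded image; out-of-gamut references are
    clipped.  Rendering is fully deterministic.
    """
    srgb_white = np.full((spec.height, spec.width, 3), spec.background_gray, dtype=np.float64)
    img = srgb_white
    for entry in palette.patches:
        rgb_lin, _ = lab_array_to_linear_rgb(entry.lab_ref.as_array(), WhitePoint.D50)
        srgb = np.where(
            rgb_lin <= 0.0031308,
            rgb_lin * 12.92,
            1.055 * np.maximum(rgb_lin, 0.0) ** (1 / 2.4) - 0.055,
        )
        for inst in layout.instance_rects(entry.id):
            rs, cs = _rect_to_slices(inst, (spec.height, spec.width))
            img[rs, cs] = srgb
    return ImageF32(
        np.clip(img, 0.0, 1.0).astype(np.float32),
        Encoding.SRGB_ENCODED,
        WhitePoint.D50,
    )


def cct_to_white(cct_K: float) -> tuple[float, float]:
    """CIE 1931 (x, y) chromaticity of the Planckian radiator at cct_K.

    Direct integration of Planck's law against the bundled CMF table.
    """
    if not 1000 <= cct_K <= 20000:
        raise ValueError("cct_K must lie in [1000, 20000]")
    h = 6.62607015e-34
    c = 2.99792458e8
    kB = 1.380649e-23
    lam = _WAVELENGTHS_NM * 1e-9
    radiance = (2 * h * c**2 / lam**5) / np.expm1(h * c / (lam * kB * cct_K))
    xyz = (_CMF_TABLE * radiance[:, None]).sum(axis=0)
    s = xyz.sum()
    return float(xyz[0] / s), float(xyz[1] / s)


def cct_from_xy_mccamy(x: float, y: float) -> float:
    """McCamy's cubic approximation of CCT from (x, y) — used as an
    independent inverse check on :func:`cct_to_white`."""
    n = (x - 0.3320) / (0.1858 - y)
    return 449.0 * n**3 + 3525.0 * n**2 + 6823.3 * n + 5520.33


def _xy_to_linear_srgb(x: float, y: float) -> np.ndarray:
    """Linear sRGB (D65-referenced primaries) of a white with chromaticity (x,y), Y=1."""
    xyz = np.array([x / y, 1.0, (1.0 - x - y) / y])
    m = np.array(
        [
            [3.2404542, -1.5371385, -0.4985314],
            [-0.9692660, 1.8760108, 0.0415560],
            [0.0556434, -0.2040259, 1.0572252],
        ]
    )
    return m @ xyz


# Reference (undegraded) white: the Planckian point at the D50 design CCT,
# so a 5003 K illuminant spec is exactly the identity degradation.  (Exact
# D50 sits on the daylight locus, a hair off the blackbody curve.)
_D50_DESIGN_CCT = 5003.0


def simulate_illumination(img: ImageF32, spec: IlluminantSpec) -> ImageF32:
    """Degrade an sRGB-encoded card image under the given illuminant.

    Applies, in linear RGB: the von Kries diagonal cast from D50 toward
    the Planckian white at ``spec.cct_K`` (gains normalized so no channel
    exceeds 1 — a colored light dims, it does not add energy), the
    brightness scale, the optional shading ramp, and seeded Gaussian
    noise; then clips and re-encodes.  Deterministic for a fixed seed.
    """
    img.require(Encoding.SRGB_ENCODED)
    lin = srgb_to_linear(img).pixels.astype(np.float64)

    target = _xy_to_linear_srgb(*cct_to_white(spec.cct_K))
    ref = _xy_to_linear_srgb(*cct_to_white(_D50_DESIGN_CCT))
    gains = target / ref
    gains = gains / gains.max()
    lin = lin * gains

    lin *= spec.brightness

    if spec.gradient_amplitude > 0:
        h, w = lin.shape[:2]
        if spec.gradient_axis == "x":
            ramp = np.linspace(-0.5, 0.5, w)[None, :, None]
        else:
            ramp = np.linspace(-0.5, 0.5, h)[:, None, None]
        lin = lin * (1.0 + spec.gradient_amplitude * ramp)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        lin = lin + rng.normal(0.0, spec.noise_sd, size=lin.shape)

    lin = np.clip(lin, 0.0, 1.0).astype(np.float32)
    return linear_to_srgb(ImageF32(lin, Encoding.LINEAR_RGB, img.white_point))


def make_site_study(
    palette: Palette,
    layout: CardLayout,
    ccts: tuple[int, ...] = DEFAULT_SITE_CCTS,
    images_per_site: int = 3,
    noise_sd: float = 0.004,
    brightness: tuple[float, ...] | None = None,
    gradient_amplitude: float = 0.0,
    seed: int = 0,
    render_spec: RenderSpec = RenderSpec(),
    correct_fn=None,
    shrink: float = 0.2,
) -> SiteStudy:
    """Render and degrade the multi-site capture study, then measure patches.

    Mirrors the five-location design (daylight 5800 K down to dim 2700 K,
    three replicate captures per location).  ``noise_sd`` (default 0.004
    in linear RGB units) models shot/read noise at a realistic handheld
    exposure; ``correct_fn``, when given, is applied to each degraded
    image (e.g. the correction pipeline) before measurement.
    """
    if brightness is None:
        brightness = tuple(1.0 for _ in ccts)
    base = render_card(palette, layout, render_spec)
    sites = []
    for s, (cct, bright) in enumerate(zip(ccts, brightness)):
        images = []
        for r in range(images_per_site):
            spec = IlluminantSpec(
                cct_K=cct,
                brightness=bright,
                noise_sd=noise_sd,
                gradient_amplitude=gradient_amplitude,
                seed=seed * 10007 + s * 101 + r,
            )
            degraded = simulate_illumination(base, spec)
            if correct_fn is not None:
                degraded = correct_fn(degraded)
            images.append(
                extract_patches(
                    degraded, layout, shrink=shrink,
                    source_image_id=f"site{s}_cct{cct}_rep{r}",
                )
            )
        sites.append(Site(label=f"{cct}K", color_temp_K=cct, images=images))
    return SiteStudy(sites=sites)
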