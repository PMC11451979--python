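"""The four-stage color-correction pipeline.

Stage order: white balance → masked MVGD color transfer → per-channel
histogram regression via dynamically selected non-linear interpolated
LUTs (DNIL) → a second MVGD pass.

*White balance* scales the linear-RGB channels by a diagonal gain so the
card's known white reference measures neutral.

*MVGD* is the closed-form optimal-transport map between two Gaussians:
with source/target sample moments (μs, Σs) and (μt, Σt) in CIELAB,

    T = Σs^(−1/2) (Σs^(1/2) Σt Σs^(1/2))^(1/2) Σs^(−1/2),
    x ↦ T (x − μs) + μt.

Only pixels inside the patch masks contribute to the fit (the masking
contract), but the fitted map is applied to every pixel of the card.

*DNIL* equates per-channel empirical CDFs: for each source value V1 the
LUT returns the target value V2 with F1(V1) = F2(V2), sampled on a
256-point quantile grid in 32-bit float.  Several interpolants are
built through the knot pairs and the one maximizing an objective
(default: negative mean ΔE00 of corrected patch means against the
palette references) is kept per channel.

The pipeline refits patch statistics from the current image state
between stages and reports the per-stage mean/max ΔE00 to ground truth.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator, UnivariateSpline

from .card_model import (
    CardLayout,
    Palette,
    PatchMeasurements,
    _rect_to_slices,
    extract_patches,
    mirror_divergence,
)
from .colorspace import (
    Encoding,
    ImageF32,
    WhitePoint,
    delta_e_2000,
    lab_array_to_linear_rgb,
    linear_rgb_array_to_lab,
    linear_to_srgb,
    srgb_to_linear,
)

__all__ = [
    "WhiteBalanceGain",
    "MvgdTransform",
    "ChannelLUT",
    "DnilConfig",
    "PipelineConfig",
    "TransferModel",
    "StageReport",
    "PipelineReport",
    "fit_white_balance",
    "apply_white_balance",
    "fit_mvgd",
    "apply_mvgd",
    "fit_dnil",
    "run_pipeline",
]

INTERPOLANTS = ("piecewise_linear", "monotone_cubic", "smoothing_spline")

# CIELAB channel bounds used to clamp LUT extrapolation.
LAB_BOUNDS = ((0.0, 100.0), (-128.0, 128.0), (-128.0, 128.0))


# ---------------------------------------------------------------------------
# White balance


@dataclass(frozen=True)
class WhiteBalanceGain:
    """Diagonal per-channel gains in linear RGB."""

    gains: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gains):
            raise ValueError("white-balance gains must be positive")


def fit_white_balance(
    measured_white_linear: np.ndarray,
    reference_white_linear: np.ndarray = np.ones(3),
    eps: float = 1e-4,
) -> WhiteBalanceGain:
    """Gains sending the measured white patch to the reference white.

    ``measured_white_linear`` is the mean linear-RGB color of the card's
    white reference patch; near-zero channels mean the exposure is too
    dark for the white patch to carry information.
    """
    measured = np.asarray(measured_white_linear, dtype=float)
    if measured.shape != (3,):
        raise ValueError("measured white must be a 3-vector")
    if np.any(measured <= eps):
        raise ValueError(
            f"white patch unusable: measured linear RGB {measured} has a channel <= {eps}"
        )
    gains = np.asarray(reference_white_linear, dtype=float) / measured
    return WhiteBalanceGain(gains=tuple(float(g) for g in gains))


def apply_white_balance(
    img: ImageF32, g: WhiteBalanceGain
) -> tuple[ImageF32, int]:
    """Channel-wise multiply in linear RGB; returns image and clipped count."""
    img.require(Encoding.LINEAR_RGB)
    out = img.pixels.astype(np.float64) * np.asarray(g.gains)
    n_clipped = int(np.count_nonzero(out > 1.0) + np.count_nonzero(out < 0.0))
    out = np.clip(out, 0.0, 1.0)
    return ImageF32(out.astype(np.float32), Encoding.LINEAR_RGB, img.white_point), n_clipped


# ---------------------------------------------------------------------------
# MVGD transfer


@dataclass
class MvgdTransform:
    """Gaussian optimal-transport map fitted between CIELAB samples."""

    mu_src: np.ndarray
    mu_tgt: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.mu_src = np.asarray(self.mu_src, dtype=float).reshape(3)
        self.mu_tgt = np.asarray(self.mu_tgt, dtype=float).reshape(3)
        self.T = np.asarray(self.T, dtype=float).reshape(3, 3)

    @classmethod
    def identity(cls) -> "MvgdTransform":
        return cls(np.zeros(3), np.zeros(3), np.eye(3))


def _sqrtm_psd(m: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(m)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fit_mvgd(
    src_pixels: np.ndarray, tgt_pixels: np.ndarray, reg_lambda: float = 1e-4
) -> MvgdTransform:
    """Closed-form Gaussian transport map from source to target moments.

    Sample covariances are regularized by +λI before the matrix roots are
    taken, which keeps the map well defined for nearly degenerate (e.g.
    noise-free synthetic) samples.
    """
    src = np.asarray(src_pixels, dtype=np.float64)
    tgt = np.asarray(tgt_pixels, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or tgt.ndim != 2 or tgt.shape[1] != 3:
        raise ValueError("samples must be N×3 arrays")
    if src.shape[0] < 4 or tgt.shape[0] < 4:
        raise ValueError("need at least 4 samples on each side")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise ValueError("non-finite values in input samples")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    cov_s = np.cov(src, rowvar=False, ddof=0) + reg_lambda * np.eye(3)
    cov_t = np.cov(tgt, rowvar=False, ddof=0) + reg_lambda * np.eye(3)
    s_half = _sqrtm_psd(cov_s)
    s_half_inv = np.linalg.inv(s_half)
    middle = _sqrtm_psd(s_half @ cov_t @ s_half)
    T = s_half_inv @ middle @ s_half_inv
    T = 0.5 * (T + T.T)  # enforce exact symmetry against roundoff
    return MvgdTransform(mu_src=mu_s, mu_tgt=mu_t, T=T)


def apply_mvgd(img: ImageF32, t: MvgdTransform) -> ImageF32:
    """Per-pixel affine map x ↦ T(x − μs) + μt in CIELAB."""
    img.require(Encoding.CIELAB)
    flat = img.pixels.reshape(-1, 3).astype(np.float64)
    out = (flat - t.mu_src) @ t.T.T + t.mu_tgt
    return ImageF32(
        out.reshape(img.pixels.shape).astype(np.float32), Encoding.CIELAB, img.white_point
    )


def apply_mvgd_array(x: np.ndarray, t: MvgdTransform) -> np.ndarray:
    return (np.asarray(x, dtype=np.float64) - t.mu_src) @ t.T.T + t.mu_tgt


# ---------------------------------------------------------------------------
# DNIL: histogram regression LUTs


@dataclass(frozen=True)
class DnilConfig:
    """Candidate interpolants and selection objective for DNIL."""

    candidates: tuple[str, ...] = INTERPOLANTS
    objective: str = "neg_mean_deltaE"
    n_quantiles: int = 256

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("candidate interpolant set must be non-empty")
        unknown = set(self.candidates) - set(INTERPOLANTS)
        if unknown:
            raise ValueError(f"unknown interpolants {sorted(unknown)}")


@dataclass
class ChannelLUT:
    """A monotone per-channel mapping through CDF-matched knot pairs."""

    knots_src: np.ndarray
    knots_tgt: np.ndarray
    interpolant: str
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        self.knots_src = np.asarray(self.knots_src, dtype=np.float64)
        self.knots_tgt = np.asarray(self.knots_tgt, dtype=np.float64)
        if self.knots_src.size >= 2 and np.any(np.diff(self.knots_src) <= 0):
            raise ValueError("knots_src must be strictly increasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        ks, kt = self.knots_src, self.knots_tgt
        if ks.size == 1:
            # constant-channel degenerate LUT: offset to the target value
            out = x + (kt[0] - ks[0])
            return np.clip(out, *self.bounds)
        if self.interpolant == "piecewise_linear":
            out = np.interp(x, ks, kt)
        elif self.interpolant == "monotone_cubic":
            out = PchipInterpolator(ks, kt, extrapolate=False)(x)
            out = np.where(np.isnan(out), 0.0, out)
        elif self.interpolant == "smoothing_spline":
            k = min(3, ks.size - 1)
            s = ks.size * 1e-4 * max(np.var(kt), 1e-12)
            spl = UnivariateSpline(ks, kt, k=k, s=s, ext="const")
            out = spl(x)
        else:
            raise ValueError(f"unknown interpolant {self.interpolant}")
        # linear extrapolation from the terminal knot slopes, then clamp
        lo_slope = self._edge_slope(0)
        hi_slope = self._edge_slope(-1)
        below = x < ks[0]
        above = x > ks[-1]
        out = np.where(below, kt[0] + lo_slope * (x - ks[0]), out)
        out = np.where(above, kt[-1] + hi_slope * (x - ks[-1]), out)
        return np.clip(out, *self.bounds)

    def _edge_slope(self, end: int) -> float:
        ks, kt = self.knots_src, self.knots_tgt
        if end == 0:
            d = (kt[1] - kt[0]) / (ks[1] - ks[0])
        else:
            d = (kt[-1] - kt[-2]) / (ks[-1] - ks[-2])
        return max(float(d), 0.0)

    def is_monotone(self, n_grid: int = 1024) -> bool:
        if self.knots_src.size < 2:
            return True
        grid = np.linspace(self.knots_src[0], self.knots_src[-1], n_grid)
        vals = self(grid)
        return bool(np.all(np.diff(vals) >= -1e-9))


def _cdf_match_knots(
    src: np.ndarray, tgt: np.ndarray, n_quantiles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-paired knots (V1, V2) with F1(V1) = F2(V2)."""
    q = np.linspace(0.0, 1.0, n_quantiles)
    v1 = np.quantile(src.astype(np.float32), q).astype(np.float64)
    v2 = np.quantile(tgt.astype(np.float32), q).astype(np.float64)
    # deduplicate source knots, averaging their paired targets
    uniq, inverse = np.unique(v1, return_inverse=True)
    v2_mean = np.zeros_like(uniq)
    counts = np.bincount(inverse)
    np.add.at(v2_mean, inverse, v2)
    v2_mean /= counts
    return uniq, v2_mean


def fit_dnil(
    src_channel: np.ndarray,
    tgt_channel: np.ndarray,
    cfg: DnilConfig,
    score_fn,
    bounds: tuple[float, float],
) -> ChannelLUT:
    """Build the CDF-matching LUT for one channel, selecting the interpolant.

    ``score_fn(lut)`` returns the objective value (higher is better); the
    argmax over ``cfg.candidates`` wins, with ties broken toward the
    earlier (simpler) candidate.  Interpolants whose evaluated map is not
    monotone over the knot range are rejected for this channel.
    """
    src = np.asarray(src_channel, dtype=np.float64).ravel()
    tgt = np.asarray(tgt_channel, dtype=np.float64).ravel()
    if src.size == 0 or tgt.size == 0:
        raise ValueError("empty channel sample")
    if np.ptp(src) < 1e-12:
        warnings.warn(
            "constant source channel; using identity-offset LUT to target median"
        )
        return ChannelLUT(
            knots_src=np.array([src[0]]),
            knots_tgt=np.array([float(np.median(tgt))]),
            interpolant="piecewise_linear",
            bounds=bounds,
        )
    ks, kt = _cdf_match_knots(src, tgt, cfg.n_quantiles)
    best: ChannelLUT | None = None
    best_score = -np.inf
    for name in INTERPOLANTS:
        if name not in cfg.candidates:
            continue
        lut = ChannelLUT(knots_src=ks, knots_tgt=kt, interpolant=name, bounds=bounds)
        if not lut.is_monotone():
            continue
        score = float(score_fn(lut))
        if score > best_score + 1e-12:
            best, best_score = lut, score
    if best is None:
        # every nonlinear candidate failed monotonicity; fall back to linear
        best = ChannelLUT(
            knots_src=ks, knots_tgt=kt, interpolant="piecewise_linear", bounds=bounds
        )
    return best


# ---------------------------------------------------------------------------
# Transfer model and full pipeline


@dataclass
class TransferModel:
    """The fitted correction stages, serializable and re-applicable."""

    wb: WhiteBalanceGain
    mvgd1: MvgdTransform
    luts: list[ChannelLUT] | None
    mvgd2: MvgdTransform
    source_image_id: str = ""
    palette_id: str = ""

    def apply(self, img: ImageF32) -> ImageF32:
        """Re-apply the frozen stages (no refitting) to an sRGB image."""
        img.require(Encoding.SRGB_ENCODED)
        lin = srgb_to_linear(img)
        lin, _ = apply_white_balance(lin, self.wb)
        lab = ImageF32(
            linear_rgb_array_to_lab(lin.pixels).astype(np.float32),
            Encoding.CIELAB,
            WhitePoint.D50,
        )
        lab = apply_mvgd(lab, self.mvgd1)
        if self.luts is not None:
            pix = lab.pixels.astype(np.float64)
            for c, lut in enumerate(self.luts):
                pix[..., c] = lut(pix[..., c])
            lab = ImageF32(pix.astype(np.float32), Encoding.CIELAB, WhitePoint.D50)
        lab = apply_mvgd(lab, self.mvgd2)
        rgb, _ = lab_array_to_linear_rgb(lab.pixels)
        return linear_to_srgb(
            ImageF32(rgb.astype(np.float32), Encoding.LINEAR_RGB, WhitePoint.D50)
        )

    def to_dict(self) -> dict:
        return {
            "wb_gains": list(self.wb.gains),
            "mvgd1": {
                "mu_src": self.mvgd1.mu_src.tolist(),
                "mu_tgt": self.mvgd1.mu_tgt.tolist(),
                "T": self.mvgd1.T.tolist(),
            },
            "luts": None
            if self.luts is None
            else [
                {
                    "knots_src": l.knots_src.tolist(),
                    "knots_tgt": l.knots_tgt.tolist(),
                    "interpolant": l.interpolant,
                    "bounds": list(l.bounds),
                }
                for l in self.luts
            ],
            "mvgd2": {
                "mu_src": self.mvgd2.mu_src.tolist(),
                "mu_tgt": self.mvgd2.mu_tgt.tolist(),
                "T": self.mvgd2.T.tolist(),
            },
            "source_image_id": self.source_image_id,
            "palette_id": self.palette_id,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, doc: dict) -> "TransferModel":
        return cls(
            wb=WhiteBalanceGain(gains=tuple(doc["wb_gains"])),
            mvgd1=MvgdTransform(**doc["mvgd1"]),
            luts=None
            if doc["luts"] is None
            else [
                ChannelLUT(
                    knots_src=np.array(l["knots_src"]),
                    knots_tgt=np.array(l["knots_tgt"]),
                    interpolant=l["interpolant"],
                    bounds=tuple(l["bounds"]),
                )
                for l in doc["luts"]
            ],
            mvgd2=MvgdTransform(**doc["mvgd2"]),
            source_image_id=doc.get("source_image_id", ""),
            palette_id=doc.get("palette_id", ""),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the correction pipeline."""

    shrink: float = 0.2
    dnil: DnilConfig = field(default_factory=DnilConfig)
    use_dnil: bool = True
    bit_depth: int = 32
    reg_lambda: float = 1e-4
    mirror_flag_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 32):
            raise ValueError("bit_depth must be 8 or 32")


@dataclass
class StageReport:
    stage: str
    mean_delta_e: float
    max_delta_e: float


@dataclass
class PipelineReport:
    stages: list[StageReport]
    mirror_flags: list[int]
    uncorrectable_warning: bool
    clipped_pixels: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s.stage, "mean_delta_e00": s.mean_delta_e, "max_delta_e00": s.max_delta_e}
                for s in self.stages
            ],
            "mirror_flags": self.mirror_flags,
            "uncorrectable_warning": self.uncorrectable_warning,
            "clipped_pixels": self.clipped_pixels,
        }


def _quantize(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """8-bit quantization of a channel range (ablation harness)."""
    t = (np.asarray(x, dtype=np.float64) - lo) / (hi - lo)
    return (np.round(np.clip(t, 0.0, 1.0) * 255.0) / 255.0) * (hi - lo) + lo


def _maybe_quantize_lab(pix: np.ndarray, bit_depth: int) -> np.ndarray:
    if bit_depth == 32:
        return pix
    out = np.empty_like(pix, dtype=np.float64)
    for c, (lo, hi) in enumerate(LAB_BOUNDS):
        out[..., c] = _quantize(pix[..., c], lo, hi)
    return out


def _masked_patch_pixels(
    lab_pixels: np.ndarray, layout: CardLayout, shrink: float
) -> dict[int, np.ndarray]:
    """Masked Lab pixels per logical patch (mirrored instances pooled)."""
    h, w = lab_pixels.shape[:2]
    out = {}
    for pid in sorted(layout.patch_regions):
        chunks = []
        for inst in layout.instance_rects(pid):
            rs, cs = _rect_to_slices(inst.shrunk(shrink), (h, w))
            chunks.append(lab_pixels[rs, cs].reshape(-1, 3))
        out[pid] = np.concatenate(chunks, axis=0)
    return out


def _stacked_src_tgt(
    patch_pixels: dict[int, np.ndarray], palette: Palette
) -> tuple[np.ndarray, np.ndarray]:
    """Masked source pixels and references replicated to pixel multiplicity."""
    srcs, tgts = [], []
    for pid, pix in patch_pixels.items():
        srcs.append(pix)
        ref = palette.entry(pid).lab_ref.as_array()
        tgts.append(np.broadcast_to(ref, pix.shape))
    return np.concatenate(srcs, axis=0), np.concatenate(tgts, axis=0)


def _patch_means(patch_pixels: dict[int, np.ndarray]) -> tuple[list[int], np.ndarray]:
    ids = sorted(patch_pixels)
    return ids, np.stack([patch_pixels[pid].mean(axis=0) for pid in ids])


def _stage_stats(
    lab_pixels: np.ndarray, layout: CardLayout, palette: Palette, shrink: float
) -> tuple[float, float]:
    pp = _masked_patch_pixels(lab_pixels, layout, shrink)
    ids, means = _patch_means(pp)
    refs = palette.ref_lab_array(ids)
    d = np.atleast_1d(delta_e_2000(means, refs))
    return float(d.mean()), float(d.max())


def run_pipeline(
    img: ImageF32,
    layout: CardLayout,
    palette: Palette,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[ImageF32, TransferModel, PipelineReport]:
    """Correct a rectified card photograph against its palette.

    Returns the corrected sRGB image, the fitted :class:`TransferModel`
    and a report with per-stage mean/max ΔE00 to the palette ground
    truth plus mirror-divergence QC flags.  A flagged mirror pair marks
    the image as suffering local illumination that color transfer alone
    cannot repair; the pipeline still runs and reports it.
    """
    img.require(Encoding.SRGB_ENCODED)
    clipped: dict[str, int] = {}
    stages: list[StageReport] = []

    # QC before any correction
    raw_measurements = extract_patches(img, layout, shrink=cfg.shrink)
    mirror = mirror_divergence(raw_measurements, palette, cfg.mirror_flag_threshold)

    lin = srgb_to_linear(img)

    # --- stage 0: uncorrected
    lab0 = linear_rgb_array_to_lab(lin.pixels)
    m, mx = _stage_stats(lab0, layout, palette, cfg.shrink)
    stages.append(StageReport("uncorrected", m, mx))

    # --- stage 1: white balance
    white_pix = _masked_patch_pixels(lin.pixels.astype(np.float64), layout, cfg.shrink)[
        palette.white_id()
    ]
    ref_white_lin, _ = lab_array_to_linear_rgb(
        palette.entry(palette.white_id()).lab_ref.as_array()
    )
    wb = fit_white_balance(white_pix.mean(axis=0), ref_white_lin)
    lin_wb, n_clip = apply_white_balance(lin, wb)
    clipped["white_balance"] = n_clip
    lin_pix = lin_wb.pixels.astype(np.float64)
    if cfg.bit_depth == 8:
        lin_pix = _quantize(lin_pix, 0.0, 1.0)
    lab = linear_rgb_array_to_lab(lin_pix)
    m, mx = _stage_stats(lab, layout, palette, cfg.shrink)
    stages.append(StageReport("white_balance", m, mx))

    # --- stage 2: first MVGD (masked fit, global application)
    pp = _masked_patch_pixels(lab, layout, cfg.shrink)
    src, tgt = _stacked_src_tgt(pp, palette)
    mvgd1 = fit_mvgd(src, tgt, cfg.reg_lambda)
    lab = apply_mvgd_array(lab.reshape(-1, 3), mvgd1).reshape(lab.shape)
    lab = _maybe_quantize_lab(lab, cfg.bit_depth)
    m, mx = _stage_stats(lab, layout, palette, cfg.shrink)
    stages.append(StageReport("mvgd_1", m, mx))

    # --- stage 3: DNIL histogram regression (refit on current state)
    luts: list[ChannelLUT] | None = None
    if cfg.use_dnil:
        pp = _masked_patch_pixels(lab, layout, cfg.shrink)
        ids, means = _patch_means(pp)
        refs = palette.ref_lab_array(ids)
        src, tgt = _stacked_src_tgt(pp, palette)
        luts = []
        current_means = means.copy()
        for c in range(3):
            def score_fn(lut, _c=c):
                trial = current_means.copy()
                trial[:, _c] = lut(trial[:, _c])
                return -float(np.mean(np.atleast_1d(delta_e_2000(trial, refs))))

            lut = fit_dnil(
                src[:, c], tgt[:, c], cfg.dnil, score_fn, LAB_BOUNDS[c]
            )
            luts.append(lut)
            current_means[:, c] = lut(current_means[:, c])
        pix = lab.reshape(-1, 3)
        for c, lut in enumerate(luts):
            pix[:, c] = lut(pix[:, c])
        lab = pix.reshape(lab.shape)
        lab = _maybe_quantize_lab(lab, cfg.bit_depth)
        m, mx = _stage_stats(lab, layout, palette, cfg.shrink)
        stages.append(StageReport("dnil", m, mx))

    # --- stage 4: second MVGD
    pp = _masked_patch_pixels(lab, layout, cfg.shrink)
    src, tgt = _stacked_src_tgt(pp, palette)
    mvgd2 = fit_mvgd(src, tgt, cfg.reg_lambda)
    lab = apply_mvgd_array(lab.reshape(-1, 3), mvgd2).reshape(lab.shape)
    lab = _maybe_quantize_lab(lab, cfg.bit_depth)
    m, mx = _stage_stats(lab, layout, palette, cfg.shrink)
    stages.append(StageReport("mvgd_2", m, mx))

    # --- back to sRGB
    rgb, n_gamut = lab_array_to_linear_rgb(lab)
    clipped["gamut"] = n_gamut
    out = linear_to_srgb(
        ImageF32(rgb.astype(np.float32), Encoding.LINEAR_RGB, WhitePoint.D50)
    )
    if cfg.bit_depth == 8:
        out = ImageF32(
            _quantize(out.pixels, 0.0, 1.0).astype(np.float32),
            Encoding.SRGB_ENCODED,
            WhitePoint.D50,
        )

    model = TransferModel(
        wb=wb,
        mvgd1=mvgd1,
        luts=luts,
        mvgd2=mvgd2,
        source_image_id=raw_measurements.source_image_id,
    )
    report = PipelineReport(
        stages=stages,
        mirror_flags=mirror.flagged,
        uncorrectable_warning=mirror.uncorrectable,
        clipped_pixels=clipped,
    )
    return out, model, report
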