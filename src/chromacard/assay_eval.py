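"""Analytical-validation statistics for a quantitative colorimetric assay.

Covers the standard clinical-chemistry validation battery for a
color-read test strip quantified from corrected card images:

* a transparent color→concentration calibrator (affine in a scalar color
  feature: the corrected well-ROI mean CIELAB projected onto the first
  principal axis of the calibration colors);
* precision with repeatability / reproducibility variance components
  (one-way site ANOVA, method of moments, negative between-site
  component truncated to zero);
* limit of blank and limit of detection by the parametric normal-quantile
  forms at α = β = 0.05 (LoB = mean_blank + 1.645·SD_blank,
  LoD = LoB + 1.645·SD_low), with a nonparametric LoB option;
* limit of quantitation from the precision profile: a power-law variance
  function cv(c) = a·c^b fitted on log scale, solved for the target CV
  (20 % by default);
* linearity by polynomial order testing: nonlinearity is declared only
  when a 2nd- or 3rd-order coefficient differs from zero at the 5 % level.

A seeded synthetic study generator produces corrected-arm-like and
uncorrected-arm-like prediction datasets for testing the statistics
without assay images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationModel",
    "PrecisionTable",
    "DetectionLimits",
    "LoqUndeterminableError",
    "lab_feature",
    "fit_calibration",
    "precision_analysis",
    "limits_of_detection",
    "loq_from_precision_profile",
    "linearity_order_test",
    "simulate_assay_study",
]

Z_95 = 1.645  # one-sided 95 % normal quantile used by the LoB/LoD forms


class LoqUndeterminableError(RuntimeError):
    """Raised when the precision profile never crosses the target CV
    within the observed concentration range (CVs too high throughout)."""


# ---------------------------------------------------------------------------
# Calibration


def lab_feature(lab: np.ndarray, axis: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project (N,3) CIELAB colors onto a scalar feature.

    ``axis`` defaults to the first principal axis of the given colors
    (the direction of maximal color change across the calibration
    levels).  Returns (features, axis).
    """
    lab = np.asarray(lab, dtype=float)
    if axis is None:
        centered = lab - lab.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        # orient so the feature increases with L decrease is avoided;
        # fix sign for determinism
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
    axis = np.asarray(axis, dtype=float)
    return lab @ axis, axis


@dataclass
class CalibrationModel:
    """Affine color-feature → concentration calibration."""

    slope: float
    intercept: float
    r_squared: float
    std_error: float
    feature_axis: np.ndarray | None = None

    def predict(self, feature: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(feature, dtype=float) + self.intercept

    def predict_lab(self, lab: np.ndarray) -> np.ndarray:
        if self.feature_axis is None:
            raise ValueError("model was fitted on precomputed features, not Lab")
        f, _ = lab_feature(lab, self.feature_axis)
        return self.predict(f)


def fit_calibration(
    feature: np.ndarray, concentration: np.ndarray, *, lab: np.ndarray | None = None
) -> CalibrationModel:
    """Least-squares affine fit of concentration on the scalar color feature.

    Pass either ``feature`` directly or ``lab`` (N×3 corrected ROI mean
    colors, from which the first-principal-axis feature is derived).
    Requires ≥ 4 distinct concentration levels.
    """
    conc = np.asarray(concentration, dtype=float)
    axis = None
    if lab is not None:
        feature, axis = lab_feature(lab)
    x = np.asarray(feature, dtype=float)
    if x.shape != conc.shape:
        raise ValueError("feature and concentration must have equal length")
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentration levels")
    if np.ptp(x) < 1e-12:
        raise ValueError("zero feature variance: color does not track concentration")
    res = stats.linregress(x, conc)
    pred = res.slope * x + res.intercept
    resid = conc - pred
    dof = max(x.size - 2, 1)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        std_error=float(np.sqrt(np.sum(resid**2) / dof)),
        feature_axis=axis,
    )


# ---------------------------------------------------------------------------
# Precision (repeatability / reproducibility)


@dataclass
class PrecisionRow:
    level: float
    mean: float
    repeatability_sd: float
    repeatability_cv: float
    reproducibility_sd: float
    reproducibility_cv: float


@dataclass
class PrecisionTable:
    rows: list[PrecisionRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def levels(self) -> np.ndarray:
        return np.array([r.level for r in self.rows])

    def reproducibility_cvs(self) -> np.ndarray:
        return np.array([r.reproducibility_cv for r in self.rows])


def precision_analysis(df: pd.DataFrame) -> PrecisionTable:
    """One-way variance-component precision analysis per concentration level.

    ``df`` needs columns ``level``, ``site``, ``prediction``; every
    level×site cell must hold ≥ 2 replicates.  Repeatability SD is the
    pooled within-site SD; reproducibility SD adds the between-site
    component (method of moments, truncated at zero).  CVs are SD/mean
    in percent.
    """
    required = {"level", "site", "prediction"}
    if not required <= set(df.columns):
        raise ValueError(f"dataframe must have columns {sorted(required)}")
    rows = []
    for level, sub in df.groupby("level", sort=True):
        groups = [g["prediction"].to_numpy(dtype=float) for _, g in sub.groupby("site")]
        if len(groups) < 2:
            raise ValueError(f"level {level}: need >= 2 sites")
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"level {level}: every site needs >= 2 replicates")
        k = len(groups)
        n_i = np.array([len(g) for g in groups])
        N = int(n_i.sum())
        grand = float(np.concatenate(groups).mean())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ms_within = ss_within / (N - k)
        ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(n_i, groups)))
        ms_between = ss_between / (k - 1)
        # effective per-group size for unbalanced designs
        n0 = (N - (n_i**2).sum() / N) / (k - 1)
        var_between = max((ms_between - ms_within) / n0, 0.0)
        sr = float(np.sqrt(ms_within))
        sR = float(np.sqrt(ms_within + var_between))
        rows.append(
            PrecisionRow(
                level=float(level),
                mean=grand,
                repeatability_sd=sr,
                repeatability_cv=100.0 * sr / grand if grand != 0 else np.inf,
                reproducibility_sd=sR,
                reproducibility_cv=100.0 * sR / grand if grand != 0 else np.inf,
            )
        )
    return PrecisionTable(rows=rows)


# ---------------------------------------------------------------------------
# Limits of detection


@dataclass(frozen=True)
class DetectionLimits:
    lob: float
    lod: float
    loq: float | None = None
    alpha: float = 0.05
    beta: float = 0.05


def limits_of_detection(
    blank_predictions: np.ndarray,
    low_level_predictions: np.ndarray,
    parametric: bool = True,
) -> DetectionLimits:
    """LoB and LoD from blank and near-limit replicate predictions.

    Parametric (default): LoB = mean_B + 1.645·SD_B and
    LoD = LoB + 1.645·SD_L, both at α = β = 0.05.  The nonparametric
    option takes the 95th percentile of the blanks as LoB.  Fewer than
    20 replicates on either side triggers a warning (quantile estimates
    become unstable).
    """
    import warnings

    blanks = np.asarray(blank_predictions, dtype=float)
    lows = np.asarray(low_level_predictions, dtype=float)
    if blanks.size == 0 or lows.size == 0:
        raise ValueError("blank and low-level predictions must be non-empty")
    if blanks.size < 20 or lows.size < 20:
        warnings.warn("fewer than 20 replicates; limit estimates may be unstable")
    if parametric:
        lob = float(blanks.mean() + Z_95 * blanks.std(ddof=1)) if blanks.size > 1 else float(blanks.mean())
    else:
        lob = float(np.percentile(blanks, 95))
    sd_low = float(lows.std(ddof=1)) if lows.size > 1 else 0.0
    lod = lob + Z_95 * sd_low
    return DetectionLimits(lob=max(lob, 0.0), lod=max(lod, 0.0))


def loq_from_precision_profile(
    levels: np.ndarray, cvs: np.ndarray, target_cv: float = 20.0
) -> float:
    """LoQ: the concentration at which the fitted precision profile
    crosses ``target_cv``.

    Fits the power variance function cv(c) = a·c^b by least squares on
    log scale and solves cv(LoQ) = target.  Raises
    :class:`LoqUndeterminableError` when the fitted profile exceeds the
    target everywhere in the observed range, and flags (warns on) a
    profile that is not overall decreasing.
    """
    import warnings

    levels = np.asarray(levels, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    if levels.size < 3:
        raise ValueError("need >= 3 levels to fit a precision profile")
    if np.any(levels <= 0) or np.any(cvs <= 0):
        raise ValueError("levels and CVs must be positive")
    b, log_a = np.polyfit(np.log(levels), np.log(cvs), 1)
    a = float(np.exp(log_a))
    if b >= 0:
        warnings.warn("precision profile is not decreasing with concentration")
    fitted = a * levels**b
    if float(fitted.min()) > target_cv:
        raise LoqUndeterminableError(
            f"unable to determine LoQ: fitted CV exceeds {target_cv}% across "
            f"the observed range ({levels.min()}–{levels.max()})"
        )
    loq = float((target_cv / a) ** (1.0 / b))
    return loq


# ---------------------------------------------------------------------------
# Linearity


@dataclass
class LinearityResult:
    best_order: int
    coefficients: dict[int, np.ndarray]
    p_values: dict[int, float]
    verdict: str


def linearity_order_test(
    known: np.ndarray, measured: np.ndarray, alpha: float = 0.05
) -> LinearityResult:
    """Polynomial order testing for linearity.

    Fits 1st–3rd order polynomials of measured on known; the assay is
    declared nonlinear only if the highest-order coefficient of the 2nd-
    or 3rd-order fit differs from zero at the ``alpha`` level (t-test).
    Requires ≥ 5 distinct levels.
    """
    x = np.asarray(known, dtype=float)
    y = np.asarray(measured, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need >= 5 distinct levels for linearity testing")
    coefficients: dict[int, np.ndarray] = {}
    p_values: dict[int, float] = {}
    for order in (1, 2, 3):
        X = np.vander(x, order + 1, increasing=True)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        coefficients[order] = beta
        resid = y - X @ beta
        dof = x.size - (order + 1)
        if dof <= 0:
            p_values[order] = 1.0
            continue
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        t_stat = beta[order] / np.sqrt(cov[order, order])
        p_values[order] = float(2.0 * stats.t.sf(abs(t_stat), dof))
    nonlinear_orders = [k for k in (2, 3) if p_values[k] < alpha]
    if nonlinear_orders:
        best = min(nonlinear_orders)
        verdict = f"nonlinear(order {best})"
    else:
        best = 1
        verdict = "linear"
    return LinearityResult(
        best_order=best, coefficients=coefficients, p_values=p_values, verdict=verdict
    )


# ---------------------------------------------------------------------------
# Synthetic assay study generator


def simulate_assay_study(
    levels: tuple[float, ...] = (1.5, 4.0, 6.5, 7.5, 9.0),
    n_sites: int = 3,
    replicates_per_site: int = 6,
    within_sd: float = 0.35,
    between_sd: float = 0.25,
    slope: float = 1.0,
    intercept: float = 0.0,
    illumination_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded synthetic prediction dataset in the multi-site design.

    Emulates the validation study's structure: five calibrator levels,
    three sites, six replicate cards per level and site.  ``within_sd``
    models replicate (card + read) noise, ``between_sd`` a site-level
    shift, and ``illumination_sd`` an extra per-card illumination error —
    zero for the corrected arm, larger for the uncorrected arm whose
    color features still carry the ambient light.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for level in levels:
        site_shift = rng.normal(0.0, between_sd, size=n_sites)
        for s in range(n_sites):
            preds = (
                slope * level
                + intercept
                + site_shift[s]
                + rng.normal(0.0, within_sd, size=replicates_per_site)
            )
            if illumination_sd > 0:
                preds = preds + rng.normal(0.0, illumination_sd, size=preds.size)
            for r, p in enumerate(preds):
                rows.append(
                    {"level": level, "site": f"site{s}", "replicate": r, "prediction": p}
                )
    return pd.DataFrame(rows)
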