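"""Technical-validation statistics for imaging biomarkers.

Test-retest repeatability is summarised by a one-way random-effects
decomposition of two-visit data into between-subject (sigma_b^2) and
within-subject (sigma_w^2) variance, the intraclass correlation
ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2), the within-subject SD or CV
(chosen by whether variability correlates with magnitude), and the
smallest detectable difference SDD = sqrt(2) * 1.96 * wSD (or wCV) —
the change interpretable as real with 95% confidence.  Observer
reproducibility uses the root-mean-square CV and Lin's concordance
correlation coefficient; group discrimination uses the standardised
mean difference (Cohen's d with pooled SD); responsiveness is the count
of subjects whose follow-up change exceeds the SDD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SDD_FACTOR", "TestRetestRecord", "RepeatabilityMetrics",
    "ReproducibilityMetrics", "GroupComparison",
    "variance_components_oneway", "icc_from_components", "icc_confint",
    "within_subject_sd", "within_subject_cv", "select_variability_scale",
    "smallest_detectable_difference", "rmscv", "lin_ccc",
    "standardized_mean_difference", "responsiveness_count",
    "repeatability_summary", "repeatability_table",
]

#: sqrt(2) * 1.96 — the repeatability-coefficient multiplier (2.77 at 2 dp).
SDD_FACTOR = float(np.sqrt(2.0) * 1.96)


@dataclass(frozen=True)
class TestRetestRecord:
    subject_id: str
    group: str                # "OA" or "HV"
    value_visit1: float
    value_visit2: float


@dataclass
class RepeatabilityMetrics:
    sigma_b2: float
    sigma_w2: float
    icc: float
    icc_lo: float
    icc_hi: float
    scale: str                # "absolute" or "relative"
    wsd_or_wcv: float         # biomarker units, or percent for relative
    sdd: float                # same scale as wsd_or_wcv
    oa_mean: float
    sdd_pct_of_mean: float


@dataclass
class ReproducibilityMetrics:
    rmscv: float              # percent
    ccc: float


@dataclass
class GroupComparison:
    mean_oa: float
    mean_hv: float
    pooled_sd: float
    smd: float


def _pairs(records) -> tuple[np.ndarray, np.ndarray]:
    """Extract (visit1, visit2) arrays from records / DataFrame / arrays."""
    if isinstance(records, tuple) and len(records) == 2:
        y1, y2 = (np.asarray(a, dtype=float) for a in records)
    elif isinstance(records, pd.DataFrame):
        y1 = records["value_visit1"].to_numpy(dtype=float)
        y2 = records["value_visit2"].to_numpy(dtype=float)
    else:
        y1 = np.array([r.value_visit1 for r in records], dtype=float)
        y2 = np.array([r.value_visit2 for r in records], dtype=float)
    complete = np.isfinite(y1) & np.isfinite(y2)
    if not complete.all():
        warnings.warn(f"excluding {np.count_nonzero(~complete)} subject(s) "
                      "with a missing visit", stacklevel=3)
    return y1[complete], y2[complete]


def variance_components_oneway(records) -> tuple[float, float]:
    """Between- and within-subject variance from two-visit data.

    One-way random-effects ANOVA with k=2 replicates per subject:
    sigma_w^2 = MS_within and sigma_b^2 = max(0, (MS_between - MS_within)/2);
    a negative between-subject component is truncated at zero.
    """
    y1, y2 = _pairs(records)
    n = y1.size
    if n < 3:
        raise ValueError("need >= 3 subjects with both visits")
    data = np.stack([y1, y2])                  # (2, n)
    subj_mean = data.mean(axis=0)
    grand = data.mean()
    ms_between = 2.0 * np.sum((subj_mean - grand) ** 2) / (n - 1)
    ms_within = np.sum((data - subj_mean) ** 2) / n    # n*(k-1) df, k=2
    sigma_w2 = float(ms_within)
    sigma_b2 = float(max(0.0, (ms_between - ms_within) / 2.0))
    return sigma_b2, sigma_w2


def icc_from_components(sigma_b2: float, sigma_w2: float) -> float:
    """One-way random-effects ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2)."""
    if sigma_b2 < 0 or sigma_w2 < 0:
        raise ValueError("variance components must be >= 0")
    tot = sigma_b2 + sigma_w2
    if tot == 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return sigma_b2 / tot


def icc_confint(records, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(1) with an F-pivot confidence interval, lower bound floored at 0.

    Returns (icc, lo, hi) for the one-way random-effects model with two
    replicates per subject.
    """
    y1, y2 = _pairs(records)
    n, k = y1.size, 2
    if n < 3:
        raise ValueError("need >= 3 subjects with both visits")
    sigma_b2, sigma_w2 = variance_components_oneway((y1, y2))
    icc = icc_from_components(sigma_b2, sigma_w2)
    data = np.stack([y1, y2])
    subj_mean = data.mean(axis=0)
    ms_b = k * np.sum((subj_mean - data.mean()) ** 2) / (n - 1)
    ms_w = np.sum((data - subj_mean) ** 2) / (n * (k - 1))
    if ms_w == 0:
        return icc, icc, icc
    f = ms_b / ms_w
    df1, df2 = n - 1, n * (k - 1)
    fl = f / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * sps.f.ppf(1 - alpha / 2, df2, df1)
    lo = max(0.0, (fl - 1) / (fl + k - 1))
    hi = min(1.0, (fu - 1) / (fu + k - 1))
    return icc, lo, hi


def within_subject_sd(records) -> float:
    """wSD = sqrt(within-subject variance), in biomarker units."""
    _, sigma_w2 = variance_components_oneway(records)
    return float(np.sqrt(sigma_w2))


def within_subject_cv(records) -> float:
    """Within-subject CV in percent, RMS pair method.

    wCV = 100 * sqrt( mean_i[ (d_i^2 / 2) / m_i^2 ] ) with d_i the visit
    difference and m_i the subject mean; requires positive subject means.
    """
    y1, y2 = _pairs(records)
    m = (y1 + y2) / 2.0
    if np.any(m <= 0):
        raise ValueError("within-subject CV requires positive subject means")
    d = y2 - y1
    return float(100.0 * np.sqrt(np.mean((d**2 / 2.0) / m**2)))


def select_variability_scale(records, alpha: float = 0.05) -> str:
    """Choose absolute (wSD) vs relative (wCV) variability scale.

    Kendall's tau between subject mean and |visit difference|; the
    relative scale is selected iff the two-sided p-value is < alpha
    (variability significantly correlated with magnitude).
    """
    y1, y2 = _pairs(records)
    if y1.size < 5:
        raise ValueError("need >= 5 subjects for scale selection")
    m = (y1 + y2) / 2.0
    d = np.abs(y2 - y1)
    if np.ptp(m) == 0 or np.ptp(d) == 0:
        return "absolute"
    tau, p = sps.kendalltau(m, d)
    return "relative" if (np.isfinite(p) and p < alpha) else "absolute"


def smallest_detectable_difference(wsd_or_wcv: float, scale: str = "absolute") -> float:
    """SDD = sqrt(2) * 1.96 * (wSD or wCV); same units/scale as the input."""
    if wsd_or_wcv < 0:
        raise ValueError("wSD/wCV must be >= 0")
    if scale not in ("absolute", "relative"):
        raise ValueError("scale must be 'absolute' or 'relative'")
    return SDD_FACTOR * wsd_or_wcv


def rmscv(x, y=None) -> float:
    """Root-mean-square coefficient of variation of repeated pairs, percent.

    Accepts either an (n, 2) array of pairs or two equal-length arrays.
    Per pair: CV = SD / mean (sample SD, ddof=1); RMSCV = 100 * RMS(CV).
    """
    if y is None:
        pairs = np.asarray(x, dtype=float)
    else:
        pairs = np.stack([np.asarray(x, dtype=float),
                          np.asarray(y, dtype=float)], axis=1)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 pairs of repeated measurements")
    m = pairs.mean(axis=1)
    if np.any(m <= 0):
        raise ValueError("RMSCV requires positive pair means")
    sd = pairs.std(axis=1, ddof=1)
    return float(100.0 * np.sqrt(np.mean((sd / m) ** 2)))


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ccc = 2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length series of >= 3")
    vx, vy = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0:
        raise ValueError("zero total variance; CCC undefined")
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * cov / denom)


def standardized_mean_difference(group_oa, group_hv) -> GroupComparison:
    """Between-group standardised mean difference with pooled SD.

    smd = (mean_OA - mean_HV) / s_pooled,
    s_pooled^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1 + n2 - 2).
    """
    a = np.asarray(group_oa, dtype=float)
    b = np.asarray(group_hv, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 observations")
    s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2)
    pooled = float(np.sqrt(s2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; SMD undefined")
    return GroupComparison(mean_oa=float(a.mean()), mean_hv=float(b.mean()),
                           pooled_sd=pooled,
                           smd=float((a.mean() - b.mean()) / pooled))


def responsiveness_count(changes, sdd: float, scale: str = "absolute",
                         baselines=None) -> int:
    """Number of subjects with follow-up change strictly exceeding the SDD.

    On the relative scale each change is expressed as a percentage of the
    subject's baseline value before comparison (``baselines`` required).
    """
    if sdd < 0:
        raise ValueError("sdd must be >= 0")
    d = np.asarray(changes, dtype=float)
    if scale == "relative":
        if baselines is None:
            raise ValueError("relative scale requires baseline values")
        base = np.asarray(baselines, dtype=float)
        d = 100.0 * d / base
    return int(np.count_nonzero(np.abs(d) > sdd))


def repeatability_summary(records, oa_values=None,
                          alpha: float = 0.05) -> RepeatabilityMetrics:
    """Full test-retest repeatability summary for one biomarker.

    Selects the variability scale, computes variance components, ICC with
    F-pivot CI, wSD or wCV, and the SDD (also as a percentage of the OA
    group mean when ``oa_values`` is given).
    """
    sigma_b2, sigma_w2 = variance_components_oneway(records)
    icc, lo, hi = icc_confint(records, alpha=alpha)
    scale = select_variability_scale(records, alpha=alpha)
    w = within_subject_sd(records) if scale == "absolute" else within_subject_cv(records)
    sdd = smallest_detectable_difference(w, scale)
    oa_mean = float(np.mean(oa_values)) if oa_values is not None else np.nan
    if scale == "absolute" and oa_values is not None and oa_mean != 0:
        sdd_pct = 100.0 * sdd / oa_mean
    else:
        sdd_pct = np.nan
    return RepeatabilityMetrics(sigma_b2=sigma_b2, sigma_w2=sigma_w2,
                                icc=icc, icc_lo=lo, icc_hi=hi, scale=scale,
                                wsd_or_wcv=w, sdd=sdd, oa_mean=oa_mean,
                                sdd_pct_of_mean=sdd_pct)


def repeatability_table(biomarker_frames: dict) -> pd.DataFrame:
    """Assemble a repeatability report table.

    ``biomarker_frames`` maps (biomarker, segmentation_method) to a
    DataFrame with columns subject_id, group, value_visit1, value_visit2.
    Returns one row per biomarker × method with the summary metrics.
    """
    rows = []
    for (bio, method), df in biomarker_frames.items():
        oa = df.loc[df["group"] == "OA", ["value_visit1"]].to_numpy().ravel()
        m = repeatability_summary(df, oa_values=oa if oa.size else None)
        rows.append({"biomarker": bio, "segmentation_method": method,
                     "sigma_b2": m.sigma_b2, "sigma_w2": m.sigma_w2,
                     "icc": m.icc, "icc_lo": m.icc_lo, "icc_hi": m.icc_hi,
                     "scale": m.scale, "wsd_or_wcv": m.wsd_or_wcv,
                     "sdd": m.sdd, "oa_mean": m.oa_mean,
                     "sdd_pct": m.sdd_pct_of_mean})
    return pd.DataFrame(rows)
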