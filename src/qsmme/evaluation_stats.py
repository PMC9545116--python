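"""Quantitative comparison of pipelines: error metrics and statistics.

Whole-volume RMSE against ground truth, per-ROI summary statistics,
line profiles through noise maps, Bland-Altman fixed-bias analysis with a
|0.01| ppm negligibility threshold, Shapiro-Wilk-gated paired tests
(sign test when normality is rejected), and pooling of per-subject
regional values by the law of total variance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BlandAltmanResult", "rmse_percent", "regional_stats",
           "line_profile", "bland_altman", "compare_pipelines",
           "pool_subjects", "difference_map"]

#: Bias magnitude below which two pipelines are considered interchangeable
#: (inter-pipeline differences are swamped by intra-pipeline variability).
NEGLIGIBLE_BIAS_PPM = 0.01


@dataclass
class BlandAltmanResult:
    roi: str
    pair: tuple[str, str]
    bias_ppm: float
    loa_low_ppm: float
    loa_high_ppm: float
    negligible: bool


def rmse_percent(estimate: np.ndarray, truth: np.ndarray,
                 mask: np.ndarray, demean: bool = False) -> float:
    """Normalized root-mean-square error in percent over the mask.

    100 * ||estimate - truth|| / ||truth||.  With ``demean`` both inputs
    are first referenced to their mask mean (appropriate for maps that are
    only defined up to a constant).
    """
    mask = np.asarray(mask, dtype=bool)
    e = np.asarray(estimate, dtype=float)[mask]
    t = np.asarray(truth, dtype=float)[mask]
    if demean:
        e = e - e.mean()
        t = t - t.mean()
    denom = np.linalg.norm(t)
    if denom == 0:
        raise ValueError("truth is identically zero over the mask")
    return 100.0 * float(np.linalg.norm(e - t) / denom)


def regional_stats(map_3d: np.ndarray, rois: dict[str, np.ndarray],
                   pipeline_tag: str, subject: str | int = 0) -> pd.DataFrame:
    """Mean, SD and voxel count of a map over each ROI (finite voxels)."""
    m = np.asarray(map_3d, dtype=float)
    rows = []
    for name, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        vals = m[roi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {name!r} is empty after masking")
        rows.append({"subject": subject, "pipeline": pipeline_tag,
                     "roi": name, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_voxels": int(vals.size)})
    return pd.DataFrame(rows)


def line_profile(map_3d: np.ndarray, start_voxel, end_voxel,
                 ) -> tuple[np.ndarray, float, float]:
    """Nearest-voxel samples along a segment at unit spacing.

    Returns floor(segment length) + 1 samples, their mean and SD.
    """
    m = np.asarray(map_3d, dtype=float)
    p0 = np.asarray(start_voxel, dtype=float)
    p1 = np.asarray(end_voxel, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ValueError("identical endpoints")
    n = int(np.floor(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    pts = np.rint(p0 + np.outer(t, p1 - p0)).astype(int)
    for ax, size in enumerate(m.shape):
        if pts[:, ax].min() < 0 or pts[:, ax].max() >= size:
            raise ValueError("profile endpoint outside grid")
    vals = m[pts[:, 0], pts[:, 1], pts[:, 2]]
    return vals, float(vals.mean()), float(vals.std(ddof=1))


def bland_altman(means_a, means_b, roi: str = "",
                 pair: tuple[str, str] = ("a", "b")) -> BlandAltmanResult:
    """Fixed-bias analysis of paired per-subject regional means.

    bias = mean(a - b); limits of agreement are bias +/- 1.96 SD of the
    differences; the bias is flagged negligible when |bias| <= 0.01 ppm.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    bias = float(d.mean())
    spread = 1.96 * float(d.std(ddof=1))
    return BlandAltmanResult(roi=roi, pair=pair, bias_ppm=bias,
                             loa_low_ppm=bias - spread,
                             loa_high_ppm=bias + spread,
                             negligible=abs(bias) <= NEGLIGIBLE_BIAS_PPM)


def _sign_test(d: np.ndarray) -> tuple[float, float]:
    """Two-tailed exact sign test on paired differences (zeros dropped)."""
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    npos = int((nz > 0).sum())
    res = stats.binomtest(npos, nz.size, 0.5, alternative="two-sided")
    return float(npos), float(res.pvalue)


def compare_pipelines(per_subject_means: dict[str, np.ndarray],
                      roi: str = "", p_threshold: float = 0.05,
                      ) -> pd.DataFrame:
    """Pairwise tests of per-subject regional means between pipelines.

    For each pair, the Shapiro-Wilk test assesses normality of the paired
    differences; if rejected (p < 0.05) a two-tailed exact sign test is
    used, otherwise a paired t-test.  P values are reported uncorrected.
    """
    names = list(per_subject_means)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a = np.asarray(per_subject_means[na], dtype=float)
            b = np.asarray(per_subject_means[nb], dtype=float)
            if a.size != b.size or a.size < 3:
                raise ValueError("need >= 3 paired subjects per comparison")
            d = a - b
            if np.allclose(d, 0.0):
                rows.append({"roi": roi, "a": na, "b": nb, "test": "sign",
                             "normality_p": 1.0, "statistic": 0.0,
                             "p_value": 1.0, "significant": False})
                continue
            if np.ptp(d) == 0:  # constant nonzero difference
                sw_p = 0.0
            else:
                sw_p = float(stats.shapiro(d).pvalue)
            if sw_p < 0.05:
                statv, p = _sign_test(d)
                test = "sign"
            else:
                t = stats.ttest_rel(a, b)
                statv, p = float(t.statistic), float(t.pvalue)
                test = "t"
            rows.append({"roi": roi, "a": na, "b": nb, "test": test,
                         "normality_p": sw_p, "statistic": statv,
                         "p_value": p, "significant": p < p_threshold})
    return pd.DataFrame(rows)


def pool_subjects(table: pd.DataFrame) -> pd.DataFrame:
    """Pool per-subject regional means/SDs across subjects.

    The pooled mean is the voxel-count-weighted mean of subject means; the
    pooled SD follows the law of total variance (weighted within-subject
    variance plus between-subject variance).  The intra-versus-inter SD
    condition (every subject SD larger than the between-subject SD) is
    checked and recorded per (pipeline, roi); pooling proceeds either way.
    """
    rows = []
    for (pipe, roi), grp in table.groupby(["pipeline", "roi"]):
        if len(grp) < 2:
            raise ValueError("need >= 2 subjects per (pipeline, roi)")
        w = grp["n_voxels"].to_numpy(dtype=float)
        mu = grp["mean"].to_numpy()
        sd = grp["sd"].to_numpy()
        w = w / w.sum()
        pooled_mean = float((w * mu).sum())
        within = float((w * sd ** 2).sum())
        between = float((w * (mu - pooled_mean) ** 2).sum())
        inter_sd = float(mu.std(ddof=1))
        rows.append({"pipeline": pipe, "roi": roi,
                     "pooled_mean": pooled_mean,
                     "pooled_sd": float(np.sqrt(within + between)),
                     "intra_gt_inter": bool((sd > inter_sd).all()),
                     "n_subjects": int(len(grp))})
    return pd.DataFrame(rows)


def difference_map(map_a: np.ndarray, map_b: np.ndarray,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Voxel-wise pairwise difference, zeroed outside the mask."""
    d = np.asarray(map_a, dtype=float) - np.asarray(map_b, dtype=float)
    if mask is not None:
        d = d * np.asarray(mask, dtype=bool)
    return d
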