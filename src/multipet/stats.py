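"""Nonparametric ROI statistics and the single-subject voxelwise contrast.

Group comparisons use two-tailed Kruskal–Wallis tests per ROI followed by
post-hoc Mann–Whitney U tests with the effect size r = z/√N, where z is the
tie-corrected normal approximation of U and N the total of the two group
sizes. Small groups are assessed individually as z-scores against the
non-carrier reference distribution, abnormal at |z| > 1.645. The voxelwise
layer compares a single subject against five age-nearest controls with a
two-sample t contrast thresholded at p < 0.001 (uncorrected) inside a binary
gray-matter mask.

No multiple-comparison correction is applied to the ROI tests (significance
p < 0.05 two-tailed); interpret the per-ROI p values accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from . import protocol

__all__ = [
    "ComparisonResult",
    "ZScoreCall",
    "kruskal_wallis",
    "mann_whitney",
    "z_scores",
    "roi_group_tests",
    "select_age_nearest_controls",
    "voxel_t_contrast",
    "TContrastResult",
]


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "KW" or "MW"
    statistic: float
    p: float
    groups: tuple[str, ...]
    n: tuple[int, ...]
    roi: str | None = None
    z: float | None = None  # MW only
    effect_size_r: float | None = None  # MW only, r = z/sqrt(N)
    p_exact: float | None = None  # MW only, exact two-sided p (untied data)


@dataclass(frozen=True)
class ZScoreCall:
    subject: str
    roi: str
    tracer: str
    z: float
    abnormal: bool


def kruskal_wallis(samples, group_names=None, roi: str | None = None) -> ComparisonResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = groups − 1).

    All values identical across groups is not an error: H = 0, p = 1.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 3:
        raise ValueError("Kruskal-Wallis requires >= 3 groups")
    if any(len(s) == 0 for s in samples):
        raise ValueError("each group must be non-empty")
    names = tuple(group_names) if group_names else tuple(f"g{i + 1}" for i in range(len(samples)))
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            test="KW", statistic=0.0, p=1.0, groups=names, n=tuple(len(s) for s in samples), roi=roi
        )
    h, p = sps.kruskal(*samples)
    return ComparisonResult(
        test="KW", statistic=float(h), p=float(p), groups=names, n=tuple(len(s) for s in samples), roi=roi
    )


def mann_whitney(
    a, b, group_names: tuple[str, str] = ("a", "b"), roi: str | None = None
) -> ComparisonResult:
    """Mann–Whitney U with tie-corrected normal z and effect size r = z/√N.

    The sign convention follows the group order: z > 0 when the first sample
    tends to be larger than the second. The default two-tailed p comes from
    the normal approximation (it is the p the z implies); for untied data the
    exact two-sided p is reported alongside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        z = 0.0
    else:
        z = (u1 - mean_u) / np.sqrt(var_u)
    p = float(2.0 * sps.norm.sf(abs(z)))
    p = min(p, 1.0)
    p_exact = None
    if counts.max() == 1:  # untied: exact null distribution of U is available
        p_exact = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return ComparisonResult(
        test="MW",
        statistic=float(u1),
        p=p,
        groups=tuple(group_names),
        n=(n1, n2),
        roi=roi,
        z=float(z),
        effect_size_r=float(z / np.sqrt(n)),
        p_exact=p_exact,
    )


def z_scores(
    values,
    reference,
    subjects=None,
    roi: str = "",
    tracer: str = "",
    threshold: float = protocol.Z_ABNORMAL,
) -> list[ZScoreCall]:
    """Individual z-scores against a reference group (n−1 SD).

    abnormal ⇔ |z| strictly greater than the threshold (default 1.645).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValueError("reference group needs at least 2 values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference group has zero standard deviation")
    mu = ref.mean()
    vals = np.atleast_1d(np.asarray(values, dtype=float))
    if subjects is None:
        subjects = [f"s{i + 1}" for i in range(vals.size)]
    calls = []
    for subject, v in zip(subjects, vals):
        z = float((v - mu) / sd)
        calls.append(
            ZScoreCall(subject=subject, roi=roi, tracer=tracer, z=z, abnormal=abs(z) > threshold)
        )
    return calls


def roi_group_tests(
    features: pd.DataFrame,
    tracer: str,
    rois=protocol.STAT_ROIS,
    groups=("presymptomatic_carrier", "MCI_PIB+", "sAD", "non_carrier"),
) -> pd.DataFrame:
    """Kruskal–Wallis per ROI over the comparison groups, with all pairwise
    Mann–Whitney post-hoc results, on one tracer's columns of a feature table."""
    rows = []
    labels = features["group"]
    for roi in rois:
        col = f"{roi}_{tracer}"
        if col not in features.columns:
            raise ValueError(f"feature table lacks column {col}")
        samples = [features.loc[labels == g, col].to_numpy() for g in groups]
        kw = kruskal_wallis(samples, group_names=groups, roi=roi)
        rows.append(
            {
                "roi": roi,
                "test": "KW",
                "groups": "|".join(groups),
                "statistic": kw.statistic,
                "z": np.nan,
                "p": kw.p,
                "effect_size_r": np.nan,
            }
        )
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                mw = mann_whitney(
                    samples[i], samples[j], group_names=(groups[i], groups[j]), roi=roi
                )
                rows.append(
                    {
                        "roi": roi,
                        "test": "MW",
                        "groups": f"{groups[i]}|{groups[j]}",
                        "statistic": mw.statistic,
                        "z": mw.z,
                        "p": mw.p,
                        "effect_size_r": mw.effect_size_r,
                    }
                )
    return pd.DataFrame(rows)


def select_age_nearest_controls(subject_age: float, controls: pd.DataFrame, n: int = 5) -> list[str]:
    """Pick the ``n`` controls closest in age; ties broken by smaller id.

    ``controls`` needs columns ``id`` and ``age``.
    """
    if len(controls) < n:
        raise ValueError(f"need at least {n} controls, have {len(controls)}")
    ranked = controls.assign(_gap=(controls["age"] - subject_age).abs()).sort_values(
        ["_gap", "id"], kind="mergesort"
    )
    return list(ranked["id"].head(n))


@dataclass
class TContrastResult:
    t_map: np.ndarray  # NaN outside mask / at excluded voxels
    df: int
    t_threshold: float
    n_excluded: int  # zero-pooled-variance voxels inside the mask
    clusters: pd.DataFrame  # direction, size, peak_t, peak_index


def voxel_t_contrast(
    subject: np.ndarray,
    controls: np.ndarray,
    gm_mask: np.ndarray,
    alpha: float = 0.001,
) -> TContrastResult:
    """Single subject (n = 1) vs control group two-sample t contrast.

    The subject contributes no variance, so the pooled SD is the control SD
    and t = (x_s − mean_c)/(s_c·√(1 + 1/n_c)) with df = n_c − 1. Both contrast
    directions are thresholded one-tailed at ``alpha``; suprathreshold voxels
    are grouped into 26-connected clusters.
    """
    subject = np.asarray(subject, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.ndim != subject.ndim + 1 or controls.shape[1:] != subject.shape:
        raise ValueError("controls must stack control images on the first axis")
    n_c = controls.shape[0]
    if n_c < 2:
        raise ValueError("need at least 2 control images")
    mask = np.asarray(gm_mask, dtype=bool)
    if mask.shape != subject.shape:
        raise ValueError("gray-matter mask shape mismatch")
    mean_c = controls.mean(axis=0)
    sd_c = controls.std(axis=0, ddof=1)
    df = n_c - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (subject - mean_c) / (sd_c * np.sqrt(1.0 + 1.0 / n_c))
    degenerate = mask & (sd_c == 0)
    t_map = np.full(subject.shape, np.nan)
    valid = mask & ~degenerate
    t_map[valid] = t[valid]
    thr = float(sps.t.ppf(1.0 - alpha, df))
    structure = np.ones((3,) * subject.ndim, dtype=bool)
    rows = []
    for direction, supra in (
        ("increase", np.nan_to_num(t_map, nan=0.0) > thr),
        ("decrease", np.nan_to_num(t_map, nan=0.0) < -thr),
    ):
        labelled, n_clusters = ndimage.label(supra, structure=structure)
        for c in range(1, n_clusters + 1):
            vox = labelled == c
            tc = t_map[vox]
            peak_flat = np.flatnonzero(vox.ravel())[np.argmax(np.abs(tc))]
            rows.append(
                {
                    "direction": direction,
                    "size": int(vox.sum()),
                    "peak_t": float(tc[np.argmax(np.abs(tc))]),
                    "peak_index": tuple(int(v) for v in np.unravel_index(peak_flat, subject.shape)),
                }
            )
    clusters = pd.DataFrame(rows, columns=["direction", "size", "peak_t", "peak_index"])
    return TContrastResult(
        t_map=t_map,
        df=df,
        t_threshold=thr,
        n_excluded=int(degenerate.sum()),
        clusters=clusters,
    )
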