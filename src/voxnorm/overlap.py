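"""Spatial agreement of thresholded maps and threshold-sweep robustness.

The Jaccard index J(X, Y) = |X n Y| / |X u Y| quantifies fractional
overlap of two binary abnormality maps.  Comparisons cover CS vs LNG at
each post-injury timepoint and SYM vs RTP under each analysis, with
paired Wilcoxon signed-rank contrasts of the per-subject overlap values
and Spearman correlations against scan-interval covariates.  Sweeps
re-threshold the retained probability maps under FDR, uncorrected-p and
percentile schemes to show that overlap conclusions are not an artifact
of one threshold.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .abnormality import AbnormalityResult, cluster_filter, fdr_threshold
from .core_io import AnalysisConfig

COMPARISONS = ("CS-vs-LNG@SYM", "CS-vs-LNG@RTP", "SYM-vs-RTP@CS", "SYM-vs-RTP@LNG")


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """|X n Y| / |X u Y|; NaN (missing) when both maps are empty."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    union = int((x | y).sum())
    if union == 0:
        return np.nan
    return float((x & y).sum() / union)


class SpearmanResult(NamedTuple):
    rho: float
    p: float


def correlate_with_time(values: Sequence[float],
                        times: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (average-tie handling), two-sided p.

    Constant inputs are not rankable: returns NaN for both fields.
    Pairs with missing values are dropped; fewer than 3 complete pairs
    is an error.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    v, t = v[ok], t[ok]
    if v.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(v) == 0 or np.ptp(t) == 0:
        return SpearmanResult(np.nan, np.nan)
    rho, p = stats.spearmanr(v, t)
    return SpearmanResult(float(rho), float(p))


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p.

    Zero differences are dropped (the classical convention); the exact
    null distribution is used for n <= 25 when there are no ties.  All
    differences zero -- a perfectly symmetric contrast -- returns p = 1.
    Fewer than 2 complete nonmissing pairs returns NaN (not computable).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    diffs = a[ok] - b[ok]
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(diffs, zero_method="wilcox", method="auto")
    return float(res.pvalue)


def _result_index(results: Iterable[AbnormalityResult]
                  ) -> dict[tuple[str, str, str, str], AbnormalityResult]:
    idx = {}
    for r in results:
        idx[(r.subject_id, r.modality.value, r.analysis, r.timepoint.value)] = r
    return idx


def jaccard_records(results: Iterable[AbnormalityResult]) -> pd.DataFrame:
    """Per-subject Jaccard for the four standard comparisons.

    Rows where either map of a pair is unavailable are skipped; rows
    where both maps are empty carry a missing (NaN) value, which is
    excluded from pooled medians.
    """
    idx = _result_index(results)
    subjects = sorted({k[0] for k in idx})
    modalities = sorted({k[1] for k in idx})
    rows = []
    pairs = {
        "CS-vs-LNG@SYM": (("CS", "SYM"), ("LNG", "SYM")),
        "CS-vs-LNG@RTP": (("CS", "RTP"), ("LNG", "RTP")),
        "SYM-vs-RTP@CS": (("CS", "SYM"), ("CS", "RTP")),
        "SYM-vs-RTP@LNG": (("LNG", "SYM"), ("LNG", "RTP")),
    }
    for mod in modalities:
        for sid in subjects:
            for comp, ((a1, t1), (a2, t2)) in pairs.items():
                r1 = idx.get((sid, mod, a1, t1))
                r2 = idx.get((sid, mod, a2, t2))
                if r1 is None or r2 is None:
                    continue
                rows.append(dict(subject_id=sid, modality=mod, comparison=comp,
                                 jaccard=jaccard(r1.abnormal, r2.abnormal)))
    return pd.DataFrame(rows, columns=["subject_id", "modality", "comparison",
                                       "jaccard"])


def pooled_overlap(records: pd.DataFrame) -> pd.DataFrame:
    """Median [Q1, Q3] of Jaccard pooled over timepoints / analyses.

    ``family`` "CS-vs-LNG" pools the SYM and RTP comparisons; family
    "SYM-vs-RTP" pools the CS and LNG comparisons -- the pooling the
    per-family paired contrast licenses when non-significant.
    """
    rec = records.copy()
    rec["family"] = rec.comparison.str.split("@").str[0]
    out = []
    for (mod, fam), grp in rec.groupby(["modality", "family"], sort=True):
        vals = grp.jaccard.dropna()
        med, q1, q3 = (np.percentile(vals, [50, 25, 75])
                       if len(vals) else (np.nan,) * 3)
        out.append(dict(modality=mod, family=fam, n=len(vals),
                        jaccard_median=med, jaccard_q1=q1, jaccard_q3=q3))
    return pd.DataFrame(out)


def paired_contrasts(records: pd.DataFrame) -> pd.DataFrame:
    """Within-family paired Wilcoxon contrasts of overlap values.

    For CS-vs-LNG overlap: SYM against RTP; for SYM-vs-RTP overlap: CS
    against LNG.  Subjects missing either member are excluded pairwise;
    a contrast with fewer than 2 complete pairs is reported with NaN p.
    """
    wide = records.pivot_table(index=["modality", "subject_id"],
                               columns="comparison", values="jaccard",
                               aggfunc="first")
    out = []
    contrasts = {
        "CS-vs-LNG: SYM vs RTP": ("CS-vs-LNG@SYM", "CS-vs-LNG@RTP"),
        "SYM-vs-RTP: CS vs LNG": ("SYM-vs-RTP@CS", "SYM-vs-RTP@LNG"),
    }
    for mod, grp in wide.groupby(level="modality"):
        for name, (c1, c2) in contrasts.items():
            a = grp[c1] if c1 in grp else pd.Series(dtype=float)
            b = grp[c2] if c2 in grp else pd.Series(dtype=float)
            ok = a.notna() & b.notna() if len(a) and len(b) else pd.Series(dtype=bool)
            n = int(ok.sum()) if len(ok) else 0
            p = paired_wilcoxon(a[ok], b[ok]) if n >= 2 else np.nan
            out.append(dict(modality=mod, contrast=name, n_pairs=n, p=p))
    return pd.DataFrame(out)


def overlap_table(results: Iterable[AbnormalityResult]
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(per-subject records, pooled medians, paired contrasts)."""
    records = jaccard_records(results)
    return records, pooled_overlap(records), paired_contrasts(records)


# ---------------------------------------------------------------------------
# Threshold sweeps


def binary_from_scheme(p_two: np.ndarray, mask: np.ndarray, scheme: str,
                       threshold: float, min_size: int = 3,
                       connectivity: int = 3) -> np.ndarray:
    """Re-threshold one probability map under a sweep scheme.

    fdr: BH step-up at q = threshold.  uncorrected: P' <= threshold.
    percentile: voxels whose P' lies below the (100 - pct)th percentile
    of this map's valid P' values (pct = threshold), i.e. the most
    extreme (100 - pct)% of voxels.  The minimum-cluster filter is
    re-applied in every scheme.
    """
    p_two = np.asarray(p_two, dtype=float)
    ok = np.isfinite(p_two)
    flagged = np.zeros(p_two.shape, dtype=bool)
    if scheme == "fdr":
        flagged = fdr_threshold(p_two, threshold)
    elif scheme == "uncorrected":
        flagged[ok] = p_two[ok] <= threshold
    elif scheme == "percentile":
        if not 0 < threshold < 100:
            raise ValueError("percentile threshold must lie in (0, 100)")
        cut = np.percentile(p_two[ok], 100.0 - threshold)
        flagged[ok] = p_two[ok] <= cut
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = flagged
    return cluster_filter(vol, min_size, connectivity)[mask]


def threshold_sweep(
    pmaps: Mapping[tuple[str, str, str], np.ndarray],
    mask: np.ndarray,
    scheme: str,
    grid: Sequence[float] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """CS-vs-LNG overlap across a threshold grid.

    ``pmaps`` maps (subject_id, analysis, timepoint) to the retained
    (V,) two-tailed probability map; both analyses must be present for
    a subject/timepoint to contribute.  Returns one row per (scheme,
    threshold, timepoint) with the median and quartiles of the
    per-subject Jaccard values.
    """
    config = config or AnalysisConfig()
    if grid is None:
        grid = config.sweep_grid(scheme)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    subjects = sorted({k[0] for k in pmaps})
    timepoints = sorted({k[2] for k in pmaps})
    rows = []
    for thr in grid:
        for tp in timepoints:
            vals = []
            for sid in subjects:
                p_cs = pmaps.get((sid, "CS", tp))
                p_lng = pmaps.get((sid, "LNG", tp))
                if p_cs is None or p_lng is None:
                    continue
                b_cs = binary_from_scheme(p_cs, mask, scheme, thr,
                                          config.min_cluster_size,
                                          config.connectivity)
                b_lng = binary_from_scheme(p_lng, mask, scheme, thr,
                                           config.min_cluster_size,
                                           config.connectivity)
                vals.append(jaccard(b_cs, b_lng))
            vals = np.asarray(vals, dtype=float)
            vals = vals[np.isfinite(vals)]
            med, q1, q3 = (np.percentile(vals, [50, 25, 75])
                           if vals.size else (np.nan,) * 3)
            rows.append(dict(scheme=scheme, threshold=float(thr), timepoint=tp,
                             n=int(vals.size), jaccard_median=med,
                             jaccard_q1=q1, jaccard_q3=q3))
    return pd.DataFrame(rows)
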