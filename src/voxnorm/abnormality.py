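"""Per-subject abnormality maps: probabilities -> FDR -> cluster filter -> direction.

A subject's map (cross-sectional: post-injury values; longitudinal:
post-minus-baseline changes) is scored against the normative model to
give one-tailed P and two-tailed P' per voxel.  Each single map is then
thresholded with a Benjamini-Hochberg step-up at FDR q over its valid
masked voxels, and connected abnormal components smaller than the
minimum cluster size (default 3, full 26-neighbourhood) are removed.
Surviving voxels are classified as positive (upper tail, P >= 0.975) or
negative (lower tail, P <= 0.025).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .core_io import AnalysisConfig, Modality, Session
from .normative import NormativeModel
from .synthetic import longitudinal_change  # re-export: LNG input construction

__all__ = [
    "AbnormalityResult", "ConsistencyError", "score_subject", "fdr_threshold",
    "cluster_filter", "threshold_map", "classify_direction", "analyze_stack",
    "summarize_extent", "representative_slice", "longitudinal_change",
]


class ConsistencyError(RuntimeError):
    """An abnormal voxel with mid-range P: upstream thresholding is broken."""


@dataclass
class AbnormalityResult:
    """Thresholded abnormality map for one (subject, modality, analysis, timepoint)."""

    subject_id: str
    modality: Modality
    analysis: str          # "CS" or "LNG"
    timepoint: Session     # baseline, SYM or RTP
    p_one: np.ndarray      # (V,) one-tailed P, NaN at invalid voxels
    p_two: np.ndarray      # (V,) two-tailed P'
    abnormal: np.ndarray   # (V,) bool, post FDR + cluster filter
    direction: np.ndarray  # (V,) int8 in {-1, 0, +1}
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.timepoint = Session(self.timepoint)
        if (self.abnormal & ~np.isfinite(self.p_two)).any():
            raise ValueError("abnormal voxels must have valid probabilities")
        if ((self.direction != 0) != self.abnormal).any():
            raise ValueError("direction must be nonzero exactly on abnormal voxels")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.p_two).sum())

    @property
    def abnormal_fraction(self) -> float:
        """Fraction of valid voxels flagged abnormal."""
        n = self.n_valid
        return float(self.abnormal.sum() / n) if n else np.nan

    @property
    def positive_fraction(self) -> float:
        """Of abnormal voxels, the fraction in the upper tail (NaN if none)."""
        n_abn = int(self.abnormal.sum())
        if n_abn == 0:
            return np.nan
        return float((self.direction == 1).sum() / n_abn)

    def volume(self, which: str = "abnormal") -> np.ndarray:
        vec = getattr(self, which)
        fill = 0.0 if which in ("abnormal", "direction") else np.nan
        vol = np.full(self.mask.shape, fill)
        vol[self.mask] = vec
        return vol


def score_subject(model: NormativeModel,
                  values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One- and two-tailed probability maps for one subject's (V,) map.

    For a longitudinal model, ``values`` must be the subject's
    post-minus-baseline change map.  Invalid voxels propagate as NaN and
    are excluded from every downstream count.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (model.n_voxels,):
        raise ValueError(f"expected a ({model.n_voxels},) map on the model grid")
    p_one = model.cdf(values)
    p_two = np.full_like(p_one, np.nan)
    ok = np.isfinite(p_one)
    p_two[ok] = 2.0 * np.minimum(p_one[ok], 1.0 - p_one[ok])
    return p_one, p_two


def fdr_threshold(p_two: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up over one map's valid voxels.

    A voxel is flagged iff its P' is at or below the BH cutoff for this
    single map.  NaN (invalid) voxels are never flagged; an all-missing
    map is an error.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p_two = np.asarray(p_two, dtype=float)
    ok = np.isfinite(p_two)
    if not ok.any():
        raise ValueError("all voxels missing: nothing to threshold")
    if (p_two[ok] < 0).any() or (p_two[ok] > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.zeros(p_two.shape, dtype=bool)
    out[ok] = multipletests(p_two[ok], alpha=q, method="fdr_bh")[0]
    return out


def cluster_filter(binary_vol: np.ndarray, min_size: int = 3,
                   connectivity: int = 3) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` voxels.

    ``connectivity`` follows scipy's rank convention on a 3-D grid:
    1 = faces (6-neighbourhood), 2 = +edges (18), 3 = +corners (26).
    """
    binary_vol = np.asarray(binary_vol, dtype=bool)
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if not binary_vol.any() or min_size == 1:
        return binary_vol.copy()
    structure = ndimage.generate_binary_structure(binary_vol.ndim, connectivity)
    labels, n = ndimage.label(binary_vol, structure=structure)
    if n == 0:
        return binary_vol.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def threshold_map(p_two: np.ndarray, mask: np.ndarray, q: float,
                  min_size: int = 3, connectivity: int = 3) -> np.ndarray:
    """FDR threshold + cluster filter; returns a (V,) boolean vector."""
    flagged = fdr_threshold(p_two, q)
    vol = np.zeros(mask.shape, dtype=bool)
    vol[mask] = flagged
    return cluster_filter(vol, min_size, connectivity)[mask]


def classify_direction(p_one: np.ndarray, abnormal: np.ndarray,
                       cutoff: float = 0.975) -> tuple[np.ndarray, float]:
    """Label abnormal voxels +1 (P >= cutoff) or -1 (P <= 1 - cutoff).

    Returns the (V,) direction map and the positive fraction (NaN when
    no voxels are abnormal).  An abnormal voxel with mid-range P cannot
    have survived FDR <= 0.05 thresholding and raises
    :class:`ConsistencyError`.
    """
    p_one = np.asarray(p_one, dtype=float)
    abnormal = np.asarray(abnormal, dtype=bool)
    direction = np.zeros(p_one.shape, dtype=np.int8)
    pos = abnormal & (p_one >= cutoff)
    neg = abnormal & (p_one <= 1.0 - cutoff)
    stray = abnormal & ~pos & ~neg
    if stray.any():
        raise ConsistencyError(
            f"{int(stray.sum())} abnormal voxels with "
            f"{1 - cutoff:g} < P < {cutoff:g}: upstream thresholding bug"
        )
    direction[pos] = 1
    direction[neg] = -1
    n_abn = int(abnormal.sum())
    positive_fraction = float(pos.sum() / n_abn) if n_abn else np.nan
    return direction, positive_fraction


def analyze_stack(model: NormativeModel, stack, analysis: str,
                  timepoint: Session | str,
                  config: AnalysisConfig | None = None
                  ) -> list[AbnormalityResult]:
    """Score and threshold every subject in a stack against one model."""
    config = config or AnalysisConfig()
    results = []
    for i, sid in enumerate(stack.subject_ids):
        p_one, p_two = score_subject(model, stack.values[i])
        abnormal = threshold_map(p_two, model.mask, config.fdr_q,
                                 config.min_cluster_size, config.connectivity)
        direction, _ = classify_direction(p_one, abnormal,
                                          config.positive_tail_cutoff)
        results.append(AbnormalityResult(
            subject_id=sid, modality=model.modality, analysis=analysis,
            timepoint=Session(timepoint), p_one=p_one, p_two=p_two,
            abnormal=abnormal, direction=direction, mask=model.mask,
            affine=model.affine))
    return results


def _quartiles(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    if len(x) == 0:
        return (np.nan, np.nan, np.nan)
    return tuple(np.percentile(x, [50, 25, 75]))


def summarize_extent(results: Iterable[AbnormalityResult]) -> pd.DataFrame:
    """Median [Q1, Q3] of abnormal-voxel percentage and positive fraction.

    One row per (modality, analysis, timepoint); missing positive
    fractions (subjects with no abnormal voxels) are excluded.
    """
    rows = [dict(modality=r.modality.value, analysis=r.analysis,
                 timepoint=r.timepoint.value, subject_id=r.subject_id,
                 abnormal_pct=100.0 * r.abnormal_fraction,
                 positive_fraction=r.positive_fraction)
            for r in results]
    if not rows:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(rows)
    out = []
    for (mod, ana, tp), grp in df.groupby(["modality", "analysis", "timepoint"],
                                          sort=True):
        med, q1, q3 = _quartiles(grp.abnormal_pct)
        pmed, pq1, pq3 = _quartiles(grp.positive_fraction)
        out.append(dict(modality=mod, analysis=ana, timepoint=tp,
                        n_subjects=len(grp),
                        abnormal_pct_median=med, abnormal_pct_q1=q1,
                        abnormal_pct_q3=q3,
                        positive_fraction_median=pmed,
                        positive_fraction_q1=pq1, positive_fraction_q3=pq3))
    return pd.DataFrame(out)


def representative_slice(maps: Sequence[np.ndarray | None]) -> int | None:
    """Axial slice maximizing the mean rank of per-map abnormal counts.

    Each available 3-D binary map ranks its axial (last-axis) slices by
    abnormal-voxel count (ties get average rank); the returned slice
    maximizes the mean rank across maps, lowest index on final ties.
    Returns None when every map is empty or missing.
    """
    from scipy.stats import rankdata

    available = [np.asarray(m, dtype=bool) for m in maps if m is not None]
    available = [m for m in available if m.any()]
    if not available:
        return None
    shapes = {m.shape for m in available}
    if len(shapes) > 1:
        raise ValueError("maps must share a grid")
    ranks = [rankdata(m.sum(axis=(0, 1))) for m in available]
    mean_rank = np.mean(ranks, axis=0)
    return int(np.argmax(mean_rank))  # argmax -> first = lowest slice index
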