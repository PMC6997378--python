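"""Control-cohort descriptive statistics and distributional QC.

CoV = std(X) / |mean(X)| per voxel across subjects (sample SD), and
CHG = 100 * (post - baseline) / baseline per voxel (median over
subjects), each summarized by the median and [Q1, Q3] over valid
voxels.  Voxel-wise Shapiro-Wilk tests with BH correction quantify the
fraction of voxels departing from normality -- the motivation for a
non-parametric normative model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import Modality, ParameterMapStack


@dataclass
class SummaryTable:
    """Per-voxel summary map plus its scalar median / quartiles."""

    measure: str            # "cov" or "chg_pct"
    modality: Modality
    map: np.ndarray         # (V,) with NaN at excluded voxels
    median: float
    q1: float
    q3: float
    n_voxels: int
    n_excluded: int


def _summarize(vec: np.ndarray, measure: str, modality: Modality,
               n_excluded: int) -> SummaryTable:
    ok = np.isfinite(vec)
    if not ok.any():
        raise ValueError("all voxels excluded: nothing to summarize")
    med, q1, q3 = np.percentile(vec[ok], [50, 25, 75])
    return SummaryTable(measure=measure, modality=modality, map=vec,
                        median=float(med), q1=float(q1), q3=float(q3),
                        n_voxels=int(ok.sum()), n_excluded=n_excluded)


def voxelwise_cov(stack: ParameterMapStack) -> SummaryTable:
    """Coefficient of variation per voxel: sample SD over |mean|.

    Voxels with zero mean are excluded (count reported); CoV is
    scale-invariant, so the summary does not depend on the map's units.
    """
    if stack.n_subjects < 2:
        raise ValueError("need at least 2 subjects for a CoV")
    mean = stack.values.mean(axis=0)
    sd = stack.values.std(axis=0, ddof=1)
    cov = np.full(stack.n_voxels, np.nan)
    ok = mean != 0
    cov[ok] = sd[ok] / np.abs(mean[ok])
    return _summarize(cov, "cov", stack.modality, int((~ok).sum()))


def percent_change(base: ParameterMapStack,
                   post: ParameterMapStack) -> SummaryTable:
    """Median longitudinal percent change per voxel.

    CHG = 100 * (post - baseline) / baseline per subject, then the
    median over subjects at each voxel; a voxel with any zero baseline
    is excluded (count reported).
    """
    base_aligned = base.select_subjects(post.subject_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        chg = 100.0 * (post.values - base_aligned.values) / base_aligned.values
    bad = (base_aligned.values == 0).any(axis=0)
    vec = np.where(bad, np.nan, np.median(chg, axis=0))
    return _summarize(vec, "chg_pct", post.modality, int(bad.sum()))


@dataclass
class NormalityQC:
    rejected_fraction: float
    p_values: np.ndarray    # (V,) Shapiro-Wilk p, NaN at excluded voxels
    rejected: np.ndarray    # (V,) bool after BH
    n_tested: int
    n_excluded: int


def normality_qc(stack: ParameterMapStack, q: float = 0.05) -> NormalityQC:
    """Fraction of voxels rejecting normality (Shapiro-Wilk, BH at FDR q).

    Degenerate (zero-variance) voxels cannot be tested and are excluded
    from both the test count and the rejected fraction.
    """
    if stack.n_subjects < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 subjects")
    sd = stack.values.std(axis=0)
    p = np.full(stack.n_voxels, np.nan)
    testable = np.flatnonzero(sd > 0)
    for v in testable:
        p[v] = stats.shapiro(stack.values[:, v]).pvalue
    if testable.size == 0:
        raise ValueError("no testable voxels")
    rejected = np.zeros(stack.n_voxels, dtype=bool)
    rejected[testable] = multipletests(p[testable], alpha=q,
                                       method="fdr_bh")[0]
    return NormalityQC(
        rejected_fraction=float(rejected.sum() / testable.size),
        p_values=p, rejected=rejected,
        n_tested=int(testable.size),
        n_excluded=int(stack.n_voxels - testable.size))
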