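"""End-to-end simulation experiments on synthetic cohorts with known truth.

Each experiment runs the full pipeline -- generate a cohort, fit the
per-voxel normative KDE, score and threshold subjects -- and measures a
single summary against the generator's ground truth: the empirical
false-discovery proportion of the cross-sectional pipeline, the
CS-vs-LNG overlap under disjoint stable-value and change injections,
and the recovery of the generator's own CoV calibration.  Problem sizes
(20^3 grids, 44 controls) are chosen so a full experiment runs in
minutes on one CPU; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .abnormality import analyze_stack, longitudinal_change
from .core_io import AnalysisConfig, Group, Modality, Session
from .normative import fit_normative_model
from .overlap import jaccard
from .summaries import voxelwise_cov
from .synthetic import (
    COV_SUMMARY, SyntheticCohortSpec, generate_cohort,
    place_disjoint_clusters, sample_cov_field,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n deterministic sub-seeds below 2^31 derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


@dataclass
class FdrExperimentResult:
    mean_fdp: float
    per_replicate_fdp: np.ndarray
    mean_sensitivity: float
    n_voxels: int
    n_replicates: int


def fdr_experiment(
    seed: int,
    n_replicates: int = 20,
    n_controls: int = 44,
    n_subjects: int = 20,
    shape: tuple[int, int, int] = (20, 20, 20),
    cov: float = 0.06,
    n_clusters: int = 26,
    cluster_size: int = 15,
    effect_sd: float = 6.0,
    config: AnalysisConfig | None = None,
) -> FdrExperimentResult:
    """False-discovery proportion of the CS pipeline under known injections.

    Pseudo-concussed subjects are drawn from the control law (Gaussian
    per-voxel, constant CoV, no skewed voxels) with +6-SD offsets
    injected into known equal-size clusters covering ~5% of the mask.
    Each replicate fits the normative model on its own control cohort,
    scores every subject at SYM, applies BH at q plus the minimum
    cluster-size filter, and pools detections over subjects; the FDP is
    the fraction of detected voxels outside the truth mask.
    """
    config = config or AnalysisConfig()
    fdps, sens = [], []
    n_voxels = 0
    for rep_seed in _child_seeds(seed, n_replicates):
        placer = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(rep_seed), 11])))
        mask = np.ones(shape, dtype=bool)
        clusters = place_disjoint_clusters(
            mask, n_clusters, cluster_size, effect_sd, placer,
            sessions="both", mode="value")
        spec = SyntheticCohortSpec(
            modality=Modality.FA, shape=shape, n_controls=n_controls,
            n_concussed=n_subjects, cov_field=cov, skew_fraction=0.0,
            injections=tuple(clusters), seed=int(rep_seed))
        cohort = generate_cohort(spec)
        model = fit_normative_model(cohort.stack(Group.CONTROL, Session.BASELINE),
                                    analysis="CS", config=config)
        results = analyze_stack(model, cohort.stack(Group.CONCUSSED, Session.SYM),
                                "CS", Session.SYM, config)
        truth = cohort.truth_mask("CS", Session.SYM)[mask]
        detected = np.sum([r.abnormal.sum() for r in results])
        false = np.sum([(r.abnormal & ~truth).sum() for r in results])
        hit = np.sum([(r.abnormal & truth).sum() for r in results])
        fdps.append(false / detected if detected else 0.0)
        sens.append(hit / (truth.sum() * len(results)))
        n_voxels = int(mask.sum())
    fdps = np.asarray(fdps, dtype=float)
    return FdrExperimentResult(
        mean_fdp=float(fdps.mean()), per_replicate_fdp=fdps,
        mean_sensitivity=float(np.mean(sens)), n_voxels=n_voxels,
        n_replicates=n_replicates)


@dataclass
class MechanismExperimentResult:
    median_jaccard: float
    per_pair_jaccard: np.ndarray
    n_voxels: int
    n_subjects: int


def mechanism_experiment(
    seed: int,
    n_controls: int = 44,
    n_concussed: int = 12,
    shape: tuple[int, int, int] = (20, 20, 20),
    n_clusters_per_mode: int = 8,
    cluster_size: int = 15,
    effect_sd: float = 6.0,
    config: AnalysisConfig | None = None,
) -> MechanismExperimentResult:
    """CS-vs-LNG overlap when the two effect types live at disjoint loci.

    Stable value offsets (cluster set A, shifting baseline and both
    post-injury sessions) model trait-like deviations the CS analysis
    should flag; change offsets (disjoint cluster set B, shifting only
    the post-injury sessions by multiples of the control change SD)
    model injury effects the LNG analysis should flag.  Both pipelines
    run at FDR 0.05 with the cluster filter, and the per-subject
    Jaccard between the two thresholded maps is collected at SYM and
    RTP.
    """
    config = config or AnalysisConfig()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 13])))
    mask = np.ones(shape, dtype=bool)
    both = place_disjoint_clusters(
        mask, 2 * n_clusters_per_mode, cluster_size, effect_sd, rng,
        sessions="both", mode="value")
    clusters = [
        replace(cl, mode="value" if i < n_clusters_per_mode else "change")
        for i, cl in enumerate(both)
    ]
    spec = SyntheticCohortSpec(
        modality=Modality.FA, shape=shape, n_controls=n_controls,
        n_concussed=n_concussed, injections=tuple(clusters), seed=seed)
    cohort = generate_cohort(spec)

    cs_model = fit_normative_model(cohort.stack(Group.CONTROL, Session.BASELINE),
                                   analysis="CS", config=config)
    ctl_change = longitudinal_change(cohort.stack(Group.CONTROL, Session.POSTSEASON),
                                     cohort.stack(Group.CONTROL, Session.BASELINE))
    lng_model = fit_normative_model(ctl_change, analysis="LNG", config=config)

    conc_base = cohort.stack(Group.CONCUSSED, Session.BASELINE)
    jaccards = []
    for tp in (Session.SYM, Session.RTP):
        conc = cohort.stack(Group.CONCUSSED, tp)
        cs_results = analyze_stack(cs_model, conc, "CS", tp, config)
        lng_results = analyze_stack(lng_model, longitudinal_change(conc, conc_base),
                                    "LNG", tp, config)
        for r_cs, r_lng in zip(cs_results, lng_results):
            jaccards.append(jaccard(r_cs.abnormal, r_lng.abnormal))
    jaccards = np.asarray(jaccards, dtype=float)
    finite = jaccards[np.isfinite(jaccards)]
    return MechanismExperimentResult(
        median_jaccard=float(np.median(finite)),
        per_pair_jaccard=jaccards, n_voxels=int(mask.sum()),
        n_subjects=n_concussed)


@dataclass
class CovCalibrationResult:
    median_cov: float
    target_median: float
    relative_error: float
    n_voxels: int


def cov_calibration_experiment(
    seed: int,
    modality: Modality | str = Modality.FA,
    n_controls: int = 44,
    shape: tuple[int, int, int] = (25, 20, 10),  # 5000 voxels
) -> CovCalibrationResult:
    """Recovery of a published control CoV summary by the generator.

    The per-voxel CoV field is sampled from a log-normal matched to the
    printed median and quartiles for the modality; 44 control baseline
    maps are simulated and the median voxel-wise sample CoV is compared
    with the printed median.
    """
    modality = Modality(modality)
    med, q1, q3 = COV_SUMMARY[modality]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 17])))
    n_vox = int(np.prod(shape))
    cov_field = sample_cov_field(med, q1, q3, n_vox, rng)
    spec = SyntheticCohortSpec(
        modality=modality, shape=shape, n_controls=n_controls, n_concussed=2,
        cov_field=cov_field, seed=seed)
    cohort = generate_cohort(spec)
    table = voxelwise_cov(cohort.stack(Group.CONTROL, Session.BASELINE))
    return CovCalibrationResult(
        median_cov=table.median, target_median=med,
        relative_error=abs(table.median - med) / med, n_voxels=n_vox)
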