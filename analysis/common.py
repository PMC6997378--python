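"""Shared study definition for the numbered analysis drivers.

One synthetic multi-modality cohort (44 controls, 12 concussed) with
stable-value injections at cluster set A (detectable cross-sectionally)
and change injections at disjoint set B (detectable longitudinally).
Cohorts regenerate deterministically from the study seed; fitted
normative models are cached under scratch/.
"""

from pathlib import Path

import numpy as np

from voxnorm.core_io import AnalysisConfig, Group, Modality, Session
from voxnorm.normative import NormativeModel, fit_normative_model
from voxnorm.abnormality import longitudinal_change
from voxnorm.synthetic import (
    SyntheticCohortSpec, generate_cohort, place_disjoint_clusters,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

STUDY_SEED = 20200203
GRID = (14, 14, 14)
N_CONTROLS = 44
N_CONCUSSED = 12
MODALITIES = (Modality.FA, Modality.MD, Modality.CBF)
CONFIG = AnalysisConfig()


def study_spec(modality: Modality) -> SyntheticCohortSpec:
    rng = np.random.default_rng(STUDY_SEED + 7)
    mask = np.ones(GRID, dtype=bool)
    clusters = place_disjoint_clusters(mask, 6, 12, 6.0, rng,
                                       sessions="both", mode="value")
    from dataclasses import replace
    clusters = [replace(cl, mode="value" if i < 3 else "change")
                for i, cl in enumerate(clusters)]
    return SyntheticCohortSpec(
        modality=modality, shape=GRID, n_controls=N_CONTROLS,
        n_concussed=N_CONCUSSED, injections=tuple(clusters),
        seed=STUDY_SEED)


def get_cohort(modality: Modality):
    return generate_cohort(study_spec(modality))


def get_model(modality: Modality, analysis: str) -> NormativeModel:
    """Fit (or reload) the normative model for one modality/analysis."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"model_{modality.value}_{analysis}.npz"
    if cache.exists():
        return NormativeModel.load(cache)
    cohort = get_cohort(modality)
    if analysis == "CS":
        stack = cohort.stack(Group.CONTROL, Session.BASELINE)
    else:
        stack = longitudinal_change(
            cohort.stack(Group.CONTROL, Session.POSTSEASON),
            cohort.stack(Group.CONTROL, Session.BASELINE))
    model = fit_normative_model(stack, analysis=analysis, config=CONFIG)
    model.save(cache)
    return model
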