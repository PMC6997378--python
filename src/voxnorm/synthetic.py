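"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator draws, for each subject s, voxel v and session,

    X = mu(v) * (1 + s_off(v) * delta_s(v) + s_noise(v) * eps + is_post * drift)

where delta_s is a unit-variance stable subject offset field (one draw
per subject, shared by every session of that subject), eps is
unit-variance session noise (one draw per session), both spatially
smoothed and optionally skewed at a designated voxel fraction, and
drift is the modality's median longitudinal percent change.  The split of the
across-subject baseline CoV field c(v) into a stable-offset share and a
session-noise share is governed by the change-scale parameter g =
sd(post - baseline) / baseline:

    s_noise(v) = g / sqrt(2)          (so sd of the change is g * mu)
    s_off(v)   = sqrt(c(v)^2 - g^2/2) (so baseline CoV across subjects is c)

Defaults for c, g and drift are calibrated to published control cohort
summaries for each modality, which makes baseline CoV, change CoV
(= g / |drift|) and median percent change come out right by
construction.  Because stable offsets dominate baseline variance (for
FA and CBF especially), cross-sectional scoring flags trait-like
deviations that longitudinal scoring cancels -- the mechanism behind
low CS-vs-LNG overlap.

Injected abnormalities are spatially clustered offsets in units of the
local control SD: "value" mode shifts the subject's baseline and the
affected post-injury sessions (a stable deviation, visible to CS only),
"change" mode shifts only the post-injury sessions by multiples of the
control change SD (visible to LNG).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core_io import (
    CohortManifest, Group, Modality, ParameterMapStack, Session, write_stack,
)

# Per-modality study conditions: baseline mean level, median across-subject
# baseline CoV, change scale g = sd(change)/baseline (the product of the
# drift magnitude and the change CoV), and median drift in percent.
MODALITY_DEFAULTS = {
    Modality.FA: dict(mean=0.5, cov=0.0586, change_rel_sd=0.0012 * 7.47,
                      drift_pct=-0.12),
    Modality.MD: dict(mean=7.0e-4, cov=0.0423, change_rel_sd=0.0141 * 2.26,
                      drift_pct=1.41),
    Modality.CBF: dict(mean=50.0, cov=0.443, change_rel_sd=0.0187 * 2.99,
                       drift_pct=-1.87),
}

# Printed control CoV summaries (median, Q1, Q3) usable as calibration
# targets for sampled CoV fields.
COV_SUMMARY = {
    Modality.FA: (0.0586, 0.0468, 0.0766),
    Modality.MD: (0.0423, 0.0324, 0.0664),
    Modality.CBF: (0.443, 0.368, 0.562),
}

_Z75 = 0.6744897501960817  # standard normal 75th percentile


def sample_cov_field(median: float, q1: float, q3: float, size: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-voxel CoV values from a log-normal matched to median and quartiles."""
    if not 0 < q1 < median < q3:
        raise ValueError("need 0 < Q1 < median < Q3")
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


@dataclass
class InjectionCluster:
    """One spatially clustered abnormality.

    The cluster is either a Euclidean ball (``radius`` in voxels) or,
    when ``n_voxels`` is given, exactly that many mask voxels nearest
    the center (raster order breaks distance ties).  ``effect_sd`` is
    in units of the local control SD: the baseline value SD for
    ``mode="value"`` and the control change SD for ``mode="change"``.
    """

    center: tuple[int, int, int]
    effect_sd: float
    radius: float = 0.0
    n_voxels: int | None = None
    sign: int = 1
    sessions: Literal["SYM", "RTP", "both"] = "both"
    mode: Literal["value", "change"] = "value"

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_sd):
            raise ValueError("effect size must be finite")
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    def affected_sessions(self) -> tuple[Session, ...]:
        if self.sessions == "both":
            return (Session.SYM, Session.RTP)
        return (Session(self.sessions),)


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for one synthetic cohort (one modality)."""

    modality: Modality = Modality.FA
    shape: tuple[int, int, int] = (20, 20, 20)
    n_controls: int = 44
    n_concussed: int = 12
    mask: np.ndarray | None = None            # default: full grid
    mean_field: np.ndarray | None = None      # default: constant modality mean
    cov_field: np.ndarray | float | None = None   # default: constant modality CoV
    change_rel_sd: float | None = None        # g = sd(change)/baseline
    drift_pct: float | None = None            # median longitudinal change, %
    skew_fraction: float = 0.15               # voxel fraction with skewed noise
    skew_strength: float = 0.8                # log-normal shape of skewed noise
    smooth_vox: float = 1.5                   # Gaussian smoothing of noise fields
    injections: tuple[InjectionCluster, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        if self.n_controls < 2:
            raise ValueError("need at least 2 controls")
        if not 0.0 <= self.skew_fraction <= 1.0:
            raise ValueError("skew_fraction must lie in [0, 1]")
        defaults = MODALITY_DEFAULTS[self.modality]
        if self.change_rel_sd is None:
            self.change_rel_sd = defaults["change_rel_sd"]
        if self.drift_pct is None:
            self.drift_pct = defaults["drift_pct"]

    def resolved_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != tuple(self.shape):
            raise ValueError("mask shape does not match grid shape")
        return m

    def resolved_mean(self, mask: np.ndarray) -> np.ndarray:
        if self.mean_field is None:
            return np.full(int(mask.sum()), MODALITY_DEFAULTS[self.modality]["mean"])
        mf = np.asarray(self.mean_field, dtype=float)
        return mf[mask] if mf.ndim == 3 else mf

    def resolved_cov(self, mask: np.ndarray) -> np.ndarray:
        cov = self.cov_field
        if cov is None:
            cov = MODALITY_DEFAULTS[self.modality]["cov"]
        if np.isscalar(cov):
            out = np.full(int(mask.sum()), float(cov))
        else:
            cov = np.asarray(cov, dtype=float)
            out = cov[mask] if cov.ndim == 3 else cov
        if (out < 0).any():
            raise ValueError("CoV field must be non-negative")
        return out


@dataclass
class SyntheticCohort:
    """Generated stacks plus ground-truth injection masks."""

    spec: SyntheticCohortSpec
    mask: np.ndarray
    affine: np.ndarray
    stacks: dict[tuple[Group, Session], ParameterMapStack]
    truth: dict[tuple[str, Session], np.ndarray]  # (mode, session) -> bool volume

    def stack(self, group: Group | str, session: Session | str) -> ParameterMapStack:
        return self.stacks[(Group(group), Session(session))]

    def truth_mask(self, analysis: Literal["CS", "LNG"],
                   session: Session | str) -> np.ndarray:
        """Injected voxels detectable by the given analysis at a session.

        CS truth is the value-mode clusters (stable deviations); LNG
        truth is the change-mode clusters (post-injury changes).
        """
        mode = "value" if analysis == "CS" else "change"
        key = (mode, Session(session))
        if key in self.truth:
            return self.truth[key]
        return np.zeros(self.mask.shape, dtype=bool)


# ---------------------------------------------------------------------------
# Noise machinery


@functools.lru_cache(maxsize=32)
def _smooth_norm(shape: tuple[int, ...], sigma: float) -> float:
    """Per-voxel SD of unit white noise after periodic Gaussian smoothing."""
    imp = np.zeros(shape)
    imp[tuple(s // 2 for s in shape)] = 1.0
    resp = gaussian_filter(imp, sigma, mode="wrap")
    return float(np.sqrt((resp ** 2).sum()))


def _unit_noise_field(rng: np.random.Generator, shape: tuple[int, ...],
                      sigma: float) -> np.ndarray:
    """Spatially smoothed noise with unit variance at every voxel.

    Smoothing uses periodic boundaries so the smoothing operator is
    stationary and the variance renormalization is exact.
    """
    x = rng.standard_normal(shape)
    if sigma <= 0:
        return x
    return gaussian_filter(x, sigma, mode="wrap") / _smooth_norm(tuple(shape), sigma)


def _skew_transform(g: np.ndarray, strength: float) -> np.ndarray:
    """Map standard-normal marginals to a standardized shifted log-normal."""
    if strength <= 0:
        return g
    m = np.exp(strength ** 2 / 2.0)
    sd = np.sqrt((np.exp(strength ** 2) - 1.0) * np.exp(strength ** 2))
    return (np.exp(strength * g) - m) / sd


def _subject_rng(seed: int, group: Group, index: int) -> np.random.Generator:
    """Deterministic per-subject stream: adding subjects never perturbs others."""
    code = 1 if group is Group.CONTROL else 2
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([seed, code, index])))


_VALUE_FLOOR = {Modality.FA: 1e-6, Modality.MD: 1e-12, Modality.CBF: 0.0}
_VALUE_CEIL = {Modality.FA: 1.0, Modality.MD: np.inf, Modality.CBF: np.inf}


# ---------------------------------------------------------------------------
# Cluster geometry


def cluster_voxel_index(mask: np.ndarray, cluster: InjectionCluster) -> np.ndarray:
    """Indices (into the masked-voxel vector) of one cluster's voxels."""
    mask = np.asarray(mask, dtype=bool)
    center = tuple(int(c) for c in cluster.center)
    if any(not 0 <= c < s for c, s in zip(center, mask.shape)):
        raise ValueError(f"cluster center {center} outside the grid")
    if not mask[center]:
        raise ValueError(f"cluster center {center} lies outside the mask")
    coords = np.argwhere(mask)  # raster order, matches the voxel vector
    dist = np.sqrt(((coords - np.asarray(center)) ** 2).sum(axis=1))
    if cluster.n_voxels is not None:
        if cluster.n_voxels > coords.shape[0]:
            raise ValueError("grid too small for requested cluster size")
        order = np.lexsort((np.arange(coords.shape[0]), dist))
        return np.sort(order[: cluster.n_voxels])
    return np.flatnonzero(dist <= cluster.radius)


def place_disjoint_clusters(
    mask: np.ndarray, n_clusters: int, n_voxels: int, effect_sd: float,
    rng: np.random.Generator, sign: int = 1,
    sessions: str = "both", mode: str = "value", min_center_dist: float = 5.0,
    max_tries: int = 10000,
) -> list[InjectionCluster]:
    """Randomly place non-overlapping equal-size clusters inside the mask."""
    coords = np.argwhere(mask)
    centers: list[np.ndarray] = []
    clusters: list[InjectionCluster] = []
    taken = np.zeros(int(mask.sum()), dtype=bool)
    tries = 0
    while len(clusters) < n_clusters:
        tries += 1
        if tries > max_tries:
            raise ValueError("grid too small for the requested clusters")
        cand = coords[rng.integers(coords.shape[0])]
        if centers and np.sqrt(((np.array(centers) - cand) ** 2).sum(axis=1)).min() < min_center_dist:
            continue
        cl = InjectionCluster(center=tuple(int(c) for c in cand),
                              effect_sd=effect_sd, n_voxels=n_voxels,
                              sign=sign, sessions=sessions, mode=mode)
        idx = cluster_voxel_index(mask, cl)
        if taken[idx].any():
            continue
        taken[idx] = True
        centers.append(cand)
        clusters.append(cl)
    return clusters


# ---------------------------------------------------------------------------
# Generation


def inject_abnormalities(
    stack: ParameterMapStack,
    clusters: Sequence[InjectionCluster],
    sd_field: np.ndarray,
) -> tuple[ParameterMapStack, np.ndarray]:
    """Shift injected voxels by sign * effect * SD(v); return stack + truth.

    ``sd_field`` is the per-voxel normative SD (vector over masked
    voxels) defining the effect-size unit.  All other voxels are
    untouched; the truth volume marks exactly the union of cluster
    voxels (recorded even for zero effect sizes).
    """
    sd_field = np.asarray(sd_field, dtype=float)
    truth = np.zeros(stack.mask.shape, dtype=bool)
    values = stack.values.copy()
    vox_idx = stack.voxel_index
    for cl in clusters:
        idx = cluster_voxel_index(stack.mask, cl)
        if not (sd_field[idx] > 0).all():
            raise ValueError("normative SD must be positive on injected voxels")
        values[:, idx] += cl.sign * cl.effect_sd * sd_field[idx]
        truth.flat[vox_idx[idx]] = True
    return replace(stack, values=values), truth


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate control and concussed stacks for every session, plus truth.

    Controls get baseline + postseason sessions; concussed subjects get
    baseline + SYM + RTP.  Identical specs (same seed) produce identical
    cohorts.
    """
    mask = spec.resolved_mask()
    n_vox = int(mask.sum())
    mu = spec.resolved_mean(mask)
    cov = spec.resolved_cov(mask)
    g = float(spec.change_rel_sd)
    s_noise = np.full(n_vox, g / np.sqrt(2.0))
    s_off = np.sqrt(np.clip(cov ** 2 - g ** 2 / 2.0, 0.0, None))
    drift = spec.drift_pct / 100.0
    affine = np.diag([3.0, 3.0, 3.0, 1.0])

    for cl in spec.injections:
        cluster_voxel_index(mask, cl)  # validate geometry up front

    cohort_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([spec.seed, 0])))
    skewed = np.zeros(n_vox, dtype=bool)
    n_skew = int(round(spec.skew_fraction * n_vox))
    if n_skew:
        skewed[cohort_rng.choice(n_vox, size=n_skew, replace=False)] = True

    def skew_if_flagged(field: np.ndarray) -> np.ndarray:
        if not n_skew:
            return field
        return np.where(skewed, _skew_transform(field, spec.skew_strength), field)

    def draw_subject(rng: np.random.Generator,
                     sessions: Sequence[Session]) -> dict[Session, np.ndarray]:
        # stable offset field: one draw per subject, shared across sessions
        delta = skew_if_flagged(_unit_noise_field(rng, spec.shape,
                                                  spec.smooth_vox)[mask])
        out = {}
        for sess in sessions:
            eps = skew_if_flagged(_unit_noise_field(rng, spec.shape,
                                                    spec.smooth_vox)[mask])
            rel = 1.0 + s_off * delta + s_noise * eps
            if sess is not Session.BASELINE:
                rel = rel + drift
            out[sess] = mu * rel
        return out

    def build_group(group: Group, n: int, sessions: tuple[Session, ...],
                    prefix: str) -> dict[Session, ParameterMapStack]:
        per_session = {s: [] for s in sessions}
        ids = [f"{prefix}{i:03d}" for i in range(n)]
        for i in range(n):
            maps = draw_subject(_subject_rng(spec.seed, group, i), sessions)
            for s in sessions:
                per_session[s].append(maps[s])
        stacks = {}
        for s in sessions:
            vals = np.vstack(per_session[s])
            vals = np.clip(vals, _VALUE_FLOOR[spec.modality],
                           _VALUE_CEIL[spec.modality])
            stacks[s] = ParameterMapStack(
                modality=spec.modality, session=s, subject_ids=list(ids),
                values=vals, mask=mask, affine=affine)
        return stacks

    ctl = build_group(Group.CONTROL, spec.n_controls,
                      (Session.BASELINE, Session.POSTSEASON), "ctl")
    conc = build_group(Group.CONCUSSED, spec.n_concussed,
                       (Session.BASELINE, Session.SYM, Session.RTP), "conc")

    # Injections: value mode shifts baseline + affected post sessions by
    # multiples of the baseline value SD; change mode shifts only the
    # affected post sessions by multiples of the control change SD.
    sd_value = cov * mu
    sd_change = g * mu
    truth: dict[tuple[str, Session], np.ndarray] = {}
    vox_idx = np.flatnonzero(mask)
    for cl in spec.injections:
        sd = sd_value if cl.mode == "value" else sd_change
        idx = cluster_voxel_index(mask, cl)
        if not (sd[idx] > 0).all():
            raise ValueError("normative SD must be positive on injected voxels")
        delta = cl.sign * cl.effect_sd * sd[idx]
        targets = list(cl.affected_sessions())
        if cl.mode == "value":
            targets.append(Session.BASELINE)
        for sess in targets:
            conc[sess].values[:, idx] += delta
        for sess in cl.affected_sessions():
            vol = truth.setdefault((cl.mode, sess),
                                   np.zeros(mask.shape, dtype=bool))
            vol.flat[vox_idx[idx]] = True

    stacks = {(Group.CONTROL, s): st for s, st in ctl.items()}
    stacks.update({(Group.CONCUSSED, s): st for s, st in conc.items()})
    return SyntheticCohort(spec=spec, mask=mask, affine=affine,
                           stacks=stacks, truth=truth)


def longitudinal_change(post: ParameterMapStack,
                        base: ParameterMapStack) -> ParameterMapStack:
    """Post-minus-baseline change stack over the subjects present in both.

    Raises naming the subjects if any post-session subject lacks a
    baseline scan.
    """
    if post.mask.shape != base.mask.shape or not np.array_equal(post.mask, base.mask):
        raise ValueError("change requires identical masks")
    missing = [s for s in post.subject_ids if s not in set(base.subject_ids)]
    if missing:
        raise ValueError(f"missing baseline data for subjects: {missing}")
    base_aligned = base.select_subjects(post.subject_ids)
    return ParameterMapStack(
        modality=post.modality, session=Session.CHANGE,
        subject_ids=list(post.subject_ids),
        values=post.values - base_aligned.values,
        mask=post.mask, affine=post.affine)


# ---------------------------------------------------------------------------
# Toy atlas


def generate_toy_atlas(mask: np.ndarray, n_regions: int, seed: int = 0):
    """Partition the mask into contiguous-ish regions by nearest seed voxel.

    Every masked voxel receives exactly one positive label and every
    region is non-empty (the seed voxel belongs to its own region).
    Distance ties resolve to the lowest region id.
    """
    from .localization import AtlasParcellation  # local import: avoid cycle

    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if not 1 <= n_regions <= n_vox:
        raise ValueError("n_regions must lie in [1, mask voxel count]")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 7])))
    coords = np.argwhere(mask)
    seeds = coords[rng.choice(n_vox, size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels_vec = np.argmin(d2, axis=1) + 1  # argmin ties -> lowest region id
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = labels_vec
    names = {r: f"region_{r:02d}" for r in range(1, n_regions + 1)}
    return AtlasParcellation(labels=labels, names=names)


# ---------------------------------------------------------------------------
# Fixture output


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> CohortManifest:
    """Write every stack as per-subject NIfTI volumes plus a manifest TSV."""
    directory = Path(directory)
    frames = []
    for (group, session), stack in cohort.stacks.items():
        if session is Session.CHANGE:
            continue
        frames.append(write_stack(stack, directory / group.value, group=group))
    frame = pd.concat(frames, ignore_index=True)
    manifest = CohortManifest(frame)
    manifest.to_tsv(directory / "manifest.tsv")
    for (mode, session), vol in cohort.truth.items():
        from .core_io import save_volume
        save_volume(vol.astype(float), cohort.affine,
                    directory / f"truth_{mode}_{session.value}.nii.gz")
    return manifest
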