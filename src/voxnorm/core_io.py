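"""Domain types, volume/table I/O, and mask construction.

All per-voxel arrays in this package are 1-D vectors over the *masked*
voxels of a single analysis grid.  The linear order is fixed: ascending
C-order (raster) index of the 3-D mask, i.e. ``np.flatnonzero(mask)``.
Extracting with ``volume[mask]`` and embedding with
``volume[mask] = vector`` both honour this order, so per-voxel arrays
align across every module.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("voxnorm")


class Modality(str, enum.Enum):
    """MRI parameter map type."""

    FA = "FA"    # fractional anisotropy, unitless in [0, 1]
    MD = "MD"    # mean diffusivity, mm^2/s
    CBF = "CBF"  # cerebral blood flow, mL/100 g/min


class Session(str, enum.Enum):
    BASELINE = "baseline"
    POSTSEASON = "postseason"
    SYM = "SYM"          # early symptomatic post-injury scan
    RTP = "RTP"          # return-to-play scan
    CHANGE = "change"    # a difference of two sessions (post - baseline)


class Group(str, enum.Enum):
    CONTROL = "control"
    CONCUSSED = "concussed"


# Tissue-mask thresholds (strict inequalities): analyses are restricted to
# white matter via mean FA > 0.25, and to grey matter via mean control
# CBF > 20 mL/100 g/min.  MD uses the FA-derived white-matter mask.
FA_MASK_THRESHOLD = 0.25
CBF_MASK_THRESHOLD = 20.0


class GridMismatchError(ValueError):
    """Volume shape or affine does not match the analysis grid."""


class MissingSessionError(ValueError):
    """Requested (subject, session) rows absent from the manifest."""


class EmptyMaskError(ValueError):
    """A tissue mask came out empty: nothing to analyze."""


def _as_value_session(session: Session) -> bool:
    return session is not Session.CHANGE


@dataclass
class ParameterMapStack:
    """Aligned masked-voxel vectors for many subjects of one modality/session.

    ``values`` has shape (n_subjects, n_voxels) with columns in the fixed
    raster order of the mask.  Range invariants (FA in [0, 1], MD > 0)
    apply to value sessions only; ``change`` stacks hold signed
    differences and are exempt.
    """

    modality: Modality
    session: Session
    subject_ids: list[str]
    values: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.modality = Modality(self.modality)
        self.session = Session(self.session)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_voxels)")
        n_vox = int(self.mask.sum())
        if self.values.shape != (len(self.subject_ids), n_vox):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {n_vox} masked voxels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite values inside the mask")
        if _as_value_session(self.session):
            if self.modality is Modality.FA and (
                (self.values < 0).any() or (self.values > 1).any()
            ):
                raise ValueError("FA values must lie in [0, 1]")
            if self.modality is Modality.MD and (self.values <= 0).any():
                raise ValueError("MD values must be positive")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def voxel_index(self) -> np.ndarray:
        """Raster indices of masked voxels (the documented linear order)."""
        return np.flatnonzero(self.mask)

    def to_volume(self, row: int, fill: float = np.nan) -> np.ndarray:
        """Embed one subject's vector back into the 3-D grid."""
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = self.values[row]
        return vol

    def select_subjects(self, subject_ids: Sequence[str]) -> "ParameterMapStack":
        order = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in order]
        if missing:
            raise MissingSessionError(
                f"subjects absent from {self.session.value} stack: {missing}"
            )
        rows = [order[s] for s in subject_ids]
        return dataclasses.replace(
            self, subject_ids=list(subject_ids), values=self.values[rows]
        )


@dataclass
class CohortManifest:
    """Tabular index of the cohort: one row per (subject, session, modality).

    Columns: subject_id, group, session, modality, path, and optional
    timing covariates days_from_baseline / days_post_concussion.
    """

    frame: pd.DataFrame

    REQUIRED = ("subject_id", "group", "session", "modality", "path")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        key = self.frame[["subject_id", "session", "modality"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (subject, session, modality) rows: {dupes}")
        for col, allowed in (("group", Group), ("session", Session), ("modality", Modality)):
            bad = set(self.frame[col]) - {m.value for m in allowed}
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortManifest":
        return cls(pd.read_csv(path, sep="\t", dtype={"subject_id": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def select(self, group: Group | str, session: Session | str,
               modality: Modality | str) -> pd.DataFrame:
        f = self.frame
        sel = f[(f.group == Group(group).value)
                & (f.session == Session(session).value)
                & (f.modality == Modality(modality).value)]
        return sel.reset_index(drop=True)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the abnormality-mapping pipeline."""

    fdr_q: float = 0.05
    min_cluster_size: int = 3
    connectivity: int = 3  # scipy connectivity rank: 1=faces, 2=+edges, 3=+corners
    bw_grid_min: float = 0.01   # bandwidth grid bounds, multiples of sample SD
    bw_grid_max: float = 10.0
    bw_grid_size: int = 50
    positive_tail_cutoff: float = 0.975
    fdr_sweep_bounds: tuple[float, float] = (0.005, 0.10)
    uncorrected_sweep_bounds: tuple[float, float] = (0.005, 0.05)
    percentile_sweep_bounds: tuple[float, float] = (95.0, 99.9)
    sweep_points: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")
        if not (0 < self.bw_grid_min < self.bw_grid_max):
            raise ValueError("bandwidth bounds must be positive and increasing")
        if self.bw_grid_size < 2:
            raise ValueError("bw_grid_size must be >= 2")
        if not 0.5 < self.positive_tail_cutoff < 1:
            raise ValueError("positive_tail_cutoff must lie in (0.5, 1)")

    @property
    def bandwidth_ratios(self) -> np.ndarray:
        """Log-spaced bandwidth candidates as multiples of the sample SD."""
        return np.geomspace(self.bw_grid_min, self.bw_grid_max, self.bw_grid_size)

    def sweep_grid(self, scheme: str) -> np.ndarray:
        bounds = {
            "fdr": self.fdr_sweep_bounds,
            "uncorrected": self.uncorrected_sweep_bounds,
            "percentile": self.percentile_sweep_bounds,
        }[scheme]
        return np.linspace(bounds[0], bounds[1], self.sweep_points)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fdr_sweep_bounds", "uncorrected_sweep_bounds",
                    "percentile_sweep_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        for key, val in raw.items():
            if isinstance(val, tuple):
                raw[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Volume I/O


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3-D volume as NIfTI, preserving float64 bit-exactly."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(dtype=np.float64)), img.affine


def load_stack(
    manifest: CohortManifest,
    group: Group | str,
    session: Session | str,
    modality: Modality | str,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    subject_ids: Sequence[str] | None = None,
) -> ParameterMapStack:
    """Load the selected cohort slice into a masked value matrix.

    Rows follow manifest order (or ``subject_ids`` order when given);
    columns follow the fixed raster order of ``mask``.  Raises
    :class:`GridMismatchError` naming the offending file on any
    shape/affine disagreement and :class:`MissingSessionError` listing
    absent (subject, session) pairs.
    """
    mask = np.asarray(mask, dtype=bool)
    sel = manifest.select(group, session, modality)
    if subject_ids is not None:
        have = set(sel.subject_id)
        missing = [(s, Session(session).value) for s in subject_ids if s not in have]
        if missing:
            raise MissingSessionError(f"missing (subject, session) pairs: {missing}")
        sel = sel.set_index("subject_id").loc[list(subject_ids)].reset_index()
    if len(sel) == 0:
        raise MissingSessionError(
            f"no rows for group={Group(group).value}, session={Session(session).value}, "
            f"modality={Modality(modality).value}"
        )
    rows, ref_affine = [], affine
    for rec in sel.itertuples():
        data, aff = load_volume(rec.path)
        if data.shape != mask.shape:
            raise GridMismatchError(
                f"{rec.path}: shape {data.shape} != mask shape {mask.shape}"
            )
        if ref_affine is None:
            ref_affine = aff
        elif not np.allclose(aff, ref_affine, atol=1e-4):
            raise GridMismatchError(f"{rec.path}: affine differs from reference grid")
        vec = data[mask]
        if not np.isfinite(vec).all():
            raise ValueError(f"{rec.path}: non-finite values inside the mask")
        rows.append(vec)
    stack = ParameterMapStack(
        modality=Modality(modality),
        session=Session(session),
        subject_ids=list(sel.subject_id),
        values=np.vstack(rows),
        mask=mask,
        affine=ref_affine,
    )
    log.info("loaded stack group=%s session=%s modality=%s subjects=%d voxels=%d",
             Group(group).value, Session(session).value, Modality(modality).value,
             stack.n_subjects, stack.n_voxels)
    return stack


def write_stack(stack: ParameterMapStack, directory: str | Path,
                group: Group | str = Group.CONTROL) -> pd.DataFrame:
    """Write one NIfTI per subject; return the matching manifest rows."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(stack.subject_ids):
        path = directory / f"{sid}_{stack.session.value}_{stack.modality.value}.nii.gz"
        save_volume(stack.to_volume(i, fill=0.0), stack.affine, path)
        rows.append(dict(subject_id=sid, group=Group(group).value,
                         session=stack.session.value,
                         modality=stack.modality.value, path=str(path)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mask construction


def threshold_mask(mean_map: np.ndarray, threshold: float) -> np.ndarray:
    """Strict-inequality mask: voxel included iff mean_map > threshold."""
    mean_map = np.asarray(mean_map, dtype=float)
    if not np.isfinite(mean_map).all():
        raise ValueError("mean map contains non-finite values")
    return mean_map > threshold


def build_tissue_mask(
    mean_map: np.ndarray,
    modality: Modality | str,
    fa_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Analysis mask for one modality from a cohort mean map.

    FA: white matter, mean FA > 0.25.  CBF: grey matter, mean CBF > 20
    mL/100 g/min.  MD: analysed within the FA-derived white-matter mask,
    which the caller must supply.
    """
    modality = Modality(modality)
    if modality is Modality.MD:
        if fa_mask is None:
            raise ValueError("MD mask is the FA-derived mask; pass fa_mask")
        mask = np.asarray(fa_mask, dtype=bool)
    elif modality is Modality.FA:
        mask = threshold_mask(mean_map, FA_MASK_THRESHOLD)
    else:
        mask = threshold_mask(mean_map, CBF_MASK_THRESHOLD)
    if not mask.any():
        raise EmptyMaskError(f"{modality.value} tissue mask is empty")
    return mask
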