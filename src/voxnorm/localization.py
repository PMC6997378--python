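"""Atlas-based regional localization of abnormality clusters.

Each thresholded map is parcellated into connected clusters; every
cluster is assigned the set of atlas regions it overlaps, falling back
to the region whose center of mass is nearest (Euclidean, voxel
coordinates) when a cluster touches only unlabeled background.  Regional
frequency counts the number of abnormality maps -- not clusters -- with
at least one cluster assigned to the region, and the concordance of the
cross-sectional and longitudinal frequency profiles is a Spearman
correlation with a bootstrap confidence interval over regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats


@dataclass
class AtlasParcellation:
    """Integer-labeled atlas volume (0 = background) with region names."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D volume")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        present = self.region_ids
        if present.size == 0:
            raise ValueError("atlas has zero regions")
        if not self.names:
            self.names = {int(r): f"region_{int(r):02d}" for r in present}
        empty = [r for r in self.names if r not in set(present.tolist())]
        if empty:
            raise ValueError(f"named regions with no voxels: {empty}")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def centers_of_mass(self) -> dict[int, np.ndarray]:
        """Region id -> center of mass in voxel coordinates."""
        ids = self.region_ids
        coms = ndimage.center_of_mass(self.labels > 0, self.labels, ids)
        return {int(r): np.asarray(c, dtype=float) for r, c in zip(ids, coms)}

    @classmethod
    def from_tsv(cls, labels: np.ndarray, lookup_path) -> "AtlasParcellation":
        """Attach a two-column id -> name lookup table to a label volume."""
        tab = pd.read_csv(lookup_path, sep="\t", header=0)
        names = dict(zip(tab.iloc[:, 0].astype(int), tab.iloc[:, 1].astype(str)))
        return cls(labels=labels, names=names)


def assign_clusters(binary_vol: np.ndarray, atlas: AtlasParcellation,
                    connectivity: int = 3) -> dict[int, frozenset[int]]:
    """Cluster id -> set of assigned atlas regions.

    Clusters come from connected-component labeling under the same
    neighbourhood as the cluster-extent filter.  A cluster overlapping
    only background is assigned the single region with the nearest
    center of mass (ties to the lowest region id), so no abnormal
    voxel is ever dropped from regional summaries.
    """
    binary_vol = np.asarray(binary_vol, dtype=bool)
    if binary_vol.shape != atlas.labels.shape:
        raise ValueError("map and atlas must share a grid")
    structure = ndimage.generate_binary_structure(3, connectivity)
    cluster_labels, n_clusters = ndimage.label(binary_vol, structure=structure)
    if n_clusters == 0:
        return {}
    coms = atlas.centers_of_mass
    region_ids = sorted(coms)
    com_matrix = np.array([coms[r] for r in region_ids])
    out: dict[int, frozenset[int]] = {}
    for cid in range(1, n_clusters + 1):
        in_cluster = cluster_labels == cid
        overlap = np.unique(atlas.labels[in_cluster])
        overlap = overlap[overlap > 0]
        if overlap.size:
            out[cid] = frozenset(int(r) for r in overlap)
            continue
        ccom = np.argwhere(in_cluster).mean(axis=0)
        d = np.sqrt(((com_matrix - ccom) ** 2).sum(axis=1))
        # argmin over ids sorted ascending -> lowest region id on ties
        out[cid] = frozenset({region_ids[int(np.argmin(d))]})
    return out


def frequency_map(maps: Iterable[np.ndarray], atlas: AtlasParcellation,
                  connectivity: int = 3, tag: str = "") -> pd.DataFrame:
    """Per-region count of maps with >= 1 assigned cluster.

    A map with several clusters in one region increments that region
    once.  Counts are invariant to map and cluster ordering.
    """
    counts = {int(r): 0 for r in atlas.region_ids}
    n_maps = 0
    for vol in maps:
        n_maps += 1
        regions: set[int] = set()
        for assigned in assign_clusters(vol, atlas, connectivity).values():
            regions |= assigned
        for r in regions:
            counts[r] += 1
    return pd.DataFrame({
        "region_id": list(counts),
        "region_name": [atlas.names.get(r, str(r)) for r in counts],
        "count": list(counts.values()),
        "n_maps": n_maps,
        "analysis": tag,
    })


class ConcordanceResult(NamedTuple):
    rho: float
    ci_low: float
    ci_high: float
    n_boot: int


def regional_concordance(freq_a: Sequence[float], freq_b: Sequence[float],
                         n_boot: int = 10000, seed: int = 0
                         ) -> ConcordanceResult:
    """Spearman correlation of two regional frequency profiles + bootstrap CI.

    Regions (the correlated units) are resampled with replacement;
    the interval is the percentile 95% CI.  Constant input profiles are
    not rankable and return NaN throughout.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frequency vectors must cover the same region set")
    if a.size < 3:
        raise ValueError("need at least 3 regions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ConcordanceResult(np.nan, np.nan, np.nan, n_boot)
    rho = float(stats.spearmanr(a, b).statistic)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, a.size, size=a.size)
        ra, rb = a[idx], b[idx]
        if np.ptp(ra) == 0 or np.ptp(rb) == 0:
            boots[i] = np.nan
            continue
        boots[i] = stats.spearmanr(ra, rb).statistic
    boots = boots[np.isfinite(boots)]
    if boots.size == 0:
        return ConcordanceResult(rho, np.nan, np.nan, n_boot)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ConcordanceResult(rho, float(lo), float(hi), n_boot)
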