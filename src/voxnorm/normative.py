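"""Per-voxel normative distributions by robust Gaussian kernel density estimation.

For each voxel, the control sample X_1..X_N defines a normative density

    f_hat(x) = sum_n w_n * phi((x - X_n) / h) / h

with a single bandwidth h chosen by least-squares leave-one-out
cross-validation over a log-spaced grid of multiples of the sample SD,
and non-negative kernel weights w_n (summing to 1) fit by an iteratively
reweighted scheme that minimizes a Hampel loss on each point's distance
to the mixture in the Gaussian-kernel feature space.  Outlying control
points are thereby down-weighted, so a few corrupted scans do not
inflate the normative tails.

New values are scored by the mixture CDF, P = sum_n w_n Phi((x - X_n)/h),
and converted to two-tailed probabilities P' = 2 * min(P, 1 - P).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import ndtr

from .core_io import AnalysisConfig, Modality, ParameterMapStack

SQRT_PI = np.sqrt(np.pi)
SQRT_2PI = np.sqrt(2.0 * np.pi)

# Hampel breakpoints (a, b, c) are set from the point-to-mixture distance
# distribution at initialization: a = median, b = maximum, and
# c = 2*max - median.  The linear zone covers the bulk, the flat zone the
# clean extremes, and the redescending zone begins only beyond the
# initial distance range, so points well separated from the sample are
# crushed while legitimate extreme controls keep most of their weight
# and the normative tails stay calibrated.
HAMPEL_A_QUANTILE = 0.50
IRLS_TOL = 1e-6
IRLS_MAX_ITER = 100


class DegenerateVoxelError(ValueError):
    """Zero-variance control sample: no normative density can be fit."""


class NotFittedError(ValueError):
    """Queried a voxel flagged invalid during fitting."""


# ---------------------------------------------------------------------------
# Bandwidth selection (least-squares leave-one-out CV)


def lscv_score(values: np.ndarray, h: float) -> float:
    """LSCV criterion CV(h) = int f_hat^2 - (2/N) sum_n f_hat_{-n}(X_n).

    Both terms are closed-form for Gaussian kernels: the squared-density
    integral is a pairwise Gaussian of center differences at variance
    2 h^2, and the leave-one-out density renormalizes the remaining
    N - 1 kernels.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    d2 = (x[:, None] - x[None, :]) ** 2
    # int f_hat^2 = (1/N^2) sum_ij N(Xi - Xj; 0, 2h^2)
    term1 = np.exp(-d2 / (4.0 * h * h)).sum() / (n * n * 2.0 * h * SQRT_PI)
    # (2/N) sum_n f_hat_{-n}(X_n), leave-one-out excludes the held-out kernel
    off = np.exp(-d2 / (2.0 * h * h)).sum() - n  # remove the unit diagonal
    term2 = 2.0 * off / (n * (n - 1) * h * SQRT_2PI)
    return float(term1 - term2)


def _pick_minimizer(scores: np.ndarray) -> int:
    """Index of the largest interior local minimizer of CV over the grid.

    Near-duplicate sample values send CV(h) to -inf as h -> 0 (the
    classical LSCV degeneracy), producing a spurious boundary minimum at
    the smallest candidates.  The standard remedy is to take the largest
    local minimizer; when the curve has no interior local minimum the
    global argmin is used (first occurrence, i.e. the smallest h on
    exact ties).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 3:
        return int(np.argmin(s))
    interior = np.flatnonzero((s[1:-1] <= s[:-2]) & (s[1:-1] <= s[2:])) + 1
    if interior.size:
        return int(interior[-1])
    return int(np.argmin(s))


def select_bandwidth(values: np.ndarray, h_grid: np.ndarray | None = None,
                     config: AnalysisConfig | None = None) -> float:
    """Bandwidth minimizing CV(h) over the candidate grid.

    The default grid is ``config.bw_grid_size`` log-spaced candidates
    between ``bw_grid_min`` and ``bw_grid_max`` times the sample SD.
    The largest interior local minimizer is selected (see
    :func:`_pick_minimizer`); exact ties resolve to the smallest h.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to select a bandwidth")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise DegenerateVoxelError("zero sample SD: degenerate voxel")
    if h_grid is None:
        config = config or AnalysisConfig()
        h_grid = config.bandwidth_ratios * sd
    h_grid = np.sort(np.asarray(h_grid, dtype=float))
    scores = np.array([lscv_score(x, h) for h in h_grid])
    return float(h_grid[_pick_minimizer(scores)])


def _lscv_batch(X: np.ndarray, ratios: np.ndarray,
                chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bandwidth selection for an (N, V) control matrix.

    Returns per-voxel bandwidths and a validity flag (sample SD > 0).
    Uses float32 pairwise kernels; selection is a discrete argmin over
    the candidate grid, so single precision is ample.
    """
    n, n_vox = X.shape
    sd = X.std(axis=0, ddof=1)
    valid = sd > 0
    ratios = np.asarray(ratios, dtype=np.float64)
    best = np.zeros(n_vox)
    for lo in range(0, n_vox, chunk):
        idx = slice(lo, min(lo + chunk, n_vox))
        x = X[:, idx]
        s = sd[idx]
        ok = valid[idx]
        safe_s = np.where(ok, s, 1.0)
        # scale-free pairwise squared distances, in units of the voxel SD
        r2 = ((x[:, None, :] - x[None, :, :]) / safe_s).astype(np.float32) ** 2
        scores = np.empty((ratios.size, x.shape[1]))
        for g, r in enumerate(ratios):
            a = np.exp(-r2 / np.float32(4.0 * r * r))   # exp(-d^2 / 4h^2)
            e1 = a.sum(axis=(0, 1), dtype=np.float64)
            e2 = (a * a).sum(axis=(0, 1), dtype=np.float64) - n
            h = r * safe_s
            scores[g] = e1 / (n * n * 2.0 * h * SQRT_PI) \
                - 2.0 * e2 / (n * (n - 1) * h * SQRT_2PI)
        # largest interior local minimizer per voxel (see _pick_minimizer)
        is_min = np.zeros_like(scores, dtype=bool)
        is_min[1:-1] = (scores[1:-1] <= scores[:-2]) & (scores[1:-1] <= scores[2:])
        has_interior = is_min.any(axis=0)
        g_rev = np.argmax(is_min[::-1], axis=0)
        g_local = scores.shape[0] - 1 - g_rev
        g_global = np.argmin(scores, axis=0)
        g_best = np.where(has_interior, g_local, g_global)
        best[idx] = ratios[g_best] * safe_s
    best[~valid] = np.nan
    return best, valid


# ---------------------------------------------------------------------------
# Robust weights (Hampel loss, iteratively reweighted)


def hampel_psi_over_d(d: np.ndarray, a: np.ndarray, b: np.ndarray,
                      c: np.ndarray) -> np.ndarray:
    """psi(d)/d for the Hampel redescending influence function.

    psi(d) = d on [0, a); a on [a, b); a (c - d)/(c - b) on [b, c); 0 beyond.
    Returned as psi(d)/d, the IRLS weight multiplier (1 at d = 0).
    """
    d = np.asarray(d, dtype=float)
    safe_d = np.where(d > 0, d, 1.0)
    span = np.where(c > b, c - b, 1.0)
    taper = a * np.clip(c - d, 0.0, None) / (span * safe_d)
    out = np.ones_like(d)
    out = np.where(d > a, a / safe_d, out)
    out = np.where(d >= b, np.where(c > b, taper, 0.0), out)
    out = np.where(d >= c, 0.0, out)
    return out


def _irls(K: np.ndarray, kxx: np.ndarray, tol: float, max_iter: int
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared IRLS core over a batch of voxels.

    K: (N, N, V) Gram matrices, kxx: (V,) kernel self-similarity.
    Returns (weights (N, V), converged (V,), n_iter (V,)).
    """
    n, _, n_vox = K.shape
    w = np.full((n, n_vox), 1.0 / n)

    def distances(w):
        kw = np.einsum("nmv,mv->nv", K, w)
        wkw = np.einsum("nv,nv->v", w, kw)
        d2 = kxx[None, :] - 2.0 * kw + wkw[None, :]
        return np.sqrt(np.clip(d2, 0.0, None))

    d0 = distances(w)
    a = np.quantile(d0, HAMPEL_A_QUANTILE, axis=0)
    b = d0.max(axis=0)
    c = 2.0 * b - a
    converged = np.zeros(n_vox, dtype=bool)
    n_iter = np.zeros(n_vox, dtype=int)
    d = d0
    for it in range(max_iter):
        raw = hampel_psi_over_d(d, a, b, c)
        total = raw.sum(axis=0)
        dead = total <= 0
        if dead.any():  # pathological: everything beyond c; keep last iterate
            raw[:, dead] = w[:, dead]
            total[dead] = raw[:, dead].sum(axis=0)
        w_new = raw / total
        delta = np.abs(w_new - w).max(axis=0)
        active = ~converged
        w[:, active] = w_new[:, active]
        n_iter[active] = it + 1
        converged |= delta < tol
        if converged.all():
            break
        d = distances(w)
    return w, converged, n_iter


def fit_robust_weights(values: np.ndarray, h: float, tol: float = IRLS_TOL,
                       max_iter: int = IRLS_MAX_ITER
                       ) -> tuple[np.ndarray, bool, int]:
    """Robust kernel weights for one voxel's control sample.

    Alternates (a) each point's distance to the current weighted kernel
    mixture in the Gaussian-kernel feature space with (b) weights
    proportional to psi(d)/d under the Hampel influence function, until
    the largest weight change falls below ``tol``.  Non-convergence
    returns the last iterate with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 1:
        return np.array([1.0]), True, 0
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    d2 = (x[:, None] - x[None, :]) ** 2
    K = (np.exp(-d2 / (2.0 * h * h)) / (h * SQRT_2PI))[:, :, None]
    kxx = np.array([1.0 / (h * SQRT_2PI)])
    w, conv, n_iter = _irls(K, kxx, tol, max_iter)
    if not conv[0]:
        warnings.warn("robust-weight IRLS did not converge; returning last iterate")
    return w[:, 0], bool(conv[0]), int(n_iter[0])


def _robust_weights_batch(X: np.ndarray, h: np.ndarray, valid: np.ndarray,
                          tol: float = IRLS_TOL, max_iter: int = IRLS_MAX_ITER,
                          chunk: int = 1024
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized robust weights for an (N, V) control matrix."""
    n, n_vox = X.shape
    W = np.full((n, n_vox), np.nan)
    converged = np.zeros(n_vox, dtype=bool)
    idx_valid = np.flatnonzero(valid)
    for lo in range(0, idx_valid.size, chunk):
        cols = idx_valid[lo:lo + chunk]
        x = X[:, cols]
        hh = h[cols]
        d2 = (x[:, None, :] - x[None, :, :]) ** 2
        K = np.exp(-d2 / (2.0 * hh * hh)) / (hh * SQRT_2PI)
        kxx = 1.0 / (hh * SQRT_2PI)
        w, conv, _ = _irls(K, kxx, tol, max_iter)
        W[:, cols] = w
        converged[cols] = conv
    return W, converged


# ---------------------------------------------------------------------------
# Probabilities


def kde_cdf(centers: np.ndarray, weights: np.ndarray, h: float | np.ndarray,
            x: np.ndarray | float) -> np.ndarray | float:
    """Mixture CDF  P = sum_n w_n Phi((x - X_n) / h).

    ``centers``/``weights`` may be (N,) with scalar x, or (N, V) with
    per-voxel h and x of shape (V,) or (S, V).
    """
    centers = np.asarray(centers, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if centers.ndim == 1:
        return float(np.clip(np.sum(weights * ndtr((x - centers) / h)), 0.0, 1.0))
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        out = np.einsum("nv,nv->v", weights, ndtr((x[None, :] - centers) / h))
    else:
        out = np.stack([
            np.einsum("nv,nv->v", weights, ndtr((row[None, :] - centers) / h))
            for row in x
        ])
    return np.clip(out, 0.0, 1.0)  # guard float summation drift past [0, 1]


def two_tailed(P: np.ndarray | float) -> np.ndarray | float:
    """P' = 2 * min(P, 1 - P): probability of a value as extreme or larger."""
    P = np.asarray(P, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("cumulative probabilities must lie in [0, 1]")
    out = 2.0 * np.minimum(P, 1.0 - P)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# The fitted model


@dataclass
class NormativeModel:
    """Per-voxel normative KDE for one modality/analysis.

    ``centers`` and ``weights`` are (N_ctl, V); ``bandwidth`` is (V,);
    degenerate voxels are flagged in ``valid`` (NaN weights/bandwidth)
    and propagate as missing probabilities, never silently filled.
    """

    centers: np.ndarray
    weights: np.ndarray
    bandwidth: np.ndarray
    valid: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    modality: Modality
    analysis: str  # "CS" or "LNG"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        v = self.valid
        sums = self.weights[:, v].sum(axis=0)
        if v.any() and not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("weights must sum to 1 on valid voxels")
        if v.any() and not (self.bandwidth[v] > 0).all():
            raise ValueError("bandwidths must be positive on valid voxels")

    @property
    def n_controls(self) -> int:
        return self.centers.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.centers.shape[1]

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """One-tailed P for a (V,) map or (S, V) stack; NaN at invalid voxels."""
        P = kde_cdf(self.centers, self.weights, self.bandwidth, x)
        P = np.asarray(P, dtype=float)
        P[..., ~self.valid] = np.nan
        return P

    def two_tailed(self, x: np.ndarray) -> np.ndarray:
        P = self.cdf(x)
        out = np.full_like(P, np.nan)
        ok = np.isfinite(P)
        out[ok] = 2.0 * np.minimum(P[ok], 1.0 - P[ok])
        return out

    def sample_voxel(self, voxel: int, n: int,
                     rng: np.random.Generator) -> np.ndarray:
        """Draw n values from the fitted mixture at one voxel."""
        if not self.valid[voxel]:
            raise NotFittedError(f"voxel {voxel} is flagged invalid")
        comp = rng.choice(self.n_controls, size=n, p=self.weights[:, voxel])
        return self.centers[comp, voxel] + self.bandwidth[voxel] * rng.standard_normal(n)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, centers=self.centers, weights=self.weights,
            bandwidth=self.bandwidth, valid=self.valid, mask=self.mask,
            affine=self.affine,
            meta=json.dumps({"modality": self.modality.value,
                             "analysis": self.analysis,
                             "provenance": self.provenance}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NormativeModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(centers=z["centers"], weights=z["weights"],
                       bandwidth=z["bandwidth"], valid=z["valid"],
                       mask=z["mask"], affine=z["affine"],
                       modality=Modality(meta["modality"]),
                       analysis=meta["analysis"],
                       provenance=meta["provenance"])


def fit_normative_model(stack: ParameterMapStack, analysis: str = "CS",
                        config: AnalysisConfig | None = None) -> NormativeModel:
    """Fit per-voxel bandwidths and robust weights to a control stack.

    The stack holds control baseline values for a cross-sectional model
    or control post-minus-baseline changes for a longitudinal model.
    Degenerate (zero-variance) voxels are flagged invalid.
    """
    if stack.n_subjects < 2:
        raise ValueError("need at least 2 controls to fit a normative model")
    config = config or AnalysisConfig()
    X = np.ascontiguousarray(stack.values)  # (N_ctl, V): rows are controls
    h, valid = _lscv_batch(X, config.bandwidth_ratios)
    W, converged = _robust_weights_batch(X, np.where(valid, h, 1.0), valid)
    n_bad = int(valid.sum() - converged[valid].sum())
    if n_bad:
        warnings.warn(f"{n_bad} voxels did not converge in robust-weight IRLS")
    return NormativeModel(
        centers=X, weights=W, bandwidth=h, valid=valid, mask=stack.mask,
        affine=stack.affine, modality=stack.modality, analysis=analysis,
        provenance={
            "n_controls": stack.n_subjects,
            "bw_grid": [config.bw_grid_min, config.bw_grid_max, config.bw_grid_size],
            "hampel_breakpoints": "a=median(d0), b=max(d0), c=2*max(d0)-median(d0)",
            "irls_tol": IRLS_TOL,
            "irls_max_iter": IRLS_MAX_ITER,
            "n_not_converged": n_bad,
            "n_invalid_voxels": int((~valid).sum()),
        },
    )
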