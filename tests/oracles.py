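"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately naive (quadrature, enumeration, flood fill)
and shares no code with the library path it checks.
"""

import itertools

import numpy as np


def lscv_quadrature(values, h, span=12.0, n_grid=200001):
    """CV(h) by numerical integration of the squared KDE density."""
    x = np.asarray(values, dtype=float)
    n = x.size
    lo = x.min() - span * h
    hi = x.max() + span * h
    grid = np.linspace(lo, hi, n_grid)
    dens = np.exp(-((grid[:, None] - x[None, :]) / h) ** 2 / 2.0)
    fhat = dens.sum(axis=1) / (n * h * np.sqrt(2 * np.pi))
    term1 = np.trapezoid(fhat ** 2, grid)
    term2 = 0.0
    for i in range(n):
        others = np.delete(x, i)
        k = np.exp(-((x[i] - others) / h) ** 2 / 2.0)
        term2 += k.sum() / ((n - 1) * h * np.sqrt(2 * np.pi))
    return term1 - 2.0 * term2 / n


def kde_cdf_quadrature(centers, weights, h, x, span=14.0, n_grid=400001):
    """Mixture CDF by numerical integration of the mixture density."""
    centers = np.asarray(centers, dtype=float)
    lo = min(centers.min(), x) - span * h
    grid = np.linspace(lo, x, n_grid)
    dens = np.exp(-((grid[:, None] - centers[None, :]) / h) ** 2 / 2.0)
    f = (dens * weights[None, :]).sum(axis=1) / (h * np.sqrt(2 * np.pi))
    return np.trapezoid(f, grid)


def bh_stepup(p, q):
    """Benjamini-Hochberg by direct definition on a 1-D p-value array."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    cutoff = 0.0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            cutoff = p[idx]
    return p <= cutoff if cutoff > 0 else np.zeros(m, dtype=bool)


def _neighbors(shape, connectivity):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=len(shape)):
        if d == (0,) * len(shape):
            continue
        if sum(abs(v) for v in d) <= connectivity:
            offs.append(d)
    return offs


def flood_fill_filter(vol, min_size, connectivity):
    """Connected-component size filter by breadth-first flood fill."""
    vol = np.asarray(vol, dtype=bool)
    offs = _neighbors(vol.shape, connectivity)
    seen = np.zeros_like(vol)
    out = np.zeros_like(vol)
    for start in zip(*np.nonzero(vol)):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        queue = [start]
        while queue:
            cur = queue.pop()
            for off in offs:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(not 0 <= v < s for v, s in zip(nb, vol.shape)):
                    continue
                if vol[nb] and not seen[nb]:
                    seen[nb] = True
                    comp.append(nb)
                    queue.append(nb)
        if len(comp) >= min_size:
            for vox in comp:
                out[vox] = True
    return out


def jaccard_naive(x, y):
    x = np.asarray(x, dtype=bool).ravel()
    y = np.asarray(y, dtype=bool).ravel()
    inter = sum(a and b for a, b in zip(x, y))
    union = sum(a or b for a, b in zip(x, y))
    return inter / union if union else float("nan")


def signed_rank_exact_p(diffs):
    """Two-sided exact Wilcoxon signed-rank p by full sign enumeration.

    Assumes no zero differences and no tied absolute values (use
    continuous random inputs).
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    ranks = np.empty(n)
    ranks[np.argsort(np.abs(d))] = np.arange(1, n + 1)
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_pos = sum(r for r, s in zip(ranks, signs) if s)
        w = min(w_pos, n * (n + 1) / 2 - w_pos)
        if w <= w_obs:
            count += 1
    return count / 2 ** n


def spearman_naive(x, y):
    """Spearman rho as Pearson correlation of average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        r = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        pos = 0
        while pos < len(v):
            j = pos
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[pos]:
                j += 1
            avg = (pos + j) / 2.0 + 1.0
            for k in range(pos, j + 1):
                r[order[k]] = avg
            pos = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def quartiles_naive(values):
    """Median and quartiles by sorted linear interpolation."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size

    def at(frac):
        pos = frac * (n - 1)
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return v[lo] + (pos - lo) * (v[hi] - v[lo])

    return at(0.5), at(0.25), at(0.75)
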