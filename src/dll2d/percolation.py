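"""Site percolation on the periodic triangular lattice.

A configuration opens each site independently with probability p; the
spanning criterion is a *wrapping* cluster — a cluster of open sites that
winds around the periodic box in at least one lattice direction, detected
with a union-find whose per-site offsets to the component root are tracked
(a union of two sites already in one component with inconsistent offsets
reveals a winding).  The torus criterion avoids the boundary ambiguity of
side-to-side spanning.  The triangular-lattice site-percolation threshold
is 1/2; :func:`estimate_threshold` recovers it as the open-site probability
at which the wrapping probability crosses one half, interpolated on a grid
and averaged over lattice sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .lattice import build_lattice

__all__ = ["PercolationResult", "spanning_probability", "estimate_threshold"]


@njit(cache=True)
def _wraps(open_sites, nbr, L):
    """True iff the open sites contain a cluster wrapping the torus.

    Union-find with raw axial offsets: ``off*[x]`` is the position of x
    relative to its parent, accumulated to the root on find; a cycle whose
    offsets do not cancel winds the torus.
    """
    n = open_sites.size
    parent = np.empty(n, np.int32)
    rank = np.zeros(n, np.int8)
    offq = np.zeros(n, np.int32)
    offr = np.zeros(n, np.int32)
    for i in range(n):
        parent[i] = i
    # the three forward edge directions cover each undirected edge once
    edq = (1, 0, -1)
    edr = (0, 1, 1)
    stack = np.empty(n, np.int32)
    for s in range(n):
        if not open_sites[s]:
            continue
        for k in range(3):
            t = nbr[s, k]
            if not open_sites[t]:
                continue
            # find root of s with accumulated offsets
            x = s
            aq = 0
            ar = 0
            depth = 0
            while parent[x] != x:
                stack[depth] = x
                depth += 1
                aq += offq[x]
                ar += offr[x]
                x = parent[x]
            rx = x
            # path compression
            cq = aq
            cr = ar
            for i in range(depth):
                y = stack[i]
                tq = offq[y]
                tr = offr[y]
                parent[y] = rx
                offq[y] = cq
                offr[y] = cr
                cq -= tq
                cr -= tr
            x = t
            bq = 0
            br = 0
            depth = 0
            while parent[x] != x:
                stack[depth] = x
                depth += 1
                bq += offq[x]
                br += offr[x]
                x = parent[x]
            ry = x
            cq = bq
            cr = br
            for i in range(depth):
                y = stack[i]
                tq = offq[y]
                tr = offr[y]
                parent[y] = ry
                offq[y] = cq
                offr[y] = cr
                cq -= tq
                cr -= tr
            # constraint: pos[t] = pos[s] + e
            eq = edq[k]
            er = edr[k]
            if rx == ry:
                if (bq - aq - eq) != 0 or (br - ar - er) != 0:
                    return True
            else:
                # attach smaller-rank root; pos[x] = pos[rx] + aq/ar etc.
                if rank[rx] < rank[ry]:
                    # pos[rx] = pos[s] - a; pos[s] = pos[t] - e; pos[t) = pos[ry] + b
                    parent[rx] = ry
                    offq[rx] = bq - eq - aq
                    offr[rx] = br - er - ar
                else:
                    parent[ry] = rx
                    offq[ry] = aq + eq - bq
                    offr[ry] = ar + er - br
                    if rank[rx] == rank[ry]:
                        rank[rx] += 1
    return False


def spanning_probability(
    L: int,
    p: float,
    n_realizations: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float], int]:
    """Monte Carlo wrapping probability with a Wilson binomial CI.

    Returns ``(estimate, (ci_lo, ci_hi), n_spanning)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    lat = build_lattice(L)
    rng = rng if rng is not None else np.random.default_rng(seed)
    nbr = lat.neighbors
    hits = 0
    for _ in range(n_realizations):
        open_sites = rng.random(lat.n_sites) < p
        if _wraps(open_sites, nbr, L):
            hits += 1
    phat = hits / n_realizations
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    denom = 1.0 + z * z / n_realizations
    centre = (phat + z * z / (2 * n_realizations)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n_realizations + z * z / (4 * n_realizations**2)) / denom
    return phat, (max(0.0, centre - half), min(1.0, centre + half)), hits


@dataclass
class PercolationResult:
    sizes: list
    p_grid: np.ndarray
    spanning: np.ndarray        # (n_sizes, n_p) wrapping probability
    counts: np.ndarray          # (n_sizes, n_p) spanning counts
    n_realizations: int
    p_c: float
    p_c_stderr: float
    p_c_per_size: dict


def _crossing(p_grid: np.ndarray, curve: np.ndarray, level: float = 0.5) -> float:
    """Linearly interpolated p at which the curve first reaches ``level``."""
    above = np.flatnonzero(curve >= level)
    if above.size == 0 or above[0] == 0 and curve[0] > level:
        raise ValueError("grid does not straddle the crossing")
    j = above[0]
    if j == 0:
        return float(p_grid[0])
    p0, p1 = p_grid[j - 1], p_grid[j]
    v0, v1 = curve[j - 1], curve[j]
    if v1 == v0:
        return float(p1)
    return float(p0 + (level - v0) / (v1 - v0) * (p1 - p0))


def estimate_threshold(
    sizes,
    p_grid,
    n_realizations: int,
    seed: int | None = None,
    n_bootstrap: int = 200,
) -> PercolationResult:
    """Percolation threshold estimate: for each lattice size, interpolate
    the open-site probability at which the wrapping probability equals one
    half; average over sizes, with a bootstrap standard error."""
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    rng = np.random.default_rng(seed)
    spanning = np.empty((len(sizes), len(p_grid)))
    counts = np.empty((len(sizes), len(p_grid)), dtype=np.int64)
    for i, L in enumerate(sizes):
        for j, p in enumerate(p_grid):
            phat, _, hits = spanning_probability(L, p, n_realizations, rng=rng)
            spanning[i, j] = phat
            counts[i, j] = hits
    per_size = {}
    for i, L in enumerate(sizes):
        per_size[int(L)] = _crossing(p_grid, spanning[i])
    p_c = float(np.mean(list(per_size.values())))

    boots = []
    for _ in range(n_bootstrap):
        vals = []
        for i in range(len(sizes)):
            sim = rng.binomial(n_realizations, spanning[i]) / n_realizations
            try:
                vals.append(_crossing(p_grid, sim))
            except ValueError:
                continue
        if vals:
            boots.append(np.mean(vals))
    stderr = float(np.std(boots)) if boots else float("nan")
    return PercolationResult(
        sizes=list(sizes),
        p_grid=p_grid,
        spanning=spanning,
        counts=counts,
        n_realizations=n_realizations,
        p_c=p_c,
        p_c_stderr=stderr,
        p_c_per_size=per_size,
    )
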