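"""One Monte Carlo step of the dynamic lattice liquid (DLL) algorithm.

Each step assigns every non-obstacle site a random unit vector toward one of
its six neighbours, identifies the closed loops (cycles of length >= 3) of
the induced successor map, rejects loops whose execution would break a rigid
dimer bond or carry an object across a simultaneously moving dimer bond, and
then executes all surviving loops synchronously (each object replaces its
successor).  Objects outside a loop are immobile for that step; mutual
two-site exchanges are detected and always rejected.

The hot path (cycle detection, loop validation, synchronous execution) is
compiled with numba and operates on the flat arrays of
:class:`dll2d.lattice.SystemState`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .lattice import (
    MER,
    OBSTACLE,
    SOLVENT,
    UNIT_X,
    UNIT_Y,
    SystemState,
    build_lattice,
)

__all__ = [
    "LoopSet",
    "StepStats",
    "TrajectoryStore",
    "assign_vectors",
    "find_loops",
    "validate_loops",
    "crossing_test",
    "execute_step",
    "run_trajectory",
    "log_schedule",
    "REJECT_NONE",
    "REJECT_BOND_BREAK",
    "REJECT_BOND_CROSS",
]

REJECT_NONE = 0
REJECT_BOND_BREAK = 1
REJECT_BOND_CROSS = 2

# Candidate bonds for the crossing test are gathered from sites within
# Cartesian distance sqrt(12) of the moving object's start site: with unit
# hops and linear interpolation, the nearer endpoint of any crossable bond
# lies within 0.5 + 3s <= 3.5 of the start, and sqrt(12) is the largest
# lattice distance below 3.5.  Offsets are stored raw (unwrapped) so that on
# very small boxes each periodic image of a bond is tested separately.
def _build_ring():
    dq_list, dr_list, bx_list, by_list = [], [], [], []
    for dq in range(-4, 5):
        for dr in range(-4, 5):
            n2 = dq * dq + dq * dr + dr * dr
            if 0 < n2 <= 12:
                dq_list.append(dq)
                dr_list.append(dr)
                bx_list.append(dq + 0.5 * dr)
                by_list.append(dr * np.sqrt(3.0) / 2.0)
    return (
        np.array(dq_list, dtype=np.int32),
        np.array(dr_list, dtype=np.int32),
        np.array(bx_list),
        np.array(by_list),
    )


RING_DQ, RING_DR, RING_BX, RING_BY = _build_ring()


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cross(Bx, By, b1x, b1y, e1x, e1y, b2x, b2y, e2x, e2y):
    """Spacetime crossing test, all coordinates relative to the moving
    object's start point.

    The moving point is p(s) = s*(Bx, By); bond endpoints are
    b_i(s) = b_i + s*e_i, s in (0, 1].  Returns True iff the signed area
    f(s) = cross(b2(s)-b1(s), p(s)-b1(s)) has a root s* in (0, 1] at which
    p(s*) projects strictly inside the segment (endpoint contact excluded).
    """
    v0x = -b1x
    v0y = -b1y
    dvx = Bx - e1x
    dvy = By - e1y
    w0x = b2x - b1x
    w0y = b2y - b1y
    dwx = e2x - e1x
    dwy = e2y - e1y
    # f(s) = a s^2 + b s + c
    a = dwx * dvy - dwy * dvx
    b = (w0x * dvy - w0y * dvx) + (dwx * v0y - dwy * v0x)
    c = w0x * v0y - w0y * v0x
    eps = 1e-12
    r0 = -1.0
    r1 = -1.0
    if abs(a) < eps:
        if abs(b) < eps:
            if abs(c) < eps:
                # collinear throughout: sample containment directly
                for i in range(1, 51):
                    s = i / 50.0
                    wx = w0x + s * dwx
                    wy = w0y + s * dwy
                    vx = v0x + s * dvx
                    vy = v0y + s * dvy
                    ww = wx * wx + wy * wy
                    if ww > 1e-18:
                        tt = (vx * wx + vy * wy) / ww
                        if 1e-9 < tt < 1.0 - 1e-9:
                            return True
            return False
        r0 = -c / b
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            return False
        sq = np.sqrt(disc)
        r0 = (-b + sq) / (2.0 * a)
        r1 = (-b - sq) / (2.0 * a)
    for r in (r0, r1):
        if eps < r <= 1.0 + 1e-9:
            s = min(r, 1.0)
            wx = w0x + s * dwx
            wy = w0y + s * dwy
            vx = v0x + s * dvx
            vy = v0y + s * dvy
            ww = wx * wx + wy * wy
            if ww > 1e-18:
                tt = (vx * wx + vy * wy) / ww
                if 1e-9 < tt < 1.0 - 1e-9:
                    return True
    return False


@njit(cache=True)
def _find_cycles(succ, visited, path, loop_sites, loop_off):
    """Cycles of the successor map.  Returns (n_loops, n_two_cycles).

    Loops of length >= 3 are written into ``loop_sites`` /``loop_off``;
    two-cycles (mutual exchange) are only counted — they are rejected by
    construction and never executed.
    """
    n = succ.size
    for i in range(n):
        visited[i] = 0
    n_loops = 0
    two = 0
    total = 0
    for s0 in range(n):
        if visited[s0] != 0:
            continue
        if succ[s0] < 0:
            visited[s0] = 2
            continue
        plen = 0
        v = s0
        while v >= 0 and visited[v] == 0:
            visited[v] = 1
            path[plen] = v
            plen += 1
            v = succ[v]
        if v >= 0 and visited[v] == 1:
            idx = plen - 1
            while path[idx] != v:
                idx -= 1
            clen = plen - idx
            if clen == 2:
                two += 1
            else:
                loop_off[n_loops] = total
                for j in range(idx, plen):
                    loop_sites[total] = path[j]
                    total += 1
                n_loops += 1
        for j in range(plen):
            visited[path[j]] = 2
    loop_off[n_loops] = total
    return n_loops, two


@njit(cache=True)
def _validate(
    loop_sites, loop_off, n_loops, order, succ, dirs,
    site_obj, obj_site, obj_species, partner, dimer_of,
    nbr, site_loop, accepted, reason,
    ring_dq, ring_dr, ring_bx, ring_by, ux, uy, L,
):
    """Iterative fixed-point rejection of candidate loops (Gauss-Seidel,
    ascending smallest-site order).  Fills ``accepted`` and ``reason``."""
    n_ring = ring_dq.size
    changed = True
    while changed:
        changed = False
        for oi in range(n_loops):
            l = order[oi]
            if not accepted[l]:
                continue
            start = loop_off[l]
            end = loop_off[l + 1]
            rej = 0
            # rigid-bond preservation for every dimer with a mer in this loop
            for j in range(start, end):
                s = loop_sites[j]
                o = site_obj[s]
                if obj_species[o] == MER:
                    dest = succ[s]
                    p = partner[o]
                    ps = obj_site[p]
                    lp = site_loop[ps]
                    if lp >= 0 and accepted[lp]:
                        pdest = succ[ps]
                    else:
                        pdest = ps
                    ok = False
                    for k in range(6):
                        if nbr[dest, k] == pdest:
                            ok = True
                            break
                    if not ok:
                        rej = REJECT_BOND_BREAK
                        break
            if rej == 0:
                # no object in this loop may cross a moving dimer bond
                for j in range(start, end):
                    s = loop_sites[j]
                    o = site_obj[s]
                    d0 = dirs[s]
                    Bx = ux[d0]
                    By = uy[d0]
                    qA = s % L
                    rA = s // L
                    for g in range(n_ring):
                        qt = (qA + ring_dq[g]) % L
                        rt = (rA + ring_dr[g]) % L
                        t = rt * L + qt
                        o2 = site_obj[t]
                        if obj_species[o2] != MER:
                            continue
                        if obj_species[o] == MER and dimer_of[o2] == dimer_of[o]:
                            continue  # an object never crosses its own bond
                        tp = obj_site[partner[o2]]
                        l1 = site_loop[t]
                        if l1 >= 0 and accepted[l1]:
                            e1x = ux[dirs[t]]
                            e1y = uy[dirs[t]]
                        else:
                            e1x = 0.0
                            e1y = 0.0
                        l2 = site_loop[tp]
                        if l2 >= 0 and accepted[l2]:
                            e2x = ux[dirs[tp]]
                            e2y = uy[dirs[tp]]
                        else:
                            e2x = 0.0
                            e2y = 0.0
                        if e1x == 0.0 and e1y == 0.0 and e2x == 0.0 and e2y == 0.0:
                            continue  # static bonds (lattice edges) cannot be crossed
                        kk = 0
                        for k in range(6):
                            if nbr[t, k] == tp:
                                kk = k
                                break
                        b1x = ring_bx[g]
                        b1y = ring_by[g]
                        if _cross(Bx, By, b1x, b1y, e1x, e1y,
                                  b1x + ux[kk], b1y + uy[kk], e2x, e2y):
                            rej = REJECT_BOND_CROSS
                            break
                    if rej != 0:
                        break
            if rej != 0:
                accepted[l] = False
                reason[l] = rej
                changed = True


@njit(cache=True)
def _run_steps(
    dirs_batch, L, nbr,
    site_obj, obj_site, obj_species, partner, dimer_of, disp,
    ring_dq, ring_dr, ring_bx, ring_by, ux, uy,
    stats_out, found_hist, acc_hist,
):
    """Advance the system by ``dirs_batch.shape[0]`` synchronous DLL steps.

    ``stats_out`` rows: [loops found (len >= 3), two-cycles, accepted,
    rejected bond_break, rejected bond_cross, objects moved].
    """
    n_steps = dirs_batch.shape[0]
    n_sites = nbr.shape[0]
    succ = np.empty(n_sites, np.int32)
    visited = np.zeros(n_sites, np.uint8)
    path = np.empty(n_sites, np.int32)
    max_loops = n_sites // 3 + 2
    loop_sites = np.empty(n_sites, np.int32)
    loop_off = np.empty(max_loops + 1, np.int32)
    loop_min = np.empty(max_loops, np.int32)
    site_loop = np.full(n_sites, -1, np.int32)
    accepted = np.empty(max_loops, np.bool_)
    reason = np.empty(max_loops, np.int8)
    buf = np.empty(n_sites, np.int32)
    hist_max = found_hist.size - 1

    for step in range(n_steps):
        dirs = dirs_batch[step]
        for s in range(n_sites):
            if obj_species[site_obj[s]] == OBSTACLE:
                succ[s] = -1
            else:
                t = nbr[s, dirs[s]]
                if obj_species[site_obj[t]] == OBSTACLE:
                    succ[s] = -1
                else:
                    succ[s] = t
        n_loops, two = _find_cycles(succ, visited, path, loop_sites, loop_off)
        for l in range(n_loops):
            mn = n_sites
            for j in range(loop_off[l], loop_off[l + 1]):
                s = loop_sites[j]
                site_loop[s] = l
                if s < mn:
                    mn = s
            loop_min[l] = mn
            accepted[l] = True
            reason[l] = 0
            clen = loop_off[l + 1] - loop_off[l]
            found_hist[min(clen, hist_max)] += 1
        order = np.argsort(loop_min[:n_loops])
        _validate(
            loop_sites, loop_off, n_loops, order, succ, dirs,
            site_obj, obj_site, obj_species, partner, dimer_of,
            nbr, site_loop, accepted, reason,
            ring_dq, ring_dr, ring_bx, ring_by, ux, uy, L,
        )
        n_acc = 0
        n_break = 0
        n_cross = 0
        moved = 0
        for l in range(n_loops):
            start = loop_off[l]
            end = loop_off[l + 1]
            if accepted[l]:
                n_acc += 1
                clen = end - start
                acc_hist[min(clen, hist_max)] += 1
                for j in range(start, end):
                    buf[j - start] = site_obj[loop_sites[j]]
                for j in range(start, end):
                    s = loop_sites[j]
                    o = buf[j - start]
                    d0 = dirs[s]
                    dest = succ[s]
                    site_obj[dest] = o
                    obj_site[o] = dest
                    disp[o, 0] += ux[d0]
                    disp[o, 1] += uy[d0]
                    moved += 1
            elif reason[l] == REJECT_BOND_BREAK:
                n_break += 1
            else:
                n_cross += 1
        # clear the per-step site -> loop map
        for j in range(loop_off[n_loops]):
            site_loop[loop_sites[j]] = -1
        stats_out[step, 0] = n_loops
        stats_out[step, 1] = two
        stats_out[step, 2] = n_acc
        stats_out[step, 3] = n_break
        stats_out[step, 4] = n_cross
        stats_out[step, 5] = moved


# ---------------------------------------------------------------------------
# Python-facing API
# ---------------------------------------------------------------------------

@dataclass
class LoopSet:
    """Closed cooperative loops induced by one direction field."""

    loops: list                      # list of int arrays (ordered site cycles)
    accepted: np.ndarray | None      # bool per loop (None before validation)
    reason: np.ndarray | None        # REJECT_* per loop
    n_two_cycles: int

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    @property
    def accepted_loops(self) -> list:
        if self.accepted is None:
            return list(self.loops)
        return [lp for lp, a in zip(self.loops, self.accepted) if a]


@dataclass
class StepStats:
    loops_found: int
    two_cycles: int
    accepted: int
    rejected_bond_break: int
    rejected_bond_cross: int
    objects_moved: int
    max_loop_length: int = 0   # longest executed loop; >= L implies possible winding


def assign_vectors(state: SystemState, rng: np.random.Generator | None = None) -> np.ndarray:
    """Independent uniform direction (0..5) for every non-obstacle site; -1 on obstacles."""
    rng = rng if rng is not None else state.rng
    dirs = rng.integers(0, 6, size=state.n_sites, dtype=np.int8)
    dirs[state.species_at_sites() == OBSTACLE] = -1
    return dirs


def _successors(state: SystemState, dirs: np.ndarray) -> np.ndarray:
    species = state.species_at_sites()
    nbr = state.lattice.neighbors
    succ = np.full(state.n_sites, -1, dtype=np.int32)
    mobile = species != OBSTACLE
    tgt = nbr[np.arange(state.n_sites), np.where(mobile, dirs, 0)]
    ok = mobile & (species[tgt] != OBSTACLE)
    succ[ok] = tgt[ok]
    return succ


def find_loops(state: SystemState, dirs: np.ndarray) -> LoopSet:
    """All cycles (length >= 3) of the successor map; two-cycles are tallied
    as rejected-by-construction and not returned as loops."""
    succ = _successors(state, dirs)
    n = state.n_sites
    visited = np.zeros(n, np.uint8)
    path = np.empty(n, np.int32)
    loop_sites = np.empty(n, np.int32)
    loop_off = np.empty(n // 3 + 3, np.int32)
    n_loops, two = _find_cycles(succ, visited, path, loop_sites, loop_off)
    loops = [loop_sites[loop_off[l]:loop_off[l + 1]].copy() for l in range(n_loops)]
    return LoopSet(loops=loops, accepted=None, reason=None, n_two_cycles=int(two))


def validate_loops(state: SystemState, dirs: np.ndarray, loopset: LoopSet) -> LoopSet:
    """Apply the bond-break and bond-cross rejection rules to fixed point."""
    succ = _successors(state, dirs)
    n_loops = loopset.n_loops
    loop_sites = np.concatenate(loopset.loops).astype(np.int32) if n_loops else np.empty(0, np.int32)
    loop_off = np.zeros(n_loops + 1, np.int32)
    for l, lp in enumerate(loopset.loops):
        loop_off[l + 1] = loop_off[l] + len(lp)
    site_loop = np.full(state.n_sites, -1, np.int32)
    loop_min = np.empty(max(n_loops, 1), np.int32)
    for l, lp in enumerate(loopset.loops):
        site_loop[lp] = l
        loop_min[l] = lp.min()
    accepted = np.ones(max(n_loops, 1), np.bool_)
    reason = np.zeros(max(n_loops, 1), np.int8)
    order = np.argsort(loop_min[:n_loops]).astype(np.int64)
    dirs8 = np.ascontiguousarray(dirs, dtype=np.int8)
    if n_loops:
        _validate(
            loop_sites, loop_off, n_loops, order, succ, dirs8,
            state.site_obj, state.obj_site, state.obj_species,
            state.partner, state.dimer_of,
            state.lattice.neighbors, site_loop, accepted, reason,
            RING_DQ, RING_DR, RING_BX, RING_BY, UNIT_X, UNIT_Y, state.lattice.L,
        )
    return LoopSet(
        loops=list(loopset.loops),
        accepted=accepted[:n_loops].copy(),
        reason=reason[:n_loops].copy(),
        n_two_cycles=loopset.n_two_cycles,
    )


def crossing_test(p_start, p_end, b1_start, b1_end, b2_start, b2_end) -> bool:
    """Does a moving point cross a (possibly moving) bond segment?

    All arguments are Cartesian pairs; the point and both bond endpoints
    move by simultaneous linear interpolation over the step.  Endpoint
    contact does not count as a crossing; a zero-length path never crosses.
    """
    ax, ay = float(p_start[0]), float(p_start[1])
    Bx, By = float(p_end[0]) - ax, float(p_end[1]) - ay
    if Bx == 0.0 and By == 0.0:
        return False
    return bool(
        _cross(
            Bx, By,
            float(b1_start[0]) - ax, float(b1_start[1]) - ay,
            float(b1_end[0]) - float(b1_start[0]), float(b1_end[1]) - float(b1_start[1]),
            float(b2_start[0]) - ax, float(b2_start[1]) - ay,
            float(b2_end[0]) - float(b2_start[0]), float(b2_end[1]) - float(b2_start[1]),
        )
    )


def _hist_size(n_sites: int) -> int:
    return n_sites + 1


def execute_step(state: SystemState, dirs: np.ndarray | None = None) -> StepStats:
    """Run one synchronous DLL step in place and return its tallies."""
    if dirs is None:
        dirs = state.rng.integers(0, 6, size=state.n_sites, dtype=np.int8)
    dirs_batch = np.ascontiguousarray(dirs, dtype=np.int8).reshape(1, -1)
    stats = np.zeros((1, 6), np.int64)
    hist = np.zeros(_hist_size(state.n_sites), np.int64)
    acc_hist = np.zeros_like(hist)
    _run_steps(
        dirs_batch, state.lattice.L, state.lattice.neighbors,
        state.site_obj, state.obj_site, state.obj_species,
        state.partner, state.dimer_of, state.disp,
        RING_DQ, RING_DR, RING_BX, RING_BY, UNIT_X, UNIT_Y,
        stats, hist, acc_hist,
    )
    state.t += 1
    nz = np.flatnonzero(acc_hist)
    max_len = int(nz[-1]) if nz.size else 0
    return StepStats(*(int(x) for x in stats[0]), max_loop_length=max_len)


def log_schedule(n_steps: int, points_per_decade: int = 20) -> np.ndarray:
    """Logarithmically spaced integer sample times in [0, n_steps], incl. 0 and 1."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pts = np.unique(
        np.round(
            10 ** np.arange(0, np.log10(n_steps) + 1e-12, 1.0 / points_per_decade)
        ).astype(np.int64)
    )
    pts = pts[pts <= n_steps]
    return np.concatenate(([0], pts, [n_steps] if pts[-1] != n_steps else []))


@dataclass
class TrajectoryStore:
    """Sampled times with per-object displacements, wrapped sites and dimer
    end-to-end vectors for one trajectory."""

    times: np.ndarray          # (k,) int64 sample times in MC steps
    disp: np.ndarray           # (k, n_objects, 2) unwrapped displacement
    sites: np.ndarray          # (k, n_objects) int32 wrapped site
    e2e: np.ndarray            # (k, n_dimers, 2) dimer end-to-end vectors
    obj_species: np.ndarray    # (n_objects,) int8
    dimers: np.ndarray         # (n_dimers, 2) int32
    L: int
    decade_stats: np.ndarray   # (n_decades, 6) summed per-step tallies by decade of t
    found_hist: np.ndarray     # loop-length histogram (all candidate loops)
    accepted_hist: np.ndarray  # loop-length histogram (executed loops)
    manifest: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return self.disp.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("times", "disp", "sites", "e2e", "obj_species",
                         "dimers", "decade_stats", "found_hist", "accepted_hist"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["L"] = self.L
            f.attrs["manifest"] = json.dumps(self.manifest)

    @classmethod
    def load(cls, path) -> "TrajectoryStore":
        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][:]
                for name in ("times", "disp", "sites", "e2e", "obj_species",
                             "dimers", "decade_stats", "found_hist", "accepted_hist")
            }
            return cls(L=int(f.attrs["L"]), manifest=json.loads(f.attrs["manifest"]), **kw)


def _initial_e2e(state: SystemState) -> np.ndarray:
    """Unit end-to-end vector of every dimer at the current instant."""
    out = np.empty((len(state.dimers), 2))
    nbr = state.lattice.neighbors
    for k, (a, b) in enumerate(state.dimers):
        sa, sb = int(state.obj_site[a]), int(state.obj_site[b])
        for kk in range(6):
            if nbr[sa, kk] == sb:
                out[k, 0] = UNIT_X[kk]
                out[k, 1] = UNIT_Y[kk]
                break
        else:  # pragma: no cover - violated invariant
            raise AssertionError("dimer mers not adjacent")
    return out


def run_trajectory(
    state: SystemState,
    n_steps: int,
    schedule: np.ndarray | None = None,
    points_per_decade: int = 20,
    chunk: int = 2048,
) -> TrajectoryStore:
    """Run ``n_steps`` DLL steps, sampling positions at a (default
    log-spaced) schedule measured from the current instant."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if schedule is None:
        schedule = log_schedule(n_steps, points_per_decade)
    schedule = np.unique(np.asarray(schedule, dtype=np.int64))
    if schedule[0] != 0:
        schedule = np.concatenate(([0], schedule))
    if schedule[-1] > n_steps:
        raise ValueError("schedule time exceeds n_steps")

    n_obj = state.n_objects
    m = len(state.dimers)
    k = len(schedule)
    disp_s = np.empty((k, n_obj, 2))
    sites_s = np.empty((k, n_obj), np.int32)
    e2e_s = np.empty((k, m, 2))
    e2e0 = _initial_e2e(state)
    disp0 = state.disp.copy()

    n_decades = int(np.floor(np.log10(max(n_steps, 1)))) + 1
    decade_stats = np.zeros((n_decades, 6), np.int64)
    hist = np.zeros(_hist_size(state.n_sites), np.int64)
    acc_hist = np.zeros_like(hist)

    a_mer = state.dimers[:, 0]
    b_mer = state.dimers[:, 1]

    def record(i):
        rel = state.disp - disp0
        disp_s[i] = rel
        sites_s[i] = state.obj_site
        e2e_s[i] = e2e0 + rel[b_mer] - rel[a_mer]

    record(0)
    current = 0
    for i, target in enumerate(schedule[1:], start=1):
        gap = int(target - current)
        while gap > 0:
            g = min(gap, chunk)
            dirs = state.rng.integers(0, 6, size=(g, state.n_sites), dtype=np.int8)
            stats = np.zeros((g, 6), np.int64)
            _run_steps(
                dirs, state.lattice.L, state.lattice.neighbors,
                state.site_obj, state.obj_site, state.obj_species,
                state.partner, state.dimer_of, state.disp,
                RING_DQ, RING_DR, RING_BX, RING_BY, UNIT_X, UNIT_Y,
                stats, hist, acc_hist,
            )
            steps_done = current + np.arange(1, g + 1)
            decades = np.floor(np.log10(np.maximum(steps_done, 1))).astype(np.int64)
            np.add.at(decade_stats, decades, stats)
            current += g
            gap -= g
            state.t += g
        record(i)

    return TrajectoryStore(
        times=schedule,
        disp=disp_s,
        sites=sites_s,
        e2e=e2e_s,
        obj_species=state.obj_species.copy(),
        dimers=state.dimers.copy(),
        L=state.lattice.L,
        decade_stats=decade_stats,
        found_hist=hist,
        accepted_hist=acc_hist,
        manifest={
            "L": state.lattice.L,
            "c": state.composition.c,
            "d": state.composition.d,
            "n_steps": int(n_steps),
            "seed": state.seed,
        },
    )
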