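"""Independent brute-force reference for DLL loop selection.

Pure-Python, dictionary/set based, with a numeric (sign-change + bisection)
crossing test — deliberately sharing no code with the package kernels.
"""

from __future__ import annotations

import math

import numpy as np

SOLVENT, MER, OBSTACLE = 0, 1, 2
H = math.sqrt(3.0) / 2.0
OFFSETS = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
UNIT = [(dq + 0.5 * dr, H * dr) for dq, dr in OFFSETS]


def neighbor(L, site, k):
    q, r = site % L, site // L
    dq, dr = OFFSETS[k]
    return ((r + dr) % L) * L + (q + dq) % L


def find_cycles(L, species_at, dirs):
    """All cycles of the successor map restricted to non-obstacle sites.

    Returns (loops_of_len_ge_3, n_two_cycles); each loop is a tuple of
    sites in successor order.
    """
    succ = {}
    for s in range(L * L):
        if species_at[s] == OBSTACLE:
            continue
        t = neighbor(L, s, dirs[s])
        if species_at[t] != OBSTACLE:
            succ[s] = t
    loops = []
    two = 0
    seen = set()
    for s0 in succ:
        if s0 in seen:
            continue
        path = []
        pos = {}
        v = s0
        while v in succ and v not in seen and v not in pos:
            pos[v] = len(path)
            path.append(v)
            v = succ[v]
        if v in pos:  # new cycle
            cyc = tuple(path[pos[v]:])
            if len(cyc) == 2:
                two += 1
            else:
                loops.append(cyc)
        seen.update(path)
    return loops, two


def _minimal_image_xy(L, a, b):
    qa, ra = a % L, a // L
    qb, rb = b % L, b // L
    best = None
    best_n = math.inf
    for iq in (-L, 0, L):
        for ir in (-L, 0, L):
            dq = qb - qa + iq
            dr = rb - ra + ir
            x, y = dq + 0.5 * dr, H * dr
            n = x * x + y * y
            if n < best_n:
                best_n, best = n, (x, y)
    return best


def _images_xy(L, a, b, radius=4.6):
    """All periodic images of b relative to a within ``radius``."""
    qa, ra = a % L, a // L
    qb, rb = b % L, b // L
    out = []
    reach = int(math.ceil(radius / L)) * L + L
    for iq in range(-reach, reach + 1, L):
        for ir in range(-reach, reach + 1, L):
            dq = qb - qa + iq
            dr = rb - ra + ir
            x, y = dq + 0.5 * dr, H * dr
            if x * x + y * y <= radius * radius:
                out.append((x, y))
    return out


def _crosses(p0, p1, b1_0, u1, b2_0, u2, samples=2000):
    """Numeric crossing: sign change (or near-zero) of the signed area
    f(s) = cross(b2(s)-b1(s), p(s)-b1(s)) refined by bisection, then a
    strict interior-projection check."""

    def f(s):
        px = p0[0] + s * (p1[0] - p0[0])
        py = p0[1] + s * (p1[1] - p0[1])
        ax = b1_0[0] + s * u1[0]
        ay = b1_0[1] + s * u1[1]
        bx = b2_0[0] + s * u2[0]
        by = b2_0[1] + s * u2[1]
        wx, wy = bx - ax, by - ay
        vx, vy = px - ax, py - ay
        return wx * vy - wy * vx, (vx * wx + vy * wy), (wx * wx + wy * wy)

    def interior(s):
        val, dot, ww = f(s)
        return ww > 1e-18 and 1e-9 < dot / ww < 1 - 1e-9

    ss = np.linspace(0.0, 1.0, samples + 1)
    vals = [f(s)[0] for s in ss]
    if all(abs(v) < 1e-12 for v in vals):
        return any(interior(s) for s in np.linspace(0.02, 1.0, 50))
    for i in range(samples):
        a, b = vals[i], vals[i + 1]
        if a == 0.0 and ss[i] > 0 and interior(ss[i]):
            return True
        if a * b < 0:
            lo, hi = ss[i], ss[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if f(lo)[0] * f(mid)[0] <= 0:
                    hi = mid
                else:
                    lo = mid
            s_root = 0.5 * (lo + hi)
            if s_root > 1e-12 and interior(s_root):
                return True
    if abs(vals[-1]) < 1e-12 and interior(1.0):
        return True
    return False


def validate(L, state_view, dirs, loops):
    """Fixed-point rejection: bond_break then bond_cross per loop,
    Gauss-Seidel in ascending smallest-site order.

    ``state_view`` is a dict with keys site_obj, obj_site, obj_species,
    partner, dimer_of (plain sequences).  Returns dict loop -> True/False
    and dict loop -> reason ('bond_break' | 'bond_cross' | None).
    """
    site_obj = state_view["site_obj"]
    obj_site = state_view["obj_site"]
    obj_species = state_view["obj_species"]
    partner = state_view["partner"]
    dimer_of = state_view["dimer_of"]

    succ = {s: neighbor(L, s, dirs[s]) for loop in loops for s in loop}
    site_loop = {}
    for li, loop in enumerate(loops):
        for s in loop:
            site_loop[s] = li
    order = sorted(range(len(loops)), key=lambda li: min(loops[li]))
    accepted = {li: True for li in range(len(loops))}
    reason = {li: None for li in range(len(loops))}

    all_dimers = {}
    for o, sp in enumerate(obj_species):
        if sp == MER and dimer_of[o] >= 0 and dimer_of[o] not in all_dimers:
            all_dimers[dimer_of[o]] = (o, partner[o])

    def moving(site):
        li = site_loop.get(site)
        return li is not None and accepted[li]

    def dest(site):
        return succ[site] if moving(site) else site

    changed = True
    while changed:
        changed = False
        for li in order:
            if not accepted[li]:
                continue
            loop = loops[li]
            rej = None
            for s in loop:
                o = site_obj[s]
                if obj_species[o] == MER:
                    new_s = succ[s]
                    ps = obj_site[partner[o]]
                    new_p = dest(ps)
                    if not any(neighbor(L, new_s, k) == new_p for k in range(6)):
                        rej = "bond_break"
                        break
            if rej is None:
                for s in loop:
                    o = site_obj[s]
                    k = dirs[s]
                    p0 = (0.0, 0.0)
                    p1 = UNIT[k]
                    for dm, (m1, m2) in all_dimers.items():
                        if obj_species[o] == MER and dimer_of[o] == dm:
                            continue
                        s1, s2 = obj_site[m1], obj_site[m2]
                        u1 = UNIT[dirs[s1]] if moving(s1) else (0.0, 0.0)
                        u2 = UNIT[dirs[s2]] if moving(s2) else (0.0, 0.0)
                        if u1 == (0.0, 0.0) and u2 == (0.0, 0.0):
                            continue
                        bond = _minimal_image_xy(L, s1, s2)
                        for b1 in _images_xy(L, s, s1):
                            b2 = (b1[0] + bond[0], b1[1] + bond[1])
                            if _crosses(p0, p1, b1, u1, b2, u2):
                                rej = "bond_cross"
                                break
                        if rej:
                            break
                    if rej:
                        break
            if rej:
                accepted[li] = False
                reason[li] = rej
                changed = True
    return accepted, reason


def accepted_loop_sets(L, state_view, dirs):
    loops, two = find_cycles(L, state_view["species_at"], dirs)
    acc, reason = validate(L, state_view, dirs, loops)
    return {frozenset(loops[li]) for li in acc if acc[li]}, loops, two, reason
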