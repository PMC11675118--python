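"""Ensemble observables of DLL trajectories.

All functions take a sequence of :class:`~dll2d.engine.TrajectoryStore`
objects sampled on the same schedule and average over objects and
trajectories (the default ensemble protocol: many independent trajectories,
single time origin at t = 0).

Species selectors:

``"solvent"``
    solvent molecules (one site each),
``"dimer_com"``
    dimer centres of mass (mean of the two mer positions; may sit at an
    edge midpoint and is treated in continuous Cartesian coordinates),
``"mer"``
    individual mers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import TrajectoryStore
from .lattice import MER, SOLVENT

__all__ = [
    "ObservableSeries",
    "msd",
    "non_gaussian",
    "end_to_end_acf",
    "position_acf",
    "trapped_fraction",
    "loop_statistics",
    "SPECIES",
]

SPECIES = ("solvent", "dimer_com", "mer")


@dataclass
class ObservableSeries:
    """A time series of one ensemble statistic."""

    times: np.ndarray
    values: np.ndarray
    n_ensemble: np.ndarray      # objects x trajectories contributing per point
    species: str
    statistic: str
    flags: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "species": self.species,
                "statistic": self.statistic,
                "value": self.values,
                "n_ensemble": self.n_ensemble,
            }
        )


def _check_ensemble(stores: Sequence[TrajectoryStore]) -> np.ndarray:
    if len(stores) == 0:
        raise ValueError("empty trajectory ensemble")
    times = stores[0].times
    for st in stores[1:]:
        if not np.array_equal(st.times, times):
            raise ValueError("trajectories must share one sampling schedule")
    return times


def _displacements(store: TrajectoryStore, species: str) -> np.ndarray:
    """(k, n, 2) displacement-from-origin array for the selected species."""
    rel = store.disp - store.disp[0]
    if species == "solvent":
        sel = store.obj_species == SOLVENT
        out = rel[:, sel, :]
    elif species == "mer":
        sel = store.obj_species == MER
        out = rel[:, sel, :]
    elif species == "dimer_com":
        a = store.dimers[:, 0]
        b = store.dimers[:, 1]
        out = 0.5 * (rel[:, a, :] + rel[:, b, :])
    else:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return out


def _multi_origin_pairs(times: np.ndarray):
    """Map each lag present in the schedule to the list of (i, j) sample pairs."""
    lags: dict[int, list[tuple[int, int]]] = {int(t): [] for t in times}
    tset = {int(t): i for i, t in enumerate(times)}
    for i, t0 in enumerate(times):
        for lag in lags:
            t1 = int(t0) + lag
            if t1 in tset:
                lags[lag].append((i, tset[t1]))
    return lags


def _moments(
    stores: Sequence[TrajectoryStore],
    species: str,
    origin_mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ensemble <r^2>, <r^4> and counts per sample time."""
    times = _check_ensemble(stores)
    k = len(times)
    s2 = np.zeros(k)
    s4 = np.zeros(k)
    n = np.zeros(k)
    if origin_mode == "single-origin":
        for st in stores:
            d = _displacements(st, species)
            r2 = d[..., 0] ** 2 + d[..., 1] ** 2
            s2 += r2.sum(axis=1)
            s4 += (r2 ** 2).sum(axis=1)
            n += r2.shape[1]
    elif origin_mode == "multi-origin":
        pairs = _multi_origin_pairs(times)
        for st in stores:
            d = _displacements(st, species)
            for li, lag in enumerate(times):
                for (i, j) in pairs[int(lag)]:
                    dd = d[j] - d[i]
                    r2 = dd[:, 0] ** 2 + dd[:, 1] ** 2
                    s2[li] += r2.sum()
                    s4[li] += (r2 ** 2).sum()
                    n[li] += r2.shape[0]
    else:
        raise ValueError("origin_mode must be 'single-origin' or 'multi-origin'")
    if np.any(n == 0):
        raise ValueError("no objects of the requested species in the ensemble")
    return times, s2 / n, s4 / n, n


def msd(
    stores: Sequence[TrajectoryStore],
    species: str = "solvent",
    origin_mode: str = "single-origin",
) -> ObservableSeries:
    """Mean square displacement <|r(t) - r(0)|^2> from unwrapped coordinates."""
    times, m2, _, n = _moments(stores, species, origin_mode)
    return ObservableSeries(
        times=times,
        values=m2,
        n_ensemble=n,
        species=species,
        statistic="msd",
        flags={"origin_mode": origin_mode},
    )


def non_gaussian(
    stores: Sequence[TrajectoryStore],
    species: str = "solvent",
    origin_mode: str = "single-origin",
) -> ObservableSeries:
    """Two-dimensional non-Gaussian parameter
    ``alpha_2(t) = <r^4> / (2 <r^2>^2) - 1`` (zero for Gaussian displacements).

    ``alpha_2(0) := 0`` by convention (0/0 limit); any later time with zero
    MSD is reported as 0 and flagged degenerate.
    """
    times, m2, m4, n = _moments(stores, species, origin_mode)
    values = np.zeros_like(m2)
    degenerate = []
    nz = m2 > 0
    values[nz] = m4[nz] / (2.0 * m2[nz] ** 2) - 1.0
    for i in np.flatnonzero(~nz):
        if times[i] > 0:
            degenerate.append(int(times[i]))
    return ObservableSeries(
        times=times,
        values=values,
        n_ensemble=n,
        species=species,
        statistic="alpha2",
        flags={"origin_mode": origin_mode, "degenerate_times": degenerate},
    )


def end_to_end_acf(stores: Sequence[TrajectoryStore]) -> ObservableSeries:
    """Orientational autocorrelation of the dimer end-to-end vector,
    ``<cos phi>(t) = <R(0) . R(t) / R(0)^2>``.

    The sign convention of each dimer's end-to-end vector is fixed at
    t = 0 (mer 0 -> mer 1) and carried through the whole trajectory.
    """
    times = _check_ensemble(stores)
    k = len(times)
    s = np.zeros(k)
    n = np.zeros(k)
    any_dimers = False
    for st in stores:
        if st.e2e.shape[1] == 0:
            continue
        any_dimers = True
        r0 = st.e2e[0]
        dots = (st.e2e * r0[None, :, :]).sum(axis=2) / (r0 ** 2).sum(axis=1)[None, :]
        s += dots.sum(axis=1)
        n += dots.shape[1]
    if not any_dimers:
        return ObservableSeries(
            times=times, values=np.full(k, np.nan), n_ensemble=n,
            species="dimer", statistic="cos_phi", flags={"empty": True},
        )
    return ObservableSeries(
        times=times, values=s / n, n_ensemble=n,
        species="dimer", statistic="cos_phi",
    )


def _site_selector(store: TrajectoryStore, species: str) -> np.ndarray:
    if species == "solvent":
        return store.obj_species == SOLVENT
    if species == "mer":
        return store.obj_species == MER
    raise ValueError(
        f"position autocorrelation is defined for site-resident species, got {species!r}"
    )


def position_acf(
    stores: Sequence[TrajectoryStore],
    species: str = "solvent",
) -> ObservableSeries:
    """Position autocorrelation ``rho(t)``: the fraction of objects found at
    their t = 0 lattice site at time t (wrapped site identity, so an object
    that wanders away and returns counts again)."""
    times = _check_ensemble(stores)
    s = np.zeros(len(times))
    n = np.zeros(len(times))
    for st in stores:
        sel = _site_selector(st, species)
        occ = st.sites[:, sel] == st.sites[0, sel][None, :]
        s += occ.sum(axis=1)
        n += occ.shape[1]
    return ObservableSeries(
        times=times, values=s / n, n_ensemble=n,
        species=species, statistic="rho",
    )


def trapped_fraction(
    stores: Sequence[TrajectoryStore],
    species: str = "solvent",
    window: tuple[float, float] | None = None,
) -> tuple[float, ObservableSeries]:
    """Fraction of objects whose wrapped site never differs from their t = 0
    site at any sample inside ``window`` (default: the whole run), together
    with ``rho(t)`` recomputed over the non-trapped objects only."""
    times = _check_ensemble(stores)
    if window is None:
        window = (0, int(times[-1]))
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError("empty trapping window")
    n_trapped = 0.0
    n_total = 0.0
    s = np.zeros(len(times))
    n_free = np.zeros(len(times))
    for st in stores:
        sel = _site_selector(st, species)
        occ = st.sites[:, sel] == st.sites[0, sel][None, :]
        trapped = occ[mask].all(axis=0)
        n_trapped += trapped.sum()
        n_total += trapped.size
        free = ~trapped
        if free.any():
            s += occ[:, free].sum(axis=1)
            n_free += free.sum()
    frac = n_trapped / n_total if n_total else float("nan")
    rho_free = ObservableSeries(
        times=times,
        values=np.divide(s, n_free, out=np.zeros_like(s), where=n_free > 0),
        n_ensemble=n_free,
        species=species,
        statistic="rho_excluding_trapped",
        flags={"window": (int(lo), int(hi)), "trapped_fraction": frac},
    )
    return frac, rho_free


def loop_statistics(stores: Sequence[TrajectoryStore]) -> dict:
    """Aggregate cooperative-loop statistics over an ensemble of runs.

    Returns the normalized accepted-loop length distribution, mean loop
    length, the mean fraction of lattice sites moving per step, and
    rejection rates per candidate loop.
    """
    if len(stores) == 0:
        raise ValueError("empty ensemble")
    hist = np.zeros_like(stores[0].accepted_hist, dtype=np.float64)
    found = np.zeros_like(hist)
    totals = np.zeros(6, dtype=np.float64)
    n_steps = 0
    n_sites = stores[0].L ** 2
    for st in stores:
        hist += st.accepted_hist
        found += st.found_hist
        totals += st.decade_stats.sum(axis=0)
        n_steps += int(st.times[-1] - st.times[0])
    total_acc = hist.sum()
    lengths = np.arange(hist.size)
    dist = hist / total_acc if total_acc > 0 else hist
    mean_len = float((lengths * dist).sum()) if total_acc > 0 else float("nan")
    candidates = totals[0] + totals[1]  # loops found (>=3) + two-cycles
    return {
        "length_distribution": dist,
        "found_length_distribution": found / found.sum() if found.sum() else found,
        "mean_loop_length": mean_len,
        "mobile_fraction_per_step": float(totals[5] / (n_steps * n_sites)) if n_steps else 0.0,
        "rejection_rates": {
            "two_cycle": float(totals[1] / candidates) if candidates else 0.0,
            "bond_break": float(totals[3] / candidates) if candidates else 0.0,
            "bond_cross": float(totals[4] / candidates) if candidates else 0.0,
        },
        "n_steps": n_steps,
        "loops_accepted": float(totals[2]),
        "loops_found": float(totals[0]),
    }
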