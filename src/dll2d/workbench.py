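"""Experiment orchestration: configuration, sweeps, fixtures and outputs.

A :class:`RunConfig` describes a concentration sweep (lists of obstacle and
dimer concentrations, ensemble sizes, sampling density and fit windows).
:func:`run_experiment` runs the full pipeline — per-matrix obstacle
generation, trajectory ensembles, ensemble observables and diffusion fits —
writing tidy CSV outputs plus a JSON manifest whose hash is embedded in
every CSV, so every output file can be traced back to its configuration.

:func:`make_fixtures` builds the small deterministic systems used by the
test suite: hand-constructed direction fields exercising each of the five
single-step outcomes (mutual exchange, no inflow, bond break, bond cross,
successful cooperative loop) plus a small seeded run for bit-for-bit
regression checks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import engine, fits, observables
from .lattice import (
    counts_from_concentrations,
    initialize_system,
    state_from_layout,
)

__all__ = [
    "RunConfig",
    "SchemaError",
    "load_config",
    "run_experiment",
    "make_fixtures",
    "write_template_config",
]


class SchemaError(ValueError):
    """Configuration file violates the documented schema."""


_DEFAULTS = {
    "n_trajectories": 1,
    "n_matrices": 1,
    "seed": 0,
    "points_per_decade": 20,
    "out_dir": None,
    "alpha_gate_strict": False,
    "short_window": [1.0, 100.0],
}
_REQUIRED = ("L", "c", "d", "n_steps")


@dataclass
class RunConfig:
    L: int
    c: list                      # obstacle concentrations to sweep
    d: list                      # dimer concentrations to sweep
    n_steps: int
    n_trajectories: int = 1
    n_matrices: int = 1
    seed: int = 0
    points_per_decade: int = 20
    out_dir: str | None = None
    alpha_gate_strict: bool = False
    short_window: tuple = (1.0, 100.0)
    cluster_scale: bool = field(init=False, default=False)

    def __post_init__(self):
        self.c = [float(x) for x in np.atleast_1d(self.c)]
        self.d = [float(x) for x in np.atleast_1d(self.d)]
        if self.n_steps < 1:
            raise SchemaError("n_steps must be >= 1")
        if self.n_trajectories < 1 or self.n_matrices < 1:
            raise SchemaError("ensemble sizes must be >= 1")
        for c in self.c:
            for d in self.d:
                counts_from_concentrations(self.L, c, d)  # raises if infeasible
        # production-scale configurations are flagged, not refused
        self.cluster_scale = bool(
            self.L >= 256 or self.n_steps >= 10**8
            or self.n_trajectories * self.n_matrices >= 40000
        )

    def manifest(self) -> dict:
        d = asdict(self)
        d["short_window"] = list(self.short_window)
        d["manifest_hash"] = self.manifest_hash()
        return d

    def manifest_hash(self) -> str:
        d = asdict(self)
        d["short_window"] = list(self.short_window)
        d.pop("out_dir", None)  # where outputs land does not change what they are
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Strict YAML key-value config: unknown keys are rejected, missing
    required keys reported together."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping")
    known = set(_REQUIRED) | set(_DEFAULTS)
    unknown = sorted(set(raw) - known)
    missing = sorted(k for k in _REQUIRED if k not in raw)
    problems = []
    if unknown:
        problems.append(f"unknown keys: {', '.join(unknown)}")
    if missing:
        problems.append(f"missing keys: {', '.join(missing)}")
    if problems:
        raise SchemaError("; ".join(problems))
    kwargs = {**_DEFAULTS, **raw}
    kwargs["short_window"] = tuple(kwargs["short_window"])
    return RunConfig(**kwargs)


def write_template_config(path) -> None:
    Path(path).write_text(
        "# dll2d run configuration\n"
        "L: 64\n"
        "c: [0.0, 0.12]\n"
        "d: [0.5]\n"
        "n_steps: 1000\n"
        "n_trajectories: 2\n"
        "n_matrices: 1\n"
        "seed: 0\n"
        "points_per_decade: 20\n"
        "alpha_gate_strict: false\n"
        "short_window: [1, 100]\n"
    )


def _sub_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _ensemble(config: RunConfig, c: float, d: float, ci: int, di: int):
    """Run the trajectory ensemble for one (c, d): n_matrices obstacle
    matrices x n_trajectories independent initializations per matrix."""
    stores = []
    seeds = []
    for j in range(config.n_matrices):
        mat_seed = _sub_seed(config.seed, 1, ci, di, j)
        rng = np.random.default_rng(mat_seed)
        comp = counts_from_concentrations(config.L, c, d)
        obstacle_sites = rng.choice(
            config.L**2, size=comp.n_obstacles, replace=False
        )
        for k in range(config.n_trajectories):
            tr_seed = _sub_seed(config.seed, 2, ci, di, j, k)
            state = initialize_system(
                config.L, c, d, seed=tr_seed, obstacle_sites=obstacle_sites
            )
            store = engine.run_trajectory(
                state, config.n_steps, points_per_decade=config.points_per_decade
            )
            store.manifest.update(
                {"matrix_seed": mat_seed, "trajectory_seed": tr_seed}
            )
            stores.append(store)
            seeds.append({"matrix": mat_seed, "trajectory": tr_seed})
    return stores, seeds


def _observable_frame(stores, has_dimers: bool) -> pd.DataFrame:
    frames = [
        observables.msd(stores, "solvent").to_frame(),
        observables.non_gaussian(stores, "solvent").to_frame(),
        observables.position_acf(stores, "solvent").to_frame(),
    ]
    if has_dimers:
        frames += [
            observables.msd(stores, "dimer_com").to_frame(),
            observables.non_gaussian(stores, "dimer_com").to_frame(),
            observables.end_to_end_acf(stores).to_frame(),
        ]
    return pd.concat(frames, ignore_index=True)


def _fit_frame(stores, config: RunConfig, c: float, d: float) -> pd.DataFrame:
    rows = []
    species_list = ["solvent"] + (["dimer_com"] if stores[0].dimers.shape[0] else [])
    for sp in species_list:
        series = observables.msd(stores, sp)
        long_window = fits.last_decade_window(series)
        for name, window in (("short", config.short_window), ("long", long_window)):
            try:
                f = fits.fit_diffusion_coefficient(
                    series, window, strict=config.alpha_gate_strict
                )
            except ValueError:
                continue
            rows.append(
                {
                    "species": sp, "c": c, "d": d, "window": name,
                    "t_lo": f.window[0], "t_hi": f.window[1],
                    "alpha": f.alpha, "d_w": f.d_w,
                    "D": np.nan if f.D is None else f.D,
                    "R2": f.r_squared, "gated": f.gated,
                }
            )
    return pd.DataFrame(rows)


def _write_csv(df: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest_hash: {manifest_hash}\n")
        df.to_csv(fh, index=False)


def run_experiment(config: RunConfig) -> dict:
    """Run the configured sweep and return (and optionally write) the bundle.

    Returns a dict keyed by ``(c, d)`` with ``stores`` (trajectory
    ensembles), ``observables`` and ``fits`` DataFrames, plus the manifest.
    Every (matrix, trajectory) pair has a recorded derived seed, so any
    piece of the sweep can be reproduced in isolation.
    """
    out = {"manifest": config.manifest(), "results": {}}
    mh = config.manifest_hash()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(out["manifest"], indent=2))
    for ci, c in enumerate(config.c):
        for di, d in enumerate(config.d):
            stores, seeds = _ensemble(config, c, d, ci, di)
            obs = _observable_frame(stores, stores[0].dimers.shape[0] > 0)
            fit = _fit_frame(stores, config, c, d)
            obs.insert(0, "c", c)
            obs.insert(1, "d", d)
            out["results"][(c, d)] = {
                "stores": stores, "observables": obs, "fits": fit, "seeds": seeds,
            }
            if out_dir:
                tag = f"c{c:.4f}_d{d:.4f}"
                _write_csv(obs, out_dir / f"observables_{tag}.csv", mh)
                _write_csv(fit, out_dir / f"fits_{tag}.csv", mh)
    if out_dir:
        all_obs = pd.concat(
            [r["observables"] for r in out["results"].values()], ignore_index=True
        )
        _write_csv(all_obs, out_dir / "observables.csv", mh)
    return out


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    name: str
    state: object
    dirs: np.ndarray
    expected: dict
    description: str


def _dirs_from_map(L: int, mapping: dict) -> np.ndarray:
    """Direction array from a complete {(q, r): direction} map."""
    dirs = np.empty(L * L, dtype=np.int8)
    for r in range(L):
        for q in range(L):
            dirs[r * L + q] = mapping[(q, r)]
    return dirs


def make_fixtures(seed: int = 0) -> dict[str, Fixture]:
    """Small deterministic systems covering each single-step outcome."""
    L = 6
    fx: dict[str, Fixture] = {}

    # variant 1/2: only a mutual exchange exists; everything else funnels
    # into the pair and is immobile (no inflow into the vacated sites).
    mapping = {(1, 1): 0, (2, 1): 3}
    for r in range(L):
        for q in range(L):
            if (q, r) in mapping:
                continue
            if r > 1:
                mapping[(q, r)] = 4
            elif r == 1:
                mapping[(q, r)] = 0 if q < 1 else 3
            else:
                mapping[(q, r)] = 1
    st = state_from_layout(L, seed=seed)
    fx["variant1_mutual_exchange"] = Fixture(
        "variant1_mutual_exchange", st, _dirs_from_map(L, mapping),
        expected={"n_loops": 0, "n_two_cycles": 1, "moved": 0},
        description="two adjacent solvents point at each other; rejected by construction",
    )

    # variant 3: a 3-loop moves one mer two lattice units away from its
    # stationary partner -> bond_break.
    mapping = {(1, 1): 3, (0, 1): 1, (0, 2): 5}
    for r in range(L):
        for q in range(L):
            if (q, r) in mapping:
                continue
            if r >= 2:
                mapping[(q, r)] = 4
            elif r == 1:
                mapping[(q, r)] = 3
            else:
                mapping[(q, r)] = 1
    st = state_from_layout(L, dimer_site_pairs=[((1, 1), (2, 1))], seed=seed)
    fx["variant3_bond_break"] = Fixture(
        "variant3_bond_break", st, _dirs_from_map(L, mapping),
        expected={"n_loops": 1, "accepted": 0, "reason": engine.REJECT_BOND_BREAK},
        description="triangle loop carries one mer away; rigid bond rejects the loop",
    )

    # variant 4: an 8-loop translates a dimer bond upward while a solvent in
    # the same loop passes through the swept area -> bond_cross.
    cycle = [(1, 0), (1, 1), (2, 0), (2, 1), (1, 2), (0, 2), (0, 1), (0, 0)]
    cycle_dirs = {
        (1, 0): 1, (1, 1): 5, (2, 0): 1, (2, 1): 2,
        (1, 2): 3, (0, 2): 4, (0, 1): 4, (0, 0): 0,
    }
    mapping = dict(cycle_dirs)
    for r in range(L):
        for q in range(L):
            if (q, r) in mapping:
                continue
            mapping[(q, r)] = 4 if r >= 3 else 3
    st = state_from_layout(L, dimer_site_pairs=[((1, 0), (2, 0))], seed=seed)
    fx["variant4_bond_cross"] = Fixture(
        "variant4_bond_cross", st, _dirs_from_map(L, mapping),
        expected={"n_loops": 1, "accepted": 0, "reason": engine.REJECT_BOND_CROSS,
                  "cycle": cycle},
        description="solvent path crosses a simultaneously translating dimer bond",
    )

    # variant 5: the 3-loop over a triangle holding both mers and one
    # solvent; the bond maps onto another triangle edge and survives.
    mapping = {(0, 0): 0, (1, 0): 2, (0, 1): 4}
    for r in range(L):
        for q in range(L):
            if (q, r) in mapping:
                continue
            if r >= 2:
                mapping[(q, r)] = 4
            elif r == 1:
                mapping[(q, r)] = 3
            else:
                mapping[(q, r)] = 3 if q >= 2 else 1
    st = state_from_layout(L, dimer_site_pairs=[((0, 0), (1, 0))], seed=seed)
    fx["variant5_cooperative_loop"] = Fixture(
        "variant5_cooperative_loop", st, _dirs_from_map(L, mapping),
        expected={"n_loops": 1, "accepted": 1, "moved": 3},
        description="cooperative 3-loop rotates the dimer; the bond does not break",
    )

    # uniform field on L=4: every row is a winding 4-loop (pure solvent).
    L4 = 4
    st = state_from_layout(L4, seed=seed)
    fx["uniform_rows"] = Fixture(
        "uniform_rows", st, np.zeros(L4 * L4, dtype=np.int8),
        expected={"n_loops": 4, "loop_length": 4},
        description="all vectors in direction 0: four disjoint winding row loops",
    )
    return fx


def golden_run(seed: int = 12345, L: int = 8, c: float = 0.125, d: float = 0.25,
               n_steps: int = 50) -> dict:
    """Deterministic small run reduced to SHA-256 hashes of its arrays,
    for bit-for-bit regression comparison against a frozen record."""
    state = initialize_system(L, c, d, seed=seed)
    store = engine.run_trajectory(state, n_steps, points_per_decade=10)

    def h(a: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()

    return {
        "seed": seed, "L": L, "c": c, "d": d, "n_steps": n_steps,
        "site_obj": h(state.site_obj),
        "disp": h(state.disp),
        "times": h(store.times),
        "sites": h(store.sites),
        "e2e": h(store.e2e),
        "decade_stats": h(store.decade_stats),
    }
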