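"""Triangular-lattice geometry, composition bookkeeping and system initialization.

The simulation box is a rhombic ``L x L`` patch of the two-dimensional
triangular lattice with periodic boundary conditions.  Sites are addressed by
axial coordinates ``(q, r)`` with ``0 <= q, r < L`` and flattened as
``site = r * L + q``.  The Cartesian embedding uses a lattice constant of 1:
``x = q + r/2``, ``y = r * sqrt(3)/2``.

Every site always holds exactly one object: a solvent molecule, one mer of a
dimer (two mers joined by a rigid nearest-neighbour bond), or an immobile
impenetrable obstacle.  Concentrations are defined as ``c = n / L**2``
(obstacles) and ``d = 2 m / L**2`` (lattice fraction covered by dimers).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SOLVENT",
    "MER",
    "OBSTACLE",
    "NEIGHBOR_OFFSETS",
    "UNIT_X",
    "UNIT_Y",
    "TriangularLattice",
    "SystemComposition",
    "SystemState",
    "build_lattice",
    "counts_from_concentrations",
    "initialize_system",
    "state_from_layout",
    "InfeasibleCompositionError",
    "InfeasiblePackingError",
]

# Species labels (also used for per-object species arrays).
SOLVENT = 0
MER = 1
OBSTACLE = 2

_SQ3H = math.sqrt(3.0) / 2.0

# Axial offsets of the six nearest neighbours, ordered so that direction k and
# direction (k + 3) % 6 are inverses.
NEIGHBOR_OFFSETS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))

# Cartesian unit vectors of the six directions (lattice constant 1).
UNIT_X = np.array([1.0, 0.5, -0.5, -1.0, -0.5, 0.5])
UNIT_Y = np.array([0.0, _SQ3H, _SQ3H, 0.0, -_SQ3H, -_SQ3H])


class InfeasibleCompositionError(ValueError):
    """Requested obstacle + dimer coverage exceeds the lattice."""


class InfeasiblePackingError(RuntimeError):
    """Dimer placement could not reach the requested dimer count."""


class TriangularLattice:
    """Periodic rhombic patch of the triangular lattice.

    Parameters
    ----------
    L : int
        Box edge in sites; the lattice has ``L**2`` sites.  ``L >= 3`` so
        that a cooperative loop of length >= 3 fits in the box.
    """

    def __init__(self, L: int):
        if int(L) != L or L < 3:
            raise ValueError(f"lattice edge L must be an integer >= 3, got {L!r}")
        self.L = int(L)
        self.n_sites = self.L * self.L
        self.neighbor_offsets = NEIGHBOR_OFFSETS
        self.unit_x = UNIT_X
        self.unit_y = UNIT_Y
        self._nbr = self._build_neighbor_table()

    def _build_neighbor_table(self) -> np.ndarray:
        L = self.L
        q, r = np.meshgrid(np.arange(L), np.arange(L), indexing="xy")
        q = q.ravel()
        r = r.ravel()
        nbr = np.empty((self.n_sites, 6), dtype=np.int32)
        for k, (dq, dr) in enumerate(NEIGHBOR_OFFSETS):
            nbr[:, k] = ((r + dr) % L) * L + (q + dq) % L
        return nbr

    @property
    def neighbors(self) -> np.ndarray:
        """``(n_sites, 6)`` int32 table: ``neighbors[s, k]`` is site ``s`` moved one step in direction ``k``."""
        return self._nbr

    def site_index(self, q: int, r: int) -> int:
        return (r % self.L) * self.L + (q % self.L)

    def axial(self, site: int | np.ndarray):
        """Axial coordinates ``(q, r)`` of a site index (vectorized)."""
        return site % self.L, site // self.L

    def cartesian(self, site: int | np.ndarray):
        """Cartesian embedding of a site (lattice constant 1)."""
        q, r = self.axial(site)
        return q + 0.5 * r, _SQ3H * r

    def neighbor(self, site: int, direction: int) -> int:
        return int(self._nbr[site, direction])

    def are_adjacent(self, a: int, b: int) -> bool:
        return b in self._nbr[a]

    def minimal_image(self, a: int, b: int) -> tuple[float, float]:
        """Minimal-image Cartesian displacement from site ``a`` to site ``b``.

        Scans the nine periodic images and returns the shortest Cartesian
        vector, so it is exact also for small boxes where naive centred
        remainders fail.
        """
        L = self.L
        qa, ra = self.axial(a)
        qb, rb = self.axial(b)
        dq0 = qb - qa
        dr0 = rb - ra
        best = None
        best_n = math.inf
        for iq in (-L, 0, L):
            for ir in (-L, 0, L):
                dq = dq0 + iq
                dr = dr0 + ir
                x = dq + 0.5 * dr
                y = _SQ3H * dr
                n = x * x + y * y
                if n < best_n:
                    best_n = n
                    best = (x, y)
        return best


def build_lattice(L: int) -> TriangularLattice:
    """Construct the periodic triangular-lattice geometry for box edge ``L``."""
    return TriangularLattice(L)


@dataclass(frozen=True)
class SystemComposition:
    """Realized object counts for a requested ``(c, d)`` composition."""

    L: int
    c_requested: float
    d_requested: float
    n_obstacles: int
    n_dimers: int
    n_solvent: int

    @property
    def c(self) -> float:
        """Realized obstacle concentration ``n / L**2``."""
        return self.n_obstacles / self.L**2

    @property
    def d(self) -> float:
        """Realized dimer concentration ``2 m / L**2``."""
        return 2 * self.n_dimers / self.L**2

    @property
    def n_objects(self) -> int:
        return self.n_obstacles + 2 * self.n_dimers + self.n_solvent


def counts_from_concentrations(L: int, c: float, d: float) -> SystemComposition:
    """Convert requested concentrations into integer object counts.

    ``n = round(c L**2)`` obstacles and ``m = round(d L**2 / 2)`` dimers,
    rounding half to even; the remaining sites are solvent.
    """
    if c < 0 or d < 0:
        raise ValueError("concentrations must be non-negative")
    if c > 1 or d > 1:
        raise ValueError("concentrations must be <= 1")
    n_sites = L * L
    n = int(round(c * n_sites))
    m = int(round(d * n_sites / 2.0))
    if n + 2 * m > n_sites:
        raise InfeasibleCompositionError(
            f"n + 2m = {n + 2 * m} exceeds L**2 = {n_sites} (c={c}, d={d})"
        )
    return SystemComposition(
        L=L,
        c_requested=float(c),
        d_requested=float(d),
        n_obstacles=n,
        n_dimers=m,
        n_solvent=n_sites - n - 2 * m,
    )


@dataclass
class SystemState:
    """Full lattice occupancy plus per-object displacement bookkeeping.

    Objects are numbered ``0 .. n_objects-1`` with obstacles first, then the
    mers (dimer ``k`` owns mers ``n_obstacles + 2k`` and ``n_obstacles +
    2k + 1``), then solvent.  ``disp`` accumulates the unwrapped Cartesian
    displacement of every object in lattice-constant units; obstacles stay
    at zero forever.
    """

    lattice: TriangularLattice
    composition: SystemComposition
    site_obj: np.ndarray          # (n_sites,) int32: object id at each site
    obj_site: np.ndarray          # (n_objects,) int32: wrapped site of each object
    obj_species: np.ndarray       # (n_objects,) int8
    partner: np.ndarray           # (n_objects,) int32: partner mer object id, -1 otherwise
    dimer_of: np.ndarray          # (n_objects,) int32: dimer index, -1 otherwise
    dimers: np.ndarray            # (n_dimers, 2) int32: the two mer object ids
    disp: np.ndarray              # (n_objects, 2) float64 unwrapped displacement
    init_site: np.ndarray         # (n_objects,) int32 site at t = 0
    t: int = 0
    seed: int | None = None
    rng: np.random.Generator = field(default=None, repr=False)

    @property
    def n_sites(self) -> int:
        return self.lattice.n_sites

    @property
    def n_objects(self) -> int:
        return self.obj_site.shape[0]

    def species_at_sites(self) -> np.ndarray:
        """Per-site species labels."""
        return self.obj_species[self.site_obj]

    def dimer_bond_vectors(self) -> np.ndarray:
        """``(n_dimers, 2)`` current end-to-end Cartesian vectors (mer0 -> mer1)."""
        out = np.empty((len(self.dimers), 2))
        for k, (a, b) in enumerate(self.dimers):
            out[k] = self.lattice.minimal_image(int(self.obj_site[a]), int(self.obj_site[b]))
        return out

    def validate(self) -> None:
        """Re-derive every structural invariant; raise ``AssertionError`` on violation."""
        lat = self.lattice
        comp = self.composition
        assert self.site_obj.shape == (lat.n_sites,)
        assert np.array_equal(np.sort(self.site_obj), np.arange(self.n_objects)), \
            "every site must hold exactly one distinct object"
        assert np.all(self.obj_site[self.site_obj] == np.arange(lat.n_sites)), \
            "site->object and object->site maps disagree"
        counts = np.bincount(self.obj_species, minlength=3)
        assert counts[OBSTACLE] == comp.n_obstacles
        assert counts[MER] == 2 * comp.n_dimers
        assert counts[SOLVENT] == comp.n_solvent
        for a, b in self.dimers:
            sa, sb = int(self.obj_site[a]), int(self.obj_site[b])
            assert sb in lat.neighbors[sa], f"dimer mers {a},{b} not adjacent"
            assert self.partner[a] == b and self.partner[b] == a
        obst = self.obj_species == OBSTACLE
        assert np.all(self.disp[obst] == 0.0), "obstacles must never move"
        assert np.all(self.obj_site[obst] == self.init_site[obst])

    def copy(self) -> "SystemState":
        new = SystemState(
            lattice=self.lattice,
            composition=self.composition,
            site_obj=self.site_obj.copy(),
            obj_site=self.obj_site.copy(),
            obj_species=self.obj_species.copy(),
            partner=self.partner.copy(),
            dimer_of=self.dimer_of.copy(),
            dimers=self.dimers.copy(),
            disp=self.disp.copy(),
            init_site=self.init_site.copy(),
            t=self.t,
            seed=self.seed,
        )
        new.rng = np.random.default_rng()
        new.rng.bit_generator.state = self.rng.bit_generator.state
        return new

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write a self-describing HDF5 snapshot (geometry, occupancy, RNG state)."""
        import json

        with h5py.File(path, "w") as f:
            f.attrs["L"] = self.lattice.L
            f.attrs["t"] = self.t
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["c_requested"] = self.composition.c_requested
            f.attrs["d_requested"] = self.composition.d_requested
            f.attrs["n_obstacles"] = self.composition.n_obstacles
            f.attrs["n_dimers"] = self.composition.n_dimers
            f.attrs["n_solvent"] = self.composition.n_solvent
            f.create_dataset("site_obj", data=self.site_obj)
            f.create_dataset("obj_site", data=self.obj_site)
            f.create_dataset("obj_species", data=self.obj_species)
            f.create_dataset("partner", data=self.partner)
            f.create_dataset("dimer_of", data=self.dimer_of)
            f.create_dataset("dimers", data=self.dimers.reshape(-1, 2))
            f.create_dataset("disp", data=self.disp)
            f.create_dataset("init_site", data=self.init_site)
            f.attrs["rng_state"] = json.dumps(self.rng.bit_generator.state)

    @classmethod
    def load(cls, path) -> "SystemState":
        import json

        with h5py.File(path, "r") as f:
            L = int(f.attrs["L"])
            comp = SystemComposition(
                L=L,
                c_requested=float(f.attrs["c_requested"]),
                d_requested=float(f.attrs["d_requested"]),
                n_obstacles=int(f.attrs["n_obstacles"]),
                n_dimers=int(f.attrs["n_dimers"]),
                n_solvent=int(f.attrs["n_solvent"]),
            )
            seed = int(f.attrs["seed"])
            state = cls(
                lattice=build_lattice(L),
                composition=comp,
                site_obj=f["site_obj"][:],
                obj_site=f["obj_site"][:],
                obj_species=f["obj_species"][:],
                partner=f["partner"][:],
                dimer_of=f["dimer_of"][:],
                dimers=f["dimers"][:],
                disp=f["disp"][:],
                init_site=f["init_site"][:],
                t=int(f.attrs["t"]),
                seed=None if seed == -1 else seed,
            )
            state.rng = np.random.default_rng()
            state.rng.bit_generator.state = json.loads(f.attrs["rng_state"])
        return state

    def debug_dump(self) -> str:
        """Plain-text dump: one line per site with index, axial coords, species, object id."""
        buf = io.StringIO()
        buf.write("# site q r species obj\n")
        species = self.species_at_sites()
        names = {SOLVENT: "SOLVENT", MER: "MER", OBSTACLE: "OBSTACLE"}
        for s in range(self.n_sites):
            q, r = self.lattice.axial(s)
            buf.write(f"{s} {q} {r} {names[int(species[s])]} {int(self.site_obj[s])}\n")
        return buf.getvalue()


def state_from_layout(
    L: int,
    obstacle_sites=(),
    dimer_site_pairs=(),
    seed: int | None = 0,
) -> SystemState:
    """Build a :class:`SystemState` from an explicit layout.

    ``obstacle_sites`` is an iterable of site indices or ``(q, r)`` pairs;
    ``dimer_site_pairs`` an iterable of 2-tuples of the same.  All remaining
    sites become solvent.  Used for hand-constructed fixtures and tests.
    """
    lat = build_lattice(L)

    def to_site(x):
        if isinstance(x, tuple):
            return lat.site_index(*x)
        return int(x)

    obst = [to_site(s) for s in obstacle_sites]
    dim = [(to_site(a), to_site(b)) for a, b in dimer_site_pairs]
    n = len(obst)
    m = len(dim)
    n_sites = lat.n_sites
    comp = SystemComposition(
        L=L,
        c_requested=n / n_sites,
        d_requested=2 * m / n_sites,
        n_obstacles=n,
        n_dimers=m,
        n_solvent=n_sites - n - 2 * m,
    )
    site_obj = np.full(n_sites, -1, dtype=np.int32)
    obj_site = np.empty(comp.n_objects, dtype=np.int32)
    obj_species = np.empty(comp.n_objects, dtype=np.int8)
    partner = np.full(comp.n_objects, -1, dtype=np.int32)
    dimer_of = np.full(comp.n_objects, -1, dtype=np.int32)
    dimers = np.empty((m, 2), dtype=np.int32)
    oid = 0
    for s in obst:
        site_obj[s] = oid
        obj_site[oid] = s
        obj_species[oid] = OBSTACLE
        oid += 1
    for k, (a, b) in enumerate(dim):
        for j, s in enumerate((a, b)):
            site_obj[s] = oid + j
            obj_site[oid + j] = s
            obj_species[oid + j] = MER
            dimer_of[oid + j] = k
        partner[oid] = oid + 1
        partner[oid + 1] = oid
        dimers[k] = (oid, oid + 1)
        oid += 2
    for s in np.flatnonzero(site_obj == -1):
        site_obj[s] = oid
        obj_site[oid] = s
        obj_species[oid] = SOLVENT
        oid += 1
    state = SystemState(
        lattice=lat,
        composition=comp,
        site_obj=site_obj,
        obj_site=obj_site,
        obj_species=obj_species,
        partner=partner,
        dimer_of=dimer_of,
        dimers=dimers,
        disp=np.zeros((comp.n_objects, 2)),
        init_site=obj_site.copy(),
        t=0,
        seed=seed,
        rng=np.random.default_rng(seed),
    )
    state.validate()
    return state


def _rsa_dimers(
    lat: TriangularLattice,
    free: np.ndarray,
    m_target: int,
    rng: np.random.Generator,
    max_repair_iter: int,
) -> list[tuple[int, int]]:
    """Place ``m_target`` dimers on the free sites of ``lat``.

    Phase 1 is random sequential adsorption on edges whose both endpoints are
    free.  Dense targets jam below the requested count, so phase 2 performs
    vacancy diffusion: an exposed free site swaps with a neighbouring dimer
    (the dimer re-orients onto the vacancy), and whenever two vacancies meet
    on adjacent sites they are converted into a new dimer.
    """
    nbr = lat.neighbors
    dimer_sites: list[tuple[int, int]] = []
    free_set = set(int(s) for s in np.flatnonzero(free))
    mer_partner_site: dict[int, int] = {}

    def place(a: int, b: int) -> None:
        dimer_sites.append((a, b))
        free_set.discard(a)
        free_set.discard(b)
        mer_partner_site[a] = b
        mer_partner_site[b] = a

    # Phase 1: RSA until target reached or attempts exhausted.
    attempts_budget = 200 * max(m_target, 1)
    attempts = 0
    free_list = list(free_set)
    while len(dimer_sites) < m_target and attempts < attempts_budget and free_set:
        attempts += 1
        a = free_list[rng.integers(len(free_list))] if free_list else -1
        if a not in free_set:
            free_list = list(free_set)
            continue
        k = int(rng.integers(6))
        b = int(nbr[a, k])
        if b in free_set:
            place(a, b)

    # Phase 2: vacancy-diffusion repair.
    it = 0
    while len(dimer_sites) < m_target:
        it += 1
        if it > max_repair_iter:
            raise InfeasiblePackingError(
                f"dimer packing stalled at {len(dimer_sites)}/{m_target} dimers"
            )
        if not free_set:
            raise InfeasiblePackingError("no free sites left but dimer count short")
        f = int(rng.choice(np.fromiter(free_set, dtype=np.int64))) if len(free_set) > 40 \
            else list(free_set)[int(rng.integers(len(free_set)))]
        nb = nbr[f]
        free_nb = [int(b) for b in nb if int(b) in free_set]
        if free_nb:
            b = free_nb[int(rng.integers(len(free_nb)))]
            place(f, b)
            continue
        mer_nb = [int(b) for b in nb if int(b) in mer_partner_site]
        if not mer_nb:
            continue  # vacancy fully caged by obstacles; try another
        a = mer_nb[int(rng.integers(len(mer_nb)))]
        p = mer_partner_site[a]
        # re-orient dimer (a, p) onto (f, a); vacancy moves to p
        dimer_sites.remove((a, p) if (a, p) in dimer_sites else (p, a))
        del mer_partner_site[a]
        del mer_partner_site[p]
        free_set.add(p)
        free_set.discard(f)
        place(f, a)
        # place() removed f and a; p was re-freed above
    return dimer_sites


def initialize_system(
    L: int,
    c: float,
    d: float,
    seed: int | None = None,
    obstacle_sites: np.ndarray | None = None,
    max_repair_iter: int | None = None,
) -> SystemState:
    """Build a random fully-occupied system at the requested composition.

    Obstacles are placed uniformly at random (or taken from
    ``obstacle_sites`` so several trajectories can share one obstacle
    matrix), dimers by random sequential adsorption with vacancy-diffusion
    repair, and the remaining sites are filled with solvent.  Deterministic
    for a fixed ``seed``.
    """
    lat = build_lattice(L)
    comp = counts_from_concentrations(L, c, d)
    rng = np.random.default_rng(seed)
    if max_repair_iter is None:
        max_repair_iter = 2000 * max(comp.n_dimers, 1) + 100_000

    if obstacle_sites is None:
        obstacle_sites = rng.choice(lat.n_sites, size=comp.n_obstacles, replace=False)
    else:
        obstacle_sites = np.asarray(obstacle_sites, dtype=np.int64)
        if obstacle_sites.shape[0] != comp.n_obstacles:
            raise ValueError(
                f"obstacle_sites has {obstacle_sites.shape[0]} sites, "
                f"composition requires {comp.n_obstacles}"
            )
        if np.unique(obstacle_sites).size != obstacle_sites.size:
            raise ValueError("obstacle_sites contains duplicates")

    free = np.ones(lat.n_sites, dtype=bool)
    free[obstacle_sites] = False
    dimer_sites = _rsa_dimers(lat, free, comp.n_dimers, rng, max_repair_iter)

    n_obj = comp.n_objects
    site_obj = np.full(lat.n_sites, -1, dtype=np.int32)
    obj_site = np.empty(n_obj, dtype=np.int32)
    obj_species = np.empty(n_obj, dtype=np.int8)
    partner = np.full(n_obj, -1, dtype=np.int32)
    dimer_of = np.full(n_obj, -1, dtype=np.int32)
    dimers = np.empty((comp.n_dimers, 2), dtype=np.int32)

    oid = 0
    for s in obstacle_sites:
        site_obj[s] = oid
        obj_site[oid] = s
        obj_species[oid] = OBSTACLE
        oid += 1
    for k, (a, b) in enumerate(dimer_sites):
        for j, s in enumerate((a, b)):
            site_obj[s] = oid + j
            obj_site[oid + j] = s
            obj_species[oid + j] = MER
            dimer_of[oid + j] = k
        partner[oid] = oid + 1
        partner[oid + 1] = oid
        dimers[k] = (oid, oid + 1)
        oid += 2
    for s in np.flatnonzero(site_obj == -1):
        site_obj[s] = oid
        obj_site[oid] = s
        obj_species[oid] = SOLVENT
        oid += 1
    assert oid == n_obj

    state = SystemState(
        lattice=lat,
        composition=comp,
        site_obj=site_obj,
        obj_site=obj_site,
        obj_species=obj_species,
        partner=partner,
        dimer_of=dimer_of,
        dimers=dimers,
        disp=np.zeros((n_obj, 2)),
        init_site=obj_site.copy(),
        t=0,
        seed=seed,
        rng=rng,
    )
    state.validate()
    return state
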