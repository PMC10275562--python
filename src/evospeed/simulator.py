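"""Spatially explicit eco-evolutionary simulator with four divergence models.

The simulator follows the diversification of a clade from a single ancestral
species on a dynamic gridded landscape.  Each time step applies, in a fixed
order: (1) bounded Brownian trait evolution, (2) Weibull-kernel dispersal,
(3) geographic clustering of populations, (4) genetic divergence accrual /
secondary-contact coalescence, (5) threshold speciation, (6) abundance from
thermal suitability and aridity-limited carrying capacity, (7) stochastic
extirpation, (8) species-level extinction cleanup.

Divergence models
-----------------
M0  null: a constant per-step increment drawn once per simulation from
    U(0.01, 1).
M1  temperature-dependent: ``g = ((T̂_i + T̂_k)/2)**λ`` with ``T̂`` the mean
    standardized temperature across each diverging population's range.
M2  body-size-dependent: ``g = (((1-B̂_i) + (1-B̂_k))/2)**λ``.
M3  both: ``g = ((B̂T̂_i + B̂T̂_k)/2)**λ`` with ``B̂T̂ = ((1-B̂) + T̂)/2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from evospeed.landscape import LandscapeSeries


try:  # numba accelerates the per-species component labelling substantially
    from numba import njit

    @njit(cache=True)
    def _uf_labels(adj):  # pragma: no cover - exercised via _components_bool
        n = adj.shape[0]
        parent = np.arange(n)
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    ri = i
                    while parent[ri] != ri:
                        ri = parent[ri]
                    rj = j
                    while parent[rj] != rj:
                        rj = parent[rj]
                    if ri < rj:
                        parent[rj] = ri
                    elif rj < ri:
                        parent[ri] = rj
        labels = np.full(n, -1)
        comp = 0
        for i in range(n):
            r = i
            while parent[r] != r:
                r = parent[r]
            if labels[r] < 0:
                labels[r] = comp
                comp += 1
            labels[i] = labels[r]
        return comp, labels

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _components_bool(adj: np.ndarray) -> tuple[int, np.ndarray]:
    """Connected-component labels of a dense boolean adjacency matrix.

    Union-find with labels assigned in index order (deterministic).  Much
    faster than building a sparse graph for the small matrices that arise per
    species; falls back to a numpy BFS when numba is unavailable.
    """
    n = adj.shape[0]
    if n <= 1:
        return n, np.zeros(n, dtype=int)
    if _HAVE_NUMBA:
        comp, labels = _uf_labels(np.ascontiguousarray(adj))
        return int(comp), labels.astype(int)
    labels = np.full(n, -1, dtype=int)
    comp = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        while True:
            new = adj[mask].any(axis=0) & ~mask
            if not new.any():
                break
            mask |= new
        labels[mask] = comp
        comp += 1
    return comp, labels

__all__ = [
    "MODELS",
    "ParameterSet",
    "InitSpec",
    "SpeciesState",
    "PhylogenyLog",
    "SimulationResult",
    "carrying_capacity",
    "suitability_abundance",
    "reapportion",
    "extirpation_probability",
    "evolve_traits",
    "cluster_populations",
    "divergence_increment",
    "update_divergence",
    "speciate_partition",
    "Simulation",
    "run_simulation",
]

MODELS = ("M0", "M1", "M2", "M3")


@dataclass
class ParameterSet:
    """One point of the simulation parameter space.

    The six varied parameters are the divergence threshold ``S`` (2-10), the
    divergence-rate exponent ``lambda_`` (2-5, used by M1-M3), the
    environmental-filter width ``omega`` (0.01-0.035), the Brownian rates
    ``sigma_B`` (0.001-0.02) and ``sigma_T`` (0.001-0.015), and the Weibull
    dispersal scale ``phi`` in km (330-880).  The shape ``psi`` (2.5), the
    maximum carrying capacity ``Kc`` (30,000) and the extirpation parameters
    ``mu_t``/``mu_d`` are fixed across an ensemble.
    """

    model: str = "M1"
    S: float = 6.0
    lambda_: float = 3.5
    omega: float = 0.02
    sigma_B: float = 0.01
    sigma_T: float = 0.008
    phi: float = 600.0
    psi: float = 2.5
    Kc: float = 30_000.0
    mu_t: float = 500.0
    mu_d: float = 0.01
    g0: float | None = None
    contact_distance: float | None = None
    m0_draw: str = "per_simulation"  # or "per_step"
    merge_rule: str = "mean"  # or "min" / "max"
    boundary: str = "reflect"  # or "truncate"
    wrap: bool = False
    seed: int = 0
    param_id: int | str | None = None

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.S <= 0:
            raise ValueError("S must be > 0")
        if self.lambda_ < 1:
            raise ValueError("lambda_ must be >= 1")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if min(self.sigma_B, self.sigma_T) < 0:
            raise ValueError("Brownian rates must be >= 0")
        if self.phi <= 0 or self.psi <= 0:
            raise ValueError("phi and psi must be > 0")
        if self.Kc <= 0:
            raise ValueError("Kc must be > 0")
        if self.mu_d <= 0:
            raise ValueError("mu_d must be > 0")
        if self.m0_draw not in ("per_simulation", "per_step"):
            raise ValueError("m0_draw must be 'per_simulation' or 'per_step'")
        if self.merge_rule not in ("mean", "min", "max"):
            raise ValueError("merge_rule must be one of mean/min/max")

    @property
    def kernel_mean_km(self) -> float:
        """Mean of the Weibull dispersal kernel, Φ·Γ(1 + 1/Ψ)."""
        return self.phi * math.gamma(1.0 + 1.0 / self.psi)

    def resolved_contact_distance(self) -> float:
        return self.contact_distance if self.contact_distance is not None else self.kernel_mean_km

    def dispersal_cap_km(self, quantile: float = 0.999) -> float:
        """Search-radius cap for dispersal, the 0.999 kernel quantile."""
        return self.phi * (-math.log(1.0 - quantile)) ** (1.0 / self.psi)


@dataclass
class InitSpec:
    """Seed species: one cell, an optional thermal optimum and body size."""

    cell: tuple[int, int] | None = None
    T_opt: float | None = None  # default: the cell's temperature at step 0
    B: float = 0.5


# ---------------------------------------------------------------------------
# model equations (pure, array-friendly)
# ---------------------------------------------------------------------------


def carrying_capacity(A_j, Kc: float = 30_000.0):
    """Site carrying capacity ``K = Kc * exp(-A_j)`` for aridity in [0, 1]."""
    A = np.asarray(A_j, dtype=float)
    if np.any((A < 0) | (A > 1)):
        raise ValueError("aridity index must lie in [0, 1]")
    return Kc * np.exp(-A)


def suitability_abundance(T_i, T_j, omega: float, K):
    """Abundance ``N = K * exp(-((T_i - T_j)/omega)**2)``.

    Equals K when the population is perfectly adapted (``T_i == T_j``); omega
    sets how sharply abundance declines with thermal mismatch.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    T_i = np.asarray(T_i, dtype=float)
    T_j = np.asarray(T_j, dtype=float)
    return np.asarray(K, dtype=float) * np.exp(-(((T_i - T_j) / omega) ** 2))


def reapportion(N_vector, K: float):
    """Rescale same-site abundances so the total never exceeds K.

    ``N̂_ij = N_ij * min(N_j, K) / N_j`` with ``N_j = sum(N_vector)``;
    proportions are preserved and the post-sum equals ``min(N_j, K)``.
    """
    N = np.asarray(N_vector, dtype=float)
    if np.any(N < 0):
        raise ValueError("abundances must be >= 0")
    total = N.sum()
    if total == 0:
        return N.copy()
    return N * (min(total, K) / total)


def extirpation_probability(N_hat, mu_t: float, mu_d: float):
    """Stochastic extirpation probability, ``1/(1 + exp(-mu_d*(mu_t - N̂)))``."""
    if mu_d <= 0:
        raise ValueError("mu_d must be > 0")
    N = np.asarray(N_hat, dtype=float)
    if np.any(N < 0):
        raise ValueError("N_hat must be >= 0")
    return 1.0 / (1.0 + np.exp(-mu_d * (mu_t - N)))


def _reflect01(x: np.ndarray) -> np.ndarray:
    r = np.mod(x, 2.0)
    return np.where(r > 1.0, 2.0 - r, r)


def evolve_traits(values, sigma: float, rng: np.random.Generator, boundary: str = "reflect"):
    """One step of bounded Brownian motion on [0, 1].

    Adds N(0, sigma) per population and maps back into the bounds by
    reflection (default) or truncation.
    """
    vals = np.asarray(values, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 or vals.size == 0:
        return vals.copy()
    moved = vals + rng.normal(0.0, sigma, size=vals.shape)
    if boundary == "reflect":
        return _reflect01(moved)
    return np.clip(moved, 0.0, 1.0)


def cluster_populations(positions_km: np.ndarray, contact_distance: float) -> np.ndarray:
    """Connected-component labels of sites linked within ``contact_distance``.

    ``positions_km`` is an (n, 2) array of planar site coordinates.  Labels are
    deterministic given the input order (component of site 0 is labelled 0 ...).
    """
    if contact_distance <= 0:
        raise ValueError("contact_distance must be > 0")
    pos = np.asarray(positions_km, dtype=float)
    n = pos.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    diff = pos[:, None, :] - pos[None, :, :]
    adj = (diff ** 2).sum(axis=-1) <= contact_distance ** 2
    _, labels = _components_bool(adj)
    return labels


def divergence_increment(
    model: str,
    Tbar_i: float,
    Tbar_k: float,
    Bbar_i: float,
    Bbar_k: float,
    lambda_: float,
    g0: float | None = None,
    rng: np.random.Generator | None = None,
):
    """Per-step divergence increment ``g`` for one pair of isolated clusters.

    Arguments are the mean standardized range temperature and body size of the
    two clusters.  Under M0 a constant ``g0`` is used (sampled once per
    simulation from U(0.01, 1) when not supplied).
    """
    if model == "M0":
        if g0 is not None:
            return float(g0)
        if rng is None:
            raise ValueError("M0 requires g0 or an rng to draw it")
        return float(rng.uniform(0.01, 1.0))
    if model == "M1":
        base = (Tbar_i + Tbar_k) / 2.0
    elif model == "M2":
        base = ((1.0 - Bbar_i) + (1.0 - Bbar_k)) / 2.0
    elif model == "M3":
        bt_i = ((1.0 - Bbar_i) + Tbar_i) / 2.0
        bt_k = ((1.0 - Bbar_k) + Tbar_k) / 2.0
        base = (bt_i + bt_k) / 2.0
    else:
        raise ValueError(f"unknown model {model!r}")
    return float(np.clip(base, 0.0, 1.0) ** lambda_)


def update_divergence(D: np.ndarray, contact: np.ndarray, increments: np.ndarray) -> np.ndarray:
    """Advance a symmetric divergence matrix by one step.

    Cluster pairs in contact coalesce by 1 per step (floored at 0); isolated
    pairs accrue their increment.  The diagonal stays zero.
    """
    D = np.asarray(D, dtype=float)
    out = np.where(contact, np.maximum(D - 1.0, 0.0), D + increments)
    np.fill_diagonal(out, 0.0)
    return out


def speciate_partition(D: np.ndarray, S: float) -> list[np.ndarray]:
    """Partition clusters into species: components of the graph ``D < S``.

    Returns index arrays, one per species, in deterministic order.
    """
    if S <= 0:
        raise ValueError("S must be > 0")
    n = D.shape[0]
    if n == 0:
        return []
    adj = D < S
    np.fill_diagonal(adj, True)
    n_comp, labels = _components_bool(adj)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesState:
    """Populations of one species: occupied sites, traits, clusters, divergence."""

    species_id: int
    sites: np.ndarray  # flat cell indices
    T_opt: np.ndarray
    B: np.ndarray
    N_hat: np.ndarray
    cluster: np.ndarray  # per-site local cluster index (into rows of D)
    D: np.ndarray  # symmetric divergence between clusters
    geo_component: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_sites(self) -> int:
        return int(self.sites.size)

    @property
    def n_clusters(self) -> int:
        return int(self.D.shape[0])

    def check(self) -> None:
        D = self.D
        assert D.shape[0] == D.shape[1]
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        assert np.all(D >= 0)
        assert self.cluster.max(initial=-1) < D.shape[0]


@dataclass
class PhylogenyLog:
    """Time-stamped speciation/extinction events of one simulation."""

    speciations: list[tuple[float, int, int]] = field(default_factory=list)
    extinctions: list[tuple[float, int]] = field(default_factory=list)
    root_species: int = 0
    root_time: float = 0.0
    final_time: float = 0.0

    def to_newick(self, extant_only: bool = False) -> str:
        """Export the logged phylogeny as a Newick string.

        Branch lengths are in time steps.  Speciation is budding: the parent
        lineage continues through each split.  With ``extant_only`` extinct
        tips are pruned (unifurcations suppressed, branch lengths summed).
        """
        children: dict[int, list[tuple[float, int]]] = {}
        for t, parent, child in self.speciations:
            children.setdefault(parent, []).append((t, child))
        for lst in children.values():
            lst.sort(key=lambda e: (e[0], e[1]))
        death = {sp: t for t, sp in self.extinctions}

        import sys

        limit = max(10_000, 10 * (len(self.speciations) + 10))
        old_limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old_limit, limit))

        def render(sp: int, t_from: float, events: list[tuple[float, int]]) -> str:
            if not events:
                end = death.get(sp, self.final_time)
                return f"s{sp}:{end - t_from:.8g}"
            (t1, c1), rest = events[0], events[1:]
            left = render(sp, t1, rest)
            right = render(c1, t1, children.get(c1, []))
            return f"({left},{right}):{t1 - t_from:.8g}"

        try:
            newick = (
                render(self.root_species, self.root_time, children.get(self.root_species, []))
                + ";"
            )
        finally:
            sys.setrecursionlimit(old_limit)
        if not extant_only:
            return newick
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        extant = [f"s{self.root_species}"] + [f"s{c}" for _, _, c in self.speciations]
        extant = [s for s in extant if int(s[1:]) not in death]
        if not extant:
            raise ValueError("no extant species to export")
        tree2 = tree.extract_tree_with_taxa_labels(extant, suppress_unifurcations=True)
        return tree2.as_string(schema="newick", suppress_rooting=True).strip()

    def extant_ids(self) -> list[int]:
        dead = {sp for _, sp in self.extinctions}
        ids = [self.root_species] + [c for _, _, c in self.speciations]
        return [i for i in ids if i not in dead]


@dataclass
class SimulationResult:
    """Outcome of one simulation run."""

    phylogeny: PhylogenyLog
    final_species: list[SpeciesState]
    richness_by_cell: np.ndarray
    per_species: "object"  # pandas.DataFrame
    params: ParameterSet
    completed: bool
    reason: str
    n_steps: int
    final_temperature01: np.ndarray
    latitude_deg: np.ndarray
    cell_size_km: float

    @property
    def richness(self) -> int:
        return len(self.final_species)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


class Simulation:
    """Stateful engine coupling a :class:`ParameterSet` to a landscape."""

    def __init__(self, params: ParameterSet, landscape: LandscapeSeries):
        params.validate()
        landscape.validate()
        self.params = params
        self.landscape = landscape
        self.n_rows, self.n_cols = landscape.shape
        self.n_cells = self.n_rows * self.n_cols
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        self.cell_row = rows
        self.cell_col = cols
        x = cols * landscape.cell_size_km
        y = rows * landscape.cell_size_km
        dx = np.abs(x[:, None] - x[None, :])
        if params.wrap:
            width = self.n_cols * landscape.cell_size_km
            dx = np.minimum(dx, width - dx)
        dy = y[:, None] - y[None, :]
        self.dist = np.sqrt(dx * dx + dy * dy).astype(np.float32)
        d_c = params.resolved_contact_distance()
        self.contact_adj = self.dist <= d_c
        cap = params.dispersal_cap_km()
        self.disp_adj = self.dist <= cap
        self.rng = np.random.default_rng(params.seed)
        self.g0 = None
        if params.model == "M0" and params.m0_draw == "per_simulation":
            self.g0 = params.g0 if params.g0 is not None else float(self.rng.uniform(0.01, 1.0))
        self.species: dict[int, SpeciesState] = {}
        self.log = PhylogenyLog()
        self._next_id = 1
        self.t = 0

    # -- initialization ----------------------------------------------------

    def initialize(self, init: InitSpec | None = None) -> None:
        init = init or InitSpec()
        temp0 = self.landscape.temperature01[0].ravel()
        hab0 = self.landscape.habitable[0].ravel()
        if init.cell is None:
            # habitable cell nearest the equator, central column
            lat = np.abs(self.landscape.latitude_deg[self.cell_row]).astype(float)
            lat[~hab0] = np.inf
            col_penalty = np.abs(self.cell_col - self.n_cols // 2) * 1e-3
            cell = int(np.argmin(lat + col_penalty))
        else:
            cell = int(init.cell[0] * self.n_cols + init.cell[1])
            if not hab0[cell]:
                raise ValueError("initial cell is not habitable")
        T_opt = float(temp0[cell]) if init.T_opt is None else float(init.T_opt)
        sp = SpeciesState(
            species_id=0,
            sites=np.array([cell], dtype=int),
            T_opt=np.array([T_opt]),
            B=np.array([init.B]),
            N_hat=np.array([0.0]),
            cluster=np.array([0], dtype=int),
            D=np.zeros((1, 1)),
            geo_component=np.array([0], dtype=int),
        )
        self.species = {0: sp}
        self.log = PhylogenyLog(root_species=0, root_time=0.0)

    # -- per-phase helpers -------------------------------------------------

    def _disperse_species(self, sp: SpeciesState, hab: np.ndarray) -> None:
        occ = sp.sites
        if occ.size == 0:
            return
        occupied = np.zeros(self.n_cells, dtype=bool)
        occupied[occ] = True
        reachable = self.disp_adj[occ[0]] if occ.size == 1 else self.disp_adj[occ].any(axis=0)
        cand = np.flatnonzero(reachable & hab & ~occupied)
        if cand.size == 0:
            return
        sub = self.dist[occ][:, cand]
        src = np.argmin(sub, axis=0)
        d0 = sub[src, np.arange(cand.size)]
        draws = self.rng.weibull(self.params.psi, size=cand.size) * self.params.phi
        hit = draws >= d0
        if not hit.any():
            return
        new_sites = cand[hit]
        src_idx = src[hit]
        sp.sites = np.concatenate([occ, new_sites])
        sp.T_opt = np.concatenate([sp.T_opt, sp.T_opt[src_idx]])
        sp.B = np.concatenate([sp.B, sp.B[src_idx]])
        sp.N_hat = np.concatenate([sp.N_hat, np.zeros(new_sites.size)])
        sp.cluster = np.concatenate([sp.cluster, sp.cluster[src_idx]])
        # founders stay in the source's cluster for the remainder of this
        # step; they become ordinary populations at the next clustering
        sp.founder_src = src_idx

    def _recluster_species(self, sp: SpeciesState) -> None:
        """Refine clusters by geographic components and rebuild divergence."""
        n = sp.n_sites
        if n == 0:
            return
        if n == 1:
            sp.cluster = np.zeros(1, dtype=int)
            sp.D = np.zeros((1, 1))
            sp.geo_component = np.zeros(1, dtype=int)
            sp.founder_src = None
            return
        founder_src = getattr(sp, "founder_src", None)
        if founder_src is not None and founder_src.size:
            # this step's founders adopt their source's geographic component
            n_old = n - founder_src.size
            if n_old == 1:
                comp = np.zeros(n, dtype=int)
                n_comp = 1
            else:
                adj = self.contact_adj[sp.sites[:n_old]][:, sp.sites[:n_old]]
                n_comp, comp_old = _components_bool(adj)
                comp = np.concatenate([comp_old, comp_old[founder_src]])
            sp.founder_src = None
        else:
            sp.founder_src = None
            adj = self.contact_adj[sp.sites][:, sp.sites]
            n_comp, comp = _components_bool(adj)
        if n_comp == 1 and sp.n_clusters == 1:
            sp.cluster = np.zeros(n, dtype=int)
            sp.geo_component = np.zeros(1, dtype=int)
            return
        keys = sp.cluster.astype(np.int64) * (comp.max() + 1) + comp
        uniq, new_label = np.unique(keys, return_inverse=True)
        old_of = (uniq // (comp.max() + 1)).astype(int)
        comp_of = (uniq % (comp.max() + 1)).astype(int)
        k = uniq.size
        D_new = sp.D[old_of][:, old_of].copy()
        same_parent = old_of[:, None] == old_of[None, :]
        D_new[same_parent] = 0.0  # fresh splits start diverging from zero
        np.fill_diagonal(D_new, 0.0)
        sp.cluster = new_label.astype(int)
        sp.D = D_new
        sp.geo_component = comp_of

    def _cluster_means(self, sp: SpeciesState, temp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = sp.n_clusters
        counts = np.bincount(sp.cluster, minlength=k).astype(float)
        Tbar = np.bincount(sp.cluster, weights=temp[sp.sites], minlength=k) / counts
        Bbar = np.bincount(sp.cluster, weights=sp.B, minlength=k) / counts
        return Tbar, Bbar

    def _pair_increments(self, sp: SpeciesState, temp: np.ndarray) -> np.ndarray:
        k = sp.n_clusters
        model = self.params.model
        lam = self.params.lambda_
        if model == "M0":
            if self.params.m0_draw == "per_simulation":
                g = np.full((k, k), self.g0)
            else:
                g = self.rng.uniform(0.01, 1.0, size=(k, k))
                g = np.triu(g, 1) + np.triu(g, 1).T
            return g
        Tbar, Bbar = self._cluster_means(sp, temp)
        if model == "M1":
            base = (Tbar[:, None] + Tbar[None, :]) / 2.0
        elif model == "M2":
            inv = 1.0 - Bbar
            base = (inv[:, None] + inv[None, :]) / 2.0
        else:  # M3
            bt = ((1.0 - Bbar) + Tbar) / 2.0
            base = (bt[:, None] + bt[None, :]) / 2.0
        return np.clip(base, 0.0, 1.0) ** lam

    def _update_divergence_species(self, sp: SpeciesState, temp: np.ndarray) -> None:
        k = sp.n_clusters
        if k <= 1:
            return
        contact = sp.geo_component[:, None] == sp.geo_component[None, :]
        g = self._pair_increments(sp, temp)
        sp.D = update_divergence(sp.D, contact, g)
        self._merge_coalesced(sp, contact)

    def _merge_coalesced(self, sp: SpeciesState, contact: np.ndarray) -> None:
        """Merge cluster pairs in contact whose divergence reached zero."""
        k = sp.n_clusters
        if k <= 1:
            return
        merged = contact & (sp.D <= 0.0)
        np.fill_diagonal(merged, True)
        n_grp, grp = _components_bool(merged)
        if n_grp == k:
            return
        rule = {"mean": np.mean, "min": np.min, "max": np.max}[self.params.merge_rule]
        D_new = np.zeros((n_grp, n_grp))
        members = [np.flatnonzero(grp == gi) for gi in range(n_grp)]
        for a in range(n_grp):
            for b in range(a + 1, n_grp):
                D_new[a, b] = D_new[b, a] = rule(sp.D[np.ix_(members[a], members[b])])
        sp.D = D_new
        sp.cluster = grp[sp.cluster]
        comp_of = np.zeros(n_grp, dtype=int)
        for gi in range(n_grp):
            comp_of[gi] = sp.geo_component[members[gi][0]]
        sp.geo_component = comp_of

    def _speciate_species(self, sp: SpeciesState) -> list[SpeciesState]:
        if sp.n_clusters <= 1:
            return [sp]
        comps = speciate_partition(sp.D, self.params.S)
        if len(comps) <= 1:
            return [sp]
        sizes = []
        counts = np.bincount(sp.cluster, minlength=sp.n_clusters)
        for comp in comps:
            sizes.append(int(counts[comp].sum()))
        order = sorted(range(len(comps)), key=lambda i: (-sizes[i], int(comps[i].min())))
        out: list[SpeciesState] = []
        for rank, ci in enumerate(order):
            comp = comps[ci]
            keep = np.isin(sp.cluster, comp)
            relabel = {int(c): j for j, c in enumerate(comp)}
            new_cluster = np.array([relabel[int(c)] for c in sp.cluster[keep]], dtype=int)
            if rank == 0:
                sid = sp.species_id
            else:
                sid = self._next_id
                self._next_id += 1
                self.log.speciations.append((float(self.t), sp.species_id, sid))
            out.append(
                SpeciesState(
                    species_id=sid,
                    sites=sp.sites[keep].copy(),
                    T_opt=sp.T_opt[keep].copy(),
                    B=sp.B[keep].copy(),
                    N_hat=sp.N_hat[keep].copy(),
                    cluster=new_cluster,
                    D=sp.D[np.ix_(comp, comp)].copy(),
                    geo_component=sp.geo_component[comp].copy(),
                )
            )
        return out

    def _abundance_and_extirpation(self, temp: np.ndarray, arid: np.ndarray, hab: np.ndarray) -> None:
        p = self.params
        ids = sorted(self.species)
        if not ids:
            return
        sp_index = []
        sites_all = []
        N_all = []
        K_cell = np.zeros(self.n_cells)
        hab_idx = np.flatnonzero(hab)
        K_cell[hab_idx] = carrying_capacity(arid[hab_idx], p.Kc)
        for i in ids:
            sp = self.species[i]
            on_hab = hab[sp.sites]
            N = np.zeros(sp.n_sites)
            if on_hab.any():
                s = sp.sites[on_hab]
                N[on_hab] = suitability_abundance(sp.T_opt[on_hab], temp[s], p.omega, K_cell[s])
            sp_index.append(i)
            sites_all.append(sp.sites)
            N_all.append(N)
        sites_cat = np.concatenate(sites_all)
        N_cat = np.concatenate(N_all)
        totals = np.bincount(sites_cat, weights=N_cat, minlength=self.n_cells)
        factor = np.ones(self.n_cells)
        over = totals > K_cell
        factor[over] = K_cell[over] / totals[over]
        N_hat_cat = N_cat * factor[sites_cat]
        probs = extirpation_probability(N_hat_cat, p.mu_t, p.mu_d)
        u = self.rng.uniform(size=N_hat_cat.size)
        survive_cat = (N_hat_cat > 0.0) & (u >= probs)
        pos = 0
        for i, sites in zip(sp_index, sites_all):
            n = sites.size
            sl = slice(pos, pos + n)
            pos += n
            sp = self.species[i]
            keep = survive_cat[sl]
            sp.N_hat = N_hat_cat[sl][keep]
            sp.sites = sp.sites[keep]
            sp.T_opt = sp.T_opt[keep]
            sp.B = sp.B[keep]
            sp.cluster = sp.cluster[keep]
            if keep.all():
                continue
            if sp.sites.size == 0:
                continue
            # drop clusters emptied by extirpation, keep divergence submatrix
            live = np.unique(sp.cluster)
            relabel = {int(c): j for j, c in enumerate(live)}
            sp.cluster = np.array([relabel[int(c)] for c in sp.cluster], dtype=int)
            sp.D = sp.D[np.ix_(live, live)]
            sp.geo_component = sp.geo_component[live] if sp.geo_component.size else sp.geo_component

    # -- the step ----------------------------------------------------------

    def step(self) -> None:
        """Advance the world by one landscape time step (fixed phase order)."""
        t = self.t
        land = self.landscape
        temp = land.temperature01[t].ravel()
        arid = land.aridity01[t].ravel()
        hab = land.habitable[t].ravel() & np.isfinite(temp) & np.isfinite(arid)
        p = self.params

        ids = sorted(self.species)
        # (1) trait evolution, (2) dispersal
        for i in ids:
            sp = self.species[i]
            sp.T_opt = evolve_traits(sp.T_opt, p.sigma_T, self.rng, p.boundary)
            sp.B = evolve_traits(sp.B, p.sigma_B, self.rng, p.boundary)
            self._disperse_species(sp, hab)
        # (3) clustering, (4) divergence, (5) speciation
        new_species: dict[int, SpeciesState] = {}
        for i in ids:
            sp = self.species[i]
            self._recluster_species(sp)
            self._update_divergence_species(sp, temp)
            for child in self._speciate_species(sp):
                new_species[child.species_id] = child
        self.species = new_species
        # (6) abundance, (7) extirpation
        self._abundance_and_extirpation(temp, arid, hab)
        # (8) extinction cleanup
        for i in sorted(self.species):
            if self.species[i].n_sites == 0:
                self.log.extinctions.append((float(t), i))
                del self.species[i]
        self.t += 1
        self.log.final_time = float(self.t)

    # -- full run ----------------------------------------------------------

    def run(
        self,
        init: InitSpec | None = None,
        richness_min: int = 20,
        richness_max: int = 6000,
    ) -> SimulationResult:
        self.initialize(init)
        completed = True
        reason = "complete"
        for _ in range(self.landscape.n_steps):
            self.step()
            if not self.species:
                completed, reason = False, "extinct"
                break
            if len(self.species) > richness_max:
                completed, reason = False, f"above maximum of {richness_max}"
                break
        richness = len(self.species)
        if completed and richness < richness_min:
            completed, reason = False, f"below minimum of {richness_min}"
        if completed and richness > richness_max:
            completed, reason = False, f"above maximum of {richness_max}"
        return self._result(completed, reason)

    def _result(self, completed: bool, reason: str) -> SimulationResult:
        import pandas as pd

        land = self.landscape
        t_last = min(self.t, land.n_steps) - 1
        temp = land.temperature01[max(t_last, 0)].ravel()
        lat_cell = land.latitude_deg[self.cell_row]
        richness = np.zeros(self.n_cells, dtype=int)
        rows = []
        for i in sorted(self.species):
            sp = self.species[i]
            richness[sp.sites] += 1
            rows.append(
                {
                    "species_id": i,
                    "range_size_cells": sp.n_sites,
                    "mean_range_temperature": float(np.nanmean(temp[sp.sites])),
                    "mean_body_size": float(sp.B.mean()),
                    "mean_abs_latitude": float(np.abs(lat_cell[sp.sites]).mean()),
                }
            )
        per_species = pd.DataFrame(
            rows,
            columns=[
                "species_id",
                "range_size_cells",
                "mean_range_temperature",
                "mean_body_size",
                "mean_abs_latitude",
            ],
        )
        return SimulationResult(
            phylogeny=self.log,
            final_species=[self.species[i] for i in sorted(self.species)],
            richness_by_cell=richness.reshape(self.n_rows, self.n_cols),
            per_species=per_species,
            params=self.params,
            completed=completed,
            reason=reason,
            n_steps=self.t,
            final_temperature01=land.temperature01[max(t_last, 0)].copy(),
            latitude_deg=land.latitude_deg.copy(),
            cell_size_km=land.cell_size_km,
        )


def run_simulation(
    params: ParameterSet,
    landscape: LandscapeSeries,
    init: InitSpec | None = None,
    richness_min: int = 20,
    richness_max: int = 6000,
) -> SimulationResult:
    """Run one simulation from a single ancestral species over the landscape.

    Fully reproducible from ``(params.seed, landscape)``.  The ``completed``
    flag is true iff the run finished with extant richness inside
    ``[richness_min, richness_max]``; global extinction yields an incomplete
    result (reason ``"extinct"``), not an exception.
    """
    sim = Simulation(params, landscape)
    return sim.run(init=init, richness_min=richness_min, richness_max=richness_max)
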