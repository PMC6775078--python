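"""Synthetic agent populations and contact structures.

The population is stored as flat numpy arrays (role, emotion, traits d/w/b,
spreader day counters) indexed by contiguous agent ids.  Contact structure is
either *spatial* — agents dropped uniformly in the unit square, neighbours =
agents within an interaction radius (a NetLogo-style interaction space) — or
*graph* — a small-world or Erdős–Rényi graph built with networkx.  Each day
every agent samples a bounded number of neighbours; the merged, deduplicated
pair list is the day's contact set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .model_core import (
    NEGATIVE_UPPER,
    POSITIVE_LOWER,
    Role,
    classify_emotions,
)

__all__ = [
    "BAND_RANGES",
    "InitSpec",
    "TopologyParams",
    "PopulationState",
    "ContactStructure",
    "generate_population",
    "build_contact_structure",
    "sample_daily_contacts",
    "default_spatial_radius",
]

#: Sampling ranges (lo, hi] / [lo, hi) used when an initial-emotion spec names
#: a band rather than an explicit range.
BAND_RANGES = {
    "negative": (0.0, NEGATIVE_UPPER),
    "immune": (NEGATIVE_UPPER, POSITIVE_LOWER),
    "positive": (POSITIVE_LOWER, 1.0),
}


@dataclass(frozen=True)
class InitSpec:
    """Initial-condition specification for :func:`generate_population`.

    Role fractions must leave room for at least one spreader; emotions are
    sampled uniformly from per-role ranges (band names accepted); traits are
    sampled uniformly from (lo, hi) ranges, so a degenerate range pins a
    trait to a constant for controlled experiments.
    """

    frac_s: float = 0.05
    frac_r: float = 0.0
    s_emotion: str | tuple[float, float] = "positive"
    r_emotion: str | tuple[float, float] = "positive"
    m_emotion: str | tuple[float, float] = "immune"
    d_range: tuple[float, float] = (1.0, 1.0)
    w_range: tuple[float, float] = (0.0, 1.0)
    b_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name, frac in (("frac_s", self.frac_s), ("frac_r", self.frac_r)):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {frac!r}")
        if self.frac_s + self.frac_r > 1.0 + 1e-12:
            raise ValueError("frac_s + frac_r must not exceed 1")
        if self.frac_s == 0.0:
            raise ValueError(
                "frac_s must be positive: at least one active spreader is "
                "required to initiate the contagion"
            )
        for name in ("s_emotion", "r_emotion", "m_emotion"):
            _resolve_range(getattr(self, name))  # validates
        for name in ("d_range", "w_range", "b_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi <= 1")


def _resolve_range(spec: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(spec, str):
        try:
            return BAND_RANGES[spec]
        except KeyError:
            raise ValueError(
                f"unknown emotion band {spec!r}; expected one of {sorted(BAND_RANGES)}"
            ) from None
    lo, hi = spec
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"emotion range must satisfy 0 <= lo <= hi <= 1, got {spec!r}")
    return float(lo), float(hi)


@dataclass
class PopulationState:
    """Mutable per-day population snapshot (arrays share an id index)."""

    roles: np.ndarray  # int8, values from Role
    emotions: np.ndarray  # float64 in [0, 1]
    d: np.ndarray
    w: np.ndarray
    b: np.ndarray
    days_active: np.ndarray  # int32; spreaders' elapsed active days
    t: int = 0

    @property
    def n(self) -> int:
        return self.roles.shape[0]

    def counts(self) -> tuple[int, int, int]:
        """(n_s, n_r, n_m) recounted from the role array."""
        c = np.bincount(self.roles, minlength=3)
        return int(c[Role.S]), int(c[Role.R]), int(c[Role.M])

    def band_counts(self) -> tuple[int, int, int]:
        """(n_negative, n_immune, n_positive) from the emotion array."""
        c = np.bincount(classify_emotions(self.emotions), minlength=3)
        return int(c[0]), int(c[1]), int(c[2])

    def copy(self) -> "PopulationState":
        return PopulationState(
            roles=self.roles.copy(),
            emotions=self.emotions.copy(),
            d=self.d.copy(),
            w=self.w.copy(),
            b=self.b.copy(),
            days_active=self.days_active.copy(),
            t=self.t,
        )


def _sample_band(rng: np.random.Generator, size: int, lo: float, hi: float) -> np.ndarray:
    # Draw in (lo, hi]: the immune and positive bands are open at the bottom,
    # and [0, 0.33) for the negative band (half-open either way is measure-
    # equivalent; the chosen direction keeps 0.33/0.66 out of the upper bands).
    if lo == 0.0:
        return rng.random(size) * hi
    return hi - rng.random(size) * (hi - lo)


def generate_population(
    n: int, init: InitSpec, rng: np.random.Generator
) -> PopulationState:
    """Sample a population of ``n`` agents from an :class:`InitSpec`.

    Deterministic for a fixed generator state: identical seeds give
    byte-identical populations.
    """
    if n < 2:
        raise ValueError("population size must be at least 2")
    n_s = int(round(init.frac_s * n))
    n_r = int(round(init.frac_r * n))
    n_s = max(n_s, 1)  # at least one active spreader must exist
    if n_s + n_r > n:
        raise ValueError("role fractions leave no room for the M compartment")
    roles = np.full(n, int(Role.M), dtype=np.int8)
    order = rng.permutation(n)
    roles[order[:n_s]] = int(Role.S)
    roles[order[n_s : n_s + n_r]] = int(Role.R)

    emotions = np.empty(n, dtype=np.float64)
    for role, spec in (
        (Role.S, init.s_emotion),
        (Role.R, init.r_emotion),
        (Role.M, init.m_emotion),
    ):
        mask = roles == int(role)
        lo, hi = _resolve_range(spec)
        emotions[mask] = _sample_band(rng, int(mask.sum()), lo, hi)

    def _traits(lohi: tuple[float, float]) -> np.ndarray:
        lo, hi = lohi
        return lo + rng.random(n) * (hi - lo)

    return PopulationState(
        roles=roles,
        emotions=emotions,
        d=_traits(init.d_range),
        w=_traits(init.w_range),
        b=_traits(init.b_range),
        days_active=np.zeros(n, dtype=np.int32),
        t=0,
    )


def default_spatial_radius(n: int, mean_degree: float = 8.0) -> float:
    """Interaction radius giving ~``mean_degree`` neighbours in the unit
    square (interior approximation n*pi*r^2 = mean_degree)."""
    return math.sqrt(mean_degree / (math.pi * n))


@dataclass(frozen=True)
class TopologyParams:
    """Contact-structure parameters.

    mode 'spatial': uniform positions in the unit square, neighbours within
    ``radius`` (default sized for mean degree ~8).  mode 'graph': a networkx
    generator — 'erdos_renyi' with edge probability ``p`` or 'watts_strogatz'
    with ring degree ``k`` and rewiring probability ``p``.
    """

    mode: str = "spatial"
    radius: float | None = None
    graph_kind: str = "watts_strogatz"
    k: int = 8
    p: float = 0.1
    contacts_per_agent_per_day: int = 8

    def __post_init__(self) -> None:
        if self.mode not in ("spatial", "graph"):
            raise ValueError(f"unknown topology mode {self.mode!r}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("spatial radius must be positive")
        if self.graph_kind not in ("erdos_renyi", "watts_strogatz"):
            raise ValueError(f"unknown graph kind {self.graph_kind!r}")
        if self.contacts_per_agent_per_day < 0:
            raise ValueError("contacts_per_agent_per_day must be non-negative")


@dataclass
class ContactStructure:
    """Frozen neighbourhood structure: flat CSR-style neighbour lists."""

    mode: str
    indptr: np.ndarray  # int64, len n+1
    indices: np.ndarray  # int64, concatenated sorted neighbour ids
    contacts_per_agent_per_day: int
    positions: np.ndarray | None = None  # (n, 2) in spatial mode
    params: TopologyParams | None = None

    @property
    def n(self) -> int:
        return self.indptr.shape[0] - 1

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def to_graph(self) -> nx.Graph:
        """Export as a networkx graph (e.g. for GraphML output)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i in range(self.n):
            for j in self.neighbors(i):
                if i < j:
                    g.add_edge(i, int(j))
        if self.positions is not None:
            for i in range(self.n):
                g.nodes[i]["x"] = float(self.positions[i, 0])
                g.nodes[i]["y"] = float(self.positions[i, 1])
        return g


def _adjacency_from_pairs(n: int, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if pairs.size == 0:
        return np.zeros(n + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst.astype(np.int64)


def build_contact_structure(
    n: int, params: TopologyParams, rng: np.random.Generator
) -> ContactStructure:
    """Build the (static) contact structure for ``n`` agents.

    Spatial mode places agents uniformly at random in the unit square and
    links every pair within ``radius``; graph mode delegates to networkx.
    Deterministic for a fixed generator state.
    """
    positions = None
    if params.mode == "spatial":
        radius = params.radius
        if radius is None:
            radius = default_spatial_radius(n)
        positions = rng.random((n, 2))
        tree = cKDTree(positions)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    else:
        seed = int(rng.integers(2**31 - 1))
        if params.graph_kind == "erdos_renyi":
            g = nx.gnp_random_graph(n, params.p, seed=seed)
        else:
            g = nx.watts_strogatz_graph(n, params.k, params.p, seed=seed)
        pairs = np.asarray(list(g.edges()), dtype=np.int64).reshape(-1, 2)
    indptr, indices = _adjacency_from_pairs(n, pairs)
    return ContactStructure(
        mode=params.mode,
        indptr=indptr,
        indices=indices,
        contacts_per_agent_per_day=params.contacts_per_agent_per_day,
        positions=positions,
        params=params,
    )


def export_graphml(structure: ContactStructure, path) -> None:
    """Write the contact structure as GraphML (positions as node attributes)."""
    nx.write_graphml(structure.to_graph(), path)


def snapshot_frame(state: PopulationState, structure: ContactStructure | None = None):
    """Population snapshot as a tidy table (id, role, emotion, x, y)."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "id": np.arange(state.n),
            "role": [Role(r).name for r in state.roles],
            "emotion": state.emotions,
        }
    )
    if structure is not None and structure.positions is not None:
        frame["x"] = structure.positions[:, 0]
        frame["y"] = structure.positions[:, 1]
    return frame


def sample_daily_contacts(
    structure: ContactStructure, rng: np.random.Generator
) -> np.ndarray:
    """Sample one day of contacts: each agent picks up to
    ``contacts_per_agent_per_day`` distinct neighbours; the union of picks,
    with duplicates merged, is returned as an (k, 2) array with
    ``pair[:, 0] < pair[:, 1]``.  Isolated agents contribute no pairs.
    """
    n = structure.n
    c = structure.contacts_per_agent_per_day
    if c == 0 or structure.indices.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    deg = structure.degrees()
    # random-key trick: per-agent uniform sampling without replacement is
    # 'sort each agent's neighbour list by an i.i.d. key, keep the first c'
    owner = np.repeat(np.arange(n, dtype=np.int64), deg)
    keys = rng.random(owner.size)
    order = np.lexsort((keys, owner))
    starts = structure.indptr[:-1]
    rank = np.arange(owner.size, dtype=np.int64) - np.repeat(starts, deg)
    mask = rank < c
    chosen = order[mask]
    owners = owner[order][mask]
    partners = structure.indices[chosen]
    left = np.minimum(owners, partners)
    right = np.maximum(owners, partners)
    pair_keys = np.unique(left * np.int64(n) + right)
    return np.column_stack([pair_keys // n, pair_keys % n]).astype(np.int64)
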