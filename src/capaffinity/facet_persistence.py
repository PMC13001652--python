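"""Persistent facet ideals over a Vietoris-Rips filtration of a 1-D point set.

As the filtration radius grows, each simplex may *become* a facet (birth:
it is maximal at that radius) and later *stop* being one (death: absorbed
into a larger clique).  Recording these intervals per simplex gives the
facet-persistence barcode; counting live bars per dimension gives the facet
curves ``F_i(t, t)``, and dividing by the radius gives the persistence
rates.  A small persistent-homology comparator is included so the two
multiscale summaries (component/loop counts vs facet counts) can be
contrasted on the same filtration.

Conventions: death is recorded at grid resolution (the smallest grid radius
at which facet status is lost); a bar alive at the last grid radius has
death ``+inf``; the persistence rate at radius 0 is defined as 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .complexes import (
    SimplicialComplex,
    Simplex,
    clique_complex,
    facet_counts,
    validate_positions,
)
from .errors import CapabilityError

__all__ = [
    "FiltrationGrid",
    "FacetBar",
    "FacetCurveSet",
    "HomologyBar",
    "facet_barcode",
    "facet_curves",
    "persistent_facet_number",
    "homology_barcode",
    "p0_h0_table",
]

#: point-count bound for the dense boundary-matrix homology path
HOMOLOGY_POINT_BOUND = 50


@dataclass(frozen=True)
class FiltrationGrid:
    """Strictly increasing grid of filtration radii.

    The default is the fixed uniform grid r = 0, 1, ..., 49 used by the
    nucleotide featurization; arbitrary grids are allowed for research use.
    """

    radii: tuple[float, ...] = tuple(float(r) for r in range(50))

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.radii)
        if len(r) == 0:
            raise ValueError("filtration grid must be non-empty")
        if any(x < 0 for x in r):
            raise ValueError("filtration radii must be non-negative")
        if any(a >= b for a, b in zip(r, r[1:])):
            raise ValueError("filtration radii must be strictly increasing")
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.radii)

    def __iter__(self):
        return iter(self.radii)

    @classmethod
    def default(cls) -> "FiltrationGrid":
        return cls()

    @classmethod
    def from_spec(cls, spec: str) -> "FiltrationGrid":
        """Parse ``"start:stop"`` (inclusive integer endpoints) into a grid."""
        lo, hi = (int(x) for x in spec.split(":"))
        return cls(tuple(float(r) for r in range(lo, hi + 1)))


@dataclass(frozen=True)
class FacetBar:
    """Interval of grid radii over which one simplex is a facet."""

    dimension: int
    simplex: Simplex
    birth: float
    death: float  # +inf if still a facet at the last grid radius

    def __post_init__(self) -> None:
        if not self.birth <= self.death:
            raise ValueError("facet bar birth must not exceed death")

    def alive_at(self, t: float) -> bool:
        return self.birth <= t < self.death

    def to_json_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "simplex": list(self.simplex.vertices),
            "birth": self.birth,
            "death": None if math.isinf(self.death) else self.death,
        }


@dataclass(frozen=True)
class FacetCurveSet:
    """Facet counts and persistence rates per dimension over a grid.

    ``counts[d, j]`` is the number of dimension-``d`` facets at grid radius
    ``grid.radii[j]``; ``rates[d, j] = counts[d, j] / radius`` for positive
    radii and 0 at radius 0.
    """

    grid: FiltrationGrid
    counts: np.ndarray  # (max_dim+1, len(grid)) ints
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        radii = np.asarray(self.grid.radii, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(radii > 0, counts / np.where(radii > 0, radii, 1.0), 0.0)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "rates", rates)


@dataclass(frozen=True)
class HomologyBar:
    """A persistent-homology interval (birth strictly before death)."""

    dimension: int
    birth: float
    death: float

    def __post_init__(self) -> None:
        if not self.birth < self.death:
            raise ValueError("homology bar birth must precede death")


def _facets_by_radius(
    positions: Iterable[int], grid: FiltrationGrid
) -> list[set[tuple[int, ...]]]:
    pts = validate_positions(positions)
    out = []
    for r in grid:
        fs = {s.vertices for s in clique_complex(pts, r).facets()}
        out.append(fs)
    return out


def facet_barcode(
    positions: Iterable[int],
    grid: FiltrationGrid | None = None,
    max_report_dim: int = 2,
) -> list[FacetBar]:
    """Facet-persistence barcode of a 1-D point set over a grid.

    For each simplex that is ever a facet along the grid: birth is the
    smallest grid radius at which it is a facet; death the smallest at
    which it no longer is (``+inf`` if it is a facet at the final radius).
    Only bars of dimension ``<= max_report_dim`` are reported.

    Raises if a simplex regains facet status after losing it — that would
    violate the contiguity guaranteed by the Rips filtration.
    """
    grid = grid or FiltrationGrid.default()
    per_radius = _facets_by_radius(positions, grid)
    born: dict[tuple[int, ...], float] = {}
    dead: dict[tuple[int, ...], tuple[float, float]] = {}
    for r, current in zip(grid, per_radius):
        for s in current:
            if s in dead:
                raise AssertionError(
                    f"facet {s} resurrected at radius {r}; "
                    "filtration contiguity violated"
                )
            if s not in born:
                born[s] = r
        for s in [s for s in born if s not in current]:
            dead[s] = (born.pop(s), r)
    bars = [
        FacetBar(len(s) - 1, Simplex(s), b, d) for s, (b, d) in dead.items()
    ] + [FacetBar(len(s) - 1, Simplex(s), b, math.inf) for s, b in born.items()]
    bars = [b for b in bars if b.dimension <= max_report_dim]
    bars.sort(key=lambda b: (b.dimension, b.birth, b.simplex.vertices))
    return bars


def facet_curves(
    positions: Iterable[int],
    grid: FiltrationGrid | None = None,
    max_report_dim: int = 2,
) -> FacetCurveSet:
    """Facet curves ``F_i(t, t)`` and persistence rates over a grid."""
    grid = grid or FiltrationGrid.default()
    per_radius = _facets_by_radius(positions, grid)
    counts = np.zeros((max_report_dim + 1, len(grid)), dtype=int)
    for j, fs in enumerate(per_radius):
        for s in fs:
            d = len(s) - 1
            if d <= max_report_dim:
                counts[d, j] += 1
    return FacetCurveSet(grid=grid, counts=counts)


def persistent_facet_number(
    positions: Iterable[int], t: float, t_prime: float, dim: int
) -> int:
    """``F_dim(t, t')``: dimension-``dim`` facets common to radii t and t'."""
    if t > t_prime:
        raise ValueError(f"need t <= t', got t={t}, t'={t_prime}")
    pts = validate_positions(positions)
    at_t = {
        s.vertices for s in clique_complex(pts, t).facets() if s.dimension == dim
    }
    at_tp = {
        s.vertices
        for s in clique_complex(pts, t_prime).facets()
        if s.dimension == dim
    }
    return len(at_t & at_tp)


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {x: x for x in items}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _h0_bars(pts: tuple[int, ...], r_max: float) -> list[HomologyBar]:
    """H0 barcode by union-find over edge insertions up to radius ``r_max``."""
    edges = sorted(
        (float(abs(a - b)), a, b)
        for a, b in itertools.combinations(pts, 2)
        if abs(a - b) <= r_max
    )
    uf = _UnionFind(pts)
    bars: list[HomologyBar] = []
    merges = 0
    for d, a, b in edges:
        if uf.union(a, b):
            bars.append(HomologyBar(0, 0.0, d))
            merges += 1
            if merges == len(pts) - 1:
                break
    n_components = len(pts) - merges
    bars.extend(HomologyBar(0, 0.0, math.inf) for _ in range(n_components))
    return bars


def _reduce_boundary(
    simplices: list[tuple[float, tuple[int, ...]]],
) -> list[tuple[int, float, float]]:
    """Standard mod-2 persistence reduction of a filtered complex.

    ``simplices``: (filtration value, vertex tuple) in filtration order
    (value, then dimension, then lexicographic).  Returns (dimension,
    birth, death) triples including infinite bars (death = inf).
    """
    index = {s: i for i, (_, s) in enumerate(simplices)}
    columns: list[set[int]] = []
    for _, s in simplices:
        if len(s) == 1:
            columns.append(set())
        else:
            columns.append(
                {index[s[:i] + s[i + 1 :]] for i in range(len(s))}
            )
    low_inverse: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j, col in enumerate(columns):
        while col:
            low = max(col)
            other = low_inverse.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col:
            low = max(col)
            low_inverse[low] = j
            pairs.append((low, j))
    paired = {i for p in pairs for i in p}
    bars = []
    for i, j in pairs:
        birth = simplices[i][0]
        death = simplices[j][0]
        if birth < death:
            bars.append((len(simplices[i][1]) - 1, birth, death))
    for i, (val, s) in enumerate(simplices):
        if i not in paired and not columns[i]:
            bars.append((len(s) - 1, val, math.inf))
    return bars


def homology_barcode(
    positions: Iterable[int],
    grid: FiltrationGrid | None = None,
    max_dim: int = 2,
) -> list[HomologyBar]:
    """Vietoris-Rips persistent homology of a 1-D point set, dims 0..max_dim.

    H0 comes from union-find over edge insertions; H1 and higher from
    mod-2 reduction of the boundary matrix of the clique complex
    restricted to simplices of dimension ``<= max_dim + 1``.  Filtration
    values are exact simplex diameters; simplices with diameter beyond the
    last grid radius are excluded.  Dense enumeration, so restricted to at
    most ``HOMOLOGY_POINT_BOUND`` points.
    """
    grid = grid or FiltrationGrid.default()
    pts = validate_positions(positions)
    if len(pts) > HOMOLOGY_POINT_BOUND:
        raise CapabilityError(
            f"homology_barcode supports at most {HOMOLOGY_POINT_BOUND} "
            f"points (got {len(pts)})"
        )
    if not pts:
        return []
    r_max = grid.radii[-1]
    bars = _h0_bars(pts, r_max)

    simplices: list[tuple[float, tuple[int, ...]]] = []
    for k in range(1, max_dim + 3):  # sizes 1 .. max_dim+2
        for combo in itertools.combinations(pts, k):
            diam = float(combo[-1] - combo[0])  # pts sorted: span = diameter
            if diam <= r_max:
                simplices.append((diam, combo))
    simplices.sort(key=lambda t: (t[0], len(t[1]), t[1]))
    reduced = _reduce_boundary(simplices)
    # dim 0 from the reduction must agree with union-find (internal check)
    assert sorted(
        (b.death for b in bars if math.isfinite(b.death))
    ) == sorted(d for dim, _, d in reduced if dim == 0 and math.isfinite(d))
    bars.extend(
        HomologyBar(dim, b, d)
        for dim, b, d in reduced
        if 1 <= dim <= max_dim
    )
    bars.sort(key=lambda b: (b.dimension, b.birth, b.death))
    return bars


def h0_count(complex: SimplicialComplex) -> int:
    """Number of connected components of a complex (isolated vertices count)."""
    g = nx.Graph()
    g.add_nodes_from(complex.vertex_set)
    g.add_edges_from(s.vertices for s in complex.faces(1))
    return nx.number_connected_components(g)


def p0_count(complex: SimplicialComplex) -> int:
    """Number of isolated vertices, i.e. 0-dimensional facets."""
    return facet_counts(complex, max_dim=0)[0]


def p0_h0_table(
    complex_sequence: Sequence[SimplicialComplex],
) -> list[tuple[int, int]]:
    """Per complex, the pair (H0, P0).

    H0 (component count) tracks how many pieces the space has; P0
    (isolated-vertex facet count) tracks how many vertices are not yet
    incident to any edge.  The two diverge as soon as an edge appears:
    adding one edge among n isolated vertices lowers H0 by one but P0 by
    two.
    """
    return [(h0_count(c), p0_count(c)) for c in complex_sequence]
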