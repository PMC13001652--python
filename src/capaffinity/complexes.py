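"""Abstract simplicial complexes and their Stanley-Reisner combinatorics.

A simplicial complex here is always finite and is stored by its *facets*
(inclusion-maximal faces); every other face is implied by downward closure.
Two constructions are provided:

* :func:`build_complex` — downward closure of an explicit face list
  (abstract complexes such as the boundary of a square pyramid);
* :func:`clique_complex` — the Vietoris-Rips complex of a one-dimensional
  point set at a given radius, i.e. the clique complex of the graph that
  connects points at distance ``<= radius`` (closed threshold).

On the algebra side, the facets index the minimal primes ``P_sigma`` of the
Stanley-Reisner ideal (each generated by the variables *outside* the facet),
and :func:`minimal_nonfaces` returns the square-free monomial generators of
the ideal itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .errors import CapabilityError, InvalidFaceError

__all__ = [
    "Simplex",
    "SimplicialComplex",
    "FacetIdeal",
    "build_complex",
    "clique_complex",
    "facets",
    "facet_counts",
    "minimal_nonfaces",
    "facet_ideal",
    "validate_positions",
]

#: vertex-count bound for the subset-enumeration path of minimal_nonfaces
MINIMAL_NONFACE_VERTEX_BOUND = 15


@dataclass(frozen=True, order=True)
class Simplex:
    """A face: a strictly increasing tuple of non-negative integer vertices."""

    vertices: tuple[int, ...]

    def __post_init__(self) -> None:
        v = tuple(int(x) for x in self.vertices)
        if len(v) == 0:
            raise InvalidFaceError("a simplex needs at least one vertex")
        if any(x < 0 for x in v):
            raise InvalidFaceError(f"negative vertex id in {v}")
        if any(a >= b for a, b in zip(v, v[1:])):
            if len(set(v)) != len(v):
                raise InvalidFaceError(f"duplicate vertices in face {v}")
            v = tuple(sorted(v))
        object.__setattr__(self, "vertices", v)

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1

    def __contains__(self, vertex: int) -> bool:
        return vertex in self.vertices

    def issubset(self, other: "Simplex") -> bool:
        return set(self.vertices) <= set(other.vertices)


class SimplicialComplex:
    """Finite abstract simplicial complex, stored by its maximal faces.

    Downward closure is implicit: ``has_face(s)`` holds iff ``s`` is a
    subset of some stored maximal face.  Isolated vertices are maximal
    faces of dimension 0.
    """

    def __init__(self, maximal_faces: Iterable[Iterable[int]]):
        candidates = {frozenset(int(v) for v in f) for f in maximal_faces}
        candidates.discard(frozenset())
        # prune non-maximal candidates
        maximal = {
            f
            for f in candidates
            if not any(f < g for g in candidates)
        }
        self._maximal: frozenset[frozenset[int]] = frozenset(maximal)
        self._vertices: frozenset[int] = frozenset(
            v for f in maximal for v in f
        )

    @property
    def vertex_set(self) -> frozenset[int]:
        return self._vertices

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    def facets(self) -> set[Simplex]:
        return {Simplex(tuple(sorted(f))) for f in self._maximal}

    def has_face(self, vertices: Iterable[int]) -> bool:
        s = frozenset(int(v) for v in vertices)
        if not s:
            return True  # the empty face belongs to every complex
        return any(s <= f for f in self._maximal)

    def dimension(self) -> int:
        return max((len(f) - 1 for f in self._maximal), default=-1)

    def faces(self, dim: int) -> set[Simplex]:
        """All faces of dimension exactly ``dim`` (enumerated from facets)."""
        out: set[tuple[int, ...]] = set()
        for f in self._maximal:
            if len(f) >= dim + 1:
                out.update(
                    itertools.combinations(sorted(f), dim + 1)
                )
        return {Simplex(t) for t in out}

    def edges(self) -> set[tuple[int, int]]:
        return {s.vertices for s in self.faces(1)}  # type: ignore[misc]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimplicialComplex):
            return NotImplemented
        return self._maximal == other._maximal

    def __hash__(self) -> int:
        return hash(self._maximal)

    def __repr__(self) -> str:
        return (
            f"SimplicialComplex({len(self._vertices)} vertices, "
            f"{len(self._maximal)} facets, dim {self.dimension()})"
        )


@dataclass(frozen=True)
class FacetIdeal:
    """The minimal prime ``P_sigma`` of a Stanley-Reisner ideal.

    Represented combinatorially: the facet ``sigma`` together with the
    vertex ids *not* in it, which index the variables generating the ideal.
    """

    facet: Simplex
    complement_variables: frozenset[int]


def build_complex(faces: Sequence[Iterable[int]]) -> SimplicialComplex:
    """Downward closure of an explicit face list.

    Isolated vertices may be declared as 1-tuples.  A tuple with repeated
    vertices raises :class:`InvalidFaceError`.
    """
    checked = []
    for f in faces:
        t = tuple(int(v) for v in f)
        if len(set(t)) != len(t):
            raise InvalidFaceError(f"duplicate vertices in face {t}")
        if any(v < 0 for v in t):
            raise InvalidFaceError(f"negative vertex id in face {t}")
        checked.append(t)
    return SimplicialComplex(checked)


def validate_positions(positions: Iterable[int]) -> tuple[int, ...]:
    """Validate a 1-D point set: distinct non-negative integers, returned sorted."""
    pts = sorted(int(p) for p in positions)
    if any(p < 0 for p in pts):
        raise InvalidFaceError(f"negative position in point set {pts}")
    if any(a == b for a, b in zip(pts, pts[1:])):
        raise InvalidFaceError(f"duplicate positions in point set {pts}")
    return tuple(pts)


def _maximal_windows(pts: tuple[int, ...], radius: float) -> list[tuple[int, ...]]:
    """Maximal cliques of the 1-D threshold graph, as index windows.

    On a line, a set of points is a clique iff its span (max - min) is
    ``<= radius``, so maximal cliques are maximal contiguous windows of
    span ``<= radius``.
    """
    n = len(pts)
    out = []
    j = 0
    for i in range(n):
        if j < i:
            j = i
        while j + 1 < n and pts[j + 1] - pts[i] <= radius:
            j += 1
        # left-maximality: cannot extend the window to include pts[i-1]
        if i == 0 or pts[j] - pts[i - 1] > radius:
            out.append(pts[i : j + 1])
    return out


def _bron_kerbosch_cliques(
    pts: tuple[int, ...], radius: float
) -> list[tuple[int, ...]]:
    g = nx.Graph()
    g.add_nodes_from(pts)
    g.add_edges_from(
        (a, b)
        for a, b in itertools.combinations(pts, 2)
        if abs(a - b) <= radius
    )
    return [tuple(sorted(c)) for c in nx.find_cliques(g)]


def clique_complex(
    positions: Iterable[int],
    radius: float,
    method: str = "window",
) -> SimplicialComplex:
    """Vietoris-Rips (clique) complex of a 1-D point set at scale ``radius``.

    A simplex is a face iff all pairwise distances are ``<= radius``
    (closed threshold).  At radius 0 the complex is the discrete vertex set.

    ``method`` selects the maximal-clique engine: ``"window"`` (1-D fast
    path, maximal windows of span <= radius) or ``"bron-kerbosch"``
    (general maximal-clique enumeration on the threshold graph).  The two
    agree on every input; the fast path is the default.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    pts = validate_positions(positions)
    if not pts:
        return SimplicialComplex([])
    if method == "window":
        cliques = _maximal_windows(pts, radius)
    elif method == "bron-kerbosch":
        cliques = _bron_kerbosch_cliques(pts, radius)
    else:
        raise ValueError(f"unknown clique method {method!r}")
    return SimplicialComplex(cliques)


def facets(complex: SimplicialComplex) -> set[Simplex]:
    """The facets (inclusion-maximal faces) of a complex.

    Isolated vertices are 0-dimensional facets.
    """
    return complex.facets()


def facet_counts(
    complex: SimplicialComplex, max_dim: int = 2
) -> tuple[int, ...]:
    """Facet count vector (P_0, ..., P_max_dim), graded by exact dimension.

    Facets of dimension > ``max_dim`` exist in the complex but are not
    reported.
    """
    if max_dim < 0:
        raise ValueError("max_dim must be >= 0")
    counts = [0] * (max_dim + 1)
    for s in complex.facets():
        if s.dimension <= max_dim:
            counts[s.dimension] += 1
    return tuple(counts)


def minimal_nonfaces(complex: SimplicialComplex) -> set[Simplex]:
    """Inclusion-minimal non-faces: the Stanley-Reisner ideal generators.

    A vertex subset is a non-face iff it lies in no facet; it is a minimal
    non-face iff additionally every proper subset is a face.  Enumerates
    subsets, so restricted to complexes with at most
    ``MINIMAL_NONFACE_VERTEX_BOUND`` vertices.
    """
    verts = sorted(complex.vertex_set)
    if len(verts) > MINIMAL_NONFACE_VERTEX_BOUND:
        raise CapabilityError(
            f"minimal_nonfaces enumerates subsets and supports at most "
            f"{MINIMAL_NONFACE_VERTEX_BOUND} vertices (got {len(verts)})"
        )
    out: set[Simplex] = set()
    for size in range(1, len(verts) + 1):
        for combo in itertools.combinations(verts, size):
            if complex.has_face(combo):
                continue
            sub_ok = all(
                complex.has_face(combo[:i] + combo[i + 1 :])
                for i in range(size)
            )
            if sub_ok:
                out.add(Simplex(combo))
    return out


def facet_ideal(facet: Simplex, vertex_set: Iterable[int]) -> FacetIdeal:
    """``P_sigma``: the prime generated by the variables outside ``facet``."""
    vs = frozenset(int(v) for v in vertex_set)
    fv = set(facet.vertices)
    if not fv <= vs:
        raise ValueError(
            f"facet {facet.vertices} not contained in vertex set {sorted(vs)}"
        )
    return FacetIdeal(facet=facet, complement_variables=frozenset(vs - fv))
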