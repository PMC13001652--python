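"""Shared fixtures and the independent brute-force facet oracle.

The oracle enumerates every vertex subset, checks the clique condition by
explicit all-pairs distance comparison, and keeps the maximal ones — no
code shared with the package's facet engine.
"""

from itertools import combinations

import pytest

PRIMER_C_POSITIONS = (2, 9, 10, 11, 12, 13, 16, 18, 21)

PYRAMID_TRIANGLES = [(0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 4, 1)]
PYRAMID_EDGES = [
    (1, 2), (2, 3), (3, 4), (4, 1), (0, 1), (0, 2), (0, 3), (0, 4),
]


def brute_force_facets(points, radius):
    """All maximal cliques of the distance-threshold graph, by enumeration.

    A subset is a face iff every pairwise distance is <= radius; it is a
    facet iff no single extra point keeps it a face.
    """
    pts = sorted(points)

    def is_face(sub):
        return all(abs(a - b) <= radius for a, b in combinations(sub, 2))

    facets = set()
    for k in range(1, len(pts) + 1):
        for sub in combinations(pts, k):
            if not is_face(sub):
                continue
            extendable = any(
                is_face(tuple(sorted(sub + (v,))))
                for v in pts
                if v not in sub
            )
            if not extendable:
                facets.add(sub)
    return facets


def brute_force_counts(points, radius, max_dim=2):
    counts = [0] * (max_dim + 1)
    for f in brute_force_facets(points, radius):
        if len(f) - 1 <= max_dim:
            counts[len(f) - 1] += 1
    return tuple(counts)


def brute_force_bars(points, radii, max_dim=2):
    """Facet bars derived purely from per-radius brute-force facet sets."""
    born, dead = {}, {}
    for r in radii:
        current = brute_force_facets(points, r)
        for s in current:
            if s not in born and s not in dead:
                born[s] = r
        for s in list(born):
            if s not in current:
                dead[s] = (born.pop(s), r)
    bars = {(s, b, d) for s, (b, d) in dead.items()}
    bars |= {(s, b, float("inf")) for s, b in born.items()}
    return {(s, b, d) for (s, b, d) in bars if len(s) - 1 <= max_dim}


@pytest.fixture
def primer_positions():
    return PRIMER_C_POSITIONS


@pytest.fixture
def pyramid():
    from capaffinity import build_complex

    return build_complex(PYRAMID_TRIANGLES)


@pytest.fixture
def pyramid_skeleton():
    from capaffinity import build_complex

    return build_complex(PYRAMID_EDGES)


@pytest.fixture
def pyramid_vertices():
    from capaffinity import build_complex

    return build_complex([(v,) for v in range(5)])
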