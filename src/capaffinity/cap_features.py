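"""1-mer algebra featurization of nucleic-acid sequences.

Each nucleotide letter defines a *channel*: the set of 1-based sequence
positions at which it occurs, viewed as a 1-D point set.  T and U share a
single channel (the alphabet is {A, C, G, T/U}), so DNA and RNA map into
the same feature space.  Per channel, the facet curves in dimensions 0-2
over the fixed 50-radius grid (r = 0..49) give 150 count features, and the
persistence rates give 150 more — 300 per channel, 1200 per sequence.

Block layout of a 300-vector (radius-major within each block):

    [counts d0 r0..r49 | counts d1 | counts d2 | rates d0 | rates d1 | rates d2]

The full 1200-vector concatenates channels in the fixed order A, C, G, T/U.
All features are translation-invariant: only pairwise position distances
within a channel matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CurationError
from .facet_persistence import FiltrationGrid, facet_curves

__all__ = [
    "ALPHABET",
    "NucleicSequence",
    "channel_positions",
    "channel_features",
    "cap_nucleic_vector",
    "feature_names",
]

#: channel order of the CAP vector
ALPHABET: tuple[str, ...] = ("A", "C", "G", "T/U")

_VALID_LETTERS = set("ACGTU")


@dataclass(frozen=True)
class NucleicSequence:
    """A DNA or RNA sequence over {A, C, G, T, U}.

    The strict type invariants (DNA has no U, RNA has no T, no mixed T/U)
    are enforced by dataset curation; the featurizer itself is total over
    the merged T/U channel, so a sequence that slipped past curation still
    maps to a well-defined vector.
    """

    symbols: str
    type_tag: str = "DNA"

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        if not s:
            raise CurationError("empty nucleic-acid sequence")
        bad = sorted(set(s) - _VALID_LETTERS)
        if bad:
            raise CurationError(
                f"non-standard bases {bad} in nucleic sequence; "
                "curate (or strip) before featurization"
            )
        if self.type_tag not in ("DNA", "RNA"):
            raise CurationError(f"unknown nucleic-acid type {self.type_tag!r}")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return len(self.symbols)


def channel_positions(seq: NucleicSequence, symbol: str) -> tuple[int, ...]:
    """1-based positions at which ``symbol`` occurs; T/U matches either letter.

    May be empty if the letter does not occur.
    """
    if symbol not in ALPHABET:
        raise ValueError(
            f"symbol must be one of {ALPHABET}, got {symbol!r}"
        )
    letters = {"T", "U"} if symbol == "T/U" else {symbol}
    return tuple(
        i for i, s in enumerate(seq.symbols, start=1) if s in letters
    )


def channel_features(
    positions: tuple[int, ...], grid: FiltrationGrid | None = None
) -> np.ndarray:
    """300-dim feature block for one channel: facet counts then rates.

    An empty channel yields all zeros; a singleton channel has dimension-0
    count 1 at every radius (a lone point is never absorbed).
    """
    grid = grid or FiltrationGrid.default()
    n = len(grid)
    if not positions:
        return np.zeros(6 * n)
    curves = facet_curves(positions, grid, max_report_dim=2)
    return np.concatenate(
        [curves.counts.reshape(-1).astype(float), curves.rates.reshape(-1)]
    )


def cap_nucleic_vector(
    seq: NucleicSequence, grid: FiltrationGrid | None = None
) -> np.ndarray:
    """The CAP vector of a sequence at k=1: channels A, C, G, T/U concatenated.

    Length 4 x 6 x len(grid) — 1200 on the default 50-radius grid.
    """
    grid = grid or FiltrationGrid.default()
    return np.concatenate(
        [channel_features(channel_positions(seq, a), grid) for a in ALPHABET]
    )


def feature_names(grid: FiltrationGrid | None = None) -> list[str]:
    """Human-readable names for the CAP vector entries, in layout order."""
    grid = grid or FiltrationGrid.default()
    names = []
    for a in ALPHABET:
        tag = a.replace("/", "")
        for family in ("count", "rate"):
            for d in range(3):
                for r in grid:
                    names.append(f"{tag}_{family}_d{d}_r{r:g}")
    return names
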