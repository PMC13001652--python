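"""Protein sequence embeddings behind a pluggable provider contract.

The affinity model consumes a fixed-length 2560-dim vector per protein.
Production use runs the ESM2-t36 (3B) protein language model and
mean-pools the final-layer residue representations; hermetic tests use a
deterministic mock provider that derives a pseudo-random vector from a
portable digest of the residue string.  Both satisfy the same contract, so
the downstream pipeline is identical either way.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import CapabilityError, ValidationError

__all__ = [
    "EMBED_DIM",
    "ProteinSequence",
    "sanitize_protein",
    "mean_pool",
    "EmbeddingProvider",
    "MockEmbeddingProvider",
    "mock_provider",
    "esm2_provider",
]

logger = logging.getLogger(__name__)

#: width of the embedding vector (ESM2-t36 hidden size)
EMBED_DIM = 2560

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def sanitize_protein(residues: str) -> str:
    """Uppercase and map any non-standard residue letter to X."""
    s = residues.upper()
    if not s:
        raise ValidationError("empty protein sequence")
    return "".join(c if c in _STANDARD_AA else "X" for c in s)


class ProteinSequence(str):
    """A validated amino-acid sequence (20 standard letters plus X)."""

    def __new__(cls, residues: str) -> "ProteinSequence":
        s = residues.upper()
        if not s:
            raise ValidationError("empty protein sequence")
        bad = sorted(set(s) - _STANDARD_AA - {"X"})
        if bad:
            raise ValidationError(
                f"non-standard residues {bad}; use sanitize_protein() first"
            )
        return super().__new__(cls, s)


def mean_pool(residue_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the residue axis of an L x 2560 matrix."""
    m = np.asarray(residue_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValidationError(
            f"expected a non-empty L x {EMBED_DIM} matrix, got shape {m.shape}"
        )
    if m.shape[1] != EMBED_DIM:
        raise ValidationError(
            f"expected embedding width {EMBED_DIM}, got {m.shape[1]}"
        )
    return m.mean(axis=0)


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: deterministic per-sequence embeddings of a fixed dimension."""

    provider_tag: str

    def embed(self, sequence: str) -> np.ndarray: ...

    def dimension(self) -> int: ...


class _CachedProvider:
    """Shared cache layer: one embedding computation per sequence per run."""

    provider_tag = "base"

    def __init__(self) -> None:
        self._cache: dict[str, np.ndarray] = {}

    def _compute(self, sequence: str) -> np.ndarray:
        raise NotImplementedError

    def embed(self, sequence: str) -> np.ndarray:
        seq = str(ProteinSequence(sanitize_protein(sequence)))
        hit = self._cache.get(seq)
        if hit is None:
            hit = self._compute(seq)
            hit.setflags(write=False)
            self._cache[seq] = hit
        return hit

    def dimension(self) -> int:
        return EMBED_DIM


class MockEmbeddingProvider(_CachedProvider):
    """Deterministic pseudo-random embeddings for hermetic testing.

    The vector for a sequence is drawn from ``numpy.random.default_rng``
    seeded by (salt, first 8 bytes of the SHA-256 of the residue string),
    so it is platform-stable, identical across calls, and almost surely
    distinct for distinct sequences.
    """

    def __init__(self, seed_salt: int = 0) -> None:
        super().__init__()
        self.seed_salt = int(seed_salt)
        self.provider_tag = f"mock-sha256-v1/salt={self.seed_salt}"

    def _compute(self, sequence: str) -> np.ndarray:
        digest = hashlib.sha256(sequence.encode("ascii")).digest()
        word = int.from_bytes(digest[:8], "little")
        rng = np.random.default_rng([self.seed_salt, word])
        return rng.standard_normal(EMBED_DIM)


def mock_provider(seed_salt: int = 0) -> MockEmbeddingProvider:
    """Factory for the deterministic mock provider."""
    return MockEmbeddingProvider(seed_salt)


class Esm2Provider(_CachedProvider):
    """ESM2-t36 (3B) backend: final-layer representations, mean-pooled.

    Requires the optional ``esm`` extra (fair-esm + torch) and locally
    available pretrained weights.  Sequences longer than ``max_length``
    residues are truncated with a logged warning.
    """

    max_length = 1022  # ESM2 positional-embedding budget minus BOS/EOS

    def __init__(self) -> None:
        super().__init__()
        try:
            import esm  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional backend
            raise CapabilityError(
                "the ESM2 backend needs the optional 'esm' extra: "
                "pip install 'capaffinity[esm]' (fair-esm + torch), "
                "plus locally cached esm2_t36_3B_UR50D weights"
            ) from exc
        self._torch = torch
        model, alphabet = esm.pretrained.esm2_t36_3B_UR50D()
        self._model = model.eval()
        self._batch_converter = alphabet.get_batch_converter()
        self.provider_tag = "esm2_t36_3B_UR50D/layer36-meanpool"

    def _compute(self, sequence: str) -> np.ndarray:  # pragma: no cover
        if len(sequence) > self.max_length:
            logger.warning(
                "truncating %d-residue protein to %d for ESM2",
                len(sequence),
                self.max_length,
            )
            warnings.warn(
                f"protein truncated from {len(sequence)} to "
                f"{self.max_length} residues for embedding",
                stacklevel=2,
            )
            sequence = sequence[: self.max_length]
        _, _, tokens = self._batch_converter([("query", sequence)])
        with self._torch.no_grad():
            out = self._model(tokens, repr_layers=[36])
        # drop BOS/EOS token positions before pooling
        reps = out["representations"][36][0, 1 : len(sequence) + 1].numpy()
        return mean_pool(reps)


def esm2_provider() -> Esm2Provider:
    """Factory for the ESM2 backend; raises a capability error if absent."""
    return Esm2Provider()
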