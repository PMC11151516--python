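"""Sentence-embedding backends and cosine similarity.

Two backends implement one contract (fixed output dimension, batch order
preserved, deterministic where declared):

* the *reference* backend wraps the frozen pre-trained sentence encoder
  ``all-mpnet-base-v2`` (output dimension 768). It is used strictly as
  shipped — no fine-tuning path is exposed anywhere in this package;
* the *test* backend is a deterministic lexical embedder (seeded feature
  hashing of lowercase token counts, L2-normalized). It needs no downloads,
  gives similarity 1 for token-identical sentences, and near-0 similarity
  for token-disjoint ones (bounded by hash collisions), which is exactly the
  behaviour the keyword-gated classifier tests rely on.

Backends carry a small in-memory cache keyed by text so that threshold
sweeps re-use one similarity computation.
"""

from __future__ import annotations

import hashlib
import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class BackendUnavailableError(RuntimeError):
    """The requested embedding backend cannot be constructed."""


class EmbeddingBackend(Protocol):
    """Contract every backend satisfies."""

    name: str
    dimension: int
    deterministic: bool

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray: ...


def embed_batch(backend: EmbeddingBackend, texts: Sequence[str]) -> np.ndarray:
    """Embed a batch of non-empty strings; returns an ``(n, D)`` array."""
    if any(not t for t in texts):
        raise ValueError("texts must be non-empty strings")
    out = backend.embed_batch(texts)
    assert out.shape == (len(texts), backend.dimension)
    return out


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity ``dot(u, v) / (|u| |v|)``, clamped to [-1, 1].

    A zero vector is a degenerate input: the similarity is defined as 0 and
    a warning is emitted.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        warnings.warn("cosine similarity of a zero vector is defined as 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass
class HashedBagBackend:
    """Deterministic lexical embedder: seeded hashed token counts, L2-normalized.

    Tokenization lowercases and keeps alphanumeric runs. Each token is
    hashed (blake2b keyed by the seed) into one of ``dimension`` buckets
    with a pseudo-random sign, so distinct token sets land on nearly
    orthogonal directions for large dimensions.
    """

    dimension: int = 512
    seed: int = 0
    name: str = field(init=False)
    deterministic: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        if self.dimension < 8:
            raise ValueError("dimension must be >= 8")
        self.name = f"test-hashed-bow-d{self.dimension}-s{self.seed}"
        self._cache: dict[str, np.ndarray] = {}

    def _bucket(self, token: str) -> tuple[int, float]:
        h = hashlib.blake2b(token.encode("utf-8"),
                            key=str(self.seed).encode("utf-8"),
                            digest_size=8).digest()
        value = int.from_bytes(h, "big")
        sign = 1.0 if value & 1 else -1.0
        return (value >> 1) % self.dimension, sign

    def _embed_one(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in _TOKEN_RE.findall(text.lower()):
            idx, sign = self._bucket(token)
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:
        out = np.empty((len(texts), self.dimension))
        for i, text in enumerate(texts):
            cached = self._cache.get(text)
            if cached is None:
                cached = self._cache[text] = self._embed_one(text)
            out[i] = cached
        return out


def make_test_backend(dimension: int = 512, seed: int = 0) -> HashedBagBackend:
    """Build the deterministic download-free test backend."""
    return HashedBagBackend(dimension=dimension, seed=seed)


class ReferenceBackend:
    """The frozen pre-trained sentence encoder (``all-mpnet-base-v2``, D=768).

    The underlying model is used exactly as published; this wrapper exposes
    no training or fine-tuning hooks.
    """

    name = "reference-all-mpnet-base-v2"
    dimension = 768
    deterministic = True

    def __init__(self) -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - depends on env
            raise BackendUnavailableError(
                "the reference encoder all-mpnet-base-v2 requires the optional "
                "sentence-transformers dependency; fall back to the "
                "deterministic test backend via make_test_backend() or "
                "make_backend('test')"
            ) from exc
        self._model = SentenceTransformer("all-mpnet-base-v2")  # pragma: no cover
        self._cache: dict[str, np.ndarray] = {}  # pragma: no cover

    def embed_batch(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        missing = [t for t in texts if t not in self._cache]
        if missing:
            vecs = self._model.encode(missing, convert_to_numpy=True,
                                      show_progress_bar=False)
            for t, v in zip(missing, vecs):
                self._cache[t] = np.asarray(v, dtype=float)
        return np.stack([self._cache[t] for t in texts])


def make_backend(name: str = "test", dimension: int = 512,
                 seed: int = 0) -> EmbeddingBackend:
    """Backend factory: ``"reference"`` or ``"test"``.

    When the reference encoder is unavailable the error names the test
    backend as the fallback; selection stays explicit — there is no silent
    substitution.
    """
    if name == "test":
        return make_test_backend(dimension=dimension, seed=seed)
    if name == "reference":
        return ReferenceBackend()
    raise ValueError(f"unknown backend {name!r}; expected 'reference' or 'test'")
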