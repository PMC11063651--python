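"""Embedding providers: per-residue vector representations of proteins.

Two providers are available.  The synthetic provider is a deterministic,
context-sensitive embedder built for testing and benchmarking: every
amino-acid letter gets a fixed pseudo-random base vector, and each residue's
embedding is its base vector plus a geometrically decaying mixture of its
neighbours' base vectors.  With a context window of zero it degenerates to a
context-free embedding (every occurrence of a letter gets the same vector);
with a positive window the same letter in different contexts gets different
vectors — the property contextual protein language models provide.

The model provider is a thin adapter around transformer protein language
models (ProtT5, ESM2, ...) and requires ``torch`` and ``transformers`` to be
installed; embeddings are cached on disk because they are expensive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RESIDUE_ALPHABET, EmbeddingCache, ProteinSequence


@dataclass(frozen=True)
class EmbeddingMatrix:
    """An m x n matrix of per-residue embedding vectors (row i-1 embeds the
    i-th residue; positions are 1-based in all public APIs)."""

    values: np.ndarray
    model_name: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError(f"embedding matrix must be 2-D, got shape {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0.0):
            bad = int(np.argmin(norms)) + 1
            raise ValueError(
                f"embedding row {bad} is the zero vector; cosine similarity "
                "is undefined for it"
            )

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> np.ndarray:
        """Embedding vector of the i-th residue (1-based)."""
        if not 1 <= i <= self.n_residues:
            raise IndexError(f"position {i} out of range 1..{self.n_residues}")
        return self.values[i - 1]


class SyntheticEmbedder:
    """Deterministic context-sensitive embedder.

    Parameters
    ----------
    dimension : int
        Embedding dimension (>= 2).
    context_window : int
        Number of neighbour positions on each side mixed into a residue's
        vector.  0 gives a context-free embedding.
    seed : int
        Seeds the per-letter base vectors; identical seeds give bit-identical
        embeddings across runs.
    decay : float
        Geometric decay of neighbour influence: a neighbour at offset k
        contributes with weight ``decay ** |k|``.
    """

    def __init__(self, dimension: int = 32, context_window: int = 2,
                 seed: int = 0, decay: float = 0.5):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        if context_window < 0:
            raise ValueError("context_window must be >= 0")
        self.dimension = int(dimension)
        self.context_window = int(context_window)
        self.seed = int(seed)
        self.decay = float(decay)
        self.name = (
            f"synthetic(dim={dimension},window={context_window},seed={seed})"
        )
        rng = np.random.default_rng(seed)
        # one fixed base vector per letter, ambiguity codes included,
        # so the shape contract holds for any valid sequence
        self._base = {
            aa: rng.standard_normal(dimension) for aa in RESIDUE_ALPHABET
        }

    def base_vector(self, letter: str) -> np.ndarray:
        return self._base[letter].copy()

    def embed(self, seq: ProteinSequence) -> EmbeddingMatrix:
        m = len(seq)
        out = np.zeros((m, self.dimension))
        for idx in range(m):
            vec = self._base[seq.residues[idx]].copy()
            for off in range(1, self.context_window + 1):
                w = self.decay ** off
                if idx - off >= 0:
                    vec += w * self._base[seq.residues[idx - off]]
                if idx + off < m:
                    vec += w * self._base[seq.residues[idx + off]]
            out[idx] = vec
        return EmbeddingMatrix(out, self.name)


def synthetic_embed(seq: ProteinSequence, dimension: int = 32,
                    context_window: int = 2, seed: int = 0,
                    decay: float = 0.5) -> EmbeddingMatrix:
    """Functional wrapper around :class:`SyntheticEmbedder`."""
    return SyntheticEmbedder(dimension, context_window, seed, decay).embed(seq)


class ModelUnavailableError(RuntimeError):
    pass


# residue remapping commonly used for ProtT5-family vocabularies
_MODEL_RESIDUE_MAP = {"U": "C", "O": "K", "B": "X", "Z": "X"}


class TransformerEmbedder:
    """Adapter for transformer protein language models (ProtT5, ESM2, ...).

    Requires ``torch`` and ``transformers``.  Special/boundary tokens added
    by the model are stripped so the returned matrix has exactly one row per
    residue.  Results are cached in an :class:`EmbeddingCache` when one is
    supplied.
    """

    def __init__(self, model_name: str, cache: EmbeddingCache | None = None,
                 max_length: int = 4000,
                 residue_map: dict | None = None):
        self.model_name = model_name
        self.name = model_name
        self.cache = cache
        self.max_length = max_length
        self.residue_map = dict(_MODEL_RESIDUE_MAP if residue_map is None
                                else residue_map)
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise ModelUnavailableError(
                f"model {model_name!r} needs the 'torch' and 'transformers' "
                "packages, which are not installed. Install them, or use the "
                "synthetic provider (escore:synthetic) which has no external "
                "dependencies."
            ) from exc
        self._torch = torch
        self._transformers = transformers
        self._model = None
        self._tokenizer = None

    def _load(self):
        if self._model is None:
            tr = self._transformers
            self._tokenizer = tr.AutoTokenizer.from_pretrained(self.model_name)
            self._model = tr.AutoModel.from_pretrained(self.model_name)
            self._model.eval()

    def embed(self, seq: ProteinSequence) -> EmbeddingMatrix:
        if len(seq) > self.max_length:
            raise ValueError(
                f"sequence {seq.id!r} has length {len(seq)} exceeding the "
                f"model limit {self.max_length}; refusing to truncate"
            )
        if self.cache is not None:
            hit = self.cache.get(self.model_name, seq.id, seq.residues)
            if hit is not None:
                return EmbeddingMatrix(hit, self.model_name)
        self._load()
        mapped = "".join(self.residue_map.get(c, c) for c in seq.residues)
        tokens = self._tokenizer(" ".join(mapped), return_tensors="pt",
                                 add_special_tokens=True)
        with self._torch.no_grad():
            out = self._model(**tokens).last_hidden_state[0].cpu().numpy()
        values = out[: len(seq)]  # strip trailing special tokens
        if values.shape[0] != len(seq):
            raise RuntimeError(
                f"model returned {values.shape[0]} residue rows for a "
                f"sequence of length {len(seq)}"
            )
        if self.cache is not None:
            self.cache.put(self.model_name, seq.id, seq.residues, values)
        return EmbeddingMatrix(values, self.model_name)


def model_embed(seq: ProteinSequence, model_name: str,
                cache: EmbeddingCache | None = None) -> EmbeddingMatrix:
    """Embed a sequence with a named transformer model (cached)."""
    return TransformerEmbedder(model_name, cache=cache).embed(seq)
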