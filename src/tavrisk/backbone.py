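"""Volumetric feature extraction: pluggable backbone + chunked compression.

A backbone embeds a preprocessed 64x64x64 ROI into a D-dimensional vector
(3D ResNet-50: D=2048, Swin UNETR: D=768, the tiny reference backbone below:
configurable, default 64).  The embedding is then compressed to d_f=16
features by splitting its dimensions into d_f contiguous chunks and taking
one inner product per chunk — exactly D extra parameters, no bias, instead of
the D*d_f a dense layer would add.

The reference backbone is a deliberately small, fully linear map
(average-pool to 4x4x4 patches -> flatten -> linear to D) so that end-to-end
joint training with the probabilistic parameters is testable on a laptop; it
implements the same contract a large pretrained network would.  Externally
computed embeddings/features can instead be supplied through the feature-CSV
cache (see :mod:`tavrisk.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np

ROI_SHAPE = (64, 64, 64)

#: CT intensity window applied before the backbone, in Hounsfield units.
HU_WINDOW = (-200.0, 800.0)


def preprocess_intensities(vol: np.ndarray,
                           window: tuple = HU_WINDOW) -> np.ndarray:
    """Clip to the HU window and min-max scale to [0, 1]."""
    lo, hi = window
    return (np.clip(np.asarray(vol, dtype=float), lo, hi) - lo) / (hi - lo)


@runtime_checkable
class BackboneContract(Protocol):
    """Anything that deterministically embeds a 64^3 volume into R^D."""

    embed_dim: int

    def embed(self, roi: np.ndarray) -> np.ndarray:
        """Map a preprocessed (64, 64, 64) volume to a (D,) embedding."""
        ...


@dataclass
class ChunkCompressor:
    """Per-chunk linear compression of a D-dim embedding to d_f values.

    ``weights`` has exactly D entries, partitioned into d_f contiguous chunks;
    output k is the inner product of chunk k's weights with the matching
    embedding slice.  No bias term, so the added parameter count is D.
    """

    weights: np.ndarray
    d_f: int = 16

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a flat vector of length D")
        if self.weights.size % self.d_f != 0:
            raise ValueError(
                f"embedding size {self.weights.size} is not divisible by "
                f"d_f={self.d_f}")

    @property
    def embed_dim(self) -> int:
        return self.weights.size

    @property
    def chunk_size(self) -> int:
        return self.weights.size // self.d_f

    @property
    def n_parameters(self) -> int:
        return self.weights.size

    @classmethod
    def init(cls, embed_dim: int, d_f: int = 16, scale: float = 0.01,
             seed: int = 0) -> "ChunkCompressor":
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0.0, scale, embed_dim), d_f)


def chunk_compress(embedding: np.ndarray, compressor: ChunkCompressor) -> np.ndarray:
    """Compress a (D,) or (n, D) embedding to (d_f,) / (n, d_f) features."""
    emb = np.asarray(embedding)
    if emb.shape[-1] != compressor.embed_dim:
        raise ValueError(
            f"embedding size {emb.shape[-1]} does not match compressor "
            f"({compressor.embed_dim})")
    cs = compressor.chunk_size
    w = compressor.weights.reshape(compressor.d_f, cs)
    e = emb.reshape(emb.shape[:-1] + (compressor.d_f, cs))
    return np.einsum("...kc,kc->...k", e, w)


class TinyBackbone:
    """Reference backbone: average-pool to 4x4x4 patches -> linear map to D.

    Linear end to end, which keeps its vector-Jacobian product exact and
    hand-computable; used for joint training demonstrations and as the
    contract's reference implementation.
    """

    POOLED = 4  # pooled grid is POOLED^3 = 64 values

    def __init__(self, embed_dim: int = 64, seed: int = 0, scale: float = 0.05):
        rng = np.random.default_rng(seed)
        self.embed_dim = int(embed_dim)
        self.W = rng.normal(0.0, scale, (self.embed_dim, self.POOLED**3))

    # -- contract ----------------------------------------------------------

    def embed(self, roi: np.ndarray) -> np.ndarray:
        return self.W @ self.pool(roi)

    # -- internals / training support --------------------------------------

    @classmethod
    def pool(cls, roi: np.ndarray) -> np.ndarray:
        roi = np.asarray(roi, dtype=float)
        if roi.shape != ROI_SHAPE:
            raise ValueError(f"expected ROI of shape {ROI_SHAPE}, got {roi.shape}")
        p = cls.POOLED
        b = ROI_SHAPE[0] // p
        pooled = roi.reshape(p, b, p, b, p, b).mean(axis=(1, 3, 5))
        return pooled.reshape(-1)

    def embed_batch(self, pooled: np.ndarray) -> np.ndarray:
        """(n, 64) pooled patches -> (n, D) embeddings."""
        return pooled @ self.W.T

    def vjp(self, pooled: np.ndarray, grad_embed: np.ndarray) -> np.ndarray:
        """d(loss)/dW given pooled inputs (n, 64) and d(loss)/d(embed) (n, D)."""
        return grad_embed.T @ pooled

    def get_params(self) -> np.ndarray:
        return self.W.ravel().copy()

    def set_params(self, flat: np.ndarray) -> None:
        self.W = np.asarray(flat, dtype=float).reshape(self.W.shape)

    @property
    def n_parameters(self) -> int:
        return self.W.size


def extract_features(roi: np.ndarray, backbone: BackboneContract,
                     compressor: ChunkCompressor,
                     preprocess: bool = True) -> np.ndarray:
    """f(I; omega): embed a 64^3 ROI and chunk-compress to d_f features."""
    roi = np.asarray(roi, dtype=float)
    if roi.shape != ROI_SHAPE:
        raise ValueError(f"expected ROI of shape {ROI_SHAPE}, got {roi.shape}")
    if preprocess:
        roi = preprocess_intensities(roi)
    emb = backbone.embed(roi)
    if emb.shape != (backbone.embed_dim,):
        raise ValueError("backbone returned an embedding of unexpected size")
    return chunk_compress(emb, compressor)
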