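"""Query-adaptive convolution matching.

Instead of comparing pooled embeddings, each gallery image's feature map is
turned into a bank of L2-normalized local kernels (one p x p patch per
spatial position, the "class memory").  Matching a query means correlating
every kernel against the query's normalized feature map — with p = 1 this is
exactly a cosine-similarity matrix between local descriptors — keeping the
best response per kernel, and feeding the S local scores through a small
BN-FC-BN head that converts them into one scalar similarity.

The head initializes to uniform positive weights and identity
normalizations, so an untrained head scores by the mean local match; it can
be fitted on match/non-match pairs with :func:`train_head`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor

__all__ = [
    "extract_local_kernels",
    "response",
    "global_mean_pool_scores",
    "SimilarityHead",
    "train_head",
    "ClassMemory",
    "build_class_memory",
    "similarity",
    "similarity_matrix",
    "match",
]


def _patches(fm: np.ndarray, p: int) -> np.ndarray:
    """All p x p patches (zero-padded at borders): (C, H, W) -> (S, C, p, p)."""
    C, H, W = fm.shape
    half = p // 2
    padded = np.pad(fm, ((0, 0), (half, half), (half, half)))
    windows = np.lib.stride_tricks.sliding_window_view(padded, (p, p), axis=(1, 2))
    # windows: (C, H, W, p, p) -> (H*W, C, p, p)
    return np.ascontiguousarray(windows.transpose(1, 2, 0, 3, 4).reshape(H * W, C, p, p))


def _normalize_rows(flat: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(flat, axis=1, keepdims=True)
    out = np.zeros_like(flat)
    np.divide(flat, norms, out=out, where=norms > 0)
    return out


def extract_local_kernels(fm: np.ndarray, patch_size: int = 1) -> np.ndarray:
    """Kernel bank (S, C, p, p) of unit-norm local patches; S = H * W.

    All-zero patches stay zero rather than becoming NaN.
    """
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError("expected a single feature map of shape (C, H, W)")
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    bank = _patches(fm, patch_size)
    S = bank.shape[0]
    flat = _normalize_rows(bank.reshape(S, -1))
    return flat.reshape(bank.shape)


def response(query_fm: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Best normalized correlation of each bank kernel over query positions.

    Returns S local scores in [-1, 1].
    """
    query_fm = np.asarray(query_fm, dtype=float)
    bank = np.asarray(bank, dtype=float)
    S, C, p, _ = bank.shape
    if query_fm.ndim != 3 or query_fm.shape[0] != C:
        raise ValueError(
            f"channel mismatch: bank has {C} channels, query has "
            f"{query_fm.shape[0] if query_fm.ndim == 3 else '?'}"
        )
    q = _normalize_rows(_patches(query_fm, p).reshape(-1, C * p * p))
    scores = bank.reshape(S, -1) @ q.T  # (S, Sq)
    return scores.max(axis=1)


def global_mean_pool_scores(scores: np.ndarray, groups: int = 1) -> np.ndarray:
    """Mean of local scores over contiguous pooling groups (default: one)."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("empty score vector")
    if groups < 1 or scores.size % groups:
        raise ValueError(f"cannot pool {scores.size} scores into {groups} groups")
    return scores.reshape(groups, -1).mean(axis=1)


class SimilarityHead(nn.Module):
    """BN -> FC(S -> 1) -> BN over the S local matching scores."""

    def __init__(self, s_dim: int):
        super().__init__()
        self.s_dim = s_dim
        self.bn_in = nn.BatchNorm1d(s_dim)
        self.fc = nn.Linear(s_dim, 1)
        self.bn_out = nn.BatchNorm1d(1)
        self.fc.weight.data[:] = 1.0 / s_dim  # start as the mean score

    def forward(self, scores) -> Tensor:
        scores = nn.as_tensor(scores)
        if scores.ndim != 2 or scores.shape[1] != self.s_dim:
            raise ValueError(
                f"expected score vectors of length {self.s_dim}, got {scores.shape}"
            )
        return self.bn_out(self.fc(self.bn_in(scores)))[:, 0]


def train_head(
    head: SimilarityHead,
    score_vectors: np.ndarray,
    is_match: np.ndarray,
    epochs: int = 100,
    lr: float = 0.05,
) -> list[float]:
    """Fit the head on labelled score vectors with logistic loss; returns the
    per-epoch loss trace."""
    x = Tensor(np.asarray(score_vectors, dtype=np.float32))
    y = np.asarray(is_match, dtype=np.float32)
    opt = nn.Adam(head.parameters(), lr=lr)
    head.train()
    losses = []
    for _ in range(epochs):
        opt.zero_grad()
        logits = head(x)
        prob = logits.sigmoid()
        eps = 1e-7
        loss = -(
            Tensor(y) * (prob + eps).log() + Tensor(1 - y) * (1 - prob + eps).log()
        ).mean()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    head.eval()
    return losses


@dataclass
class ClassMemory:
    patch_size: int
    entries: list[tuple[int, np.ndarray]]  # (gallery_id, kernel bank)

    def __len__(self):
        return len(self.entries)


def build_class_memory(feature_maps, gallery_ids, patch_size: int = 1) -> ClassMemory:
    entries = [
        (int(gid), extract_local_kernels(fm, patch_size))
        for gid, fm in zip(gallery_ids, feature_maps)
    ]
    return ClassMemory(patch_size=patch_size, entries=entries)


def similarity(query_fm, bank, head: SimilarityHead) -> float:
    """Scalar similarity of one query map to one memory entry (higher = closer)."""
    scores = response(query_fm, bank)
    with nn.no_grad():
        return float(head(scores[None, :]).data[0])


def similarity_matrix(query_fms, memory: ClassMemory, head: SimilarityHead) -> np.ndarray:
    if len(memory) == 0:
        raise ValueError("empty gallery memory")
    # batch all (query, gallery) score vectors through the head in one pass
    all_scores = np.stack(
        [
            np.stack([response(fm, bank) for _, bank in memory.entries])
            for fm in query_fms
        ]
    )  # (Q, G, S)
    Q, G, S = all_scores.shape
    with nn.no_grad():
        sims = head(all_scores.reshape(Q * G, S)).data
    return sims.reshape(Q, G)


def match(query_fms, memory: ClassMemory, head: SimilarityHead) -> np.ndarray:
    """Ranked gallery indices per query (descending similarity, ties by index)."""
    sims = similarity_matrix(query_fms, memory, head)
    return np.argsort(-sims, axis=1, kind="stable")
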