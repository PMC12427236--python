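"""Training and retrieval evaluation.

Training follows the metric-learning recipe standard in re-identification:
P x K identity-balanced batches, batch-hard triplet loss
max(0, d_ap - d_an + margin) on Euclidean embedding distances, Adam with
first-moment decay 0.9 and learning rate 1e-4, and the usual augmentations
(pad-and-crop, horizontal flip, random erasing).

Evaluation ranks the gallery per query — by embedding distance, or by
negative QAConv similarity when the matcher is enabled — and reports CMC
Rank-1/Rank-5 and mAP.  Ties are broken by gallery index (stable sort) so
results are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn, qaconv
from .backbone import CowReIDBackbone, build_backbone
from .config import ModelConfig, TrainConfig
from .nn import functional as F
from .nn.tensor import Tensor
from .synthetic import ImageRecord

__all__ = [
    "EvalResult",
    "augment",
    "triplet_loss",
    "batch_hard_triplet_loss",
    "normalization_stats",
    "records_to_batch",
    "train",
    "compute_cmc",
    "compute_map",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class EvalResult:
    rank1: float
    rank5: float
    mAP: float
    n_queries: int

    def to_dict(self):
        return {
            "rank1": self.rank1,
            "rank5": self.rank5,
            "mAP": self.mAP,
            "n_queries": self.n_queries,
        }


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(pixels: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Pad-and-random-crop, horizontal flip (p=0.5), random erasing (p=0.5).

    Output always has the input's height and width.
    """
    out = pixels
    H, W = out.shape[:2]
    if "random_crop" in cfg.augmentations and cfg.padding > 0:
        p = cfg.padding
        padded = np.pad(out, ((p, p), (p, p), (0, 0)), mode="edge")
        oy = int(rng.integers(0, 2 * p + 1))
        ox = int(rng.integers(0, 2 * p + 1))
        out = padded[oy : oy + H, ox : ox + W]
    if "horizontal_flip" in cfg.augmentations and rng.random() < 0.5:
        out = out[:, ::-1]
    if "random_erasing" in cfg.augmentations and rng.random() < 0.5:
        area = float(rng.uniform(0.02, 0.2)) * H * W
        aspect = float(rng.uniform(0.3, 3.3))
        eh = min(H, max(1, int(round(np.sqrt(area * aspect)))))
        ew = min(W, max(1, int(round(np.sqrt(area / aspect)))))
        ey = int(rng.integers(0, H - eh + 1))
        ex = int(rng.integers(0, W - ew + 1))
        out = out.copy()
        out[ey : ey + eh, ex : ex + ew] = int(out.mean())
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def triplet_loss(d_ap, d_an, margin: float):
    """Hinge loss max(0, d_ap - d_an + margin) on precomputed distances."""
    return np.maximum(0.0, np.asarray(d_ap) - np.asarray(d_an) + margin)


def batch_hard_triplet_loss(embeddings: Tensor, labels: np.ndarray, margin: float) -> Tensor:
    """Batch-hard mining: per anchor, farthest positive and nearest negative."""
    labels = np.asarray(labels)
    B = embeddings.shape[0]
    dist = (F.pairwise_sqdist(embeddings, embeddings) + 1e-12).sqrt()
    same = labels[:, None] == labels[None, :]
    d = dist.data
    pos_masked = np.where(same, d, -np.inf)
    np.fill_diagonal(pos_masked, -np.inf)
    neg_masked = np.where(same, np.inf, d)
    idx = np.arange(B)
    pos_idx = pos_masked.argmax(axis=1)
    neg_idx = neg_masked.argmin(axis=1)
    # anchors with no positive (singleton identity) fall back to themselves
    has_pos = np.isfinite(pos_masked.max(axis=1))
    pos_idx = np.where(has_pos, pos_idx, idx)
    d_ap = dist[idx, pos_idx]
    d_an = dist[idx, neg_idx]
    return (d_ap - d_an + margin).clamp_min(0.0).mean()


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def normalization_stats(records: list[ImageRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std of the (training) pixel values, on the 0-1 scale."""
    acc = np.zeros(3)
    acc2 = np.zeros(3)
    n = 0
    for rec in records:
        x = rec.pixels.reshape(-1, 3) / 255.0
        acc += x.sum(axis=0)
        acc2 += (x**2).sum(axis=0)
        n += x.shape[0]
    mean = acc / n
    std = np.sqrt(np.maximum(acc2 / n - mean**2, 1e-8))
    return mean.astype(np.float32), std.astype(np.float32)


def records_to_batch(pixel_arrays, mean, std) -> Tensor:
    """Stack H x W x 3 uint8 images into a normalized (B, 3, H, W) tensor."""
    x = np.stack([np.asarray(p, dtype=np.float32) / 255.0 for p in pixel_arrays])
    x = (x - mean[None, None, None, :]) / std[None, None, None, :]
    return Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _pk_batches(train_records, cfg: TrainConfig, rng: np.random.Generator):
    """Identity-balanced P x K batches over one epoch."""
    by_id: dict[int, list[int]] = {}
    for i, rec in enumerate(train_records):
        by_id.setdefault(rec.identity_id, []).append(i)
    ids = sorted(by_id)
    if len(ids) < 2:
        raise ValueError("P x K sampling needs at least 2 training identities")
    K = cfg.num_instances
    P = max(2, min(cfg.batch_size // K, len(ids)))
    order = rng.permutation(len(ids)).tolist()
    # wrap so every identity appears at least once per epoch
    n_batches = -(-len(ids) // P)
    if len(order) < n_batches * P:
        order += order[: n_batches * P - len(order)]
    batches = []
    for start in range(0, n_batches * P, P):
        chosen = [ids[j] for j in order[start : start + P]]
        batch = []
        for cid in chosen:
            pool = by_id[cid]
            replace = len(pool) < K
            batch.extend(rng.choice(pool, size=K, replace=replace).tolist())
        batches.append(batch)
    return batches


def train(
    model: CowReIDBackbone,
    records: list[ImageRecord],
    cfg: TrainConfig,
    progress=None,
) -> dict:
    """Train on the 'train' split; returns {'loss_log': [...], 'stats': (mean, std)}.

    Deterministic for a fixed ``cfg.seed`` and fixed model initialization.
    """
    train_records = [r for r in records if r.split == "train"]
    if not train_records:
        raise ValueError("no training records")
    rng = np.random.default_rng(cfg.seed)
    mean, std = normalization_stats(train_records)
    if cfg.optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, betas=(cfg.momentum, 0.999))
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(model.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    from .nn.layers import _BatchNorm

    def to_train_mode():
        model.train()
        if cfg.freeze_bn:
            for _, mod in model.named_modules():
                if isinstance(mod, _BatchNorm):
                    mod.train(False)

    loss_log = []
    to_train_mode()
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for batch in _pk_batches(train_records, cfg, rng):
            pix = [augment(train_records[i].pixels, cfg, rng) for i in batch]
            labels = np.array([train_records[i].identity_id for i in batch])
            x = records_to_batch(pix, mean, std)
            opt.zero_grad()
            emb = model(x)
            loss = batch_hard_triplet_loss(emb, labels, cfg.margin)
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        loss_log.append(float(np.mean(epoch_losses)))
        if progress is not None:
            progress(epoch, loss_log[-1])
    model.eval()
    return {"loss_log": loss_log, "stats": (mean, std)}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_eval_inputs(distmat, q_ids, g_ids):
    distmat = np.asarray(distmat, dtype=float)
    q_ids = np.asarray(q_ids)
    g_ids = np.asarray(g_ids)
    if distmat.ndim != 2 or distmat.shape != (len(q_ids), len(g_ids)):
        raise ValueError("distmat shape must be (n_queries, n_gallery)")
    if len(q_ids) == 0 or len(g_ids) == 0:
        raise ValueError("empty query or gallery")
    missing = set(q_ids.tolist()) - set(g_ids.tolist())
    if missing:
        raise ValueError(f"query identities absent from gallery: {sorted(missing)}")
    return distmat, q_ids, g_ids


def compute_cmc(distmat, q_ids, g_ids, ranks=(1, 5)) -> dict[int, float]:
    """Cumulative matching: fraction of queries with a correct identity in
    the top-k (gallery sorted by ascending distance, ties by index)."""
    distmat, q_ids, g_ids = _check_eval_inputs(distmat, q_ids, g_ids)
    order = np.argsort(distmat, axis=1, kind="stable")
    hits = g_ids[order] == q_ids[:, None]
    first_hit = hits.argmax(axis=1)  # every query has >= 1 hit (checked above)
    return {k: float((first_hit < k).mean()) for k in ranks}


def compute_map(distmat, q_ids, g_ids) -> float:
    """mAP with AP = mean over relevant items of precision at their rank."""
    distmat, q_ids, g_ids = _check_eval_inputs(distmat, q_ids, g_ids)
    order = np.argsort(distmat, axis=1, kind="stable")
    hits = (g_ids[order] == q_ids[:, None]).astype(float)
    cum_hits = hits.cumsum(axis=1)
    ranks = np.arange(1, len(g_ids) + 1)
    precision = cum_hits / ranks
    ap = (precision * hits).sum(axis=1) / hits.sum(axis=1)
    return float(ap.mean())


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _embed(model, records, mean, std, batch_size=16) -> np.ndarray:
    out = []
    with nn.no_grad():
        for start in range(0, len(records), batch_size):
            chunk = records[start : start + batch_size]
            x = records_to_batch([r.pixels for r in chunk], mean, std)
            out.append(model(x).data)
    return np.concatenate(out)


def _stage_maps(model, records, mean, std, stage: int, batch_size=16) -> list[np.ndarray]:
    maps = []
    key = f"stage{stage}"
    with nn.no_grad():
        for start in range(0, len(records), batch_size):
            chunk = records[start : start + batch_size]
            x = records_to_batch([r.pixels for r in chunk], mean, std)
            fm = model.forward_features(x)[key].data
            maps.extend(fm[i] for i in range(fm.shape[0]))
    return maps


def evaluate(
    model: CowReIDBackbone,
    gallery: list[ImageRecord],
    query: list[ImageRecord],
    stats: tuple[np.ndarray, np.ndarray],
    head: qaconv.SimilarityHead | None = None,
) -> EvalResult:
    """Rank the gallery per query and report Rank-1/Rank-5/mAP.

    Uses negative QAConv similarity on the configured feature stage when the
    matcher is enabled in the model config, Euclidean embedding distance
    otherwise.
    """
    if not gallery or not query:
        raise ValueError("empty query or gallery")
    mean, std = stats
    model.eval()
    g_ids = np.array([r.identity_id for r in gallery])
    q_ids = np.array([r.identity_id for r in query])
    qa = model.config.qaconv
    if model.config.use_qaconv and qa.enabled:
        stage = qa.feature_stage
        g_maps = _stage_maps(model, gallery, mean, std, stage)
        q_maps = _stage_maps(model, query, mean, std, stage)
        memory = qaconv.build_class_memory(g_maps, g_ids, qa.patch_size)
        if head is None:
            s_dim = g_maps[0].shape[1] * g_maps[0].shape[2]
            head = qaconv.SimilarityHead(s_dim)
            head.eval()
        distmat = -qaconv.similarity_matrix(q_maps, memory, head)
    else:
        g_emb = _embed(model, gallery, mean, std)
        q_emb = _embed(model, query, mean, std)
        distmat = np.sqrt(
            np.maximum(F.pairwise_sqdist(Tensor(q_emb), Tensor(g_emb)).data, 0.0)
        )
    cmc = compute_cmc(distmat, q_ids, g_ids, ranks=(1, 5))
    return EvalResult(
        rank1=cmc[1],
        rank5=cmc[5],
        mAP=compute_map(distmat, q_ids, g_ids),
        n_queries=len(query),
    )


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: CowReIDBackbone, train_cfg: TrainConfig, stats, rng=None):
    """Weights + config + normalization statistics in one .npz archive."""
    from .config import _as_plain

    mean, std = stats
    payload = dict(model.state_dict())
    payload["__model_config__"] = np.frombuffer(
        json.dumps(_as_plain(model.config)).encode(), dtype=np.uint8
    )
    payload["__train_config__"] = np.frombuffer(
        json.dumps(_as_plain(train_cfg)).encode(), dtype=np.uint8
    )
    payload["__norm_mean__"] = mean
    payload["__norm_std__"] = std
    if rng is not None:
        payload["__rng_state__"] = np.frombuffer(
            json.dumps(rng.bit_generator.state).encode(), dtype=np.uint8
        )
    np.savez(path, **payload)


def load_checkpoint(path):
    """Rebuild the model; returns (model, train_cfg, (mean, std))."""
    from .config import _build

    with np.load(path) as data:
        model_raw = json.loads(bytes(data["__model_config__"]).decode())
        train_raw = json.loads(bytes(data["__train_config__"]).decode())
        mean = data["__norm_mean__"]
        std = data["__norm_std__"]
        state = {
            k: data[k]
            for k in data.files
            if not k.startswith("__")
        }
    model = build_backbone(_build(ModelConfig, model_raw))
    model.load_state_dict(state)
    model.eval()
    train_cfg = _build(TrainConfig, train_raw)
    return model, train_cfg, (mean, std)
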