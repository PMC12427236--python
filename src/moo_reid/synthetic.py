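"""Procedural coat-pattern image generator.

Every identity is a fixed set of dark elliptical patches on a light coat
(Holstein-style), laid out in normalized body coordinates.  A render projects
the patches through a view transform (horizontal shear + scale standing in
for the camera angle), pastes the body onto one of a few flat-texture
backgrounds, applies multiplicative illumination, optional occlusion and
pixel noise.  Because patch geometry is tied to the identity and everything
else varies per render, nearest-neighbour retrieval on these images is
learnable but not trivial — the same regime as coat-pattern re-identification
from barn imagery.

Splits follow the re-identification convention: train / gallery / query at
6:3:1, either image-level or with train and test identities disjoint
(``split_mode``).
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "IdentitySpec",
    "RenderConfig",
    "ImageRecord",
    "generate_identity_bank",
    "render_image",
    "generate_dataset",
    "body_mask",
    "pattern_vector",
    "write_dataset",
    "load_dataset",
]

_BACKGROUND_LEVELS = (100, 140, 70, 170)


@dataclass(frozen=True)
class IdentitySpec:
    identity_id: int
    pattern_seed: int
    n_blobs: int
    # (center_u, center_v, radius_u, radius_v, rotation) in body coordinates [0,1]
    blob_params: tuple[tuple[float, float, float, float, float], ...]
    base_coat: int  # grayscale level 0-255


@dataclass(frozen=True)
class RenderConfig:
    image_height: int = 384
    image_width: int = 192
    view_angle: float = 0.0  # degrees, [-60, 60]
    illumination: float = 1.0  # multiplicative, [0.3, 1.2]
    background_id: int = 0
    occlusion_fraction: float = 0.0  # [0, 0.5]
    noise_sigma: float = 0.0

    def __post_init__(self):
        if not -60.0 <= self.view_angle <= 60.0:
            raise ValueError("view_angle must lie in [-60, 60] degrees")
        if not 0.0 <= self.illumination <= 1.2:
            raise ValueError("illumination must lie in [0, 1.2]")
        if not 0.0 <= self.occlusion_fraction <= 0.5:
            raise ValueError("occlusion_fraction must lie in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class ImageRecord:
    pixels: np.ndarray  # H x W x 3 uint8
    identity_id: int
    split: str  # train | gallery | query
    meta: RenderConfig = field(default_factory=RenderConfig)


def generate_identity_bank(n_ids: int, seed: int) -> list[IdentitySpec]:
    """Draw ``n_ids`` identity patterns; ids are contiguous from 0.

    Deterministic for a fixed seed: the bank rng only emits one pattern seed
    per identity and the pattern seed alone determines the blob layout.
    """
    if n_ids < 1:
        raise ValueError("n_ids must be >= 1")
    bank_rng = np.random.default_rng(seed)
    specs = []
    for identity_id in range(n_ids):
        pattern_seed = int(bank_rng.integers(0, 2**31 - 1))
        rng = np.random.default_rng(pattern_seed)
        n_blobs = int(rng.integers(4, 10))
        blobs = tuple(
            (
                float(rng.uniform(0.08, 0.92)),
                float(rng.uniform(0.08, 0.92)),
                float(rng.uniform(0.07, 0.22)),
                float(rng.uniform(0.07, 0.22)),
                float(rng.uniform(0.0, np.pi)),
            )
            for _ in range(n_blobs)
        )
        specs.append(
            IdentitySpec(
                identity_id=identity_id,
                pattern_seed=pattern_seed,
                n_blobs=n_blobs,
                blob_params=blobs,
                base_coat=int(rng.integers(205, 240)),
            )
        )
    return specs


def body_mask(height: int, width: int) -> np.ndarray:
    """Boolean mask of the elliptical body region (True inside)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ay, ax = 0.46 * height, 0.42 * width
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _body_coords(height: int, width: int):
    """(U, V) body coordinates in [0,1] for every pixel (V along the body axis)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ay, ax = 0.46 * height, 0.42 * width
    u = (xx - cx) / (2 * ax) + 0.5
    v = (yy - cy) / (2 * ay) + 0.5
    return u, v


def render_image(
    spec: IdentitySpec, cfg: RenderConfig, noise_seed: int = 0
) -> ImageRecord:
    """Render one view of an identity.  Deterministic in (spec, cfg, noise_seed)."""
    H, W = cfg.image_height, cfg.image_width
    noise_rng = np.random.default_rng(noise_seed)

    # background: flat level plus a frozen texture tied to the scene index
    level = _BACKGROUND_LEVELS[cfg.background_id % len(_BACKGROUND_LEVELS)]
    tex_rng = np.random.default_rng(1000 + cfg.background_id)
    coarse = tex_rng.normal(0.0, 12.0, size=(H // 8 + 1, W // 8 + 1))
    texture = np.kron(coarse, np.ones((8, 8)))[:H, :W]
    img = np.full((H, W), float(level)) + texture

    # body coat
    mask = body_mask(H, W)
    img[mask] = spec.base_coat

    # blobs, drawn at view-transformed positions: invert the shear+scale so a
    # pixel is dark iff its pre-view body coordinate falls inside a blob
    a = np.deg2rad(cfg.view_angle)
    scale = max(np.cos(a), 0.4)
    shear = 0.5 * np.sin(a)
    u, v = _body_coords(H, W)
    u0 = 0.5 + (u - 0.5 - shear * (v - 0.5)) / scale
    blob_rng = np.random.default_rng(spec.pattern_seed + 1)
    for cu, cv, ru, rv, rot in spec.blob_params:
        du, dv = u0 - cu, v - cv
        cr, sr = np.cos(rot), np.sin(rot)
        q = ((du * cr + dv * sr) / ru) ** 2 + ((-du * sr + dv * cr) / rv) ** 2
        dark = float(blob_rng.integers(20, 60))
        img[mask & (q <= 1.0)] = dark

    # occlusion: flat gray rectangle over part of the body
    if cfg.occlusion_fraction > 0:
        frac = cfg.occlusion_fraction
        oh = max(1, int(round(H * np.sqrt(frac))))
        ow = max(1, int(round(W * np.sqrt(frac))))
        oy = int(noise_rng.integers(0, H - oh + 1))
        ox = int(noise_rng.integers(0, W - ow + 1))
        img[oy : oy + oh, ox : ox + ow] = 128.0

    img = img * cfg.illumination
    if cfg.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255)
    pixels = np.repeat(img[:, :, None], 3, axis=2).astype(np.uint8)
    return ImageRecord(pixels=pixels, identity_id=spec.identity_id, split="train", meta=cfg)


def pattern_vector(record: ImageRecord) -> np.ndarray:
    """Grayscale body-region pixels as a flat vector (for raw-pixel baselines)."""
    gray = record.pixels.mean(axis=2)
    mask = body_mask(*gray.shape)
    return gray[mask]


def _largest_remainder(total: int, ratio) -> list[int]:
    ratio = np.asarray(ratio, dtype=float)
    shares = total * ratio / ratio.sum()
    counts = np.floor(shares).astype(int)
    rem = shares - counts
    for i in np.argsort(-rem)[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _split_within_identity(n: int, ratio, rng) -> list[str]:
    """Assign n images of one identity to splits; every query needs a gallery mate."""
    counts = _largest_remainder(n, ratio)
    names = ["train", "gallery", "query"]
    if counts[2] > 0 and counts[1] == 0:
        counts[1] += 1
        counts[2] -= 1
    labels = sum(([nm] * c for nm, c in zip(names, counts)), [])
    rng.shuffle(labels)
    return labels


def generate_dataset(
    n_ids: int,
    images_per_id: int,
    seed: int,
    split_ratio=(6, 3, 1),
    split_mode: str = "identity",
    image_size=(384, 192),
    view_range=(-60.0, 60.0),
    illumination_range=(0.3, 1.2),
    n_backgrounds: int = 4,
    noise_sigma: float = 3.0,
    occlusion_fraction: float = 0.0,
) -> list[ImageRecord]:
    """Generate a labelled train/gallery/query dataset.

    ``split_mode='identity'`` (the re-identification convention) holds out
    whole identities for testing, with their images split gallery:query;
    ``split_mode='image'`` splits each identity's images 6:3:1 directly.
    """
    if images_per_id < 1:
        raise ValueError("images_per_id must be >= 1")
    ratio = tuple(split_ratio)
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ValueError("split_ratio must be three nonnegative shares")
    if ratio[1] == 0:
        raise ValueError("gallery share of split_ratio must be positive")
    if split_mode not in ("identity", "image"):
        raise ValueError(f"unknown split_mode {split_mode!r}")

    specs = generate_identity_bank(n_ids, seed)
    rng = np.random.default_rng(seed + 1)
    H, W = image_size

    if split_mode == "identity":
        if n_ids < 2:
            raise ValueError("identity-level split needs >= 2 identities")
        train_share = ratio[0] / sum(ratio)
        n_train_ids = min(max(int(round(train_share * n_ids)), 1), n_ids - 1)
        perm = rng.permutation(n_ids)
        train_ids = set(perm[:n_train_ids].tolist())

    records = []
    for spec in specs:
        if split_mode == "image":
            labels = _split_within_identity(images_per_id, ratio, rng)
        elif spec.identity_id in train_ids:
            labels = ["train"] * images_per_id
        else:
            labels = _split_within_identity(images_per_id, (0, ratio[1], ratio[2]), rng)
        for label in labels:
            cfg = RenderConfig(
                image_height=H,
                image_width=W,
                view_angle=float(rng.uniform(*view_range)),
                illumination=float(rng.uniform(*illumination_range)),
                background_id=int(rng.integers(0, n_backgrounds)),
                occlusion_fraction=occlusion_fraction,
                noise_sigma=noise_sigma,
            )
            rec = render_image(spec, cfg, noise_seed=int(rng.integers(0, 2**31 - 1)))
            rec.split = label
            records.append(rec)
    return records


def write_dataset(records: list[ImageRecord], root) -> Path:
    """Write PNGs as <root>/<split>/<identity_id>/<index>.png plus manifest.csv."""
    root = Path(root)
    counters: dict[tuple[str, int], int] = {}
    rows = []
    for rec in records:
        key = (rec.split, rec.identity_id)
        idx = counters.get(key, 0)
        counters[key] = idx + 1
        rel = Path(rec.split) / str(rec.identity_id) / f"{idx}.png"
        path = root / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(rec.pixels).save(path)
        rows.append(
            {
                "path": str(rel),
                "identity_id": rec.identity_id,
                "split": rec.split,
                "view_angle": rec.meta.view_angle,
                "illumination": rec.meta.illumination,
                "background_id": rec.meta.background_id,
            }
        )
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return root


def load_dataset(root) -> list[ImageRecord]:
    root = Path(root)
    records = []
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = np.asarray(Image.open(root / row["path"]).convert("RGB"))
            meta = RenderConfig(
                image_height=pixels.shape[0],
                image_width=pixels.shape[1],
                view_angle=float(row["view_angle"]),
                illumination=float(row["illumination"]),
                background_id=int(row["background_id"]),
            )
            records.append(
                ImageRecord(
                    pixels=pixels,
                    identity_id=int(row["identity_id"]),
                    split=row["split"],
                    meta=meta,
                )
            )
    return records
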