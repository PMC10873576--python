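"""Latent-factor synthetic multiplexed images with known ground truth.

The generator emulates the statistical structure the selection method
exploits in real multiplexed tissue images: a small number K of latent
spatial factors (cell populations / signalling programs) drive N >= K
marker channels through a fixed N x K mixing matrix, so most channels are
redundant given a few well-chosen ones. Per image, cell centers are placed
uniformly at random; each latent field is a sum of truncated-Gaussian
radial kernels around the centers with cell-specific latent weights and
jittered radii, giving the blobby, spatially correlated channels typical of
CODEX/IMC data. Channel c is (mixing row c) . latents, optionally passed
through a softplus, z-scored with statistics pooled over every generated
image (so one affine latent-to-channel map holds across splits), plus
Gaussian channel noise of standard deviation ``noise_sd`` in z-score units,
and a final pooled re-z-scoring.

With ``noise_sd = 0`` and no nonlinearity every channel is exactly an
affine combination of the K *anchor* channels (the first K markers, whose
K x K mixing submatrix is kept well-conditioned), so a linear predictor
given the anchors achieves zero risk — the ground truth the recovery tests
rely on. Masks (nearest-center discs) share the cell centers, so cell mean
intensities track the per-cell latent weights.

Three independent seed streams (mixing, fields, noise) let experiments vary
one ingredient at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import (
    CellMask,
    MultichannelDataset,
    MultichannelImage,
    write_mask,
    write_multichannel,
)
from .paneldesign import MarkerFeatures


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults generate the small noiseless benchmark: 12 markers driven by 3
    latent factors on 64 x 64 images, split 4/2/2 (train/val/test) as in
    small multiplexed imaging studies, with ~25 cells per image.
    """

    n_markers: int = 12
    n_latents: int = 3
    height: int = 64
    width: int = 64
    n_train: int = 4
    n_val: int = 2
    n_test: int = 2
    n_cells: int = 25
    noise_sd: float = 0.0
    nonlinearity: str = "none"  # none | softplus
    mixing_seed: int = 11
    field_seed: int = 22
    noise_seed: int = 33

    def __post_init__(self) -> None:
        if self.n_latents > self.n_markers:
            raise ValueError("n_latents must be <= n_markers")
        if self.n_latents < 1 or self.n_markers < 2:
            raise ValueError("need >= 2 markers and >= 1 latent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in ("none", "softplus"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if min(self.n_train, self.n_val) < 1:
            raise ValueError("need at least one train and one validation image")

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(f"M{i:02d}" for i in range(self.n_markers))

    @property
    def anchor_markers(self) -> tuple[str, ...]:
        return self.marker_names[: self.n_latents]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    config: SyntheticConfig
    mixing: np.ndarray  # (n_markers, n_latents)
    anchors: list[str]
    latent_fields: list[np.ndarray] = field(default_factory=list)  # (K, H, W) per image
    cell_centers: list[np.ndarray] = field(default_factory=list)  # (n_cells, 2) per image
    cell_weights: list[np.ndarray] = field(default_factory=list)  # (n_cells, K) per image
    masks: list[CellMask] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "mixing": self.mixing.tolist(),
                "anchors": self.anchors,
                "seeds": {
                    "mixing": self.config.mixing_seed,
                    "field": self.config.field_seed,
                    "noise": self.config.noise_seed,
                },
                "n_markers": self.config.n_markers,
                "n_latents": self.config.n_latents,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc


def _sample_mixing(config: SyntheticConfig) -> np.ndarray:
    """N x K mixing with a well-conditioned anchor submatrix (resampled if not)."""
    rng = np.random.default_rng(config.mixing_seed)
    K = config.n_latents
    for _ in range(100):
        mixing = rng.normal(size=(config.n_markers, K))
        if K == 1 or np.linalg.cond(mixing[:K, :K]) < 1e4:
            return mixing
    raise RuntimeError("could not draw an invertible anchor mixing submatrix")


def _image_internals(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell centers, per-cell latent weights and latent fields for one image."""
    h, w = config.height, config.width
    K = config.n_latents
    centers = np.column_stack(
        [rng.uniform(0, h, config.n_cells), rng.uniform(0, w, config.n_cells)]
    )
    weights = rng.normal(size=(config.n_cells, K))
    base_radius = 0.35 * np.sqrt(h * w / max(config.n_cells, 1))
    radii = base_radius * rng.uniform(0.7, 1.3, size=config.n_cells)
    rr, cc = np.mgrid[0:h, 0:w]
    fields = np.zeros((K, h, w))
    for c in range(config.n_cells):
        d2 = (rr - centers[c, 0]) ** 2 + (cc - centers[c, 1]) ** 2
        kernel = np.exp(-d2 / (2 * radii[c] ** 2))
        kernel[d2 > (3 * radii[c]) ** 2] = 0.0  # truncate to a compact blob
        fields += weights[c][:, None, None] * kernel[None]
    return centers, weights, fields


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[MultichannelDataset, SyntheticTruth]:
    """Generate a full train/validation/test dataset plus its ground truth.

    Deterministic for a given config: the field stream spawns one substream
    per image (splits are therefore disjoint draws) and the noise stream is
    independent of the fields.
    """
    mixing = _sample_mixing(config)
    n_images = config.n_train + config.n_val + config.n_test
    field_streams = np.random.SeedSequence(config.field_seed).spawn(n_images)
    noise_rng = np.random.default_rng(config.noise_seed)

    truth = SyntheticTruth(
        config=config, mixing=mixing, anchors=list(config.anchor_markers)
    )
    raw: list[np.ndarray] = []
    for s in field_streams:
        rng = np.random.default_rng(s)
        centers, weights, fields = _image_internals(config, rng)
        truth.cell_centers.append(centers)
        truth.cell_weights.append(weights)
        truth.latent_fields.append(fields)
        channels = np.tensordot(mixing, fields, axes=(1, 0))  # (N, H, W)
        if config.nonlinearity == "softplus":
            channels = _softplus(channels)
        raw.append(channels)

    stack = np.stack(raw)  # (n_images, N, H, W)
    # one affine latent->channel map across all splits: pool the statistics
    mu = stack.mean(axis=(0, 2, 3), keepdims=True)
    sd = stack.std(axis=(0, 2, 3), keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    stack = (stack - mu) / sd
    if config.noise_sd > 0:
        stack = stack + noise_rng.normal(scale=config.noise_sd, size=stack.shape)
        mu = stack.mean(axis=(0, 2, 3), keepdims=True)
        sd = stack.std(axis=(0, 2, 3), keepdims=True)
        sd = np.where(sd < 1e-12, 1.0, sd)
        stack = (stack - mu) / sd

    names = config.marker_names
    images = [MultichannelImage(stack[i], names, normalized="z") for i in range(n_images)]
    dataset = MultichannelDataset(
        images[: config.n_train],
        images[config.n_train : config.n_train + config.n_val],
        images[config.n_train + config.n_val :],
    )
    truth.masks = _masks_from_centers(config, truth.cell_centers)
    return dataset, truth


def _masks_from_centers(
    config: SyntheticConfig, centers_per_image: list[np.ndarray]
) -> list[CellMask]:
    h, w = config.height, config.width
    base_radius = 0.35 * np.sqrt(h * w / max(config.n_cells, 1))
    rr, cc = np.mgrid[0:h, 0:w]
    masks = []
    for centers in centers_per_image:
        d2 = (
            (rr[None] - centers[:, 0, None, None]) ** 2
            + (cc[None] - centers[:, 1, None, None]) ** 2
        )
        nearest = np.argmin(d2, axis=0)
        within = np.take_along_axis(d2, nearest[None], axis=0)[0] <= base_radius**2
        labels = np.where(within, nearest + 1, 0).astype(np.int32)
        masks.append(CellMask(labels))
    return masks


def generate_cell_masks(config: SyntheticConfig) -> list[CellMask]:
    """Nearest-center disc masks aligned with :func:`generate_dataset`.

    Regenerates the same cell centers deterministically from the field seed,
    so masks match the images of ``generate_dataset(config)`` label for
    label (labels 1..n_cells per image).
    """
    n_images = config.n_train + config.n_val + config.n_test
    centers = []
    for s in np.random.SeedSequence(config.field_seed).spawn(n_images):
        rng = np.random.default_rng(s)
        c, _, _ = _image_internals(config, rng)
        centers.append(c)
    return _masks_from_centers(config, centers)


def generate_marker_features(
    truth: SyntheticTruth, noise: float = 0.0, seed: int = 0
) -> MarkerFeatures:
    """Per-marker feature vectors correlated with the ground-truth mixing.

    Each marker's feature is its mixing row plus isotropic Gaussian noise —
    a stand-in for embeddings learned from independent stainings: markers
    with similar mixing (hence similar channels) get similar features.
    """
    rng = np.random.default_rng(seed)
    names = truth.config.marker_names
    vectors = truth.mixing + rng.normal(scale=noise, size=truth.mixing.shape)
    return MarkerFeatures(
        features={m: vectors[i].copy() for i, m in enumerate(names)},
        source="synthetic-mixing",
    )


def write_study(
    dataset: MultichannelDataset,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> Path:
    """Write a self-contained study directory: OME-TIFFs, masks, truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    splits = {
        "train": dataset.train_images,
        "val": dataset.val_images,
        "test": dataset.test_images,
    }
    i = 0
    for split, images in splits.items():
        for k, img in enumerate(images):
            write_multichannel(img, out_dir / f"{split}_{k}.ome.tif")
            if i < len(truth.masks):
                write_mask(truth.masks[i], out_dir / f"{split}_{k}.mask.tif")
            i += 1
    truth.to_json(out_dir / "truth.json")
    return out_dir
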