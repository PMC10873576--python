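"""Multichannel image containers, I/O, normalization recipes and patch plumbing.

Images are held channel-first (``C x H x W``) with an ordered list of marker
names. Three normalization recipes used for multiplexed proteomics are
provided:

``arcsinh_z``
    The CODEX recipe: each channel is divided by ``max(5 * q20, 15)`` where
    ``q20`` is its 20th percentile, passed through ``arcsinh`` and z-scored.
``clip_blur_z``
    The IMC recipe: clip to ``[0, q98]`` of the positive pixel values,
    Gaussian-blur (sigma 1.5 by default), z-score.
``z``
    Plain per-channel z-score.

All z-scores use the population standard deviation (divide by ``n``).
Channels whose standard deviation falls below ``SIGMA_GUARD`` are emitted as
all zeros together with a warning instead of dividing by ~0.

Patch plumbing (random crops for training, sliding-window tiling plus mean
stitching for whole-image inference) lives here as well, because predictors
of every backend share it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

#: standard deviations below this are treated as zero-variance channels
SIGMA_GUARD = 1e-12

#: mean/SD tolerance the normalization contract promises
NORM_TOL = 1e-6


class ZeroVarianceWarning(UserWarning):
    """A channel had (numerically) zero variance; it was set to all zeros."""


def _zscore(channel: np.ndarray, name: str) -> np.ndarray:
    """Population z-score of one channel with the zero-variance guard."""
    mu = channel.mean()
    sigma = channel.std()  # population SD (ddof=0)
    if sigma < SIGMA_GUARD:
        warnings.warn(
            f"channel {name!r} has zero variance; emitting zeros",
            ZeroVarianceWarning,
            stacklevel=3,
        )
        return np.zeros_like(channel)
    return (channel - mu) / sigma


@dataclass(frozen=True)
class MultichannelImage:
    """A named multichannel image.

    Parameters
    ----------
    pixels
        Float array of shape ``(channels, height, width)``.
    channel_names
        Unique marker identifiers, one per channel, in channel order.
    normalized
        Which recipe produced the pixel values: ``"none"``, ``"arcsinh_z"``,
        ``"clip_blur_z"`` or ``"z"``.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    normalized: str = "none"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3:
            raise ValueError(f"pixels must be (C, H, W), got shape {px.shape}")
        if px.shape[1] < 1 or px.shape[2] < 1:
            raise ValueError("image height and width must be >= 1")
        names = tuple(str(n) for n in self.channel_names)
        if len(names) != px.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {px.shape[0]} channels"
            )
        if len(names) == 0:
            raise ValueError("image must have at least one channel")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if self.normalized not in ("none", "arcsinh_z", "clip_blur_z", "z"):
            raise ValueError(f"unknown normalization flag {self.normalized!r}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width)."""
        return self.pixels.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Pixel array of a single named channel."""
        return self.pixels[self.channel_names.index(name)]

    def select_channels(self, names: Sequence[str]) -> "MultichannelImage":
        """Sub-image restricted to ``names``, in the given order."""
        idx = [self.channel_names.index(n) for n in names]
        return MultichannelImage(self.pixels[idx], tuple(names), self.normalized)


@dataclass(frozen=True)
class CellMask:
    """Integer cell-label mask: 0 is background, ``k >= 1`` labels cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if lab.min() < 0:
            raise ValueError("mask labels must be >= 0")
        object.__setattr__(self, "labels", lab)

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class MultichannelDataset:
    """Train (S) / validation (P) / test splits sharing one channel list."""

    train_images: list[MultichannelImage]
    val_images: list[MultichannelImage]
    test_images: list[MultichannelImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = self.channel_names
        for img in self.train_images + self.val_images + self.test_images:
            if img.channel_names != names:
                raise ValueError("all images in a dataset must share channel names")

    @property
    def channel_names(self) -> tuple[str, ...]:
        for split in (self.train_images, self.val_images, self.test_images):
            if split:
                return split[0].channel_names
        raise ValueError("dataset is empty")

    def select_channels(self, names: Sequence[str]) -> "MultichannelDataset":
        return MultichannelDataset(
            [im.select_channels(names) for im in self.train_images],
            [im.select_channels(names) for im in self.val_images],
            [im.select_channels(names) for im in self.test_images],
        )

    def map_images(self, fn) -> "MultichannelDataset":
        return MultichannelDataset(
            [fn(im) for im in self.train_images],
            [fn(im) for im in self.val_images],
            [fn(im) for im in self.test_images],
        )


# ---------------------------------------------------------------------------
# I/O: OME-TIFF images, label-TIFF masks, sidecar channel tables
# ---------------------------------------------------------------------------

def read_channel_table(path: str | Path) -> list[str]:
    """Read a two-column (index,name) CSV sidecar channel table."""
    rows: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("index", ""):
                continue
            rows.append((int(row[0]), row[1].strip()))
    rows.sort()
    return [name for _, name in rows]


def write_channel_table(names: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "name"])
        for i, n in enumerate(names):
            w.writerow([i, n])
    return path


def read_multichannel(
    path: str | Path, names: Sequence[str] | None = None
) -> MultichannelImage:
    """Read a multi-page / OME TIFF as a :class:`MultichannelImage`.

    Channel names are taken from, in order of preference: the ``names``
    argument, OME metadata, or a ``<stem>.channels.csv`` sidecar table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_names: list[str] | None = None
        if names is None and tif.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            found = [
                ch.get("Name")
                for ch in root.iter(f"{{{ns['ome']}}}Channel")
                if ch.get("Name")
            ]
            if found:
                meta_names = found
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {arr.shape}")
    if names is None:
        if meta_names is not None:
            names = meta_names
        else:
            sidecar = path.with_suffix("").with_suffix(".channels.csv")
            if not sidecar.exists():
                sidecar = Path(str(path) + ".channels.csv")
            if sidecar.exists():
                names = read_channel_table(sidecar)
            else:
                raise ValueError(
                    f"no channel names supplied and none found for {path}"
                )
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{len(names)} channel names for a {arr.shape[0]}-page TIFF"
        )
    return MultichannelImage(arr, tuple(names))


def write_multichannel(img: MultichannelImage, path: str | Path) -> Path:
    """Write an OME-TIFF with channel names in the metadata.

    Pixels are stored as float32; reads back bit-exactly for float32 data.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        img.pixels.astype(np.float32),
        ome=True,
        metadata={"axes": "CYX", "Channel": {"Name": list(img.channel_names)}},
    )
    return path


def read_mask(path: str | Path) -> CellMask:
    labels = tifffile.imread(path)
    return CellMask(np.asarray(labels).astype(np.int32))


def write_mask(mask: CellMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.labels.astype(np.int32))
    return path


# ---------------------------------------------------------------------------
# Normalization recipes
# ---------------------------------------------------------------------------

def _require_raw(img: MultichannelImage) -> None:
    if img.normalized != "none":
        raise ValueError(
            f"image already normalized with recipe {img.normalized!r}"
        )


def arcsinh_divisor(channel: np.ndarray, positive_only: bool = False) -> float:
    """The variance-stabilizing divisor ``max(5 * q20, 15)``.

    ``q20`` is the 20th percentile (linear interpolation) over all pixels by
    default; ``positive_only`` restricts it to positive pixels.
    """
    vals = np.asarray(channel, dtype=np.float64).ravel()
    if positive_only:
        pos = vals[vals > 0]
        q20 = float(np.percentile(pos, 20)) if pos.size else 0.0
    else:
        q20 = float(np.percentile(vals, 20))
    return max(5.0 * q20, 15.0)


def normalize_arcsinh_z(
    img: MultichannelImage, positive_only_percentile: bool = False
) -> MultichannelImage:
    """CODEX recipe: ``z-score(arcsinh(x / max(5 * q20(x), 15)))`` per channel."""
    _require_raw(img)
    out = np.empty_like(img.pixels)
    for c, name in enumerate(img.channel_names):
        d = arcsinh_divisor(img.pixels[c], positive_only_percentile)
        out[c] = _zscore(np.arcsinh(img.pixels[c] / d), name)
    return replace(img, pixels=out, normalized="arcsinh_z")


def normalize_clip_blur_z(
    img: MultichannelImage, clip_percentile: float = 98.0, sigma: float = 1.5
) -> MultichannelImage:
    """IMC recipe: clip to [0, q98 of positive pixels], Gaussian blur, z-score.

    The blur uses reflective boundary handling so tissue edges do not darken.
    """
    _require_raw(img)
    out = np.empty_like(img.pixels)
    for c, name in enumerate(img.channel_names):
        ch = img.pixels[c]
        pos = ch[ch > 0]
        hi = float(np.percentile(pos, clip_percentile)) if pos.size else 0.0
        clipped = np.clip(ch, 0.0, hi)
        blurred = gaussian_filter(clipped, sigma=sigma, mode="reflect")
        out[c] = _zscore(blurred, name)
    return replace(img, pixels=out, normalized="clip_blur_z")


def normalize_z(img: MultichannelImage) -> MultichannelImage:
    """Plain per-channel z-score."""
    _require_raw(img)
    out = np.empty_like(img.pixels)
    for c, name in enumerate(img.channel_names):
        out[c] = _zscore(img.pixels[c], name)
    return replace(img, pixels=out, normalized="z")


NORMALIZERS = {
    "arcsinh_z": normalize_arcsinh_z,
    "clip_blur_z": normalize_clip_blur_z,
    "z": normalize_z,
    "none": lambda img: img,
}


def normalize_dataset(
    dataset: MultichannelDataset, recipe: str
) -> MultichannelDataset:
    """Apply one normalization recipe to every image of every split."""
    try:
        fn = NORMALIZERS[recipe]
    except KeyError:
        raise ValueError(f"unknown normalization recipe {recipe!r}") from None
    return dataset.map_images(fn)


# ---------------------------------------------------------------------------
# Patch extraction and stitching
# ---------------------------------------------------------------------------

def random_patches(
    img: MultichannelImage, size: int, count: int, seed: int
) -> list[MultichannelImage]:
    """``count`` random ``size x size`` crops, reproducible for a seed.

    Positions are top-left corners drawn uniformly (with replacement) via
    ``numpy.random.default_rng(seed)``, so the chosen offsets are identical
    across platforms.
    """
    h, w = img.shape
    if size > h or size > w:
        raise ValueError(f"patch size {size} exceeds image shape {(h, w)}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - size + 1, size=count)
    cols = rng.integers(0, w - size + 1, size=count)
    return [
        replace(img, pixels=img.pixels[:, r : r + size, c : c + size])
        for r, c in zip(rows, cols)
    ]


def tile_patches(
    img: MultichannelImage, size: int
) -> list[tuple[MultichannelImage, tuple[int, int]]]:
    """Sliding-window tiling with stride = size.

    The final row/column of patches is re-anchored to the image edge so the
    union of patches covers every pixel; positions are (row, col) top-left
    corners, 0-based.
    """
    h, w = img.shape
    if size > h or size > w:
        raise ValueError(f"patch size {size} exceeds image shape {(h, w)}")

    def offsets(extent: int) -> list[int]:
        offs = list(range(0, extent - size + 1, size))
        if offs[-1] + size < extent:
            offs.append(extent - size)
        return offs

    out = []
    for r in offsets(h):
        for c in offsets(w):
            patch = replace(img, pixels=img.pixels[:, r : r + size, c : c + size])
            out.append((patch, (r, c)))
    return out


def stitch_patches(
    patches: Sequence[tuple[MultichannelImage, tuple[int, int]]],
    height: int,
    width: int,
) -> MultichannelImage:
    """Reassemble patches onto a canvas; overlaps receive the mean.

    ``stitch_patches(tile_patches(img, s), *img.shape)`` reproduces ``img``
    bit-identically when the patch values are untouched.
    """
    if not patches:
        raise ValueError("no patches to stitch")
    first = patches[0][0]
    acc = np.zeros((first.n_channels, height, width))
    cnt = np.zeros((height, width))
    for patch, (r, c) in patches:
        ph, pw = patch.shape
        acc[:, r : r + ph, c : c + pw] += patch.pixels
        cnt[r : r + ph, c : c + pw] += 1
    if (cnt == 0).any():
        gaps = np.argwhere(cnt == 0)
        raise ValueError(
            f"{len(gaps)} pixels uncovered by patches, first at "
            f"(row={gaps[0][0]}, col={gaps[0][1]})"
        )
    # exact round trip when every pixel is covered exactly once
    pixels = np.where(cnt == 1, acc, acc / cnt)
    return MultichannelImage(pixels, first.channel_names, first.normalized)
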