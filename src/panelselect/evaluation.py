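"""Pixel- and single-cell-level quality measures for predicted images.

Pixel level: per-channel reconstruction MSE and Pearson correlation between
predicted and real images. Single-cell level: from a segmentation label
mask, a cells x markers matrix of mean intensities and a cells x
marker-pairs matrix of within-cell Pearson correlations (the *correlation
profile*). Profiles from real and predicted images are compared with the
normalized Frobenius norm, defined here as the root-mean-square of the
entrywise differences over the entries that are defined in both profiles.

Correlations over cells with fewer than two pixels, or over constant
channels, are undefined; they are stored as NaN *flags* and excluded from
distances rather than zero-filled (zero-filling would fabricate agreement
in tiny cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import CellMask, MultichannelImage


def _check_pair(pred: MultichannelImage, real: MultichannelImage) -> None:
    if pred.channel_names != real.channel_names:
        raise ValueError("channel names must match (same markers, same order)")
    if pred.shape != real.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {real.shape}")


def image_mse(
    pred: MultichannelImage, real: MultichannelImage
) -> tuple[dict[str, float], float]:
    """Per-channel mean squared error and its mean over channels."""
    _check_pair(pred, real)
    per = {
        m: float(((pred.pixels[i] - real.pixels[i]) ** 2).mean())
        for i, m in enumerate(pred.channel_names)
    }
    return per, float(np.mean(list(per.values())))


def image_pcc(
    pred: MultichannelImage, real: MultichannelImage
) -> dict[str, Optional[float]]:
    """Pixel-wise Pearson correlation per channel; None where undefined."""
    _check_pair(pred, real)
    out: dict[str, Optional[float]] = {}
    for i, m in enumerate(pred.channel_names):
        a = pred.pixels[i].ravel()
        b = real.pixels[i].ravel()
        if a.std() < 1e-12 or b.std() < 1e-12:
            out[m] = None
        else:
            out[m] = float(np.corrcoef(a, b)[0, 1])
    return out


@dataclass
class SingleCellProfile:
    """Per-cell marker means and within-cell marker-pair correlations.

    ``mean_matrix``: cells x markers; ``corr_matrix``: cells x marker pairs
    (columns labelled ``"A|B"`` with pairs ordered lexicographically by
    channel index, i < j). NaN entries flag undefined correlations.
    """

    mean_matrix: pd.DataFrame
    corr_matrix: Optional[pd.DataFrame] = None

    @property
    def cell_ids(self) -> list[int]:
        return list(self.mean_matrix.index)

    def write_csv(self, mean_path: str | Path, corr_path: str | Path | None = None) -> None:
        self.mean_matrix.to_csv(mean_path, index_label="cell")
        if corr_path is not None and self.corr_matrix is not None:
            self.corr_matrix.to_csv(corr_path, index_label="cell")

    @classmethod
    def read_csv(
        cls, mean_path: str | Path, corr_path: str | Path | None = None
    ) -> "SingleCellProfile":
        read = dict(index_col="cell", float_precision="round_trip")
        mean = pd.read_csv(mean_path, **read)
        mean.index.name = None
        corr = None
        if corr_path:
            corr = pd.read_csv(corr_path, **read)
            corr.index.name = None
        return cls(mean, corr)


def _check_mask(img: MultichannelImage, mask: CellMask) -> np.ndarray:
    if mask.labels.shape != img.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != image shape {img.shape}"
        )
    ids = mask.cell_ids
    if ids.size == 0:
        raise ValueError("mask contains no cells")
    return ids.astype(np.int64)  # platform-stable index dtype


def cell_mean_profile(img: MultichannelImage, mask: CellMask) -> SingleCellProfile:
    """Mean intensity of every marker within every cell (background excluded)."""
    ids = _check_mask(img, mask)
    data = np.column_stack(
        [
            ndimage.mean(img.pixels[c], labels=mask.labels, index=ids)
            for c in range(img.n_channels)
        ]
    )
    mean = pd.DataFrame(data, index=ids, columns=list(img.channel_names))
    return SingleCellProfile(mean_matrix=mean)


def cell_correlation_profile(
    img: MultichannelImage, mask: CellMask
) -> SingleCellProfile:
    """Within-cell Pearson correlation for every marker pair and cell.

    Cells with fewer than two pixels, or channels constant within a cell,
    yield NaN flags for the affected pairs.
    """
    ids = _check_mask(img, mask)
    names = img.channel_names
    pairs = list(combinations(range(len(names)), 2))
    cols = [f"{names[i]}|{names[j]}" for i, j in pairs]
    out = np.full((len(ids), len(pairs)), np.nan)
    flat_labels = mask.labels.ravel()
    flat_pixels = img.pixels.reshape(img.n_channels, -1)
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    bounds = np.searchsorted(sorted_labels, np.concatenate([ids, [ids[-1] + 1]]))
    for row, cid in enumerate(ids):
        sel = order[bounds[row] : np.searchsorted(sorted_labels, cid + 1)]
        if sel.size < 2:
            continue
        block = flat_pixels[:, sel]
        sd = block.std(axis=1)
        centered = block - block.mean(axis=1, keepdims=True)
        for k, (i, j) in enumerate(pairs):
            if sd[i] < 1e-12 or sd[j] < 1e-12:
                continue
            out[row, k] = float(
                (centered[i] * centered[j]).mean() / (sd[i] * sd[j])
            )
    corr = pd.DataFrame(out, index=ids, columns=cols)
    mean = cell_mean_profile(img, mask).mean_matrix
    return SingleCellProfile(mean_matrix=mean, corr_matrix=corr)


def profile_distance(
    a: pd.DataFrame, b: pd.DataFrame, normalization: str = "rms"
) -> float:
    """Normalized Frobenius distance between two equally shaped profiles.

    ``rms`` (default): ``||A - B||_F / sqrt(#compared entries)`` — the
    root-mean-square entry difference. ``relative``: ``||A - B||_F /
    ||B||_F`` over the same entries. Entries undefined (NaN) in either
    profile are excluded pairwise.
    """
    if a.shape != b.shape or list(a.columns) != list(b.columns) or list(a.index) != list(b.index):
        raise ValueError("profiles must share shape, labels and cell ids")
    av = a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    ok = np.isfinite(av) & np.isfinite(bv)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (defined-in-both) entries")
    diff = av[ok] - bv[ok]
    if normalization == "rms":
        return float(np.sqrt((diff**2).sum() / n))
    if normalization == "relative":
        denom = float(np.sqrt((bv[ok] ** 2).sum()))
        if denom == 0:
            raise ValueError("reference profile is all zero on compared entries")
        return float(np.sqrt((diff**2).sum()) / denom)
    raise ValueError(f"unknown normalization {normalization!r}")
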