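"""Designing overlapping marker panels from per-marker feature vectors.

Before any multiplexed imaging happens, markers must be assigned to panels;
grouping markers with similar expression patterns into the same panel gives
each panel model the best chance of predicting its markers from each other.
Similarity is not measurable in the target tissue beforehand, so it is
approximated by per-marker feature vectors from an external source (e.g.
embeddings of independently acquired stainings); this module consumes such
a feature table, reduces it to 2 principal components, clusters the markers,
and builds balanced, chained-overlap panels that always satisfy the layout
invariants (union, capacity, connectivity). Markers without features are
assigned uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .multipanel import PanelLayout


@dataclass
class MarkerFeatures:
    """Per-marker feature vectors (or None for featureless markers)."""

    features: dict[str, Optional[np.ndarray]]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.features.values() if v is not None}
        if len(dims) > 1:
            raise ValueError(f"feature vectors have mixed shapes: {dims}")
        if sum(v is not None for v in self.features.values()) < 2:
            raise ValueError("need features for at least 2 markers")

    @property
    def featured(self) -> list[str]:
        return [m for m, v in self.features.items() if v is not None]

    @property
    def featureless(self) -> list[str]:
        return [m for m, v in self.features.items() if v is None]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = []
        dim = len(next(v for v in self.features.values() if v is not None))
        for m, v in self.features.items():
            rows.append([m] + (list(v) if v is not None else [""] * dim))
        pd.DataFrame(rows, columns=["marker"] + [f"f{i+1}" for i in range(dim)]).to_csv(
            path, index=False
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerFeatures":
        df = pd.read_csv(path)
        feats: dict[str, Optional[np.ndarray]] = {}
        for _, row in df.iterrows():
            vec = row.iloc[1:].to_numpy(dtype=object)
            if any(pd.isna(v) or v == "" for v in vec):
                feats[str(row.iloc[0])] = None
            else:
                feats[str(row.iloc[0])] = vec.astype(float)
        return cls(feats, source=str(path))


def reduce_features(features: MarkerFeatures) -> pd.DataFrame:
    """Project centered feature vectors onto their top 2 principal components.

    Sign convention: within each component, the largest-magnitude loading is
    made positive, so the projection is deterministic across platforms.
    Markers without features are absent from the result.
    """
    names = features.featured
    X = np.stack([features.features[m] for m in names])
    if X.shape[1] < 2:
        raise ValueError("feature dimension must be >= 2 for a 2-D reduction")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(2):
        comp = pca.components_[k]
        if comp[np.argmax(np.abs(comp))] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(coords, index=names, columns=["pc1", "pc2"])


def cluster_markers(coords: pd.DataFrame, k: int, seed: int = 0) -> dict[str, int]:
    """k-means clustering of the 2-D marker coordinates.

    Cluster ids are relabelled by each cluster's lowest member row index, so
    the assignment is deterministic for a fixed seed regardless of k-means'
    internal label order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(coords):
        raise ValueError("k exceeds the number of featured markers")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(coords.to_numpy())
    first_row = {}
    for row, lab in enumerate(raw):
        first_row.setdefault(lab, row)
    relabel = {
        lab: rank
        for rank, lab in enumerate(sorted(first_row, key=first_row.get))
    }
    return {m: relabel[lab] for m, lab in zip(coords.index, raw)}


def build_panels(
    assignment: dict[str, int],
    capacity: int,
    overlap_size: int = 2,
    seed: int = 0,
    featureless: list[str] | None = None,
) -> PanelLayout:
    """Balanced, chained-overlap panels from a cluster assignment.

    Panels are seeded from the clusters, rebalanced until base sizes differ
    by at most one (moving the lowest-index marker from the largest to the
    smallest panel), featureless markers are placed uniformly at random, and
    each consecutive panel pair is connected by copying ``overlap_size``
    markers from panel i into panel i+1 — guaranteeing a connected panel
    chain. Fails if the capacity cannot accommodate base size + overlap.
    """
    if overlap_size < 1:
        raise ValueError("overlap_size must be >= 1 (panels would disconnect)")
    if capacity < overlap_size + 1:
        raise ValueError("capacity must exceed overlap_size")
    k = max(assignment.values()) + 1
    panels: list[list[str]] = [[] for _ in range(k)]
    for m in assignment:  # insertion order of the assignment dict
        panels[assignment[m]].append(m)

    rng = np.random.default_rng(seed)
    for m in featureless or []:
        panels[int(rng.integers(0, k))].append(m)

    total = sum(len(p) for p in panels)
    if total > k * (capacity - overlap_size):
        raise ValueError(
            f"{total} markers cannot fit in {k} panels of capacity {capacity} "
            f"with overlap {overlap_size}"
        )

    # rebalance: move lowest-index marker from largest into smallest panel
    while max(len(p) for p in panels) - min(len(p) for p in panels) > 1:
        big = max(range(k), key=lambda i: (len(panels[i]), -i))
        small = min(range(k), key=lambda i: (len(panels[i]), i))
        panels[small].append(panels[big].pop(0))

    if k > 1:
        if overlap_size > min(len(p) for p in panels):
            raise ValueError("overlap_size exceeds the smallest panel")
        for i in range(k - 1):
            shared = [m for m in panels[i] if m not in panels[i + 1]][:overlap_size]
            panels[i + 1].extend(shared)

    return PanelLayout(panels=panels, capacity=capacity)


def within_panel_dissimilarity(
    layout_panels: list[list[str]], dissim: pd.DataFrame
) -> float:
    """Mean pairwise dissimilarity within panels, averaged over panels.

    ``dissim`` is a symmetric markers x markers dissimilarity table (e.g.
    channel L1 distances); used to compare feature-guided layouts against
    random partitions of the same sizes.
    """
    vals = []
    for p in layout_panels:
        if len(p) < 2:
            continue
        pair_vals = [
            float(dissim.loc[a, b]) for ai, a in enumerate(p) for b in p[ai + 1 :]
        ]
        vals.append(float(np.mean(pair_vals)))
    if not vals:
        raise ValueError("no panel has >= 2 markers")
    return float(np.mean(vals))


def random_partition_dissimilarities(
    markers: list[str],
    sizes: list[int],
    dissim: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Within-panel dissimilarity of ``n_draws`` random partitions.

    Each draw shuffles the markers and cuts them into panels of the given
    sizes (no overlaps) — the null distribution a feature-guided layout is
    compared against.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    arr = list(markers)
    for d in range(n_draws):
        perm = [arr[i] for i in rng.permutation(len(arr))]
        panels, pos = [], 0
        for s in sizes:
            panels.append(perm[pos : pos + s])
            pos += s
        out[d] = within_panel_dissimilarity(panels, dissim)
    return out
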