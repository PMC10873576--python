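"""Directed complete graph over markers with loadings, tags and node costs.

The selection method maintains a clique with one node per marker. Each
directed edge ``(i, j)`` carries a nonnegative *loading* ``w[i, j]``: an
(approximate upper bound on the) risk of predicting marker ``j`` from
marker ``i``. Loadings start as the pairwise L1 dissimilarity of the two
channels over the training set; once a joint predictor is trained, every
edge leaving an observed marker into a predicted marker ``j`` is overwritten
with the predictor's validation risk for ``j``, and edges between two
observed markers are zeroed. Edges leaving predicted markers are never
updated — unpredictability is directional, from observation to prediction.

A predicted marker's *node cost* is the minimum loading among its activated
in-edges (edges from observed markers); observed markers cost 0. The sum of
node costs is the quantity the greedy selection minimizes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .images import MultichannelDataset, MultichannelImage

TAG_INITIAL = "initial_dissimilarity"
TAG_RISK = "model_risk"
TAG_ZEROED = "zeroed"
TAG_INFERRED = "inferred_bound"

_VALID_TAGS = {TAG_INITIAL, TAG_RISK, TAG_ZEROED, TAG_INFERRED}


def dissimilarity(
    a: np.ndarray | Sequence[np.ndarray], b: np.ndarray | Sequence[np.ndarray]
) -> float:
    """Mean absolute per-pixel difference between two channel sets.

    ``a`` and ``b`` are single 2-D channels or sequences of them (one per
    image); the mean is taken over all pixels of all images, i.e. the
    empirical L1 risk of predicting one channel by echoing the other.
    """
    a_list = [np.asarray(a)] if isinstance(a, np.ndarray) else [np.asarray(x) for x in a]
    b_list = [np.asarray(b)] if isinstance(b, np.ndarray) else [np.asarray(x) for x in b]
    if len(a_list) != len(b_list):
        raise ValueError("channel sets must pair up image for image")
    total = 0.0
    n = 0
    for xa, xb in zip(a_list, b_list):
        if xa.shape != xb.shape:
            raise ValueError(f"shape mismatch {xa.shape} vs {xb.shape}")
        total += float(np.abs(xa - xb).sum())
        n += xa.size
    if n == 0:
        raise ValueError("empty channel sets")
    return total / n


@dataclass
class NodeCostVector:
    """Per-marker costs q(v) plus their sum."""

    costs: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.costs.values()))

    @property
    def mean(self) -> float:
        return self.total / len(self.costs)


@dataclass
class MarkerGraph:
    """Dense directed complete graph over markers.

    ``loadings`` is an ``N x N`` float matrix with NaN on the (invalid)
    diagonal; ``tags`` records each edge's provenance for auditability.
    """

    markers: list[str]
    loadings: np.ndarray
    tags: np.ndarray  # dtype=object, same shape as loadings
    observed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.markers)
        if len(set(self.markers)) != n:
            raise ValueError("marker names must be unique")
        self.loadings = np.asarray(self.loadings, dtype=np.float64)
        if self.loadings.shape != (n, n):
            raise ValueError("loadings must be N x N")
        off = ~np.eye(n, dtype=bool)
        vals = self.loadings[off]
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("off-diagonal loadings must be finite and >= 0")
        unknown = set(self.observed) - set(self.markers)
        if unknown:
            raise ValueError(f"observed markers not in graph: {sorted(unknown)}")

    # -- basic queries ----------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def predicted(self) -> list[str]:
        obs = set(self.observed)
        return [m for m in self.markers if m not in obs]

    def index(self, marker: str) -> int:
        return self.markers.index(marker)

    def loading(self, i: str, j: str) -> float:
        return float(self.loadings[self.index(i), self.index(j)])

    def is_activated(self, i: str, j: str) -> bool:
        """An edge is activated iff it leaves an observed marker."""
        if i == j:
            raise ValueError("no self-edges")
        return i in self.observed

    def copy(self) -> "MarkerGraph":
        return MarkerGraph(
            list(self.markers),
            self.loadings.copy(),
            self.tags.copy(),
            list(self.observed),
        )

    # -- node costs (min over activated in-edges) -------------------------
    def node_costs(self) -> NodeCostVector:
        """Cost 0 for observed markers; min activated in-edge loading else."""
        if not self.observed:
            raise ValueError("node costs are undefined before any marker is observed")
        obs_idx = [self.index(m) for m in self.observed]
        obs_set = set(self.observed)
        costs: dict[str, float] = {}
        for j, m in enumerate(self.markers):
            if m in obs_set:
                costs[m] = 0.0
            else:
                costs[m] = float(self.loadings[obs_idx, j].min())
        return NodeCostVector(costs)

    # -- risk-driven loading update ---------------------------------------
    def update_edge_loadings(self, risks: Mapping[str, float]) -> None:
        """Overwrite activated edges with the joint model's validation risks.

        For observed ``i`` and predicted ``j``: ``w[i, j] = risks[j]``.
        Both-observed edges are zeroed. Edges leaving predicted markers are
        left untouched.
        """
        predicted = set(self.predicted)
        if set(risks) != predicted:
            raise ValueError(
                f"risks must cover exactly the predicted markers; "
                f"got {sorted(risks)} for predicted {sorted(predicted)}"
            )
        for m, r in risks.items():
            if r < 0 or not np.isfinite(r):
                raise ValueError(f"risk for {m!r} must be finite and >= 0, got {r}")
        obs_idx = [self.index(m) for m in self.observed]
        for j_name, r in risks.items():
            j = self.index(j_name)
            self.loadings[obs_idx, j] = r
            self.tags[obs_idx, j] = TAG_RISK
        for a in obs_idx:
            for b in obs_idx:
                if a != b:
                    self.loadings[a, b] = 0.0
                    self.tags[a, b] = TAG_ZEROED

    def observe(self, marker: str) -> None:
        if marker in self.observed:
            raise ValueError(f"{marker!r} already observed")
        if marker not in self.markers:
            raise ValueError(f"{marker!r} not in graph")
        self.observed.append(marker)

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        n = self.n_markers
        load = [
            [None if i == j else float(self.loadings[i, j]) for j in range(n)]
            for i in range(n)
        ]
        tags = [
            [None if i == j else str(self.tags[i, j]) for j in range(n)]
            for i in range(n)
        ]
        doc = json.dumps(
            {
                "markers": self.markers,
                "observed": self.observed,
                "loadings": load,
                "tags": tags,
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "MarkerGraph":
        if isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc and doc.endswith(".json")):
            doc = Path(doc).read_text()
        data = json.loads(doc)
        n = len(data["markers"])
        loadings = np.array(
            [[np.nan if v is None else v for v in row] for row in data["loadings"]]
        )
        tags = np.empty((n, n), dtype=object)
        for i, row in enumerate(data["tags"]):
            for j, t in enumerate(row):
                tags[i, j] = t
        return cls(data["markers"], loadings, tags, data["observed"])

    def to_edge_csv(self, path: str | Path) -> Path:
        """Edge-list CSV (source, target, loading, tag, activated) for inspection."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "loading", "tag", "activated"])
            for i, a in enumerate(self.markers):
                for j, b in enumerate(self.markers):
                    if i == j:
                        continue
                    w.writerow(
                        [a, b, repr(self.loadings[i, j]), self.tags[i, j],
                         int(a in self.observed)]
                    )
        return path


def _channel_stack(images: Iterable[MultichannelImage], name: str) -> list[np.ndarray]:
    return [img.channel(name) for img in images]


def init_edge_loadings(dataset: MultichannelDataset) -> MarkerGraph:
    """Build the complete graph with loadings = pairwise L1 dissimilarities.

    Dissimilarities are computed over the training split S; the graph starts
    symmetric with an empty observed set and all edges tagged
    ``initial_dissimilarity``.
    """
    names = list(dataset.channel_names)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 markers to build a graph")
    loadings = np.full((n, n), np.nan)
    tags = np.empty((n, n), dtype=object)
    tags[:] = None
    for i in range(n):
        a = _channel_stack(dataset.train_images, names[i])
        for j in range(i + 1, n):
            b = _channel_stack(dataset.train_images, names[j])
            d = dissimilarity(a, b)
            loadings[i, j] = loadings[j, i] = d
            tags[i, j] = tags[j, i] = TAG_INITIAL
    return MarkerGraph(names, loadings, tags)
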