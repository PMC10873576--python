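"""Selection when the marker set is split across overlapping imaging panels.

When more markers are desired than one sample can carry, the markers are
partitioned into panels imaged on different samples, with deliberate overlap
markers shared between panels. Within a panel, edge loadings are the usual
training dissimilarities (averaged across panels for pairs that co-occur in
more than one). Two markers never co-imaged have no measurable
dissimilarity, but if the dissimilarity is a norm the triangle inequality
chains through overlap markers: the loading of a cross-panel edge is the
minimum, over all panel-connecting paths of intra-panel edges, of the summed
leg loadings — an upper bound, found here by Dijkstra shortest path on the
graph restricted to intra-panel edges (equivalent to depth-first search over
all paths with a min, and cheaper).

Each selection round retrains only the model(s) of the panel(s) containing
the newly admitted marker, updates that panel's intra-panel edges with the
per-panel validation risks, and (by default) re-derives the cross-panel
bounds from the current loadings. Markers predicted by several panel models
get the average of their predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .graph import (
    TAG_INFERRED,
    TAG_INITIAL,
    MarkerGraph,
    dissimilarity,
    init_edge_loadings,
)
from .images import MultichannelDataset, MultichannelImage
from .predictors import FittedPredictor
from .selection import (
    PredictorFactory,
    SelectionRound,
    SelectionTrace,
    StoppingCriterion,
    choose_initial_marker,
    expected_improvement,
    stop_satisfied,
)


@dataclass
class PanelLayout:
    """Markers partitioned into overlapping panels with per-panel datasets.

    ``panels`` lists the marker subsets; ``datasets[i]`` (if attached) holds
    the images of panel i restricted to exactly that panel's channels. The
    panel graph — panels as nodes, an edge wherever two panels intersect —
    must be connected, otherwise cross-panel loadings cannot be inferred.
    """

    panels: list[list[str]]
    capacity: Optional[int] = None
    datasets: Optional[list[MultichannelDataset]] = None

    def __post_init__(self) -> None:
        if not self.panels:
            raise ValueError("layout needs at least one panel")
        for p in self.panels:
            if len(set(p)) != len(p):
                raise ValueError("duplicate marker within a panel")
            if self.capacity is not None and len(p) > self.capacity:
                raise ValueError(
                    f"panel of size {len(p)} exceeds capacity {self.capacity}"
                )
        if self.datasets is not None:
            if len(self.datasets) != len(self.panels):
                raise ValueError("one dataset per panel required")
            for p, ds in zip(self.panels, self.datasets):
                if set(ds.channel_names) != set(p):
                    raise ValueError(
                        "panel dataset channels must equal the panel's markers"
                    )
        g = self.panel_graph()
        if not nx.is_connected(g):
            comps = list(nx.connected_components(g))
            raise ValueError(
                f"panel graph is disconnected: isolated panel group {sorted(comps[-1])}"
            )

    @property
    def markers(self) -> list[str]:
        """Union of panels, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.panels:
            for m in p:
                seen.setdefault(m)
        return list(seen)

    @property
    def n_panels(self) -> int:
        return len(self.panels)

    def overlap(self, i: int, j: int) -> set[str]:
        return set(self.panels[i]) & set(self.panels[j])

    def panels_of(self, marker: str) -> list[int]:
        return [i for i, p in enumerate(self.panels) if marker in p]

    def panel_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.panels)))
        for i in range(len(self.panels)):
            for j in range(i + 1, len(self.panels)):
                if self.overlap(i, j):
                    g.add_edge(i, j)
        return g

    # -- persistence -------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"capacity": self.capacity, "panels": self.panels}, indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "PanelLayout":
        if isinstance(doc, Path) or (isinstance(doc, str) and doc.endswith(".json")):
            doc = Path(doc).read_text()
        data = json.loads(doc)
        return cls(panels=data["panels"], capacity=data.get("capacity"))


def mask_dataset_to_layout(
    dataset: MultichannelDataset, layout: PanelLayout
) -> PanelLayout:
    """Simulate multi-panel acquisition by channel-masking a full dataset.

    Each panel receives copies of the train/validation images restricted to
    its own channels (as if that sample had been stained with that panel
    only); test images are left to the caller, who typically evaluates
    merged predictions against the full test split.
    """
    datasets = [
        MultichannelDataset(
            [im.select_channels(p) for im in dataset.train_images],
            [im.select_channels(p) for im in dataset.val_images],
        )
        for p in layout.panels
    ]
    return PanelLayout(layout.panels, layout.capacity, datasets)


@dataclass
class CompletedGraph:
    """A marker graph whose cross-panel edges are chained triangle bounds.

    ``witness[(i, j)]`` records the marker path realizing each inferred
    loading: the sum of the path's intra-panel leg loadings equals the
    stored bound.
    """

    graph: MarkerGraph
    witness: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        data = json.loads(self.graph.to_json())
        data["witness_paths"] = {f"{a}->{b}": p for (a, b), p in self.witness.items()}
        doc = json.dumps(data, indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc


def _intra_panel_edges(
    layout: PanelLayout, panel_graphs: Sequence[MarkerGraph]
) -> dict[tuple[str, str], float]:
    """Directed intra-panel loadings; overlap pairs average across panels."""
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for pg in panel_graphs:
        for a in pg.markers:
            for b in pg.markers:
                if a == b:
                    continue
                key = (a, b)
                sums[key] = sums.get(key, 0.0) + pg.loading(a, b)
                counts[key] = counts.get(key, 0) + 1
    return {k: sums[k] / counts[k] for k in sums}


def complete_cross_panel(
    panel_graphs: Sequence[MarkerGraph], layout: PanelLayout
) -> CompletedGraph:
    """Complete the full graph from per-panel subgraphs.

    Intra-panel edges keep their (panel-averaged) loadings; every
    cross-panel edge gets the minimal path sum over intra-panel edges,
    found by Dijkstra, with the witness path recorded. Directions are
    respected: the bound for ``i -> j`` chains ``i -> q -> ... -> j`` legs.
    """
    markers = layout.markers
    n = len(markers)
    idx = {m: i for i, m in enumerate(markers)}
    intra = _intra_panel_edges(layout, panel_graphs)

    dg = nx.DiGraph()
    dg.add_nodes_from(markers)
    for (a, b), w in intra.items():
        dg.add_edge(a, b, weight=w)

    loadings = np.full((n, n), np.nan)
    tags = np.empty((n, n), dtype=object)
    tags[:] = None
    witness: dict[tuple[str, str], list[str]] = {}

    for (a, b), w in intra.items():
        loadings[idx[a], idx[b]] = w
        tags[idx[a], idx[b]] = TAG_INITIAL

    for a in markers:
        lengths, paths = nx.single_source_dijkstra(dg, a)
        for b in markers:
            if a == b or (a, b) in intra:
                continue
            if b not in lengths:
                raise ValueError(
                    f"no panel-connecting path from {a!r} to {b!r}; "
                    "panel graph must be connected"
                )
            loadings[idx[a], idx[b]] = lengths[b]
            tags[idx[a], idx[b]] = TAG_INFERRED
            witness[(a, b)] = paths[b]

    graph = MarkerGraph(markers, loadings, tags)
    return CompletedGraph(graph, witness)


def init_multipanel_graph(layout: PanelLayout) -> CompletedGraph:
    """Round-0 graph: per-panel dissimilarity subgraphs + chained bounds.

    Three cases: both markers share a panel's overlap with another panel →
    average of the two per-panel dissimilarities; both in one panel →
    that panel's dissimilarity; different panels → minimal chained triangle
    bound over connecting paths.
    """
    if layout.datasets is None:
        raise ValueError("layout must carry per-panel datasets")
    panel_graphs = [init_edge_loadings(ds) for ds in layout.datasets]
    return complete_cross_panel(panel_graphs, layout)


def merge_predictions(
    predictions: Sequence[MultichannelImage],
) -> MultichannelImage:
    """Combine per-panel-model predictions into one image.

    Markers predicted by several models receive the unweighted pixel-wise
    mean; markers from a single model pass through unchanged. Channel order
    is first appearance across the inputs.
    """
    if not predictions:
        raise ValueError("no predictions to merge")
    shape = predictions[0].shape
    for p in predictions:
        if p.shape != shape:
            raise ValueError("all predictions must share the same pixel grid")
    order: list[str] = []
    for p in predictions:
        for m in p.channel_names:
            if m not in order:
                order.append(m)
    out = np.zeros((len(order), *shape))
    for k, m in enumerate(order):
        contribs = [p.channel(m) for p in predictions if m in p.channel_names]
        out[k] = np.mean(contribs, axis=0)
    return MultichannelImage(out, tuple(order), predictions[0].normalized)


def _fit_panel_model(
    layout: PanelLayout,
    predictor_factory: PredictorFactory,
    panel: int,
    observed: Sequence[str],
    seed: int,
) -> Optional[FittedPredictor]:
    """Fit panel ``panel``'s model from its observed channels, if possible.

    Returns None when the panel has no observed marker yet (nothing to
    predict from) or all its markers are observed (nothing to predict).
    """
    assert layout.datasets is not None
    panel_markers = layout.panels[panel]
    obs_in_panel = [m for m in panel_markers if m in set(observed)]
    pred_in_panel = [m for m in panel_markers if m not in set(observed)]
    if not obs_in_panel or not pred_in_panel:
        return None
    return predictor_factory(layout.datasets[panel], obs_in_panel, seed)


def _apply_panel_risks(
    pg: MarkerGraph, observed_in_panel: Sequence[str], risks: dict[str, float]
) -> None:
    """Per-panel analogue of the risk-driven loading update."""
    pg.observed = list(observed_in_panel)
    pg.update_edge_loadings(risks)


def run_multipanel_selection(
    layout: PanelLayout,
    predictor_factory: PredictorFactory,
    stop: StoppingCriterion,
    seed: int = 0,
    refresh_bounds: bool = True,
) -> SelectionTrace:
    """Greedy selection with per-panel retraining on a multi-panel layout.

    Round 0 completes the graph from per-panel dissimilarities. Each round
    retrains only the model(s) of the panel(s) containing the last admitted
    marker (both models when it is an overlap marker), applies that panel's
    validation risks to its intra-panel edges, re-derives the cross-panel
    bounds (unless ``refresh_bounds=False`` freezes the Round-0 bounds) and
    picks the next marker on the completed graph. The trace's per-round
    ``risks`` aggregate the freshest per-panel risks.
    """
    if layout.datasets is None:
        raise ValueError("layout must carry per-panel datasets")
    markers = layout.markers
    if stop.kind == "budget" and stop.budget > len(markers):
        raise ValueError("budget exceeds marker count")

    panel_graphs = [init_edge_loadings(ds) for ds in layout.datasets]
    completed = complete_cross_panel(panel_graphs, layout)
    frozen_round0 = None if refresh_bounds else complete_cross_panel(panel_graphs, layout)

    round_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn((len(markers) + 1) * layout.n_panels)
    ]
    seed_iter = iter(round_seeds)

    graph = completed.graph
    first = choose_initial_marker(graph)
    graph.observe(first)
    observed: list[str] = [first]
    trace = SelectionTrace(initial_marker=first, final_observed=list(observed))
    trace.graph = graph
    panel_models: list[Optional[FittedPredictor]] = [None] * layout.n_panels
    retrained_log: list[list[int]] = []
    last_selected = first

    def rebuild() -> None:
        nonlocal completed, graph
        if refresh_bounds:
            completed = complete_cross_panel(panel_graphs, layout)
        else:
            # keep Round-0 cross-panel bounds, refresh intra-panel edges only
            completed = complete_cross_panel(panel_graphs, layout)
            assert frozen_round0 is not None
            g0 = frozen_round0.graph
            g = completed.graph
            for (a, b), path in frozen_round0.witness.items():
                g.loadings[g.index(a), g.index(b)] = g0.loading(a, b)
                completed.witness[(a, b)] = path
        completed.graph.observed = list(observed)
        graph = completed.graph
        trace.graph = graph

    t = 0
    while not stop_satisfied(stop, trace) and graph.predicted:
        t += 1
        panels_hit = layout.panels_of(last_selected)
        retrained_log.append(panels_hit)
        for p in panels_hit:
            model = _fit_panel_model(
                layout, predictor_factory, p, observed, next(seed_iter)
            )
            panel_models[p] = model
            if model is not None:
                obs_in_panel = [m for m in layout.panels[p] if m in set(observed)]
                _apply_panel_risks(panel_graphs[p], obs_in_panel, model.validation_risk)
        rebuild()
        # freshest per-marker risks across panels (node cost = min in-edge)
        risks: dict[str, float] = {}
        for p, model in enumerate(panel_models):
            if model is None:
                continue
            for m, r in model.validation_risk.items():
                if m not in set(observed):
                    risks[m] = min(risks.get(m, np.inf), r)
        costs = graph.node_costs()
        rec = SelectionRound(
            round=t,
            observed_before=list(observed),
            risks=risks,
            total_cost=costs.total,
            mean_cost=costs.mean,
            selected=None,
            psi=None,
        )
        trace.rounds.append(rec)
        if stop_satisfied(stop, trace) or not graph.predicted:
            break
        pick, psi = expected_improvement(graph)
        rec.selected = pick
        rec.psi = psi
        graph.observe(pick)
        observed.append(pick)
        trace.final_observed = list(observed)
        last_selected = pick

    # ensure every panel model reflects the final observed set (the loop can
    # exit right after an admission, before any retraining on the final set)
    if not trace.rounds or trace.rounds[-1].observed_before != list(observed):
        for p in range(layout.n_panels):
            model = _fit_panel_model(
                layout, predictor_factory, p, observed, next(seed_iter)
            )
            panel_models[p] = model
            if model is not None:
                obs_in_panel = [m for m in layout.panels[p] if m in set(observed)]
                _apply_panel_risks(panel_graphs[p], obs_in_panel, model.validation_risk)
        rebuild()
        costs = graph.node_costs()
        risks = {}
        for model in panel_models:
            if model is None:
                continue
            for m, r in model.validation_risk.items():
                if m not in set(observed):
                    risks[m] = min(risks.get(m, np.inf), r)
        trace.rounds.append(
            SelectionRound(
                round=t + 1,
                observed_before=list(observed),
                risks=risks,
                total_cost=costs.total,
                mean_cost=costs.mean,
                selected=None,
                psi=None,
            )
        )
    trace.final_observed = list(observed)
    trace.panel_models = panel_models  # type: ignore[attr-defined]
    trace.retrained_panels = retrained_log  # type: ignore[attr-defined]
    return trace


def predict_full_image(
    layout: PanelLayout,
    panel_models: Sequence[Optional[FittedPredictor]],
    img: MultichannelImage,
    observed: Sequence[str],
) -> MultichannelImage:
    """Predict every non-observed marker of a full image via the panel models.

    Each trained panel model predicts from the observed channels of its
    panel; multiply-predicted markers are averaged. A marker in no trainable
    panel falls back to the constant (training-mean) prediction — all zeros
    in z-score units — the ERM-optimal constant predictor.
    """
    obs = set(observed)
    targets = [m for m in img.channel_names if m not in obs]
    preds: list[MultichannelImage] = []
    covered: set[str] = set()
    from .predictors import predict as _predict

    for model in panel_models:
        if model is None:
            continue
        wanted = [m for m in model.output_markers if m in targets]
        if not wanted:
            continue
        full = _predict(model, img)
        preds.append(full.select_channels(wanted))
        covered.update(wanted)
    missing = [m for m in targets if m not in covered]
    if missing:
        preds.append(
            MultichannelImage(
                np.zeros((len(missing), *img.shape)), tuple(missing), img.normalized
            )
        )
    merged = merge_predictions(preds)
    return merged.select_channels(targets)
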