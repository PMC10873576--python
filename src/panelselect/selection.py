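"""Greedy selection of a minimal predictive marker set.

The loop maintains the marker graph and a joint predictor. Starting from the
marker with the smallest weighted out-degree, each round (1) fits the
predictor from the currently observed channels by ERM, (2) overwrites the
activated edge loadings with the model's per-marker validation risks,
(3) recomputes node costs, and (4) admits the candidate marker whose
hypothetical observation would most reduce the summed node cost (the
``expectedImprovement`` step), until the stopping criterion holds. A final
model is fit on the final observed set so the trace ends with risks and
costs that describe the returned predictive set.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .graph import MarkerGraph, init_edge_loadings
from .images import MultichannelDataset
from .predictors import FittedPredictor


@dataclass(frozen=True)
class StoppingCriterion:
    """When to stop admitting markers into the predictive set.

    Exactly one kind is active:

    - ``budget``: stop once ``|observed| >= budget`` markers are selected.
    - ``cost_threshold``: stop once the mean node cost drops to ``threshold``.
    - ``relative_improvement``: stop once a round improves the total node
      cost by less than ``min_improvement`` relative to the previous round.
    """

    kind: str = "budget"
    budget: int = 1
    threshold: float = 0.0
    min_improvement: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("budget", "cost_threshold", "relative_improvement"):
            raise ValueError(f"unknown stopping kind {self.kind!r}")
        if self.kind == "budget" and self.budget < 1:
            raise ValueError("budget must be >= 1")
        if self.threshold < 0 or self.min_improvement < 0:
            raise ValueError("threshold and min_improvement must be >= 0")


@dataclass
class SelectionRound:
    """One pass of the loop: train, update loadings, (maybe) pick a marker."""

    round: int
    observed_before: list[str]
    risks: dict[str, float]
    total_cost: float
    mean_cost: float
    selected: Optional[str]  # marker admitted at the end of this round
    psi: Optional[float]  # the winner's expected-improvement value


@dataclass
class SelectionTrace:
    """Full record of a selection run."""

    initial_marker: str
    rounds: list[SelectionRound] = field(default_factory=list)
    final_observed: list[str] = field(default_factory=list)
    graph: Optional[MarkerGraph] = None
    final_model: Optional[FittedPredictor] = None

    @property
    def total_costs(self) -> list[float]:
        return [r.total_cost for r in self.rounds]

    def to_csv(self, path: str | Path) -> Path:
        """Selection log: one row per round plus per-marker risk columns."""
        path = Path(path)
        markers = sorted({m for r in self.rounds for m in r.risks})
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["round", "selected", "psi", "total_cost", "mean_cost"]
                + [f"risk_{m}" for m in markers]
            )
            for r in self.rounds:
                w.writerow(
                    [
                        r.round,
                        r.selected if r.selected is not None else "",
                        "" if r.psi is None else repr(r.psi),
                        repr(r.total_cost),
                        repr(r.mean_cost),
                    ]
                    + ["" if m not in r.risks else repr(r.risks[m]) for m in markers]
                )
        return path

    def write_observed(self, path: str | Path) -> Path:
        Path(path).write_text("\n".join(self.final_observed) + "\n")
        return Path(path)


# ---------------------------------------------------------------------------
# Greedy primitives
# ---------------------------------------------------------------------------

def choose_initial_marker(graph: MarkerGraph, weighted: bool = True) -> str:
    """The marker with minimal (weighted) out-degree; lowest index on ties.

    Before anything is observed no edge is activated and node costs are
    undefined, so the seed marker is picked by out-degree: the sum of
    outgoing loadings (or the plain out-degree count when
    ``weighted=False``, which ties everywhere on a complete graph and falls
    back to the first marker).
    """
    if graph.observed:
        raise ValueError("initial marker is only defined on an empty observed set")
    if graph.n_markers == 0:
        raise ValueError("empty graph")
    if weighted:
        off = ~np.eye(graph.n_markers, dtype=bool)
        sums = np.where(off, graph.loadings, 0.0).sum(axis=1)
    else:
        sums = np.full(graph.n_markers, graph.n_markers - 1, dtype=float)
    return graph.markers[int(np.argmin(sums))]  # argmin takes the first minimum


def expected_improvement(graph: MarkerGraph) -> tuple[str, float]:
    """Best next marker under the hypothetical-cost objective ψ.

    For each candidate ``k`` in the predicted set, compute hypothetical node
    costs with ``k`` treated as observed — the min runs over edges from
    currently observed markers or from ``k``, and both ``k`` and the
    observed markers cost 0 — and sum them into ``ψ(k)``. Returns the
    candidate minimizing ψ (lowest marker index on ties) with its ψ value.
    """
    candidates = graph.predicted
    if not candidates:
        raise ValueError("predicted set is empty; nothing to select")
    obs_idx = [graph.index(m) for m in graph.observed]
    obs_set = set(graph.observed)
    best: tuple[float, int, str] | None = None
    for k_name in candidates:
        k = graph.index(k_name)
        psi = 0.0
        for j, m in enumerate(graph.markers):
            if m in obs_set or j == k:
                continue
            psi += float(graph.loadings[obs_idx + [k], j].min())
        key = (psi, k)
        if best is None or key < best[:2]:
            best = (psi, k, k_name)
    assert best is not None
    return best[2], best[0]


def stop_satisfied(stop: StoppingCriterion, trace: SelectionTrace) -> bool:
    """Evaluate the stopping criterion against the trace so far."""
    if stop.kind == "budget":
        return len(trace.final_observed) >= stop.budget
    if not trace.rounds:
        return False
    if stop.kind == "cost_threshold":
        return trace.rounds[-1].mean_cost <= stop.threshold
    # relative_improvement
    if len(trace.rounds) < 2:
        return False
    prev, last = trace.rounds[-2].total_cost, trace.rounds[-1].total_cost
    if prev <= 0:
        return True
    return (prev - last) / prev < stop.min_improvement


# ---------------------------------------------------------------------------
# The full loop
# ---------------------------------------------------------------------------

PredictorFactory = Callable[[MultichannelDataset, Sequence[str], int], FittedPredictor]


def run_selection(
    dataset: MultichannelDataset,
    predictor_factory: PredictorFactory,
    stop: StoppingCriterion,
    seed: int = 0,
    graph: MarkerGraph | None = None,
) -> SelectionTrace:
    """Run the greedy selection loop on a single panel.

    Parameters
    ----------
    dataset
        Normalized train/validation(/test) splits over the full marker set.
    predictor_factory
        ``(dataset, observed, round_seed) -> FittedPredictor``; refit each
        round on the training split. Round seeds are spawned from ``seed``
        so reruns with the same seed reproduce the trace exactly.
    stop
        Stopping criterion; a ``budget`` of B yields exactly B observed
        markers.
    graph
        Optional pre-initialized graph (used by the multi-panel driver);
        by default the graph is initialized from training dissimilarities.

    Returns
    -------
    SelectionTrace
        Round-by-round log, the final graph, the final observed set and a
        model fit on that final set.
    """
    names = list(dataset.channel_names)
    if stop.kind == "budget" and stop.budget > len(names):
        raise ValueError(
            f"budget {stop.budget} exceeds the {len(names)} available markers"
        )
    if graph is None:
        graph = init_edge_loadings(dataset)
    round_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(names) + 1)
    ]

    first = choose_initial_marker(graph)
    graph.observe(first)
    trace = SelectionTrace(initial_marker=first, final_observed=list(graph.observed))
    trace.graph = graph

    t = 0
    while not stop_satisfied(stop, trace) and graph.predicted:
        t += 1
        try:
            model = predictor_factory(dataset, list(graph.observed), round_seeds[t - 1])
        except Exception as exc:
            raise RuntimeError(
                f"predictor failed in round {t} "
                f"(observed={graph.observed})"
            ) from exc
        risks = dict(model.validation_risk)
        graph.update_edge_loadings(risks)
        costs = graph.node_costs()
        rec = SelectionRound(
            round=t,
            observed_before=list(graph.observed),
            risks=risks,
            total_cost=costs.total,
            mean_cost=costs.mean,
            selected=None,
            psi=None,
        )
        trace.rounds.append(rec)
        trace.final_model = model
        if stop_satisfied(stop, trace) or not graph.predicted:
            break
        pick, psi = expected_improvement(graph)
        rec.selected = pick
        rec.psi = psi
        graph.observe(pick)
        trace.final_observed = list(graph.observed)

    # final model for the final observed set (the loop above trains on the
    # set *before* its last admission)
    if graph.predicted and (
        trace.final_model is None
        or set(trace.final_model.input_markers) != set(graph.observed)
    ):
        model = predictor_factory(dataset, list(graph.observed), round_seeds[-1])
        risks = dict(model.validation_risk)
        graph.update_edge_loadings(risks)
        costs = graph.node_costs()
        trace.rounds.append(
            SelectionRound(
                round=t + 1,
                observed_before=list(graph.observed),
                risks=risks,
                total_cost=costs.total,
                mean_cost=costs.mean,
                selected=None,
                psi=None,
            )
        )
        trace.final_model = model
    trace.final_observed = list(graph.observed)
    return trace
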