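import itertools

import numpy as np
import pytest

from panelselect import (
    MultichannelImage,
    PredictorSpec,
    StoppingCriterion,
    SyntheticConfig,
    complete_cross_panel,
    generate_dataset,
    init_multipanel_graph,
    make_factory,
    merge_predictions,
    run_multipanel_selection,
    run_selection,
)
from panelselect.cli import chained_layout
from panelselect.graph import TAG_INFERRED, TAG_INITIAL, MarkerGraph
from panelselect.multipanel import (
    PanelLayout,
    mask_dataset_to_layout,
    predict_full_image,
)


def graph_from_loadings(markers, pairs):
    """Symmetric MarkerGraph from {(a, b): w} (both directions)."""
    n = len(markers)
    loadings = np.full((n, n), np.nan)
    tags = np.empty((n, n), dtype=object)
    tags[:] = None
    idx = {m: i for i, m in enumerate(markers)}
    for (a, b), w in pairs.items():
        loadings[idx[a], idx[b]] = loadings[idx[b], idx[a]] = w
        tags[idx[a], idx[b]] = tags[idx[b], idx[a]] = TAG_INITIAL
    return MarkerGraph(list(markers), loadings, tags)


def brute_force_cross(panel_graphs, layout, a, b):
    """Min over ALL simple marker paths of summed intra-panel leg loadings."""
    intra = {}
    for pg in panel_graphs:
        for x in pg.markers:
            for y in pg.markers:
                if x != y:
                    key = (x, y)
                    intra.setdefault(key, []).append(pg.loading(x, y))
    intra = {k: float(np.mean(v)) for k, v in intra.items()}
    markers = layout.markers
    best = np.inf
    others = [m for m in markers if m not in (a, b)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = [a, *mid, b]
            total = 0.0
            ok = True
            for x, y in zip(path, path[1:]):
                if (x, y) not in intra:
                    ok = False
                    break
                total += intra[(x, y)]
            if ok:
                best = min(best, total)
    return best


class TestPanelLayout:
    def test_connectivity_required(self):
        with pytest.raises(ValueError, match="disconnected"):
            PanelLayout([["A", "B"], ["C", "D"]])

    def test_capacity_enforced(self):
        with pytest.raises(ValueError, match="capacity"):
            PanelLayout([["A", "B", "C"], ["C", "D"]], capacity=2)

    def test_json_round_trip(self, tmp_path):
        layout = PanelLayout([["A", "B", "M"], ["M", "C"]], capacity=3)
        path = tmp_path / "layout.json"
        path.write_text(layout.to_json())
        back = PanelLayout.from_json(path)
        assert back.panels == layout.panels
        assert back.capacity == 3

    def test_chained_layout_is_balanced_and_connected(self):
        markers = [f"M{i:02d}" for i in range(12)]
        panels = chained_layout(markers, 3, 4)
        layout = PanelLayout(panels)
        sizes = [len(p) for p in panels]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(layout.markers) == sorted(markers)
        for i in range(2):
            assert len(layout.overlap(i, i + 1)) == 4


class TestThreeCaseInit:
    @pytest.fixture
    def two_panel_layout(self, rng):
        # panels {1,2,M}, {M,3}; hand-set channels so dissimilarities differ
        base = rng.normal(size=(8, 8))
        names_a = ("X1", "X2", "XM")
        names_b = ("XM", "X3")
        chans_a = np.stack([base, base + 0.1, base + 0.3])
        chans_b = np.stack([base + 0.32, base + 0.52])  # XM shifts differ per panel
        from .conftest import make_dataset

        ds_a = make_dataset([[chans_a], []], names_a)
        ds_b = make_dataset([[chans_b], []], names_b)
        return PanelLayout([["X1", "X2", "XM"], ["XM", "X3"]], datasets=[ds_a, ds_b])

    def test_same_panel_pairs_use_panel_dissimilarity(self, two_panel_layout):
        completed = init_multipanel_graph(two_panel_layout)
        g = completed.graph
        assert g.loading("X1", "X2") == pytest.approx(0.1)
        assert g.loading("X1", "XM") == pytest.approx(0.3)
        assert g.loading("XM", "X3") == pytest.approx(0.2)

    def test_cross_panel_single_path_triangle_bound(self, two_panel_layout):
        completed = init_multipanel_graph(two_panel_layout)
        g = completed.graph
        # X1 -> XM -> X3 = 0.3 + 0.2
        assert g.loading("X1", "X3") == pytest.approx(0.5)
        i, j = g.index("X1"), g.index("X3")
        assert g.tags[i, j] == TAG_INFERRED
        assert completed.witness[("X1", "X3")] == ["X1", "XM", "X3"]

    def test_overlap_pair_averages_the_two_panels(self, rng):
        from .conftest import make_dataset

        base = rng.normal(size=(8, 8))
        ds_a = make_dataset([[np.stack([base, base + 0.2, base])], []], ("M1", "M2", "A"))
        ds_b = make_dataset([[np.stack([base, base + 0.4, base])], []], ("M1", "M2", "B"))
        layout = PanelLayout(
            [["M1", "M2", "A"], ["M1", "M2", "B"]], datasets=[ds_a, ds_b]
        )
        g = init_multipanel_graph(layout).graph
        assert g.loading("M1", "M2") == pytest.approx(0.3)  # (0.2 + 0.4) / 2


class TestCompleteCrossPanel:
    def test_two_overlap_markers_pick_the_cheaper_path(self):
        pg_a = graph_from_loadings(
            ["X1", "M", "Mp"], {("X1", "M"): 0.3, ("X1", "Mp"): 0.5, ("M", "Mp"): 0.9}
        )
        pg_b = graph_from_loadings(
            ["M", "Mp", "X3"], {("M", "X3"): 0.2, ("Mp", "X3"): 0.2, ("M", "Mp"): 0.9}
        )
        layout = PanelLayout([["X1", "M", "Mp"], ["M", "Mp", "X3"]])
        completed = complete_cross_panel([pg_a, pg_b], layout)
        # X1-M-X3 = 0.5 vs X1-Mp-X3 = 0.7
        assert completed.graph.loading("X1", "X3") == pytest.approx(0.5)
        assert completed.witness[("X1", "X3")] == ["X1", "M", "X3"]

    def test_all_zero_loadings_infer_zero(self):
        pg_a = graph_from_loadings(["A", "M"], {("A", "M"): 0.0})
        pg_b = graph_from_loadings(["M", "B"], {("M", "B"): 0.0})
        layout = PanelLayout([["A", "M"], ["M", "B"]])
        completed = complete_cross_panel([pg_a, pg_b], layout)
        assert completed.graph.loading("A", "B") == 0.0

    def test_witness_legs_sum_to_stored_loading(self, rng):
        layouts = random_layouts(rng, 5)
        for layout, pgs in layouts:
            completed = complete_cross_panel(pgs, layout)
            g = completed.graph
            intra = {}
            for pg in pgs:
                for x in pg.markers:
                    for y in pg.markers:
                        if x != y:
                            intra.setdefault((x, y), []).append(pg.loading(x, y))
            intra = {k: float(np.mean(v)) for k, v in intra.items()}
            for (a, b), path in completed.witness.items():
                legs = sum(intra[(x, y)] for x, y in zip(path, path[1:]))
                assert g.loading(a, b) == pytest.approx(legs)

    def test_equals_exhaustive_path_enumeration(self, rng):
        for layout, pgs in random_layouts(rng, 8):
            completed = complete_cross_panel(pgs, layout)
            g = completed.graph
            in_same_panel = {
                frozenset((a, b))
                for p in layout.panels
                for a in p
                for b in p
                if a != b
            }
            for a in layout.markers:
                for b in layout.markers:
                    if a == b or frozenset((a, b)) in in_same_panel:
                        continue
                    oracle = brute_force_cross(pgs, layout, a, b)
                    assert g.loading(a, b) == pytest.approx(oracle), (a, b)


def random_layouts(rng, count):
    """Random chained layouts (<= 4 panels, <= 9 markers) with random loadings."""
    out = []
    for _ in range(count):
        n_panels = int(rng.integers(2, 5))
        n_markers = int(rng.integers(n_panels + 2, 10))
        markers = [f"m{i}" for i in range(n_markers)]
        panels = chained_layout(markers, n_panels, 1)
        layout = PanelLayout(panels)
        pgs = []
        for p in panels:
            pairs = {
                (a, b): float(rng.uniform(0.01, 1.0))
                for ai, a in enumerate(p)
                for b in p[ai + 1 :]
            }
            pgs.append(graph_from_loadings(p, pairs))
        out.append((layout, pgs))
    return out


class TestMergePredictions:
    def test_mean_of_two(self):
        a = MultichannelImage(np.full((1, 2, 2), 1.0), ("M",))
        b = MultichannelImage(np.full((1, 2, 2), 3.0), ("M",))
        out = merge_predictions([a, b])
        np.testing.assert_array_equal(out.pixels, 2.0)

    def test_single_model_marker_passes_through(self, rng):
        x = rng.normal(size=(1, 3, 3))
        a = MultichannelImage(x, ("M",))
        b = MultichannelImage(rng.normal(size=(1, 3, 3)), ("N",))
        out = merge_predictions([a, b])
        np.testing.assert_array_equal(out.channel("M"), x[0])

    def test_three_models_elementwise_oracle(self, rng):
        imgs = [MultichannelImage(rng.normal(size=(1, 4, 4)), ("M",)) for _ in range(3)]
        out = merge_predictions(imgs)
        oracle = np.mean([im.pixels[0] for im in imgs], axis=0)
        np.testing.assert_allclose(out.channel("M"), oracle)

    def test_grid_mismatch_errors(self, rng):
        a = MultichannelImage(rng.normal(size=(1, 2, 2)), ("M",))
        b = MultichannelImage(rng.normal(size=(1, 3, 3)), ("M",))
        with pytest.raises(ValueError, match="grid"):
            merge_predictions([a, b])


class TestRunMultipanelSelection:
    def test_single_panel_layout_degenerates_to_run_selection(self, noisy_dataset):
        ds, _ = noisy_dataset
        stop = StoppingCriterion(kind="budget", budget=4)
        layout = mask_dataset_to_layout(ds, PanelLayout([list(ds.channel_names)]))
        tm = run_multipanel_selection(layout, make_factory(PredictorSpec()), stop, seed=5)
        ts = run_selection(ds, make_factory(PredictorSpec()), stop, seed=5)
        assert tm.final_observed == ts.final_observed
        assert tm.initial_marker == ts.initial_marker
        np.testing.assert_allclose(tm.total_costs, ts.total_costs)

    def test_non_overlap_marker_retrains_exactly_one_panel(self, noisy_dataset):
        ds, _ = noisy_dataset
        panels = chained_layout(list(ds.channel_names), 3, 2)
        layout = mask_dataset_to_layout(ds, PanelLayout(panels))
        stop = StoppingCriterion(kind="budget", budget=5)
        trace = run_multipanel_selection(layout, make_factory(PredictorSpec()), stop, seed=2)
        overlap = {
            m
            for i in range(3)
            for j in range(i + 1, 3)
            for m in layout.overlap(i, j)
        }
        picks = [trace.initial_marker] + [
            r.selected for r in trace.rounds if r.selected is not None
        ]
        for pick, panels_hit in zip(picks, trace.retrained_panels):
            expected = 2 if pick in overlap else 1
            assert len(panels_hit) >= expected if pick in overlap else len(panels_hit) == 1

    def test_identical_seed_identical_trace(self, noisy_dataset):
        ds, _ = noisy_dataset
        panels = chained_layout(list(ds.channel_names), 3, 4)
        layout = mask_dataset_to_layout(ds, PanelLayout(panels))
        stop = StoppingCriterion(kind="budget", budget=6)
        t1 = run_multipanel_selection(layout, make_factory(PredictorSpec()), stop, seed=9)
        t2 = run_multipanel_selection(layout, make_factory(PredictorSpec()), stop, seed=9)
        assert t1.final_observed == t2.final_observed
        assert t1.total_costs == t2.total_costs

    def test_parity_with_single_panel_at_study_conditions(self, noisy_dataset):
        """3 chained panels (overlap 4) track the single-panel test MSE."""
        ds, _ = noisy_dataset
        panels = chained_layout(list(ds.channel_names), 3, 4)
        layout = mask_dataset_to_layout(ds, PanelLayout(panels))
        stop = StoppingCriterion(kind="budget", budget=8)
        tm = run_multipanel_selection(layout, make_factory(PredictorSpec()), stop, seed=1)
        ts = run_selection(ds, make_factory(PredictorSpec()), stop, seed=1)
        from panelselect import predict

        model = ts.final_model
        single = float(
            np.mean(
                [
                    np.mean(
                        (predict(model, im).pixels
                         - im.select_channels(model.output_markers).pixels) ** 2
                    )
                    for im in ds.test_images
                ]
            )
        )
        multi_vals = []
        for im in ds.test_images:
            pred = predict_full_image(layout, tm.panel_models, im, tm.final_observed)
            real = im.select_channels(pred.channel_names)
            multi_vals.append(float(np.mean((pred.pixels - real.pixels) ** 2)))
        multi = float(np.mean(multi_vals))
        assert abs(single - multi) / single <= 0.25
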