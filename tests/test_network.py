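"""Similarity network assembly and exploratory views."""

import itertools
import warnings

import numpy as np
import pytest

from covrec import network, synthetic
from covrec.coverage import DatasetProfile, DatasetRecord
from covrec.network import (
    SimilarityEdge,
    add_dataset,
    build_network,
    compare_all,
    fit_pca,
    hierarchical_dendrogram,
    layout_force_directed,
)


def _record(did, cell_type="heart", target=None, experiment_type="RNA-seq", **kw):
    return DatasetRecord(did, f"e-{did}", "toy1", experiment_type, cell_type, target, **kw)


class TestSimilarityEdge:
    def test_canonical_order_and_pair(self):
        e = SimilarityEdge("zz", "aa", True, False)
        assert (e.dataset_id_a, e.dataset_id_b) == ("aa", "zz")
        assert e == SimilarityEdge("aa", "zz", True, False)

    def test_self_edges_and_flagless_edges_rejected(self):
        with pytest.raises(ValueError):
            SimilarityEdge("a", "a", True, False)
        with pytest.raises(ValueError):
            SimilarityEdge("a", "b", False, False)


class TestCompareAll:
    def test_identical_metadata_gives_complete_graph(self, ontology_set):
        records = {f"d{i}": _record(f"d{i}") for i in range(3)}
        edges = compare_all({}, records, {}, ontology_set)
        assert len(edges) == 3
        assert all(e.by_metadata and not e.by_primary for e in edges)

    def test_different_experiment_types_never_compared(self, ontology_set):
        records = {
            "d0": _record("d0", experiment_type="RNA-seq"),
            "d1": _record("d1", experiment_type="ChIP-seq", target="H3K4me3"),
        }
        assert compare_all({}, records, {}, ontology_set) == set()

    def test_argument_order_invariance(self, ontology_set):
        records = {f"d{i}": _record(f"d{i}", ct) for i, ct in
                   enumerate(["heart", "cardiomyocyte", "neuron", "brain"])}
        fwd = compare_all({}, records, {}, ontology_set)
        rev = compare_all({}, dict(reversed(records.items())), {}, ontology_set)
        assert fwd == rev

    def test_mislabeled_dataset_linked_by_primary_only(
        self, ontology_set, trained_model, small_cohort
    ):
        # a stem-signal dataset annotated as neuron: coverage says stem,
        # metadata says nothing shared with the stem group
        matrix, records = small_cohort
        profiles, recs = {}, {}
        for rec, row in zip(records[:5], matrix[:5]):  # 5 stem-signal datasets
            profiles[rec.dataset_id] = DatasetProfile(
                rec.dataset_id, rec.experiment_id, "toy1", "RNA-seq", "transcript", row
            )
            recs[rec.dataset_id] = rec
        mislabeled = _record("d0000_bad", "neuron")
        recs["d0000_bad"] = mislabeled
        profiles["d0000_bad"] = DatasetProfile(
            "d0000_bad", "x", "toy1", "RNA-seq", "transcript", matrix[5]
        )
        models = {("toy1", "RNA-seq", "cell_type"): trained_model}
        edges = compare_all(profiles, recs, models, ontology_set)
        bad_edges = [e for e in edges if "d0000_bad" in e.pair]
        assert bad_edges and all(e.by_primary and not e.by_metadata for e in bad_edges)

    def test_missing_profile_falls_back_to_metadata_with_warning(
        self, ontology_set, trained_model
    ):
        records = {"d0": _record("d0"), "d1": _record("d1")}
        models = {("toy1", "RNA-seq", "cell_type"): trained_model}
        with pytest.warns(UserWarning, match="no profile"):
            edges = compare_all({}, records, models, ontology_set)
        assert len(edges) == 1 and next(iter(edges)).by_metadata


class TestIncrementalUpdate:
    def test_add_dataset_agrees_with_full_recompute(self, ontology_set):
        rng = np.random.default_rng(2)
        cells = ["heart", "cardiomyocyte", "neuron", "brain", "embryonic stem cell"]
        for trial in range(10):
            ids = [f"d{i}" for i in range(int(rng.integers(3, 10)))]
            records = {d: _record(d, str(rng.choice(cells))) for d in ids}
            new_id = ids[-1]
            without = {d: r for d, r in records.items() if d != new_id}
            base = compare_all({}, without, {}, ontology_set)
            incremental = add_dataset(base, new_id, {}, records, {}, ontology_set)
            full = compare_all({}, records, {}, ontology_set)
            assert incremental == full
            # incrementality: only edges touching the new dataset were added
            assert all(new_id in e.pair for e in incremental - base)


class TestBuildNetwork:
    def test_no_edges_gives_isolated_nodes(self):
        records = {"a": _record("a", "heart"), "b": _record("b", "neuron")}
        net = build_network([], records)
        assert net.graph.number_of_nodes() == 2 and net.graph.number_of_edges() == 0

    def test_same_annotation_collapses_to_one_sized_node(self):
        records = {f"d{i}": _record(f"d{i}", "heart", "GATA4") for i in range(3)}
        net = build_network([], records)
        assert net.graph.number_of_nodes() == 1
        node = next(iter(net.graph.nodes(data=True)))
        assert node[1]["size"] == 3

    def test_node_sizes_conserve_dataset_count_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        cells = ["heart", "neuron", "brain", "esc", "cm"]
        targets = [None, "GATA4", "H3K4me3"]
        for _ in range(1000):
            n = int(rng.integers(1, 15))
            records = {
                f"d{i}": _record(
                    f"d{i}", str(rng.choice(cells)), rng.choice(targets)
                )
                for i in range(n)
            }
            ids = sorted(records)
            edges = {
                SimilarityEdge(a, b, True, bool(rng.integers(2)))
                for a, b in itertools.combinations(ids, 2)
                if rng.random() < 0.2
            }
            net = build_network(edges, records)
            assert net.total_datasets == n

    def test_intergroup_edge_flags_or_over_member_pairs(self):
        records = {
            "a1": _record("a1", "heart"), "a2": _record("a2", "heart"),
            "b1": _record("b1", "neuron"),
        }
        edges = [
            SimilarityEdge("a1", "b1", True, False),
            SimilarityEdge("a2", "b1", False, True),
        ]
        net = build_network(edges, records)
        (u, v, data), = net.graph.edges(data=True)
        assert data["by_primary"] and data["by_metadata"]


class TestLayout:
    def test_single_node_at_origin(self):
        net = build_network([], {"a": _record("a")})
        coords = layout_force_directed(net, seed=0)
        assert list(coords.values()) == [(0.0, 0.0)]

    def test_deterministic_for_fixed_seed(self):
        records = {f"d{i}": _record(f"d{i}", f"cell{i}") for i in range(6)}
        edges = {SimilarityEdge(f"d{i}", f"d{i+1}", True, True) for i in range(5)}
        net = build_network(edges, records)
        assert layout_force_directed(net, seed=5) == layout_force_directed(net, seed=5)

    def test_cliques_stay_closer_than_the_bridge(self):
        # two 5-cliques joined by one edge: intra-clique distances should
        # be smaller on average than inter-clique ones
        records = {f"d{i}": _record(f"d{i}", f"cell{i}") for i in range(10)}
        edges = set()
        for group in (range(5), range(5, 10)):
            for a, b in itertools.combinations(group, 2):
                edges.add(SimilarityEdge(f"d{a}", f"d{b}", True, True))
        edges.add(SimilarityEdge("d0", "d5", True, True))
        net = build_network(edges, records)
        coords = layout_force_directed(net, seed=1)
        xy = {k: np.array(v) for k, v in coords.items()}
        keys = {i: f"cell{i}|-" for i in range(10)}
        intra, inter = [], []
        for a, b in itertools.combinations(range(10), 2):
            d = np.linalg.norm(xy[keys[a]] - xy[keys[b]])
            (intra if (a < 5) == (b < 5) else inter).append(d)
        assert np.mean(intra) < np.mean(inter)


def _naive_average_linkage(D):
    """Brute-force agglomeration oracle: merge closest clusters, average
    over all inter-cluster point pairs."""
    clusters = {i: [i] for i in range(D.shape[0])}
    merges = []
    next_id = D.shape[0]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((d, sorted(clusters[a] + clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestDendrogram:
    def test_identical_profiles_merge_at_height_zero(self):
        row = np.abs(np.random.default_rng(0).normal(size=50)) * 100
        matrix = np.vstack([row, row, row * 0 + 1])
        dg = hierarchical_dendrogram(matrix, ["a", "b", "c"])
        assert dg.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_leaf_count_matches_dataset_count(self, small_cohort):
        matrix, records = small_cohort
        ids = [r.dataset_id for r in records[:12]]
        dg = hierarchical_dendrogram(matrix[:12], ids)
        newick = dg.to_newick()
        assert all(i in newick for i in ids)
        assert dg.linkage_matrix.shape == (11, 4)

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_dendrogram(np.ones((1, 5)), ["a"])

    def test_matches_naive_average_linkage_oracle(self):
        rng = np.random.default_rng(4)
        matrix = np.abs(rng.normal(size=(4, 30))) * 50
        from covrec.network import _profile_distance_matrix

        D = _profile_distance_matrix(matrix)
        expected = _naive_average_linkage(D)
        dg = hierarchical_dendrogram(matrix, ["a", "b", "c", "d"])
        np.testing.assert_allclose(
            dg.merge_heights, [m[0] for m in expected], rtol=1e-9
        )

    def test_merge_heights_are_ultrametric(self, small_cohort):
        matrix, _ = small_cohort
        dg = hierarchical_dendrogram(matrix[:20], [f"d{i}" for i in range(20)])
        heights = dg.merge_heights
        assert np.all(np.diff(heights) >= -1e-12)


class TestPCA:
    def test_reference_projection_equals_fit_scores(self, small_cohort):
        matrix, _ = small_cohort
        model = fit_pca(matrix[:30])
        np.testing.assert_allclose(
            model.project(matrix[:30]), model.pca.transform(np.log2(matrix[:30] + 1))
        )

    def test_mean_profile_projects_to_origin(self):
        rng = np.random.default_rng(6)
        ref = np.abs(rng.normal(size=(20, 10)))
        model = fit_pca(ref, log_transform=False)
        np.testing.assert_allclose(model.project(ref.mean(axis=0)), 0.0, atol=1e-9)

    def test_pc1_aligns_with_planted_axis(self):
        rng = np.random.default_rng(7)
        t = rng.normal(size=200)
        axis = np.ones(12) / np.sqrt(12)
        data = 50 + 10 * t[:, None] * axis[None, :] + 0.1 * rng.normal(size=(200, 12))
        model = fit_pca(data, log_transform=False)
        coords = model.project(data)
        corr = np.corrcoef(coords[:, 0], t)[0, 1]
        assert abs(corr) >= 0.99

    def test_projection_never_refits_and_checks_dimensions(self, small_cohort):
        matrix, _ = small_cohort
        model = fit_pca(matrix[:20])
        before = model.pca.components_.copy()
        model.project(matrix[25])
        np.testing.assert_array_equal(model.pca.components_, before)
        with pytest.raises(ValueError, match="features"):
            model.project(np.ones(3))


def test_edge_serialization_round_trip(tmp_path):
    edges = {
        SimilarityEdge("a", "b", True, False),
        SimilarityEdge("b", "c", False, True),
        SimilarityEdge("a", "c", True, True),
    }
    network.write_edges(edges, tmp_path / "edges.json")
    assert network.read_edges(tmp_path / "edges.json") == edges


def test_network_json_export_includes_coordinates(tmp_path):
    records = {"a": _record("a", "heart"), "b": _record("b", "neuron")}
    net = build_network({SimilarityEdge("a", "b", True, False)}, records)
    layout_force_directed(net, seed=0)
    doc = net.to_json(tmp_path / "net.json")
    assert {n["id"] for n in doc["nodes"]} == {"heart|-", "neuron|-"}
    assert all("x" in n and "y" in n for n in doc["nodes"])
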