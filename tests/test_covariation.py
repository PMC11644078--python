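import numpy as np
import pandas as pd
import pytest

from metabodyn.covariation import (
    build_network,
    cluster_dynamics,
    cluster_nodes,
    correlation_matrix,
    layout_signed,
    pathway_pair_correlations,
)
from metabodyn.table import MeanProfileMatrix, PathwayAnnotation


def _profiles(rows, names=None):
    rows = np.asarray(rows, dtype=float)
    days = list(range(1, rows.shape[1] + 1))
    names = names or [f"m{i}" for i in range(rows.shape[0])]
    return MeanProfileMatrix(
        values=pd.DataFrame(rows, index=names, columns=days), days=days
    )


class TestCorrelationMatrix:
    def test_affine_copy_perfect_correlation(self):
        prof = _profiles([[1, 2, 3, 4], [2, 4, 6, 8]])
        for method in ("pearson", "spearman"):
            c = correlation_matrix(prof, method)
            assert c.iloc[0, 1] == pytest.approx(1.0)

    def test_spearman_hand_example(self):
        prof = _profiles([[1, 2, 3], [10, 30, 20]])
        c = correlation_matrix(prof, "spearman")
        assert c.iloc[0, 1] == pytest.approx(0.5)

    def test_reversed_profile_anticorrelated(self):
        prof = _profiles([[1, 2, 3], [3, 2, 1]])
        c = correlation_matrix(prof, "pearson")
        assert c.iloc[0, 1] == pytest.approx(-1.0)

    def test_too_few_timepoints_rejected(self):
        prof = _profiles([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="time points"):
            correlation_matrix(prof)

    def test_symmetric_unit_diagonal_constant_zeroed(self):
        prof = _profiles([[1, 2, 3, 1], [5, 5, 5, 5], [0, 1, 0, 2]])
        c = correlation_matrix(prof)
        np.testing.assert_allclose(c.to_numpy(), c.to_numpy().T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.iloc[0, 1] == 0.0  # constant profile: undefined -> 0


class TestBuildNetwork:
    def test_threshold_application_with_signs(self):
        corr = pd.DataFrame(
            [[1.0, 0.99, -0.99], [0.99, 1.0, 0.10], [-0.99, 0.10, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        net = build_network(corr, threshold=0.85)
        assert net.graph.number_of_edges() == 2
        assert net.graph["a"]["b"]["sign"] == 1
        assert net.graph["a"]["c"]["sign"] == -1

    def test_extreme_threshold_no_edges(self):
        rng = np.random.default_rng(0)
        prof = _profiles(rng.normal(size=(5, 6)))
        net = build_network(correlation_matrix(prof), threshold=0.999999)
        assert net.graph.number_of_edges() == 0

    def test_duplicate_metabolite_single_unit_edge(self):
        prof = _profiles([[1, 2, 3, 0], [1, 2, 3, 0], [0, -5, 2, 1]])
        net = build_network(correlation_matrix(prof), threshold=0.95)
        assert net.graph.number_of_edges() == 1
        assert net.graph["m0"]["m1"]["r"] == pytest.approx(1.0)

    def test_invalid_threshold_rejected(self):
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                build_network(corr, threshold=bad)

    def test_edge_count_matches_superthreshold_pairs(self):
        rng = np.random.default_rng(1)
        prof = _profiles(rng.normal(size=(12, 8)))
        corr = correlation_matrix(prof)
        net = build_network(corr, threshold=0.5)
        r = corr.to_numpy()
        iu, ju = np.triu_indices(12, k=1)
        assert net.graph.number_of_edges() == int((np.abs(r[iu, ju]) > 0.5).sum())
        assert not any(u == v for u, v in net.graph.edges())


class TestLayout:
    def test_positive_pair_closer_than_negative(self):
        corr = pd.DataFrame(
            [
                [1.0, 0.95, 0.0, 0.0],
                [0.95, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, -0.95],
                [0.0, 0.0, -0.95, 1.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        net = build_network(corr, threshold=0.85)
        pos = layout_signed(net, seed=0, iterations=80)
        d_pos = np.linalg.norm(pos.loc["a"] - pos.loc["b"])
        d_neg = np.linalg.norm(pos.loc["c"] - pos.loc["d"])
        assert d_pos < d_neg

    def test_same_seed_identical_coordinates(self):
        rng = np.random.default_rng(2)
        prof = _profiles(rng.normal(size=(10, 6)))
        net = build_network(correlation_matrix(prof), threshold=0.5)
        a = layout_signed(net, seed=5, iterations=30)
        b = layout_signed(net, seed=5, iterations=30)
        pd.testing.assert_frame_equal(a, b)

    def test_centered_at_origin(self):
        rng = np.random.default_rng(3)
        prof = _profiles(rng.normal(size=(8, 6)))
        net = build_network(correlation_matrix(prof), threshold=0.5)
        pos = layout_signed(net, seed=1, iterations=30)
        np.testing.assert_allclose(pos.mean(axis=0), 0.0, atol=1e-9)

    def test_two_block_structure_separates(self):
        # two planted blocks of strongly correlated profiles
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            base1, base2 = rng.normal(size=(2, 8))
            rows = [base1 + 0.1 * rng.normal(size=8) for _ in range(6)]
            rows += [base2 + 0.1 * rng.normal(size=8) for _ in range(6)]
            net = build_network(correlation_matrix(_profiles(rows)), threshold=0.6)
            pos = layout_signed(net, seed=seed, iterations=80).to_numpy()
            within = np.mean(
                [np.linalg.norm(pos[i] - pos[j]) for g in (range(6), range(6, 12))
                 for i in g for j in g if i < j]
            )
            between = np.mean(
                [np.linalg.norm(pos[i] - pos[j]) for i in range(6) for j in range(6, 12)]
            )
            ok += within < between
        assert ok >= 9


class TestClusterNodes:
    def _blob_network(self):
        corr = pd.DataFrame(np.eye(6), index=[f"m{i}" for i in range(6)],
                            columns=[f"m{i}" for i in range(6)])
        net = build_network(corr, threshold=0.85)
        net.layout = pd.DataFrame(
            np.array([[0, 0], [0.1, 0], [0, 0.1], [5, 5], [5.1, 5], [5, 5.1]]),
            index=corr.index, columns=["x", "y"],
        )
        return net

    def test_two_blobs_exact_partition(self):
        net = self._blob_network()
        labels = cluster_nodes(net, k=2, seed=0)
        assert len(set(labels.iloc[:3])) == 1
        assert len(set(labels.iloc[3:])) == 1
        assert labels.iloc[0] != labels.iloc[3]

    def test_k_equals_nodes_singletons(self):
        net = self._blob_network()
        labels = cluster_nodes(net, k=6, seed=0)
        assert labels.nunique() == 6

    def test_k_below_two_rejected(self):
        net = self._blob_network()
        with pytest.raises(ValueError):
            cluster_nodes(net, k=1)

    def test_labels_ordered_by_size(self):
        net = self._blob_network()
        net.layout.iloc[5] = [0.05, 0.05]  # make first blob larger
        labels = cluster_nodes(net, k=2, seed=0)
        sizes = labels.value_counts()
        assert sizes.loc[0] >= sizes.loc[1]


class TestClusterDynamics:
    def test_singleton_cluster(self):
        prof = _profiles([[0.0, 1.0, 2.0]])
        labels = pd.Series([0], index=["m0"])
        classes = pd.Series(["sugars"], index=["m0"])
        (d,) = cluster_dynamics(labels, prof, classes)
        np.testing.assert_allclose(d.median, [0, 1, 2])
        np.testing.assert_allclose(d.q75 - d.q25, 0.0)

    def test_median_of_two(self):
        prof = _profiles([[0.0, 1.0], [0.0, 3.0]])
        labels = pd.Series([0, 0], index=["m0", "m1"])
        classes = pd.Series(["a", "b"], index=["m0", "m1"])
        (d,) = cluster_dynamics(labels, prof, classes)
        np.testing.assert_allclose(d.median, [0.0, 2.0])

    def test_composition_sums_to_cluster_sizes(self, small_dataset, small_processed):
        from metabodyn.preprocess import aggregate_means

        prof = aggregate_means(small_processed)
        net = build_network(correlation_matrix(prof), threshold=0.85)
        layout_signed(net, seed=0, iterations=50)
        labels = cluster_nodes(net, k=4, seed=0)
        for d in cluster_dynamics(labels, prof, small_processed.classes()):
            assert sum(d.composition.values()) == d.size


class TestPathwayPairContrast:
    def test_single_pathway_all_inside(self):
        corr = pd.DataFrame(
            np.array([[1, 0.5, 0.2], [0.5, 1, -0.1], [0.2, -0.1, 1]]),
            index=list("abc"), columns=list("abc"),
        )
        ann = PathwayAnnotation(sets={"P": ("", ("a", "b", "c"))})
        pc = pathway_pair_correlations(corr, ann)
        assert pc.inside.size == 3 and pc.outside.size == 0

    def test_two_pathway_enumeration(self):
        names = ["m1", "m2", "m3", "m4"]
        rng = np.random.default_rng(0)
        r = rng.uniform(-1, 1, (4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r, index=names, columns=names)
        ann = PathwayAnnotation(sets={"P1": ("", ("m1", "m2")), "P2": ("", ("m3", "m4"))})
        pc = pathway_pair_correlations(corr, ann)
        assert pc.inside.size == 2 and pc.outside.size == 4
        assert pc.all_pairs.size == 6
        assert set(pc.per_pathway) == {"P1", "P2"}

    def test_partition_accounts_for_unannotated(self):
        names = [f"m{i}" for i in range(6)]
        rng = np.random.default_rng(1)
        r = rng.uniform(-1, 1, (6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = pd.DataFrame(r, index=names, columns=names)
        ann = PathwayAnnotation(sets={"P1": ("", ("m0", "m1")), "P2": ("", ("m2", "m3"))})
        pc = pathway_pair_correlations(corr, ann)
        unannotated_pairs = pc.all_pairs.size - pc.inside.size - pc.outside.size
        # pairs touching m4/m5 (unannotated): 4*2/... = C(6,2)-C(4,2) = 9
        assert unannotated_pairs == 9

    def test_no_annotated_pair_rejected(self):
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        ann = PathwayAnnotation(sets={"P": ("", ("zz",))})
        with pytest.raises(ValueError, match="no metabolite pair"):
            pathway_pair_correlations(corr, ann)

    def test_coupling_shifts_inside_median(self):
        from metabodyn.preprocess import aggregate_means, preprocess
        from metabodyn.simulate import SimulationConfig, simulate_metabolome

        shifts = {}
        quiet = {"early": 0.0, "late": 0.0}
        for c in (0.9, 0.0):
            vals = []
            for seed in range(3):
                ds = simulate_metabolome(
                    SimulationConfig(seed=seed, n_metabolites=240,
                                     within_pathway_coupling=c,
                                     phase_noise_coupling=quiet)
                )
                prof = aggregate_means(preprocess(ds.table))
                corr = correlation_matrix(prof, "spearman")
                vals.append(pathway_pair_correlations(corr, ds.truth_pathways).median_shift)
            shifts[c] = np.mean(vals)
        assert shifts[0.9] > shifts[0.0]
        assert shifts[0.9] > 0
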