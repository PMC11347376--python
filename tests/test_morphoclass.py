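import numpy as np
import pandas as pd
import pytest

from vesselmorph.efd_core import descriptor_table
from vesselmorph.morphoclass import (
    classify_samples,
    cut_tree,
    export_newick,
    hcluster,
    sample_mean_fd,
    silhouette_report,
)
from vesselmorph.reference_shapes import (
    SyntheticSample,
    default_sample_specs,
    make_panel,
    make_sample_set,
)

from ._oracles import scipy_average_linkage

D_COLS = ["D1", "D2", "D3", "D4", "D5"]


def _fd(rows, ids=None, k=5):
    ids = ids if ids is not None else [f"s{i}" for i in range(len(rows))]
    df = pd.DataFrame(np.asarray(rows, dtype=float),
                      columns=[f"D{i+1}" for i in range(k)])
    df.insert(0, "sample_id", ids)
    return df


class TestSampleMeans:
    def test_mean_of_two_vessels(self):
        tab = pd.DataFrame(
            {
                "sample_id": ["s", "s"],
                "vessel_id": ["a", "b"],
                "D1": [1.0, 3.0], "D2": [0.0, 2.0],
                "D3": [0.0, 0.0], "D4": [0.0, 0.0], "D5": [0.0, 0.0],
            }
        )
        out = sample_mean_fd(tab)
        assert out.loc[0, ["D1", "D2"]].tolist() == [2.0, 1.0]
        assert out.loc[0, "n_vessels"] == 2

    def test_single_vessel_sample_is_its_own_mean(self):
        tab = pd.DataFrame(
            {"sample_id": ["x"], "vessel_id": ["v"],
             "D1": [1.3], "D2": [0.1], "D3": [0.0], "D4": [0.0], "D5": [0.0]}
        )
        out = sample_mean_fd(tab)
        assert out.loc[0, "D1"] == 1.3

    def test_vessel_order_irrelevant(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.random((12, 5)), columns=D_COLS)
        tab.insert(0, "sample_id", list("aabbcc") * 2)
        tab.insert(1, "vessel_id", [f"v{i}" for i in range(12)])
        shuffled = tab.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            sample_mean_fd(tab), sample_mean_fd(shuffled)
        )

    def test_missing_values_rejected(self):
        tab = _fd([[1, 0, 0, 0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            sample_mean_fd(tab)


class TestHCluster:
    def test_three_point_line_heights_by_hand(self):
        # 1-D rows {0, 1, 5}: merge (0,1) at 1; then average linkage distance
        # to 5 is (|0-5| + |1-5|)/2 = 4.5
        m = _fd([[0, 0, 0, 0, 0], [1, 0, 0, 0, 0], [5, 0, 0, 0, 0]],
                ids=["a", "b", "c"])
        dend = hcluster(m)
        np.testing.assert_allclose(dend.heights, [1.0, 4.5])
        # topology ((a,b),c): the singleton keeps its lower cluster id and
        # is rendered first
        assert export_newick(dend) == "(c:4.5,(a:1,b:1):3.5);"

    def test_identical_rows_merge_at_zero(self):
        m = _fd([[1, 2, 0, 0, 0], [1, 2, 0, 0, 0], [4, 0, 0, 0, 0]])
        assert hcluster(m).heights[0] == 0.0

    def test_duplicate_ids_rejected(self):
        m = _fd([[0] * 5, [1] * 5], ids=["x", "x"])
        with pytest.raises(ValueError, match="duplicate"):
            hcluster(m)

    @pytest.mark.parametrize("seed", range(100))
    def test_merge_heights_match_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        x = rng.random((n, 5))
        dend = hcluster(_fd(x))
        np.testing.assert_allclose(
            dend.heights, scipy_average_linkage(x), atol=1e-9
        )
        assert np.all(np.diff(dend.heights) >= -1e-12)


class TestCutTree:
    def test_extreme_cuts(self):
        m = _fd(np.random.default_rng(1).random((6, 5)))
        dend = hcluster(m)
        assert cut_tree(dend, 6).nunique() == 6
        assert cut_tree(dend, 1).nunique() == 1

    def test_panel_cut_recovers_designed_classes(self):
        contours, labels = make_panel(n_per_class=6, seed=2)
        tab = descriptor_table(contours).rename(columns={"vessel_id": "row"})
        dend = hcluster(tab, id_col="row")
        clusters = cut_tree(dend, 5).to_numpy()
        df = pd.DataFrame({"cluster": clusters, "label": labels})
        purity = df.groupby("cluster")["label"].agg(
            lambda s: s.value_counts().iloc[0] / len(s)
        )
        assert (purity == 1.0).all()
        assert df["cluster"].nunique() == 5

    def test_invalid_k_rejected(self):
        dend = hcluster(_fd([[0] * 5, [1] * 5]))
        with pytest.raises(ValueError):
            cut_tree(dend, 3)


class TestClassify:
    def _group_means(self, seed, n_per_group=4):
        specs = default_sample_specs(n_per_group=n_per_group, n_vessels=10,
                                     seed=seed)
        by_sample, truth = make_sample_set(specs)
        flat = [c for v in by_sample.values() for c in v]
        means = sample_mean_fd(descriptor_table(flat))
        means["label"] = means["sample_id"].map(truth)
        return means, truth

    def test_sample_at_centroid_gets_zero_distance(self):
        panel = _fd([[1.4, 0, 0, 0, 0], [1.1, 0.2, 0, 0, 0]], ids=["p0", "p1"])
        panel["label"] = ["circular", "indented"]
        sample = _fd([[1.4, 0, 0, 0, 0]], ids=["q"])
        out = classify_samples(sample, panel, method="centroid")
        assert out.loc[0, "label"] == "circular"
        assert out.loc[0, "distance"] == pytest.approx(0.0)

    @pytest.mark.parametrize("method", ["centroid", "cocluster"])
    def test_pure_class_zero_noise_samples_fully_recovered(self, method):
        specs = [
            SyntheticSample(f"{g}_{i}", g, n_vessels=6, weights={c: 1.0},
                            seed=10 * i + j, noise=0.0)
            for j, (g, c) in enumerate(
                [("normal", "circular"), ("indented", "indented"),
                 ("angular", "rectangular")]
            )
            for i in range(3)
        ]
        by_sample, truth = make_sample_set(specs)
        flat = [c for v in by_sample.values() for c in v]
        means = sample_mean_fd(descriptor_table(flat))
        panel, _ = self._group_means(seed=500)
        out = classify_samples(means, panel, method=method)
        out["truth"] = out["sample_id"].map(truth)
        assert (out["label"] == out["truth"]).all()
        assert not out["fallback"].any()

    def test_three_group_recovery_with_both_methods(self):
        samples, truth = self._group_means(seed=17)
        panel, _ = self._group_means(seed=23)
        for method in ("centroid", "cocluster"):
            out = classify_samples(
                samples.drop(columns="label"), panel, method=method
            )
            out["truth"] = out["sample_id"].map(truth)
            assert (out["label"] == out["truth"]).all(), method

    def test_descriptor_mismatch_rejected(self):
        panel = _fd([[1, 0, 0, 0, 0]], ids=["p"])
        panel["label"] = ["circular"]
        sample = _fd([[1, 0, 0]], ids=["q"], k=3)
        with pytest.raises(ValueError, match="descriptor"):
            classify_samples(sample, panel)


class TestNewickExport:
    def test_two_leaf_tree(self):
        m = _fd([[0, 0, 0, 0, 0], [2, 0, 0, 0, 0]], ids=["A", "B"])
        assert export_newick(hcluster(m)) == "(A:2,B:2);"

    def test_round_trips_through_newick_parser(self):
        import skbio

        contours, _ = make_panel(n_per_class=3, seed=5)
        tab = descriptor_table(contours).rename(columns={"vessel_id": "row"})
        dend = hcluster(tab, id_col="row")
        tree = skbio.TreeNode.read([export_newick(dend)])
        assert sorted(t.name for t in tree.tips()) == sorted(dend.ids)
        # total height of every tip equals its merge-root height
        root_height = dend.heights[-1]
        for tip in tree.tips():
            assert tip.accumulate_to_ancestor(tree) == pytest.approx(
                root_height, abs=1e-6
            )


class TestSilhouette:
    def test_report_covers_requested_range(self):
        contours, _ = make_panel(n_per_class=4, seed=6)
        tab = descriptor_table(contours).rename(columns={"vessel_id": "row"})
        dend = hcluster(tab, id_col="row")
        rep = silhouette_report(tab.rename(columns={"row": "sample_id"}), dend)
        assert rep["k"].tolist() == [2, 3, 4, 5, 6]
        assert rep["mean_silhouette"].between(-1, 1).all()
        # the designed panel has exactly 5 classes; silhouette should peak there
        assert rep.loc[rep["mean_silhouette"].idxmax(), "k"] == 5
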