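import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from trackmigrate.clustering import (
    ClusterModel,
    assign,
    default_mode_map,
    elbow_scan,
    feature_dendrogram_groups,
    fit_reference_model,
    map_modes,
    mode_composition,
    reorder_clusters,
)
from trackmigrate.track_io import FeatureTable


def _blob_table(seed=0, n_per=50, sep=20.0, n_features=6, groups=None):
    """Three well-separated Gaussian blobs; feature 0 is 'speed_mean' with
    blob means descending so reordering is testable."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((3, n_features))
    centers[0, 0], centers[1, 0], centers[2, 0] = 3 * sep, 2 * sep, sep
    for i in range(3):
        centers[i, 1:] = rng.normal(0, sep, n_features - 1)
    rows, labels = [], []
    for i in range(3):
        rows.append(centers[i] + rng.normal(0, 1.0, size=(n_per, n_features)))
        labels += [i] * n_per
    x = np.vstack(rows)
    names = ["speed_mean"] + [f"f{j}" for j in range(1, n_features)]
    df = pd.DataFrame(x, columns=names, index=[f"t{i}" for i in range(len(x))])
    df.insert(0, "group", groups if groups is not None else "control")
    return FeatureTable(data=df), np.array(labels)


class TestFit:
    def test_three_blobs_perfect_recovery(self):
        table, truth = _blob_table(seed=1)
        model = fit_reference_model(table, k=3, seed=0)
        labels = assign(model, table)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicate_rows_leave_centers_unchanged(self):
        table, _ = _blob_table(seed=2)
        doubled = FeatureTable(data=pd.concat([table.data, table.data.set_axis(
            [f"d{i}" for i in range(len(table.data))])]))
        m1 = fit_reference_model(table, k=3, seed=0)
        m2 = fit_reference_model(doubled, k=3, seed=0)
        np.testing.assert_allclose(
            np.sort(m1.centers, axis=0), np.sort(m2.centers, axis=0), atol=1e-6
        )

    def test_deterministic_given_seed(self):
        table, _ = _blob_table(seed=3)
        m1 = fit_reference_model(table, k=3, seed=7)
        m2 = fit_reference_model(table, k=3, seed=7)
        np.testing.assert_array_equal(m1.centers, m2.centers)

    def test_k_exceeding_reference_size_is_error(self):
        table, _ = _blob_table(seed=4, n_per=3)
        with pytest.raises(ValueError, match="fewer than k"):
            fit_reference_model(table, k=50)

    def test_zero_variance_feature_dropped_with_warning(self):
        table, _ = _blob_table(seed=5)
        table.data["constant"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            model = fit_reference_model(table, k=3, seed=0)
        assert "constant" not in model.feature_names

    def test_variance_threshold_met(self):
        table, _ = _blob_table(seed=6)
        model = fit_reference_model(table, k=3, variance_threshold=0.95, seed=0)
        assert model.explained_variance_ratio.sum() >= 0.95

    def test_affine_rescaling_of_feature_is_absorbed(self):
        table, _ = _blob_table(seed=7)
        scaled = FeatureTable(data=table.data.copy())
        scaled.data["f1"] = scaled.data["f1"] * 10.0 + 5.0
        l1 = assign(fit_reference_model(table, k=3, seed=0), table)
        l2 = assign(fit_reference_model(scaled, k=3, seed=0), scaled)
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_json_round_trip(self, tmp_path):
        table, _ = _blob_table(seed=8)
        model = fit_reference_model(table, k=3, seed=0)
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ClusterModel.from_json(p)
        np.testing.assert_allclose(back.centers, model.centers)
        assert back.mode_map == model.mode_map
        np.testing.assert_array_equal(assign(back, table), assign(model, table))


class TestAssign:
    def test_reference_rows_keep_fit_labels(self):
        table, _ = _blob_table(seed=9)
        model = fit_reference_model(table, k=3, seed=0)
        l1 = assign(model, table)
        l2 = assign(model, table)
        np.testing.assert_array_equal(l1, l2)

    def test_row_at_center_assigned_to_it(self):
        table, _ = _blob_table(seed=10)
        model = fit_reference_model(table, k=3, seed=0)
        # invert the transform for center 1: z = P^T c, x = z * sd + mean
        z = model.centers[1] @ model.components
        x = z * model.feature_sds + model.feature_means
        probe = pd.DataFrame([x], columns=model.feature_names, index=["probe"])
        probe.insert(0, "group", "control")
        assert assign(model, FeatureTable(data=probe)).iloc[0] == 1

    def test_missing_descriptor_is_error(self):
        table, _ = _blob_table(seed=11)
        model = fit_reference_model(table, k=3, seed=0)
        crippled = FeatureTable(data=table.data.drop(columns=["f2"]))
        with pytest.raises(ValueError, match="f2"):
            assign(model, crippled)

    def test_same_distribution_gives_same_proportions(self):
        """A treated cohort drawn from the reference distribution lands in
        clusters with reference-like proportions."""
        big, _ = _blob_table(seed=12, n_per=400)
        half = big.data.index[::2]
        other = big.data.index[1::2]
        table = FeatureTable(data=big.data.loc[half])
        fresh = FeatureTable(data=big.data.loc[other])
        model = fit_reference_model(table, k=3, seed=0)
        p_ref = assign(model, table).value_counts(normalize=True).sort_index()
        p_new = assign(model, fresh).value_counts(normalize=True).sort_index()
        assert np.abs(p_ref - p_new).max() < 0.05


class TestElbow:
    def test_inertia_non_increasing_and_zero_at_n(self):
        table, _ = _blob_table(seed=14, n_per=8)
        n = len(table.data)
        scan = elbow_scan(table, [2, 3, 6, n], n_init=5)
        inertia = scan["inertia"].to_numpy()
        assert np.all(np.diff(inertia) <= 1e-9)
        assert inertia[-1] == pytest.approx(0.0, abs=1e-9)

    def test_three_blob_elbow_at_three(self):
        table, _ = _blob_table(seed=15)
        scan = elbow_scan(table, [2, 3, 4, 5], n_init=5)
        inertia = scan["inertia"].to_numpy()
        drops = inertia[:-1] / inertia[1:]
        assert np.argmax(drops) == 0  # 2 -> 3 is the big relative drop


class TestReorder:
    def test_fastest_blob_becomes_cluster_zero(self):
        table, truth = _blob_table(seed=16)
        model = fit_reference_model(table, k=3, seed=0)  # reorders by default
        labels = assign(model, table)
        # blob 0 was built with the highest speed_mean
        assert labels[truth == 0].mode()[0] == 0
        assert labels[truth == 2].mode()[0] == 2

    def test_idempotent(self):
        table, _ = _blob_table(seed=17)
        model = fit_reference_model(table, k=3, seed=0)
        again = reorder_clusters(model, table)
        np.testing.assert_allclose(again.centers, model.centers)

    def test_composition_invariant_under_relabeling(self):
        table, _ = _blob_table(seed=18)
        model = fit_reference_model(table, k=3, seed=0, reorder=False)
        labels_a = assign(model, table)
        labels_b = assign(reorder_clusters(model, table), table)
        counts_a = np.sort(labels_a.value_counts().to_numpy())
        counts_b = np.sort(labels_b.value_counts().to_numpy())
        np.testing.assert_array_equal(counts_a, counts_b)


class TestDendrogram:
    def test_correlated_descriptors_co_group(self):
        rng = np.random.default_rng(19)
        base = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "a": base,
                "a_twin": base * 2 + 3,  # perfectly correlated after z-score
                "b": rng.normal(size=200),
                "c": rng.normal(size=200),
            },
            index=[f"t{i}" for i in range(200)],
        )
        df.insert(0, "group", "control")
        groups = feature_dendrogram_groups(FeatureTable(data=df), n_groups=3)
        assert groups["a"] == groups["a_twin"]

    def test_planted_blocks_recovered(self):
        """9 latent signals, 2 descriptors each: the 9-group cut pairs them."""
        rng = np.random.default_rng(20)
        latents = rng.normal(size=(300, 9))
        cols = {}
        for j in range(9):
            cols[f"s{j}a"] = latents[:, j] + rng.normal(0, 0.01, 300)
            cols[f"s{j}b"] = latents[:, j] * 1.5 + rng.normal(0, 0.01, 300)
        df = pd.DataFrame(cols, index=[f"t{i}" for i in range(300)])
        df.insert(0, "group", "control")
        groups = feature_dendrogram_groups(FeatureTable(data=df), n_groups=9)
        assert len(set(groups.values())) == 9
        for j in range(9):
            assert groups[f"s{j}a"] == groups[f"s{j}b"]


class TestModes:
    def test_default_map_at_k10(self):
        m = default_mode_map(10)
        assert [m[i] for i in range(10)] == (
            ["Directed"] * 4 + ["Exploratory"] * 3 + ["Confined"] * 3
        )

    def test_map_modes_requires_coverage(self):
        labels = pd.Series([0, 1, 2], index=list("abc"))
        with pytest.raises(ValueError, match="mode_map lacks"):
            map_modes(labels, {0: "Directed", 1: "Confined"})

    def test_composition_arithmetic(self):
        modes = pd.Series(
            ["Directed"] * 4 + ["Exploratory"] * 2 + ["Confined"] * 4
            + ["Directed"] * 2 + ["Exploratory"] * 4 + ["Confined"] * 4,
            index=[f"t{i}" for i in range(20)],
        )
        groups = pd.Series(["control"] * 10 + ["drug"] * 10, index=modes.index)
        comp = mode_composition(modes, groups)
        assert np.allclose(comp.proportions.sum(axis=1), 1.0)
        assert comp.proportions.loc["control", "Directed"] == pytest.approx(0.4)
        # Directed: 0.2 treated vs 0.4 control -> fold change 0.5
        assert comp.fold_change.loc["drug", "Directed"] == pytest.approx(0.5)
        assert np.allclose(comp.fold_change.loc["control"], 1.0)

    def test_missing_control_warns(self):
        modes = pd.Series(["Directed", "Confined"], index=["a", "b"])
        groups = pd.Series(["drug", "drug"], index=modes.index)
        with pytest.warns(UserWarning, match="absent"):
            comp = mode_composition(modes, groups)
        assert comp.fold_change is None
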