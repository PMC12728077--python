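"""Colour classification: threshold rule, clustering, PCA, ranges."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

from fruitlab.classify import (
    HarvestColorClassifier,
    agreement,
    classify_harvest,
    derive_category_ranges,
    intensity_from_note,
    kmeans_fit,
    map_ripeness_clusters,
    pca_scores,
    purple_k2_intensity_map,
    select_k,
    silhouette_mean,
)
from fruitlab.panel import DEFAULT_CATEGORY_MIX, HARVEST_SPECS, PanelConfig, generate_panel

# --- independent oracles -------------------------------------------------


def brute_silhouette(points, labels):
    points, labels = np.asarray(points, float), np.asarray(labels)
    n = len(points)
    d = np.sqrt(((points[:, None] - points[None, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            vals.append(0.0)
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def brute_ari(x, y):
    x, y = np.asarray(x), np.asarray(y)
    both = same_x = same_y = 0
    n = len(x)
    for i, j in itertools.combinations(range(n), 2):
        sx, sy = x[i] == x[j], y[i] == y[j]
        both += sx and sy
        same_x += sx
        same_y += sy
    pairs = n * (n - 1) / 2
    expected = same_x * same_y / pairs
    max_index = (same_x + same_y) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


# --- threshold classification --------------------------------------------


class TestHarvestClassifier:
    @pytest.mark.parametrize(
        "lab, label",
        [
            ((80, 0, 10), "white"),
            ((50, -12, 20), "green"),
            ((30, 6, -6), "purple-violet"),
            ((30, 6, 0), "purple-red"),
            ((70, -20, 5), "white"),  # L* checked first
        ],
    )
    def test_threshold_rule(self, lab, label):
        cat = classify_harvest(lab)
        assert cat.full_label == label

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 100), st.floats(-40, 40), st.floats(-40, 40))
    def test_total_function_with_margin_flags(self, L, a, b):
        cat = classify_harvest((L, a, b))
        assert cat.label in ("white", "green", "purple")
        near = (
            abs(L - 70) < 2
            or (L < 70 and abs(a + 5) < 2)
            or (cat.label == "purple" and abs(b + 2.5) < 2)
        )
        assert bool(cat.borderline) == near

    def test_green_pulp_context_on_borderline(self):
        cat = classify_harvest((50, -4.5, 5), pulp_green=True)
        assert cat.label == "purple" and "green pulp" in cat.borderline

    def test_sklearn_estimator_interface(self):
        clf = HarvestColorClassifier()
        X = np.array([[80.0, 0, 10], [50, -12, 20]])
        assert list(clf.fit(X).predict(X)) == ["white", "green"]
        assert clf.get_params()["l_white"] == 70.0
        assert clf.set_params(l_white=75).predict([[72, 0, 0]])[0] != "white"

    def test_intensity_notes(self):
        assert [intensity_from_note(k) for k in (1, 4, 5, 6, 7, 9)] == [
            "light", "light", "medium", "medium", "dark", "dark",
        ]
        with pytest.raises(ValueError):
            intensity_from_note(0)


# --- K-means, silhouette, model selection ---------------------------------


class TestKMeans:
    def test_k1_centroid_is_mean(self, rng):
        X = rng.normal(size=(30, 3))
        m = kmeans_fit(X, 1, seed=0)
        assert np.allclose(m.cluster_centers_[0], X.mean(axis=0))
        assert m.wcss_ == pytest.approx(((X - X.mean(0)) ** 2).sum(), rel=1e-9)

    def test_k_equals_n_gives_zero_wcss(self, rng):
        X = rng.normal(size=(6, 3))
        assert kmeans_fit(X, 6, seed=0).wcss_ == pytest.approx(0.0, abs=1e-9)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_fit(rng.normal(size=(3, 3)), 5)

    def test_separated_clouds_recovered(self, rng):
        truth = np.repeat([0, 1, 2], 40)
        centers = np.array([[75, 4, 35], [55, 12, 22], [32, 9, 9]], float)
        X = centers[truth] + rng.normal(0, 3, size=(120, 3))
        m = kmeans_fit(X, 3, seed=0)
        _, ari = agreement(m.labels_, truth)
        assert ari >= 0.9

    def test_lloyd_iterations_never_increase_wcss(self, rng):
        X = rng.normal(size=(200, 3))
        w = [
            KMeans(4, init="k-means++", n_init=1, max_iter=it, random_state=7)
            .fit(X).inertia_
            for it in (1, 2, 5, 50)
        ]
        assert all(x >= y - 1e-9 for x, y in zip(w, w[1:]))


class TestSilhouette:
    def test_matches_brute_force_oracle(self):
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [8, 8, 8], [9, 8, 8], [8, 9, 9], [4, 4, 4], [20, 0, 0]],
            float,
        )
        labels = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        assert silhouette_mean(pts, labels) == pytest.approx(
            brute_silhouette(pts, labels), abs=1e-12
        )

    def test_tight_far_pairs_approach_one(self):
        pts = np.array([[0, 0], [0.01, 0], [100, 0], [100.01, 0]])
        assert silhouette_mean(pts, [0, 0, 1, 1]) > 0.99

    def test_identical_points_give_zero(self):
        pts = np.ones((6, 3))
        assert silhouette_mean(pts, [0, 0, 0, 1, 1, 1]) == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.ones((4, 2)), [0, 0, 0, 0])


class TestSelectK:
    def test_two_coincident_clouds_select_two(self, rng):
        X = np.vstack([np.tile([0.0, 0, 0], (10, 1)), np.tile([50.0, 0, 0], (10, 1))])
        X += rng.normal(0, 0.01, X.shape)
        assert select_k(X, range(2, 6), seed=0).silhouette_k == 2

    def test_three_ripeness_clouds_select_three(self, default_panel):
        p = default_panel.truth.accessions[["P_L", "P_a", "P_b"]].to_numpy()
        res = select_k(p, range(2, 9), seed=0)
        assert res.silhouette_k == 3
        assert {"K", "wcss", "silhouette", "wcss_second_diff"} <= set(res.diagnostics.columns)

    def test_range_validation(self, rng):
        with pytest.raises(ValueError):
            select_k(rng.normal(size=(10, 3)), range(1, 4))


# --- descriptor mapping ----------------------------------------------------


class TestDescriptorMaps:
    def _model(self, centers, k):
        X = np.repeat(np.asarray(centers, float), 10, axis=0)
        X += np.random.default_rng(0).normal(0, 0.1, X.shape)
        return kmeans_fit(X, k, seed=0)

    def test_ripeness_ordered_by_lightness(self):
        m = self._model([[75, 4, 35], [55, 12, 22], [35, 9, 9]], 3)
        mapping = map_ripeness_clusters(m)
        by_l = {mapping[int(np.argmax(m.cluster_centers_[:, 0]))],
                mapping[int(np.argmin(m.cluster_centers_[:, 0]))]}
        assert by_l == {"yellow", "brown"}
        assert sorted(mapping.values()) == ["brown", "ochre", "yellow"]

    def test_ripeness_tie_broken_by_yellowness(self):
        m = self._model([[50, 5, 30], [50, 5, 5], [20, 5, 5]], 3)
        m.cluster_centers_[:, 0] = np.round(m.cluster_centers_[:, 0], 0)  # force L* tie
        mapping = map_ripeness_clusters(m)
        tied = [i for i in range(3) if m.cluster_centers_[i, 0] == 50]
        yellower = max(tied, key=lambda i: m.cluster_centers_[i, 2])
        assert mapping[yellower] == "yellow"

    def test_ripeness_requires_k3(self):
        with pytest.raises(ValueError):
            map_ripeness_clusters(self._model([[10, 0, 0], [50, 0, 0]], 2))

    def test_purple_k2_dark_is_lower_lightness(self):
        m = self._model([[28, 5, -6], [45, 5, -6]], 2)
        mapping = purple_k2_intensity_map(m)
        dark = int(np.argmin(m.cluster_centers_[:, 0]))
        assert mapping[dark] == "dark" and mapping[1 - dark] == "light/medium"

    def test_purple_k2_recovers_dark_vs_light(self):
        mix = {k: 0.0 for k in DEFAULT_CATEGORY_MIX}
        mix.update(violet_light=0.3, red_light=0.2, violet_dark=0.3, red_dark=0.2)
        p = generate_panel(PanelConfig(category_mix=mix, seed=6))
        t = p.truth.accessions
        m = kmeans_fit(t[["H_L", "H_a", "H_b"]].to_numpy(), 2, seed=0).map_purple_intensity()
        _, ari = agreement(m.descriptor_labels(), t.intensity.to_numpy())
        assert ari >= 0.8

    def test_purple_map_requires_k2(self):
        with pytest.raises(ValueError):
            purple_k2_intensity_map(self._model([[10, 0, 0], [50, 0, 0], [80, 0, 0]], 3))


# --- agreement -------------------------------------------------------------


class TestAgreement:
    def test_identical_labelings(self):
        _, ari = agreement([0, 0, 1, 1, 2], [5, 5, 6, 6, 7])
        assert ari == pytest.approx(1.0)

    def test_constant_labeling(self):
        _, ari = agreement([0, 0, 0, 0], [0, 1, 0, 1])
        assert ari == pytest.approx(0.0)

    def test_matches_pair_counting_oracle(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 1, 2, 0]
        table, ari = agreement(a, b)
        assert ari == pytest.approx(brute_ari(a, b), abs=1e-12)
        assert table.to_numpy().sum() == 6

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 3), min_size=4, max_size=12), st.permutations(range(4)))
    def test_invariant_under_label_permutation(self, labels, perm):
        other = list(range(len(labels)))
        _, ari1 = agreement(labels, other)
        _, ari2 = agreement([perm[v] for v in labels], other)
        assert ari1 == pytest.approx(ari2, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            agreement([0, 1], [0, 1, 2])


# --- PCA -------------------------------------------------------------------


class TestPca:
    def test_collinear_points_explained_by_pc1(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([t, 2 * t, -t]) + 5
        res = pca_scores(X)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance(self, rng):
        X = rng.normal(size=(4000, 3))
        res = pca_scores(X)
        assert res.explained[0] == pytest.approx(1 / 3, abs=0.05)

    def test_matches_rank2_svd_reconstruction(self, rng):
        X = rng.normal(size=(40, 3)) @ np.diag([3.0, 1.5, 0.5])
        Z = (X - X.mean(0)) / X.std(0)
        res = pca_scores(X)
        recon = res.scores.to_numpy() @ res.loadings
        u, s, vt = np.linalg.svd(Z, full_matrices=False)
        svd_err = ((Z - u[:, :2] * s[:2] @ vt[:2]) ** 2).sum()
        assert ((Z - recon) ** 2).sum() == pytest.approx(svd_err, rel=1e-9)

    def test_zero_variance_column_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError):
            pca_scores(X)


# --- category ranges -------------------------------------------------------


class TestCategoryRanges:
    def test_single_accession_degenerate_box(self):
        df = pd.DataFrame({"L": [50.0], "a": [5.0], "b": [-6.0], "label": ["violet"]})
        (r,) = derive_category_ranges(df)
        assert r.lab_min == r.lab_max
        assert len(set(r.hex_codes)) == 1 and len(r.gradient) == 8

    def test_synthetic_white_box_inside_generator_truncation(self, default_panel):
        t = default_panel.truth.accessions
        white = t[t.harvest_category == "white"]
        df = white[["H_L", "H_a", "H_b"]].rename(columns={"H_L": "L", "H_a": "a", "H_b": "b"})
        (r,) = derive_category_ranges(df.assign(label="white"))
        box = HARVEST_SPECS["white"].box
        for lo, hi, (blo, bhi) in zip(r.lab_min, r.lab_max, box):
            assert blo <= lo <= hi <= bhi

    def test_white_and_green_boxes_disjoint_in_l_and_a(self, default_panel):
        t = default_panel.truth.accessions
        df = t[["H_L", "H_a", "H_b", "harvest_category"]].rename(
            columns={"H_L": "L", "H_a": "a", "H_b": "b", "harvest_category": "label"}
        )
        ranges = {r.label: r for r in derive_category_ranges(df)}
        w, g = ranges["white"], ranges["green"]
        assert w.lab_min[0] > g.lab_max[0]  # L* separates white above green
        assert g.lab_max[1] < w.lab_min[1]  # a* separates green below white

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            derive_category_ranges(pd.DataFrame({"L": [], "a": [], "b": [], "label": []}))
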