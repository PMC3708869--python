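"""Feature tables, cross-validated forests, ROC/AUC, importance and phase sets."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cyclescan.classifier import (
    FeatureTable,
    PhaseBinSpec,
    ablate_features,
    build_feature_table,
    cross_validate,
    importance,
    match_expression_negatives,
    phase_training_sets,
    roc_auc,
    topk_model,
)


def make_table(rng, n=200, n_signal=1, n_noise=5, effect=2.0):
    y = np.repeat([1, 0], n // 2)
    cols = [y * effect + rng.normal(0, 1, n) for _ in range(n_signal)]
    cols += [rng.normal(0, 1, n) for _ in range(n_noise)]
    names = [f"sig{i:02d}" for i in range(n_signal)] + [f"zz_noise{i:02d}" for i in range(n_noise)]
    return FeatureTable(
        [f"g{i}" for i in range(n)], np.column_stack(cols), names, ["tf"] * len(names), y
    )


class TestBuildFeatureTable:
    def setup_method(self):
        self.tf_scores = {
            "TF_b": {"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0},
            "TF_a": {"g1": 5.0, "g2": 6.0, "g3": 7.0},  # g4 missing -> 0
        }
        self.B = pd.DataFrame(
            np.arange(12, dtype=float).reshape(4, 3),
            index=["g1", "g2", "g3", "g4"],
            columns=["M2", "M1", "M3"],
        )
        self.labels = {"g1": 1, "g2": 0, "g3": 1, "g4": 0}

    def test_combined_shape_and_deterministic_column_order(self):
        t = build_feature_table(self.tf_scores, self.B, self.labels)
        assert t.X.shape == (4, 5)
        assert t.feature_names == ["TF_a", "TF_b", "M1", "M2", "M3"]
        assert t.feature_kinds == ["tf", "tf", "motif", "motif", "motif"]

    def test_tf_only_subset_drops_motifs(self):
        t = build_feature_table(self.tf_scores, self.B, self.labels, feature_subset="tf")
        assert t.feature_kinds == ["tf", "tf"]

    def test_missing_gene_imputed_zero(self):
        t = build_feature_table(self.tf_scores, self.B, self.labels)
        g4 = t.gene_ids.index("g4")
        col = t.feature_names.index("TF_a")
        assert t.X[g4, col] == 0.0

    def test_no_features_is_error(self):
        with pytest.raises(ValueError):
            build_feature_table(None, None, self.labels)


class TestRocAuc:
    def test_perfect_scores(self):
        res = roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0, abs=1e-9)
        assert res.auc_exact == pytest.approx(1.0)

    def test_constant_scores_are_chance(self):
        res = roc_auc([0.5] * 10, [0, 1] * 5)
        assert res.auc == pytest.approx(0.5, abs=1e-9)
        assert res.auc_exact == pytest.approx(0.5)

    def test_eight_point_toy_close_to_rank_statistic(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.3, 0.7]
        labels = [0, 0, 1, 1, 0, 1, 0, 1]
        res = roc_auc(scores, labels)
        pos = [s for s, y in zip(scores, labels) if y]
        neg = [s for s, y in zip(scores, labels) if not y]
        u = stats.mannwhitneyu(pos, neg).statistic
        assert abs(res.auc - u / (len(pos) * len(neg))) <= 0.01

    def test_roc_monotone_with_unit_endpoints(self, rng):
        for _ in range(10):
            scores = rng.normal(0, 1, 50)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            res = roc_auc(scores, labels)
            assert tuple(res.roc[0]) == (0.0, 0.0)
            assert tuple(res.roc[-1]) == (1.0, 1.0)
            assert np.all(np.diff(res.roc[:, 0]) >= 0)
            assert np.all(np.diff(res.roc[:, 1]) >= -1e-12)
            assert 0.0 <= res.auc <= 1.0

    def test_trapezoid_close_to_exact_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 120))
            scores = rng.normal(0, 1, n)
            labels = (rng.uniform(size=n) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            res = roc_auc(scores, labels)
            assert abs(res.auc - res.auc_exact) <= 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCrossValidate:
    def test_separable_data_near_perfect(self, rng):
        t = make_table(rng, n=100, effect=8.0, n_noise=3)
        res = cross_validate(t, k=10, seed=0, n_trees=100)
        assert res.auc >= 0.99

    def test_each_gene_scored_once(self, rng):
        t = make_table(rng, n=60)
        res = cross_validate(t, k=10, seed=0, n_trees=50)
        assert len(np.unique(res.fold_assignments)) == 10
        counts = np.bincount(res.fold_assignments)
        assert counts.sum() == 60

    def test_permuted_labels_are_chance(self, rng):
        aucs = []
        for seed in range(20):
            local = np.random.default_rng(seed)
            t = make_table(local, n=120, effect=3.0, n_noise=4)
            t_perm = FeatureTable(
                t.gene_ids, t.X, t.feature_names, t.feature_kinds, local.permutation(t.y)
            )
            aucs.append(cross_validate(t_perm, k=5, seed=seed, n_trees=60).auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_single_class_fold_warns_but_completes(self):
        rng = np.random.default_rng(0)
        # 12 genes, 1 positive: some training partitions lose the positive
        y = np.zeros(12, dtype=int)
        y[0] = 1
        t = FeatureTable(
            [f"g{i}" for i in range(12)], rng.normal(size=(12, 2)), ["a", "b"], ["tf"] * 2, y
        )
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            cross_validate(t, k=12, seed=0, n_trees=20)
        assert any("single class" in str(x.message) for x in w)

    def test_deterministic_given_seed(self, rng):
        t = make_table(rng, n=80)
        a = cross_validate(t, k=5, seed=3, n_trees=50)
        b = cross_validate(t, k=5, seed=3, n_trees=50)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestImportance:
    def test_single_informative_column_ranks_first(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = make_table(rng, n=200, n_signal=1, n_noise=50, effect=2.5)
            rank = importance(t, seed=seed, n_trees=150, n_permutations=3, k=3)
            hits += rank.ranked("mdg")[0] == "sig00"
            assert rank.normalized("mdg").max() == pytest.approx(1.0)
        assert hits >= 4

    def test_duplicated_informative_pair_beats_noise(self):
        rng = np.random.default_rng(1)
        t = make_table(rng, n=200, n_signal=2, n_noise=20, effect=2.5)
        rank = importance(t, seed=1, n_trees=150, n_permutations=3, k=3)
        mdg = dict(zip(rank.feature_names, rank.mdg))
        pair = mdg["sig00"] + mdg["sig01"]
        assert all(pair > mdg[f] for f in rank.feature_names if f.startswith("zz_noise"))

    def test_all_noise_importance_not_persistent(self):
        tops = set()
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            t = make_table(rng, n=150, n_signal=0, n_noise=12, effect=0.0)
            rank = importance(t, seed=seed, n_trees=80, n_permutations=2, k=3)
            tops.add(rank.ranked("mdg")[0])
        assert len(tops) > 1

    def test_permutation_importance_flags_signal(self):
        rng = np.random.default_rng(2)
        t = make_table(rng, n=200, n_signal=1, n_noise=10, effect=3.0)
        rank = importance(t, seed=2, n_trees=150, n_permutations=5, k=3)
        assert rank.ranked("pct_inc_mse")[0] == "sig00"


class TestAblation:
    def test_single_informative_feature_collapses_after_first_removal(self):
        rng = np.random.default_rng(3)
        t = make_table(rng, n=200, n_signal=1, n_noise=6, effect=4.0)
        curve = ablate_features(t, seed=3, n_trees=100, k=5)
        assert curve[0][1] > 0.9
        assert curve[1][0] == "sig00"  # the informative feature goes first
        assert all(auc < 0.65 for _, auc in curve[2:])

    def test_terminates_with_one_feature_left(self):
        rng = np.random.default_rng(4)
        t = make_table(rng, n=60, n_signal=1, n_noise=3)
        curve = ablate_features(t, seed=4, n_trees=30, k=5)
        assert len(curve) == t.p  # full model + one entry per removal down to 1 left
        removed = [f for f, _ in curve[1:]]
        assert len(set(removed)) == t.p - 1


class TestTopK:
    def test_k_exceeding_features_selects_everything(self):
        rng = np.random.default_rng(5)
        t = make_table(rng, n=100, n_signal=2, n_noise=3)
        res, selected = topk_model(t, k_tf=50, k_motif=50, seed=5, n_trees=50, k_folds=5)
        assert set(selected) == set(t.feature_names)

    def test_k_tf_zero_keeps_only_motif_columns(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 4))
        y = np.repeat([0, 1], 30)
        t = FeatureTable(
            [f"g{i}" for i in range(60)], X,
            ["TF1", "TF2", "M1", "M2"], ["tf", "tf", "motif", "motif"], y,
        )
        _, selected = topk_model(t, k_tf=0, k_motif=2, seed=6, n_trees=30, k_folds=5)
        assert selected == ["M1", "M2"]

    def test_selected_features_come_from_importance_ranking(self):
        rng = np.random.default_rng(7)
        t = make_table(rng, n=200, n_signal=2, n_noise=10, effect=3.0)
        _, selected = topk_model(t, k_tf=2, k_motif=0, seed=7, n_trees=100, k_folds=5)
        assert set(selected) == {"sig00", "sig01"}


class TestPhaseBins:
    @pytest.mark.parametrize(
        "peak_time,expected",
        [
            (50.0, {"S", "G1/S"}),
            (85.0, {"G2", "G2/M"}),
            (10.0, {"M/G1"}),
            (20.0, {"G1/S"}),       # M/G1 upper bound is exclusive at 20
            (95.0, {"M/G1"}),       # G2/M [80, 95) excludes 95
            (47.0, {"S", "G1/S"}),
            (0.0, {"M/G1"}),
            (75.0, {"G2"}),
            (92.0, {"G2/M"}),
            (65.0, {"S"}),
        ],
    )
    def test_selection_ranges(self, peak_time, expected):
        assert set(PhaseBinSpec().phases_of(peak_time)) == expected

    def test_phase_training_sets_share_negatives_and_overlap(self):
        rng = np.random.default_rng(8)
        n = 40
        y = np.array([1] * 20 + [0] * 20)
        t = FeatureTable(
            [f"g{i}" for i in range(n)], rng.normal(size=(n, 3)), ["a", "b", "c"], ["tf"] * 3, y
        )
        peak_times = {f"g{i}": float(5 * i) for i in range(20)}  # 0,5,...,95
        sets = phase_training_sets(t, peak_times)
        for phase, tbl in sets.items():
            assert (tbl.y == 0).sum() == 20  # all negatives in every phase set
        g17 = "g17"  # peak time 85 -> in both G2 and G2/M
        assert g17 in sets["G2"].gene_ids and g17 in sets["G2/M"].gene_ids


class TestExpressionMatching:
    def test_identical_pool_passes_ks(self, rng):
        pos = {f"p{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 150))}
        neg = {f"n{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 1500))}
        chosen = match_expression_negatives(pos, neg, seed=0)
        assert len(chosen) == len(pos)
        ks = stats.ks_2samp(list(pos.values()), [neg[g] for g in chosen])
        assert ks.pvalue > 0.1

    def test_shifted_wide_pool_matches(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            pos = {f"p{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 120))}
            neg = {f"n{i}": float(v) for i, v in enumerate(rng.normal(2, 3, 2000))}
            chosen = match_expression_negatives(pos, neg, seed=seed)
            ks = stats.ks_2samp(list(pos.values()), [neg[g] for g in chosen])
            ok += ks.pvalue > 0.1
        assert ok >= 9

    def test_pool_below_positives_warns(self, rng):
        pos = {f"p{i}": float(v) for i, v in enumerate(rng.normal(10, 1, 50))}
        neg = {f"n{i}": float(v) for i, v in enumerate(rng.normal(-10, 1, 100))}
        with pytest.warns(UserWarning, match="negatives available"):
            chosen = match_expression_negatives(pos, neg, seed=0)
        assert len(chosen) == len(pos)  # best-effort fill
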