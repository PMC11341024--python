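import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dommech import thresholds_and_ranking as tr


def brute_force_auroc(scores, labels):
    """Pairwise-comparison oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0], 0.75),
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
    ])
    def test_examples(self, scores, labels, expected):
        assert tr.auroc(scores, labels) == pytest.approx(expected)

    def test_matches_pairwise_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.round(rng.uniform(size=10), 2), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert tr.auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            tr.auroc([0.5, 0.3], [1, 1])

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1, 1, 80), rng.normal(0, 1, 80)])
        labels = np.repeat([1, 0], 80)
        res = tr.auroc_auprc_ci(scores, labels, n_boot=200, seed=0)
        lo, hi = res["auroc_ci"]
        assert lo <= res["auroc"] <= hi
        assert res["auprc_ci"][0] <= res["auprc"] <= res["auprc_ci"][1]
        assert res["n_boot"] == 200


def brute_force_confusion(scores, labels, theta):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= theta
    return (
        int(np.sum(pred & labels)), int(np.sum(pred & ~labels)),
        int(np.sum(~pred & ~labels)), int(np.sum(~pred & labels)),
    )


class TestThresholdTable:
    def test_half_half_example(self):
        t = tr.threshold_table([0.9, 0.7, 0.4, 0.2], [1, 0, 1, 0])
        row = t[t["threshold"] == 0.5].iloc[0]
        assert row["sensitivity"] == pytest.approx(0.5)
        assert row["specificity"] == pytest.approx(0.5)
        assert row["accuracy"] == pytest.approx(0.5)
        assert row["mcc"] == pytest.approx(0.0)
        assert row["f1"] == pytest.approx(0.5)

    def test_perfect_separation(self):
        t = tr.threshold_table([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        row = t[t["threshold"] == 0.5].iloc[0]
        for m in ("sensitivity", "specificity", "accuracy", "mcc", "f1", "ppv", "npv"):
            assert row[m] == pytest.approx(1.0)

    def test_zero_threshold_all_positive(self):
        t = tr.threshold_table([0.9, 0.1], [1, 0])
        row = t[t["threshold"] == 0.0].iloc[0]
        assert row["sensitivity"] == 1.0 and row["specificity"] == 0.0

    def test_matches_brute_force_confusion_on_random_vectors(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.uniform(size=60), 2)
        labels = rng.integers(0, 2, 60)
        t = tr.threshold_table(scores, labels).set_index("threshold")
        for theta in (0.0, 0.13, 0.5, 0.77, 1.0):
            tp, fp, tn, fn = brute_force_confusion(scores, labels, theta)
            row = t.loc[round(theta, 2)]
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (tp, fp, tn, fn)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=40),
        data=st.data(),
    )
    def test_monotonicity_invariants(self, scores, data):
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if sum(labels) == 0 or sum(labels) == len(labels):
            labels[0] = 1 - labels[0]
        t = tr.threshold_table(scores, labels)
        sens = t["sensitivity"].to_numpy()
        spec = t["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()   # non-increasing in threshold
        assert (np.diff(spec) >= -1e-12).all()  # non-decreasing in threshold


class TestDeriveT50:
    def test_grid_point_just_above_half_sensitivity(self):
        # 25 positives: 12 high, one at 0.615, 12 low -> sens(0.61)=0.52,
        # sens(0.62)=0.48; brute-force construction
        pos = [0.9] * 12 + [0.615] + [0.1] * 12
        neg = [0.05] * 25
        t = tr.threshold_table(pos + neg, [1] * 25 + [0] * 25)
        assert tr.derive_t50(t) == pytest.approx(0.61)
        sens_at = t.set_index("threshold").loc[0.61, "sensitivity"]
        assert sens_at == pytest.approx(13 / 25)

    def test_all_positives_at_one_gives_grid_max(self):
        t = tr.threshold_table([1.0, 1.0, 0.2], [1, 1, 0])
        assert tr.derive_t50(t) == pytest.approx(1.0)

    def test_no_positives_is_error(self):
        t = tr.threshold_table([0.4, 0.2], [0, 0])
        with pytest.raises(ValueError):
            tr.derive_t50(t)


T50 = {"DN": 0.61, "GOF": 0.63, "LOF": 0.64}


class TestRankClassify:
    def test_toy_assignment_brute_force(self):
        trio = pd.DataFrame(
            {
                "pDN": [0.9, 0.2, 0.1],
                "pGOF": [0.5, 0.8, 0.2],
                "pLOF": [0.4, 0.3, 0.9],
            },
            index=["A", "B", "C"],
        )
        res = tr.rank_classify(trio, T50)
        # A tops the DN ranking with pDN=0.9 > 0.61 -> DN, etc.
        assert res.loc["A", "rank_class"] == "DN"
        assert res.loc["B", "rank_class"] == "GOF"
        assert res.loc["C", "rank_class"] == "LOF"

    def test_winner_below_cutoff_unclassified(self):
        trio = pd.DataFrame(
            {"pDN": [0.5, 0.2], "pGOF": [0.1, 0.3], "pLOF": [0.2, 0.4]},
            index=["A", "B"],
        )
        res = tr.rank_classify(trio, T50)
        assert res.loc["A", "rank_class"] == "unclassified"  # 0.5 <= 0.61
        assert res.loc["A", "rank_class_no_cutoff"] == "DN"

    def test_cutoff_is_strictly_greater_than(self):
        trio = pd.DataFrame(
            {"pDN": [0.61, 0.1], "pGOF": [0.1, 0.2], "pLOF": [0.1, 0.3]},
            index=["A", "B"],
        )
        res = tr.rank_classify(trio, T50)
        assert res.loc["A", "rank_class"] == "unclassified"  # == t50 fails

    def test_without_cutoff_everyone_assigned(self, trio_frame):
        res = tr.rank_classify(trio_frame, T50, use_cutoff=False)
        assert (res["rank_class"] != "unclassified").all()

    def test_unclassified_iff_winner_at_or_below_t50(self, trio_frame):
        res = tr.rank_classify(trio_frame, T50)
        cols = {"DN": "pDN", "GOF": "pGOF", "LOF": "pLOF"}
        for _, row in res.iterrows():
            winner = row["winner"]
            if row["rank_class"] == "unclassified":
                assert row[cols[winner]] <= T50[winner]
            else:
                assert row[cols[winner]] > T50[winner]

    def test_invariance_under_monotone_transform(self, trio_frame):
        base = tr.rank_classify(trio_frame, T50, use_cutoff=False)
        warped = trio_frame.copy()
        warped["pGOF"] = warped["pGOF"] ** 3  # strictly increasing on [0,1]
        res = tr.rank_classify(warped, T50, use_cutoff=False)
        assert (res["rank_class"] == base["rank_class"]).all()

    def test_rank_tie_broken_by_class_priority(self):
        trio = pd.DataFrame(
            {"pDN": [0.9, 0.1], "pGOF": [0.9, 0.1], "pLOF": [0.1, 0.9]},
            index=["A", "B"],
        )
        res = tr.rank_classify(trio, T50, use_cutoff=False)
        assert res.loc["A", "rank_class"] == "DN"  # DN beats GOF on equal rank

    def test_missing_probability_unclassified(self):
        trio = pd.DataFrame(
            {"pDN": [np.nan, 0.9], "pGOF": [0.5, 0.1], "pLOF": [0.5, 0.1]},
            index=["A", "B"],
        )
        res = tr.rank_classify(trio, T50)
        assert res.loc["A", "rank_class"] == "unclassified"
        assert res.loc["B", "rank_class"] == "DN"

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            tr.rank_classify(pd.DataFrame({"pDN": [0.5]}), T50)
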