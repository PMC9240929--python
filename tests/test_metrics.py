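import numpy as np
import pytest

from fairaudit.errors import DegenerateSampleError, UndefinedMetricError
from fairaudit.metrics import (
    FairnessReport,
    GroupedConfusion,
    balanced_error_rate,
    confusion_by_group,
    delta_accuracy,
    delta_fpr,
    delta_tpr,
    disparate_impact,
    is_biased,
    overall_error_rate,
    statistical_parity_difference,
    t_test_two_tailed,
)
from conftest import random_predictions


def brute_force_metrics(y_true, y_pred, group, privileged):
    """Independent per-row recomputation of every metric (plain loops)."""
    tally = {g: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for g in ("p", "u")}
    for t, p, g in zip(y_true, y_pred, group):
        role = "p" if g == privileged else "u"
        if t == 1 and p == 1:
            tally[role]["tp"] += 1
        elif t == 0 and p == 1:
            tally[role]["fp"] += 1
        elif t == 0 and p == 0:
            tally[role]["tn"] += 1
        else:
            tally[role]["fn"] += 1

    out = {}
    n = {g: sum(tally[g].values()) for g in ("p", "u")}
    acc = {g: (tally[g]["tp"] + tally[g]["tn"]) / n[g] for g in ("p", "u")}
    out["delta_accuracy"] = 100 * (acc["p"] - acc["u"])
    pos = {g: tally[g]["tp"] + tally[g]["fn"] for g in ("p", "u")}
    neg = {g: tally[g]["fp"] + tally[g]["tn"] for g in ("p", "u")}
    if pos["p"] > 0 and pos["u"] > 0:
        out["delta_tpr"] = 100 * (
            tally["p"]["tp"] / pos["p"] - tally["u"]["tp"] / pos["u"]
        )
    if neg["p"] > 0 and neg["u"] > 0:
        out["delta_fpr"] = 100 * (
            tally["p"]["fp"] / neg["p"] - tally["u"]["fp"] / neg["u"]
        )
    rate = {g: (tally[g]["tp"] + tally[g]["fp"]) / n[g] for g in ("p", "u")}
    out["spd"] = 100 * (rate["p"] - rate["u"])
    if rate["p"] > 0:
        out["disparate_impact"] = rate["u"] / rate["p"]
    out["ber"] = ((1 - acc["p"]) + (1 - acc["u"])) / 2
    errors = sum(tally[g]["fp"] + tally[g]["fn"] for g in ("p", "u"))
    out["overall_error_rate"] = errors / (n["p"] + n["u"])
    return tally, out


class TestConfusionByGroup:
    def test_two_row_example(self):
        c = confusion_by_group([1, 0], [1, 0], ["m", "w"], privileged="m")
        assert (c.tp_priv, c.tn_unpriv) == (1, 1)
        assert c.n == 2 and c.tp_unpriv == c.tn_priv == 0

    def test_all_wrong_has_no_true_cells(self):
        c = confusion_by_group([1, 0, 1, 0], [0, 1, 0, 1], list("mmww"), "m")
        assert c.tp_priv == c.tn_priv == c.tp_unpriv == c.tn_unpriv == 0
        assert c.n == 4

    def test_counts_partition_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_true, y_pred, group = random_predictions(rng)
            c = confusion_by_group(y_true, y_pred, group, "m")
            assert c.n == len(y_true)

    def test_matches_per_row_tally(self):
        rng = np.random.default_rng(1)
        y_true, y_pred, group = random_predictions(rng, n_max=200)
        c = confusion_by_group(y_true, y_pred, group, "m")
        tally, _ = brute_force_metrics(y_true, y_pred, group, "m")
        assert (c.tp_priv, c.fp_priv, c.tn_priv, c.fn_priv) == tuple(
            tally["p"][k] for k in ("tp", "fp", "tn", "fn")
        )

    def test_length_mismatch_and_extra_groups_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_by_group([1], [1, 0], ["m", "w"], "m")
        with pytest.raises(ValueError, match="binary"):
            confusion_by_group([1, 0, 1], [1, 0, 1], ["m", "w", "x"], "m")


class TestMetricExamples:
    def test_equal_accuracies_give_zero_delta(self):
        c = GroupedConfusion(tp_priv=5, fn_priv=5, tp_unpriv=3, fn_unpriv=3)
        assert delta_accuracy(c) == 0.0

    def test_extreme_delta_accuracy(self):
        c = GroupedConfusion(tp_priv=10, fn_unpriv=10)
        assert delta_accuracy(c) == 100.0

    def test_hand_counted_delta_accuracy(self):
        c = GroupedConfusion(
            tp_priv=9, fn_priv=1, tp_unpriv=6, fn_unpriv=4
        )  # 90% vs 60%
        assert delta_accuracy(c) == pytest.approx(30.0)

    def test_hand_counted_delta_tpr(self):
        c = GroupedConfusion(tp_priv=8, fn_priv=2, tp_unpriv=3, fn_unpriv=7)
        assert delta_tpr(c) == pytest.approx(50.0)

    def test_symmetric_confusions_zero_deltas(self):
        c = GroupedConfusion(
            tp_priv=3, fp_priv=2, tn_priv=4, fn_priv=1,
            tp_unpriv=3, fp_unpriv=2, tn_unpriv=4, fn_unpriv=1,
        )
        assert delta_tpr(c) == 0.0
        assert delta_fpr(c) == 0.0
        assert statistical_parity_difference(c) == 0.0

    def test_hand_counted_spd(self):
        c = GroupedConfusion(
            tp_priv=14, tn_priv=6, tp_unpriv=6, tn_unpriv=9
        )  # 14/20 vs 6/15 predicted positive
        assert statistical_parity_difference(c) == pytest.approx(30.0)

    def test_spd_sign_flip_option(self):
        c = GroupedConfusion(tp_priv=14, tn_priv=6, tp_unpriv=6, tn_unpriv=9)
        assert statistical_parity_difference(
            c, priv_minus_unpriv=False
        ) == pytest.approx(-30.0)

    def test_disparate_impact_ratio_and_flag(self):
        c = GroupedConfusion(tp_priv=7, tn_priv=3, tp_unpriv=4, tn_unpriv=6)
        di = disparate_impact(c)  # 0.40 / 0.70
        assert di == pytest.approx(0.5714, abs=1e-4)
        assert is_biased(di)

    def test_disparate_impact_zero_unprivileged_rate(self):
        c = GroupedConfusion(tp_priv=5, tn_priv=5, tn_unpriv=10)
        assert disparate_impact(c) == 0.0
        assert is_biased(0.0)

    def test_equal_rates_unflagged(self):
        c = GroupedConfusion(tp_priv=5, tn_priv=5, tp_unpriv=3, tn_unpriv=3)
        assert disparate_impact(c) == pytest.approx(1.0)
        assert not is_biased(1.0)

    def test_ber_sacrificed_minority_toy(self):
        """90 privileged all right, 10 unprivileged all wrong: overall error
        0.1 but balanced error 0.5."""
        c = GroupedConfusion(tp_priv=45, tn_priv=45, fp_unpriv=5, fn_unpriv=5)
        assert overall_error_rate(c) == pytest.approx(0.1)
        assert balanced_error_rate(c) == pytest.approx(0.5)

    def test_ber_perfect_and_mean_cases(self):
        perfect = GroupedConfusion(tp_priv=5, tn_priv=5, tp_unpriv=5, tn_unpriv=5)
        assert balanced_error_rate(perfect) == 0.0
        c = GroupedConfusion(  # err_priv 0.2, err_unpriv 0.4
            tp_priv=8, fn_priv=2, tp_unpriv=6, fn_unpriv=4
        )
        assert balanced_error_rate(c) == pytest.approx(0.3)

    def test_overall_error_rate_simple_count(self):
        c = GroupedConfusion(tp_priv=5, fn_priv=2, tn_unpriv=4, fp_unpriv=1)
        assert overall_error_rate(c) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "metric", [delta_accuracy, statistical_parity_difference, balanced_error_rate]
    )
    def test_empty_group_raises(self, metric):
        c = GroupedConfusion(tp_priv=5, tn_priv=5)
        with pytest.raises(UndefinedMetricError):
            metric(c)

    def test_zero_denominator_names_group(self):
        c = GroupedConfusion(tp_priv=5, fn_priv=5, fp_unpriv=5, tn_unpriv=5)
        with pytest.raises(UndefinedMetricError, match="unprivileged"):
            delta_tpr(c)
        c2 = GroupedConfusion(fp_priv=2, tn_priv=8, tp_unpriv=10)
        with pytest.raises(UndefinedMetricError, match="unprivileged"):
            delta_fpr(c2)


class TestMetricProperties:
    def test_brute_force_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(300):
            y_true, y_pred, group = random_predictions(rng)
            c = confusion_by_group(y_true, y_pred, group, "m")
            _, expected = brute_force_metrics(y_true, y_pred, group, "m")
            assert delta_accuracy(c) == pytest.approx(
                expected["delta_accuracy"], abs=1e-12
            )
            assert statistical_parity_difference(c) == pytest.approx(
                expected["spd"], abs=1e-12
            )
            assert balanced_error_rate(c) == pytest.approx(expected["ber"], abs=1e-12)
            assert overall_error_rate(c) == pytest.approx(
                expected["overall_error_rate"], abs=1e-12
            )
            if "delta_tpr" in expected:
                assert delta_tpr(c) == pytest.approx(expected["delta_tpr"], abs=1e-12)
            if "disparate_impact" in expected:
                assert disparate_impact(c) == pytest.approx(
                    expected["disparate_impact"], abs=1e-12
                )
                checked += 1
        assert checked > 100

    def test_group_swap_negates_deltas_and_inverts_di(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            y_true, y_pred, group = random_predictions(rng)
            c = confusion_by_group(y_true, y_pred, group, "m")
            s = c.swapped()
            try:
                assert delta_accuracy(s) == pytest.approx(-delta_accuracy(c))
                assert statistical_parity_difference(s) == pytest.approx(
                    -statistical_parity_difference(c)
                )
                di, di_s = disparate_impact(c), disparate_impact(s)
                if di > 0:
                    assert di_s == pytest.approx(1.0 / di)
            except UndefinedMetricError:
                continue

    def test_ber_equals_overall_error_for_equal_sized_equal_error_groups(self):
        # both groups size 10 with error rate 0.2
        c = GroupedConfusion(tp_priv=8, fn_priv=2, tp_unpriv=8, fn_unpriv=2)
        assert balanced_error_rate(c) == pytest.approx(overall_error_rate(c))

    def test_di_is_one_iff_spd_is_zero(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            y_true, y_pred, group = random_predictions(rng)
            c = confusion_by_group(y_true, y_pred, group, "m")
            try:
                di = disparate_impact(c)
            except UndefinedMetricError:
                continue
            spd = statistical_parity_difference(c)
            if abs(di - 1.0) < 1e-12:
                assert spd == pytest.approx(0.0, abs=1e-9)
            if abs(spd) < 1e-12 and di > 0:
                assert di == pytest.approx(1.0)


class TestTTest:
    def test_identical_samples(self):
        assert t_test_two_tailed([1, 2, 3], [3, 2, 1]) == (0.0, 1.0)
        assert t_test_two_tailed([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_clearly_separated_samples_significant(self):
        t, p = t_test_two_tailed([85, 87, 86], [70, 72, 71])
        assert p < 0.01
        # pooled variant agrees on equal-sized equal-variance samples
        t_pooled, p_pooled = t_test_two_tailed([85, 87, 86], [70, 72, 71], equal_var=True)
        assert t == pytest.approx(t_pooled)

    def test_welch_matches_textbook_formula(self):
        a = np.array([3.1, 2.8, 3.6, 3.0])
        b = np.array([2.1, 2.5, 1.9])
        t, _ = t_test_two_tailed(a, b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx((a.mean() - b.mean()) / se)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            t_test_two_tailed([1.0], [2.0, 3.0])
        with pytest.raises(DegenerateSampleError):
            t_test_two_tailed([1.0, 1.0], [2.0, 2.0])


class TestFairnessReport:
    def test_report_fields_match_individual_metrics(self):
        rng = np.random.default_rng(21)
        y_true, y_pred, group = random_predictions(rng, n_max=100)
        c = confusion_by_group(y_true, y_pred, group, "m")
        try:
            report = FairnessReport.from_confusion(c)
        except UndefinedMetricError:
            pytest.skip("degenerate random draw")
        assert report.delta_accuracy == delta_accuracy(c)
        assert report.spd == statistical_parity_difference(c)
        assert report.ber == balanced_error_rate(c)
        d = report.to_dict()
        assert d["di_biased"] == is_biased(report.disparate_impact)
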