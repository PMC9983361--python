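"""Agreement metrics, interpretation bands, splitting and balance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rigipose as rp
from rigipose.errors import RigiposeError, SchemaError
from rigipose.evaluation import cohort_balance_tests, describe_cohort


def reference_weighted_kappa(true, pred, weights="linear", n_classes=4):
    """Independent contingency-table weighted kappa (textbook formula)."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    O = np.zeros((n_classes, n_classes))
    for t, p in zip(true, pred):
        O[t, p] += 1
    O /= O.sum()
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    E = np.outer(row, col)
    i, j = np.indices((n_classes, n_classes))
    if weights == "linear":
        W = np.abs(i - j)
    else:
        W = (i - j) ** 2
    return 1.0 - (W * O).sum() / (W * E).sum()


class TestAccWithin:
    def test_perfect_agreement(self):
        y = [0, 1, 2, 3, 1]
        assert rp.acc_within(y, y, 0) == 1.0
        assert rp.acc_within(y, y, 1) == 1.0

    def test_hand_counted_example(self):
        true = [0, 1, 2, 3]
        pred = [0, 2, 2, 1]  # absolute differences 0, 1, 0, 2
        assert rp.acc_within(true, pred, 0) == 0.5
        assert rp.acc_within(true, pred, 1) == 0.75

    def test_empty_errors(self):
        with pytest.raises(SchemaError):
            rp.acc_within([], [], 0)

    @given(
        st.lists(st.integers(0, 3), min_size=2, max_size=40),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, derandomize=True)
    def test_acc1_dominates_acc0_and_permutation_invariant(self, true, rnd):
        pred = [rnd.randint(0, 3) for _ in true]
        acc0 = rp.acc_within(true, pred, 0)
        acc1 = rp.acc_within(true, pred, 1)
        assert acc1 >= acc0
        order = list(range(len(true)))
        rnd.shuffle(order)
        assert rp.acc_within(
            [true[i] for i in order], [pred[i] for i in order], 0
        ) == pytest.approx(acc0)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self):
        y = [0, 1, 2, 3, 2, 1]
        k, _ = rp.weighted_kappa_ci(y, y, n_boot=50, seed=0)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_constant_rater_is_zero(self):
        true = [0, 1, 2, 3, 0, 1, 2, 3]
        pred = [2] * 8
        k, _ = rp.weighted_kappa_ci(true, pred, n_boot=50, seed=0)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_three_class_toy_table_closed_form(self):
        # contingency counts ((2,1,0),(1,3,1),(0,1,2))
        true, pred = [], []
        counts = [[2, 1, 0], [1, 3, 1], [0, 1, 2]]
        for t in range(3):
            for p in range(3):
                true += [t] * counts[t][p]
                pred += [p] * counts[t][p]
        k, _ = rp.weighted_kappa_ci(true, pred, "linear", n_boot=50, seed=0)
        assert k == pytest.approx(
            reference_weighted_kappa(true, pred, "linear"), abs=1e-12
        )

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_reference_on_random_tables(self, weights):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(20, 60))
            true = rng.integers(0, 4, size=n)
            pred = np.clip(true + rng.integers(-2, 3, size=n), 0, 3)
            if len(set(true) | set(pred)) < 2:
                continue
            k, _ = rp.weighted_kappa_ci(true, pred, weights, n_boot=20, seed=1)
            assert k == pytest.approx(
                reference_weighted_kappa(true, pred, weights), abs=1e-12
            )

    def test_symmetric_in_raters(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, size=40)
        b = np.clip(a + rng.integers(-1, 2, size=40), 0, 3)
        ka, _ = rp.weighted_kappa_ci(a, b, n_boot=20, seed=0)
        kb, _ = rp.weighted_kappa_ci(b, a, n_boot=20, seed=0)
        assert ka == pytest.approx(kb, abs=1e-12)

    def test_ci_contains_point_and_shrinks_with_n(self):
        rng = np.random.default_rng(11)

        def width(n):
            true = rng.integers(0, 4, size=n)
            pred = np.clip(true + (rng.random(n) < 0.25) * rng.choice([-1, 1], n), 0, 3)
            k, (lo, hi) = rp.weighted_kappa_ci(
                true.astype(int), pred.astype(int), n_boot=400, seed=3
            )
            assert lo <= k <= hi
            return hi - lo

        assert width(150) < width(15)


class TestSpearman:
    def test_identical_gives_one(self):
        rho, _ = rp.spearman_with_p([0, 1, 2, 3, 1], [0, 1, 2, 3, 1])
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        rho, _ = rp.spearman_with_p([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_toy_case_exact(self):
        rho, p = rp.spearman_with_p([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert 0 < p < 1

    def test_constant_vector_errors(self):
        with pytest.raises(RigiposeError):
            rp.spearman_with_p([1, 1, 1, 1], [0, 1, 2, 3])


class TestInterpretLevel:
    @pytest.mark.parametrize(
        "metric,value,label",
        [
            ("kappa", 0.58, "Moderate"),
            ("kappa", 0.66, "Substantial"),
            ("kappa", 0.60, "Moderate"),   # upper bound inclusive
            ("kappa", 0.93, "Almost Perfect"),
            ("kappa", -0.1, "Poor"),
            ("kappa", 0.05, "Slight"),
            ("rho", 0.76, "Strong"),
            ("rho", 0.68, "Moderate"),
            ("rho", 0.05, "Negligible"),
            ("rho", 0.95, "Very Strong"),
            ("rho", -0.5, "Moderate"),     # magnitude is banded
        ],
    )
    def test_bands(self, metric, value, label):
        assert rp.interpret_level(metric, value) == label

    def test_out_of_range_errors(self):
        with pytest.raises(SchemaError):
            rp.interpret_level("kappa", 1.5)


class TestStratifiedSplit:
    def test_104_subjects_split_89_15(self):
        rng = np.random.default_rng(0)
        totals = pd.Series(
            rng.integers(0, 13, size=104),
            index=[f"S{i:04d}" for i in range(104)],
        )
        res = rp.stratified_split(totals, test_fraction=15 / 104, seed=4)
        assert len(res.train_ids) == 89
        assert len(res.test_ids) == 15
        assert not set(res.train_ids) & set(res.test_ids)

    def test_reproducible(self):
        totals = pd.Series(
            np.random.default_rng(1).integers(0, 10, size=50),
            index=[f"S{i}" for i in range(50)],
        )
        a = rp.stratified_split(totals, 0.2, seed=9)
        b = rp.stratified_split(totals, 0.2, seed=9)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_two_equal_strata_proportional(self):
        totals = pd.Series([0] * 10 + [5] * 10, index=[f"S{i}" for i in range(20)])
        res = rp.stratified_split(totals, 0.2, seed=2)
        test_low = sum(1 for s in res.test_ids if totals[s] == 0)
        test_high = sum(1 for s in res.test_ids if totals[s] == 5)
        assert test_low == 2 and test_high == 2


class TestBalance:
    def test_identical_groups_all_p_one(self):
        rng = np.random.default_rng(3)
        demo = pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], size=30),
                "age": rng.normal(63, 10, size=30),
            }
        )
        table = cohort_balance_tests(demo, demo.copy())
        np.testing.assert_allclose(table["p"].dropna().to_numpy(), 1.0)

    def test_paper_style_sex_counts(self):
        train = pd.DataFrame({"sex": ["F"] * 39 + ["M"] * 50})
        test = pd.DataFrame({"sex": ["F"] * 5 + ["M"] * 10})
        table = cohort_balance_tests(train, test)
        row = table[table["variable"] == "sex (female)"].iloc[0]
        assert row["train"] == "39(43.8%)"
        assert row["test"] == "5(33.3%)"
        assert row["p"] > 0.05  # matched groups

    def test_severe_sex_imbalance_detected(self):
        train = pd.DataFrame({"sex": ["F"] * 50})
        test = pd.DataFrame({"sex": ["M"] * 50})
        table = cohort_balance_tests(train, test)
        assert table.iloc[0]["p"] < 0.001

    def test_constant_variable_skipped(self):
        train = pd.DataFrame({"sex": ["F", "M"] * 5, "age": [60.0] * 10})
        test = pd.DataFrame({"sex": ["F", "M"] * 3, "age": [60.0] * 6})
        table = cohort_balance_tests(train, test)
        row = table[table["variable"] == "age"].iloc[0]
        assert row["flag"] == "constant"


def test_describe_cohort_percent_strings():
    demo = pd.DataFrame(
        {"sex": ["F"] * 39 + ["M"] * 50, "age": np.linspace(40, 80, 89)}
    )
    out = describe_cohort(demo)
    assert out["sex_female"] == "39(43.8%)"


def test_evaluation_report_invariants():
    true = [0, 1, 2, 3, 2, 1, 0, 2, 3, 1, 2, 0]
    pred = [0, 1, 2, 2, 2, 1, 1, 2, 3, 1, 3, 0]
    report = rp.evaluate_predictions(true, pred, target="PS", n_boot=200, seed=0)
    assert 0 <= report.acc0 <= report.acc1 <= 1
    lo, hi = report.kappa_ci
    assert lo <= report.kappa <= hi
    assert report.kappa_level in (
        "Poor", "Slight", "Fair", "Moderate", "Substantial", "Almost Perfect"
    )
    assert "weighted kappa" in report.to_text()
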