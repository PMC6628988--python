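"""Control filtering, normalization, MA statistics and the variance model."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screenma import (
    ScreenCountTable,
    VarianceModel,
    compute_ma,
    control_median_normalize,
    fit_variance_model,
    score_sgrnas,
    select_stable_controls,
)


def make_table(counts: pd.DataFrame) -> ScreenCountTable:
    rows = []
    for i, col in enumerate(counts.columns):
        rep = f"r{i+1}"
        rows.append((col, "pre_induction", rep, None))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate_id", "paired_control_id"]
    )
    return ScreenCountTable(counts=counts, samples=samples)


class TestSelectStableControls:
    def test_rank_extremes_removed(self):
        ids = [f"c{i}" for i in range(10)]
        base = np.array([100, 120, 130, 140, 150, 160, 170, 180, 500, 10])
        counts = pd.DataFrame(
            {"s1": base, "s2": base + 7}, index=pd.Index(ids, name="sgrna_id")
        )
        sel = select_stable_controls(make_table(counts), ids, 0.10)
        assert set(sel.removed_ids) == {"c8", "c9"}
        assert len(sel.retained_ids) == 8

    def test_all_ties_all_retained(self):
        ids = [f"c{i}" for i in range(20)]
        counts = pd.DataFrame(
            {"s1": [77] * 20, "s2": [42] * 20}, index=pd.Index(ids, name="sgrna_id")
        )
        sel = select_stable_controls(make_table(counts), ids, 0.10)
        assert sel.retained_ids == ids and len(sel.removed_ids) == 0

    def test_matches_brute_force_rank_scan(self):
        """Removal set equals an independent per-sample two-tail rank scan."""
        rng = np.random.default_rng(0)
        ids = [f"c{i:03d}" for i in range(100)]
        base = rng.integers(10, 10_000, size=100)
        counts = pd.DataFrame(
            {f"s{j}": rng.permutation(base) for j in range(4)},
            index=pd.Index(ids, name="sgrna_id"),
        )
        sel = select_stable_controls(make_table(counts), ids, 0.10)

        removed = set()
        for col in counts.columns:
            vals = counts[col].to_numpy()
            for i, v in enumerate(vals):
                below = np.sum(vals < v)
                tied = np.sum(vals == v)
                avg_rank = below + (tied + 1) / 2
                pct = (avg_rank - 0.5) / len(vals)
                if pct >= 0.9 or pct <= 0.1:
                    removed.add(ids[i])
        assert set(sel.removed_ids) == removed
        assert set(sel.retained_ids) == set(ids) - removed

    def test_all_removed_is_fatal(self):
        ids = ["c0", "c1"]
        counts = pd.DataFrame(
            {"s1": [1, 2]}, index=pd.Index(ids, name="sgrna_id")
        )
        with pytest.raises(ValueError, match="trim_fraction"):
            select_stable_controls(make_table(counts), ids, 0.4)


class TestNormalization:
    def test_direct_division(self):
        ids = ["g1", "c1", "c2", "c3"]
        counts = pd.DataFrame(
            {"s1": [10, 15, 20, 25]}, index=pd.Index(ids, name="sgrna_id")
        )
        table = make_table(counts)
        sel = select_stable_controls(table, ["c1", "c2", "c3"], 0.0)
        norm, medians = control_median_normalize(table, sel)
        assert medians["s1"] == 20
        np.testing.assert_allclose(norm["s1"], [0.5, 0.75, 1.0, 1.25])

    def test_retained_control_median_is_one(self, small_screen):
        table, truth, library = small_screen
        ctrl = [r.sgrna_id for r in library if r.is_negative_control]
        sel = select_stable_controls(table, ctrl)
        norm, _ = control_median_normalize(table, sel)
        med = norm.loc[sel.retained_ids].median(axis=0)
        np.testing.assert_allclose(med.to_numpy(), 1.0)

    def test_zero_median_is_fatal(self):
        ids = ["c1", "c2", "c3"]
        counts = pd.DataFrame(
            {"s1": [0, 0, 0], "s2": [1, 2, 3]}, index=pd.Index(ids, name="sgrna_id")
        )
        table = make_table(counts)
        sel = select_stable_controls(table, ids, 0.0)
        with pytest.raises(ValueError, match="s1"):
            control_median_normalize(table, sel)


class TestComputeMA:
    def test_powers_of_ten(self):
        a, m = compute_ma(pd.Series([100.0]), pd.Series([1.0]), pseudocount=0.0)
        assert a.iloc[0] == pytest.approx(1.0) and m.iloc[0] == pytest.approx(2.0)

    def test_equal_counts_give_zero_m(self):
        x = pd.Series([3.7, 0.2, 12.0])
        a, m = compute_ma(x, x, pseudocount=0.5)
        np.testing.assert_allclose(m, 0.0, atol=1e-12)
        np.testing.assert_allclose(a, np.log10(x + 0.5))

    def test_zero_count_with_pseudocount(self):
        a, m = compute_ma(pd.Series([0.0]), pd.Series([99.5]), pseudocount=0.5)
        assert a.iloc[0] == pytest.approx((math.log10(0.5) + math.log10(100)) / 2)
        assert m.iloc[0] == pytest.approx(math.log10(0.5) - 2)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_ma(pd.Series([-1.0]), pd.Series([1.0]), 0.5)


class TestFitVarianceModel:
    def test_two_point_closed_form(self):
        """With exactly two windows the exponential passes through both."""
        rng = np.random.default_rng(1)
        # two clusters of 20 controls each -> exactly two windows at step 20
        a = np.concatenate([np.full(20, 0.5), np.full(20, 2.0)])
        m = np.concatenate(
            [rng.normal(0, 0.4, 20), rng.normal(0, 0.1, 20)]
        )
        model = fit_variance_model(a, m, window_fraction=0.5, window_step=20)
        assert len(model.windows) == 2
        (a1, s1), (a2, s2) = model.windows[["a_center", "sigma"]].to_numpy()
        beta = math.log(s1 / s2) / (a2 - a1)
        alpha = s1 * math.exp(beta * a1)
        assert model.beta == pytest.approx(beta, abs=1e-9)
        assert model.alpha == pytest.approx(alpha, abs=1e-9)
        # the curve passes through both window summaries
        assert model.predict_sigma(a1) == pytest.approx(s1, abs=1e-9)
        assert model.predict_sigma(a2) == pytest.approx(s2, abs=1e-9)

    def test_flat_variance_recovers_zero_beta(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 3, 5000)
        m = rng.normal(0, 0.3, 5000)
        model = fit_variance_model(a, m)
        assert abs(model.beta) < 0.05
        assert model.alpha == pytest.approx(0.3, rel=0.10)

    def test_exponential_parameter_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 3, 5000)
        m = rng.normal(0, 0.5 * np.exp(-0.8 * a))
        model = fit_variance_model(a, m)
        assert model.alpha == pytest.approx(0.5, rel=0.10)
        assert model.beta == pytest.approx(0.8, rel=0.15)
        assert model.fit_mode == "nls"

    def test_window_table_matches_brute_force(self):
        """Window SDs recomputed independently match the model's table."""
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 2, 200)
        m = rng.normal(0, 0.2, 200)
        model = fit_variance_model(a, m, window_fraction=0.15, window_step=7)
        order = np.argsort(a)
        a_s, m_s = a[order], m[order]
        w = max(math.ceil(0.15 * 200), 20)
        expected = []
        for s in range(0, 200 - w + 1, 7):
            expected.append(
                (a_s[s : s + w].mean(), m_s[s : s + w].std(ddof=1), w)
            )
        expected = sorted(expected)
        got = model.windows[["a_center", "sigma", "n_members"]].to_numpy()
        np.testing.assert_allclose(got, np.array(expected), rtol=0, atol=1e-12)

    def test_windows_sorted_by_a_center(self):
        rng = np.random.default_rng(5)
        a, m = rng.uniform(0, 3, 500), rng.normal(0, 0.2, 500)
        model = fit_variance_model(a, m)
        assert model.windows["a_center"].is_monotonic_increasing

    def test_too_few_windows_is_fatal(self):
        with pytest.raises(ValueError, match="windows"):
            fit_variance_model(np.linspace(0, 1, 10), np.zeros(10))


class TestScoreSgrnas:
    @pytest.fixture
    def model(self):
        windows = pd.DataFrame(
            {"a_center": [0.0, 2.0], "sigma": [0.5, 0.1], "n_members": [20, 20]}
        )
        return VarianceModel(alpha=0.5, beta=0.8, windows=windows)

    def test_null_symmetry(self, model):
        s = score_sgrnas(pd.Series([1.0]), pd.Series([0.0]), model)
        assert s["Z"].iloc[0] == 0.0 and s["p"].iloc[0] == pytest.approx(0.5)

    def test_z_two_upper_tail(self):
        windows = pd.DataFrame(
            {"a_center": [0.0, 1.0], "sigma": [0.2, 0.2], "n_members": [20, 20]}
        )
        model = VarianceModel(alpha=0.2, beta=0.0, windows=windows)
        s = score_sgrnas(pd.Series([0.5]), pd.Series([0.4]), model)
        assert s["Z"].iloc[0] == pytest.approx(2.0)
        assert s["p"].iloc[0] == pytest.approx(0.0227501319, abs=1e-9)

    def test_p_monotone_in_m(self, model):
        a = pd.Series(np.full(50, 1.0))
        m = pd.Series(np.linspace(-1, 1, 50))
        s = score_sgrnas(a, m, model)
        assert np.all(np.diff(s["p"]) < 0)

    def test_sigma_positive_and_monotone(self, model):
        grid = np.linspace(-2, 5, 100)
        sig = model.predict_sigma(grid)
        assert np.all(sig > 0) and np.all(np.diff(sig) < 0)

    def test_two_sided_doubles_tail(self, model):
        a, m = pd.Series([1.0, 1.0]), pd.Series([0.3, -0.3])
        one = score_sgrnas(a, m, model)
        two = score_sgrnas(a, m, model, two_sided=True)
        assert two["p"].iloc[0] == pytest.approx(2 * one["p"].iloc[0])
        assert two["p"].iloc[0] == pytest.approx(two["p"].iloc[1])

    def test_nonfinite_m_rejected(self, model):
        with pytest.raises(ValueError):
            score_sgrnas(pd.Series([1.0]), pd.Series([np.inf]), model)


def test_scale_equivariance(small_screen):
    """Multiplying one sample's counts by k cancels in the normalization."""
    from screenma import analyze_counts

    table, truth, library = small_screen
    res1 = analyze_counts(table, library)

    scaled = table.counts.copy()
    scaled["ind_r1"] = scaled["ind_r1"] * 7
    res2 = analyze_counts(
        ScreenCountTable(counts=scaled, samples=table.samples), library
    )
    for col in ("A", "M", "Z", "p"):
        np.testing.assert_allclose(
            res1.scores["r1"][col], res2.scores["r1"][col], rtol=1e-9, atol=1e-12
        )
    pd.testing.assert_frame_equal(res1.genes, res2.genes)
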