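import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scatdiet.records import AvailabilityTable, FrequencyTable
from scatdiet.selection import g_test, selection_ratios, selection_report


class TestGTest:
    def test_null_identity(self):
        # observed exactly proportional to availability -> G = 0, p = 1
        freq = FrequencyTable("wolf", {"a": 30, "b": 70})
        avail = AvailabilityTable({"a": 3, "b": 7})
        res = g_test(freq, avail)
        assert res.g_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # O=(10,20), E=(15,15): 2*(10*ln(10/15)+20*ln(20/15)) = 3.39798
        freq = FrequencyTable("wolf", {"a": 10, "b": 20})
        avail = AvailabilityTable({"a": 1, "b": 1})
        res = g_test(freq, avail)
        assert res.g_statistic == pytest.approx(3.39798, abs=1e-4)
        assert res.df == 1

    def test_df_is_categories_minus_one(self):
        avail = AvailabilityTable({f"p{i}": 1 for i in range(11)})
        freq = FrequencyTable("wolf", {f"p{i}": 5 for i in range(11)})
        assert g_test(freq, avail).df == 10

    def test_observed_without_availability_errors(self):
        freq = FrequencyTable("wolf", {"a": 5, "ghost": 2})
        avail = AvailabilityTable({"a": 10, "ghost": 0})
        with pytest.raises(ValueError, match="ghost"):
            g_test(freq, avail)

    def test_zero_observed_total_errors(self):
        freq = FrequencyTable("wolf", {"a": 0})
        avail = AvailabilityTable({"a": 1, "b": 1})
        with pytest.raises(ValueError):
            g_test(freq, avail)

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=5),
        st.lists(st.integers(min_value=1, max_value=20), min_size=5, max_size=5),
    )
    @settings(max_examples=200)
    def test_matches_literal_oracle(self, obs, avail_counts):
        k = len(obs)
        if sum(obs) == 0:
            return
        freq = FrequencyTable("wolf", {f"p{i}": o for i, o in enumerate(obs)})
        avail = AvailabilityTable(
            {f"p{i}": c for i, c in enumerate(avail_counts[:k])}
        )
        res = g_test(freq, avail)
        # independent literal evaluation of 2*sum(O*ln(O/E))
        o = np.array(obs, dtype=float)
        pi = np.array(avail_counts[:k], dtype=float)
        pi = pi / pi.sum()
        e = o.sum() * pi
        oracle = 2.0 * sum(
            oi * np.log(oi / ei) for oi, ei in zip(o, e) if oi > 0
        )
        assert res.g_statistic == pytest.approx(oracle, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(oracle, k - 1))


class TestSelectionRatios:
    def test_proportional_use_is_neutral(self):
        freq = FrequencyTable("wolf", {"a": 25, "b": 75})
        avail = AvailabilityTable({"a": 1, "b": 3})
        res = selection_ratios(freq, avail)
        assert np.allclose(res.table["ratio"], 1.0)
        assert (res.table["classification"] == "neutral").all()

    def test_stated_formula_arithmetic(self):
        # o=0.5, pi=0.25 -> w=2; se = sqrt(0.25/(100*0.0625)) = 0.2
        freq = FrequencyTable("wolf", {"a": 50, "b": 50})
        avail = AvailabilityTable({"a": 25, "b": 75})
        res = selection_ratios(freq, avail, alpha=0.05)
        row = res.table.set_index("prey").loc["a"]
        assert row["ratio"] == pytest.approx(2.0)
        z = stats.norm.ppf(1 - 0.05 / 4)  # k=2 categories
        assert row["ci_low"] == pytest.approx(2.0 - z * 0.2)
        assert row["ci_high"] == pytest.approx(2.0 + z * 0.2)

    def test_bonferroni_quantile_k11(self):
        freq = FrequencyTable("wolf", {f"p{i}": 10 for i in range(11)})
        avail = AvailabilityTable({f"p{i}": 1 for i in range(11)})
        res = selection_ratios(freq, avail, alpha=0.05)
        assert res.z == pytest.approx(stats.norm.ppf(1 - 0.05 / 22))
        assert res.z == pytest.approx(2.8376, abs=1e-3)

    def test_zero_observed_prey(self):
        freq = FrequencyTable("wolf", {"a": 100})
        avail = AvailabilityTable({"a": 50, "b": 50})
        with pytest.warns(UserWarning, match="zero observed"):
            res = selection_ratios(freq, avail)
        row = res.table.set_index("prey").loc["b"]
        assert row["ratio"] == 0.0
        assert (row["ci_low"], row["ci_high"]) == (0.0, 0.0)
        assert row["classification"] == "avoidance"

    def test_single_category_errors(self):
        freq = FrequencyTable("wolf", {"a": 10})
        avail = AvailabilityTable({"a": 1})
        with pytest.raises(ValueError):
            selection_ratios(freq, avail)

    def test_weighted_mean_of_ratios_is_unity(self):
        freq = FrequencyTable("wolf", {"a": 10, "b": 30, "c": 60})
        avail = AvailabilityTable({"a": 5, "b": 2, "c": 3})
        res = selection_ratios(freq, avail)
        t = res.table
        assert t["used_prop"].sum() == pytest.approx(1.0)
        assert (t["avail_prop"] * t["ratio"]).sum() == pytest.approx(1.0)

    def test_wider_ci_never_creates_nonneutral(self):
        freq = FrequencyTable("wolf", {"a": 12, "b": 8, "c": 30})
        avail = AvailabilityTable({"a": 20, "b": 20, "c": 60})
        loose = selection_ratios(freq, avail, alpha=0.25).table
        tight = selection_ratios(freq, avail, alpha=0.01).table  # wider CIs
        for prey in loose["prey"]:
            before = loose.set_index("prey").loc[prey, "classification"]
            after = tight.set_index("prey").loc[prey, "classification"]
            if before == "neutral":
                assert after == "neutral"

    def test_familywise_error_under_null(self):
        # use == availability: expect few non-neutral calls (<= ~alpha rate)
        rng = np.random.default_rng(0)
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        avail = AvailabilityTable({f"p{i}": v for i, v in enumerate(pi)})
        flagged = 0
        n_sims = 300
        for _ in range(n_sims):
            counts = rng.multinomial(200, pi)
            freq = FrequencyTable("wolf", {f"p{i}": int(c) for i, c in enumerate(counts)})
            with np.errstate(all="ignore"):
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    res = selection_ratios(freq, avail, alpha=0.05)
            if (res.table["classification"] != "neutral").any():
                flagged += 1
        assert flagged / n_sims <= 0.05 + 0.03


class TestSelectionReport:
    def test_preference_bar_right_of_line(self):
        freq = FrequencyTable("wolf", {"a": 90, "b": 10})
        avail = AvailabilityTable({"a": 10, "b": 90})
        res = selection_ratios(freq, avail)
        table, fig = selection_report(res)
        row = table.set_index("prey").loc["a"]
        assert row["classification"] == "preference"
        assert row["ci_low"] > 1.0

    def test_all_neutral_fixture(self):
        freq = FrequencyTable("wolf", {"a": 26, "b": 74})
        avail = AvailabilityTable({"a": 25, "b": 75})
        res = selection_ratios(freq, avail)
        table, fig = selection_report(res)
        assert (table["classification"] == "neutral").all()
        assert ((table["ci_low"] <= 1.0) & (table["ci_high"] >= 1.0)).all()

    def test_plot_file_written(self, tmp_path):
        freq = FrequencyTable("wolf", {"a": 30, "b": 70})
        avail = AvailabilityTable({"a": 50, "b": 50})
        res = selection_ratios(freq, avail)
        out = tmp_path / "selection.svg"
        table, fig = selection_report(res, plot_path=out)
        assert out.exists() and out.stat().st_size > 0
        assert list(table["classification"]) == list(
            res.table.sort_values("ratio")["classification"]
        )
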