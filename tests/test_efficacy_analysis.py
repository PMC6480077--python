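"""ΔVAS derivation and score–efficacy association tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from morscore import efficacy_analysis as ea
from morscore import mor_scoring as ms
from morscore.signature_selection import default_mor_panel


class TestVasWindows:
    def test_baseline_is_mean_of_four_days(self):
        v = ea.VasSeries("p1", {-3: 10, -2: 12, -1: 14, 1: 16})
        assert ea.baseline_vas(v) == (13.0, 4)

    def test_baseline_partial_days(self):
        v = ea.VasSeries("p1", {1: 20})
        value, n_days = ea.baseline_vas(v)
        assert (value, n_days) == (20.0, 1)

    def test_baseline_missing(self):
        value, n_days = ea.baseline_vas(ea.VasSeries("p1", {2: 5}))
        assert math.isnan(value) and n_days == 0

    def test_delta_vas_arithmetic(self):
        v = ea.VasSeries("p1", {-3: 10, -2: 12, -1: 14, 1: 16, 2: 9, 3: 9, 4: 12})
        res = ea.delta_vas(v)
        assert res.delta == pytest.approx(-3.0)
        assert res.baseline == pytest.approx(13.0)
        assert res.treatment == pytest.approx(10.0)

    def test_delta_vas_missing_treatment_window(self):
        res = ea.delta_vas(ea.VasSeries("p1", {-3: 10, 1: 12}))
        assert math.isnan(res.delta) and res.n_treatment_days == 0

    def test_constant_vas_gives_zero_delta(self):
        v = ea.VasSeries("p1", {d: 30 for d in ea.VALID_DAYS})
        assert ea.delta_vas(v).delta == pytest.approx(0.0)

    def test_validation(self):
        with pytest.raises(ValueError, match="day indices"):
            ea.VasSeries("p1", {5: 10})
        with pytest.raises(ValueError, match="\\[0, 100\\]"):
            ea.VasSeries("p1", {1: 120})

    def test_summary_and_reader_round_trip(self, tmp_path):
        frame = pd.DataFrame(
            [("p1", -3, 10.0), ("p1", 2, 9.0), ("p2", 1, 20.0)],
            columns=["patient", "day", "vas_mm"],
        )
        frame.to_csv(tmp_path / "vas.tsv", sep="\t", index=False)
        series = ea.read_vas_table(tmp_path / "vas.tsv")
        summary = ea.efficacy_summary(series)
        assert summary.loc["p1", "delta_vas"] == pytest.approx(-1.0)
        assert math.isnan(summary.loc["p2", "delta_vas"])  # empty treatment window


def spearman_perm_oracle(x, y):
    """Exhaustive two-sided permutation p using scipy's rho on every ordering."""
    rho_obs = abs(stats.spearmanr(x, y).statistic)
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        hits += abs(stats.spearmanr(x, perm).statistic) >= rho_obs - 1e-12
    return hits / total


class TestSpearman:
    def test_perfect_monotone(self):
        res = ea.spearman_assoc([1, 2, 3, 4, 5], [2, 4, 9, 16, 30], exact=False)
        assert res.rho == pytest.approx(1.0)

    def test_exact_permutation_matches_oracle(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        y = [2.0, 7.0, 1.0, 8.0, 2.5, 8.5]
        res = ea.spearman_assoc(x, y, exact=True)
        assert res.p_exact == pytest.approx(spearman_perm_oracle(x, y))

    def test_degenerate_constant_input(self):
        res = ea.spearman_assoc([1, 2, 3, 4], [5, 5, 5, 5], exact=False)
        assert math.isnan(res.rho)

    def test_listwise_missing_exclusion(self):
        res = ea.spearman_assoc([1, 2, 3, 4, 5, np.nan], [1, 2, 3, 4, np.nan, 6], exact=False)
        assert res.n == 4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_sign_flip_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        base = ea.spearman_assoc(x, y, exact=False)
        assert -1 <= base.rho <= 1
        flipped = ea.spearman_assoc(x, -y, exact=False)
        assert flipped.rho == pytest.approx(-base.rho)
        transformed = ea.spearman_assoc(np.exp(x), y ** 3, exact=False)
        assert transformed.rho == pytest.approx(base.rho)
        assert transformed.p_value == pytest.approx(base.p_value)


def fisher_oracle(table):
    """Two-sided Fisher p by direct enumeration of hypergeometric tables."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    def prob(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom
    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p for k in range(lo, hi + 1) if (p := prob(k)) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_hand_built_table(self):
        # 13/2 vs 1/7: enumeration gives ~1.05e-3
        res = ea.fisher_enrichment(
            classes=[1] * 15 + [2] * 8,
            dvas=[1] * 13 + [-1] * 2 + [1] * 1 + [-1] * 7,
        )
        assert res.table == ((13, 2), (1, 7))
        assert res.p_value == pytest.approx(fisher_oracle(res.table), rel=1e-9)
        assert res.p_value == pytest.approx(1.05e-3, rel=0.01)

    def test_balanced_table_p_one(self):
        res = ea.fisher_enrichment([1] * 10 + [2] * 10, [1, -1] * 10)
        assert res.table == ((5, 5), (5, 5))
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_zero_delta_counts_as_not_improved(self):
        res = ea.fisher_enrichment([1, 1, 2, 2], [0.0, 1.0, -1.0, 0.0])
        assert res.table == ((1, 1), (0, 2))

    def test_zero_cell_uses_haldane_for_display(self):
        res = ea.fisher_enrichment([1, 1, 2, 2], [1.0, 1.0, -1.0, -1.0])
        assert res.table == ((2, 0), (0, 2))
        assert res.odds_ratio == pytest.approx((2.5 * 2.5) / (0.5 * 0.5))

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError, match="class 2"):
            ea.fisher_enrichment([1, 1, 1], [1.0, -1.0, 1.0])

    def test_matches_oracle_on_small_grid(self):
        for a in range(0, 7):
            for b in range(0, 7 - a):
                for c in range(0, 7):
                    for d in range(0, 7 - c):
                        if (a + b) == 0 or (c + d) == 0:
                            continue
                        p = stats.fisher_exact([[a, b], [c, d]])[1]
                        assert p == pytest.approx(fisher_oracle(((a, b), (c, d))), abs=1e-10)


def score_table_from(scores, labels):
    table = pd.DataFrame({"score": scores, "class_label": labels})
    table.index = [f"p{i}" for i in range(len(table))]
    return ms.ScoreTable(table=table, panel=default_mor_panel())


class TestAssociationReport:
    def test_reference_cohort_has_23_evaluable(self, table2_delta_cq, table2):
        st = ms.classify_patients(table2_delta_cq)
        # the fixture ships precomputed ΔVAS (raw daily VAS was not published)
        eff = pd.DataFrame({"delta_vas": table2["delta_vas"]})
        report = ea.association_report(st, eff)
        assert report["n_evaluable"] == 23
        assert "#9" not in report["evaluable_patients"]
        assert "#17" not in report["evaluable_patients"]
        assert report["spearman"]["p_value"] < 0.01
        assert report["fisher"]["p_value"] < 0.01

    def test_order_invariance(self, table2_delta_cq, table2):
        st = ms.classify_patients(table2_delta_cq)
        eff = pd.DataFrame({"delta_vas": table2["delta_vas"]})
        shuffled = eff.sample(frac=1, random_state=11)
        assert ea.association_report(st, eff) == ea.association_report(st, shuffled)

    def test_single_class_skips_fisher_keeps_spearman(self):
        st = score_table_from([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 1, 1, 1])
        eff = pd.DataFrame({"delta_vas": [1.0, -1.0, 2.0, -2.0, 0.5]},
                           index=[f"p{i}" for i in range(5)])
        report = ea.association_report(st, eff)
        assert "skipped" in report["fisher"]
        assert np.isfinite(report["spearman"]["rho"])

    def test_empty_join_is_error(self):
        st = score_table_from([1.0, 2.0], [1, 2])
        eff = pd.DataFrame({"delta_vas": [1.0]}, index=["other"])
        with pytest.raises(ValueError, match="no shared"):
            ea.association_report(st, eff)
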