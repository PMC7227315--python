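import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from kinfam.expression import (QpcrRecord, classify_drought_response,
                               concordance_r, fold_change, fpkm,
                               heatmap_normalize, relative_expression_dct,
                               relative_water_content, stomatal_ratio_summary,
                               student_t_test, survival_rate)


class TestFpkm:
    def test_closed_form_example(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g"])
        out = fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s1": 1_000_000}))
        assert out.loc["g", "s1"] == pytest.approx(10.0)

    def test_zero_counts_stay_zero_and_doubling_library_halves(self):
        counts = pd.DataFrame({"s1": [0, 40], "s2": [0, 40]}, index=["g0", "g1"])
        lengths = pd.Series({"g0": 500, "g1": 2000})
        lib1 = pd.Series({"s1": 1e6, "s2": 2e6})
        out = fpkm(counts, lengths, lib1)
        assert out.loc["g0", "s1"] == 0.0
        assert out.loc["g1", "s1"] == pytest.approx(2 * out.loc["g1", "s2"])

    def test_zero_length_gene_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series({"g": 0}), pd.Series({"s1": 1e6}))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(0, 1000, size=(5, 4)),
                              index=[f"g{i}" for i in range(5)],
                              columns=[f"s{j}" for j in range(4)])
        lengths = pd.Series(rng.integers(200, 3000, size=5),
                            index=counts.index)
        lib = pd.Series(rng.integers(10**6, 10**7, size=4),
                        index=counts.columns)
        out = fpkm(counts, lengths, lib)
        for g in counts.index:
            for s in counts.columns:
                expected = 1e9 * counts.loc[g, s] / (lib[s] * lengths[g])
                assert out.loc[g, s] == pytest.approx(expected, abs=1e-10)


class TestHeatmapNormalize:
    def test_constant_row_flagged_and_zeroed(self):
        m = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 3.0]}, index=["flat", "g"])
        z, constant = heatmap_normalize(m)
        assert constant == ["flat"]
        assert (z.loc["flat"] == 0).all()

    def test_hand_computed_row(self):
        m = pd.DataFrame({"a": [1.0], "b": [3.0]}, index=["g"])
        z, _ = heatmap_normalize(m)
        # log2(2)=1, log2(4)=2 -> z-scores -/+ 1/sqrt(2)
        assert z.loc["g", "a"] == pytest.approx(-1 / math.sqrt(2))
        assert z.loc["g", "b"] == pytest.approx(+1 / math.sqrt(2))

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.uniform(0, 100, size=(6, 8)))
        z, constant = heatmap_normalize(m)
        assert constant == []
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)


class TestQpcr:
    @pytest.mark.parametrize("ct_t,ct_r,expected", [
        (25.0, 25.0, 1.0), (26.0, 25.0, 0.5), (23.0, 25.0, 4.0),
    ])
    def test_delta_ct_closed_form(self, ct_t, ct_r, expected):
        rec = QpcrRecord(gene="g", sample="s", ct_target=ct_t, ct_reference=ct_r)
        assert relative_expression_dct(rec) == pytest.approx(expected)

    def test_missing_or_out_of_range_ct_rejected(self):
        with pytest.raises(ValueError):
            QpcrRecord(gene="g", sample="s", ct_target=float("nan"),
                       ct_reference=25.0)
        with pytest.raises(ValueError):
            QpcrRecord(gene="g", sample="s", ct_target=55.0, ct_reference=25.0)


class TestFoldChange:
    def test_basic_ratios(self):
        assert fold_change(5.0, 5.0) == 1.0
        assert fold_change(8.0, 2.0) == 4.0

    def test_zero_control_without_pseudocount_names_gene(self):
        with pytest.raises(ValueError, match="myGene"):
            fold_change(3.0, 0.0, gene="myGene")

    def test_pseudocount_rescues_zero_control(self):
        assert fold_change(3.0, 0.0, pseudocount=1.0) == 4.0


class TestConcordance:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert concordance_r(x, [2 * v for v in x]) == pytest.approx(1.0)
        assert concordance_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert concordance_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            concordance_r([1, 1, 1], [1, 2, 3])

    def test_parameter_recovery_at_known_rho(self):
        rng = np.random.default_rng(7)
        rho = 0.8
        n = 100
        x = rng.normal(size=n)
        y = rho * x + math.sqrt(1 - rho**2) * rng.normal(size=n)
        assert abs(concordance_r(x, y) - rho) < 0.1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        mx, my = sum(x) / 20, sum(y) / 20
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        naive = cov / math.sqrt(sum((a - mx) ** 2 for a in x)
                                * sum((b - my) ** 2 for b in y))
        assert concordance_r(x, y) == pytest.approx(naive, abs=1e-10)


class TestDroughtClassification:
    @pytest.mark.parametrize("series,expected", [
        ((2.5, 3.1, 4.0, 5.2), "continuously_induced"),
        ((2.5, 1.1, 1.0, 0.9), "induced"),
        ((1.0, 1.2, 0.8, 1.1), "unchanged"),
        ((0.4, 0.3, 0.6, 0.8), "repressed"),
        ((2.5, 0.3, 1.0, 1.0), "induced"),  # conflict resolves to induced
    ])
    def test_rule_application(self, series, expected):
        assert classify_drought_response(series) == expected

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            classify_drought_response([2.5])

    def test_planted_profiles_recovered(self, sim_truth, sim_report):
        classes = sim_report["drought_response"]["classes"]
        mapping = {"continuous": "continuously_induced", "induced": "induced",
                   "repressed": "repressed", "unchanged": "unchanged"}
        for g, info in sim_truth.genes.items():
            if info.get("is_family"):
                assert classes[g] == mapping[info["profile"]]


def _t_sf_by_quadrature(t, df):
    """Independent Student-t survival function via numerical integration."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    val, _ = integrate.quad(lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2),
                            abs(t), np.inf)
    return val


class TestStudentT:
    def test_identical_groups_give_t0_p1(self):
        res = student_t_test([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["stars"] == ""

    def test_separated_groups_closed_form(self):
        res = student_t_test([1, 2, 3], [11, 12, 13])
        # pooled sd = 1, t = -10 / sqrt(2/3)
        assert res["t"] == pytest.approx(-10 / math.sqrt(2 / 3))
        assert res["p"] < 0.01 and res["stars"] == "**"

    @pytest.mark.parametrize("seed", range(3))
    def test_p_value_matches_independent_t_cdf(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=6)
        b = rng.normal(1, 1, size=8)
        res = student_t_test(a, b)
        na, nb = len(a), len(b)
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
            / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res["t"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(2 * _t_sf_by_quadrature(t, na + nb - 2),
                                         abs=1e-8)

    def test_p_monotone_in_separation(self):
        base = np.array([1.0, 2.0, 3.0])
        ps = [student_t_test(base, base + shift)["p"] for shift in (1, 2, 4, 8)]
        assert all(b <= a for a, b in zip(ps, ps[1:]))


class TestPhysiologyClosedForms:
    @pytest.mark.parametrize("s,n,expected", [(3, 6, 50.0), (0, 10, 0.0),
                                              (12, 12, 100.0)])
    def test_survival_rate(self, s, n, expected):
        assert survival_rate(s, n) == expected

    def test_survival_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            survival_rate(1, 0)
        with pytest.raises(ValueError):
            survival_rate(5, 3)

    @pytest.mark.parametrize("fw,tw,dw,expected", [
        (1.0, 1.0, 0.2, 100.0), (0.2, 1.0, 0.2, 0.0), (0.8, 1.0, 0.2, 75.0),
    ])
    def test_relative_water_content(self, fw, tw, dw, expected):
        assert relative_water_content(fw, tw, dw) == pytest.approx(expected)

    def test_rwc_rejects_turgid_equal_dry(self):
        with pytest.raises(ValueError):
            relative_water_content(0.5, 0.3, 0.3)

    def test_stomatal_ratios_and_small_n_warning(self):
        out = stomatal_ratio_summary([10, 12], [5, 4])
        assert out["ratios"] == [2.0, 3.0]
        assert out["mean"] == pytest.approx(2.5)
        assert out["warning"] is not None  # n = 2 <= 50
        big = stomatal_ratio_summary([10.0] * 51, [10.0] * 51)
        assert big["warning"] is None and big["mean"] == 1.0

    def test_stomatal_zero_width_rejected(self):
        with pytest.raises(ValueError):
            stomatal_ratio_summary([10], [0])
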