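"""Mendelian randomization: score construction, 2SLS, summary estimators."""

import numpy as np
import pandas as pd
import pytest

from metabcc import (DosagePanel, build_weighted_score, cochran_q_two,
                     confounder_screen, stage1_fit, summary_mr, tsls_fit)
from metabcc.mr import AlleleMismatchError, _weighted_quantile


def brute_force_weighted_median(x, w):
    """Independent weighted-percentile construction on a fine grid of the
    standardised cumulative weights, with midpoint interpolation."""
    order = np.argsort(x)
    xs = np.asarray(x, float)[order]
    ws = np.asarray(w, float)[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum = cum / np.sum(ws)
    if 0.5 <= cum[0]:
        return xs[0]
    if 0.5 >= cum[-1]:
        return xs[-1]
    k = np.searchsorted(cum, 0.5, side="right") - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return xs[k] + frac * (xs[k + 1] - xs[k])


def make_panel(dosages: np.ndarray, ea=None, oa=None) -> DosagePanel:
    snps = [f"snp{j}" for j in range(dosages.shape[1])]
    return DosagePanel(
        dosages=pd.DataFrame(dosages.astype(float), columns=snps),
        effect_allele=pd.Series(ea or ["A"] * len(snps), index=snps),
        other_allele=pd.Series(oa or ["B"] * len(snps), index=snps),
    )


class TestWeightedScore:
    def test_weighted_sum(self):
        panel = make_panel(np.array([[0, 1, 2], [2, 2, 2]]))
        w = pd.DataFrame({"snp_id": ["snp0", "snp1", "snp2"],
                          "effect_allele": ["A"] * 3, "weight": [0.1] * 3})
        score, report = build_weighted_score(panel, w, maf_threshold=0.0)
        assert score.iloc[0] == pytest.approx(0.3)
        assert score.iloc[1] == pytest.approx(0.6)
        assert report.empty

    def test_low_maf_excluded_and_reported(self):
        rng = np.random.default_rng(0)
        d = np.column_stack([rng.binomial(2, 0.3, 1000),
                             rng.binomial(2, 0.005, 1000)])
        panel = make_panel(d)
        w = pd.DataFrame({"snp_id": ["snp0", "snp1"],
                          "effect_allele": ["A"] * 2, "weight": [0.1, 0.2]})
        score, report = build_weighted_score(panel, w, maf_threshold=0.01)
        assert report["snp_id"].tolist() == ["snp1"]
        assert report["reason"].tolist() == ["low_maf"]
        assert np.allclose(score, 0.1 * d[:, 0])

    def test_missing_weight_reported(self):
        panel = make_panel(np.array([[1, 1], [2, 0]]))
        w = pd.DataFrame({"snp_id": ["snp0"], "effect_allele": ["A"],
                          "weight": [0.5]})
        _, report = build_weighted_score(panel, w, maf_threshold=0.0)
        assert ("snp1", "missing_weight") in list(
            zip(report["snp_id"], report["reason"]))

    def test_allele_flip_orientation_algebra(self):
        # weight on the other allele: contribution w*(2-d), so the score
        # differs from the same-orientation score by 2w - 2wd per subject
        d = np.array([[0.0], [1.0], [2.0]])
        panel = make_panel(d)
        w_same = pd.DataFrame({"snp_id": ["snp0"], "effect_allele": ["A"],
                               "weight": [0.4]})
        w_flip = pd.DataFrame({"snp_id": ["snp0"], "effect_allele": ["B"],
                               "weight": [0.4]})
        s_same, _ = build_weighted_score(panel, w_same, maf_threshold=0.0)
        s_flip, _ = build_weighted_score(panel, w_flip, maf_threshold=0.0)
        assert np.allclose(s_flip - s_same, 2 * 0.4 - 2 * 0.4 * d[:, 0])

    def test_irreconcilable_allele_raises(self):
        panel = make_panel(np.array([[1.0]]))
        w = pd.DataFrame({"snp_id": ["snp0"], "effect_allele": ["C"],
                          "weight": [0.1]})
        with pytest.raises(AlleleMismatchError, match="snp0"):
            build_weighted_score(panel, w, maf_threshold=0.0)


class TestStage1:
    def test_noiseless(self):
        idx = pd.RangeIndex(50)
        rng = np.random.default_rng(1)
        score = pd.Series(rng.normal(size=50), index=idx)
        res = stage1_fit(2.0 * score, score)
        assert res.coef == pytest.approx(2.0, abs=1e-10)
        assert res.r2_incremental == pytest.approx(1.0, abs=1e-10)

    def test_recovers_configured_variance_explained(self):
        rng = np.random.default_rng(2)
        n = 75_000
        g = rng.normal(size=n)
        y = np.sqrt(0.011) * g + np.sqrt(1 - 0.011) * rng.normal(size=n)
        idx = pd.RangeIndex(n)
        res = stage1_fit(pd.Series(y, index=idx), pd.Series(g, index=idx))
        assert abs(res.r2_incremental - 0.011) < 0.002
        assert res.f_stat > 100

    def test_constant_score_fails(self):
        idx = pd.RangeIndex(10)
        with pytest.raises(ValueError, match="constant"):
            stage1_fit(pd.Series(np.arange(10.0), index=idx),
                       pd.Series(1.0, index=idx))


class TestTsls:
    def _confounded(self, rng, n1=20_000, n2=180, r2=0.1):
        g = rng.binomial(2, 0.3, n1).astype(float)
        u = rng.normal(size=n1)
        gs = (g - g.mean()) / g.std()
        bmi = np.sqrt(r2) * gs + 0.5 * u + np.sqrt(1 - r2 - 0.25) * rng.normal(size=n1)
        met = 0.3 * bmi + 0.5 * u + 0.5 * rng.normal(size=n1)
        idx = pd.RangeIndex(n1)
        return (pd.Series(met[:n2], index=idx[:n2]),
                pd.Series(bmi, index=idx), pd.Series(g, index=idx))

    def test_affine_score_invariance(self):
        rng = np.random.default_rng(3)
        met, bmi, score = self._confounded(rng)
        e1 = tsls_fit(met, bmi, score, sd_exposure=1.0)
        e2 = tsls_fit(met, bmi, 5.0 * score + 3.0, sd_exposure=1.0)
        assert e1.estimate == pytest.approx(e2.estimate, abs=1e-10)
        assert e1.se == pytest.approx(e2.se, abs=1e-10)

    def test_unbiased_under_confounding_vs_ols(self):
        rng = np.random.default_rng(4)
        ests, olss = [], []
        for _ in range(40):
            met, bmi, score = self._confounded(rng)
            ests.append(tsls_fit(met, bmi, score, sd_exposure=1.0).estimate)
            b = np.polyfit(bmi.iloc[:180], met, 1)[0]
            olss.append(b)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.3) < 4 * mc_se
        assert np.mean(olss) - 0.3 > 5 * mc_se  # OLS biased upward

    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(5)
        met, bmi, score = self._confounded(rng, n1=300, r2=0.001)
        est = tsls_fit(met.iloc[:100], bmi, score, sd_exposure=1.0)
        assert any("weak instrument" in w for w in est.warnings)

    def test_constant_predictor_fails(self):
        idx = pd.RangeIndex(50)
        rng = np.random.default_rng(6)
        met = pd.Series(rng.normal(size=50), index=idx)
        bmi = pd.Series(rng.normal(size=50), index=idx)
        score = pd.Series(rng.normal(size=50), index=idx)
        with pytest.raises(ValueError, match="constant"):
            # zero stage-1 coefficient forced via a degenerate stage1
            from metabcc.mr import Stage1Result
            tsls_fit(met, bmi, score, sd_exposure=1.0,
                     stage1=Stage1Result(0.0, 1.0, 0.0, 0.0, 50))

    def test_per_sd_scaling(self):
        rng = np.random.default_rng(7)
        met, bmi, score = self._confounded(rng)
        e = tsls_fit(met, bmi, score, sd_exposure=3.4)
        assert e.estimate == pytest.approx(3.4 * e.estimate_per_unit)


class TestSummaryMR:
    def test_single_snp_ivw_is_wald_ratio(self):
        est = summary_mr([0.2], [0.02], [0.1], [0.05], "ivw")
        assert est.estimate == pytest.approx(0.5)
        assert est.se == pytest.approx(0.05 / 0.2)

    def test_equal_weights_ivw_is_mean_ratio(self):
        bx = np.full(4, 0.1)
        by = np.array([0.05, 0.1, 0.2, 0.4])
        est = summary_mr(bx, np.full(4, 0.01), by, np.full(4, 0.03), "ivw")
        assert est.estimate == pytest.approx(np.mean(by / bx))

    def test_egger_zero_intercept_reproduces_ivw(self):
        rng = np.random.default_rng(8)
        bx = rng.normal(0.1, 0.05, 10)
        bx[bx == 0] = 0.01
        by = 0.4 * bx + rng.normal(0, 0.02, 10)
        sx = np.full(10, 0.01)
        sy = rng.uniform(0.02, 0.05, 10)
        ivw = summary_mr(bx, sx, by, sy, "ivw")
        egger0 = summary_mr(bx, sx, by, sy, "egger", egger_intercept=False)
        assert abs(egger0.estimate - ivw.estimate) < 1e-10

    def test_egger_carries_intercept_others_do_not(self):
        bx, sx = np.array([0.1, 0.2, 0.3]), np.full(3, 0.01)
        by, sy = np.array([0.05, 0.1, 0.2]), np.full(3, 0.03)
        egger = summary_mr(bx, sx, by, sy, "egger")
        assert egger.intercept is not None and egger.intercept_se is not None
        assert summary_mr(bx, sx, by, sy, "ivw").intercept is None

    def test_weighted_median_hand_example(self):
        est = summary_mr([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.9],
                         [0.05] * 3, "wmedian", n_boot=50)
        assert est.estimate == pytest.approx(2.0)

    def test_weighted_quantile_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            k = rng.integers(3, 12)
            x = rng.normal(size=k)
            w = rng.uniform(0.1, 5.0, size=k)
            assert _weighted_quantile(x, w) == pytest.approx(
                brute_force_weighted_median(x, w), abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            summary_mr([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.03] * 2, "egger")
        with pytest.raises(ValueError, match="zero exposure"):
            summary_mr([0.0, 0.1, 0.2], [0.01] * 3, [0.1] * 3, [0.03] * 3, "ivw")
        with pytest.raises(ValueError):
            summary_mr([0.1], [0.01], [0.1], [-0.5], "ivw")

    def test_wmedian_bootstrap_seeded(self):
        bx, sx = np.array([0.1, 0.2, 0.15]), np.full(3, 0.02)
        by, sy = np.array([0.05, 0.1, 0.07]), np.full(3, 0.03)
        a = summary_mr(bx, sx, by, sy, "wmedian", seed=3)
        b = summary_mr(bx, sx, by, sy, "wmedian", seed=3)
        assert a.se == b.se


class TestCochranQ:
    def test_equal_estimates(self):
        q, p = cochran_q_two(0.4, 0.1, 0.4, 0.2)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_value(self):
        q, _ = cochran_q_two(1.0, 1.0, -1.0, 1.0)
        assert q == pytest.approx(2.0)

    def test_symmetry(self):
        a = cochran_q_two(0.3, 0.05, 0.1, 0.2)
        b = cochran_q_two(0.1, 0.2, 0.3, 0.05)
        assert a == pytest.approx(b)


class TestConfounderScreen:
    def test_null_calibration_and_power(self):
        rng = np.random.default_rng(10)
        n = 10_000
        idx = pd.RangeIndex(n)
        score = pd.Series(rng.normal(size=n), index=idx)
        conf = pd.DataFrame(rng.normal(size=(n, 40)),
                            columns=[f"c{i}" for i in range(40)], index=idx)
        tab = sc = confounder_screen(score, conf)
        assert (tab["p"] < 0.05).mean() < 0.2  # ~5% nominal, loose binomial
        conf["driven"] = 0.1 * score + rng.normal(size=n)
        tab = confounder_screen(score, conf)
        assert tab.loc["driven", "p"] < 1e-3

    def test_empty_confounder_set(self):
        score = pd.Series(np.arange(5.0))
        tab = confounder_screen(score, pd.DataFrame(index=score.index))
        assert tab.empty
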