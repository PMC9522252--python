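"""Evaluation statistics against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from overscanqa.stats import (
    ContingencyTable,
    build_contingency,
    cohens_kappa,
    diagnostic_metrics,
    evaluate_predictions,
    fisher_exact,
    proportion_ci,
    roc_sweep,
    univariate_or,
    univariate_or_levels,
    workload_reduction,
)
from overscanqa.volume import GoldRecord

INTERNAL = ContingencyTable(46, 6, 1, 157)
EXTERNAL = ContingencyTable(15, 1, 1, 33)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_enumeration(tp, fp, fn, tn):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    n = tp + fp + fn + tn
    r, c = tp + fp, tp + fn
    kmin, kmax = max(0, r + c - n), min(r, c)
    support = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(support, n, c, r)
    observed = sps.hypergeom.pmf(tp, n, c, r)
    return float(pmf[pmf <= observed * (1 + 1e-9)].sum())

def clopper_pearson_by_inversion(k, n, level=0.95):
    """CP bounds by numerically inverting the binomial tail probabilities."""
    from scipy.optimize import brentq

    alpha = 1 - level
    lo = 0.0 if k == 0 else brentq(
        lambda p: sps.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    hi = 1.0 if k == n else brentq(
        lambda p: sps.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    return lo, hi

def auc_by_pair_counting(scores, labels):
    """Probability of correct ranking, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestContingency:
    def test_build_from_paired_records(self):
        preds, gold = {}, []
        k = 0
        for tp_fp_fn_tn, (p, g) in zip(
            (46, 6, 1, 157), ((1, 1), (1, 0), (0, 1), (0, 0))
        ):
            for _ in range(tp_fp_fn_tn):
                sid = f"s{k}"
                preds[sid] = bool(p)
                gold.append(GoldRecord(series_id=sid, overscan=bool(g)))
                k += 1
        t = build_contingency(preds, gold)
        assert (t.tp, t.fp, t.fn, t.tn) == (46, 6, 1, 157)
        assert t.n == 210

    def test_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="unmatched"):
            build_contingency({"a": True}, [GoldRecord(series_id="b", overscan=True)])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_contingency({}, [])


class TestProportionCI:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(203, 210, 0.9325, 0.9865), (46, 47, 0.8871, 0.9995), (157, 163, 0.9216, 0.9864)],
    )
    def test_published_intervals(self, k, n, lo, hi):
        res = proportion_ci(k, n)
        assert res.ci_low == pytest.approx(lo, abs=5e-5)
        assert res.ci_high == pytest.approx(hi, abs=5e-5)

    def test_edge_conventions(self):
        assert proportion_ci(0, 10).ci_low == 0.0
        assert proportion_ci(10, 10).ci_high == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(n=st.integers(1, 60), frac=st.floats(0, 1), level=st.sampled_from([0.9, 0.95, 0.99]))
    def test_matches_inversion_oracle(self, n, frac, level):
        k = min(n, int(frac * (n + 1)))
        res = proportion_ci(k, n, level)
        lo, hi = clopper_pearson_by_inversion(k, n, level)
        assert res.ci_low == pytest.approx(lo, abs=1e-8)
        assert res.ci_high == pytest.approx(hi, abs=1e-8)
        assert res.ci_low <= k / n <= res.ci_high

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 10, level=1.5)

    def test_logit_flag(self):
        res = proportion_ci(203, 210, method="logit")
        assert res.method == "logit"
        assert res.ci_low < 203 / 210 < res.ci_high

    def test_coverage_simulation(self):
        # exact interval must cover at >= nominal rate (here p=0.9, n=210)
        rng = np.random.default_rng(42)
        p, n, reps = 0.9, 210, 2000
        draws = rng.binomial(n, p, size=reps)
        bounds = {k: proportion_ci(k, n) for k in np.unique(draws)}
        covered = sum(bounds[k].ci_low <= p <= bounds[k].ci_high for k in draws)
        assert covered / reps >= 0.95 - 0.01


class TestDiagnosticMetrics:
    def test_internal_published_values(self):
        m = diagnostic_metrics(INTERNAL)
        assert m["accuracy"].as_percent() == (96.67, 93.25, 98.65)
        assert m["sensitivity"].as_percent() == (97.87, 88.71, 99.95)
        assert m["specificity"].as_percent() == (96.32, 92.16, 98.64)

    def test_external_published_values(self):
        m = diagnostic_metrics(EXTERNAL)
        assert m["accuracy"].as_percent()[0] == 96.00
        assert m["sensitivity"].as_percent()[0] == 93.75
        assert m["specificity"].as_percent()[0] == 97.06

    def test_perfect_table(self):
        m = diagnostic_metrics(ContingencyTable(5, 0, 0, 7))
        assert all(res.estimate == 1.0 for res in m.values())

    def test_zero_denominator_flagged_undefined(self):
        m = diagnostic_metrics(ContingencyTable(0, 3, 0, 5))
        assert not m["sensitivity"].defined
        assert m["specificity"].defined


class TestKappa:
    def test_published_tables(self):
        assert cohens_kappa(INTERNAL) == pytest.approx(0.9076, abs=5e-5)
        assert cohens_kappa(EXTERNAL) == pytest.approx(0.9081, abs=5e-5)

    def test_perfect_agreement(self):
        assert cohens_kappa(ContingencyTable(4, 0, 0, 9)) == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 20)] * 4))
    def test_transpose_invariance_and_sklearn_agreement(self, cells):
        tp, fp, fn, tn = cells
        if tp + fp + fn + tn == 0:
            return
        t = ContingencyTable(tp, fp, fn, tn)
        assert cohens_kappa(t) == pytest.approx(cohens_kappa(t.transpose()), abs=1e-12)
        from sklearn.metrics import cohen_kappa_score

        a = [1] * (tp + fp) + [0] * (fn + tn)
        b = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        expected = cohen_kappa_score(a, b)
        if not math.isnan(expected):
            assert cohens_kappa(t) == pytest.approx(expected, abs=1e-12)

    def test_kappa_one_iff_no_disagreement(self):
        assert cohens_kappa(ContingencyTable(3, 1, 0, 6)) < 1.0
        assert cohens_kappa(ContingencyTable(3, 0, 0, 6)) == 1.0


class TestFisher:
    def test_published_tables_significant(self):
        assert fisher_exact(INTERNAL) < 0.001
        assert fisher_exact(EXTERNAL) < 0.001

    def test_no_association(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_diagonal_three_by_enumeration(self):
        # all tables with margins (3,3)/(3,3): only k=0 and k=3 are as
        # extreme as observed, each with probability 1/20
        assert fisher_exact(ContingencyTable(3, 0, 0, 3)) == pytest.approx(0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 8)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        tp, fp, fn, tn = cells
        if tp + fp + fn + tn == 0:
            return
        ours = fisher_exact(ContingencyTable(tp, fp, fn, tn))
        assert ours == pytest.approx(
            fisher_two_sided_enumeration(tp, fp, fn, tn), abs=1e-9
        )


class TestRocSweep:
    def test_separable_cohort_gives_auc_one(self):
        scores = [12.0, 15, 20, 30, 1, 2, 0, 4]
        gold = [True] * 4 + [False] * 4
        curve = roc_sweep(scores, gold)
        assert curve.auc == pytest.approx(1.0)

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(7)
        gold = np.concatenate([np.ones(47, bool), np.zeros(163, bool)])
        scores = np.concatenate([rng.uniform(10, 30, 47), rng.uniform(0, 8, 163)])
        aucs = []
        for _ in range(20):
            aucs.append(roc_sweep(rng.permutation(scores), gold).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_sign_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=30)
        gold = rng.random(30) > 0.5
        if gold.all() or not gold.any():
            gold[0] = ~gold[0]
        a = roc_sweep(scores, gold).auc
        b = roc_sweep(-scores, ~gold).auc
        assert a == pytest.approx(b, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = rng.integers(0, 10, n).astype(float)
        gold = rng.random(n) > 0.5
        if gold.all() or not gold.any():
            gold[0] = ~gold[0]
        curve = roc_sweep(scores, gold)
        assert curve.auc == pytest.approx(auc_by_pair_counting(scores, gold), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_sweep([1.0, 2.0], [True, True])


class TestUnivariateOR:
    def test_published_data_source_odds_ratio(self):
        res = univariate_or((203, 7), (48, 2))
        assert res["or"] == pytest.approx(0.828, abs=5e-4)
        assert res["ci_low"] == pytest.approx(0.17, abs=5e-3)
        assert res["ci_high"] == pytest.approx(4.11, abs=5e-3)
        assert res["p"] == pytest.approx(0.817, abs=5e-3)

    def test_identical_rows_or_one(self):
        assert univariate_or((30, 5), (30, 5))["or"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = univariate_or((10, 0), (8, 2))
        assert math.isfinite(res["or"]) and res["or"] > 0

    def test_degenerate_level_rejected(self):
        with pytest.raises(ValueError):
            univariate_or((0, 0), (5, 5))

    def test_matches_logistic_regression(self):
        import statsmodels.api as sm

        a, b, c, d = 203, 7, 48, 2
        y = [1] * a + [0] * b + [1] * c + [0] * d
        x = [0] * (a + b) + [1] * (c + d)
        fit = sm.Logit(y, sm.add_constant(np.array(x, float))).fit(disp=0)
        res = univariate_or((a, b), (c, d))
        assert res["or"] == pytest.approx(math.exp(fit.params[1]), rel=1e-6)
        assert res["p"] == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_multi_level_contrasts(self):
        levels = {"siemens": (80, 3), "ge": (68, 3), "philips": (63, 2)}
        out = univariate_or_levels(levels, "siemens")
        assert out["siemens"]["or"] == 1.0
        assert set(out) == set(levels)


class TestWorkloadReduction:
    def test_published_values(self):
        assert workload_reduction((47, 210)) == pytest.approx(77.6, abs=0.05)
        assert workload_reduction((16, 50)) == pytest.approx(68.0)

    def test_zero_prevalence(self):
        assert workload_reduction((0, 99)) == 100.0

    def test_from_records(self):
        recs = [GoldRecord(series_id=str(i), overscan=i < 4) for i in range(10)]
        assert workload_reduction(recs) == pytest.approx(60.0)


class TestEvaluatePredictions:
    def test_full_report_shape(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        gold, rows = [], []
        for i in range(40):
            tag = i < 10
            gold.append(GoldRecord(series_id=f"s{i}", overscan=tag))
            rows.append(
                {
                    "series_id": f"s{i}",
                    "predicted_overscan": int(tag),
                    "score_mm": rng.uniform(10, 25) if tag else rng.uniform(0, 7),
                }
            )
        report = evaluate_predictions(pd.DataFrame(rows), gold)
        assert report["contingency"] == {"tp": 10, "fp": 0, "fn": 0, "tn": 30}
        assert report["metrics"]["accuracy"]["percent"] == 100.0
        assert report["kappa"] == 1.0
        assert report["auroc"] == 1.0
        assert report["workload_reduction_percent"] == 75.0
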