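"""Diagnostic-accuracy statistics for scan-range decision validation.

Covers the complete evaluation design: 2x2 contingency tables of
algorithm-vs-radiologist overscan tags; accuracy, sensitivity and
specificity with exact Clopper-Pearson confidence intervals (a logit
interval is available behind a flag); Cohen's kappa by the standard
(p_o - p_e)/(1 - p_e) formula; Fisher's exact test (two-sided,
probability-mass criterion); a linear-approximation ROC over a decision
threshold sweep with trapezoid AUC; univariate odds ratios with Wald
intervals (the single-binary-covariate logistic estimate equals the
cross-product ratio); and the workload-reduction summary.

Display conventions follow the field's reporting style: percentages to
two decimals, kappa and odds ratios to three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .volume import GoldRecord

__all__ = [
    "ContingencyTable",
    "MetricResult",
    "RocCurve",
    "build_contingency",
    "proportion_ci",
    "diagnostic_metrics",
    "cohens_kappa",
    "fisher_exact",
    "roc_sweep",
    "univariate_or",
    "univariate_or_levels",
    "workload_reduction",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of algorithm vs gold-standard overscan tags.

    tp: algorithm overscan & gold overscan; fp: algorithm overscan & gold
    none; fn: algorithm none & gold overscan; tn: both none.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0 or v != int(v):
                raise ValueError("cell counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


@dataclass
class MetricResult:
    """Point estimate with a two-sided confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper-pearson"
    defined: bool = True

    def __post_init__(self):
        if self.defined and not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("interval must contain the point estimate")

    def as_percent(self, digits: int = 2) -> tuple[float, float, float]:
        return (
            round(100 * self.estimate, digits),
            round(100 * self.ci_low, digits),
            round(100 * self.ci_high, digits),
        )


def build_contingency(
    predictions: Mapping[str, bool] | pd.DataFrame,
    gold: Sequence[GoldRecord] | Mapping[str, bool],
) -> ContingencyTable:
    """Pair per-series predictions with gold tags into a 2x2 table.

    Every series must appear on both sides; unmatched ids raise, listing
    the offenders.
    """
    if isinstance(predictions, pd.DataFrame):
        predictions = dict(
            zip(
                predictions["series_id"].astype(str),
                predictions["predicted_overscan"].astype(int).astype(bool),
            )
        )
    if not isinstance(gold, Mapping):
        gold = {r.series_id: r.overscan for r in gold}
    if len(predictions) == 0 or len(gold) == 0:
        raise ValueError("empty predictions or gold records")
    missing = sorted(set(predictions) ^ set(gold))
    if missing:
        raise ValueError(f"unmatched series ids: {missing[:10]}")
    tp = fp = fn = tn = 0
    for sid, pred in predictions.items():
        g = bool(gold[sid])
        if pred and g:
            tp += 1
        elif pred and not g:
            fp += 1
        elif not pred and g:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "clopper-pearson"
) -> MetricResult:
    """Exact (Clopper-Pearson) two-sided binomial interval.

    Edge conventions: lower bound 0 when successes = 0, upper bound 1 when
    successes = n.  ``method='logit'`` gives the Wald interval on the
    log-odds scale instead.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n with n > 0")
    p = successes / n
    alpha = 1.0 - level
    if method in ("clopper-pearson", "beta", "exact"):
        lo, hi = proportion_confint(successes, n, alpha=alpha, method="beta")
        lo = 0.0 if successes == 0 else float(lo)
        hi = 1.0 if successes == n else float(hi)
        return MetricResult(p, lo, hi, level, "clopper-pearson")
    if method == "logit":
        if successes in (0, n):
            raise ValueError("logit interval undefined at the boundary")
        z = sps.norm.ppf(1 - alpha / 2)
        logit = math.log(p / (1 - p))
        se = math.sqrt(1.0 / (n * p * (1 - p)))
        lo = 1 / (1 + math.exp(-(logit - z * se)))
        hi = 1 / (1 + math.exp(-(logit + z * se)))
        return MetricResult(p, lo, hi, level, "logit")
    raise ValueError(f"unknown CI method '{method}'")


def diagnostic_metrics(
    table: ContingencyTable, level: float = 0.95, method: str = "clopper-pearson"
) -> dict[str, MetricResult]:
    """Accuracy, sensitivity and specificity with exact CIs.

    A metric whose denominator is zero is returned flagged undefined.
    """
    if table.n <= 0:
        raise ValueError("empty table")
    out: dict[str, MetricResult] = {}
    pairs = {
        "accuracy": (table.tp + table.tn, table.n),
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            out[name] = MetricResult(float("nan"), float("nan"), float("nan"),
                                     level, "undefined", defined=False)
        else:
            out[name] = proportion_ci(num, den, level, method)
    return out


def cohens_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e uses the marginal products.  Returns 1 for
    perfect agreement with degenerate margins (p_e = 1, p_o = 1).
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty table")
    po = (table.tp + table.tn) / n
    row1, row0 = table.tp + table.fp, table.fn + table.tn
    col1, col0 = table.tp + table.fn, table.fp + table.tn
    pe = (row1 * col1 + row0 * col0) / (n * n)
    if pe >= 1.0:
        return 1.0 if po >= 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (probability-mass criterion): the sum of
    hypergeometric probabilities of all tables with fixed margins whose
    probability does not exceed the observed table's."""
    if table.n <= 0:
        raise ValueError("empty table")
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


@dataclass
class RocCurve:
    """Linear-approximation ROC from a decision-threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def plot(self, ax=None, label: Optional[str] = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.fpr, self.tpr, marker="o",
                label=label or f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_sweep(
    scores: Sequence[float],
    gold: Sequence[bool],
    thresholds: Optional[Sequence[float]] = None,
) -> RocCurve:
    """ROC points from sweeping the decision threshold over case scores.

    A case is called overscan when its score (max per-side excess length,
    mm) strictly exceeds the threshold.  One (FPR, TPR) point per
    threshold; endpoints (0,0) and (1,1) are appended and the AUC is the
    trapezoid-rule area.
    """
    scores = np.asarray(scores, dtype=float)
    gold = np.asarray(gold, dtype=bool)
    if scores.shape != gold.shape:
        raise ValueError("scores and gold labels must align")
    n_pos, n_neg = int(gold.sum()), int((~gold).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative case")
    if thresholds is None:
        thresholds = np.unique(scores)
    thresholds = np.asarray(sorted(thresholds), dtype=float)

    fpr = np.empty(thresholds.size)
    tpr = np.empty(thresholds.size)
    for k, tau in enumerate(thresholds):
        called = scores > tau
        tpr[k] = (called & gold).sum() / n_pos
        fpr[k] = (called & ~gold).sum() / n_neg
    order = np.lexsort((tpr, fpr))
    fpr, tpr = fpr[order], tpr[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def univariate_or(
    reference: tuple[int, int],
    other: tuple[int, int],
    level: float = 0.95,
) -> dict[str, float]:
    """Odds ratio of decision correctness for a binary covariate.

    ``reference`` and ``other`` are (correct, incorrect) counts; the OR of
    the other level against the reference is the cross-product ratio,
    which equals the single-covariate logistic estimate.  The CI and p
    are Wald on the log scale; zero cells get the Haldane-Anscombe +0.5
    correction.
    """
    a, b = reference
    c, d = other
    if a + b == 0 or c + d == 0:
        raise ValueError("degenerate covariate: a level has no observations")
    cells = [a, b, c, d]
    if 0 in cells:
        a, b, c, d = (v + 0.5 for v in cells)
    or_ = (c / d) / (a / b)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(or_)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return {
        "or": or_,
        "ci_low": math.exp(log_or - z * se),
        "ci_high": math.exp(log_or + z * se),
        "p": float(p),
        "level": level,
    }


def univariate_or_levels(
    levels: Mapping[str, tuple[int, int]],
    reference: str,
    level: float = 0.95,
) -> dict[str, dict[str, float]]:
    """Dummy contrasts of each covariate level against a reference level
    (multi-level covariates such as CT vendor)."""
    if reference not in levels:
        raise ValueError(f"reference level '{reference}' not present")
    if len(levels) < 2:
        raise ValueError("need at least two covariate levels")
    ref = levels[reference]
    out = {reference: {"or": 1.0, "ci_low": float("nan"),
                       "ci_high": float("nan"), "p": float("nan"), "level": level}}
    for name, counts in levels.items():
        if name == reference:
            continue
        out[name] = univariate_or(ref, counts, level)
    return out


def workload_reduction(gold: Sequence[GoldRecord] | tuple[int, int]) -> float:
    """Percent of cases needing no human review when only alerted cases
    are checked: 100 x (1 - overscan prevalence)."""
    if isinstance(gold, tuple):
        tagged, n = gold
    else:
        n = len(gold)
        tagged = sum(1 for r in gold if r.overscan)
    if n <= 0:
        raise ValueError("empty gold records")
    return 100.0 * (1.0 - tagged / n)


def evaluate_predictions(
    predictions: pd.DataFrame,
    gold: Sequence[GoldRecord],
    level: float = 0.95,
    roc: bool = True,
) -> dict:
    """Full evaluation report for a per-case prediction table.

    ``predictions`` needs columns series_id, predicted_overscan and
    (for the ROC sweep) score_mm.
    """
    table = build_contingency(predictions, gold)
    metrics = diagnostic_metrics(table, level)
    report = {
        "n": table.n,
        "contingency": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "metrics": {
            name: {
                "percent": res.as_percent()[0],
                "ci_low_percent": res.as_percent()[1],
                "ci_high_percent": res.as_percent()[2],
                "level": res.level,
                "method": res.method,
            }
            for name, res in metrics.items()
        },
        "kappa": round(cohens_kappa(table), 3),
        "fisher_p": fisher_exact(table),
        "workload_reduction_percent": round(workload_reduction(gold), 1),
    }
    if roc and "score_mm" in predictions.columns:
        gold_map = {r.series_id: r.overscan for r in gold}
        labels = [gold_map[sid] for sid in predictions["series_id"].astype(str)]
        if any(labels) and not all(labels):
            curve = roc_sweep(predictions["score_mm"].to_numpy(), labels)
            report["auroc"] = round(curve.auc, 3)
    return report
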