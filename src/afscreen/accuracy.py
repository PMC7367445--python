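"""Diagnostic accuracy of categorical AF calls against a reference rater.

Each index test (pulse palpation, device algorithm, pharmacist read) is
compared with the cardiologist's single-lead ECG interpretation through a
2x2 confusion table after dichotomising the four call categories into
AF-positive / AF-negative / excluded.  Point estimates carry exact
Clopper-Pearson 95% intervals; chance-corrected agreement is Cohen's kappa
with an asymptotic-SE interval; paired accuracy differences are tested with
Cochran's Q followed by post-hoc McNemar tests under a Bonferroni
correction.

Two dichotomy conventions matter in practice.  The library default excludes
unreadable traces pairwise.  :meth:`DichotomyPolicy.published_tables`
instead counts unreadable as AF-negative with no exclusions, which is the
convention that reproduces the reference study's published accuracy table
(including its confidence intervals) exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls import AF, CALL_CATEGORIES, SR, UNCLASSIFIED, UNREADABLE

__all__ = [
    "DichotomyPolicy",
    "ConfusionTable",
    "Estimate",
    "AccuracyReport",
    "PairedComparisonResult",
    "UndefinedMeasureError",
    "dichotomize",
    "build_confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "ppv_and_fdr",
    "false_positive_rate",
    "exact_binomial_ci",
    "cohens_kappa",
    "mcnemar_test",
    "cochran_q",
    "bonferroni",
    "accuracy_report",
    "table2_report",
]

INDEX_TESTS = ("device", "pharmacist", "pulse")
REFERENCE = "cardiologist"


class UndefinedMeasureError(ZeroDivisionError):
    """A measure's denominator is empty (e.g. no reference positives)."""


@dataclass(frozen=True)
class DichotomyPolicy:
    """Partition of the four call categories into positive/negative/excluded."""

    positive: frozenset = frozenset({AF})
    negative: frozenset = frozenset({SR, UNCLASSIFIED})
    excluded: frozenset = frozenset({UNREADABLE})
    exclusion_mode: str = "pairwise"

    def __post_init__(self) -> None:
        sets = (self.positive, self.negative, self.excluded)
        union = self.positive | self.negative | self.excluded
        total = sum(len(s) for s in sets)
        if union != CALL_CATEGORIES or total != len(CALL_CATEGORIES):
            raise ValueError(
                "positive/negative/excluded must partition "
                f"{sorted(CALL_CATEGORIES)}; got {[sorted(s) for s in sets]}"
            )
        if self.exclusion_mode not in ("pairwise", "listwise"):
            raise ValueError(f"exclusion_mode must be pairwise or listwise, got {self.exclusion_mode!r}")

    @classmethod
    def published_tables(cls) -> "DichotomyPolicy":
        """Unreadable counted as AF-negative, nothing excluded (n = all screened).

        This is the convention under which the reference study's published
        summary table (point values and intervals) is reproduced exactly.
        """
        return cls(
            positive=frozenset({AF}),
            negative=frozenset({SR, UNCLASSIFIED, UNREADABLE}),
            excluded=frozenset(),
        )


def dichotomize(call: str, policy: DichotomyPolicy | None = None) -> str:
    """Map a call category to ``'positive'``, ``'negative'`` or ``'excluded'``."""
    policy = policy or DichotomyPolicy()
    if call not in CALL_CATEGORIES:
        raise ValueError(f"unknown call category {call!r}")
    if call in policy.positive:
        return "positive"
    if call in policy.negative:
        return "negative"
    return "excluded"


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn, self.n_excluded) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_effective(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _call_masks(calls: Sequence[str], policy: DichotomyPolicy) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(calls, dtype=object)
    unknown = set(arr) - CALL_CATEGORIES
    if unknown:
        raise ValueError(f"unknown call categories {sorted(map(str, unknown))}")
    pos = np.isin(arr, list(policy.positive))
    exc = np.isin(arr, list(policy.excluded)) if policy.excluded else np.zeros(len(arr), bool)
    return pos, exc


def build_confusion(
    index_calls: Sequence[str],
    reference_calls: Sequence[str],
    policy: DichotomyPolicy | None = None,
    *,
    extra_exclude: np.ndarray | None = None,
) -> ConfusionTable:
    """Cross-tabulate dichotomised index vs reference calls.

    A pair is dropped when either side falls in the excluded set (pairwise
    exclusion); ``extra_exclude`` lets a caller impose a listwise mask
    computed across several raters.
    """
    if len(index_calls) != len(reference_calls):
        raise ValueError(
            f"index and reference call sequences differ in length "
            f"({len(index_calls)} vs {len(reference_calls)})"
        )
    policy = policy or DichotomyPolicy()
    ipos, iexc = _call_masks(index_calls, policy)
    rpos, rexc = _call_masks(reference_calls, policy)
    drop = iexc | rexc
    if extra_exclude is not None:
        drop = drop | np.asarray(extra_exclude, dtype=bool)
    keep = ~drop
    if not keep.any():
        raise UndefinedMeasureError("no usable index/reference pairs after exclusions")
    ipos, rpos = ipos[keep], rpos[keep]
    return ConfusionTable(
        tp=int((ipos & rpos).sum()),
        fp=int((ipos & ~rpos).sum()),
        fn=int((~ipos & rpos).sum()),
        tn=int((~ipos & ~rpos).sum()),
        n_excluded=int(drop.sum()),
    )


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a two-sided confidence interval."""

    value: float
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise ValueError(f"CI {self.ci} does not contain the point estimate {self.value}")


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval from beta quantiles.

    The lower bound is exactly 0 when ``successes == 0`` and the upper bound
    exactly 1 when ``successes == n``.
    """
    if not 0 <= successes <= n or n <= 0:
        raise ValueError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha, successes + 1, n - successes))
    return lo, hi


def _proportion(successes: int, n: int, level: float, what: str) -> Estimate:
    if n <= 0:
        raise UndefinedMeasureError(f"{what} undefined: empty denominator")
    return Estimate(successes / n, exact_binomial_ci(successes, n, level))


def sensitivity(ct: ConfusionTable, level: float = 0.95) -> Estimate:
    """TP / (TP + FN): probability of a positive call given reference AF."""
    return _proportion(ct.tp, ct.tp + ct.fn, level, "sensitivity")


def specificity(ct: ConfusionTable, level: float = 0.95) -> Estimate:
    """TN / (TN + FP): probability of a negative call given reference non-AF."""
    return _proportion(ct.tn, ct.tn + ct.fp, level, "specificity")


def accuracy(ct: ConfusionTable, level: float = 0.95) -> Estimate:
    """(TP + TN) / n: the correct classification rate."""
    return _proportion(ct.tp + ct.tn, ct.n_effective, level, "accuracy")


def ppv_and_fdr(ct: ConfusionTable, level: float = 0.95) -> tuple[Estimate, Estimate]:
    """PPV = TP / test-positives and FDR = FP / test-positives (= 1 - PPV)."""
    return (
        _proportion(ct.tp, ct.tp + ct.fp, level, "PPV"),
        _proportion(ct.fp, ct.tp + ct.fp, level, "FDR"),
    )


def false_positive_rate(
    ct: ConfusionTable, level: float = 0.95, *, denominator: str = "negatives", n_screened: int | None = None
) -> Estimate:
    """FP over reference negatives (default, = 1 - specificity) or over all screened."""
    if denominator == "negatives":
        return _proportion(ct.fp, ct.fp + ct.tn, level, "false-positive rate")
    if denominator == "screened":
        n = ct.n_effective + ct.n_excluded if n_screened is None else n_screened
        return _proportion(ct.fp, n, level, "false-positive rate")
    raise ValueError(f"denominator must be 'negatives' or 'screened', got {denominator!r}")


def cohens_kappa(ct: ConfusionTable, level: float = 0.95) -> Estimate:
    """Chance-corrected agreement on the dichotomised 2x2 table.

    kappa = (p_obs - p_exp) / (1 - p_exp) with the simple asymptotic
    standard error sqrt(p_obs (1 - p_obs) / n) / (1 - p_exp).
    """
    n = ct.n_effective
    if n <= 0:
        raise UndefinedMeasureError("kappa undefined: empty table")
    p_obs = (ct.tp + ct.tn) / n
    p_exp = ((ct.tp + ct.fp) * (ct.tp + ct.fn) + (ct.fn + ct.tn) * (ct.fp + ct.tn)) / n**2
    if p_exp >= 1.0 - 1e-12:
        raise UndefinedMeasureError("kappa undefined: degenerate marginals (p_exp = 1)")
    kappa = (p_obs - p_exp) / (1.0 - p_exp)
    se = math.sqrt(p_obs * (1.0 - p_obs) / n) / (1.0 - p_exp)
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo, hi = max(-1.0, kappa - z * se), min(1.0, kappa + z * se)
    return Estimate(kappa, (lo, hi))


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # pairs where only the first classifier is correct
    c: int  # pairs where only the second classifier is correct
    method: str


def mcnemar_test(
    correct_a: Sequence[bool], correct_b: Sequence[bool], *, method: str = "auto", exact_threshold: int = 25
) -> McNemarResult:
    """Paired test of marginal accuracy between two classifiers.

    ``method='auto'`` uses the exact two-sided binomial test when the
    discordant total b + c is below ``exact_threshold`` and the
    continuity-corrected chi-squared test otherwise.  With no discordant
    pairs the statistic is 0 and p = 1 by convention.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("correctness flag sequences must be aligned and equal length")
    b = int((a & ~bb).sum())
    c = int((~a & bb).sum())
    n_disc = b + c
    if method not in ("auto", "exact", "chi2"):
        raise ValueError(f"method must be auto/exact/chi2, got {method!r}")
    use_exact = method == "exact" or (method == "auto" and n_disc < exact_threshold)
    if n_disc == 0:
        return McNemarResult(0.0, 1.0, b, c, "exact" if use_exact else "chi2")
    if use_exact:
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n_disc, 0.5)))
        return McNemarResult(float(k), p, b, c, "exact")
    statistic = (abs(b - c) - 1.0) ** 2 / n_disc
    p = float(stats.chi2.sf(statistic, df=1))
    return McNemarResult(statistic, p, b, c, "chi2")


@dataclass(frozen=True)
class CochranQResult:
    statistic: float
    df: int
    p_value: float


def cochran_q(correctness: np.ndarray) -> CochranQResult:
    """Cochran's Q over a participants x classifiers matrix of correctness flags.

    With k = 2 classifiers Q reduces to the uncorrected McNemar chi-squared
    statistic.  All-identical columns give Q = 0, p = 1.
    """
    x = np.asarray(correctness, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 1:
        raise ValueError("need a 2-D matrix with >= 1 row and >= 2 columns")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("correctness matrix must be binary with no missing flags")
    n, k = x.shape
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - (row**2).sum()
    if denom == 0:
        return CochranQResult(0.0, k - 1, 1.0)
    q = k * (k - 1) * ((col - col.mean()) ** 2).sum() / denom
    return CochranQResult(float(q), k - 1, float(stats.chi2.sf(q, df=k - 1)))


def bonferroni(p_values: Iterable[float], m_comparisons: int | None = None) -> list[float]:
    """Multiply each p-value by the number of comparisons, capping at 1."""
    ps = list(p_values)
    m = len(ps) if m_comparisons is None else m_comparisons
    if m < len(ps):
        raise ValueError(f"m_comparisons ({m}) smaller than the number of p-values ({len(ps)})")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return [min(1.0, p * m) for p in ps]


@dataclass(frozen=True)
class AccuracyReport:
    """One index test's accuracy measures vs the reference: a report row.

    A measure whose denominator is empty (e.g. specificity with no
    reference negatives) is ``None`` rather than an error, so degenerate
    inputs still yield a report.
    """

    name: str
    table: ConfusionTable
    sensitivity: Estimate | None
    specificity: Estimate | None
    accuracy: Estimate | None
    ppv: Estimate | None
    fdr: Estimate | None
    fpr: Estimate | None
    kappa: Estimate | None

    @property
    def n_effective(self) -> int:
        return self.table.n_effective


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mcnemar_statistic: float
    raw_p: float
    bonferroni_adjusted_p: float
    method: str


@dataclass(frozen=True)
class PairedComparisonResult:
    cochran_q_statistic: float
    cochran_q_df: int
    cochran_q_p: float
    n_complete: int
    pairwise: tuple[PairwiseComparison, ...] = field(default_factory=tuple)


def accuracy_report(
    index_calls: Sequence[str],
    reference_calls: Sequence[str],
    policy: DichotomyPolicy | None = None,
    *,
    name: str = "index",
    level: float = 0.95,
    extra_exclude: np.ndarray | None = None,
) -> AccuracyReport:
    """Full accuracy row for one index test against the reference."""
    ct = build_confusion(index_calls, reference_calls, policy, extra_exclude=extra_exclude)

    def attempt(fn):
        try:
            return fn(ct, level)
        except UndefinedMeasureError:
            return None

    pf = attempt(ppv_and_fdr)
    return AccuracyReport(
        name=name,
        table=ct,
        sensitivity=attempt(sensitivity),
        specificity=attempt(specificity),
        accuracy=attempt(accuracy),
        ppv=pf[0] if pf else None,
        fdr=pf[1] if pf else None,
        fpr=attempt(false_positive_rate),
        kappa=attempt(cohens_kappa),
    )


def table2_report(
    records: pd.DataFrame,
    policy: DichotomyPolicy | None = None,
    *,
    level: float = 0.95,
    tests: Sequence[str] = INDEX_TESTS,
    reference: str = REFERENCE,
) -> tuple[dict[str, AccuracyReport], PairedComparisonResult]:
    """Accuracy rows for every index test plus the paired comparison chain.

    ``records`` must carry ``call_<rater>`` columns.  Rows are computed per
    test with the policy's exclusion mode; the Cochran Q / McNemar chain
    runs on the complete-case subset where every rater's call is usable.
    """
    policy = policy or DichotomyPolicy()
    ref = records[f"call_{reference}"].to_numpy()
    all_calls = {t: records[f"call_{t}"].to_numpy() for t in tests}

    _, ref_exc = _call_masks(ref, policy)
    listwise = ref_exc.copy()
    for calls in all_calls.values():
        listwise |= _call_masks(calls, policy)[1]

    rows: dict[str, AccuracyReport] = {}
    for t, calls in all_calls.items():
        extra = listwise if policy.exclusion_mode == "listwise" else None
        rows[t] = accuracy_report(calls, ref, policy, name=t, level=level, extra_exclude=extra)

    keep = ~listwise
    rpos = _call_masks(ref[keep], policy)[0]
    correct = {
        t: (_call_masks(calls[keep], policy)[0] == rpos) for t, calls in all_calls.items()
    }
    matrix = np.column_stack([correct[t] for t in tests])
    q = cochran_q(matrix)
    pairs = [(a, b) for i, a in enumerate(tests) for b in tests[i + 1:]]
    raw = [mcnemar_test(correct[a], correct[b]) for a, b in pairs]
    adj = bonferroni([r.p_value for r in raw], len(pairs))
    pairwise = tuple(
        PairwiseComparison(pair, r.statistic, r.p_value, p_adj, r.method)
        for pair, r, p_adj in zip(pairs, raw, adj)
    )
    comparison = PairedComparisonResult(q.statistic, q.df, q.p_value, int(keep.sum()), pairwise)
    return rows, comparison


# ---------------------------------------------------------------------------
# Report serialisation (CSV in published-table column order, and nested JSON)


def report_to_frame(rows: Mapping[str, AccuracyReport]) -> pd.DataFrame:
    nan = float("nan")

    def pct(e: Estimate | None) -> tuple[float, float, float]:
        return (100 * e.value, 100 * e.ci[0], 100 * e.ci[1]) if e else (nan, nan, nan)

    records = []
    for name, r in rows.items():
        rec = {"index_test": name}
        for key, est in (("sensitivity", r.sensitivity), ("specificity", r.specificity),
                         ("accuracy", r.accuracy), ("fdr", r.fdr)):
            rec[f"{key}_pct"], rec[f"{key}_ci_low"], rec[f"{key}_ci_high"] = pct(est)
        if r.kappa:
            rec["kappa"], rec["kappa_ci_low"], rec["kappa_ci_high"] = (
                r.kappa.value, r.kappa.ci[0], r.kappa.ci[1])
        else:
            rec["kappa"] = rec["kappa_ci_low"] = rec["kappa_ci_high"] = nan
        rec["fpr_pct"] = 100 * r.fpr.value if r.fpr else nan
        rec["n_effective"] = r.n_effective
        records.append(rec)
    return pd.DataFrame.from_records(records)


def report_to_json(
    rows: Mapping[str, AccuracyReport], comparison: PairedComparisonResult | None = None
) -> str:
    def est(e: Estimate | None) -> dict | None:
        return {"value": e.value, "ci": list(e.ci)} if e else None

    payload: dict = {
        "tests": {
            name: {
                "confusion": {
                    "tp": r.table.tp,
                    "fp": r.table.fp,
                    "fn": r.table.fn,
                    "tn": r.table.tn,
                    "n_excluded": r.table.n_excluded,
                },
                "sensitivity": est(r.sensitivity),
                "specificity": est(r.specificity),
                "accuracy": est(r.accuracy),
                "ppv": est(r.ppv),
                "fdr": est(r.fdr),
                "fpr": est(r.fpr),
                "kappa": est(r.kappa),
                "n_effective": r.n_effective,
            }
            for name, r in rows.items()
        }
    }
    if comparison is not None:
        payload["comparison"] = {
            "cochran_q": {
                "statistic": comparison.cochran_q_statistic,
                "df": comparison.cochran_q_df,
                "p": comparison.cochran_q_p,
                "n_complete": comparison.n_complete,
            },
            "pairwise": [
                {
                    "pair": list(p.pair),
                    "mcnemar_statistic": p.mcnemar_statistic,
                    "raw_p": p.raw_p,
                    "bonferroni_adjusted_p": p.bonferroni_adjusted_p,
                    "method": p.method,
                }
                for p in comparison.pairwise
            ],
        }
    return json.dumps(payload, indent=2)
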