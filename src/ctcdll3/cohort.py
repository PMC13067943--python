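"""Patient-level DLL3 scoring, stratification and predictive metrics.

Patients are stratified on their DLL3-positive CTC fraction at a 25% cutoff
(DLL3-Pos at or above, DLL3-Low below; a >75% sub-stratum is flagged High).
The 2x2 table of stratum against clinical benefit (PR or SD under RECIST)
yields sensitivity, specificity and PPV with exact Clopper-Pearson binomial
intervals: a two-sided (1 - alpha) interval when the point estimate is
interior, and the one-sided (1 - alpha/2) bound when the estimate is exactly
0% or 100%.  Rank-based group comparisons and the IHC H-score round out the
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

BENEFIT_RESPONSES = ("PR", "SD")
RESPONSES = ("PR", "SD", "PD")


class Stratum(NamedTuple):
    label: str       # "Pos" or "Low"
    high: bool       # Pos sub-stratum above the high cutoff


def stratify_patient(fraction_pct: float, cutoff: float = 25.0,
                     high_cutoff: float = 75.0) -> Stratum:
    """Stratify one patient by DLL3-positive CTC percentage.

    Fractions below ``cutoff`` are Low; at or above are Pos (the exact-cutoff
    case is assigned Pos by convention); strictly above ``high_cutoff`` also
    carries the High flag.
    """
    if not 0.0 <= fraction_pct <= 100.0:
        raise ValueError(f"fraction must be in [0, 100], got {fraction_pct}")
    if fraction_pct < cutoff:
        return Stratum("Low", False)
    return Stratum("Pos", fraction_pct > high_cutoff)


def summarize_patients(enumeration: pd.DataFrame, clinical: pd.DataFrame,
                       cutoff: float = 25.0, high_cutoff: float = 75.0) -> pd.DataFrame:
    """Join per-patient CTC enumeration with clinical labels into patient
    summaries.  Patients with zero CTCs have an undefined DLL3 fraction and
    are excluded from stratification with a logged reason."""
    df = enumeration.merge(clinical, on="patient_id", how="inner")
    zero = df["total_ctc"] == 0
    if zero.any():
        log.warning("excluding %d patient(s) with zero CTCs (fraction undefined): %s",
                    int(zero.sum()), list(df.loc[zero, "patient_id"]))
        df = df[~zero].copy()
    strata = [stratify_patient(f, cutoff, high_cutoff)
              for f in df["dll3_fraction_pct"]]
    df["stratum"] = [s.label for s in strata]
    df["high"] = [s.high for s in strata]
    df["benefit"] = df["response"].isin(BENEFIT_RESPONSES)
    return df


@dataclass(frozen=True)
class ContingencyTable:
    """Benefit-vs-stratum 2x2 table.  TP = Pos with benefit, FN = Low with
    benefit, FP = Pos without benefit, TN = Low without benefit."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def build_contingency(summaries: pd.DataFrame) -> ContingencyTable:
    """Count patients into the benefit-vs-stratum table.  Rows with a missing
    response are excluded with a warning."""
    df = summaries
    missing = df["response"].isna() | ~df["response"].isin(RESPONSES)
    if missing.any():
        log.warning("excluding %d patient(s) with missing/unknown response",
                    int(missing.sum()))
        df = df[~missing]
    benefit = df["response"].isin(BENEFIT_RESPONSES)
    pos = df["stratum"] == "Pos"
    return ContingencyTable(
        tp=int((pos & benefit).sum()), fn=int((~pos & benefit).sum()),
        fp=int((pos & ~benefit).sum()), tn=int((~pos & ~benefit).sum()))


class BinomialCI(NamedTuple):
    point_pct: float
    lower_pct: float
    upper_pct: float
    one_sided: bool


def exact_binomial_ci(x: int, n: int, alpha: float = 0.05) -> BinomialCI:
    """Clopper-Pearson interval on the percent scale.

    Interior estimates get the two-sided (1 - alpha) interval from Beta
    quantiles; x = n reports the one-sided (1 - alpha/2) lower bound
    (alpha/2)^(1/n) with upper 100, and x = 0 the mirror-image upper bound.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= x <= n:
        raise ValueError("x must be in [0, n]")
    point = 100.0 * x / n
    if x == 0:
        return BinomialCI(point, 0.0, 100.0 * (1.0 - (alpha / 2) ** (1.0 / n)), True)
    if x == n:
        return BinomialCI(point, 100.0 * (alpha / 2) ** (1.0 / n), 100.0, True)
    lo = stats.beta.ppf(alpha / 2, x, n - x + 1)
    hi = stats.beta.ppf(1 - alpha / 2, x + 1, n - x)
    return BinomialCI(point, 100.0 * lo, 100.0 * hi, False)


@dataclass(frozen=True)
class PredictiveMetrics:
    sensitivity: BinomialCI | None
    specificity: BinomialCI | None
    ppv: BinomialCI | None

    def rounded(self) -> dict[str, dict[str, float] | None]:
        """Display form: nearest-integer percents (internal full precision)."""
        out = {}
        for name in ("sensitivity", "specificity", "ppv"):
            ci = getattr(self, name)
            out[name] = None if ci is None else {
                "point": round(ci.point_pct), "lower": round(ci.lower_pct),
                "upper": round(ci.upper_pct)}
        return out


def predictive_metrics(table: ContingencyTable, alpha: float = 0.05) -> PredictiveMetrics:
    """Sensitivity, specificity and PPV of the Pos stratum for clinical
    benefit, each with its exact binomial interval.  A zero denominator
    leaves the metric undefined (None), never 0."""
    def metric(x: int, n: int) -> BinomialCI | None:
        return exact_binomial_ci(x, n, alpha) if n > 0 else None
    return PredictiveMetrics(
        sensitivity=metric(table.tp, table.tp + table.fn),
        specificity=metric(table.tn, table.tn + table.fp),
        ppv=metric(table.tp, table.tp + table.fp))


def group_marker_totals(summaries: pd.DataFrame,
                        by: str = "response") -> pd.DataFrame:
    """Pooled CTC and DLL3-positive counts per response group.

    Pooled percent = 100 x pooled positive / pooled total (the CTC-weighted
    mean of per-patient fractions), with a nearest-integer display column.
    Empty groups report zeros.
    """
    rows = []
    for key, grp in summaries.groupby(by, observed=True, sort=True):
        total = int(grp["total_ctc"].sum())
        pos = int(grp["dll3_pos_ctc"].sum())
        pct = 100.0 * pos / total if total else 0.0
        rows.append({by: key, "n_patients": int(len(grp)), "total_ctc": total,
                     "dll3_pos_ctc": pos, "dll3_pct": pct,
                     "dll3_pct_display": round(pct)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-based tests and friends


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def _degenerate(*groups: Sequence[float]) -> bool:
    vals = np.concatenate([np.asarray(g, float) for g in groups])
    return vals.size > 0 and np.all(vals == vals[0])


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test: exact null when the
    combined sample is small (n <= 20) and tie-free, otherwise the normal
    approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    if _degenerate(x, y):
        return TestResult(np.nan, 1.0, degenerate=True)
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    if _degenerate(*groups):
        return TestResult(np.nan, 1.0, degenerate=True)
    res = stats.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, max-accumulated)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (average ranks on ties), two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if _degenerate(x) or _degenerate(y):
        return TestResult(np.nan, 1.0, degenerate=True)
    res = stats.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue))


def t_unpaired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    if _degenerate(x, y):
        return TestResult(np.nan, 1.0, degenerate=True)
    res = stats.ttest_ind(x, y)
    return TestResult(float(res.statistic), float(res.pvalue))


def t_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired test requires equal lengths")
    if _degenerate(x - y):
        return TestResult(np.nan, 1.0, degenerate=True)
    res = stats.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# IHC H-score


def h_score(bin_percentages: Sequence[float]) -> float:
    """H-score in [0, 300]: sum of intensity bin (0-3) x percent of cells in
    the bin.  Percentages must be nonnegative and sum to at most 100."""
    pct = np.asarray(bin_percentages, float)
    if pct.shape != (4,):
        raise ValueError("expected four intensity-bin percentages (bins 0-3)")
    if (pct < 0).any():
        raise ValueError("bin percentages must be nonnegative")
    if pct.sum() > 100.0 + 1e-9:
        raise ValueError("bin percentages must sum to at most 100")
    return float(np.dot(np.arange(4), pct))
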