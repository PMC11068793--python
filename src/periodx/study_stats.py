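"""Diagnostic-accuracy scoring and the matched-pairs signed-rank test.

Accuracy tables follow the study-report convention "correct/total (percent)"
with rows keyed by gold-standard diagnosis label and columns by participant
group, plus pooled margins; cells with an empty denominator render as
``0/0 (-)``. Primary-diagnosis correctness is an exact match of the
(category, extent, stage, grade) tuple against the gold label. Secondary
conditions are scored per *diagnosis incident* — one gold-standard secondary
condition on one patient — so one patient can contribute several incidents
to the denominator.

The Wilcoxon matched-pairs signed-rank statistic is W+, the sum of the ranks
of the positive differences after zeros are dropped. For n <= 25 without
ties in |d| the two-sided p-value is exact, from the convolution of the null
distribution of W+ over all sign assignments; otherwise mid-ranks and the
normal approximation with tie correction are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

GROUPS = ("DS3", "DS4", "ISP2")


# ---------------------------------------------------------------------------
# pooled "n/n (%)" cells
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding, as printed accuracy tables use."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PooledCell:
    correct: int
    total: int
    percent: float | None  # None renders as "(-)"

    def render(self, decimals: int = 2) -> str:
        if self.percent is None:
            return f"{self.correct}/{self.total} (–)"
        pct = round_half_up(self.percent, decimals)
        txt = f"{pct:.{decimals}f}".rstrip("0").rstrip(".")
        if "." not in txt and decimals > 0:
            txt = f"{pct:.1f}"
        return f"{self.correct}/{self.total} ({txt})"


def pool_row(cells: Iterable[tuple[int, int]], decimals: int = 2) -> PooledCell:
    """Component-wise pooling of (correct, total) cells.

    Percent is 100*sum(correct)/sum(total), half-up rounded; an all-zero
    denominator yields the undefined marker.
    """
    correct = total = 0
    for c, t in cells:
        if c < 0 or t < 0 or c > t:
            raise ValueError(f"invalid cell ({c}, {t})")
        correct += c
        total += t
    if total == 0:
        return PooledCell(0, 0, None)
    return PooledCell(correct, total, round_half_up(100 * correct / total, decimals))


# ---------------------------------------------------------------------------
# study records and accuracy tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedStudyRecord:
    case_id: str
    group: str
    gold_label: str
    control_primary_correct: bool
    test_primary_correct: bool
    secondary_gold: frozenset[str] = frozenset()
    secondary_found_control: frozenset[str] = frozenset()
    secondary_found_test: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"record {self.case_id}: unknown group {self.group!r}")


@dataclass(frozen=True)
class AccuracyTable:
    """Rows: gold label; columns: groups + Total; values: PooledCell."""

    rows: dict[str, dict[str, PooledCell]]
    pooled: dict[str, PooledCell]  # per-group margin + grand Total

    def to_markdown(self, decimals: int = 2) -> str:
        groups = [g for g in GROUPS if g in self.pooled] + ["Total"]
        lines = ["| Diagnosis | " + " | ".join(groups) + " |",
                 "|" + "---|" * (len(groups) + 1)]
        for label in sorted(self.rows):
            cells = self.rows[label]
            lines.append(
                f"| {label} | "
                + " | ".join(cells[g].render(decimals) for g in groups)
                + " |"
            )
        lines.append(
            "| Total | " + " | ".join(self.pooled[g].render(decimals) for g in groups) + " |"
        )
        return "\n".join(lines)


def _table_from_counts(counts: dict[str, dict[str, tuple[int, int]]],
                       groups: Sequence[str], decimals: int) -> AccuracyTable:
    rows: dict[str, dict[str, PooledCell]] = {}
    for label, per_group in counts.items():
        cells = {g: pool_row([per_group.get(g, (0, 0))], decimals) for g in groups}
        cells["Total"] = pool_row([per_group.get(g, (0, 0)) for g in groups], decimals)
        rows[label] = cells
    pooled = {
        g: pool_row([counts[l].get(g, (0, 0)) for l in counts], decimals) for g in groups
    }
    pooled["Total"] = pool_row(
        [counts[l].get(g, (0, 0)) for l in counts for g in groups], decimals
    )
    return AccuracyTable(rows=rows, pooled=pooled)


def score_accuracy(records: Sequence[PairedStudyRecord], condition: str = "control",
                   decimals: int = 2) -> tuple[AccuracyTable, AccuracyTable]:
    """Primary table (per gold label) and secondary incident table.

    ``condition`` selects which arm's correctness/detections are scored.
    """
    if condition not in ("control", "test"):
        raise ValueError("condition must be 'control' or 'test'")
    groups = [g for g in GROUPS if any(r.group == g for r in records)]
    primary_counts: dict[str, dict[str, tuple[int, int]]] = {}
    for r in records:
        ok = r.control_primary_correct if condition == "control" else r.test_primary_correct
        c, t = primary_counts.setdefault(r.gold_label, {}).get(r.group, (0, 0))
        primary_counts[r.gold_label][r.group] = (c + int(ok), t + 1)

    secondary_counts: dict[str, dict[str, tuple[int, int]]] = {}
    for r in records:
        found = r.secondary_found_control if condition == "control" else r.secondary_found_test
        for cond in r.secondary_gold:  # one incident per gold condition per case
            c, t = secondary_counts.setdefault(cond, {}).get(r.group, (0, 0))
            secondary_counts[cond][r.group] = (c + int(cond in found), t + 1)

    return (
        _table_from_counts(primary_counts, groups, decimals),
        _table_from_counts(secondary_counts, groups, decimals),
    )


# ---------------------------------------------------------------------------
# Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

def signed_rank_null_counts(n: int) -> np.ndarray:
    """Counts of W+ values over all 2^n sign assignments (convolution)."""
    c = np.zeros(n * (n + 1) // 2 + 1)
    c[0] = 1.0
    for k in range(1, n + 1):
        c[k:] += c[:-k].copy()
    return c


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of positive ranks)
    pvalue: float
    n_used: int       # nonzero differences retained
    exact: bool
    degenerate: bool = False


def wilcoxon_signed_rank(differences: Sequence[float],
                         alternative: str = "two-sided") -> WilcoxonResult:
    """Matched-pairs signed-rank test of median difference zero.

    Zeros are dropped before ranking; an all-zero input is degenerate and
    returns p = 1 by convention. Exact for n <= 25 without ties in |d|.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, exact=True, degenerate=True)
    n = d.size
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= 25 and not has_ties:
        counts = signed_rank_null_counts(n)
        total = counts.sum()
        w = int(round(w_plus))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        p = min(1.0, 2 * min(cdf, sf))
        return WilcoxonResult(statistic=w_plus, pvalue=p, n_used=n, exact=True)

    # normal approximation with tie correction on mid-ranks
    mean = n * (n + 1) / 4
    tie_term = 0.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts) / 48).sum())
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    z = (w_plus - mean) / sqrt(var)
    p = float(min(1.0, 2 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, pvalue=max(p, np.finfo(float).tiny),
                          n_used=n, exact=False)


# ---------------------------------------------------------------------------
# paired condition comparison and Likert summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    n: int
    control_mean: float
    control_sem: float
    test_mean: float
    test_sem: float
    statistic: float
    pvalue: float
    alpha: float
    reject: bool
    degenerate: bool

    def summary(self) -> str:
        verdict = "reject" if self.reject else "fail to reject"
        return (
            f"test {self.test_mean:.2f} ± {self.test_sem:.2f} vs control "
            f"{self.control_mean:.2f} ± {self.control_sem:.2f} "
            f"(n={self.n}, Wilcoxon p={self.pvalue:.4f}, {verdict} at α={self.alpha})"
        )


def compare_conditions(control_scores: Sequence[float], test_scores: Sequence[float],
                       alpha: float = 0.01) -> ComparisonReport:
    """Paired per-participant accuracy comparison at two-sided alpha."""
    control = np.asarray(control_scores, dtype=float)
    test = np.asarray(test_scores, dtype=float)
    if control.shape != test.shape or control.ndim != 1 or control.size == 0:
        raise ValueError("control and test must be equal-length non-empty paired vectors")
    res = wilcoxon_signed_rank(test - control)
    n = control.size
    sem = lambda v: float(v.std(ddof=1) / sqrt(n)) if n > 1 else 0.0
    return ComparisonReport(
        n=n,
        control_mean=float(control.mean()), control_sem=sem(control),
        test_mean=float(test.mean()), test_sem=sem(test),
        statistic=res.statistic, pvalue=res.pvalue, alpha=alpha,
        reject=(not res.degenerate) and res.pvalue < alpha,
        degenerate=res.degenerate,
    )


def summarize_likert(scores: Sequence[int]) -> dict[str, float | tuple[int, int]]:
    """Mean and range of 1-5 Likert scores, as survey sections report them."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0 or arr.min() < 1 or arr.max() > 5:
        raise ValueError("Likert scores must be a non-empty collection in 1..5")
    return {
        "mean": round_half_up(float(arr.mean()), 2),
        "range": (int(arr.min()), int(arr.max())),
        "n": int(arr.size),
    }


def records_to_frame(records: Sequence[PairedStudyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "group": [r.group for r in records],
            "gold_label": [r.gold_label for r in records],
            "control_correct": [r.control_primary_correct for r in records],
            "test_correct": [r.test_primary_correct for r in records],
            "secondary_gold": [";".join(sorted(r.secondary_gold)) for r in records],
            "secondary_found_control": [";".join(sorted(r.secondary_found_control)) for r in records],
            "secondary_found_test": [";".join(sorted(r.secondary_found_test)) for r in records],
        }
    )


def records_from_frame(df: pd.DataFrame) -> list[PairedStudyRecord]:
    def _set(v) -> frozenset[str]:
        if pd.isna(v) or not str(v):
            return frozenset()
        return frozenset(str(v).split(";"))

    return [
        PairedStudyRecord(
            case_id=str(row.case_id),
            group=str(row.group),
            gold_label=str(row.gold_label),
            control_primary_correct=bool(row.control_correct),
            test_primary_correct=bool(row.test_correct),
            secondary_gold=_set(getattr(row, "secondary_gold", "")),
            secondary_found_control=_set(getattr(row, "secondary_found_control", "")),
            secondary_found_test=_set(getattr(row, "secondary_found_test", "")),
        )
        for row in df.itertuples(index=False)
    ]
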