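"""Statistical core: exact 2x2 Fisher test, Wilcoxon rank-sum test, and the
four-rung promoter-class comparison ladder.

Both tests are implemented here from first principles. The Fisher test sums
hypergeometric masses in log space; its two-sided rule is the
point-probability convention (every table with fixed margins whose
probability does not exceed the observed table's contributes), which is the
convention of R's ``fisher.test``. The rank-sum test uses midranks for ties,
an exact null distribution by subset-sum recursion for small tie-free
samples, and a tie-corrected, continuity-corrected normal approximation
otherwise — matching R's ``wilcox.test`` defaults.

The ladder runs a fixed sequence of stratified comparisons across promoter
classes: AP (pooled) vs SP, then AP=2 vs SP, AP=3~4 vs AP=2, and AP>=5 vs
AP=3~4 — rank-sum for continuous per-gene metrics, Fisher for boolean flags.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr
from scipy.stats import rankdata

from .promoters import PromoterClass

__all__ = [
    "ContingencyTable2x2",
    "ComparisonResult",
    "LadderResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "median",
    "fraction",
    "contingency_2x2",
    "class_ladder",
    "p_display",
    "P_FLOOR",
]

P_FLOOR = 2.2e-16  # display floor used by R's test printers
_REL_TOL = 1.0 + 1e-7  # two-sided point-probability comparison tolerance


# ---------------------------------------------------------------------------
# 2x2 exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are gene groups, columns flag yes/no."""

    a: int
    b: int
    c: int
    d: int
    n_unknown_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_choose(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    With margins fixed, cell ``a`` follows a hypergeometric law; ``greater``
    and ``less`` sum the upper/lower tail in ``a``, and ``two_sided`` sums
    the probabilities of all tables whose point probability is at most the
    observed one (within a small relative tolerance to absorb rounding).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise ValueError("cannot test an all-zero table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_choose(r1, support)
        + _log_choose(n - r1, c1 - support)
        - _log_choose(n, c1)
    )
    pmf = np.exp(logpmf)
    obs = pmf[a - lo]
    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    elif alternative == "two_sided":
        p = float(pmf[pmf <= obs * _REL_TOL].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, max(p, float(obs)))


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_counts(n1: int, n: int) -> list[int]:
    """Null distribution of the rank-sum statistic for tie-free ranks:
    ``counts[s]`` = number of size-n1 subsets of {1..N} summing to s,
    by subset-sum recursion."""
    max_sum = n1 * (2 * n - n1 + 1) // 2
    ways = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            row, prev = ways[k], ways[k - 1]
            for s in range(max_sum, r - 1, -1):
                if prev[s - r]:
                    row[s] += prev[s - r]
    return ways[n1]


def _exact_p(w2: int, n1: int, n2: int, alternative: str) -> float:
    """Exact rank-sum p for tie-free integer ranks; w2 = doubled statistic."""
    n = n1 + n2
    counts = _rank_sum_counts(n1, n)
    denom = math.comb(n, n1)
    mu2 = n1 * (n + 1)  # doubled mean
    if alternative == "greater":
        return sum(c for s, c in enumerate(counts) if 2 * s >= w2) / denom
    if alternative == "less":
        return sum(c for s, c in enumerate(counts) if 2 * s <= w2) / denom
    d2 = abs(w2 - mu2)
    lower = sum(c for s, c in enumerate(counts) if 2 * s <= mu2 - d2)
    upper = sum(c for s, c in enumerate(counts) if 2 * s >= mu2 + d2)
    return min(1.0, (lower + upper) / denom)


def _exact_p_permutation(
    ranks: np.ndarray, n1: int, w: float, alternative: str
) -> float:
    """Full enumeration over rank-subset assignments; handles midranks."""
    n = len(ranks)
    mu = n1 * float(ranks.sum()) / n
    eps = 1e-9
    lo = up = 0
    total = 0
    d = abs(w - mu)
    for idx in itertools.combinations(range(n), n1):
        s = float(ranks[list(idx)].sum())
        total += 1
        if s <= mu - d + eps:
            lo += 1
        if s >= mu + d - eps:
            up += 1
    if alternative == "greater":
        up = sum(
            1
            for idx in itertools.combinations(range(n), n1)
            if float(ranks[list(idx)].sum()) >= w - eps
        )
        return up / total
    if alternative == "less":
        lo = sum(
            1
            for idx in itertools.combinations(range(n), n1)
            if float(ranks[list(idx)].sum()) <= w + eps
        )
        return lo / total
    return min(1.0, (lo + up) / total)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sample Wilcoxon (Mann-Whitney) rank-sum test.

    Returns ``(W, p)`` where W is the sum of the midranks of ``x`` in the
    pooled sample. ``mode="auto"`` uses the exact subset-sum distribution
    when n_x + n_y <= 30 and the pooled data are tie-free, else a normal
    approximation with tie and continuity corrections. Two-sided p-values
    are the probability mass at least as far from the null mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if mode == "auto":
        mode = "exact" if (n <= 30 and not has_ties) else "normal"
    if mode == "exact":
        if not has_ties:
            p = _exact_p(int(round(2 * w)), n1, n2, alternative)
        elif math.comb(n, n1) <= 200_000:
            p = _exact_p_permutation(ranks, n1, w, alternative)
        else:
            raise ValueError("exact mode infeasible: ties and a large sample")
        return w, p
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n1 * (n + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return w, 1.0
    sigma = math.sqrt(sigma2)
    diff = w - mu
    if alternative == "two_sided":
        z = (abs(diff) - 0.5) / sigma
        p = 2.0 * float(ndtr(-max(z, 0.0)))
    elif alternative == "greater":
        z = (diff - 0.5) / sigma
        p = float(ndtr(-z))
    else:
        z = (diff + 0.5) / sigma
        p = float(ndtr(z))
    return w, min(1.0, p)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def median(values: Sequence[float]) -> float:
    """Sample median, midpoint convention for even n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(arr))


def fraction(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*numerator/denominator, half-up rounded to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    from decimal import ROUND_HALF_UP, Decimal

    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def contingency_2x2(
    flags: Mapping[str, bool | None],
    group1: Sequence[str] | set[str],
    group2: Sequence[str] | set[str],
) -> ContingencyTable2x2:
    """Build [[a,b],[c,d]] from per-gene booleans and two disjoint groups.

    Genes whose flag is missing (absent from ``flags`` or None) are dropped;
    the number dropped is recorded on the returned table.
    """
    g1, g2 = set(group1), set(group2)
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    overlap = g1 & g2
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} gene(s)")
    dropped = 0
    cells = [0, 0, 0, 0]
    for offset, group in ((0, g1), (2, g2)):
        for gene in group:
            val = flags.get(gene)
            if val is None:
                dropped += 1
            elif val:
                cells[offset] += 1
            else:
                cells[offset + 1] += 1
    return ContingencyTable2x2(*cells, n_unknown_dropped=dropped)


# ---------------------------------------------------------------------------
# the class-comparison ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """One stratified two-group comparison."""

    label: str
    kind: str  # "rank_sum" or "fisher"
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    group_summaries: tuple[float, float]  # medians (rank_sum) or % (fisher)

    def as_row(self) -> dict:
        return {
            "label": self.label,
            "kind": self.kind,
            "n1": self.n_per_group[0],
            "n2": self.n_per_group[1],
            "summary1": self.group_summaries[0],
            "summary2": self.group_summaries[1],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "p_display": p_display(self.p_value),
        }


@dataclass(frozen=True, slots=True)
class LadderResult:
    """The four ladder comparisons plus per-class summary values."""

    comparisons: tuple[ComparisonResult, ...]
    class_summaries: pd.DataFrame  # columns: class, n, summary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.comparisons])


_CLASS_ORDER = [
    PromoterClass.SP,
    PromoterClass.AP2,
    PromoterClass.AP3_4,
    PromoterClass.AP5PLUS,
]
_LADDER = [
    ("AP_vs_SP", ("AP2", "AP3_4", "AP5plus"), ("SP",)),
    ("AP2_vs_SP", ("AP2",), ("SP",)),
    ("AP3_4_vs_AP2", ("AP3_4",), ("AP2",)),
    ("AP5plus_vs_AP3_4", ("AP5plus",), ("AP3_4",)),
]


def p_display(p: float) -> str:
    """Render a p-value the way R's test printers do, flooring tiny values."""
    return "<2.2e-16" if p < P_FLOOR else format(p, ".4g")


def _class_members(profiles: pd.DataFrame) -> dict[str, list[str]]:
    members: dict[str, list[str]] = {cls.value: [] for cls in _CLASS_ORDER}
    for gene, cls in zip(profiles["gene_id"], profiles["promoter_class"]):
        members[str(cls)].append(gene)
    return members


def class_ladder(
    data: Mapping[str, float | bool | None],
    profiles: pd.DataFrame,
    kind: str,
    alternative: str = "two_sided",
    fraction_decimals: int = 1,
) -> LadderResult:
    """Run the fixed ladder of promoter-class comparisons on one quantity.

    ``data`` maps gene id to a continuous metric (``kind="rank_sum"``) or a
    boolean flag (``kind="fisher"``); genes missing from ``data`` or mapped
    to None/NaN are excluded. Rungs whose class has no usable genes are
    skipped with a warning; output order and labels are otherwise fixed
    regardless of input ordering.
    """
    if kind not in ("rank_sum", "fisher"):
        raise ValueError(f"unknown ladder kind {kind!r}")
    members = _class_members(profiles)

    def usable(genes: list[str]):
        vals = []
        for g in genes:
            v = data.get(g)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            vals.append((g, v))
        return vals

    per_class = {cls: usable(genes) for cls, genes in members.items()}

    # per-class summary block
    summary_rows = []
    for cls in (c.value for c in _CLASS_ORDER):
        vals = [v for _, v in per_class[cls]]
        if not vals:
            summ = math.nan
        elif kind == "rank_sum":
            summ = median([float(v) for v in vals])
        else:
            summ = fraction(sum(bool(v) for v in vals), len(vals), fraction_decimals)
        summary_rows.append({"class": cls, "n": len(vals), "summary": summ})
    class_summaries = pd.DataFrame(summary_rows)

    comparisons: list[ComparisonResult] = []
    for label, cls1, cls2 in _LADDER:
        pairs1 = [p for c in cls1 for p in per_class[c]]
        pairs2 = [p for c in cls2 for p in per_class[c]]
        if not pairs1 or not pairs2:
            warnings.warn(f"ladder rung {label} skipped: an empty class", stacklevel=2)
            continue
        if kind == "rank_sum":
            v1 = [float(v) for _, v in pairs1]
            v2 = [float(v) for _, v in pairs2]
            stat, p = wilcoxon_rank_sum(v1, v2, alternative=alternative)
            summaries = (median(v1), median(v2))
        else:
            flags = {g: bool(v) for g, v in itertools.chain(pairs1, pairs2)}
            table = contingency_2x2(flags, [g for g, _ in pairs1], [g for g, _ in pairs2])
            p = fisher_exact(table, alternative=alternative)
            stat = float(table.a)
            summaries = (
                fraction(table.a, table.a + table.b, fraction_decimals),
                fraction(table.c, table.c + table.d, fraction_decimals),
            )
        comparisons.append(
            ComparisonResult(
                label=label,
                kind=kind,
                statistic=stat,
                p_value=p,
                n_per_group=(len(pairs1), len(pairs2)),
                group_summaries=summaries,
            )
        )
    return LadderResult(comparisons=tuple(comparisons), class_summaries=class_summaries)
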