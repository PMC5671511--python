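"""Expression stratification and per-codon exact tests of usage bias.

Genes are stratified by expression (intensity thresholds or top-n rank), the
codon counts of a group are pooled and compared against a background pool,
and each testable codon gets a two-sided exact p-value from the 2x2 table

    [[group codon count, group rest], [background codon count, background rest]]

where "rest" is either the other synonymous codons of the same amino acid
(``within_family``, the default) or all other sense codons (``vs_all``).
The full p vector is adjusted jointly by Benjamini-Hochberg step-up (Holm
available) and directions are assigned only below the significance level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .codon_core import CodonCounts, GeneticCode, pool_counts, standard_code

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "StratificationConfig",
    "stratify_by_expression",
    "fisher_exact_two_sided",
    "UntestableCodonError",
    "codon_bias_test",
    "adjust_fdr",
    "BiasResult",
    "BiasResultSet",
    "detect_bias",
    "ScanRow",
    "ScanTable",
    "rank_scan",
]

#: Tables whose grand total is at most this are evaluated with exact integer
#: arithmetic; larger tables fall back to scipy's float implementation.
EXACT_TOTAL_LIMIT = 2000

DEFAULT_STRONG_CUTOFF = 200_000.0
DEFAULT_HIGH_CUTOFF = 450_000.0


@dataclass(frozen=True)
class ExpressionTable:
    """Gene id -> normalized expression intensity records."""

    records: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in expression table")
        for g, v in self.records:
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{g}: intensity must be finite and non-negative")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]]) -> "ExpressionTable":
        return cls(records=tuple((str(g), float(v)) for g, v in pairs))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def intensities(self) -> dict[str, float]:
        return dict(self.records)

    def ranked_ids(self) -> list[str]:
        """Gene ids sorted by decreasing intensity; ties broken by id."""
        return [g for g, _ in sorted(self.records, key=lambda r: (-r[1], r[0]))]


@dataclass(frozen=True)
class StratificationConfig:
    """How to split genes into expression strata.

    ``threshold`` mode uses two intensity cutoffs (strongly / highly
    expressed); ``top_n`` mode takes the n highest-intensity genes.
    """

    mode: str = "threshold"
    strong_cutoff: float = DEFAULT_STRONG_CUTOFF
    high_cutoff: float = DEFAULT_HIGH_CUTOFF
    n: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "top_n"):
            raise ValueError(f"unknown stratification mode {self.mode!r}")
        if self.high_cutoff < self.strong_cutoff:
            raise ValueError("high_cutoff must be >= strong_cutoff")
        if self.mode == "top_n" and (self.n is None or self.n < 1):
            raise ValueError("top_n mode requires n >= 1")


def stratify_by_expression(
    expr: ExpressionTable, cfg: StratificationConfig
) -> dict[str, set[str]]:
    """Split genes into strata; ``all`` always contains every gene.

    Threshold mode returns ``{strong, high, all}`` with intensities strictly
    above each cutoff; top_n mode returns ``{top, all}``.
    """
    if len(expr) == 0:
        raise ValueError("empty expression table")
    all_ids = {g for g, _ in expr.records}
    if cfg.mode == "threshold":
        return {
            "strong": {g for g, v in expr.records if v > cfg.strong_cutoff},
            "high": {g for g, v in expr.records if v > cfg.high_cutoff},
            "all": all_ids,
        }
    assert cfg.n is not None
    if cfg.n > len(expr):
        raise ValueError(f"n={cfg.n} exceeds table size {len(expr)}")
    return {"top": set(expr.ranked_ids()[: cfg.n]), "all": all_ids}


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums, over the hypergeometric support with the table's fixed
    margins, every table whose probability does not exceed the observed
    table's.  Small tables (grand total <= ``EXACT_TOTAL_LIMIT``) are
    evaluated in exact integer arithmetic so the result is the correctly
    rounded float of the underlying rational; larger tables use
    :func:`scipy.stats.fisher_exact`.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    if n <= EXACT_TOTAL_LIMIT:
        lo, hi = max(0, c1 - r2), min(r1, c1)
        weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
        observed = weights[a - lo]
        tail = sum(w for w in weights if w <= observed)
        return min(1.0, tail / comb(n, c1))
    return float(_sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


class UntestableCodonError(ValueError):
    """The codon cannot be tested in the requested mode (e.g. Met/Trp)."""


def codon_bias_test(
    group: CodonCounts,
    background: CodonCounts,
    codon: str,
    mode: str = "within_family",
    code: GeneticCode | None = None,
) -> tuple[float, str]:
    """Exact test of one codon's usage in a group versus a background.

    Returns ``(p_value, direction)`` with direction ``over`` / ``under`` /
    ``tie`` from comparing the group's within-table proportion with the
    background's.  Raises :class:`UntestableCodonError` for single-codon
    families in ``within_family`` mode or when either family total is zero.
    """
    code = code or standard_code()
    if mode not in ("within_family", "vs_all"):
        raise ValueError(f"unknown mode {mode!r}")
    aa = code.aa_of(codon)
    if aa == "*":
        raise UntestableCodonError(f"{codon} is a stop codon")
    if mode == "within_family":
        family = code.family(aa)
        if len(family) < 2:
            raise UntestableCodonError(
                f"{codon} ({aa}) is a single-codon family: untestable within family"
            )
        group_total = sum(group.get(x) for x in family)
        background_total = sum(background.get(x) for x in family)
    else:
        group_total = group.sense_total(code)
        background_total = background.sense_total(code)
    if group_total == 0 or background_total == 0:
        raise UntestableCodonError(f"{codon} ({aa}): a family total is zero")
    a, c = group.get(codon), background.get(codon)
    b, d = group_total - a, background_total - c
    p = fisher_exact_two_sided(a, b, c, d)
    lhs, rhs = a * background_total, c * group_total  # integer proportion compare
    direction = "over" if lhs > rhs else "under" if lhs < rhs else "tie"
    return p, direction


def adjust_fdr(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment, returned in input order.

    ``bh``: Benjamini-Hochberg step-up, q_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1.  ``holm``: Holm step-down.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    if method == "bh":
        scaled = ranked * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    elif method == "holm":
        scaled = ranked * (m - np.arange(m))
        q_sorted = np.maximum.accumulate(scaled)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out.tolist()


@dataclass(frozen=True)
class BiasResult:
    """Test outcome for one codon in a group-vs-background comparison."""

    codon: str
    amino_acid: str
    direction: str  # over | under | none
    p_value: float
    q_value: float
    group_count: int
    group_family_total: int
    background_count: int
    background_family_total: int


@dataclass(frozen=True)
class BiasResultSet:
    """All per-codon results of one comparison, plus the derived summaries."""

    results: tuple[BiasResult, ...]
    alpha: float
    mode: str
    biased_amino_acids: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        derived = frozenset(r.amino_acid for r in self.results if r.direction != "none")
        if self.biased_amino_acids != derived:
            object.__setattr__(self, "biased_amino_acids", derived)

    @property
    def significant_codons(self) -> frozenset[str]:
        return frozenset(r.codon for r in self.results if r.direction != "none")

    def __iter__(self):
        return iter(self.results)


def detect_bias(
    group: CodonCounts,
    background: CodonCounts,
    alpha: float = 0.05,
    mode: str = "within_family",
    code: GeneticCode | None = None,
    fdr_method: str = "bh",
) -> BiasResultSet:
    """Run :func:`codon_bias_test` on every testable sense codon with FDR.

    Untestable codons (stops, single-codon families within family, empty
    families) never enter the p vector, so the number of tests m counts only
    testable codons.  Directions are assigned where q < alpha; a proportion
    tie is reported as ``none`` with a logged warning even if significant.
    """
    code = code or standard_code()
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    tested: list[tuple[str, str, float, str]] = []  # codon, aa, p, raw direction
    for codon in code.sense_codons:
        try:
            p, direction = codon_bias_test(group, background, codon, mode, code)
        except UntestableCodonError:
            continue
        tested.append((codon, code.aa_of(codon), p, direction))
    if not tested:
        raise ValueError("no testable codons: both count vectors are degenerate")
    q_values = adjust_fdr([t[2] for t in tested], method=fdr_method)
    results = []
    for (codon, aa, p, direction), q in zip(tested, q_values):
        if q < alpha:
            if direction == "tie":
                logger.warning(
                    "%s (%s): significant q=%.3g but tied proportions; direction=none",
                    codon, aa, q,
                )
                final = "none"
            else:
                final = direction
        else:
            final = "none"
        if mode == "within_family":
            g_tot = group.family_total(aa, code)
            b_tot = background.family_total(aa, code)
        else:
            g_tot = group.sense_total(code)
            b_tot = background.sense_total(code)
        results.append(
            BiasResult(
                codon=codon,
                amino_acid=aa,
                direction=final,
                p_value=p,
                q_value=q,
                group_count=group.get(codon),
                group_family_total=g_tot,
                background_count=background.get(codon),
                background_family_total=b_tot,
            )
        )
    return BiasResultSet(results=tuple(results), alpha=alpha, mode=mode)


@dataclass(frozen=True)
class ScanRow:
    n_top: int
    significant_codons: tuple[str, ...]
    n_significant_amino_acids: int


@dataclass(frozen=True)
class ScanTable:
    rows: tuple[ScanRow, ...]

    def __post_init__(self) -> None:
        ns = [r.n_top for r in self.rows]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValueError("n_top must be strictly increasing across rows")

    def __iter__(self):
        return iter(self.rows)


def rank_scan(
    expr: ExpressionTable,
    cds_index: Mapping[str, CodonCounts],
    n_grid: Sequence[int],
    alpha: float = 0.05,
    mode: str = "within_family",
    code: GeneticCode | None = None,
    exclusive_background: bool = False,
) -> ScanTable:
    """Detection depth over expression rank.

    For each n in the strictly increasing grid, pool the codon counts of the
    top-n expressed genes and test them against the pooled counts of all
    genes (inclusive background by default).  Genes lacking codon counts are
    dropped with a logged count.
    """
    code = code or standard_code()
    grid = [int(n) for n in n_grid]
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_grid must be a non-empty strictly increasing list")
    ranked = [g for g in expr.ranked_ids() if g in cds_index]
    dropped = len(expr) - len(ranked)
    if dropped:
        logger.info("rank_scan: dropped %d genes without codon counts", dropped)
    if grid[-1] > len(ranked):
        raise ValueError(
            f"grid value {grid[-1]} exceeds the {len(ranked)} usable genes"
        )
    background = pool_counts([cds_index[g] for g in ranked])
    rows = []
    running = None
    taken = 0
    for n in grid:
        for g in ranked[taken:n]:
            running = cds_index[g] if running is None else running + cds_index[g]
        taken = n
        assert running is not None
        bg = background - running if exclusive_background else background
        result = detect_bias(running, bg, alpha=alpha, mode=mode, code=code)
        sig = tuple(sorted(result.significant_codons))
        rows.append(
            ScanRow(
                n_top=n,
                significant_codons=sig,
                n_significant_amino_acids=len(result.biased_amino_acids),
            )
        )
    return ScanTable(rows=tuple(rows))
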