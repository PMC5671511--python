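"""Genetic-code bookkeeping, codon counting, usage frequencies, GC statistics,
and Wright's effective number of codons (ENC).

This module owns the low-level vocabulary shared by the rest of the package:
the :class:`GeneticCode` (codon -> amino acid table plus synonymous-family
structure), validated :class:`CodingSequence` objects, :class:`CodonCounts`
vectors and :class:`FrequencyTable` summaries.  All higher-level operations
(bias testing, recoding, simulation) are expressed in terms of these types.

Conventions
-----------
* Codons are upper-case 3-mers over ``{A, C, G, T}``.
* Stop codons are carried in raw counts but excluded from frequency tables,
  ENC, and downstream bias testing.
* Codon positions are reported 1-based.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable as _BioCodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
STOP = "*"

__all__ = [
    "STOP",
    "GeneticCode",
    "standard_code",
    "CodingSequenceError",
    "CodingSequence",
    "translate",
    "CodonCounts",
    "count_codons",
    "pool_counts",
    "FrequencyTable",
    "frequencies",
    "gc_content",
    "effective_number_of_codons",
    "gene_stats",
]


class CodingSequenceError(ValueError):
    """Raised when a coding sequence fails validation."""


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or not set(codon) <= NUCLEOTIDES:
        raise ValueError(f"invalid codon {codon!r}")
    return codon


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus its synonymous-family structure.

    Parameters
    ----------
    table:
        Mapping of all 64 codons to a one-letter amino acid or ``"*"`` for
        stop.
    families:
        Mapping of amino acid -> ordered (alphabetical) tuple of synonymous
        codons.  Derived from ``table``; stops are not a family.
    name:
        Informal label for the table.
    """

    table: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]]
    name: str = "custom"

    def __post_init__(self) -> None:
        for codon in self.table:
            _check_codon(codon)
        if len(self.table) != 64:
            raise ValueError("genetic code must cover exactly the 64 codons")
        derived = _families_from_table(self.table)
        if dict(self.families) != derived:
            raise ValueError("families inconsistent with translation table")

    # -- lookups ---------------------------------------------------------
    def aa_of(self, codon: str) -> str:
        """Amino acid (or ``"*"``) encoded by ``codon``."""
        return self.table[codon]

    def is_stop(self, codon: str) -> bool:
        return self.table[codon] == STOP

    def family(self, amino_acid: str) -> tuple[str, ...]:
        """Synonymous codons of ``amino_acid`` in alphabetical order."""
        return self.families[amino_acid]

    def synonyms(self, codon: str) -> tuple[str, ...]:
        return self.families[self.table[codon]]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa != STOP))

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.table.items() if aa == STOP))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))

    def degeneracy(self, amino_acid: str) -> int:
        return len(self.families[amino_acid])


def _families_from_table(table: Mapping[str, str]) -> dict[str, tuple[str, ...]]:
    fams: dict[str, list[str]] = {}
    for codon in sorted(table):
        aa = table[codon]
        if aa != STOP:
            fams.setdefault(aa, []).append(codon)
    return {aa: tuple(codons) for aa, codons in fams.items()}


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    table = {str(c): str(aa) for c, aa in bio.forward_table.items()}
    for stop in bio.stop_codons:
        table[str(stop)] = STOP
    return GeneticCode(table=table, families=_families_from_table(table), name="standard")


@dataclass(frozen=True)
class CodingSequence:
    """A validated frame-0 coding sequence.

    In strict mode (the default) an internal stop codon is a validation
    error; permissive mode (``strict=False``) logs a warning instead, for
    exploratory use.
    """

    id: str
    seq: str
    strict: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.id:
            raise CodingSequenceError("coding sequence needs a non-empty id")
        if len(self.seq) < 3:
            raise CodingSequenceError(f"{self.id}: sequence shorter than one codon")
        if len(self.seq) % 3:
            raise CodingSequenceError(
                f"{self.id}: length {len(self.seq)} not divisible by 3"
            )
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise CodingSequenceError(
                f"{self.id}: invalid characters {sorted(bad)} (ambiguity codes rejected)"
            )
        stop_at = _first_internal_stop(self.codons)
        if stop_at is not None:
            if self.strict:
                raise CodingSequenceError(
                    f"{self.id}: internal stop codon at codon {stop_at}"
                )
            logger.warning("%s: internal stop codon at codon %d (permissive mode)",
                           self.id, stop_at)

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.seq[i : i + 3] for i in range(0, len(self.seq), 3))

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3


def _first_internal_stop(codons: Sequence[str], code: GeneticCode | None = None) -> int | None:
    code = code or standard_code()
    for i, codon in enumerate(codons[:-1], start=1):
        if code.is_stop(codon):
            return i
    return None


def translate(cds: CodingSequence, code: GeneticCode | None = None) -> str:
    """Translate a CDS to its protein string.

    A terminal stop codon, if present, is omitted.  An internal stop codon is
    always an error naming the (1-based) codon index, regardless of how the
    :class:`CodingSequence` was validated.
    """
    code = code or standard_code()
    codons = cds.codons
    stop_at = _first_internal_stop(codons, code)
    if stop_at is not None:
        raise CodingSequenceError(f"{cds.id}: internal stop codon at codon {stop_at}")
    if code.is_stop(codons[-1]):
        codons = codons[:-1]
    return "".join(code.aa_of(c) for c in codons)


@dataclass(frozen=True)
class CodonCounts:
    """A 64-cell codon count vector (only non-zero cells stored)."""

    counts: Mapping[str, int]
    n_total: int

    def __post_init__(self) -> None:
        total = 0
        for codon, n in self.counts.items():
            _check_codon(codon)
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            total += n
        if total != self.n_total:
            raise ValueError(f"n_total={self.n_total} but counts sum to {total}")

    @classmethod
    def from_mapping(cls, counts: Mapping[str, int]) -> "CodonCounts":
        clean = {c: int(n) for c, n in counts.items() if n}
        return cls(counts=clean, n_total=sum(clean.values()))

    def get(self, codon: str) -> int:
        return int(self.counts.get(codon, 0))

    def family_total(self, amino_acid: str, code: GeneticCode | None = None) -> int:
        code = code or standard_code()
        return sum(self.get(c) for c in code.family(amino_acid))

    def sense_total(self, code: GeneticCode | None = None) -> int:
        code = code or standard_code()
        return self.n_total - sum(self.get(c) for c in code.stop_codons)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts.from_mapping(merged)

    def __sub__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.subtract(other.counts)
        if any(v < 0 for v in merged.values()):
            raise ValueError("subtraction would produce negative codon counts")
        return CodonCounts.from_mapping(merged)


def count_codons(cds: CodingSequence) -> CodonCounts:
    """Frame-0 codon counts of a CDS (stop codons included)."""
    return CodonCounts.from_mapping(Counter(cds.codons))


def pool_counts(counts_list: Iterable[CodonCounts]) -> CodonCounts:
    """Cell-wise sum of several count vectors; ``n_total`` is additive."""
    pooled: Counter[str] = Counter()
    n_seen = 0
    for counts in counts_list:
        pooled.update(counts.counts)
        n_seen += 1
    if n_seen == 0:
        raise ValueError("pool_counts requires a non-empty list")
    return CodonCounts.from_mapping(pooled)


@dataclass(frozen=True)
class FrequencyTable:
    """Codon usage as fractions, either global or within synonymous families.

    ``freq`` carries one entry per sense codon whose family (within-family
    scope) or whose table (global scope) has observations; families with a
    zero total are left out of ``freq`` (undefined, not 0/0) but still appear
    in ``family_totals``.
    """

    scope: str
    freq: Mapping[str, float]
    family_totals: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.scope not in ("global", "within_family"):
            raise ValueError(f"unknown scope {self.scope!r}")

    def family_freqs(self, amino_acid: str, code: GeneticCode | None = None) -> dict[str, float]:
        code = code or standard_code()
        if self.family_totals.get(amino_acid, 0) <= 0:
            raise ValueError(f"family {amino_acid} has no observations")
        return {c: self.freq[c] for c in code.family(amino_acid)}


def frequencies(
    counts: CodonCounts,
    scope: str = "within_family",
    code: GeneticCode | None = None,
) -> FrequencyTable:
    """Turn codon counts into a :class:`FrequencyTable`.

    Stop codons are excluded.  ``within_family`` divides each codon count by
    its synonymous-family total; ``global`` divides by the total sense count.
    """
    code = code or standard_code()
    if scope not in ("global", "within_family"):
        raise ValueError(f"unknown scope {scope!r}")
    sense_total = counts.sense_total(code)
    if sense_total <= 0:
        raise ValueError("cannot compute frequencies of an empty count vector")
    family_totals = {aa: counts.family_total(aa, code) for aa in code.amino_acids}
    freq: dict[str, float] = {}
    if scope == "global":
        for codon in code.sense_codons:
            freq[codon] = counts.get(codon) / sense_total
    else:
        for aa, total in family_totals.items():
            if total == 0:
                continue
            for codon in code.family(aa):
                freq[codon] = counts.get(codon) / total
    return FrequencyTable(scope=scope, freq=freq, family_totals=family_totals)


_POSITION_OFFSETS = {"first": 0, "second": 1, "third": 2}


def gc_content(seq: "str | CodingSequence", positions: str = "all") -> float:
    """G+C fraction of a sequence over all or one codon position.

    ``positions`` is one of ``all``, ``first``, ``second``, ``third``;
    positional modes require a length divisible by 3 (``third`` is GC3).
    """
    s = seq.seq if isinstance(seq, CodingSequence) else seq.upper()
    if not s:
        raise ValueError("empty sequence")
    if not set(s) <= NUCLEOTIDES:
        raise ValueError("sequence contains non-ACGT characters")
    if positions == "all":
        sub = s
    else:
        try:
            off = _POSITION_OFFSETS[positions]
        except KeyError:
            raise ValueError(f"unknown positions {positions!r}") from None
        if len(s) % 3:
            raise ValueError("positional GC requires length divisible by 3")
        sub = s[off::3]
    return (sub.count("G") + sub.count("C")) / len(sub)


def _family_homozygosity(counts: CodonCounts, codons: Sequence[str]) -> float | None:
    """Wright's F for one family: (n * sum p_i^2 - 1) / (n - 1); None if n < 2."""
    ns = [counts.get(c) for c in codons]
    n = sum(ns)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in ns)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def effective_number_of_codons(
    counts: CodonCounts, code: GeneticCode | None = None
) -> float:
    """Wright's effective number of codons, Nc in [20, 61].

    Nc = (#single-codon families) + sum over degeneracy classes k of
    (#families in class k) / mean F of class k, with per-family homozygosity
    F = (n * sum p_i^2 - 1) / (n - 1).  Six-fold families form their own
    class.  Families with n < 2 are excluded from their class mean; a class
    with no usable F (none defined, or mean F = 0) falls back to the mean of
    the defined class means.  The result is clamped at the number of sense
    codons (61 for the standard code).
    """
    code = code or standard_code()
    classes: dict[int, list[str]] = {}
    n_single = 0
    for aa in code.amino_acids:
        k = code.degeneracy(aa)
        if k == 1:
            n_single += 1
        else:
            classes.setdefault(k, []).append(aa)

    class_mean_f: dict[int, float | None] = {}
    for k, aas in classes.items():
        fs = [
            f
            for aa in aas
            if (f := _family_homozygosity(counts, code.family(aa))) is not None
        ]
        if fs and (mean_f := sum(fs) / len(fs)) > 0:
            class_mean_f[k] = mean_f
        else:
            class_mean_f[k] = None

    defined = [f for f in class_mean_f.values() if f is not None]
    if not defined:
        raise ValueError("insufficient counts: no synonymous family has n >= 2")
    fallback = sum(defined) / len(defined)

    nc = float(n_single)
    for k, aas in classes.items():
        mean_f = class_mean_f[k]
        nc += len(aas) / (mean_f if mean_f is not None else fallback)
    return min(nc, float(len(code.sense_codons)))


def gene_stats(cds: CodingSequence, code: GeneticCode | None = None) -> dict:
    """Per-gene summary row: id, codon count, GC, GC3 and ENC.

    ENC is NaN when the sequence is too short for any family to reach n >= 2.
    """
    code = code or standard_code()
    counts = count_codons(cds)
    try:
        enc = effective_number_of_codons(counts, code)
    except ValueError:
        enc = math.nan
    return {
        "gene_id": cds.id,
        "n_codons": cds.n_codons,
        "gc": gc_content(cds, "all"),
        "gc3": gc_content(cds, "third"),
        "enc": enc,
    }
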