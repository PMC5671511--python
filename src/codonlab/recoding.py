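"""Deterministic codon recoding toward or away from a preferred-codon profile.

A :class:`RecodingMap` assigns one target codon per amino acid in scope —
built from a bias result set plus the high-expression group's within-family
frequencies — and :func:`recode` rewrites every in-scope codon to its target
while leaving the protein sequence untouched.  Every change is recorded in an
auditable ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .bias_detection import BiasResultSet
from .codon_core import (
    CodingSequence,
    FrequencyTable,
    GeneticCode,
    gc_content,
    standard_code,
    translate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RecodingMap",
    "CodonChange",
    "RecodedSequence",
    "build_recoding_map",
    "recode",
    "diff_codons",
    "apply_changes",
]


@dataclass(frozen=True)
class RecodingMap:
    """Amino acid -> target codon map with mode and scope."""

    mode: str  # high | low
    targets: Mapping[str, str]
    scope: frozenset[str]

    def __post_init__(self) -> None:
        if self.mode not in ("high", "low"):
            raise ValueError(f"unknown recoding mode {self.mode!r}")
        code = standard_code()
        if set(self.targets) != set(self.scope):
            raise ValueError("scope and target keys must coincide")
        for aa, codon in self.targets.items():
            if code.degeneracy(aa) < 2:
                raise ValueError(f"{aa} has a single codon and cannot be recoded")
            if code.aa_of(codon) != aa:
                raise ValueError(f"target {codon} does not encode {aa}")


@dataclass(frozen=True)
class CodonChange:
    codon_index: int  # 1-based
    from_codon: str
    to_codon: str


@dataclass(frozen=True)
class RecodedSequence:
    """A recoded CDS plus its change ledger and GC bookkeeping."""

    original_id: str
    seq: str
    changes: tuple[CodonChange, ...]
    gc_before: float
    gc_after: float

    @property
    def n_changes(self) -> int:
        return len(self.changes)

    def to_coding_sequence(self, suffix: str = "_recoded") -> CodingSequence:
        return CodingSequence(id=self.original_id + suffix, seq=self.seq)


def build_recoding_map(
    bias: BiasResultSet,
    group_freq: FrequencyTable,
    mode: str,
    scope: Iterable[str] | None = None,
    code: GeneticCode | None = None,
) -> RecodingMap:
    """Pick one target codon per biased amino acid from group frequencies.

    ``high`` targets the codon with maximal within-family frequency in the
    high-expression group, ``low`` the minimal.  Frequency ties are broken
    alphabetically (logged).  Scope defaults to ``bias.biased_amino_acids``;
    single-codon amino acids are never in scope.
    """
    code = code or standard_code()
    if group_freq.scope != "within_family":
        raise ValueError("group_freq must have within_family scope")
    if mode not in ("high", "low"):
        raise ValueError(f"unknown recoding mode {mode!r}")
    chosen_scope = frozenset(scope) if scope is not None else bias.biased_amino_acids
    chosen_scope = frozenset(aa for aa in chosen_scope if code.degeneracy(aa) >= 2)
    targets: dict[str, str] = {}
    for aa in sorted(chosen_scope):
        try:
            fam = group_freq.family_freqs(aa, code)
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{aa}: family frequencies undefined in group") from exc
        extreme = max(fam.values()) if mode == "high" else min(fam.values())
        candidates = sorted(c for c, f in fam.items() if f == extreme)
        if len(candidates) > 1:
            logger.warning(
                "%s: frequency tie among %s; picking %s alphabetically",
                aa, candidates, candidates[0],
            )
        targets[aa] = candidates[0]
    return RecodingMap(mode=mode, targets=targets, scope=chosen_scope)


def recode(
    cds: CodingSequence,
    rmap: RecodingMap,
    code: GeneticCode | None = None,
) -> RecodedSequence:
    """Rewrite every in-scope codon to its target; protein is unchanged.

    Stop codons and out-of-scope amino acids are untouched.  The ledger
    records each change with its 1-based codon index.
    """
    code = code or standard_code()
    new_codons: list[str] = []
    changes: list[CodonChange] = []
    for i, codon in enumerate(cds.codons, start=1):
        aa = code.aa_of(codon)
        target = rmap.targets.get(aa)
        if aa != "*" and target is not None and codon != target:
            changes.append(CodonChange(codon_index=i, from_codon=codon, to_codon=target))
            new_codons.append(target)
        else:
            new_codons.append(codon)
    new_seq = "".join(new_codons)
    recoded = RecodedSequence(
        original_id=cds.id,
        seq=new_seq,
        changes=tuple(changes),
        gc_before=gc_content(cds, "all"),
        gc_after=gc_content(new_seq, "all"),
    )
    # protein invariance is a hard guarantee, not a hope
    assert translate(recoded.to_coding_sequence(), code) == translate(cds, code)
    return recoded


def diff_codons(
    a: CodingSequence, b: CodingSequence
) -> list[tuple[int, str, str]]:
    """All 1-based frame-0 codon positions where two equal-length CDS differ."""
    if len(a.seq) != len(b.seq):
        raise ValueError(
            f"length mismatch: {a.id} has {len(a.seq)} nt, {b.id} has {len(b.seq)} nt"
        )
    return [
        (i, ca, cb)
        for i, (ca, cb) in enumerate(zip(a.codons, b.codons), start=1)
        if ca != cb
    ]


def apply_changes(cds: CodingSequence, changes: Sequence[CodonChange]) -> str:
    """Replay a change ledger against the original sequence.

    Verifies each ``from_codon`` against the original and returns the
    resulting nucleotide string.
    """
    codons = list(cds.codons)
    for ch in changes:
        idx = ch.codon_index - 1
        if not 0 <= idx < len(codons):
            raise ValueError(f"change index {ch.codon_index} outside sequence")
        if codons[idx] != ch.from_codon:
            raise ValueError(
                f"ledger mismatch at codon {ch.codon_index}: "
                f"expected {ch.from_codon}, found {codons[idx]}"
            )
        codons[idx] = ch.to_codon
    return "".join(codons)
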