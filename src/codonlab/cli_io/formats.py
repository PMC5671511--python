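"""Readers and writers for the plain-text formats used across the package.

All tabular formats are UTF-8 TSV/CSV with a header row and ``.`` decimals.
Writes are atomic (temp file + rename) so a failing command leaves no
partial outputs behind.  Every writer has a matching reader and the pair
round-trips exactly.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..bias_detection import BiasResult, BiasResultSet, ExpressionTable, ScanRow, ScanTable
from ..codon_core import CodingSequence
from ..fluor_norm import Plate
from ..recoding import CodonChange, RecodingMap

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_bias_tsv",
    "read_bias_tsv",
    "write_scan_tsv",
    "read_scan_tsv",
    "write_gene_stats_tsv",
    "write_counts_tsv",
    "write_ledger_tsv",
    "read_ledger_tsv",
    "write_map_tsv",
    "read_map_tsv",
    "read_plate_csv",
    "write_plate_csv",
    "write_summary_tsv",
    "read_summary_tsv",
]


@contextmanager
def _atomic_path(path: "str | Path"):
    """Yield a temp path in the target directory, renamed into place on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=f".{path.name}.")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_frame(df: pd.DataFrame, path: "str | Path", sep: str = "\t") -> None:
    # render floats via repr (shortest round-trip form) so write -> read is
    # exact; pandas' default float formatting truncates at 16 digits
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    with _atomic_path(path) as tmp:
        out.to_csv(tmp, sep=sep, index=False)


# -- FASTA ---------------------------------------------------------------


def read_fasta(path: "str | Path", strict: bool = True) -> list[CodingSequence]:
    """Read a CDS FASTA; ids are truncated at the first whitespace.

    Duplicate ids are rejected.  ``strict=False`` tolerates internal stop
    codons (logged by the sequence validator).
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(CodingSequence(id=rec.id, seq=str(rec.seq), strict=strict))
    return records


def write_fasta(records: Iterable[CodingSequence], path: "str | Path") -> None:
    """Write CDS records wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with _atomic_path(path) as tmp:
        with open(tmp, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
            writer.write_file(seqs)


# -- expression ----------------------------------------------------------


def read_expression_tsv(path: "str | Path") -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["gene_id", "intensity"]:
        raise ValueError("expression TSV must have header: gene_id, intensity")
    return ExpressionTable.from_pairs(zip(df["gene_id"], df["intensity"]))


def write_expression_tsv(expr: ExpressionTable, path: "str | Path") -> None:
    df = pd.DataFrame(expr.records, columns=["gene_id", "intensity"])
    _write_frame(df, path)


# -- bias report ---------------------------------------------------------

_BIAS_COLUMNS = [
    "codon",
    "amino_acid",
    "group_count",
    "group_family_total",
    "background_count",
    "background_family_total",
    "p",
    "q",
    "direction",
]


def write_bias_tsv(bias: BiasResultSet, path: "str | Path") -> None:
    """One row per testable codon, sorted by q then codon."""
    rows = sorted(bias.results, key=lambda r: (r.q_value, r.codon))
    df = pd.DataFrame(
        [
            {
                "codon": r.codon,
                "amino_acid": r.amino_acid,
                "group_count": r.group_count,
                "group_family_total": r.group_family_total,
                "background_count": r.background_count,
                "background_family_total": r.background_family_total,
                "p": r.p_value,
                "q": r.q_value,
                "direction": r.direction,
            }
            for r in rows
        ],
        columns=_BIAS_COLUMNS,
    )
    _write_frame(df, path)


def read_bias_tsv(path: "str | Path", alpha: float = 0.05, mode: str = "within_family") -> BiasResultSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != _BIAS_COLUMNS:
        raise ValueError("malformed bias report TSV")
    results = tuple(
        BiasResult(
            codon=row.codon,
            amino_acid=row.amino_acid,
            direction=row.direction,
            p_value=float(row.p),
            q_value=float(row.q),
            group_count=int(row.group_count),
            group_family_total=int(row.group_family_total),
            background_count=int(row.background_count),
            background_family_total=int(row.background_family_total),
        )
        for row in df.itertuples()
    )
    return BiasResultSet(results=results, alpha=alpha, mode=mode)


# -- rank scan -----------------------------------------------------------


def write_scan_tsv(scan: ScanTable, path: "str | Path") -> None:
    df = pd.DataFrame(
        [
            {
                "n_top": r.n_top,
                "n_significant_codons": len(r.significant_codons),
                "n_significant_amino_acids": r.n_significant_amino_acids,
                "codons": ",".join(r.significant_codons),
            }
            for r in scan.rows
        ],
        columns=["n_top", "n_significant_codons", "n_significant_amino_acids", "codons"],
    )
    _write_frame(df, path)


def read_scan_tsv(path: "str | Path") -> ScanTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    rows = tuple(
        ScanRow(
            n_top=int(row.n_top),
            significant_codons=tuple(c for c in str(row.codons).split(",") if c),
            n_significant_amino_acids=int(row.n_significant_amino_acids),
        )
        for row in df.itertuples()
    )
    return ScanTable(rows=rows)


# -- per-gene reports ----------------------------------------------------


def write_gene_stats_tsv(rows: Sequence[Mapping], path: "str | Path") -> None:
    """Columns: gene_id, n_codons, gc, gc3, enc."""
    df = pd.DataFrame(rows, columns=["gene_id", "n_codons", "gc", "gc3", "enc"])
    _write_frame(df, path)


def write_counts_tsv(counts_by_gene: Mapping[str, Mapping[str, int]], path: "str | Path") -> None:
    """Long-format per-gene codon counts: gene_id, codon, count."""
    rows = [
        {"gene_id": g, "codon": c, "count": n}
        for g, counts in counts_by_gene.items()
        for c, n in sorted(counts.items())
    ]
    _write_frame(pd.DataFrame(rows, columns=["gene_id", "codon", "count"]), path)


# -- recoding ------------------------------------------------------------


def write_ledger_tsv(changes: Sequence[CodonChange], path: "str | Path") -> None:
    df = pd.DataFrame(
        [
            {"codon_index": c.codon_index, "from_codon": c.from_codon, "to_codon": c.to_codon}
            for c in changes
        ],
        columns=["codon_index", "from_codon", "to_codon"],
    )
    _write_frame(df, path)


def read_ledger_tsv(path: "str | Path") -> tuple[CodonChange, ...]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["codon_index", "from_codon", "to_codon"]:
        raise ValueError("malformed ledger TSV")
    return tuple(
        CodonChange(int(r.codon_index), str(r.from_codon), str(r.to_codon))
        for r in df.itertuples()
    )


def write_map_tsv(rmap: RecodingMap, path: "str | Path") -> None:
    df = pd.DataFrame(
        [{"amino_acid": aa, "target_codon": rmap.targets[aa]} for aa in sorted(rmap.targets)],
        columns=["amino_acid", "target_codon"],
    )
    _write_frame(df, path)


def read_map_tsv(path: "str | Path", mode: str) -> RecodingMap:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != ["amino_acid", "target_codon"]:
        raise ValueError("malformed map TSV (need amino_acid, target_codon)")
    targets = {str(r.amino_acid): str(r.target_codon) for r in df.itertuples()}
    return RecodingMap(mode=mode, targets=targets, scope=frozenset(targets))


# -- plates and summaries ------------------------------------------------


def read_plate_csv(path: "str | Path") -> Plate:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"well", "construct", "role", "channel", "value"}
    if not needed <= set(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(needed)}")
    return Plate(data=df)


def write_plate_csv(plate: Plate, path: "str | Path") -> None:
    cols = ["well", "construct", "role", "channel", "value"]
    if "transfection" in plate.data.columns:
        cols.append("transfection")
    _write_frame(plate.data[cols], path, sep=",")


def write_summary_tsv(summary: pd.DataFrame, path: "str | Path") -> None:
    cols = ["construct", "n", "mean_ratio", "sd", "cv", "relative", "p_vs_reference"]
    _write_frame(summary[cols], path)


def read_summary_tsv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
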