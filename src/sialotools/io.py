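"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (nucleotide and protein), BLAST-style tabular hit tables (the common
12-column layout extended with query/subject lengths and the subject
description), TSV count matrices and the final annotation table.  All
coordinate conversion between the 1-based inclusive convention of the hit
tables and the package's internal 0-based half-open convention happens here.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

#: default column order of an extended tabular hit file: the standard
#: 12 columns plus qlen, slen and the subject title appended.
HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "pident",
    "align_len",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "slen",
    "subject_desc",
)


@dataclass
class SeqRecord:
    """A named sequence; ``kind`` is ``"nt"`` or ``"aa"``."""

    id: str
    seq: str
    description: str = ""
    kind: str = "nt"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class HitTableRow:
    """One homology match (BLASTp/RPS-BLAST style) against a database.

    Coordinates are kept 1-based inclusive, the convention of the source
    format; use :func:`to_zero_based` to convert.
    """

    query_id: str
    subject_id: str
    subject_desc: str
    db_tag: str
    pident: float
    align_len: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    @property
    def subject_cov(self) -> float:
        """Fraction of the subject (matching protein) covered by the hit."""
        return (self.send - self.sstart + 1) / self.slen


@dataclass
class PipelineConfig:
    """All numeric cut-offs of the pipeline in one place."""

    min_orf_nt: int = 150
    min_sp_aa: int = 40
    min_subject_cov: float = 0.70
    dedup_identity: float = 0.95
    tpm_min: float = 3.0
    lfc_thresh: float = 2.0
    fdr_thresh: float = 0.05
    min_accept_pident: float = 35.0
    min_accept_cov: float = 0.50
    db_precedence: tuple[str, ...] = ("NR", "TSA", "Refseq-invertebrate", "CDD")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_orf_nt", "min_sp_aa", "min_subject_cov", "tpm_min",
                     "lfc_thresh", "fdr_thresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must lie in (0, 1]")
        if not self.db_precedence:
            raise ValueError("db_precedence must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "db_precedence" in data:
            data["db_precedence"] = tuple(data["db_precedence"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def to_zero_based(start_1based: int, end_1based_incl: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open interval."""
    return start_1based - 1, end_1based_incl


def to_one_based(start0: int, end0_excl: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive interval."""
    return start0 + 1, end0_excl


def _clean_seq(seq: str, kind: str, rec_id: str) -> str:
    seq = seq.upper()
    if kind == "nt":
        seq = seq.replace("U", "T")
        alphabet = NT_ALPHABET
    elif kind == "aa":
        alphabet = AA_ALPHABET
    else:
        raise ValueError(f"kind must be 'nt' or 'aa', got {kind!r}")
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"illegal character {ch!r} at position {pos} in record {rec_id!r}"
            )
    return seq


def read_fasta(path: str | Path, kind: str = "nt") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Sequence is upper-cased; for nucleotide input ``U`` is folded to ``T``.
    Duplicate ids, empty sequences and illegal characters raise ``ValueError``.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"empty sequence under header {cur_id!r}")
        records.append(SeqRecord(cur_id, _clean_seq(seq, kind, cur_id), cur_desc, kind))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                parts = header.split(None, 1)
                if not parts:
                    raise ValueError("empty FASTA header")
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise ValueError(f"duplicate record id {cur_id!r}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.strip())
        flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_hit_table(
    path: str | Path,
    db_tag: str,
    columns: Sequence[str] = HIT_COLUMNS,
) -> list[HitTableRow]:
    """Parse a tab-separated hit table; ``#`` lines are comments.

    ``columns`` declares the on-disk column order and must cover every
    field of :class:`HitTableRow` except ``db_tag``.
    """
    int_fields = {"align_len", "qstart", "qend", "sstart", "send", "qlen", "slen"}
    float_fields = {"pident", "evalue", "bitscore"}
    needed = {f.name for f in dataclasses.fields(HitTableRow)} - {"db_tag"}
    missing = needed - set(columns)
    if missing:
        raise ValueError(f"column spec is missing fields: {sorted(missing)}")

    rows: list[HitTableRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"line {lineno}: expected {len(columns)} columns, got {len(fields)}"
                )
            values: dict[str, object] = {}
            for name, raw in zip(columns, fields):
                if name not in needed:
                    continue
                try:
                    if name in int_fields:
                        values[name] = int(float(raw))
                    elif name in float_fields:
                        values[name] = float(raw)
                    else:
                        values[name] = raw
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: non-numeric value {raw!r} for column {name}"
                    ) from exc
            row = HitTableRow(db_tag=db_tag, **values)  # type: ignore[arg-type]
            if row.qstart > row.qend or row.sstart > row.send:
                raise ValueError(f"line {lineno}: inverted coordinates")
            if not 0 <= row.pident <= 100:
                raise ValueError(f"line {lineno}: pident outside [0, 100]")
            if row.slen <= 0:
                raise ValueError(f"line {lineno}: non-positive subject length")
            rows.append(row)
    return rows


def write_hit_table(rows: Iterable[HitTableRow], path: str | Path,
                    columns: Sequence[str] = HIT_COLUMNS) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            # columns of the source format absent from the model (mismatch,
            # gapopen) are emitted as 0
            fh.write("\t".join(str(getattr(row, c, 0)) for c in columns) + "\n")


ANNOTATION_COLUMNS = (
    "id", "class", "family", "mean_tpm_ref", "mean_tpm_alt",
    "logFC", "fdr", "status", "matched_term", "pident", "subject_cov",
)


def write_annotation_table(rows: Iterable[dict], path: str | Path,
                           databases: Sequence[str] = ()) -> None:
    """Write the final annotation table as TSV.

    One column per evidence database is appended after the fixed schema.
    Numbers use fixed precision: TPM one decimal, logFC two decimals,
    FDR two significant digits in scientific notation.  Missing values
    are emitted as empty strings.
    """
    header = list(ANNOTATION_COLUMNS) + [f"best_hit_{db}" for db in databases]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            out: list[str] = []
            for col in header:
                val = row.get(col)
                if val is None or (isinstance(val, float) and pd.isna(val)):
                    out.append("")
                elif col in ("mean_tpm_ref", "mean_tpm_alt"):
                    out.append(f"{float(val):.1f}")
                elif col == "logFC":
                    out.append(f"{float(val):.2f}")
                elif col == "fdr":
                    out.append(f"{float(val):.2e}")
                elif col in ("pident", "subject_cov"):
                    out.append(f"{float(val):.3g}")
                else:
                    out.append(str(val))
            fh.write("\t".join(out) + "\n")


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False,
                       na_values=[""])


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix TSV: columns transcript_id, eff_length, one per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    if "transcript_id" not in df.columns or "eff_length" not in df.columns:
        raise ValueError("counts TSV needs 'transcript_id' and 'eff_length' columns")
    return df.set_index("transcript_id")


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Sample metadata TSV with columns sample, condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "condition" not in df.columns:
        raise ValueError("metadata TSV needs 'sample' and 'condition' columns")
    return dict(zip(df["sample"], df["condition"]))


def write_metadata(meta: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, cond in meta.items():
            fh.write(f"{sample}\t{cond}\n")
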