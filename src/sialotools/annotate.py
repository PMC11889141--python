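"""Vocabulary-driven functional classification and abundance summaries.

Each coding sequence is classified by scanning the description string of
its best homology hit against an ordered keyword lexicon.  The lexicon
maps terms to functional classes (and, for the secreted class, protein
families); term selection is by priority tier first and position of
appearance second, so specific family terms ("kunitz") outrank generic
enzyme terms ("serine protease") wherever they co-occur in a description.

Coding sequences with no informative hit are classified "secreted /
Unknown" when they carry a predicted signal peptide and "unknown"
otherwise; viral-source sequences are always class "virus".
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cds import CodingSequence
from .io import HitTableRow
from .quant import ExpressionTable
from .sigpep import SignalPrediction

#: classes of the shipped default lexicon; user lexica may declare others
DEFAULT_CLASSES = (
    "secreted", "virus", "unknown",
    "Met/Energy", "transcription machinery", "protein synthesis",
    "protein modification", "protein export", "proteasome", "transporter",
    "cytoskeletal", "signal transduction", "nuclear regulation", "immunity",
    "carbohydrate metabolism", "lipid metabolism", "amino acid metabolism",
    "nucleotide metabolism", "detoxification", "oxidant metabolism",
    "storage", "extracellular matrix", "chromatin", "transposable element",
    "apoptosis", "chaperone", "cell cycle", "RNA processing",
)


@dataclass
class LexiconEntry:
    term: str
    class_label: str
    family: str | None
    priority: int
    order: int  # file order, last tie-break


@dataclass
class Lexicon:
    entries: list[LexiconEntry]
    class_list: tuple[str, ...]
    db_precedence: tuple[str, ...]

    def __post_init__(self) -> None:
        terms = [e.term for e in self.entries]
        if len(terms) != len(set(terms)):
            dup = next(t for t in terms if terms.count(t) > 1)
            raise ValueError(f"duplicate lexicon term {dup!r}")
        for e in self.entries:
            if e.class_label not in self.class_list:
                raise ValueError(
                    f"term {e.term!r} uses unknown class {e.class_label!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, term: str) -> LexiconEntry | None:
        term = _normalize(term)
        for e in self.entries:
            if e.term == term:
                return e
        return None

    def scan(self, description: str) -> LexiconEntry | None:
        """Best-matching term in a hit description.

        Among all terms occurring as substrings of the normalised
        description, the highest priority wins; ties go to the earliest
        position of appearance, then to lexicon file order.
        """
        text = _normalize(description)
        best: tuple[int, int, int] | None = None  # (-prio, pos, order)
        best_entry: LexiconEntry | None = None
        for e in self.entries:
            pos = text.find(e.term)
            if pos < 0:
                continue
            key = (-e.priority, pos, e.order)
            if best is None or key < best:
                best = key
                best_entry = e
        return best_entry


@dataclass
class AnnotationResult:
    cds_id: str
    class_label: str
    family: str | None = None
    evidence: dict[str, HitTableRow] = field(default_factory=dict)
    matched_term: str | None = None
    pident: float | None = None
    subject_cov: float | None = None


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def load_lexicon(
    path: str | Path,
    class_list: Sequence[str] | None = None,
    db_precedence: Sequence[str] = ("NR", "TSA", "Refseq-invertebrate", "CDD"),
) -> Lexicon:
    """Load a lexicon TSV (columns term, class, family, priority).

    Entries are lower-cased and whitespace-normalised, keeping file
    order.  With ``class_list=None`` the classes are taken from the file
    plus the three structural classes (secreted, unknown, virus).
    """
    entries: list[LexiconEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["term", "class", "family", "priority"]:
            raise ValueError("lexicon TSV must start with columns "
                             "term, class, family, priority")
        for order, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"lexicon row with {len(fields)} columns: {line!r}")
            term, cls, family, priority = fields
            entries.append(LexiconEntry(
                term=_normalize(term),
                class_label=cls.strip(),
                family=family.strip() or None,
                priority=int(priority),
                order=order,
            ))
    if not entries:
        raise ValueError("lexicon file contains no entries")
    if class_list is None:
        classes = {e.class_label for e in entries} | {"secreted", "unknown", "virus"}
        class_list = tuple(sorted(classes))
    return Lexicon(entries=entries, class_list=tuple(class_list),
                   db_precedence=tuple(db_precedence))


def default_lexicon() -> Lexicon:
    """The shipped reconstruction of the classification vocabulary."""
    ref = importlib.resources.files("sialotools") / "data" / "lexicon.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_lexicon(path, class_list=DEFAULT_CLASSES)


def classify_cds(
    cds: CodingSequence,
    hits: Iterable[HitTableRow],
    sp: SignalPrediction | None,
    lexicon: Lexicon,
    min_accept: tuple[float, float] = (35.0, 0.50),
) -> AnnotationResult:
    """Classify one coding sequence from its homology evidence.

    Viral-source sequences are class "virus" outright.  Otherwise the
    databases are visited in precedence order; the first database with a
    hit meeting the identity/coverage floor contributes its best-bitscore
    hit, whose description is scanned against the lexicon.  Sequences
    with no informative hit or no matching term fall back to "secreted /
    Unknown" if signal-positive, else "unknown".
    """
    min_pident, min_cov = min_accept
    by_db: dict[str, list[HitTableRow]] = {}
    for h in hits:
        by_db.setdefault(h.db_tag, []).append(h)
    evidence = {
        db: max(rows, key=lambda h: h.bitscore)
        for db, rows in by_db.items()
    }

    if cds.source == "viral":
        return AnnotationResult(cds.id, "virus", evidence=evidence)

    chosen: HitTableRow | None = None
    for db in lexicon.db_precedence:
        accepted = [h for h in by_db.get(db, ())
                    if h.pident >= min_pident and h.subject_cov >= min_cov]
        if accepted:
            chosen = max(accepted, key=lambda h: h.bitscore)
            break

    has_sp = bool(sp and sp.has_sp) or (cds.sp is not None and cds.sp.has_sp)
    if chosen is not None:
        entry = lexicon.scan(chosen.subject_desc)
        if entry is not None:
            family = entry.family if entry.class_label == "secreted" else None
            return AnnotationResult(
                cds.id, entry.class_label, family=family, evidence=evidence,
                matched_term=entry.term, pident=chosen.pident,
                subject_cov=chosen.subject_cov,
            )
    if has_sp:
        return AnnotationResult(cds.id, "secreted", family="Unknown",
                                evidence=evidence)
    return AnnotationResult(cds.id, "unknown", evidence=evidence)


def annotate_all(
    cds_list: Sequence[CodingSequence],
    hits: Sequence[HitTableRow],
    lexicon: Lexicon,
    min_accept: tuple[float, float] = (35.0, 0.50),
) -> dict[str, AnnotationResult]:
    """Classify every CDS, routing hits by parent transcript (or own id)."""
    by_query: dict[str, list[HitTableRow]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, AnnotationResult] = {}
    for cds in cds_list:
        qids = {cds.id, cds.parent_transcript or cds.id}
        own_hits = [h for q in qids for h in by_query.get(q, ())]
        res = classify_cds(cds, own_hits, cds.sp, lexicon, min_accept)
        res.cds_id = cds.id
        out[cds.id] = res
    return out


def class_abundance_summary(
    annotations: Mapping[str, AnnotationResult],
    expr: ExpressionTable,
) -> pd.DataFrame:
    """Percent of total TPM per functional class, per condition.

    Per sample the share of a class is the summed TPM of its members
    divided by 1e6, times 100; per condition the mean and standard
    deviation of the per-replicate shares are reported.  Shares within a
    sample sum to 100 (when any reads are present).
    """
    missing = [tid for tid in expr.tpm.index if tid not in annotations]
    if missing:
        raise ValueError(f"expressed CDS without annotation: {missing[:5]}")
    classes = pd.Series({tid: annotations[tid].class_label for tid in expr.tpm.index})
    shares = expr.tpm.groupby(classes).sum() / 1e6 * 100  # classes x samples

    conditions = sorted(set(expr.sample_condition.values()))
    out = {}
    for cond in conditions:
        cols = [s for s in expr.tpm.columns if expr.sample_condition[s] == cond]
        out[(cond, "mean")] = shares[cols].mean(axis=1)
        out[(cond, "sd")] = shares[cols].std(axis=1, ddof=1)
    summary = pd.DataFrame(out)
    summary.columns = pd.MultiIndex.from_tuples(summary.columns)
    summary.attrs["per_sample_shares"] = shares
    return summary.sort_values((conditions[0], "mean"), ascending=False)


def secreted_family_table(
    annotations: Mapping[str, AnnotationResult],
    expr: ExpressionTable,
    tpm_min: float = 3.0,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per secreted family: detected-member counts and summed mean TPM.

    A member is counted for a condition when its condition-mean TPM is at
    least ``tpm_min``; the TPM column sums the condition means of those
    members.  ``reduction_pct`` is the percent decrease from the
    reference condition (default: first alphabetically) to the other.
    """
    conds = list(expr.condition_means.columns)
    if len(conds) != 2:
        raise ValueError("secreted family table needs exactly 2 conditions")
    ref = reference or conds[0]
    if ref not in conds:
        raise ValueError(f"unknown reference condition {ref!r}")
    alt = next(c for c in conds if c != ref)

    rows = []
    families = sorted({a.family for a in annotations.values()
                       if a.class_label == "secreted" and a.family})
    for fam in families:
        members = [tid for tid, a in annotations.items()
                   if a.class_label == "secreted" and a.family == fam
                   and tid in expr.condition_means.index]
        rec: dict[str, object] = {"family": fam}
        sums = {}
        for cond in (ref, alt):
            means = expr.condition_means.loc[members, cond]
            detected = means[means >= tpm_min]
            rec[f"n_cds_{cond}"] = int(len(detected))
            sums[cond] = float(detected.sum())
            rec[f"tpm_{cond}"] = sums[cond]
        if sums[ref] > 0:
            rec["reduction_pct"] = (sums[ref] - sums[alt]) / sums[ref] * 100
        else:
            rec["reduction_pct"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows, columns=["family", f"n_cds_{ref}", f"n_cds_{alt}",
                                       f"tpm_{ref}", f"tpm_{alt}",
                                       "reduction_pct"])
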