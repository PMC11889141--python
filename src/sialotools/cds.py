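"""Coding-sequence extraction from assembled transcripts.

Two routes promote an open reading frame to a coding sequence:

* homology: a protein-space hit covering at least 70% of its matching
  protein overlaps the ORF (the ORF is kept whole, not trimmed to the hit);
* signal peptide: among Met-initiated sub-ORFs of at least 40 aa, the most
  5' methionine whose downstream sequence carries a predicted signal
  peptide becomes the start.

Extracted coding sequences are merged with reference-genome and viral CDS
sets and consolidated at 95% nucleotide identity by greedy longest-first
clustering (CD-HIT style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io import HitTableRow, SeqRecord
from .sigpep import SignalPrediction, predict_signal_peptide

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class OrfCandidate:
    """A maximal stop-to-stop (or edge-delimited) segment in one frame.

    ``nt_start``/``nt_end`` are 0-based half-open on the forward strand of
    the transcript; the span includes the terminal stop codon when present.
    ``nt_seq`` is the strand-oriented nucleotide sequence of the span.
    """

    transcript_id: str
    strand: str  # '+' or '-'
    frame: int  # 0-2, relative to the strand-oriented sequence
    nt_start: int
    nt_end: int
    aa_seq: str
    met_positions: list[int]
    has_terminal_stop: bool
    nt_seq: str = ""

    @property
    def coding_nt(self) -> str:
        """Nucleotide sequence without the terminal stop codon."""
        return self.nt_seq[:-3] if self.has_terminal_stop else self.nt_seq


@dataclass
class CodingSequence:
    id: str
    source: str  # denovo | genome | viral
    nt_seq: str  # coding nucleotides, stop codon excluded
    aa_seq: str
    start_anchor: str = "none"  # none | homology | signal_peptide
    parent_transcript: str | None = None
    evidence: HitTableRow | None = None
    sp: SignalPrediction | None = None


@dataclass
class ConsolidationReport:
    clusters: list[tuple[str, list[str]]]
    identity_threshold: float


def translate(nt_seq: str) -> str:
    """Translate a nucleotide sequence; trailing partial codon dropped."""
    usable = len(nt_seq) - len(nt_seq) % 3
    return str(Seq(nt_seq[:usable]).translate())


def revcomp(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())


def find_orfs(transcript: SeqRecord, min_nt: int = 150,
              require_met: bool = False) -> list[OrfCandidate]:
    """Enumerate ORFs of at least ``min_nt`` nucleotides over all 6 frames.

    An ORF is a maximal run of non-stop codons delimited by stop codons or
    the sequence edges; a run must abut at least one stop codon (frames
    never interrupted by a stop are not ORFs), so stop-to-stop,
    edge-to-stop and truncated stop-to-edge segments all qualify.  The
    nucleotide length counts the terminal stop codon when one is
    present.  With ``require_met``, segments containing no in-frame
    methionine are dropped (the segment start is still reported;
    ``met_positions`` lists candidate starts for downstream selection).
    """
    if min_nt < 3:
        raise ValueError("min_nt must be >= 3")
    seq = transcript.seq
    if not set(seq) <= {"A", "C", "G", "T", "N"}:
        raise ValueError(f"non-nucleotide alphabet in {transcript.id!r}")
    length = len(seq)
    out: list[OrfCandidate] = []
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            n_codons = (length - frame) // 3
            if n_codons <= 0:
                continue
            # split codon indices into stop-delimited runs
            run_start = 0
            for ci in range(n_codons + 1):
                codon = oriented[frame + 3 * ci : frame + 3 * ci + 3] if ci < n_codons else None
                is_stop = codon in STOP_CODONS
                if ci == n_codons or is_stop:
                    bounded = is_stop or run_start > 0
                    if ci > run_start and bounded:
                        s = frame + 3 * run_start
                        e = frame + 3 * ci + (3 if is_stop else 0)
                        if e - s >= min_nt:
                            orf = _make_orf(transcript.id, strand, frame,
                                            oriented, length, s, e, is_stop)
                            if not require_met or orf.met_positions:
                                out.append(orf)
                    run_start = ci + 1
    out.sort(key=lambda o: (o.nt_start, o.nt_end, o.strand, o.frame))
    return out


def _make_orf(tid: str, strand: str, frame: int, oriented: str,
              length: int, s: int, e: int, has_stop: bool) -> OrfCandidate:
    nt_seq = oriented[s:e]
    coding = nt_seq[:-3] if has_stop else nt_seq
    aa = translate(coding)
    if strand == "+":
        nt_start, nt_end = s, e
    else:
        nt_start, nt_end = length - e, length - s
    mets = [i for i, ch in enumerate(aa) if ch == "M"]
    return OrfCandidate(tid, strand, frame, nt_start, nt_end, aa, mets,
                        has_stop, nt_seq)


def _best_hit_per_orf(
    orf_list: Sequence[OrfCandidate],
    hits: Iterable[HitTableRow],
    min_subject_cov: float,
    known_transcripts: set[str] | None = None,
) -> list[HitTableRow | None]:
    """For each ORF, the highest-bitscore qualifying overlapping hit."""
    by_transcript: dict[str, list[HitTableRow]] = {}
    tids = {o.transcript_id for o in orf_list}
    if known_transcripts is not None:
        tids |= known_transcripts
    for hit in hits:
        if hit.query_id not in tids:
            logger.warning("hit references unknown transcript %r; skipped",
                           hit.query_id)
            continue
        by_transcript.setdefault(hit.query_id, []).append(hit)

    best_hits: list[HitTableRow | None] = []
    for orf in orf_list:
        best: HitTableRow | None = None
        for hit in by_transcript.get(orf.transcript_id, ()):
            if hit.subject_cov < min_subject_cov:
                continue
            h_start, h_end = hit.qstart - 1, hit.qend
            if h_start < orf.nt_end and orf.nt_start < h_end:
                if best is None or hit.bitscore > best.bitscore:
                    best = hit
        best_hits.append(best)
    return best_hits


def extract_cds_by_homology(
    orfs: Iterable[OrfCandidate],
    hits: Iterable[HitTableRow],
    min_subject_cov: float = 0.70,
    known_transcripts: set[str] | None = None,
) -> list[CodingSequence]:
    """Promote ORFs overlapped by a hit covering >= ``min_subject_cov`` of
    its matching protein.

    Hit query coordinates are 1-based nucleotide positions on the forward
    strand of the transcript (blastx convention).  Among qualifying hits
    the highest bitscore provides the reported evidence; the ORF
    boundaries are not trimmed to the hit.
    """
    orf_list = list(orfs)
    best_hits = _best_hit_per_orf(orf_list, hits, min_subject_cov,
                                  known_transcripts)
    out: list[CodingSequence] = []
    for orf, best in zip(orf_list, best_hits):
        if best is not None:
            out.append(CodingSequence(
                id=orf.transcript_id,
                source="denovo",
                nt_seq=orf.coding_nt,
                aa_seq=orf.aa_seq,
                start_anchor="homology",
                parent_transcript=orf.transcript_id,
                evidence=best,
            ))
    return out


def anchor_start_by_sp(
    orf: OrfCandidate,
    sp_calls: Mapping[int, SignalPrediction],
    min_sp_aa: int = 40,
) -> CodingSequence | None:
    """Pick the most 5' signal-positive methionine as the start.

    ``sp_calls`` maps each Met aa-offset (for sub-ORFs of length >=
    ``min_sp_aa``) to its signal-peptide prediction.  Returns ``None``
    when no candidate is signal-positive.
    """
    for m in orf.met_positions:
        if len(orf.aa_seq) - m < min_sp_aa:
            break  # met_positions ascending: later Mets are shorter still
        pred = sp_calls.get(m)
        if pred is not None and pred.has_sp:
            return CodingSequence(
                id=orf.transcript_id,
                source="denovo",
                nt_seq=orf.coding_nt[3 * m:],
                aa_seq=orf.aa_seq[m:],
                start_anchor="signal_peptide",
                parent_transcript=orf.transcript_id,
                sp=pred,
            )
    return None


def predict_sp_for_orf(
    orf: OrfCandidate,
    min_sp_aa: int = 40,
    predictor: Callable[[str], SignalPrediction] = None,
) -> dict[int, SignalPrediction]:
    """Run the signal-peptide predictor on every qualifying Met sub-ORF."""
    predictor = predictor or (lambda s: predict_signal_peptide(s))
    calls: dict[int, SignalPrediction] = {}
    for m in orf.met_positions:
        if len(orf.aa_seq) - m < min_sp_aa:
            break
        calls[m] = predictor(orf.aa_seq[m:])
    return calls


def extract_cds(
    transcripts: Sequence[SeqRecord],
    hits: Sequence[HitTableRow],
    min_orf_nt: int = 150,
    min_subject_cov: float = 0.70,
    min_sp_aa: int = 40,
    sp_predictor: Callable[[str], SignalPrediction] | None = None,
) -> list[CodingSequence]:
    """Run both extraction routes over a transcript set.

    When an ORF qualifies on both routes the homology anchor wins (it
    fixes the reading frame more reliably) and the signal-peptide
    evidence is recorded alongside.  At most one CDS is reported per
    transcript/ORF pair; ids are suffixed when a transcript yields
    several.
    """
    all_orfs: list[OrfCandidate] = []
    for tr in transcripts:
        all_orfs.extend(find_orfs(tr, min_nt=min_orf_nt))
    best_hits = _best_hit_per_orf(all_orfs, hits, min_subject_cov,
                                  {t.id for t in transcripts})
    out: list[CodingSequence] = []
    per_transcript_n: dict[str, int] = {}
    for orf, best in zip(all_orfs, best_hits):
        sp_calls = predict_sp_for_orf(orf, min_sp_aa, sp_predictor)
        sp_cds = anchor_start_by_sp(orf, sp_calls, min_sp_aa)
        if best is not None:
            cds = CodingSequence(
                id=orf.transcript_id,
                source="denovo",
                nt_seq=orf.coding_nt,
                aa_seq=orf.aa_seq,
                start_anchor="homology",
                parent_transcript=orf.transcript_id,
                evidence=best,
            )
            if sp_cds is not None:  # record the signal evidence on the winner
                cds.sp = sp_cds.sp
        else:
            cds = sp_cds
        if cds is None:
            continue
        n = per_transcript_n.get(cds.parent_transcript, 0)
        per_transcript_n[cds.parent_transcript] = n + 1
        if n:
            cds.id = f"{cds.parent_transcript}.{n + 1}"
        out.append(cds)
    return out


def merge_cds_sources(
    denovo: Iterable[CodingSequence],
    genome: Iterable[CodingSequence],
    viral: Iterable[CodingSequence],
) -> list[CodingSequence]:
    """Union of the three CDS sets.

    On an id collision across sources precedence is genome > viral >
    de novo; a collision within one source is an error.
    """
    merged: dict[str, CodingSequence] = {}
    for records, source in ((genome, "genome"), (viral, "viral"),
                            (denovo, "denovo")):
        seen_here: set[str] = set()
        for rec in records:
            if rec.id in seen_here:
                raise ValueError(f"duplicate id {rec.id!r} within source {source}")
            seen_here.add(rec.id)
            if rec.id not in merged:  # earlier source wins
                rec.source = source
                merged[rec.id] = rec
    return list(merged.values())


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment columns."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def consolidate_identity(
    cds: Sequence[CodingSequence],
    threshold: float = 0.95,
    level: str = "nt",
) -> tuple[list[CodingSequence], ConsolidationReport]:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are sorted by length descending (ties by id ascending);
    each joins the first cluster whose representative aligns at identity
    >= ``threshold``, else founds a new cluster.  ``level`` selects
    whether nucleotide or amino-acid sequences are compared.

    Two exact prefilters keep the O(n^2) alignment loop fast: identity
    can never exceed shorter/longer length ratio, and at >= 90% identity
    two sequences of >= 150 residues must share at least one 12-mer.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    key = (lambda c: c.nt_seq) if level == "nt" else (lambda c: c.aa_seq)
    order = sorted(cds, key=lambda c: (-len(key(c)), c.id))
    aligner = _make_aligner()
    k = 12
    use_kmers = threshold >= 0.90
    reps: list[CodingSequence] = []
    rep_kmers: list[set[str]] = []
    clusters: dict[str, list[str]] = {}
    for rec in order:
        seq = key(rec)
        kmers = _kmer_set(seq, k) if use_kmers else set()
        placed = False
        for rep, rkm in zip(reps, rep_kmers):
            rseq = key(rep)
            if len(seq) < threshold * len(rseq):
                continue
            if use_kmers and len(seq) >= 150 and not (kmers & rkm):
                continue
            if pairwise_identity(seq, rseq, aligner) >= threshold:
                clusters[rep.id].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            rep_kmers.append(kmers)
            clusters[rec.id] = [rec.id]
    report = ConsolidationReport(
        clusters=[(rid, members) for rid, members in clusters.items()],
        identity_threshold=threshold,
    )
    return reps, report
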