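"""End-to-end orchestration: transcripts + hits + counts -> annotated,
quantified, differentially-expressed CDS catalogue."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import annotate as _annotate
from . import cds as _cds
from . import diffexp as _diffexp
from . import quant as _quant
from .io import HitTableRow, PipelineConfig, SeqRecord


@dataclass
class PipelineResult:
    cds: list[_cds.CodingSequence]
    consolidation: _cds.ConsolidationReport
    expression: _quant.ExpressionTable
    partition: _quant.PresencePartition
    annotations: dict[str, _annotate.AnnotationResult]
    class_summary: pd.DataFrame
    de: pd.DataFrame | None
    phi_common: float | None


def run_pipeline(
    transcripts: Sequence[SeqRecord],
    hits: Sequence[HitTableRow],
    counts: pd.DataFrame,
    sample_condition: dict[str, str],
    viral_cds: Sequence[SeqRecord] = (),
    genome_cds: Sequence[SeqRecord] = (),
    config: PipelineConfig | None = None,
    lexicon: _annotate.Lexicon | None = None,
    reference: str | None = None,
    run_de: bool = True,
) -> PipelineResult:
    """Run extraction, consolidation, quantification, annotation and DE.

    ``counts`` rows must be keyed by final CDS id (reads are assumed
    mapped against the merged CDS set); rows without an extracted CDS
    are dropped with the decoys.
    """
    cfg = config or PipelineConfig()
    lexicon = lexicon or _annotate.default_lexicon()

    denovo = _cds.extract_cds(
        transcripts, hits,
        min_orf_nt=cfg.min_orf_nt,
        min_subject_cov=cfg.min_subject_cov,
        min_sp_aa=cfg.min_sp_aa,
    )
    viral = [_cds.CodingSequence(
        id=r.id, source="viral", nt_seq=r.seq[:-3] if _is_stop(r.seq[-3:]) else r.seq,
        aa_seq=_cds.translate(r.seq[:-3] if _is_stop(r.seq[-3:]) else r.seq))
        for r in viral_cds]
    genome = [_cds.CodingSequence(
        id=r.id, source="genome", nt_seq=r.seq[:-3] if _is_stop(r.seq[-3:]) else r.seq,
        aa_seq=_cds.translate(r.seq[:-3] if _is_stop(r.seq[-3:]) else r.seq))
        for r in genome_cds]
    merged = _cds.merge_cds_sources(denovo, genome, viral)
    final_cds, report = _cds.consolidate_identity(merged, cfg.dedup_identity)

    keep = [c.id for c in final_cds if c.id in counts.index]
    expr = _quant.compute_tpm(counts.loc[keep], sample_condition)
    partition = _quant.presence_partition(expr, cfg.tpm_min)

    retained = sorted(partition.retained)
    cds_by_id = {c.id: c for c in final_cds}
    annotations = _annotate.annotate_all(
        [cds_by_id[i] for i in retained], list(hits), lexicon,
        (cfg.min_accept_pident, cfg.min_accept_cov))

    retained_counts = counts.loc[retained]
    retained_expr = _quant.compute_tpm(retained_counts, sample_condition)
    class_summary = _annotate.class_abundance_summary(annotations, retained_expr)

    de = None
    phi = None
    if run_de:
        de = _diffexp.de_pipeline(
            retained_counts.drop(columns=["eff_length"]),
            sample_condition,
            reference=reference or sorted(set(sample_condition.values()))[0],
            lfc_thresh=cfg.lfc_thresh,
            fdr_thresh=cfg.fdr_thresh,
        )
        phi = de.attrs.get("phi_common")

    return PipelineResult(
        cds=final_cds, consolidation=report, expression=expr,
        partition=partition, annotations=annotations,
        class_summary=class_summary, de=de, phi_common=phi,
    )


def viral_census(partition: _quant.PresencePartition,
                 viral_ids: Sequence[str]) -> int:
    """Number of viral ORFs detected at the TPM threshold in >= 1 condition."""
    return len(partition.retained & set(viral_ids))


def _is_stop(codon: str) -> bool:
    return codon in _cds.STOP_CODONS
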