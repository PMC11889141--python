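"""Fully-labelled synthetic inputs for every pipeline stage.

The generator emulates a 3+3 replicate salivary-gland RNA-seq study of a
host fly infected with a salivary-gland hypertrophy virus:

* host transcripts with planted Met-initiated ORFs (uniform 150-1800 nt)
  embedded in random UTR, secreted-class transcripts carrying a
  generative signal-peptide N-terminus, plus ~10% short non-coding
  decoys;
* a 108-member viral CDS set in which seven designated ORFs are absent
  from the libraries (zero counts in every sample);
* homology-hit tables whose description strings embed exactly one
  lexicon term matching the true class/family;
* negative-binomial counts whose per-condition means are calibrated to
  the reported class-abundance profile (PBS: secreted 38.8%, Met/Energy
  22.6%, unknown 20.2%; infected: virus 62.1%, unknown 22.8%, secreted
  4.3%), partitioned within class by a symmetric Dirichlet.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import Lexicon, default_lexicon
from .io import (HitTableRow, SeqRecord, write_fasta, write_hit_table,
                 write_metadata)

CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

# one representative codon per amino acid, for reverse-translation
CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

SECRETED_FAMILIES = (
    "Antigen-5", "Apolipoprotein", "Amylase", "Maltase", "Acid phosphatase",
    "Cysteine peptidase", "Serine peptidase", "Lipase", "Lectin", "Lysozyme",
    "Defensin", "Odorant-binding protein", "Kunitz", "Kazal", "Serpin",
    "Unknown",
)

HOST_CLASSES = (
    "secreted", "unknown", "Met/Energy", "transcription machinery",
    "protein synthesis", "signal transduction", "cytoskeletal", "immunity",
)

#: calibration: printed average-TPM shares per class and condition (%)
CLASS_SHARE_TARGETS = {
    "PBS": {"secreted": 38.8, "Met/Energy": 22.6, "unknown": 20.2,
            "virus": 0.0},
    "infected": {"virus": 62.1, "unknown": 22.8, "secreted": 4.3},
}

#: fraction of host coding transcripts per class (transcript counts,
#: independent of the abundance shares above)
CLASS_TRANSCRIPT_FRACTIONS = {
    "secreted": 0.30, "unknown": 0.22, "Met/Energy": 0.14,
    "transcription machinery": 0.08, "protein synthesis": 0.08,
    "signal transduction": 0.06, "cytoskeletal": 0.06, "immunity": 0.06,
}

FILLER_WORDS = ("conserved", "hypothetical", "product", "precursor",
                "isoform", "partial", "putative")


@dataclass
class SimulationConfig:
    seed: int
    n_host_transcripts: int = 300
    n_viral: int = 108
    absent_viral: frozenset[int] = frozenset({6, 7, 8, 9, 26, 60, 61})
    replicates: int = 3
    phi: float = 0.1
    fraction_de: float = 0.1
    planted_lfc: float = 3.0
    decoy_fraction: float = 0.10
    lib_size: int = 300_000
    within_class_alpha: float = 5.0
    conditions: tuple[str, str] = ("PBS", "infected")
    orf_nt_range: tuple[int, int] = (150, 1800)
    utr_nt_range: tuple[int, int] = (30, 300)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.orf_nt_range
        if lo < 150 or hi < lo:
            raise ValueError("infeasible ORF length range")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(cfg.seed), stream))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _signal_peptide_aa(rng: np.random.Generator) -> str:
    """A signal peptide from the generative template: positively charged
    n-region, hydrophobic h-region, A-X-A cleavage site."""
    n_region = "M" + "".join(rng.choice(list("KRNS"), rng.integers(1, 4)))
    h_region = "".join(rng.choice(list("LAVIF"), rng.integers(8, 11)))
    return n_region + h_region + "AQA"


def _reverse_translate(aa: str) -> str:
    return "".join(CODON_OF[ch] for ch in aa)


def _coding_transcript(rng: np.random.Generator, cfg: SimulationConfig,
                       with_sp: bool) -> tuple[str, int, int]:
    """Random transcript with one planted ORF; returns (seq, start, end)
    with the 0-based half-open coding interval including the stop codon."""
    lo, hi = cfg.orf_nt_range
    orf_nt = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
    n_codons = orf_nt // 3 - 1  # minus the stop codon
    if with_sp:
        sp = _signal_peptide_aa(rng)
        head = _reverse_translate(sp)
        n_rest = n_codons - len(sp)
    else:
        head = "ATG"
        n_rest = n_codons - 1
    body = "".join(np.array(SENSE_CODONS)[rng.integers(0, len(SENSE_CODONS), n_rest)])
    stop = STOP_CODONS[rng.integers(0, 3)]
    orf = head + body + stop
    utr_lo, utr_hi = cfg.utr_nt_range
    utr5 = _random_nt(rng, int(rng.integers(utr_lo, utr_hi)))
    utr3 = _random_nt(rng, int(rng.integers(utr_lo, utr_hi)))
    # in-frame stop just upstream keeps the planted ORF maximal and exact
    upstream_stop = STOP_CODONS[rng.integers(0, 3)]
    seq = utr5 + upstream_stop + orf + utr3
    start = len(utr5) + 3
    return seq, start, start + len(orf)


def _decoy_transcript(rng: np.random.Generator) -> str:
    """Short fragment: shorter than any qualifying ORF by construction."""
    return _random_nt(rng, int(rng.integers(100, 150)))


def simulate_transcriptome(cfg: SimulationConfig) -> tuple[
        list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Host transcripts, viral CDS set and the truth table."""
    rng = _rng(cfg, 1)
    n_decoy = int(round(cfg.n_host_transcripts * cfg.decoy_fraction))
    n_coding = cfg.n_host_transcripts - n_decoy

    # class assignment for coding transcripts
    classes: list[str] = []
    for cls, frac in CLASS_TRANSCRIPT_FRACTIONS.items():
        classes.extend([cls] * int(round(frac * n_coding)))
    while len(classes) < n_coding:
        classes.append("unknown")
    classes = classes[:n_coding]
    rng.shuffle(classes)

    transcripts: list[SeqRecord] = []
    rows: list[dict] = []
    for i, cls in enumerate(classes):
        tid = f"HOST_{i + 1:04d}"
        family = None
        if cls == "secreted":
            family = str(rng.choice(SECRETED_FAMILIES))
        has_sp = cls == "secreted"
        seq, start, end = _coding_transcript(rng, cfg, with_sp=has_sp)
        transcripts.append(SeqRecord(tid, seq, kind="nt"))
        rows.append({
            "id": tid, "true_class": cls, "true_family": family,
            "has_sp": has_sp, "coding_start": start, "coding_end": end,
            "strand": "+", "source": "denovo", "viral_orf_index": 0,
            "length_nt": len(seq), "cds_nt": end - start - 3,
        })
    for i in range(n_decoy):
        tid = f"DECOY_{i + 1:04d}"
        seq = _decoy_transcript(rng)
        transcripts.append(SeqRecord(tid, seq, kind="nt"))
        rows.append({
            "id": tid, "true_class": "decoy", "true_family": None,
            "has_sp": False, "coding_start": -1, "coding_end": -1,
            "strand": "+", "source": "denovo", "viral_orf_index": 0,
            "length_nt": len(seq), "cds_nt": 0,
        })

    viral: list[SeqRecord] = []
    for k in range(1, cfg.n_viral + 1):
        vid = f"MdSGHV_ORF_{k:03d}"
        n_codons = int(rng.integers(60, 400))
        body = "".join(np.array(SENSE_CODONS)[rng.integers(0, len(SENSE_CODONS), n_codons)])
        seq = "ATG" + body + STOP_CODONS[rng.integers(0, 3)]
        viral.append(SeqRecord(vid, seq, kind="nt"))
        rows.append({
            "id": vid, "true_class": "virus", "true_family": None,
            "has_sp": False, "coding_start": 0, "coding_end": len(seq),
            "strand": "+", "source": "viral", "viral_orf_index": k,
            "length_nt": len(seq), "cds_nt": len(seq) - 3,
        })

    truth = pd.DataFrame(rows).set_index("id")
    truth = _assign_expression(truth, cfg)
    return transcripts, viral, truth


def _class_share_table(cfg: SimulationConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percent-of-TPM target per class, with the remainder
    spread evenly over the classes the calibration does not pin."""
    present = [c for c in truth["true_class"].unique() if c != "decoy"]
    out = {}
    for cond in cfg.conditions:
        targets = dict(CLASS_SHARE_TARGETS.get(cond, {}))
        pinned = sum(targets.values())
        rest = [c for c in present if c not in targets]
        fill = max(0.0, 100.0 - pinned) / len(rest) if rest else 0.0
        shares = {c: targets.get(c, fill) for c in present}
        out[cond] = shares
    return pd.DataFrame(out).fillna(0.0)


def _assign_expression(truth: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Per-condition true mean TPM per transcript.

    Class totals follow the calibration shares; within a class the total
    is partitioned by a symmetric Dirichlet (alpha = within_class_alpha,
    concentrated enough that no present member falls under the
    detection threshold).  Absent viral ORFs get zero in both
    conditions.
    """
    rng = _rng(cfg, 2)
    shares = _class_share_table(cfg, truth)
    for cond in cfg.conditions:
        tpm = pd.Series(0.0, index=truth.index)
        for cls in shares.index:
            members = truth.index[(truth["true_class"] == cls)]
            if cls == "virus":
                members = [m for m in members
                           if truth.loc[m, "viral_orf_index"] not in cfg.absent_viral]
            members = list(members)
            if not members:
                continue
            total = shares.loc[cls, cond] / 100.0 * 1e6
            if total <= 0:
                continue
            w = rng.dirichlet([cfg.within_class_alpha] * len(members))
            tpm.loc[members] = w * total
        truth[f"mean_tpm_{cond}"] = tpm
    a, b = cfg.conditions
    eps = 0.5
    truth["true_logFC"] = np.log2(
        (truth[f"mean_tpm_{b}"] + eps) / (truth[f"mean_tpm_{a}"] + eps))
    return truth


# ---------------------------------------------------------------------------
# hit tables


def _planting_term(lexicon: Lexicon, cls: str, family: str | None) -> str:
    """A lexicon term that scans back to the wanted class/family."""
    for e in lexicon.entries:
        if e.class_label != cls:
            continue
        if cls == "secreted" and e.family != family:
            continue
        got = lexicon.scan(e.term)
        if got is not None and got.class_label == cls and (
                cls != "secreted" or got.family == family):
            return e.term
    raise ValueError(f"no plantable lexicon term for {cls!r}/{family!r}")


def simulate_hits(truth: pd.DataFrame, cfg: SimulationConfig,
                  lexicon: Lexicon | None = None,
                  db_tag: str = "NR") -> list[HitTableRow]:
    """Homology hits for the host transcripts.

    Classed transcripts receive 1-5 hits whose best (highest-bitscore)
    hit covers >= 75% of its subject so the homology extraction route
    always fires; its description embeds exactly one lexicon term for
    the true class/family.  "unknown"-class transcripts get
    well-covered hits with percent identity 20-30, below the annotation
    acceptance floor.  Secreted/Unknown and decoy transcripts get no
    hits; viral CDS get no host-database hits.
    """
    lexicon = lexicon or default_lexicon()
    rng = _rng(cfg, 3)
    hits: list[HitTableRow] = []
    for tid, row in truth.iterrows():
        cls = row["true_class"]
        if cls in ("decoy", "virus"):
            continue
        if cls == "secreted" and row["true_family"] == "Unknown":
            continue  # no informative homology: SP route + fallback class
        if cls == "unknown" and rng.random() < 0.3:
            continue  # hitless unknowns stay out of the extracted set
        n_hits = int(rng.integers(1, 6))
        if cls == "unknown":
            # term from some housekeeping class: only relevant once the
            # acceptance identity floor is lowered
            term = _planting_term(lexicon, "Met/Energy", None)
            pidents = rng.uniform(20, 30, n_hits)
        else:
            term = _planting_term(lexicon, cls, row["true_family"])
            pidents = rng.uniform(40, 95, n_hits)
        desc = " ".join([
            str(rng.choice(FILLER_WORDS)), term, str(rng.choice(FILLER_WORDS)),
        ])
        start, end = int(row["coding_start"]), int(row["coding_end"])
        aa_len = (end - start - 3) // 3
        covs = rng.uniform(0.55, 1.0, n_hits)
        covs[0] = rng.uniform(0.75, 0.98)
        bitscores = rng.uniform(60, 200, n_hits)
        bitscores[0] = 200 + rng.uniform(0, 100)  # best evidence: covered hit
        for j in range(n_hits):
            slen = max(40, int(aa_len * rng.uniform(0.8, 1.2)))
            span = max(1, int(round(covs[j] * slen)))
            sstart = int(rng.integers(1, slen - span + 2))
            q_span_nt = min(span * 3, end - start - 3)
            qstart = start + 1
            qend = qstart + q_span_nt - 1
            hits.append(HitTableRow(
                query_id=tid,
                subject_id=f"SBJ_{tid}_{j}",
                subject_desc=desc,
                db_tag=db_tag,
                pident=float(round(pidents[j], 1)),
                align_len=span,
                qstart=qstart, qend=qend,
                sstart=sstart, send=sstart + span - 1,
                evalue=float(10 ** -rng.uniform(10, 80)),
                bitscore=float(round(bitscores[j], 1)),
                qlen=int(row["length_nt"]),
                slen=slen,
            ))
    return hits


# ---------------------------------------------------------------------------
# counts


def simulate_counts(truth: pd.DataFrame, cfg: SimulationConfig) -> tuple[
        pd.DataFrame, dict[str, str]]:
    """NB-distributed counts for every coding transcript and viral ORF.

    The expected count of transcript i in condition c is proportional to
    true_tpm_i * length_i (so that TPM recomputed from the counts matches
    the planted shares in expectation), scaled to the library size.
    Returns the counts DataFrame (with an eff_length column) and the
    sample->condition map.
    """
    rng = _rng(cfg, 4)
    expressed = truth[truth["true_class"] != "decoy"]
    ids = list(expressed.index)
    lengths = expressed["cds_nt"].to_numpy(dtype=float)

    samples: dict[str, str] = {}
    data: dict[str, np.ndarray] = {}
    for cond in cfg.conditions:
        w = expressed[f"mean_tpm_{cond}"].to_numpy(dtype=float)
        mass = w * lengths
        frac = mass / mass.sum() if mass.sum() > 0 else mass
        for r in range(1, cfg.replicates + 1):
            name = f"{cond}_{r}"
            samples[name] = cond
            lib = cfg.lib_size * rng.uniform(0.85, 1.15)
            mu = frac * lib
            if cfg.phi <= 0:
                counts = rng.poisson(mu)
            else:
                rr = 1.0 / cfg.phi
                counts = np.where(
                    mu > 0,
                    rng.negative_binomial(rr, rr / (rr + np.maximum(mu, 1e-12))),
                    0,
                )
            data[name] = counts.astype(np.int64)
    df = pd.DataFrame(data, index=ids)
    df.insert(0, "eff_length", lengths)
    return df, samples


def simulate_de_matrix(
    n_genes: int = 2000,
    n_per_group: int = 3,
    phi: float = 0.1,
    fraction_de: float = 0.1,
    lfc: float = 3.0,
    seed: int = 0,
    mean_range: tuple[float, float] = (20.0, 2000.0),
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """A controlled two-group NB count matrix with planted fold changes.

    Baseline means are log-uniform over ``mean_range``; a ``fraction_de``
    subset gets its group-B mean scaled by 2**(+/-lfc), directions
    alternating.  Returns counts, the sample->group map and a truth
    frame with ``is_de`` and ``direction``.
    """
    rng = np.random.default_rng((int(seed), 5))
    base = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_genes))
    n_de = int(round(fraction_de * n_genes))
    de_idx = rng.choice(n_genes, n_de, replace=False)
    direction = np.zeros(n_genes)
    direction[de_idx] = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    mean_a = base
    mean_b = base * 2.0 ** (direction * lfc)

    groups: dict[str, str] = {}
    data: dict[str, np.ndarray] = {}
    for grp, means in (("A", mean_a), ("B", mean_b)):
        for r in range(1, n_per_group + 1):
            name = f"{grp}_{r}"
            groups[name] = grp
            if phi <= 0:
                counts = rng.poisson(means)
            else:
                rr = 1.0 / phi
                counts = rng.negative_binomial(rr, rr / (rr + means))
            data[name] = counts.astype(np.int64)
    ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(data, index=ids)
    truth = pd.DataFrame(
        {"is_de": direction != 0, "direction": direction,
         "mean_A": mean_a, "mean_B": mean_b},
        index=ids,
    )
    return counts_df, groups, truth


# ---------------------------------------------------------------------------
# file emission


def write_simulation(cfg: SimulationConfig, out_dir: str | Path,
                     lexicon: Lexicon | None = None) -> dict[str, Path]:
    """Run the full generator and write all pipeline input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts, viral, truth = simulate_transcriptome(cfg)
    hits = simulate_hits(truth, cfg, lexicon)
    counts, samples = simulate_counts(truth, cfg)

    paths = {
        "transcripts": out / "transcripts.fasta",
        "viral": out / "viral.fasta",
        "hits": out / "hits_NR.tsv",
        "counts": out / "counts.tsv",
        "meta": out / "meta.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(transcripts, paths["transcripts"])
    write_fasta(viral, paths["viral"])
    write_hit_table(hits, paths["hits"])
    counts.to_csv(paths["counts"], sep="\t", index_label="transcript_id")
    write_metadata(samples, paths["meta"])
    truth.to_csv(paths["truth"], sep="\t")
    return paths
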