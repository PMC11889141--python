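"""Rule-based signal-peptide prediction.

A classical secretion signal has three parts: a short, positively charged
n-region, a hydrophobic h-region, and a c-region ending in a cleavage site
that follows the von Heijne (-3, -1) small-residue rule.  The caller here
tests those three properties directly:

1. net charge of the first five residues is non-negative,
2. an h-region exists: an 8-residue window within residues 3-20
   (1-based) with mean Kyte-Doolittle hydropathy >= 2.0 and no charged
   residue (h-regions are uninterrupted hydrophobic stretches; a looser
   mean-only rule misfires on any realistic background composition),
3. a cleavage position exists in the aa-offset range [12, 35) whose -1
   residue is small (A, G, S, C, T) and whose -3 residue is neither
   charged nor aromatic.

Window size and hydropathy threshold are module constants a caller may
override.

It is a transparent, deterministic stand-in for an external neural-network
predictor; external calls can be substituted via
:func:`parse_external_sp_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

# Kyte & Doolittle hydropathy index
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}
SMALL_RESIDUES = set("AGSCT")
CHARGED_OR_AROMATIC = set("KRDEFWY")

HYDROPATHY_THRESHOLD = 2.0
HYDROPATHY_WINDOW = 8
CLEAVAGE_RANGE = (12, 35)  # 0-based aa offsets, half-open
MIN_CALL_LEN = 15


@dataclass
class SignalPrediction:
    query_id: str
    has_sp: bool
    cleavage_pos: int | None  # 0-based offset of the -1 residue; cleavage after it
    n_charge: int = 0
    max_h_window: float = float("-inf")
    site_ok: bool = False
    too_short: bool = False


def _net_charge(seq: str) -> int:
    return sum(CHARGE.get(aa, 0) for aa in seq)


def _max_hydropathy_window(seq: str, lo: int = 2, hi: int = 20,
                           window: int = HYDROPATHY_WINDOW) -> float:
    """Max mean hydropathy over charge-free windows inside seq[lo:hi].

    Windows containing a charged residue (D, E, K, R) do not qualify as
    an h-region and score -inf.
    """
    region = seq[lo:hi]
    if len(region) < window:
        return float("-inf")
    best = float("-inf")
    for i in range(len(region) - window + 1):
        chunk = region[i : i + window]
        if any(aa in CHARGE for aa in chunk):
            continue
        mean = sum(KD.get(aa, 0.0) for aa in chunk) / window
        best = max(best, mean)
    return best


def _find_cleavage(seq: str) -> int | None:
    lo, hi = CLEAVAGE_RANGE
    for p in range(lo, min(hi, len(seq) - 1)):
        if seq[p] in SMALL_RESIDUES and seq[p - 2] not in CHARGED_OR_AROMATIC:
            return p
    return None


def predict_signal_peptide(aa_seq: str, query_id: str = "") -> SignalPrediction:
    """Call a signal peptide on a Met-initiated amino-acid sequence.

    Positive iff all three rules (charge, hydrophobic core, cleavage
    site) hold.  Sequences shorter than 15 aa are called negative and
    flagged ``too_short``.
    """
    aa_seq = aa_seq.upper()
    if len(aa_seq) < MIN_CALL_LEN:
        return SignalPrediction(query_id, False, None, too_short=True)
    n_charge = _net_charge(aa_seq[:5])
    max_h = _max_hydropathy_window(aa_seq)
    cleavage = _find_cleavage(aa_seq)
    site_ok = cleavage is not None
    has_sp = n_charge >= 0 and max_h >= HYDROPATHY_THRESHOLD and site_ok
    return SignalPrediction(
        query_id=query_id,
        has_sp=has_sp,
        cleavage_pos=cleavage if has_sp else None,
        n_charge=n_charge,
        max_h_window=max_h,
        site_ok=site_ok,
    )


def parse_external_sp_table(path: str | Path) -> list[SignalPrediction]:
    """Import predictions from an external tool.

    TSV columns: id, decision (Y/N), cleavage position as a 1-based
    between-residue index (the position of the first residue of the
    mature protein); '-' when negative.  Converted to the internal
    0-based -1-residue offset.
    """
    preds: list[SignalPrediction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 3 columns")
            qid, decision, pos = fields
            if decision == "Y":
                preds.append(SignalPrediction(qid, True, int(pos) - 1))
            elif decision == "N":
                preds.append(SignalPrediction(qid, False, None))
            else:
                raise ValueError(
                    f"line {lineno}: unknown decision token {decision!r}"
                )
    return preds
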