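"""TPM quantification, the expression filter and z-score summaries.

Counts and per-transcript effective lengths come in as a pandas DataFrame
(rows = transcripts, columns = samples, plus an ``eff_length`` column);
sample-to-condition assignment is a plain mapping.  TPM per sample is the
length-normalised read rate rescaled to sum to one million.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Per-sample TPM with per-condition means."""

    tpm: pd.DataFrame  # transcripts x samples
    condition_means: pd.DataFrame  # transcripts x conditions
    sample_condition: dict[str, str]


@dataclass
class PresencePartition:
    """Split of transcripts by the TPM detection threshold (two conditions)."""

    both: set[str]
    only_a: set[str]
    only_b: set[str]
    dropped: set[str]
    condition_a: str
    condition_b: str

    @property
    def retained(self) -> set[str]:
        return self.both | self.only_a | self.only_b

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            f"only_{self.condition_a}": len(self.only_a),
            f"only_{self.condition_b}": len(self.only_b),
            "dropped": len(self.dropped),
        }


def split_counts(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Separate the sample columns from the eff_length column."""
    if "eff_length" not in df.columns:
        raise ValueError("count matrix must carry an 'eff_length' column")
    eff_length = df["eff_length"].astype(float)
    counts = df.drop(columns=["eff_length"]).astype(float)
    return counts, eff_length


def compute_tpm(df: pd.DataFrame, sample_condition: dict[str, str]) -> ExpressionTable:
    """Transcripts-per-million from counts and effective lengths.

    Per sample: rate_i = count_i / eff_length_i, TPM_i = 1e6 * rate_i /
    sum(rate).  An all-zero sample yields an all-zero column with a
    warning.
    """
    counts, eff_length = split_counts(df)
    if (eff_length <= 0).any():
        bad = eff_length.index[eff_length <= 0][0]
        raise ValueError(f"non-positive effective length for {bad!r}")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    missing = set(counts.columns) - set(sample_condition)
    if missing:
        raise ValueError(f"samples without condition label: {sorted(missing)}")

    rates = counts.div(eff_length, axis=0)
    totals = rates.sum(axis=0)
    zero_samples = totals[totals == 0].index
    for s in zero_samples:
        logger.warning("sample %r has no reads; TPM column left at zero", s)
    safe_totals = totals.replace(0, np.nan)
    tpm = rates.div(safe_totals, axis=1).fillna(0.0) * 1e6

    conditions = sorted(set(sample_condition[s] for s in counts.columns))
    cond_means = pd.DataFrame(index=tpm.index)
    for cond in conditions:
        cols = [s for s in counts.columns if sample_condition[s] == cond]
        cond_means[cond] = tpm[cols].mean(axis=1)
    return ExpressionTable(tpm=tpm, condition_means=cond_means,
                           sample_condition=dict(sample_condition))


def presence_partition(expr: ExpressionTable, tpm_min: float = 3.0) -> PresencePartition:
    """Partition transcripts by detection (condition mean TPM >= tpm_min).

    Requires exactly two conditions; returns the detected-in-both,
    A-only, B-only and dropped sets.
    """
    conds = list(expr.condition_means.columns)
    if len(conds) != 2:
        raise ValueError(f"presence partition needs exactly 2 conditions, got {conds}")
    a, b = conds
    in_a = expr.condition_means[a] >= tpm_min
    in_b = expr.condition_means[b] >= tpm_min
    idx = expr.condition_means.index
    return PresencePartition(
        both=set(idx[in_a & in_b]),
        only_a=set(idx[in_a & ~in_b]),
        only_b=set(idx[~in_a & in_b]),
        dropped=set(idx[~in_a & ~in_b]),
        condition_a=a,
        condition_b=b,
    )


def zscore_matrix(tpm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores of a TPM matrix (sample sd, ddof=1).

    Constant rows map to all-zero rows; used as heatmap input.
    """
    if tpm.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    means = tpm.mean(axis=1)
    sds = tpm.std(axis=1, ddof=1)
    safe = sds.replace(0, np.nan)
    z = tpm.sub(means, axis=0).div(safe, axis=0)
    return z.fillna(0.0)
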