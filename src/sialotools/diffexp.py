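"""Two-group negative-binomial exact-test differential expression.

The model: counts for gene g in sample s of group k are NB(mu_gk, phi)
with a single common dispersion phi shared across genes.  Because a sum
of n iid NB(mu, phi) variables is NB(n mu, phi/n), the two group totals
(after scaling all samples to a common library size) are NB with means
proportional to the group sizes under the null; conditioning on the
grand total yields an exact two-sided test by summing the probabilities
of every split as or less likely than the observed one.  phi = 0
degenerates to the Poisson limit, where the conditional law of the
reference-group total is Binomial(s, n_ref/n_total).

The common dispersion is estimated by maximising the conditional
(given the per-group totals) log-likelihood summed over genes, the
classical qCML approach.  Multiplicity is handled with the
Benjamini-Hochberg step-up; calls use |log2 fold change| and FDR
thresholds.  "Up" means up in the reference group (logFC is
log2(other/reference)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

_PHI_LO, _PHI_HI = 1e-6, 10.0


@dataclass
class DispersionEstimate:
    phi_common: float
    method: str = "qCML-grid-golden"


# ---------------------------------------------------------------------------
# library-size normalisation


def normalize_library_sizes(counts: pd.DataFrame, method: str = "libsize") -> pd.Series:
    """Per-sample effective library sizes.

    ``libsize``: column sums.  ``tmm``: column sums times trimmed-mean-
    of-M-values factors (30% M-trim, 5% A-trim, factors centred to a
    geometric mean of one).
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs == 0).any():
        bad = libs.index[libs == 0][0]
        raise ValueError(f"sample {bad!r} has no reads")
    if method == "libsize":
        return libs
    if method != "tmm":
        raise ValueError(f"unknown normalisation method {method!r}")

    y = counts.to_numpy(dtype=float)
    n = libs.to_numpy()
    # reference: sample whose upper-quartile CPM is closest to the mean
    uq = np.array([np.quantile(y[:, j][y[:, j] > 0] / n[j], 0.75)
                   if (y[:, j] > 0).any() else 0.0 for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_factor(y[:, j], n[j], y[:, ref], n[ref])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(libs.to_numpy() * factors, index=counts.columns)


def _tmm_factor(obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
                logratio_trim: float = 0.30, sum_trim: float = 0.05) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + \
        (n_ref - ref[keep]) / (n_ref * ref[keep])
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n_kept = m.size
    lo_m, hi_m = np.floor(n_kept * logratio_trim) + 1, n_kept + 1 - (np.floor(n_kept * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n_kept * sum_trim) + 1, n_kept + 1 - (np.floor(n_kept * sum_trim) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** f)


# ---------------------------------------------------------------------------
# dispersion estimation


def _equalize(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Scale every column to the geometric-mean library size."""
    target = np.exp(np.mean(np.log(lib_sizes)))
    return counts * (target / lib_sizes)[None, :]


def _group_cond_loglik(y: np.ndarray, phi: float) -> float:
    """Conditional NB log-likelihood of one group's genes x replicates,
    conditioning each gene on its group total (equal library sizes)."""
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (gammaln(y + r).sum(axis=1) - n * gammaln(r)
          + gammaln(n * r) - gammaln(z + n * r))
    return float(ll.sum())


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    lib_sizes: pd.Series | None = None,
) -> DispersionEstimate:
    """Common dispersion by maximising the summed conditional NB
    log-likelihood over a log-scale phi grid refined by golden section.

    Counts are first scaled to equal library sizes.  All-zero matrices
    are an error; a matrix with no overdispersion signal returns the
    lower bound (1e-6, i.e. effectively Poisson).
    """
    groups = pd.Series(dict(groups) if isinstance(groups, dict) else groups)
    labels = sorted(set(groups[counts.columns]))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    y = counts.to_numpy(dtype=float)
    if not (y > 0).any():
        raise ValueError("all-zero count matrix")
    libs = (lib_sizes if lib_sizes is not None else counts.sum(axis=0)).to_numpy(dtype=float)
    y = _equalize(y, libs)

    group_blocks = []
    for lab in labels:
        cols = [i for i, s in enumerate(counts.columns) if groups[s] == lab]
        block = y[:, cols]
        block = block[block.sum(axis=1) > 0]  # genes with no counts carry no signal
        if block.shape[1] >= 2 and block.size:
            group_blocks.append(block)
    if not group_blocks:
        raise ValueError("no group with >= 2 replicates")

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_group_cond_loglik(b, phi) for b in group_blocks)

    grid = np.log(np.logspace(np.log10(_PHI_LO), np.log10(_PHI_HI), 31))
    vals = np.array([neg_ll(g) for g in grid])
    k = int(np.argmin(vals))
    if k == 0:
        return DispersionEstimate(_PHI_LO)
    if k == len(grid) - 1:
        return DispersionEstimate(_PHI_HI)
    res = optimize.minimize_scalar(neg_ll, bracket=(grid[k - 1], grid[k], grid[k + 1]),
                                   method="golden", options={"xtol": 1e-6})
    return DispersionEstimate(float(np.exp(res.x)))


# ---------------------------------------------------------------------------
# the exact test


def _exact_pvalue(a: int, s: int, n_ref: int, n_other: int, phi: float) -> float:
    """Two-sided exact p for observing reference-group total ``a`` of ``s``.

    Sums P(x) over every split x with P(x) <= P(a) (probability-mass
    rule), normalised by the total over all splits.
    """
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    frac_ref = n_ref / (n_ref + n_other)
    if phi <= 0:
        logf = stats.binom.logpmf(x, s, frac_ref)
    else:
        mu_a = s * frac_ref
        mu_b = s - mu_a
        # total of n iid NB(mu, phi) is NB(n*mu, phi/n)
        r_a, r_b = n_ref / phi, n_other / phi
        logf = (stats.nbinom.logpmf(x, r_a, r_a / (r_a + mu_a))
                + stats.nbinom.logpmf(s - x, r_b, r_b / (r_b + mu_b)))
    logf -= logf.max()
    f = np.exp(logf)
    obs = f[a]
    return float(f[f <= obs * (1 + 1e-12)].sum() / f.sum())


def exact_test_nb(
    counts: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    phi: float,
    lib_sizes: pd.Series | None = None,
    reference: str | None = None,
    pseudo_count: float = 0.125,
) -> pd.DataFrame:
    """Per-gene exact-test p-values and log2 fold changes.

    Samples are scaled to the geometric-mean library size, summed within
    groups and rounded; the split of the grand total is tested against
    its conditional null.  ``logFC = log2((other/n_other + c) /
    (ref/n_ref + c))`` with pseudo-count c (p-values never use it).
    """
    groups = pd.Series(dict(groups) if isinstance(groups, dict) else groups)
    labels = sorted(set(groups[counts.columns]))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    ref = reference if reference is not None else labels[0]
    if ref not in labels:
        raise ValueError(f"reference {ref!r} not among groups {labels}")
    other = next(l for l in labels if l != ref)

    y = counts.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    libs = (lib_sizes if lib_sizes is not None else counts.sum(axis=0)).to_numpy(dtype=float)
    y_eq = _equalize(y, libs)
    ref_cols = [i for i, s in enumerate(counts.columns) if groups[s] == ref]
    oth_cols = [i for i, s in enumerate(counts.columns) if groups[s] == other]
    a = np.rint(y_eq[:, ref_cols].sum(axis=1)).astype(np.int64)
    b = np.rint(y_eq[:, oth_cols].sum(axis=1)).astype(np.int64)
    n_ref, n_oth = len(ref_cols), len(oth_cols)

    pvals = np.ones(len(a))
    cache: dict[tuple[int, int], float] = {}
    for i, (ai, bi) in enumerate(zip(a, b)):
        key = (int(ai), int(ai + bi))
        if key not in cache:
            cache[key] = _exact_pvalue(int(ai), int(ai + bi), n_ref, n_oth, phi)
        pvals[i] = cache[key]

    c = pseudo_count
    logfc = np.where(
        a + b == 0, 0.0,
        np.log2((b / n_oth + c) / (a / n_ref + c)),
    )
    return pd.DataFrame(
        {"logFC": logfc, "pvalue": pvals}, index=counts.index
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(
    results: pd.DataFrame,
    lfc_thresh: float = 2.0,
    fdr_thresh: float = 0.05,
) -> pd.DataFrame:
    """Assign up/down/ns status and append the modulation census.

    With the reference group as baseline, "up" means up-regulated in the
    reference (logFC <= -lfc_thresh), "down" down-regulated in the
    reference (logFC >= +lfc_thresh), both at FDR < fdr_thresh.
    The census is stored in ``result.attrs['census']``.
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    sig = out["fdr"] < fdr_thresh
    out["status"] = "ns"
    out.loc[sig & (out["logFC"] <= -lfc_thresh), "status"] = "up"
    out.loc[sig & (out["logFC"] >= lfc_thresh), "status"] = "down"
    census = {
        "n_up": int((out["status"] == "up").sum()),
        "n_down": int((out["status"] == "down").sum()),
    }
    census["n_total_modulated"] = census["n_up"] + census["n_down"]
    out.attrs["census"] = census
    return out


def de_pipeline(
    counts: pd.DataFrame,
    groups: dict[str, str],
    reference: str,
    lfc_thresh: float = 2.0,
    fdr_thresh: float = 0.05,
    norm: str = "libsize",
) -> pd.DataFrame:
    """Dispersion estimation, exact test, BH adjustment and calls."""
    libs = normalize_library_sizes(counts, norm)
    phi = estimate_common_dispersion(counts, groups, libs).phi_common
    res = exact_test_nb(counts, groups, phi, libs, reference)
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res = call_de(res, lfc_thresh, fdr_thresh)
    res.attrs["phi_common"] = phi
    return res


# ---------------------------------------------------------------------------
# multidimensional scaling


def mds_coordinates(
    counts: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
    top_n: int = 500,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS of pairwise expression distances.

    The distance between two samples is the root-mean-square of the
    ``top_n`` largest absolute log2 fold changes of their log-CPM
    profiles (pseudo-count 2), the standard "leading log-fold-change"
    distance for bulk RNA-seq sample overviews.  Returns 2-D
    coordinates and per-axis variance shares.
    """
    if counts.shape[1] < 3:
        raise ValueError("MDS needs at least 3 samples")
    libs = (lib_sizes if lib_sizes is not None else counts.sum(axis=0)).to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    logcpm = np.log2((y + 2.0) / libs[None, :] * 1e6)
    ns = counts.shape[1]
    d = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1, ns):
            diff = np.abs(logcpm[:, i] - logcpm[:, j])
            k = min(top_n, diff.size)
            top = np.partition(diff, diff.size - k)[diff.size - k:]
            d[i, j] = d[j, i] = np.sqrt(np.mean(top ** 2))
    # double-centred Gram matrix
    j_mat = np.eye(ns) - np.ones((ns, ns)) / ns
    b = -0.5 * j_mat @ (d ** 2) @ j_mat
    evals, evecs = np.linalg.eigh(b)
    idx = np.argsort(evals)[::-1]
    evals, evecs = evals[idx], evecs[:, idx]
    pos = np.clip(evals, 0, None)
    coords = evecs[:, :2] * np.sqrt(pos[:2])[None, :]
    total = pos.sum()
    shares = pos[:2] / total if total > 0 else np.zeros(2)
    return (pd.DataFrame(coords, index=counts.columns, columns=["dim1", "dim2"]),
            shares)
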