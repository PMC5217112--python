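"""Restricted-reference trimmed-mean normalization and gene filters.

Library scale factors are estimated by a weighted trimmed mean of per-gene
log expression ratios (M values) against a reference sample — the classic
composition-robust TMM estimator — but computed **only over a restricted
reference gene set**: nuclear-encoded ORFs excluding any chromosome that is
disomic in the experiment.  The factor estimated on that set is then applied
to all genes.  Restricting the estimator keeps the doubled transcriptional
output of a disomic chromosome from masquerading as extra sequencing depth.

For tests of genes *on* a disomic chromosome, independent of the direct
copy-number effect, a variant result doubles the disomic samples' scale
factor ("doubled-factor" normalization): under pure dosage, genes on the
doubled chromosome then show no residual fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import KaryodiffError, NormalizationError
from .io import CountMatrix


@dataclass
class NormalizationResult:
    """Per-sample scale factors and effective library sizes.

    ``samples`` has columns ``scale_factor``, ``library_size`` (total counts
    over the reference gene set), ``doubling`` (1 or 2) and
    ``effective_library_size`` = library_size x scale_factor x doubling.
    ``reference_gene_mask`` flags the genes the estimator used.
    """

    samples: pd.DataFrame
    reference_gene_mask: pd.Series
    reference_sample: str

    @property
    def scale_factors(self) -> pd.Series:
        return self.samples["scale_factor"]

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.samples["effective_library_size"]

    @property
    def doubling(self) -> pd.Series:
        return self.samples["doubling"]


def _sample_m_a_weights(y_s, y_r, n_s, n_r):
    """M (log ratio), A (log abundance) and inverse asymptotic-variance
    weights for one sample against the reference, positive counts only."""
    keep = (y_s > 0) & (y_r > 0)
    y_s = y_s[keep].astype(float)
    y_r = y_r[keep].astype(float)
    p_s = y_s / n_s
    p_r = y_r / n_r
    m = np.log2(p_s / p_r)
    a = 0.5 * np.log2(p_s * p_r)
    with np.errstate(divide="ignore"):
        w = 1.0 / ((n_s - y_s) / (n_s * y_s) + (n_r - y_r) / (n_r * y_r))
    # a gene carrying a whole library has zero binomial variance; cap it
    if np.isinf(w).any():
        finite = w[np.isfinite(w)]
        cap = 10.0 * finite.max() if finite.size else 1.0
        w = np.where(np.isfinite(w), w, cap)
    return m, a, w


def _tmm_one(y_s, y_r, n_s, n_r, m_trim=0.30, a_trim=0.05) -> float:
    """Weighted trimmed mean of M values for one sample (log2 factor)."""
    m, a, w = _sample_m_a_weights(y_s, y_r, n_s, n_r)
    if m.size == 0:
        return 0.0
    if np.allclose(m, m[0]) and np.allclose(a, a[0]):
        return float(m[0])
    n = m.size
    lo_m = np.floor(n * m_trim) + 1
    lo_a = np.floor(n * a_trim) + 1
    # ranks are 1-based; keep genes inside both trims
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (
        (rank_m >= lo_m)
        & (rank_m <= n + 1 - lo_m)
        & (rank_a >= lo_a)
        & (rank_a <= n + 1 - lo_a)
    )
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(
    counts: CountMatrix,
    reference_mask: pd.Series,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean scale factors estimated on a restricted gene set.

    Parameters
    ----------
    counts
        The experiment's count matrix (all genes).
    reference_mask
        Boolean flag per gene; only flagged genes enter the estimator.
        Typically: nuclear ORFs not on any disomic chromosome.

    The reference sample is the one whose masked-gene upper quartile of
    relative abundance is closest to the across-sample mean upper quartile.
    Factors are rescaled so their geometric mean over samples is 1.
    """
    mask = reference_mask.reindex(counts.gene_ids, fill_value=False).astype(bool)
    if not mask.any():
        raise NormalizationError("reference gene mask is empty")
    sub = counts.counts.loc[mask.to_numpy()]
    libsize = sub.sum(axis=0).astype(float)
    if (counts.counts.sum(axis=0) == 0).any():
        dead = counts.counts.columns[counts.counts.sum(axis=0) == 0][0]
        raise NormalizationError(f"sample {dead!r} has no counts")
    if (libsize == 0).any():
        dead = libsize.index[libsize == 0][0]
        raise NormalizationError(
            f"sample {dead!r} has no counts over the reference gene set"
        )
    if counts.counts.shape[1] < 2:
        raise NormalizationError("need at least 2 samples to normalize")

    rel = sub.to_numpy(dtype=float) / libsize.to_numpy()
    uq = np.quantile(rel, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref_sample = str(counts.sample_ids[ref_j])

    y_r = sub.iloc[:, ref_j].to_numpy()
    n_r = float(libsize.iloc[ref_j])
    log2f = np.zeros(len(libsize))
    for j in range(sub.shape[1]):
        if j == ref_j:
            continue
        log2f[j] = _tmm_one(
            sub.iloc[:, j].to_numpy(), y_r, float(libsize.iloc[j]), n_r, m_trim, a_trim
        )
    factors = np.exp2(log2f)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1

    samples = pd.DataFrame(
        {
            "scale_factor": factors,
            "library_size": libsize,
            "doubling": 1.0,
        },
        index=counts.sample_ids,
    )
    samples["effective_library_size"] = (
        samples["library_size"] * samples["scale_factor"] * samples["doubling"]
    )
    return NormalizationResult(samples, mask, ref_sample)


def doubled_factor_variant(
    norm: NormalizationResult,
    disomic_samples: Sequence[str],
    restricted_mask: pd.Series | None = None,
) -> NormalizationResult:
    """Normalization variant for testing genes on a disomic chromosome.

    Doubles the effective library size of each disomic sample: twice the
    factor estimated on the euploid-chromosome reference set.  Under pure
    dosage this makes the disomic chromosome's genes test as unchanged, so
    any residual fold change is expression change beyond copy number.

    ``restricted_mask``, when given, must equal the mask the input
    normalization was computed on (the estimator must not have seen the
    disomic chromosomes).
    """
    if restricted_mask is not None:
        rm = restricted_mask.reindex(norm.reference_gene_mask.index, fill_value=False)
        if not rm.astype(bool).equals(norm.reference_gene_mask.astype(bool)):
            raise NormalizationError(
                "doubled-factor variant requires factors estimated on the "
                "restricted (euploid-chromosome) mask"
            )
    missing = [s for s in disomic_samples if s not in norm.samples.index]
    if missing:
        raise KaryodiffError(f"unknown disomic samples: {missing}")
    samples = norm.samples.copy()
    samples["doubling"] = 1.0
    samples.loc[list(disomic_samples), "doubling"] = 2.0
    samples["effective_library_size"] = (
        samples["library_size"] * samples["scale_factor"] * samples["doubling"]
    )
    return NormalizationResult(
        samples, norm.reference_gene_mask.copy(), norm.reference_sample
    )


def moderated_log_cpm(
    counts: CountMatrix, norm: NormalizationResult, prior: float = 2.0
) -> pd.DataFrame:
    """log2 counts per million with a pseudo-count.

    ``log2((count + prior) / effective_library_size * 1e6)``; the +2 prior
    stabilises the log for weakly expressed genes.
    """
    if prior <= 0:
        raise KaryodiffError("moderated log-CPM requires a positive prior count")
    eff = norm.effective_library_sizes.reindex(counts.sample_ids)
    if (eff <= 0).any():
        raise NormalizationError("effective library sizes must be positive")
    vals = (counts.counts.to_numpy(dtype=float) + prior) / eff.to_numpy() * 1e6
    return pd.DataFrame(
        np.log2(vals), index=counts.gene_ids, columns=counts.sample_ids
    )


def cpm(counts: CountMatrix, norm: NormalizationResult | None = None) -> pd.DataFrame:
    """Unmoderated counts per million (effective sizes when ``norm`` given,
    raw column totals otherwise)."""
    if norm is not None:
        size = norm.effective_library_sizes.reindex(counts.sample_ids).to_numpy()
    else:
        size = counts.counts.sum(axis=0).to_numpy(dtype=float)
    return counts.counts / size * 1e6


def basal_expression_filter(
    counts: CountMatrix,
    reference_samples: Sequence[str],
    min_cpm: float = 1.0,
    norm: NormalizationResult | None = None,
) -> pd.Series:
    """Keep genes whose median CPM across the reference-genotype samples is
    at least ``min_cpm`` (boundary inclusive).  Unmoderated CPM is used so a
    gene must genuinely be expressed in the baseline strain."""
    if len(reference_samples) == 0:
        raise KaryodiffError("basal filter needs at least one reference sample")
    table = cpm(counts, norm)[list(reference_samples)]
    return table.median(axis=1) >= min_cpm


def variance_filter(
    logcpm: pd.DataFrame,
    genotype_grouping: pd.Series,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Per-genotype replicate-variance masks (True = keep).

    A gene is dropped from any analysis using a genotype when the sample
    variance (n-1 denominator) of its moderated log2 CPM across that
    genotype's replicates is >= ``threshold``.  Technically noisy genes —
    paralog cross-mapping, low-complexity regions — show exactly this
    replicate instability.  Genotypes with a single replicate keep every
    gene (variance undefined) with a warning.
    """
    groups = genotype_grouping.reindex(logcpm.columns)
    out = {}
    for genotype, cols in groups.groupby(groups).groups.items():
        block = logcpm[list(cols)]
        if block.shape[1] < 2:
            warnings.warn(
                f"genotype {genotype!r} has a single replicate; "
                "variance filter keeps all genes",
                stacklevel=2,
            )
            out[genotype] = pd.Series(True, index=logcpm.index)
        else:
            out[genotype] = block.var(axis=1, ddof=1) < threshold
    return pd.DataFrame(out)
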