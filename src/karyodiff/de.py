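"""Negative-binomial GLM differential expression.

Counts are modelled as NB(mu, phi) with variance ``mu + phi * mu**2`` and a
log link, one coefficient per genotype (cell-means coding) plus a per-sample
offset equal to the log effective library size.  The stages mirror standard
count-model practice:

1. per-gene dispersion by profile-likelihood maximisation;
2. a locally weighted (lowess) dispersion-abundance trend;
3. trend-anchored empirical-Bayes shrinkage of the per-gene estimates;
4. a GLM fit per gene (vectorised IRLS across genes);
5. likelihood-ratio tests of arbitrary weighted genotype contrasts via a
   constrained refit in the contrast's null space, chi-square with 1 df;
6. Benjamini-Hochberg FDR over the tested genes.

Fold changes can be copy-number adjusted: subtracting the log2 chromosome
copy ratio isolates expression change beyond the direct dosage effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import (
    AdjustmentError,
    ContrastError,
    DesignError,
    DispersionError,
)
from .io import CountMatrix, GeneAnnotation, Karyotype
from .normalize import NormalizationResult, moderated_log_cpm

LN2 = np.log(2.0)

# dispersion grid spans Poisson-like to wildly overdispersed
_PHI_GRID = np.concatenate(([1e-8], np.logspace(-4, 1, 16)))
# prior weight of the dispersion trend; with few residual df the per-gene
# estimates are noisy and light shrinkage leaves the LRT anticonservative
_PRIOR_DF = 30.0


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def genotype_design(sample_meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cell-means design matrix: one indicator column per genotype."""
    genotypes = list(pd.unique(sample_meta["genotype"]))
    X = np.zeros((len(sample_meta), len(genotypes)))
    for j, g in enumerate(genotypes):
        X[(sample_meta["genotype"] == g).to_numpy(), j] = 1.0
    return X, genotypes


# ---------------------------------------------------------------------------
# vectorised IRLS
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; phi -> 0 is Poisson."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    out = np.where(
        phi > 1e-10,
        special.gammaln(y + 1.0 / np.maximum(phi, 1e-10))
        - special.gammaln(1.0 / np.maximum(phi, 1e-10))
        - special.gammaln(y + 1.0)
        + y * np.log(phi * mu / (1.0 + phi * mu))
        - (1.0 / np.maximum(phi, 1e-10)) * np.log1p(phi * mu),
        y * np.log(mu) - mu - special.gammaln(y + 1.0),
    )
    return out.sum(axis=1)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB unit deviance summed per gene (Poisson limit at phi=0)."""
    mu = np.maximum(mu, 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = np.where(
            phi > 1e-10,
            (y + 1.0 / np.maximum(phi, 1e-10))
            * np.log((1.0 + phi * mu) / (1.0 + phi * np.maximum(y, 0.0))),
            mu - y,
        )
    return 2.0 * (term1 + term2).sum(axis=1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB log-link GLMs for all genes at once.

    Parameters
    ----------
    y : (G, S) counts;  X : (S, p) design;  offsets : (S,) or (G, S) log
    effective library sizes;  phi : (G,) dispersions.

    Returns (beta (G, p), mu (G, S), converged (G,)).
    """
    G, S = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("design matrix is not full rank")
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), (G, S))
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(G, float(phi))

    if beta0 is None:
        # start from offset-adjusted group means pushed through the design
        adj = (y + 0.5) / np.exp(offsets)
        eta0 = np.log(adj)
        beta = np.linalg.lstsq(X, eta0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()

    converged = np.zeros(G, dtype=bool)
    dev = np.full(G, np.inf)
    for _ in range(max_iter):
        eta = beta @ X.T + offsets
        mu = np.exp(np.clip(eta, -700, 700))
        mu = np.maximum(mu, 1e-10)
        w = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offsets) + (y - mu) / mu
        # batched weighted least squares: solve (X^T W X) b = X^T W z
        XtWX = np.einsum("si,gs,sj->gij", X, w, X)
        XtWz = np.einsum("si,gs,gs->gi", X, w, z)
        # ridge jitter keeps all-zero groups solvable
        XtWX += 1e-12 * np.eye(p)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        new_dev = _nb_deviance(y, np.exp(np.clip(beta @ X.T + offsets, -700, 700)), phi)
        done = (step < 1e-8) | (np.abs(new_dev - dev) < tol * (np.abs(dev) + 1))
        converged |= done
        dev = new_dev
        if converged.all():
            break
    mu = np.exp(np.clip(beta @ X.T + offsets, -700, 700))
    return beta, np.maximum(mu, 1e-10), converged


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionEstimates:
    """Raw, trended and shrunken (tagwise) dispersions per gene."""

    table: pd.DataFrame  # columns: raw, trended, tagwise, mean_logcpm
    prior_df: float = _PRIOR_DF

    @property
    def tagwise(self) -> pd.Series:
        return self.table["tagwise"]


def estimate_dispersions(
    counts: CountMatrix,
    design: tuple[np.ndarray, list[str]] | None,
    norm: NormalizationResult,
    prior_df: float = _PRIOR_DF,
    lowess_frac: float = 0.3,
) -> DispersionEstimates:
    """Profile-likelihood dispersions with a lowess trend and shrinkage.

    For each gene the NB profile log-likelihood is evaluated on a fixed
    dispersion grid (the GLM refit at every grid point), maximised with a
    parabolic refinement.  The trend is a lowess fit of the raw estimates
    against average moderated log2 CPM; tagwise values shrink the raw
    estimate toward the trend with weight ``prior_df`` against the residual
    degrees of freedom (a convex combination, so tagwise always lies between
    raw and trended).
    """
    if design is None:
        design = genotype_design(counts.sample_meta)
    X, genotypes = design
    G, S = counts.counts.shape
    resid_df = S - X.shape[1]
    if resid_df <= 0:
        raise DispersionError(
            "no residual degrees of freedom: dispersion needs replication"
        )

    y = counts.counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective_library_sizes.reindex(counts.sample_ids).to_numpy())
    logcpm = moderated_log_cpm(counts, norm)
    mean_logcpm = logcpm.mean(axis=1)

    nonzero = y.sum(axis=1) > 0
    ll = np.full((G, _PHI_GRID.size), -np.inf)
    beta_ws = None
    for k, phi in enumerate(_PHI_GRID):
        phi_vec = np.full(nonzero.sum(), phi)
        beta_ws, mu, _ = _irls(y[nonzero], X, offsets, phi_vec, beta0=beta_ws)
        # Cox-Reid adjustment: penalise the likelihood for the fitted means,
        # removing the downward bias of the plain dispersion MLE
        w = mu / (1.0 + phi * mu)
        XtWX = np.einsum("si,gs,sj->gij", X, w, X) + 1e-12 * np.eye(X.shape[1])
        _, logdet = np.linalg.slogdet(XtWX)
        ll[nonzero, k] = _nb_loglik(y[nonzero], mu, phi_vec) - 0.5 * logdet

    raw = np.full(G, np.nan)
    best = np.argmax(ll[nonzero], axis=1)
    log_grid = np.log(_PHI_GRID)
    phi_hat = _PHI_GRID[best].astype(float)
    # parabolic refinement in log-phi for interior maxima
    interior = (best > 0) & (best < _PHI_GRID.size - 1)
    idx = np.flatnonzero(nonzero)
    bi = best[interior]
    l0 = ll[idx[interior], bi - 1]
    l1 = ll[idx[interior], bi]
    l2 = ll[idx[interior], bi + 1]
    x0, x1, x2 = log_grid[bi - 1], log_grid[bi], log_grid[bi + 1]
    denom = (l0 - l1) * (x1 - x2) - (l1 - l2) * (x0 - x1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = 0.5 * (
            (l0 - l1) * (x1**2 - x2**2) - (l1 - l2) * (x0**2 - x1**2)
        ) / np.where(denom == 0, np.nan, denom)
    ok = np.isfinite(vertex) & (vertex > x0) & (vertex < x2)
    refined = phi_hat[interior]
    refined[ok] = np.exp(vertex[ok])
    phi_hat[interior] = refined
    phi_hat[best == 0] = 0.0  # boundary: effectively Poisson
    raw[nonzero] = phi_hat

    # lowess trend on the raw estimates vs abundance
    x = mean_logcpm.to_numpy()[nonzero]
    r = raw[nonzero]
    if nonzero.sum() >= 10:
        fitted = lowess(r, x, frac=lowess_frac, it=2, return_sorted=False)
        trended_nz = np.maximum(fitted, 1e-6)
    else:
        trended_nz = np.full(nonzero.sum(), max(np.median(r), 1e-6))
    trended = np.full(G, np.nan)
    trended[nonzero] = trended_nz
    fill = np.nanmedian(trended) if np.isfinite(np.nanmedian(trended)) else 1e-6
    trended[~nonzero] = fill

    w = resid_df / (resid_df + prior_df)
    tagwise = np.where(np.isnan(raw), trended, w * np.nan_to_num(raw) + (1 - w) * trended)

    table = pd.DataFrame(
        {
            "raw": raw,
            "trended": trended,
            "tagwise": tagwise,
            "mean_logcpm": mean_logcpm,
        },
        index=counts.gene_ids,
    )
    return DispersionEstimates(table, prior_df)


# ---------------------------------------------------------------------------
# GLM fit and contrasts
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    """Per-gene NB GLM fit under cell-means genotype coding."""

    coefficients: pd.DataFrame  # genes x genotypes, natural-log scale
    genotypes: list[str]
    design: np.ndarray
    offsets: np.ndarray  # (S,) log effective library sizes
    dispersions: pd.Series
    deviance: pd.Series
    fitted_means: pd.DataFrame
    converged: pd.Series
    mean_logcpm: pd.Series
    counts: CountMatrix = field(repr=False)

    @property
    def all_zero(self) -> pd.Series:
        """Genes with zero counts everywhere (never tested)."""
        return self.counts.counts.sum(axis=1) == 0


@dataclass
class DifferentialProfile:
    """Per-gene result of one contrast.

    ``table`` columns: ``log2fc``, ``adjusted_log2fc``, ``pvalue``, ``fdr``,
    ``mean_logcpm``.  ``adjusted_log2fc`` equals ``log2fc`` until
    :func:`copy_adjust` subtracts the chromosome copy ratio.
    """

    table: pd.DataFrame
    contrast: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for col in ("log2fc", "adjusted_log2fc", "pvalue", "fdr"):
            if col not in self.table.columns:
                raise ContrastError(f"profile missing column {col!r}")

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def adjusted_log2fc(self) -> pd.Series:
        return self.table["adjusted_log2fc"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def fit_glm(
    counts: CountMatrix,
    design: tuple[np.ndarray, list[str]] | None,
    norm: NormalizationResult,
    dispersions: DispersionEstimates,
) -> GlmFit:
    """IRLS fit of the NB GLM for every gene at its tagwise dispersion."""
    if design is None:
        design = genotype_design(counts.sample_meta)
    X, genotypes = design
    y = counts.counts.to_numpy(dtype=float)
    offsets = np.log(norm.effective_library_sizes.reindex(counts.sample_ids).to_numpy())
    phi = dispersions.table["tagwise"].reindex(counts.gene_ids).to_numpy()
    beta, mu, conv = _irls(y, X, offsets, phi)
    dev = _nb_deviance(y, mu, phi)
    if not conv.all():
        n_bad = int((~conv).sum())
        warnings.warn(f"{n_bad} gene fits did not converge; flagged", stacklevel=2)
    return GlmFit(
        coefficients=pd.DataFrame(beta, index=counts.gene_ids, columns=genotypes),
        genotypes=genotypes,
        design=X,
        offsets=offsets,
        dispersions=pd.Series(phi, index=counts.gene_ids),
        deviance=pd.Series(dev, index=counts.gene_ids),
        fitted_means=pd.DataFrame(
            mu, index=counts.gene_ids, columns=counts.sample_ids
        ),
        converged=pd.Series(conv, index=counts.gene_ids),
        mean_logcpm=dispersions.table["mean_logcpm"].reindex(counts.gene_ids),
        counts=counts,
    )


def contrast_vector(
    weights: Sequence[tuple[str, float]] | Mapping[str, float],
    genotypes: Sequence[str],
) -> np.ndarray:
    """Expand (genotype, weight) pairs into a vector over the coefficient
    order; genotypes not mentioned get weight 0."""
    if isinstance(weights, Mapping):
        pairs = list(weights.items())
    else:
        pairs = list(weights)
    w = np.zeros(len(genotypes))
    for name, value in pairs:
        if name not in genotypes:
            raise ContrastError(f"contrast references unknown genotype {name!r}")
        w[list(genotypes).index(name)] = value
    if np.allclose(w, 0):
        raise ContrastError("contrast weights are all zero")
    return w


def lrt_contrast(
    fit: GlmFit,
    weights: Sequence[tuple[str, float]] | Mapping[str, float] | np.ndarray,
    tested_mask: pd.Series | None = None,
) -> DifferentialProfile:
    """Likelihood-ratio test of H0: w . beta = 0 for every gene.

    The null model refits the GLM with the design projected onto the
    contrast's null space (a reduced-basis reparameterisation); the LRT
    statistic is the deviance difference, chi-square with 1 df.  BH-FDR is
    computed over the tested genes only, so the correction's m matches the
    set actually analysed.  ``log2fc`` is ``w . beta / ln 2``: a simple
    (A, +1), (B, -1) contrast yields log2(A/B).
    """
    if isinstance(weights, np.ndarray):
        w = weights.astype(float)
        if w.size != len(fit.genotypes):
            raise ContrastError("weight vector length does not match design")
        if np.allclose(w, 0):
            raise ContrastError("contrast weights are all zero")
    else:
        w = contrast_vector(weights, fit.genotypes)

    y = fit.counts.counts.to_numpy(dtype=float)
    phi = fit.dispersions.to_numpy()
    # null-space basis of w^T over the coefficient space
    from scipy.linalg import null_space

    B = null_space(w[None, :])
    X_red = fit.design @ B
    beta_r, mu_r, _ = _irls(y, X_red, fit.offsets, phi)
    dev_red = _nb_deviance(y, mu_r, phi)
    stat = np.maximum(dev_red - fit.deviance.to_numpy(), 0.0)
    pvals = stats.chi2.sf(stat, df=1)

    log2fc = (fit.coefficients.to_numpy() @ w) / LN2

    tested = ~fit.all_zero.to_numpy()
    if tested_mask is not None:
        tested &= tested_mask.reindex(fit.counts.gene_ids, fill_value=False).to_numpy()

    fdr = np.full(y.shape[0], np.nan)
    pv = pvals.copy()
    pv[~tested] = np.nan
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "adjusted_log2fc": log2fc,
            "pvalue": pv,
            "fdr": fdr,
            "mean_logcpm": fit.mean_logcpm.to_numpy(),
        },
        index=fit.counts.gene_ids,
    )
    contrast = None
    nonzero = [g for g, x in zip(fit.genotypes, w) if x != 0]
    if len(nonzero) == 2 and np.isclose(sorted(w[w != 0])[0], -sorted(w[w != 0])[1]):
        pos = fit.genotypes[int(np.argmax(w))]
        neg = fit.genotypes[int(np.argmin(w))]
        contrast = (pos, neg)
    return DifferentialProfile(table, contrast)


def pairwise_contrast(
    fit: GlmFit,
    genotype_a: str,
    genotype_b: str,
    tested_mask: pd.Series | None = None,
) -> DifferentialProfile:
    """Convenience: LRT of genotype_a vs genotype_b (log2FC = a over b)."""
    profile = lrt_contrast(
        fit, [(genotype_a, 1.0), (genotype_b, -1.0)], tested_mask
    )
    profile.contrast = (genotype_a, genotype_b)
    return profile


def copy_adjust(
    profile: DifferentialProfile,
    karyotype: Karyotype,
    annotation: GeneAnnotation,
    genotype_pair: tuple[str, str] | None = None,
) -> DifferentialProfile:
    """Subtract the log2 chromosome copy ratio from each gene's fold change.

    Genes on chromosome ``"unplaced"`` (strain-specific genes whose encoding
    chromosome is unknown) are never adjusted.
    """
    pair = genotype_pair or profile.contrast
    if pair is None:
        raise AdjustmentError("no genotype pair available for copy adjustment")
    ga, gb = pair
    chroms = annotation.chromosome_of(profile.genes)
    adjustment = pd.Series(0.0, index=profile.genes)
    for chrom in chroms.unique():
        if chrom == "unplaced":
            continue
        if chrom not in karyotype.chromosomes:
            raise AdjustmentError(f"chromosome {chrom!r} missing from karyotype")
        ratio = karyotype.ratio_between(ga, gb, chrom)
        adjustment[chroms == chrom] = np.log2(ratio)
    table = profile.table.copy()
    table["adjusted_log2fc"] = table["log2fc"] - adjustment
    return DifferentialProfile(table, pair)


def significant_genes(
    profile: DifferentialProfile, fdr: float = 0.01, min_fold: float = 2.0
) -> tuple[list[str], list[str]]:
    """Up/down gene lists at an FDR cutoff and a minimum adjusted fold
    change (``min_fold=1`` returns all FDR-significant genes by sign)."""
    cut = np.log2(min_fold)
    sig = profile.fdr < fdr
    up = profile.genes[sig & (profile.adjusted_log2fc >= cut) & (profile.adjusted_log2fc > 0)]
    down = profile.genes[sig & (profile.adjusted_log2fc <= -cut) & (profile.adjusted_log2fc < 0)]
    return list(up), list(down)
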