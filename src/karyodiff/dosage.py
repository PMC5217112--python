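"""Dosage summaries, orthogonal regression and copy-number interactions.

Comparing two differential profiles gene by gene — the effect of reducing a
regulator's copy number against the effect of increasing it — calls for a
regression treating both axes symmetrically.  Total least squares (TLS)
minimises orthogonal distances and is equivalent to the first principal
component of the centered 2-D cloud; rotating the data so the TLS line
becomes the x-axis turns the second component into a per-gene score of
departure from the shared linear trend.

A simple proportional model predicts the TLS slope: if one perturbation
changes the regulator ``r_up``-fold and the other reduces it ``r_down``-fold,
genes responding linearly to regulator level should fall on a line of slope
``-log(r_down)/log(r_up)``.  Genes that do not — significant second-PC
scores under a weighted GLM contrast — respond nonlinearly to the joint
copy-number change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DifferentialProfile, GlmFit, lrt_contrast
from .errors import DegenerateFitError, DesignError, KaryodiffError
from .io import GeneAnnotation, GeneSet


# ---------------------------------------------------------------------------
# per-chromosome dosage summaries
# ---------------------------------------------------------------------------


def chromosome_summary(
    profile: DifferentialProfile,
    annotation: GeneAnnotation,
    gene_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Median linear fold change and SD of log2 ratios per chromosome.

    Raw (not copy-adjusted) fold changes are summarised: a disomic
    chromosome under pure dosage shows a median near its copy ratio.
    Chromosomes with no surviving genes are omitted with a warning.
    """
    genes = profile.genes
    keep = pd.Series(True, index=genes)
    if gene_mask is not None:
        keep &= gene_mask.reindex(genes, fill_value=False)
    keep &= profile.log2fc.notna()
    chroms = annotation.chromosome_of(genes)
    rows = {}
    for chrom in pd.unique(chroms):
        sel = keep & (chroms == chrom)
        if not sel.any():
            warnings.warn(f"chromosome {chrom!r}: no genes survive filters", stacklevel=2)
            continue
        vals = profile.log2fc[sel]
        rows[chrom] = {
            "median_fold_change": float(2.0 ** vals.median()),
            "sd_log2fc": float(vals.std(ddof=1)) if sel.sum() > 1 else np.nan,
            "n_genes": int(sel.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("chromosome")


# ---------------------------------------------------------------------------
# total least squares
# ---------------------------------------------------------------------------


@dataclass
class TLSFit:
    """Orthogonal-regression line and the rotation it implies.

    ``rotation`` maps centered (x, y) to (PC1, PC2): its first row is the
    unit vector along the fitted line (x-component positive), its second the
    perpendicular chosen so points above the line score positive PC2.
    """

    slope: float
    intercept: float
    center: tuple[float, float]
    rotation: np.ndarray

    def __post_init__(self) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(2), atol=1e-10):
            raise DegenerateFitError("rotation is not orthonormal")


def tls_fit(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> TLSFit:
    """Total-least-squares line through paired per-gene values.

    The direction is the leading eigenvector of the 2x2 covariance of the
    centered data (sign fixed so the x-component is positive); the intercept
    follows from the line passing through the centroid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DegenerateFitError("TLS needs at least 3 finite paired values")
    cx, cy = x.mean(), y.mean()
    cov = np.cov(np.vstack([x, y]))
    if np.allclose(cov, 0):
        raise DegenerateFitError("no variance in either coordinate")
    evals, evecs = np.linalg.eigh(cov)
    v1 = evecs[:, np.argmax(evals)]
    if v1[0] < 0 or (v1[0] == 0 and v1[1] < 0):
        v1 = -v1
    if v1[0] == 0:
        raise DegenerateFitError("TLS line is vertical; slope undefined")
    slope = v1[1] / v1[0]
    # perpendicular with positive projection for points displaced toward +y
    v2 = np.array([-v1[1], v1[0]])
    rotation = np.vstack([v1, v2])
    intercept = cy - slope * cx
    return TLSFit(float(slope), float(intercept), (float(cx), float(cy)), rotation)


def expected_slope(r_up: float, r_down: float) -> float:
    """Slope predicted by proportional response to regulator level.

    ``r_up`` is the fold increase of the regulator in one perturbation,
    ``r_down`` the fold decrease in the other (both > 1).  The model line
    through the origin has slope ``-log(r_down)/log(r_up)`` — base-free,
    since the ratio of logs cancels the base.
    """
    if r_up <= 1 or r_down <= 1:
        raise KaryodiffError("expected_slope requires fold changes > 1")
    return -np.log(r_down) / np.log(r_up)


def pc_scores(
    x: pd.Series | np.ndarray, y: pd.Series | np.ndarray, fit: TLSFit
) -> pd.DataFrame:
    """Project (x, y) onto the TLS rotation: PC1 along the fitted line,
    PC2 the signed orthogonal departure.  The loadings come from the fitted
    (filtered) gene set but may be applied to any genes."""
    index = x.index if isinstance(x, pd.Series) else None
    pts = np.vstack([np.asarray(x, float) - fit.center[0],
                     np.asarray(y, float) - fit.center[1]])
    scores = fit.rotation @ pts
    return pd.DataFrame({"PC1": scores[0], "PC2": scores[1]}, index=index)


# ---------------------------------------------------------------------------
# second-PC interaction contrast
# ---------------------------------------------------------------------------


def second_pc_contrast(
    fit: GlmFit,
    slope: float,
    genotype_order: tuple[str, str, str, str],
    tested_mask: pd.Series | None = None,
    fdr: float = 0.01,
    min_fold: float = 2.0,
) -> tuple[DifferentialProfile, pd.DataFrame]:
    """Identify genes off the proportional-response line.

    ``genotype_order`` is (hemizygote, disome, overexpression, control).
    With a negative TLS slope ``s``, a gene on the line satisfies
    ``1*(hemi - disome) + |s|*(over - control) = 0``; the LRT with weights
    ``(1, -1, |s|, -|s|)`` therefore tests for significant second-PC values.

    Returns the contrast profile plus a classification of significant genes:
    ``higher_than_expected`` (positive contrast: the hemizygote responds
    more than the overexpression trend predicts) or ``lower_than_expected``,
    each with a flag for deviations of at least ``min_fold`` on the
    hemizygote (weight-1) scale.
    """
    if slope >= 0:
        raise DesignError("second-PC contrast expects a negative slope")
    hemi, disome, over, control = genotype_order
    for g in genotype_order:
        if g not in fit.genotypes:
            raise DesignError(f"genotype {g!r} missing from the GLM fit")
    s = abs(slope)
    weights = [(hemi, 1.0), (disome, -1.0), (over, s), (control, -s)]
    profile = lrt_contrast(fit, weights, tested_mask)

    cut = np.log2(min_fold)
    sig = profile.fdr < fdr
    value = profile.log2fc
    classification = pd.DataFrame(
        {
            "contrast_log2": value,
            "significant": sig.fillna(False),
            "direction": np.where(value > 0, "higher_than_expected", "lower_than_expected"),
            "twofold_deviation": value.abs() >= cut,
        },
        index=profile.genes,
    )
    classification = classification[classification["significant"]]
    return profile, classification


# ---------------------------------------------------------------------------
# quadrant enrichment
# ---------------------------------------------------------------------------


def fisher_exact_two_tailed(table: np.ndarray) -> tuple[float, float]:
    """Two-tailed Fisher exact test on a 2x2 table (odds ratio, p).

    The two-tailed p sums all hypergeometric outcomes with probability no
    greater than the observed table's — the standard convention.
    """
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def quadrant_table(
    x: pd.Series,
    y: pd.Series,
    motif_set: GeneSet,
    quadrant: tuple[int, int] = (-1, 1),
    gene_mask: pd.Series | None = None,
) -> np.ndarray:
    """2x2 table of (in quadrant vs not) x (in set vs not).

    ``quadrant`` gives the required signs of (x, y); the default (-1, +1)
    selects genes repressed on the x profile and induced on the y profile.
    """
    genes = x.index
    keep = x.notna() & y.reindex(genes).notna()
    if gene_mask is not None:
        keep &= gene_mask.reindex(genes, fill_value=False)
    x, y = x[keep], y.reindex(genes)[keep]
    qx, qy = quadrant
    in_q = (np.sign(x) == qx) & (np.sign(y) == qy)
    in_set = x.index.isin(motif_set.members)
    return np.array(
        [
            [int((in_q & in_set).sum()), int((in_q & ~in_set).sum())],
            [int((~in_q & in_set).sum()), int((~in_q & ~in_set).sum())],
        ]
    )


def quadrant_enrichment(
    x: pd.Series,
    y: pd.Series,
    motif_set: GeneSet,
    quadrant: tuple[int, int] = (-1, 1),
    gene_mask: pd.Series | None = None,
) -> tuple[float, float]:
    """Fisher exact enrichment of a gene set in one quadrant of the
    two-profile scatter.  Returns (odds ratio, two-tailed p); an empty
    quadrant yields p = 1 with a warning."""
    if len(motif_set) == 0:
        raise KaryodiffError("motif set is empty")
    table = quadrant_table(x, y, motif_set, quadrant, gene_mask)
    if table[0].sum() == 0:
        warnings.warn("quadrant contains no genes; p = 1", stacklevel=2)
        return np.nan, 1.0
    return fisher_exact_two_tailed(table)
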