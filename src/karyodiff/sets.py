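"""Directional gene-set shift tests and profile-level comparisons.

The question "is the stress response reversed in the disomes?" is a
location-shift question: do the copy-adjusted fold changes of a defined set
(e.g. the genes repressed in the environmental stress response) sit above or
below those of the remaining genes?  A two-sample rank-sum test answers it
without distributional assumptions, and is invariant under any monotone
transform of the fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DifferentialProfile
from .errors import CombineError, CorrelationError, KaryodiffError
from .io import GeneSet


@dataclass
class SetShiftResult:
    """Rank-sum comparison of one gene set against the background."""

    set_name: str
    W: float
    p: float
    median_set: float
    median_background: float
    direction_of_shift: str  # "up" | "down" | "none"
    n_set: int
    n_background: int
    low_power: bool = False


def directional_ranksum(
    profile: DifferentialProfile,
    gene_set: GeneSet,
    background_mask: pd.Series,
    exact_below: int = 25,
) -> SetShiftResult:
    """Two-sample rank-sum test of the set's adjusted log2 fold changes
    against non-member background genes.

    ``background_mask`` flags the eligible gene universe (typically filtered
    nuclear ORFs); set members are removed from the background.  The normal
    approximation with tie and continuity corrections is used, except for
    tiny problems (combined n below ``exact_below``) where the exact null
    distribution is enumerated.  W is the rank-sum U statistic of the set
    sample, as reported by standard two-sample Wilcoxon implementations.
    """
    values = profile.adjusted_log2fc
    mask = background_mask.reindex(values.index, fill_value=False).astype(bool)
    in_set = values.index.isin(gene_set.members)
    set_vals = values[mask & in_set].dropna()
    bg_vals = values[mask & ~in_set].dropna()
    if len(set_vals) == 0 or len(bg_vals) == 0:
        raise KaryodiffError(
            f"set {gene_set.name!r}: empty set or background after filtering"
        )
    low_power = len(set_vals) < 5
    method = "exact" if len(set_vals) + len(bg_vals) < exact_below else "asymptotic"
    res = stats.mannwhitneyu(
        set_vals, bg_vals, alternative="two-sided", method=method
    )
    med_s, med_b = float(set_vals.median()), float(bg_vals.median())
    if med_s > med_b:
        direction = "up"
    elif med_s < med_b:
        direction = "down"
    else:
        direction = "none"
    return SetShiftResult(
        set_name=gene_set.name,
        W=float(res.statistic),
        p=float(res.pvalue),
        median_set=med_s,
        median_background=med_b,
        direction_of_shift=direction,
        n_set=len(set_vals),
        n_background=len(bg_vals),
        low_power=low_power,
    )


def profile_correlation(
    a: DifferentialProfile,
    b: DifferentialProfile,
    gene_mask: pd.Series,
) -> tuple[float, float, int, float]:
    """Pearson correlation of two profiles' adjusted log2 fold changes.

    Returns (R, t, df, p) with t = R * sqrt(df / (1 - R^2)) and df = n - 2.
    """
    genes = a.genes.intersection(b.genes)
    mask = gene_mask.reindex(genes, fill_value=False).astype(bool)
    x = a.adjusted_log2fc.reindex(genes)[mask]
    y = b.adjusted_log2fc.reindex(genes)[mask]
    ok = x.notna() & y.notna()
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise CorrelationError("need at least 3 paired genes to correlate")
    r, p = stats.pearsonr(x, y)
    df = len(x) - 2
    if 1.0 - r * r <= 0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    return float(r), float(t), int(df), float(p)


def combine_profiles(
    profiles: list[DifferentialProfile], mode: str = "mean"
) -> DifferentialProfile:
    """Per-gene mean of adjusted log2 fold changes across profiles.

    The combined profile is descriptive (used for e.g. "mean change across
    the two disomes"); its p/FDR columns are null.
    """
    if mode != "mean":
        raise KaryodiffError(f"unknown combine mode {mode!r}")
    if not profiles:
        raise CombineError("no profiles to combine")
    genes = profiles[0].genes
    for pr in profiles[1:]:
        genes = genes.intersection(pr.genes)
    if len(genes) == 0:
        raise CombineError("profiles share no genes")
    adj = np.mean([pr.adjusted_log2fc.reindex(genes) for pr in profiles], axis=0)
    raw = np.mean([pr.log2fc.reindex(genes) for pr in profiles], axis=0)
    mean_logcpm = np.mean(
        [pr.table["mean_logcpm"].reindex(genes) for pr in profiles], axis=0
    )
    table = pd.DataFrame(
        {
            "log2fc": raw,
            "adjusted_log2fc": adj,
            "pvalue": np.nan,
            "fdr": np.nan,
            "mean_logcpm": mean_logcpm,
        },
        index=genes,
    )
    return DifferentialProfile(table)


def mean_absolute_log2fc(profile: DifferentialProfile, gene_mask: pd.Series) -> float:
    """Mean |adjusted log2FC| over a gene mask (a profile-magnitude summary)."""
    mask = gene_mask.reindex(profile.genes, fill_value=False).astype(bool)
    vals = profile.adjusted_log2fc[mask].dropna()
    if vals.empty:
        raise KaryodiffError("no genes survive the mask")
    return float(vals.abs().mean())
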