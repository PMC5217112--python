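"""End-to-end orchestration of the karyotype-aware expression analysis.

A run proceeds batch by batch (batches are sequenced and normalised
separately, each against its own euploid control):

normalize (restricted-reference trimmed mean) -> basal/variance filters ->
dispersions -> GLM -> pairwise contrasts (with a doubled-factor rerun for
genes on disomic chromosomes) -> per-chromosome dosage summaries ->
TLS / second-PC interaction analysis (when the four-genotype regulator
design is present) -> directional gene-set tests.

Every output table carries a provenance header (config hash, seed, package
version) and uses a fixed numeric format, so a rerun with the same inputs is
byte-identical.  A bookkeeping table records genes in/out of every filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .de import (
    DifferentialProfile,
    copy_adjust,
    estimate_dispersions,
    fit_glm,
    pairwise_contrast,
    significant_genes,
)
from .dosage import (
    chromosome_summary,
    pc_scores,
    quadrant_enrichment,
    second_pc_contrast,
    tls_fit,
)
from .errors import ConfigurationError
from .io import (
    CountMatrix,
    GeneAnnotation,
    GeneSet,
    Karyotype,
    read_annotation,
    read_count_table,
    read_gene_sets,
    read_karyotype,
    write_profile,
)
from .normalize import (
    basal_expression_filter,
    doubled_factor_variant,
    moderated_log_cpm,
    tmm_factors,
    variance_filter,
)
from .sets import SetShiftResult, directional_ranksum

logger = logging.getLogger("karyodiff")


@dataclass
class InteractionDesign:
    """The four genotypes of the regulator copy-number interaction analysis."""

    hemizygote: str
    disome: str
    overexpression: str
    control: str
    motif_set: str | None = None

    def order(self) -> tuple[str, str, str, str]:
        return (self.hemizygote, self.disome, self.overexpression, self.control)


@dataclass
class PipelineConfig:
    """Paths, contrasts and thresholds for one full run.

    ``contrasts`` lists (genotype, control) pairs; each is analysed within
    the batch containing both genotypes.  Thresholds default to the
    conventional colony RNA-seq settings: BH FDR 0.01, twofold minimum
    change, +2 CPM prior, replicate-variance cutoff 3, basal median 1 CPM.
    """

    counts_path: str | None = None
    meta_path: str | None = None
    annotation_path: str | None = None
    karyotype_path: str | None = None
    gene_sets_path: str | None = None
    contrasts: Sequence[tuple[str, str]] = ()
    interaction: InteractionDesign | None = None
    fdr: float = 0.01
    min_fold: float = 2.0
    prior: float = 2.0
    variance_threshold: float = 3.0
    min_cpm: float = 1.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("fdr", "min_fold", "prior", "variance_threshold", "min_cpm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (where results are written
        does not change what they are)."""
        doc = asdict(self)
        doc.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ContrastResult:
    name: str
    profile: DifferentialProfile  # raw + copy-adjusted fold changes
    merged_profile: DifferentialProfile  # doubled-factor rows for disomic chroms
    up: list[str]
    down: list[str]
    summary: pd.DataFrame


@dataclass
class InteractionResult:
    slope: float
    intercept: float
    profile: DifferentialProfile
    classification: pd.DataFrame
    scores: pd.DataFrame
    enrichment: tuple[float, float] | None


@dataclass
class BatchResult:
    batch: str
    norm_samples: pd.DataFrame
    tested_mask: pd.Series
    contrasts: dict[str, ContrastResult]
    set_shifts: list[SetShiftResult]
    interaction: InteractionResult | None
    bookkeeping: pd.DataFrame


@dataclass
class PipelineReport:
    config_hash: str
    batches: dict[str, BatchResult]


def _bookkeep(rows: list[dict], stage: str, genes_in: int, genes_out: int) -> None:
    rows.append(
        {
            "stage": stage,
            "genes_in": genes_in,
            "genes_out": genes_out,
            "genes_filtered": genes_in - genes_out,
        }
    )
    logger.info("%s: %d -> %d genes", stage, genes_in, genes_out)


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    annotation: GeneAnnotation | None = None,
    karyotype: Karyotype | None = None,
    gene_sets: Sequence[GeneSet] | None = None,
) -> PipelineReport:
    """Run every configured analysis; inputs may be passed in memory or
    loaded from the configured paths."""
    if counts is None:
        if config.counts_path is None or config.meta_path is None:
            raise ConfigurationError("no counts provided (paths or in-memory)")
        counts = read_count_table(config.counts_path, config.meta_path)
    if annotation is None:
        if config.annotation_path is None:
            raise ConfigurationError("no annotation provided")
        annotation = read_annotation(config.annotation_path)
    if karyotype is None:
        if config.karyotype_path is None:
            raise ConfigurationError("no karyotype provided")
        karyotype = read_karyotype(config.karyotype_path)
    if gene_sets is None:
        gene_sets = (
            read_gene_sets(config.gene_sets_path) if config.gene_sets_path else []
        )

    known = set(counts.genotypes)
    for a, b in config.contrasts:
        if a not in known or b not in known:
            raise ConfigurationError(
                f"contrast {a}:{b} references a genotype absent from the metadata"
            )
    if config.interaction is not None:
        for g in config.interaction.order():
            if g not in known:
                raise ConfigurationError(
                    f"interaction design genotype {g!r} absent from the metadata"
                )

    report = PipelineReport(config.digest(), {})
    for batch in sorted(counts.sample_meta["batch"].unique()):
        sub = counts.subset_batch(batch)
        result = _run_batch(config, batch, sub, annotation, karyotype, gene_sets)
        report.batches[batch] = result
        if config.output_dir is not None:
            _write_batch(config, result)
    return report


def _run_batch(
    config: PipelineConfig,
    batch: str,
    counts: CountMatrix,
    annotation: GeneAnnotation,
    karyotype: Karyotype,
    gene_sets: Sequence[GeneSet],
) -> BatchResult:
    rows: list[dict] = []
    genotypes_here = list(pd.unique(counts.genotypes))
    anno = annotation.resolve(counts.gene_ids)
    nuclear = anno["gene_class"] == "nuclear_ORF"

    # chromosomes disomic in any genotype of this batch leave the reference set
    excluded: set[str] = set()
    for g in genotypes_here:
        if g in karyotype.genotypes:
            excluded.update(karyotype.disomic_chromosomes(g))
    ref_mask = nuclear & ~anno["chromosome"].isin(excluded)
    _bookkeep(rows, "reference_mask", len(counts.gene_ids), int(ref_mask.sum()))

    norm = tmm_factors(counts, ref_mask)
    logcpm = moderated_log_cpm(counts, norm, config.prior)

    reference = karyotype.reference_genotype
    ref_samples = counts.samples_for(reference)
    if not ref_samples:
        # batches with a re-labelled control (e.g. vector-carrying euploid)
        # fall back to the control side of the first contrast present
        candidates = [b for _, b in config.contrasts if b in genotypes_here]
        if not candidates:
            raise ConfigurationError(
                f"batch {batch!r}: no reference genotype for the basal filter"
            )
        ref_samples = counts.samples_for(candidates[0])
    basal = basal_expression_filter(counts, ref_samples, config.min_cpm, norm)
    _bookkeep(rows, "basal_filter", len(counts.gene_ids), int(basal.sum()))

    var_masks = variance_filter(
        logcpm, counts.genotypes, config.variance_threshold
    )

    dispersions = estimate_dispersions(counts, None, norm)
    fit = fit_glm(counts, None, norm, dispersions)

    contrast_results: dict[str, ContrastResult] = {}
    tested_any = pd.Series(False, index=counts.gene_ids)
    for a, b in config.contrasts:
        if a not in genotypes_here or b not in genotypes_here:
            continue
        mask = basal & var_masks[a] & var_masks[b]
        _bookkeep(rows, f"tested_mask[{a}:{b}]", len(counts.gene_ids), int(mask.sum()))
        tested_any |= mask

        base = pairwise_contrast(fit, a, b, mask)
        base = copy_adjust(base, karyotype, annotation, (a, b))

        # doubled-factor rerun for genes on chromosomes disomic in this pair
        pair_chroms = [
            c
            for c in karyotype.chromosomes
            if karyotype.ratio_between(a, b, c) != 1.0
        ]
        merged = base
        if pair_chroms:
            doubled_genotype = a if karyotype.copies.at[a, pair_chroms[0]] > karyotype.copies.at[b, pair_chroms[0]] else b
            norm2 = doubled_factor_variant(norm, counts.samples_for(doubled_genotype))
            disp2 = estimate_dispersions(counts, None, norm2)
            fit2 = fit_glm(counts, None, norm2, disp2)
            doubled = pairwise_contrast(fit2, a, b, mask)
            on_disomic = anno["chromosome"].isin(pair_chroms)
            table = base.table.copy()
            dbl = doubled.table.loc[on_disomic.to_numpy()]
            table.loc[on_disomic.to_numpy(), ["adjusted_log2fc", "pvalue", "fdr"]] = dbl[
                ["log2fc", "pvalue", "fdr"]
            ].to_numpy()
            merged = DifferentialProfile(table, (a, b))

        up, down = significant_genes(merged, config.fdr, config.min_fold)
        summary = chromosome_summary(base, annotation, mask & nuclear)
        name = f"{a}_vs_{b}"
        contrast_results[name] = ContrastResult(name, base, merged, up, down, summary)

    set_results: list[SetShiftResult] = []
    for gs in gene_sets:
        for name, cr in contrast_results.items():
            mask = basal & nuclear
            res = directional_ranksum(cr.merged_profile, gs, mask)
            res.set_name = f"{gs.name}[{name}]"
            set_results.append(res)

    interaction_result = None
    design = config.interaction
    if design is not None and all(g in genotypes_here for g in design.order()):
        interaction_result = _run_interaction(
            config, counts, annotation, karyotype, fit, design,
            basal, var_masks, nuclear, gene_sets,
        )

    return BatchResult(
        batch=batch,
        norm_samples=norm.samples,
        tested_mask=tested_any,
        contrasts=contrast_results,
        set_shifts=set_results,
        interaction=interaction_result,
        bookkeeping=pd.DataFrame(rows),
    )


def _run_interaction(
    config, counts, annotation, karyotype, fit, design,
    basal, var_masks, nuclear, gene_sets,
) -> InteractionResult:
    hemi, disome, over, control = design.order()
    mask = (
        basal
        & nuclear
        & var_masks[hemi]
        & var_masks[disome]
        & var_masks[over]
        & var_masks[control]
    )
    y_prof = copy_adjust(
        pairwise_contrast(fit, hemi, disome, mask), karyotype, annotation, (hemi, disome)
    )
    x_prof = copy_adjust(
        pairwise_contrast(fit, over, control, mask), karyotype, annotation, (over, control)
    )
    x = x_prof.adjusted_log2fc[mask.to_numpy()]
    y = y_prof.adjusted_log2fc[mask.to_numpy()]
    fit_tls = tls_fit(x, y)
    scores = pc_scores(x_prof.adjusted_log2fc, y_prof.adjusted_log2fc, fit_tls)

    profile, classification = second_pc_contrast(
        fit, fit_tls.slope, design.order(), mask, config.fdr, config.min_fold
    )

    enrichment = None
    if design.motif_set is not None:
        match = [g for g in gene_sets if g.name == design.motif_set]
        if not match:
            raise ConfigurationError(
                f"motif set {design.motif_set!r} not among the loaded gene sets"
            )
        enrichment = quadrant_enrichment(
            x_prof.adjusted_log2fc, y_prof.adjusted_log2fc, match[0], (-1, 1), mask
        )
    return InteractionResult(
        slope=fit_tls.slope,
        intercept=fit_tls.intercept,
        profile=profile,
        classification=classification,
        scores=scores,
        enrichment=enrichment,
    )


def _write_batch(config: PipelineConfig, result: BatchResult) -> None:
    out = Path(config.output_dir) / f"batch_{result.batch}"
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"karyodiff {__version__}",
        f"config {config.digest()}",
        f"seed {config.seed}",
    ]
    for name, cr in result.contrasts.items():
        write_profile(cr.merged_profile, out / f"de_{name}.tsv", header)
        cr.summary.to_csv(out / f"chromosome_summary_{name}.tsv", sep="\t",
                          float_format="%.5e")
        (out / f"genes_up_{name}.txt").write_text("\n".join(cr.up) + "\n" if cr.up else "")
        (out / f"genes_down_{name}.txt").write_text(
            "\n".join(cr.down) + "\n" if cr.down else ""
        )
    if result.set_shifts:
        pd.DataFrame([vars(s) for s in result.set_shifts]).to_csv(
            out / "set_shifts.tsv", sep="\t", index=False, float_format="%.5e"
        )
    if result.interaction is not None:
        ir = result.interaction
        write_profile(ir.profile, out / "interaction_contrast.tsv", header)
        ir.classification.to_csv(
            out / "interaction_classification.tsv", sep="\t", float_format="%.5e"
        )
        ir.scores.to_csv(out / "pc_scores.tsv", sep="\t", float_format="%.5e")
        lines = [f"slope\t{ir.slope:.5e}", f"intercept\t{ir.intercept:.5e}"]
        if ir.enrichment is not None:
            lines += [
                f"quadrant_odds_ratio\t{ir.enrichment[0]:.5e}",
                f"quadrant_p\t{ir.enrichment[1]:.5e}",
            ]
        (out / "tls_fit.tsv").write_text("\n".join(lines) + "\n")
    result.bookkeeping.to_csv(out / "bookkeeping.tsv", sep="\t", index=False)
    result.norm_samples.to_csv(
        out / "normalization.tsv", sep="\t", float_format="%.5e"
    )
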