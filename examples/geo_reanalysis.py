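"""Reanalyse the deposited colony RNA-seq counts (requires local data).

The deposited gene count tables (GEO accession GSE85843; reads under ENA
PRJEB15176) are not redistributable with this package.  To run this script,
place under data/GSE85843/:

  counts.tsv       gene x library integer counts (first batch libraries)
  samples.tsv      sample, genotype, batch, replicate columns; genotypes
                   F45, disomeXV, disomeXVI, hemiXVI, overexpression,
                   vector_control
  annotation.tsv   gene, chromosome, class columns (or a GFF3)
  karyotype.yaml   reference F45; disomeXV/disomeXVI/hemiXVI copies

The analysis mirrors the pipeline applied to the simulations: restricted
reference normalization excluding chrXV/chrXVI, basal and variance filters,
NB-GLM contrasts, chromosome XV dosage medians (expected ~1.79-fold vs the
euploid and ~1.98-fold between the disomes).
"""

from pathlib import Path

import karyodiff as kd

DATA = Path(__file__).resolve().parent.parent / "data" / "GSE85843"
if not (DATA / "counts.tsv").exists():
    raise SystemExit(f"deposited counts not found under {DATA}; see module docstring")

counts = kd.read_count_table(DATA / "counts.tsv", DATA / "samples.tsv")
annotation = kd.read_annotation(DATA / "annotation.tsv")
karyotype = kd.read_karyotype(DATA / "karyotype.yaml")

anno = annotation.resolve(counts.gene_ids)
ref_mask = (anno["gene_class"] == "nuclear_ORF") & ~anno["chromosome"].isin(
    ["chrXV", "chrXVI"]
)
norm = kd.tmm_factors(counts, ref_mask)
dispersions = kd.estimate_dispersions(counts, None, norm)
fit = kd.fit_glm(counts, None, norm, dispersions)
basal = kd.basal_expression_filter(counts, counts.samples_for("F45"), 1.0, norm)
logcpm = kd.moderated_log_cpm(counts, norm)
var_masks = kd.variance_filter(logcpm, counts.genotypes)

for a, b, chrom in (
    ("disomeXV", "F45", "chrXV"),
    ("disomeXV", "disomeXVI", "chrXV"),
):
    mask = basal & var_masks[a] & var_masks[b] & (anno["gene_class"] == "nuclear_ORF")
    profile = kd.pairwise_contrast(fit, a, b, mask)
    summary = kd.chromosome_summary(profile, annotation, mask)
    print(
        f"{a} vs {b}: {chrom} median fold change "
        f"{summary.loc[chrom, 'median_fold_change']:.2f} "
        f"(SD of log2 ratios {summary.loc[chrom, 'sd_log2fc']:.2f}, "
        f"n={summary.loc[chrom, 'n_genes']:.0f})"
    )
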