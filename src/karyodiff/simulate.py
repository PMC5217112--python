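"""Synthetic colony RNA-seq experiments with known ground truth.

The generator draws negative-binomial counts whose log2-scale expected
expression decomposes additively into the mechanisms by which whole-chromosome
aneuploidy can change a transcriptome:

* **cis dosage** — genes on a chromosome present at ``c`` copies shift by
  exactly ``log2(c / c_reference)``;
* **trans regulation** — a subset of genes responds linearly (on the log2
  scale) to the expression level of a dosage-sensitive regulator, emulating a
  repressor such as DIG1 whose copy number varies across genotypes;
* **shared response** — a karyotype-independent effect vector (stress-like,
  or driven by colony morphology) scaled per genotype;
* **nonlinear interaction** — designated genes receive genotype-specific
  offsets that break the linear regulator model, the signal the second-PC
  contrast is designed to detect;
* **directional set shifts** — signed gene sets (induced/repressed) moved
  coherently in designated genotypes.

Per-sample relative abundances are renormalised to sum to one before scaling
by library size, so "library size" keeps its usual meaning even when a disome
adds transcriptional mass.  Every effect is recorded exactly in a
:class:`SimTruth` table so downstream stages can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, KaryodiffError
from .io import CountMatrix, GeneAnnotation, Karyotype


@dataclass(frozen=True)
class GenotypeSpec:
    """One strain in the simulated design.

    Parameters
    ----------
    name
        Genotype label (also used in sample ids).
    chromosome_copies
        Chromosome -> copy number; chromosomes not listed carry 1 copy.
    regulator_expression_multiplier
        Fold change of the regulator's expression relative to the reference
        genotype (e.g. 4.25 for a strong overexpression plasmid, 1/2.28 for
        a hemizygous deletion).  Drives the linear trans responses.
    shared_effect_scale
        Multiplier applied to the shared (karyotype-independent) effect
        vector in this genotype; 0 disables it.
    batch
        Batch label; batches are normalised and analysed separately.
    """

    name: str
    chromosome_copies: Mapping[str, float] = field(default_factory=dict)
    regulator_expression_multiplier: float = 1.0
    shared_effect_scale: float = 0.0
    batch: str = "batch1"

    def __post_init__(self) -> None:
        if self.regulator_expression_multiplier <= 0:
            raise ConfigurationError(
                f"genotype {self.name!r}: regulator multiplier must be > 0"
            )
        for chrom, n in self.chromosome_copies.items():
            if n < 1:
                raise ConfigurationError(
                    f"genotype {self.name!r}: copy number {n} for {chrom} is < 1"
                )


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated experiment.

    Defaults mirror a two-batch colony RNA-seq design: gene-specific
    baselines spread over a wide log2-CPM range, a decreasing
    dispersion-abundance trend ``phi(mu) = asymptote + slope / mu``, and
    per-library depths of a few million read pairs.
    """

    n_genes: int
    chromosomes: tuple[tuple[str, int], ...]
    genotypes: tuple[GenotypeSpec, ...]
    replicates_per_genotype: int = 4
    baseline_log_mean_range: tuple[float, float] = (0.0, 9.0)
    dispersion_model: tuple[float, float] = (0.05, 2.0)
    library_size_range: tuple[float, float] = (2_000_000, 6_000_000)
    seed: int = 0
    reference_genotype: str | None = None
    # effect structure ------------------------------------------------------
    trans_fraction: float = 0.2
    trans_coefficient_sd: float = 0.25
    shared_fraction: float = 0.3
    shared_effect_sd: float = 0.4
    n_interaction_genes: int = 0
    interaction_offsets: Mapping[str, float] = field(default_factory=dict)
    esr_up_size: int = 0
    esr_down_size: int = 0
    motif_set_size: int = 0
    esr_shift_log2: Mapping[str, float] = field(default_factory=dict)
    replicate_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if sum(n for _, n in self.chromosomes) != self.n_genes:
            raise ConfigurationError(
                "per-chromosome gene counts must sum to n_genes"
            )
        if self.replicates_per_genotype < 2:
            raise ConfigurationError("need at least 2 replicates per genotype")
        for name, (lo, hi) in (
            ("baseline_log_mean_range", self.baseline_log_mean_range),
            ("library_size_range", self.library_size_range),
        ):
            if hi < lo:
                raise ConfigurationError(f"{name} is empty")
        if len({g.name for g in self.genotypes}) != len(self.genotypes):
            raise ConfigurationError("genotype names must be unique")

    def resolved_reference(self) -> str:
        """The euploid baseline genotype; defaults to the first genotype
        whose chromosome copies are all 1."""
        if self.reference_genotype is not None:
            if self.reference_genotype not in {g.name for g in self.genotypes}:
                raise ConfigurationError(
                    f"reference genotype {self.reference_genotype!r} not in design"
                )
            return self.reference_genotype
        for g in self.genotypes:
            if all(v == 1 for v in g.chromosome_copies.values()):
                return g.name
        raise ConfigurationError("no euploid genotype to serve as reference")


@dataclass
class SimTruth:
    """Exact record of every effect used to generate a simulated dataset.

    All effect tables are on the log2 scale, genes as rows, genotypes as
    columns.  ``expected_log2fc`` composes them into the true fold change of
    any genotype contrast.
    """

    cis_log2_ratio: pd.DataFrame
    trans_coefficient: pd.Series
    shared_effect: pd.DataFrame
    interaction_offset: pd.DataFrame
    set_membership: pd.DataFrame
    library_size: pd.Series
    regulator_log2: pd.Series
    baseline_log2: pd.Series

    def expected_mean(self, genotype: str) -> pd.Series:
        """Configured NB mean per gene for one library of ``genotype`` at
        unit depth (multiply by a library size to get expected counts).
        Exact only when replicate noise is disabled."""
        log2_expr = self.baseline_log2 + self.total_effect()[genotype]
        rel = np.exp2(log2_expr)
        return rel / rel.sum()

    def total_effect(self) -> pd.DataFrame:
        """Sum of all log2 effects per gene x genotype (excluding baseline)."""
        trans = np.outer(self.trans_coefficient, self.regulator_log2)
        trans = pd.DataFrame(
            trans, index=self.trans_coefficient.index, columns=self.regulator_log2.index
        )
        return self.cis_log2_ratio + trans + self.shared_effect + self.interaction_offset

    def expected_log2fc(self, gene: str, genotype_a: str, genotype_b: str) -> float:
        """True log2 fold change of ``gene`` between two genotypes
        (cis + trans + shared + interaction difference)."""
        total = self.total_effect()
        try:
            return float(total.at[gene, genotype_a] - total.at[gene, genotype_b])
        except KeyError as exc:
            raise KaryodiffError(f"unknown gene or genotype: {exc}") from exc


def expected_log2fc(
    gene: str, genotype_a: str, genotype_b: str, truth: SimTruth
) -> float:
    """Functional alias for :meth:`SimTruth.expected_log2fc`."""
    return truth.expected_log2fc(gene, genotype_a, genotype_b)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) draw with variance mean + phi * mean^2."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    poisson = pos & (phi <= 1e-12)
    nb = pos & ~poisson
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, GeneAnnotation, Karyotype, SimTruth]:
    """Draw one synthetic experiment.

    Returns the count matrix (with sample metadata), the matching gene
    annotation and karyotype, and the ground-truth effect tables.
    Deterministic given ``config`` (including its seed): gene-level
    parameters are drawn from a root stream and each sample's counts from a
    child stream spawned in fixed sample order.
    """
    root = np.random.SeedSequence(config.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])

    # gene ids and chromosome layout; systematic names start with Y so the
    # default nuclear-ORF predicate recognises them
    gene_ids: list[str] = []
    chrom_of: list[str] = []
    for ci, (chrom, n) in enumerate(config.chromosomes):
        tag = chrom.replace("chr", "")
        for i in range(n):
            gene_ids.append(f"Y{tag}{i + 1:04d}")
            chrom_of.append(chrom)
    genes = pd.Index(gene_ids, name="gene")
    annotation = GeneAnnotation(
        pd.DataFrame(
            {"chromosome": chrom_of, "gene_class": "nuclear_ORF"}, index=genes
        )
    )

    genotype_names = [g.name for g in config.genotypes]
    reference = config.resolved_reference()
    chrom_names = [c for c, _ in config.chromosomes]
    copies = pd.DataFrame(1.0, index=genotype_names, columns=chrom_names)
    for g in config.genotypes:
        for chrom, n in g.chromosome_copies.items():
            if chrom not in copies.columns:
                raise ConfigurationError(
                    f"genotype {g.name!r} references unknown chromosome {chrom!r}"
                )
            copies.at[g.name, chrom] = float(n)
    karyotype = Karyotype(reference, copies)

    # --- gene-level parameters -------------------------------------------
    lo, hi = config.baseline_log_mean_range
    baseline = param_rng.uniform(lo, hi, size=config.n_genes)  # log2 CPM-ish

    cis = pd.DataFrame(0.0, index=genes, columns=genotype_names)
    for g in config.genotypes:
        for chrom in chrom_names:
            ratio = copies.at[g.name, chrom] / copies.at[reference, chrom]
            if ratio != 1.0:
                on_chrom = np.array(chrom_of) == chrom
                cis.loc[on_chrom, g.name] = np.log2(ratio)

    trans_coef = np.zeros(config.n_genes)
    n_trans = int(round(config.trans_fraction * config.n_genes))
    trans_idx = param_rng.choice(config.n_genes, size=n_trans, replace=False)
    trans_coef[trans_idx] = param_rng.normal(
        0.0, config.trans_coefficient_sd, size=n_trans
    )
    regulator_log2 = pd.Series(
        {g.name: np.log2(g.regulator_expression_multiplier) for g in config.genotypes}
    )

    shared_vec = np.zeros(config.n_genes)
    n_shared = int(round(config.shared_fraction * config.n_genes))
    shared_idx = param_rng.choice(config.n_genes, size=n_shared, replace=False)
    shared_vec[shared_idx] = param_rng.normal(0.0, config.shared_effect_sd, n_shared)
    shared = pd.DataFrame(
        np.outer(shared_vec, [g.shared_effect_scale for g in config.genotypes]),
        index=genes,
        columns=genotype_names,
    )

    interaction = pd.DataFrame(0.0, index=genes, columns=genotype_names)
    interaction_flag = np.zeros(config.n_genes, dtype=bool)
    if config.n_interaction_genes:
        pool = np.setdiff1d(np.arange(config.n_genes), trans_idx)
        pick = param_rng.choice(pool, size=config.n_interaction_genes, replace=False)
        interaction_flag[pick] = True
        for genotype, offset in config.interaction_offsets.items():
            if genotype not in interaction.columns:
                raise ConfigurationError(
                    f"interaction offset for unknown genotype {genotype!r}"
                )
            interaction.loc[interaction_flag, genotype] = offset

    membership = pd.DataFrame(
        False, index=genes, columns=["esr_up", "esr_down", "motif"]
    )
    taken = set(np.flatnonzero(interaction_flag))
    free = [i for i in range(config.n_genes) if i not in taken]
    param_rng.shuffle(free)
    cursor = 0
    for col, size in (
        ("esr_up", config.esr_up_size),
        ("esr_down", config.esr_down_size),
        ("motif", config.motif_set_size),
    ):
        if size:
            sel = free[cursor : cursor + size]
            if len(sel) < size:
                raise ConfigurationError(f"not enough genes for set {col!r}")
            membership.iloc[sel, membership.columns.get_loc(col)] = True
            cursor += size
    esr_shift = pd.DataFrame(0.0, index=genes, columns=genotype_names)
    for genotype, shift in config.esr_shift_log2.items():
        esr_shift.loc[membership["esr_up"].to_numpy(), genotype] += shift
        esr_shift.loc[membership["esr_down"].to_numpy(), genotype] -= shift
    # set shifts are a shared (karyotype-independent) mechanism: fold them
    # into the shared-effect table so the truth decomposition stays additive
    shared = shared + esr_shift

    truth_total = (
        cis
        + pd.DataFrame(
            np.outer(trans_coef, regulator_log2[genotype_names]),
            index=genes,
            columns=genotype_names,
        )
        + shared
        + interaction
    )

    # --- samples ----------------------------------------------------------
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for g in config.genotypes:
        for r in range(1, config.replicates_per_genotype + 1):
            sample_ids.append(f"{g.name}_r{r}")
            meta_rows.append(
                {"genotype": g.name, "batch": g.batch, "replicate": str(r)}
            )
    sample_meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample"))

    sample_seeds = root.spawn(1 + len(sample_ids))[1:]
    lib_lo, lib_hi = config.library_size_range
    asym, slope = config.dispersion_model

    counts = np.zeros((config.n_genes, len(sample_ids)), dtype=np.int64)
    libsizes = np.zeros(len(sample_ids))
    for j, (sid, meta) in enumerate(zip(sample_ids, meta_rows)):
        rng = np.random.default_rng(sample_seeds[j])
        libsize = float(rng.uniform(lib_lo, lib_hi))
        libsizes[j] = libsize
        log2_expr = baseline + truth_total[meta["genotype"]].to_numpy()
        if config.replicate_noise_sd > 0:
            log2_expr = log2_expr + rng.normal(
                0.0, config.replicate_noise_sd, size=config.n_genes
            )
        rel = np.exp2(log2_expr)
        rel /= rel.sum()
        mean = libsize * rel
        with np.errstate(divide="ignore"):
            phi = asym + np.where(mean > 0, slope / np.maximum(mean, 1e-12), 0.0)
        counts[:, j] = _nb_draw(rng, mean, phi)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids), sample_meta
    )
    truth = SimTruth(
        cis_log2_ratio=cis,
        trans_coefficient=pd.Series(trans_coef, index=genes, name="trans_coefficient"),
        shared_effect=shared,
        interaction_offset=interaction,
        set_membership=membership,
        library_size=pd.Series(libsizes, index=sample_ids, name="library_size"),
        regulator_log2=regulator_log2,
        baseline_log2=pd.Series(baseline, index=genes, name="baseline_log2"),
    )
    return matrix, annotation, karyotype, truth


def write_truth(truth: SimTruth, path) -> None:
    """Flatten the truth tables into one TSV (gene-level effects only)."""
    out = truth.cis_log2_ratio.add_prefix("cis_log2_ratio.")
    out = out.join(truth.trans_coefficient)
    out = out.join(truth.shared_effect.add_prefix("shared_effect."))
    out = out.join(truth.interaction_offset.add_prefix("interaction_offset."))
    out = out.join(truth.set_membership.astype(int).add_prefix("in_set."))
    out.to_csv(path, sep="\t", index_label="gene", float_format="%.5e")


def default_disome_design(
    n_genes: int = 2400,
    genes_per_disomic_chromosome: int = 400,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A compact version of the colony RNA-seq design: euploid reference,
    two disomes, a disome hemizygous for the regulator, a regulator
    overexpression strain and its vector control (first batch), plus a
    second batch with the euploid control and two deletion-like genotypes.

    The regulator multipliers follow the magnitudes measured in the study
    system (4.25-fold overexpression; 2.28-fold hemizygous reduction from
    the 1.90-fold disome level).
    """
    n_other = n_genes - 2 * genes_per_disomic_chromosome
    per = n_other // 4
    chromosomes = (
        ("chrA", per),
        ("chrB", per),
        ("chrC", per),
        ("chrD", n_other - 3 * per),
        ("chrXV", genes_per_disomic_chromosome),
        ("chrXVI", genes_per_disomic_chromosome),
    )
    disome_level = 1.90  # regulator sits on chrXVI, so the disome doubles it
    genotypes = (
        GenotypeSpec("F45"),
        GenotypeSpec("disomeXV", {"chrXV": 2}, shared_effect_scale=1.0),
        GenotypeSpec(
            "disomeXVI",
            {"chrXVI": 2},
            regulator_expression_multiplier=disome_level,
            shared_effect_scale=1.0,
        ),
        GenotypeSpec(
            "hemiXVI",
            {"chrXVI": 2},
            regulator_expression_multiplier=disome_level / 2.28,
            shared_effect_scale=1.0,
        ),
        GenotypeSpec("overexpression", regulator_expression_multiplier=4.25),
        GenotypeSpec("vector_control"),
    )
    cfg = dict(
        n_genes=n_genes,
        chromosomes=chromosomes,
        genotypes=genotypes,
        seed=seed,
        # a large minority of the genome responds to the regulator, as for a
        # repressor of a developmental MAPK pathway
        trans_fraction=0.3,
        trans_coefficient_sd=0.5,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
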