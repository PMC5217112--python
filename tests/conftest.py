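"""Shared fixtures: small simulated experiments and toy tables.

Everything is generated programmatically with fixed seeds; session scope
keeps the heavier simulations to one run each.
"""

import pandas as pd
import pytest

import karyodiff as kd


@pytest.fixture(scope="session")
def disome_sim():
    """Euploid + one disome, cis dosage only (no trans/shared effects)."""
    cfg = kd.SimConfig(
        n_genes=1200,
        chromosomes=(("chrA", 400), ("chrB", 300), ("chrXV", 500)),
        genotypes=(
            kd.GenotypeSpec("F45"),
            kd.GenotypeSpec("disomeXV", {"chrXV": 2}),
        ),
        replicates_per_genotype=4,
        seed=11,
        trans_fraction=0.0,
        shared_fraction=0.0,
        replicate_noise_sd=0.0,
    )
    return cfg, kd.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def disome_analysis(disome_sim):
    """Normalization + dispersions + GLM fit for the cis-only disome sim."""
    _, (counts, annotation, karyotype, truth) = disome_sim
    anno = annotation.resolve(counts.gene_ids)
    ref_mask = (anno["gene_class"] == "nuclear_ORF") & (anno["chromosome"] != "chrXV")
    norm = kd.tmm_factors(counts, ref_mask)
    dispersions = kd.estimate_dispersions(counts, None, norm)
    fit = kd.fit_glm(counts, None, norm, dispersions)
    return dict(
        counts=counts,
        annotation=annotation,
        karyotype=karyotype,
        truth=truth,
        ref_mask=ref_mask,
        norm=norm,
        dispersions=dispersions,
        fit=fit,
    )


def interaction_config(seed: int, n_interaction: int = 20) -> kd.SimConfig:
    """Four-genotype regulator design with planted nonlinear interactions:
    genes repressed twofold by BOTH the hemizygous reduction and the
    overexpression of the regulator."""
    return kd.SimConfig(
        n_genes=2000,
        chromosomes=(("chrA", 500), ("chrB", 500), ("chrC", 500), ("chrXVI", 500)),
        genotypes=(
            kd.GenotypeSpec(
                "hemiXVI",
                {"chrXVI": 2},
                regulator_expression_multiplier=1.90 / 2.28,
                shared_effect_scale=1.0,
            ),
            kd.GenotypeSpec(
                "disomeXVI",
                {"chrXVI": 2},
                regulator_expression_multiplier=1.90,
                shared_effect_scale=1.0,
            ),
            kd.GenotypeSpec("overexpression", regulator_expression_multiplier=4.25),
            kd.GenotypeSpec("vector_control"),
            kd.GenotypeSpec("F45"),
        ),
        reference_genotype="F45",
        replicates_per_genotype=4,
        seed=seed,
        trans_fraction=0.3,
        trans_coefficient_sd=0.5,
        shared_fraction=0.2,
        n_interaction_genes=n_interaction,
        interaction_offsets={"hemiXVI": -1.0, "overexpression": -1.0},
        library_size_range=(8e6, 12e6),
    )


@pytest.fixture(scope="session")
def interaction_sim():
    cfg = interaction_config(seed=7)
    return cfg, kd.simulate_experiment(cfg)


@pytest.fixture
def toy_counts():
    """A 4-gene, 4-sample hand-sized count matrix (2 genotypes x 2 reps)."""
    counts = pd.DataFrame(
        {
            "wt_r1": [100, 200, 50, 0],
            "wt_r2": [110, 190, 55, 0],
            "mut_r1": [220, 210, 45, 0],
            "mut_r2": [180, 205, 60, 0],
        },
        index=pd.Index(["YA0001", "YA0002", "YB0001", "YB0002"], name="gene"),
    )
    meta = pd.DataFrame(
        {
            "genotype": ["wt", "wt", "mut", "mut"],
            "batch": ["b1"] * 4,
            "replicate": ["1", "2", "1", "2"],
        },
        index=counts.columns,
    )
    return kd.CountMatrix(counts, meta)


@pytest.fixture
def toy_annotation():
    table = pd.DataFrame(
        {
            "chromosome": ["chrA", "chrA", "chrB", "chrB"],
            "gene_class": ["nuclear_ORF"] * 4,
        },
        index=pd.Index(["YA0001", "YA0002", "YB0001", "YB0002"], name="gene"),
    )
    return kd.GeneAnnotation(table)
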