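"""NB-GLM differential expression: dispersions, contrasts, adjustment."""

import numpy as np
import pandas as pd
import pytest

import karyodiff as kd
from karyodiff.de import _irls
from karyodiff.errors import AdjustmentError, ContrastError, DesignError, DispersionError


def _sim(seed, n_genes=600, phi=0.05, reps=4, fold_genes=(), fold=4.0, depth=2e6):
    """Two-genotype NB simulation with optional planted fold changes."""
    cfg = kd.SimConfig(
        n_genes=n_genes,
        chromosomes=(("chrA", n_genes),),
        genotypes=(kd.GenotypeSpec("wt"), kd.GenotypeSpec("mut")),
        replicates_per_genotype=reps,
        seed=seed,
        trans_fraction=0.0,
        shared_fraction=0.0,
        replicate_noise_sd=0.0,
        dispersion_model=(phi, 1.0),
        library_size_range=(depth, depth),
        baseline_log_mean_range=(2.0, 9.0),
    )
    counts, annotation, karyotype, truth = kd.simulate_experiment(cfg)
    if fold_genes:
        # plant fold changes by thinning the wt samples binomially
        rng = np.random.default_rng(seed + 10_000)
        arr = counts.counts.to_numpy().copy()
        wt_cols = [i for i, s in enumerate(counts.sample_ids) if s.startswith("wt")]
        for g in fold_genes:
            for j in wt_cols:
                arr[g, j] = rng.binomial(arr[g, j], 1.0 / fold)
        counts = kd.CountMatrix(
            pd.DataFrame(arr, index=counts.gene_ids, columns=counts.sample_ids),
            counts.sample_meta,
        )
    mask = pd.Series(True, index=counts.gene_ids)
    norm = kd.tmm_factors(counts, mask)
    return counts, annotation, karyotype, norm


class TestDispersions:
    def test_poisson_counts_give_near_zero_tagwise(self):
        counts, _, _, norm = _sim(seed=2, phi=0.0, reps=4)
        # dispersion_model=(0,1) still adds 1/mu; use truly Poisson draws
        cfg = kd.SimConfig(
            n_genes=400,
            chromosomes=(("chrA", 400),),
            genotypes=(kd.GenotypeSpec("wt"), kd.GenotypeSpec("mut")),
            replicates_per_genotype=4,
            seed=3,
            trans_fraction=0.0,
            shared_fraction=0.0,
            replicate_noise_sd=0.0,
            dispersion_model=(0.0, 0.0),
            library_size_range=(2e6, 2e6),
            baseline_log_mean_range=(4.0, 9.0),
        )
        counts, _, _, _ = kd.simulate_experiment(cfg)
        norm = kd.tmm_factors(counts, pd.Series(True, index=counts.gene_ids))
        est = kd.estimate_dispersions(counts, None, norm)
        assert est.table["tagwise"].median() < 0.02

    def test_recovers_constant_dispersion(self):
        counts, _, _, norm = _sim(seed=4, phi=0.1, n_genes=500)
        est = kd.estimate_dispersions(counts, None, norm)
        mean_counts = counts.counts.mean(axis=1)
        well_expressed = mean_counts > 50
        trended = est.table.loc[well_expressed, "trended"]
        # generator adds 1/mu on top of the 0.1 asymptote; genes above 50
        # counts sit within a few hundredths of the asymptote
        assert abs(trended.median() - 0.1) < 0.03

    def test_tagwise_between_raw_and_trended(self):
        counts, _, _, norm = _sim(seed=5)
        est = kd.estimate_dispersions(counts, None, norm)
        t = est.table.dropna()
        lo = np.minimum(t["raw"], t["trended"]) - 1e-12
        hi = np.maximum(t["raw"], t["trended"]) + 1e-12
        assert ((t["tagwise"] >= lo) & (t["tagwise"] <= hi)).all()

    def test_huge_prior_weight_collapses_to_trended(self):
        counts, _, _, norm = _sim(seed=6, n_genes=100)
        est = kd.estimate_dispersions(counts, None, norm, prior_df=1e12)
        t = est.table.dropna()
        np.testing.assert_allclose(t["tagwise"], t["trended"], rtol=1e-6)

    def test_no_replication_rejected(self):
        counts, *_ = kd.simulate_experiment(
            kd.SimConfig(
                n_genes=10,
                chromosomes=(("chrA", 10),),
                genotypes=(kd.GenotypeSpec("a"), kd.GenotypeSpec("b")),
                replicates_per_genotype=2,
                seed=1,
                library_size_range=(1e5, 1e5),
            )
        )
        solo = counts.subset_samples(["a_r1", "b_r1"])
        norm = kd.tmm_factors(solo, pd.Series(True, index=solo.gene_ids))
        with pytest.raises(DispersionError):
            kd.estimate_dispersions(solo, None, norm)


class TestGlmFit:
    def test_intercept_only_matches_weighted_mean(self):
        """With one genotype and equal offsets the NB MLE of the mean is the
        sample mean, whatever the dispersion."""
        rng = np.random.default_rng(8)
        y = rng.poisson(50, size=(20, 6)).astype(float)
        X = np.ones((6, 1))
        offsets = np.zeros(6)
        beta, mu, conv = _irls(y, X, offsets, np.full(20, 0.2))
        np.testing.assert_allclose(mu[:, 0], y.mean(axis=1), rtol=1e-6)
        assert conv.all()

    def test_null_simulation_coefficients_centered_at_zero(self):
        counts, _, _, norm = _sim(seed=9)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        diff = fit.coefficients["mut"] - fit.coefficients["wt"]
        assert abs(diff.mean()) < 0.02

    def test_all_zero_gene_flagged_not_tested(self):
        counts, _, _, norm = _sim(seed=10, n_genes=50)
        arr = counts.counts.to_numpy().copy()
        arr[0, :] = 0
        cm = kd.CountMatrix(
            pd.DataFrame(arr, index=counts.gene_ids, columns=counts.sample_ids),
            counts.sample_meta,
        )
        norm = kd.tmm_factors(cm, pd.Series(True, index=cm.gene_ids))
        est = kd.estimate_dispersions(cm, None, norm)
        fit = kd.fit_glm(cm, None, norm, est)
        assert bool(fit.all_zero.iloc[0]) is True
        profile = kd.pairwise_contrast(fit, "mut", "wt")
        assert np.isnan(profile.table["pvalue"].iloc[0])

    def test_singular_design_rejected(self):
        counts, _, _, norm = _sim(seed=11, n_genes=20)
        X = np.ones((counts.counts.shape[1], 2))  # duplicated column
        est = kd.estimate_dispersions(counts, None, norm)
        with pytest.raises(DesignError):
            kd.fit_glm(counts, (X, ["a", "b"]), norm, est)


class TestLrtContrast:
    def test_null_pvalues_roughly_uniform(self):
        counts, _, _, norm = _sim(seed=12, n_genes=2000)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        profile = kd.pairwise_contrast(fit, "mut", "wt")
        frac = (profile.table["pvalue"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_fourfold_changes_detected(self):
        planted = tuple(range(25))
        counts, _, _, norm = _sim(seed=13, fold_genes=planted, fold=4.0)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        profile = kd.pairwise_contrast(fit, "mut", "wt")
        fdr = profile.fdr.iloc[list(planted)]
        assert (fdr < 0.01).mean() >= 0.95

    def test_weighted_pairwise_equals_two_group_reduction(self):
        """A (+1, -1) weighted LRT is the same test as the explicit
        two-group reduced model."""
        counts, _, _, norm = _sim(seed=14, n_genes=300)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        p_weighted = kd.lrt_contrast(fit, [("mut", 1.0), ("wt", -1.0)])
        # explicit reduced model: single shared mean
        X_red = np.ones((counts.counts.shape[1], 1))
        y = counts.counts.to_numpy(dtype=float)
        from karyodiff.de import _nb_deviance

        beta_r, mu_r, _ = _irls(
            y, X_red, fit.offsets, fit.dispersions.to_numpy()
        )
        dev_red = _nb_deviance(y, mu_r, fit.dispersions.to_numpy())
        from scipy import stats as sps

        stat = np.maximum(dev_red - fit.deviance.to_numpy(), 0)
        p_direct = sps.chi2.sf(stat, 1)
        np.testing.assert_allclose(
            p_weighted.table["pvalue"], p_direct, rtol=1e-6, atol=1e-12
        )

    def test_symmetry_under_genotype_swap(self):
        counts, _, _, norm = _sim(seed=15, n_genes=200)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        ab = kd.pairwise_contrast(fit, "mut", "wt")
        ba = kd.pairwise_contrast(fit, "wt", "mut")
        np.testing.assert_allclose(ab.log2fc, -ba.log2fc, atol=1e-8)
        np.testing.assert_allclose(
            ab.table["pvalue"], ba.table["pvalue"], atol=1e-8
        )

    def test_all_zero_weights_rejected(self):
        counts, _, _, norm = _sim(seed=16, n_genes=50)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        with pytest.raises(ContrastError):
            kd.lrt_contrast(fit, [("mut", 0.0), ("wt", 0.0)])


class TestDoubledFactorTesting:
    def test_pure_cis_disome_centres_at_zero_under_doubling(self):
        """With the doubled-factor normalization, genes on a purely
        dosage-doubled chromosome test as unchanged (median log2FC ~ 0)."""
        medians = []
        for seed in (31, 32, 33):
            cfg = kd.SimConfig(
                n_genes=900,
                chromosomes=(("chrA", 300), ("chrB", 300), ("chrXV", 300)),
                genotypes=(
                    kd.GenotypeSpec("F45"),
                    kd.GenotypeSpec("disomeXV", {"chrXV": 2}),
                ),
                replicates_per_genotype=4,
                seed=seed,
                trans_fraction=0.0,
                shared_fraction=0.0,
                replicate_noise_sd=0.0,
            )
            counts, annotation, karyotype, _ = kd.simulate_experiment(cfg)
            anno = annotation.resolve(counts.gene_ids)
            ref_mask = (anno["gene_class"] == "nuclear_ORF") & (
                anno["chromosome"] != "chrXV"
            )
            norm = kd.tmm_factors(counts, ref_mask)
            doubled = kd.doubled_factor_variant(
                norm, counts.samples_for("disomeXV")
            )
            est = kd.estimate_dispersions(counts, None, doubled)
            fit = kd.fit_glm(counts, None, doubled, est)
            profile = kd.pairwise_contrast(fit, "disomeXV", "F45")
            on_xv = (anno["chromosome"] == "chrXV").to_numpy()
            medians.append(profile.log2fc[on_xv].median())
        assert abs(np.mean(medians)) < 0.05


class TestSdReduction:
    def test_shared_effects_inflate_disome_vs_euploid_spread(self):
        """With shared (karyotype-independent) effects on top of cis dosage,
        the SD of disome:euploid log2 ratios on the disomic chromosome
        exceeds the SD of disome:disome ratios, where the shared component
        cancels."""
        cfg = kd.SimConfig(
            n_genes=1200,
            chromosomes=(("chrA", 400), ("chrXV", 400), ("chrXVI", 400)),
            genotypes=(
                kd.GenotypeSpec("F45"),
                kd.GenotypeSpec("disomeXV", {"chrXV": 2}, shared_effect_scale=1.0),
                kd.GenotypeSpec("disomeXVI", {"chrXVI": 2}, shared_effect_scale=1.0),
            ),
            replicates_per_genotype=4,
            seed=41,
            trans_fraction=0.0,
            shared_fraction=0.5,
            shared_effect_sd=0.5,
        )
        counts, annotation, karyotype, _ = kd.simulate_experiment(cfg)
        anno = annotation.resolve(counts.gene_ids)
        ref_mask = (anno["gene_class"] == "nuclear_ORF") & ~anno["chromosome"].isin(
            ["chrXV", "chrXVI"]
        )
        norm = kd.tmm_factors(counts, ref_mask)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        vs_euploid = kd.pairwise_contrast(fit, "disomeXV", "F45")
        vs_disome = kd.pairwise_contrast(fit, "disomeXV", "disomeXVI")
        on_xv = (anno["chromosome"] == "chrXV").to_numpy()
        sd_euploid = vs_euploid.log2fc[on_xv].std()
        sd_disome = vs_disome.log2fc[on_xv].std()
        assert sd_euploid > sd_disome


class TestCopyAdjust:
    def _profile(self, genes, log2fc):
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "adjusted_log2fc": log2fc,
                "pvalue": 0.5,
                "fdr": 0.5,
                "mean_logcpm": 5.0,
            },
            index=pd.Index(genes, name="gene"),
        )
        return kd.DifferentialProfile(table, ("disomeXV", "F45"))

    def _karyotype(self):
        copies = pd.DataFrame(
            {"chrXV": [1.0, 2.0], "chrII": [1.0, 1.0]},
            index=["F45", "disomeXV"],
        )
        return kd.Karyotype("F45", copies)

    def _annotation(self):
        return kd.GeneAnnotation(
            pd.DataFrame(
                {
                    "chromosome": ["chrXV", "chrII", "unplaced"],
                    "gene_class": ["nuclear_ORF", "nuclear_ORF", "nonreference"],
                },
                index=pd.Index(["YOL001W", "YBL001C", "59A_0034g"], name="gene"),
            )
        )

    def test_ratio_two_subtracts_one(self):
        profile = self._profile(["YOL001W", "YBL001C", "59A_0034g"], [1.0, 0.3, 2.0])
        adjusted = kd.copy_adjust(profile, self._karyotype(), self._annotation())
        assert adjusted.adjusted_log2fc["YOL001W"] == pytest.approx(0.0)
        # ratio 1 chromosome unchanged
        assert adjusted.adjusted_log2fc["YBL001C"] == pytest.approx(0.3)
        # unplaced genes are never adjusted
        assert adjusted.adjusted_log2fc["59A_0034g"] == pytest.approx(2.0)

    def test_missing_chromosome_rejected(self):
        profile = self._profile(["YOL001W"], [1.0])
        ann = kd.GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chrXII"], "gene_class": ["nuclear_ORF"]},
                index=pd.Index(["YOL001W"], name="gene"),
            )
        )
        with pytest.raises(AdjustmentError):
            kd.copy_adjust(profile, self._karyotype(), ann)


class TestSignificantGenes:
    def _profile(self):
        table = pd.DataFrame(
            {
                "log2fc": [1.4, 0.6, -2.0, -1.4, 1.5],
                "adjusted_log2fc": [1.4, 0.6, -2.0, -1.4, 1.5],
                "pvalue": [1e-4, 1e-4, 1e-4, 0.5, 1e-4],
                "fdr": [0.005, 0.005, 0.005, 0.6, 0.02],
                "mean_logcpm": 5.0,
            },
            index=pd.Index(["up_big", "up_small", "down_big", "down_ns", "up_weak_fdr"], name="gene"),
        )
        return kd.DifferentialProfile(table)

    def test_thresholds(self):
        up, down = kd.significant_genes(self._profile(), fdr=0.01, min_fold=2)
        assert up == ["up_big"]  # 1.4 >= log2(2), FDR ok
        assert down == ["down_big"]

    def test_min_fold_one_returns_all_significant(self):
        up, down = kd.significant_genes(self._profile(), fdr=0.01, min_fold=1)
        assert set(up) == {"up_big", "up_small"}
        assert down == ["down_big"]
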