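"""TLS geometry, the predicted-slope model, quadrant enrichment, and the
second-PC interaction contrast."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import karyodiff as kd
from karyodiff.dosage import quadrant_table
from karyodiff.errors import DegenerateFitError, DesignError, KaryodiffError


def _profile_from(values, genes=None):
    genes = genes or [f"Y{i:04d}" for i in range(len(values))]
    table = pd.DataFrame(
        {
            "log2fc": values,
            "adjusted_log2fc": values,
            "pvalue": 0.5,
            "fdr": 0.5,
            "mean_logcpm": 5.0,
        },
        index=pd.Index(genes, name="gene"),
    )
    return kd.DifferentialProfile(table)


class TestChromosomeSummary:
    def test_exact_twofold_chromosome(self):
        ann = kd.GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chrXV"] * 3 + ["chrI"] * 2,
                 "gene_class": ["nuclear_ORF"] * 5},
                index=pd.Index([f"Y{i}" for i in range(5)], name="gene"),
            )
        )
        profile = _profile_from([1.0, 1.0, 1.0, 0.0, 0.1], list(ann.table.index))
        summary = kd.chromosome_summary(profile, ann)
        assert summary.loc["chrXV", "median_fold_change"] == pytest.approx(2.0)
        assert summary.loc["chrXV", "sd_log2fc"] == pytest.approx(0.0)
        assert summary.loc["chrXV", "n_genes"] == 3

    def test_simulated_disome_median_near_two(self, disome_analysis):
        d = disome_analysis
        profile = kd.pairwise_contrast(d["fit"], "disomeXV", "F45")
        anno = d["annotation"].resolve(profile.genes)
        summary = kd.chromosome_summary(
            profile, d["annotation"], anno["gene_class"] == "nuclear_ORF"
        )
        assert 1.9 < summary.loc["chrXV", "median_fold_change"] < 2.1
        assert 0.9 < summary.loc["chrA", "median_fold_change"] < 1.1

    def test_empty_chromosome_omitted_with_warning(self):
        ann = kd.GeneAnnotation(
            pd.DataFrame(
                {"chromosome": ["chrI", "chrII"], "gene_class": ["nuclear_ORF"] * 2},
                index=pd.Index(["Y1", "Y2"], name="gene"),
            )
        )
        profile = _profile_from([0.5, np.nan], ["Y1", "Y2"])
        with pytest.warns(UserWarning, match="chrII"):
            summary = kd.chromosome_summary(profile, ann)
        assert "chrII" not in summary.index


def oracle_tls_slope(x, y, grid=20001):
    """Grid search minimising total squared orthogonal distance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx, cy = x.mean(), y.mean()
    best, best_cost = None, np.inf
    for theta in np.linspace(-np.pi / 2 + 1e-6, np.pi / 2 - 1e-6, grid):
        s = np.tan(theta)
        # orthogonal distance to line through centroid with slope s
        d2 = ((y - cy) - s * (x - cx)) ** 2 / (1 + s * s)
        cost = d2.sum()
        if cost < best_cost:
            best, best_cost = s, cost
    return best


class TestTlsFit:
    def test_exact_line(self):
        fit = kd.tls_fit([0.0, 1.0, 2.0], [0.0, -1.0, -2.0])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=150)
        x = t + rng.normal(scale=0.1, size=150)
        y = -0.7 * t + rng.normal(scale=0.1, size=150)
        f_xy = kd.tls_fit(x, y)
        f_yx = kd.tls_fit(y, x)
        assert f_yx.slope == pytest.approx(1.0 / f_xy.slope, rel=1e-6)

    def test_recovers_orthogonal_slope_vs_grid_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        slope_true = -0.6
        direction = np.array([1.0, slope_true]) / np.hypot(1, slope_true)
        pts = np.outer(t, direction)
        pts += rng.normal(scale=0.05, size=pts.shape)  # isotropic noise
        fit = kd.tls_fit(pts[:, 0], pts[:, 1])
        assert abs(fit.slope - slope_true) < 0.03
        oracle = oracle_tls_slope(pts[:, 0], pts[:, 1])
        assert abs(fit.slope - oracle) < 5e-4

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            kd.tls_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_rotation_orthonormal_and_invertible(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = -0.5 * x + rng.normal(scale=0.2, size=50)
        fit = kd.tls_fit(x, y)
        r = fit.rotation
        np.testing.assert_allclose(r @ r.T, np.eye(2), atol=1e-10)
        scores = kd.pc_scores(pd.Series(x), pd.Series(y), fit)
        back = scores.to_numpy() @ r  # inverse rotation (orthonormal)
        np.testing.assert_allclose(back[:, 0], x - fit.center[0], atol=1e-10)
        np.testing.assert_allclose(back[:, 1], y - fit.center[1], atol=1e-10)


class TestExpectedSlope:
    @pytest.mark.parametrize(
        "r_up,r_down,expected",
        [(4.25, 2.28, -0.57), (2.0, 2.0, -1.0), (4.0, 2.0, -0.5)],
    )
    def test_values(self, r_up, r_down, expected):
        assert round(kd.expected_slope(r_up, r_down), 2) == expected

    def test_base_invariance(self):
        a = -np.log(2.28) / np.log(4.25)
        b = -np.log2(2.28) / np.log2(4.25)
        assert a == pytest.approx(b, rel=1e-14)
        assert kd.expected_slope(4.25, 2.28) == pytest.approx(a)

    @pytest.mark.parametrize("bad", [(1.0, 2.0), (2.0, 0.5)])
    def test_domain_errors(self, bad):
        with pytest.raises(KaryodiffError):
            kd.expected_slope(*bad)


class TestPcScores:
    def test_point_on_line_has_zero_pc2(self):
        fit = kd.tls_fit([0.0, 1.0, 2.0, 0.5], [0.0, -1.0, -2.0, -0.5])
        scores = kd.pc_scores(pd.Series([1.5]), pd.Series([-1.5]), fit)
        assert scores["PC2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_center_maps_to_origin(self):
        fit = kd.tls_fit([0.0, 1.0, 2.0], [1.0, 0.0, -1.0])
        scores = kd.pc_scores(
            pd.Series([fit.center[0]]), pd.Series([fit.center[1]]), fit
        )
        np.testing.assert_allclose(scores.iloc[0], 0.0, atol=1e-12)

    def test_planted_orthogonal_outlier_distance(self):
        """A point displaced orthogonally by d from the line scores |PC2|=d,
        with sign positive for +y displacement."""
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = -0.5 * x
        fit = kd.tls_fit(x, y)
        d = 0.8
        normal = np.array([0.5, 1.0]) / np.hypot(0.5, 1.0)  # unit normal, +y side
        px, py = 1.0 + d * normal[0], -0.5 + d * normal[1]
        scores = kd.pc_scores(pd.Series([px]), pd.Series([py]), fit)
        assert scores["PC2"].iloc[0] == pytest.approx(d, abs=1e-12)


def oracle_fisher_two_tailed(a, b, c, d):
    """Brute force: enumerate every table with the same margins, sum the
    hypergeometric probabilities not exceeding the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-10):
            total += pk
    return min(total, 1.0)


class TestQuadrantEnrichment:
    def test_printed_contingency_table(self):
        # 29 of 2197 quadrant genes in the motif set vs 12 of 4388 outside
        _, p = kd.fisher_exact_two_tailed([[29, 2197 - 29], [12, 4388 - 12]])
        assert p <= 1.1e-06

    def test_proportional_table_p_one(self):
        _, p = kd.fisher_exact_two_tailed([[10, 90], [100, 900]])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = kd.fisher_exact_two_tailed([[a, b], [c, d]])
            assert p == pytest.approx(oracle_fisher_two_tailed(a, b, c, d), rel=1e-9)

    def test_quadrant_table_construction(self):
        x = pd.Series([-1.0, -0.5, 0.5, -2.0], index=list("abcd"))
        y = pd.Series([1.0, -0.5, 1.0, 2.0], index=list("abcd"))
        gs = kd.GeneSet("m", ("a", "c"))
        table = quadrant_table(x, y, gs, (-1, 1))
        # quadrant (-x, +y): a and d; a in set
        np.testing.assert_array_equal(table, [[1, 1], [1, 1]])

    def test_empty_quadrant_warns_p_one(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        y = pd.Series([1.0, 2.0], index=list("ab"))
        gs = kd.GeneSet("m", ("a",))
        with pytest.warns(UserWarning, match="quadrant"):
            _, p = kd.quadrant_enrichment(x, y, gs, (-1, 1))
        assert p == 1.0


class TestSecondPcContrast:
    def test_slope_zero_limit_equals_pairwise(self, disome_analysis):
        """As |slope| -> 0 the weighted contrast reduces to the pairwise
        hemizygote-vs-disome test (here: the two genotypes available)."""
        fit = disome_analysis["fit"]
        prof_pair = kd.pairwise_contrast(fit, "disomeXV", "F45")
        prof_w = kd.lrt_contrast(fit, [("disomeXV", 1.0), ("F45", -1.0)])
        np.testing.assert_allclose(
            prof_pair.table["pvalue"], prof_w.table["pvalue"], atol=1e-12
        )

    def test_missing_genotype_rejected(self, disome_analysis):
        with pytest.raises(DesignError):
            kd.second_pc_contrast(
                disome_analysis["fit"], -0.5, ("a", "b", "c", "d")
            )


class TestInteractionDetection:
    def test_planted_interaction_genes_recovered(self, interaction_sim):
        """Genes repressed twofold by BOTH regulator perturbations violate
        the proportional model and are flagged with high precision/recall."""
        cfg, (counts, annotation, karyotype, truth) = interaction_sim
        anno = annotation.resolve(counts.gene_ids)
        mask = (anno["gene_class"] == "nuclear_ORF") & (
            anno["chromosome"] != "chrXVI"
        )
        norm = kd.tmm_factors(counts, mask)
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        y_prof = kd.pairwise_contrast(fit, "hemiXVI", "disomeXVI")
        x_prof = kd.pairwise_contrast(fit, "overexpression", "vector_control")
        tls = kd.tls_fit(x_prof.log2fc, y_prof.log2fc)
        assert -0.7 < tls.slope < -0.35
        order = ("hemiXVI", "disomeXVI", "overexpression", "vector_control")
        with pytest.raises(DesignError):
            kd.second_pc_contrast(fit, abs(tls.slope), order)
        _, cls = kd.second_pc_contrast(fit, tls.slope, order)
        hits = set(cls.index[cls["twofold_deviation"]])
        true_genes = set(
            truth.interaction_offset.index[truth.interaction_offset["hemiXVI"] != 0]
        )
        tp = len(hits & true_genes)
        assert tp / max(len(hits), 1) >= 0.8  # precision
        assert tp / len(true_genes) >= 0.8  # recall
        # both perturbations repress: classified lower than expected
        assert (
            cls.loc[sorted(hits & true_genes), "direction"]
            == "lower_than_expected"
        ).all()

    def test_null_identity_genes_uniform_p(self):
        """Genes whose four genotype means satisfy the weight identity
        exactly produce uniform LRT p-values."""
        from scipy.stats import kstest

        cfg = kd.SimConfig(
            n_genes=2000,
            chromosomes=(("chrA", 2000),),
            genotypes=(
                kd.GenotypeSpec("hemi", regulator_expression_multiplier=1 / 2.28),
                kd.GenotypeSpec("disome"),
                kd.GenotypeSpec("over", regulator_expression_multiplier=4.25),
                kd.GenotypeSpec("control"),
            ),
            replicates_per_genotype=4,
            seed=21,
            trans_fraction=0.5,
            trans_coefficient_sd=0.5,
            shared_fraction=0.0,
            replicate_noise_sd=0.0,
            library_size_range=(5e6, 5e6),
            baseline_log_mean_range=(3.0, 9.0),
        )
        counts, annotation, karyotype, truth = kd.simulate_experiment(cfg)
        norm = kd.tmm_factors(counts, pd.Series(True, index=counts.gene_ids))
        est = kd.estimate_dispersions(counts, None, norm)
        fit = kd.fit_glm(counts, None, norm, est)
        slope = kd.expected_slope(4.25, 2.28)
        profile, _ = kd.second_pc_contrast(
            fit, slope, ("hemi", "disome", "over", "control")
        )
        pv = profile.table["pvalue"].dropna()
        assert kstest(pv, "uniform").pvalue > 0.01
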