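"""Generator behaviour: LD structure, heritability wiring, cohorts, rare variants."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, kstest, ttest_ind

from twaskit.io import read_truth_json, write_truth_json
from twaskit.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_genotypes,
    simulate_gwas_cohorts,
    simulate_rare_variants,
    simulate_reference_panel,
)


def copula_pair_oracle(rho, maf, n, seed):
    """Independent Monte-Carlo oracle: dosage correlation of two variants whose
    latent normals correlate at `rho`, thresholded at HWE genotype quantiles."""
    from scipy.special import ndtri

    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    t0 = ndtri((1 - maf) ** 2)
    t1 = ndtri(1 - maf**2)
    d1 = (z1 > t0).astype(float) + (z1 > t1)
    d2 = (z2 > t0).astype(float) + (z2 > t1)
    return np.corrcoef(d1, d2)[0, 1]


class TestGenotypes:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=4, seed=9)
        a = simulate_genotypes(cfg, 100)
        b = simulate_genotypes(cfg, 100)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_dosages_are_hard_calls(self):
        cfg = SimulationConfig(n_genes=3, seed=1)
        g = simulate_genotypes(cfg, 50)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}

    def test_independent_variants_uncorrelated(self):
        n = 2000
        cfg = SimulationConfig(n_genes=4, snps_per_gene=5, ld_rho=0.0, seed=2)
        g = simulate_genotypes(cfg, n)
        r = np.corrcoef(g.dosages, rowvar=False)
        off = r[~np.eye(r.shape[0], dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_high_ld_adjacent_correlation(self):
        n = 2000
        cfg = SimulationConfig(
            n_genes=2, snps_per_gene=4, genes_per_block=1, ld_rho=0.99,
            maf_range=(0.3, 0.3), seed=3,
        )
        g = simulate_genotypes(cfg, n)
        r = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        oracle = copula_pair_oracle(0.99, 0.3, 200_000, seed=11)
        assert r > 0.9
        assert r == pytest.approx(oracle, abs=0.05)

    def test_empirical_maf_matches_drawn(self):
        cfg = SimulationConfig(n_genes=10, seed=4)
        g = simulate_genotypes(cfg, 800)
        np.testing.assert_allclose(
            g.alt_freq(), g.variants["true_maf"].to_numpy(), atol=0.05
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(ld_rho=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(prevalence=0.0)
        cfg = SimulationConfig()
        with pytest.raises(ConfigurationError):
            simulate_genotypes(cfg, 0)


class TestReferencePanel:
    def test_null_gene_independent_of_genotype(self):
        cfg = SimulationConfig(n_genes=10, h2_cis_range=(0.0, 0.0), seed=5)
        g = simulate_genotypes(cfg, 300)
        expr, _, _ = simulate_reference_panel(cfg, g)
        e = expr["T0"]
        rs = []
        for gi in range(e.n_genes):
            for j in range(g.n_variants):
                if g.dosages[:, j].std() > 0:
                    rs.append(np.corrcoef(e.values[gi], g.dosages[:, j])[0, 1])
        # null correlations: sd ≈ 1/sqrt(n)
        assert np.abs(rs).max() < 6 / np.sqrt(300)

    def test_high_h2_single_causal_recovers_r2(self):
        cfg = SimulationConfig(
            n_genes=4, h2_cis_range=(0.99, 0.99), n_causal_snps_per_gene=1, seed=6
        )
        g = simulate_genotypes(cfg, 1000)
        expr, _, truth = simulate_reference_panel(cfg, g)
        e = expr["T0"]
        vid_col = {v: j for j, v in enumerate(g.variants["variant_id"])}
        for gi in range(e.n_genes):
            gid = e.genes.loc[gi, "gene_id"]
            (v, _), = truth.eqtl_effects["T0"][gid]
            r2 = np.corrcoef(e.values[gi], g.dosages[:, vid_col[v]])[0, 1] ** 2
            assert r2 > 0.9

    def test_expression_variance_tracks_h2(self):
        cfg = SimulationConfig(n_genes=40, h2_cis_range=(0.3, 0.3), seed=7)
        g = simulate_genotypes(cfg, 500)
        expr, _, truth = simulate_reference_panel(cfg, g)
        e = expr["T0"]
        vid_col = {v: j for j, v in enumerate(g.variants["variant_id"])}
        h2_emp = []
        for gi in range(e.n_genes):
            gid = e.genes.loc[gi, "gene_id"]
            genetic = np.zeros(500)
            for v, b in truth.eqtl_effects["T0"][gid]:
                genetic += b * g.dosages[:, vid_col[v]]
            h2_emp.append(genetic.var() / e.values[gi].var())
        assert np.mean(h2_emp) == pytest.approx(0.3, abs=0.05)

    def test_no_enrichment_when_or_is_one(self):
        cfg = SimulationConfig(
            n_genes=60, annotation_enrichment_or=1.0, annotation_baseline_rate=0.3, seed=8
        )
        g = simulate_genotypes(cfg, 50)
        _, ann, truth = simulate_reference_panel(cfg, g)
        causal = {
            v for genes in truth.eqtl_effects.values() for lst in genes.values() for v, _ in lst
        }
        flags = ann.set_index("variant_id")["annotated"]
        causal_rate = flags[list(causal)].mean()
        # binomial CI around the baseline rate
        n_causal = len(causal)
        assert abs(causal_rate - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n_causal)

    def test_enrichment_when_or_large(self):
        cfg = SimulationConfig(
            n_genes=80, annotation_enrichment_or=8.0, annotation_baseline_rate=0.2, seed=9
        )
        g = simulate_genotypes(cfg, 50)
        _, ann, truth = simulate_reference_panel(cfg, g)
        causal = {
            v for genes in truth.eqtl_effects.values() for lst in genes.values() for v, _ in lst
        }
        flags = ann.set_index("variant_id")["annotated"]
        background = flags[~flags.index.isin(causal)].mean()
        assert flags[list(causal)].mean() > background + 0.2

    def test_panel_b_shares_truth(self):
        cfg = SimulationConfig(n_genes=10, seed=10)
        ga = simulate_genotypes(cfg, 200)
        _, _, truth = simulate_reference_panel(cfg, ga)
        gb = simulate_genotypes(cfg, 150, rng=np.random.default_rng(12345))
        _, _, truth_b = simulate_reference_panel(cfg, gb, truth=truth, panel="B")
        assert truth_b.eqtl_effects == truth.eqtl_effects

    def test_truth_round_trips_through_json(self, tmp_path, small_config):
        g = simulate_genotypes(small_config, 100)
        _, _, truth = simulate_reference_panel(small_config, g)
        path = tmp_path / "truth.json"
        write_truth_json(truth, path)
        back = read_truth_json(path)
        assert back.eqtl_effects == truth.eqtl_effects
        assert back.causal_genes == truth.causal_genes
        assert back.annotation_flags == truth.annotation_flags
        assert back.h2_cis == truth.h2_cis


class TestCohorts:
    def test_requested_counts_honoured(self):
        cfg = SimulationConfig(
            n_genes=6, n_cohorts=2, cohort_sizes=[(100, 100), (200, 300)], seed=11
        )
        g = simulate_genotypes(cfg, 100)
        _, _, truth = simulate_reference_panel(cfg, g)
        cohorts = simulate_gwas_cohorts(cfg, truth)
        got = [
            (int(p["status"].sum()), int((1 - p["status"]).sum())) for _, p in cohorts
        ]
        assert got == [(100, 100), (200, 300)]

    def test_null_model_case_control_frequencies_match(self):
        cfg = SimulationConfig(
            n_genes=8, causal_gene_fraction=0.0, cohort_sizes=[(400, 400)],
            n_cohorts=1, seed=12,
        )
        g = simulate_genotypes(cfg, 100)
        _, _, truth = simulate_reference_panel(cfg, g)
        assert truth.causal_genes == {}
        (geno, pheno), = simulate_gwas_cohorts(cfg, truth)
        status = pheno["status"].to_numpy()
        ps = []
        for j in range(geno.n_variants):
            tab = np.zeros((2, 3))
            for s in (0, 1):
                for d in (0, 1, 2):
                    tab[s, d] = np.sum((status == s) & (geno.dosages[:, j] == d))
            tab = tab[:, tab.sum(axis=0) > 0]
            ps.append(chi2_contingency(tab)[1])
        # per-variant chi-square P approximately uniform under the null
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_causal_gene_shifts_case_grex(self):
        cfg = SimulationConfig(
            n_genes=6, causal_gene_fraction=0.5, liability_effect_sd=1.0,
            cohort_sizes=[(500, 500)], n_cohorts=1, seed=13,
        )
        g = simulate_genotypes(cfg, 100)
        _, _, truth = simulate_reference_panel(cfg, g)
        (geno, pheno), = simulate_gwas_cohorts(cfg, truth)
        status = pheno["status"].to_numpy()
        vid_col = {v: j for j, v in enumerate(geno.variants["variant_id"])}
        # liability-threshold oracle: signed mean shift of the genetic score
        shift = 0.0
        for gid, a in truth.causal_genes.items():
            grex = np.zeros(geno.n_samples)
            for v, b in truth.eqtl_effects["T0"][gid]:
                grex += b * geno.dosages[:, vid_col[v]]
            shift += a * (grex[status == 1].mean() - grex[status == 0].mean())
        assert shift > 0


class TestRareVariants:
    def test_population_maf_below_one_percent(self):
        cfg = SimulationConfig(n_genes=10, seed=14)
        geno, ann, pheno, _ = simulate_rare_variants(cfg, n=500)
        assert (ann["maf"] < 0.01).all()
        assert set(ann["class"]) <= {"LoF", "clinvar_pathogenic", "missense_damaging", "benign"}

    def test_null_effects_balanced(self):
        cfg = SimulationConfig(n_genes=10, seed=15)
        geno, ann, pheno, _ = simulate_rare_variants(cfg, n=3000, effect_genes={})
        carrier = (geno.dosages > 0).any(axis=1)
        t = ttest_ind(pheno["trait_0"][carrier], pheno["trait_0"][~carrier])
        assert t.pvalue > 0.001

    def test_carrier_shift_recovered(self):
        cfg = SimulationConfig(n_genes=10, rare_maf_range=(0.005, 0.009), seed=16)
        geno, ann, pheno, truth = simulate_rare_variants(
            cfg, n=4000, effect_genes={"G0000": ("trait_0", 1.0)}
        )
        vmask = ((ann["gene"] == "G0000") & (ann["class"] != "benign")).to_numpy()
        carrier = (geno.dosages[:, vmask] > 0).any(axis=1)
        assert carrier.sum() >= 50
        diff = pheno["trait_0"][carrier].mean() - pheno["trait_0"][~carrier].mean()
        se = np.sqrt(
            pheno["trait_0"][carrier].var() / carrier.sum()
            + pheno["trait_0"][~carrier].var() / (~carrier).sum()
        )
        assert abs(diff - 1.0) < 3 * se
        assert truth.rare_effects == {"G0000": [("trait_0", 1.0)]}

    def test_expected_carrier_count(self):
        cfg = SimulationConfig(n_genes=1, rare_maf_range=(0.009, 0.009), seed=17)
        geno, ann, _, _ = simulate_rare_variants(cfg, n=10_000, n_rare_per_gene=1)
        expected = (1 - (1 - 0.009) ** 2) * 10_000  # ≈ 179
        carriers = int((geno.dosages[:, 0] > 0).sum())
        assert abs(carriers - expected) < 4 * np.sqrt(expected)
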