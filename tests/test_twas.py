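"""GReX imputation, association, meta-analysis, merging and novelty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from twaskit.datatypes import ModelEntry, PredictionModelSet
from twaskit.twas import (
    MergeCounts,
    annotate_novelty,
    associate_grex,
    bonferroni_threshold,
    impute_grex,
    merge_panels,
    meta_analyze,
    twas_genes,
)

from conftest import make_genotypes


def _model(weights, vids=None, ref="A", alt="G", gene="g1", tissue="T0", panel="A"):
    vids = vids or [f"v{j}" for j in range(len(weights))]
    return ModelEntry(
        gene=gene, tissue=tissue, panel=panel, variant_ids=vids,
        weights=np.asarray(weights, dtype=float),
        ref=[ref] * len(vids), alt=[alt] * len(vids),
        intercept=0.0, cv_r2=0.5, cv_r2_var=0.5, n_train=100,
    )


class TestImputeGrex:
    def test_hand_dot_product(self):
        g = make_genotypes(np.array([[2.0, 1.0]]))
        ms = PredictionModelSet()
        ms.add(_model([0.5, -1.0]))
        grex = impute_grex(g, ms)
        assert grex.values[0, 0] == pytest.approx(0.0)

    def test_all_zero_weights(self):
        g = make_genotypes(np.array([[1.0, 2.0], [0.0, 1.0]]))
        ms = PredictionModelSet()
        ms.add(_model([0.0, 0.0]))
        grex = impute_grex(g, ms)
        np.testing.assert_array_equal(grex.values[:, 0], [0.0, 0.0])

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(30, 2)).astype(float)
        ms = PredictionModelSet()
        ms.add(_model([0.7, -0.2]))
        straight = impute_grex(make_genotypes(d), ms)
        flipped_geno = make_genotypes(2.0 - d, ref="G", alt="A")
        flipped = impute_grex(flipped_geno, ms)
        np.testing.assert_allclose(flipped.values, straight.values, atol=1e-12)

    def test_low_coverage_model_skipped(self):
        g = make_genotypes(np.ones((5, 1)))
        ms = PredictionModelSet()
        ms.add(_model([0.5, 0.5, 0.5], vids=["v0", "missing1", "missing2"]))
        grex = impute_grex(g, ms, coverage_floor=0.5)
        assert grex.values.shape[1] == 0
        grex = impute_grex(g, ms, coverage_floor=0.2)
        assert grex.values.shape[1] == 1
        assert grex.coverage[("g1", "T0", "A")] == pytest.approx(1 / 3)


class TestAssociateGrex:
    def _grex(self, values):
        from twaskit.twas import GReXMatrix

        n = values.shape[0]
        cols = [(f"g{j}", "T0", "A") for j in range(values.shape[1])]
        return GReXMatrix([f"s{i}" for i in range(n)], cols, values)

    def test_permutation_destroys_signal(self):
        rng = np.random.default_rng(1)
        n = 400
        x = rng.normal(size=(n, 1))
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x[:, 0]))).astype(float)
        true_z = associate_grex(self._grex(x), y)["z"].iloc[0]
        assert abs(true_z) > 5
        zs = []
        for rep in range(20):
            yp = rng.permutation(y)
            tab = associate_grex(self._grex(x), yp)
            zs.append(abs(tab["z"].iloc[0]))
        assert np.median(zs) < 2

    def test_sign_matches_generating_model(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=(n, 1))
        lin = 0.8 * x[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float)
        tab = associate_grex(self._grex(x), y)
        assert tab["z"].iloc[0] > 3

    def test_constant_column_skipped(self):
        rng = np.random.default_rng(3)
        vals = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = (rng.random(100) < 0.5).astype(float)
        tab = associate_grex(self._grex(vals), y)
        assert list(tab["gene"]) == ["g1"]

    def test_requires_min_cases(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 1))
        y = np.r_[np.ones(5), np.zeros(25)]
        with pytest.raises(ValueError):
            associate_grex(self._grex(x), y)

    def test_covariates_accepted(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=(n, 1))
        cov = rng.normal(size=(n, 2))
        y = (rng.random(n) < 0.4).astype(float)
        tab = associate_grex(self._grex(x), y, covariates=cov)
        assert len(tab) == 1 and np.isfinite(tab["p"].iloc[0])


def _tab(rows):
    return pd.DataFrame(
        rows, columns=["gene", "tissue", "panel", "beta", "se", "z", "p", "n_case", "n_control"]
    )


class TestMetaAnalyze:
    def test_identical_cohorts_closed_form(self):
        row = ["g1", "T0", "A", 0.5, 0.2, 2.5, 0.0124, 100, 100]
        meta = meta_analyze([_tab([row]), _tab([row]), _tab([row]), _tab([row])])
        assert meta["beta"].iloc[0] == pytest.approx(0.5)
        assert meta["se"].iloc[0] == pytest.approx(0.2 / 2.0)
        assert meta["Q"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_effects(self):
        a = _tab([["g1", "T0", "A", 1.0, 1.0, 1.0, 0.32, 50, 50]])
        b = _tab([["g1", "T0", "A", -1.0, 1.0, -1.0, 0.32, 50, 50]])
        meta = meta_analyze([a, b])
        assert meta["beta"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert meta["Q"].iloc[0] == pytest.approx(2.0)
        assert meta["I2"].iloc[0] == pytest.approx(0.5)

    def test_inverse_variance_weighting(self):
        a = _tab([["g1", "T0", "A", 1.0, 0.5, 2.0, 0.05, 50, 50]])
        b = _tab([["g1", "T0", "A", 0.0, 1.0, 0.0, 1.0, 50, 50]])
        meta = meta_analyze([a, b])
        # weights 4:1 → beta = 4/5
        assert meta["beta"].iloc[0] == pytest.approx(0.8)

    def test_single_cohort_passthrough(self):
        a = _tab([["g1", "T0", "A", 0.3, 0.1, 3.0, 0.0027, 70, 80]])
        meta = meta_analyze([a])
        assert meta["beta"].iloc[0] == pytest.approx(0.3)
        assert np.isnan(meta["Q"].iloc[0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            meta_analyze([_tab([["g1", "T0", "A", 0, 1, 0, 1, 10, 10]])], method="random")


class TestMergePanels:
    def _records(self, pairs, panel, p=1e-4):
        return pd.DataFrame(
            [
                {"gene": g, "tissue": t, "panel": panel, "beta": 0.1, "se": 0.05,
                 "z": 2.0, "p": p}
                for g, t in pairs
            ]
        )

    def test_study_scale_counts(self):
        # 129 and 106 gene-tissue pairs sharing 42 → union 193
        pairs_a = [(f"g{i}", f"T{i % 3}") for i in range(129)]
        shared = pairs_a[:42]
        pairs_b = shared + [(f"h{i}", f"T{i % 3}") for i in range(64)]
        assert len(pairs_b) == 106
        merged, counts = merge_panels(self._records(pairs_a, "A"), self._records(pairs_b, "B"))
        assert (counts.n_a, counts.n_b, counts.n_overlap) == (129, 106, 42)
        assert counts.n_union == 193
        assert len(merged) == 193

    def test_disjoint_sets_concatenate(self):
        a = self._records([("g1", "T0")], "A")
        b = self._records([("g2", "T0")], "B")
        merged, counts = merge_panels(a, b)
        assert counts.n_union == 2 == len(merged)

    def test_min_p_rule_keeps_smaller(self):
        a = self._records([("g1", "T0")], "A", p=1e-7)
        b = self._records([("g1", "T0")], "B", p=1e-9)
        merged, _ = merge_panels(a, b)
        assert merged["panel"].iloc[0] == "B"
        assert merged["p"].iloc[0] == 1e-9

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        sa=st.sets(st.integers(0, 80), max_size=60),
        sb=st.sets(st.integers(0, 80), max_size=60),
    )
    def test_count_algebra_property(self, sa, sb):
        a = self._records([(f"g{i}", "T0") for i in sa], "A")
        b = self._records([(f"g{i}", "T0") for i in sb], "B")
        if len(a) == 0 or len(b) == 0:
            a = pd.DataFrame(columns=["gene", "tissue", "panel", "beta", "se", "z", "p"]) if len(a) == 0 else a
            b = pd.DataFrame(columns=["gene", "tissue", "panel", "beta", "se", "z", "p"]) if len(b) == 0 else b
        merged, counts = merge_panels(a, b)
        assert counts.n_union == len(sa | sb)
        assert counts.n_overlap == len(sa & sb)
        assert len(merged) == counts.n_union


class TestThresholdAndNovelty:
    def test_bonferroni_basic(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def _genes(self, tss, chrom="chr1"):
        return pd.DataFrame(
            {
                "gene": ["g1"], "best_tissues": ["T0"], "best_panel": ["A"],
                "z": [3.0], "min_p": [1e-8], "n_tissues_tested": [1],
                "significant": [True], "chrom": [chrom], "tss_pos": [tss],
            }
        )

    def test_within_window_is_known(self):
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000], "label": ["L1"]})
        out = annotate_novelty(self._genes(1_900_000), catalog)
        assert out["novelty"].iloc[0] == "known"

    def test_just_outside_window_is_novel(self):
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000], "label": ["L1"]})
        out = annotate_novelty(self._genes(2_000_001), catalog)
        assert out["novelty"].iloc[0] == "novel"
        boundary = annotate_novelty(self._genes(2_000_000), catalog)
        assert boundary["novelty"].iloc[0] == "known"

    def test_other_chromosome_is_novel(self):
        catalog = pd.DataFrame({"chrom": ["chr2"], "pos": [1_900_000], "label": ["L1"]})
        out = annotate_novelty(self._genes(1_900_000), catalog)
        assert out["novelty"].iloc[0] == "novel"

    def test_empty_catalog_all_novel(self):
        catalog = pd.DataFrame({"chrom": [], "pos": [], "label": []})
        out = annotate_novelty(self._genes(500), catalog)
        assert out["novelty"].iloc[0] == "novel"

    def test_missing_position_unclassified(self):
        g = self._genes(np.nan)
        catalog = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "label": ["L1"]})
        out = annotate_novelty(g, catalog)
        assert out["novelty"].iloc[0] == "unclassified"

    def test_twas_genes_min_p_and_flag(self):
        merged = pd.DataFrame(
            [
                {"gene": "g1", "tissue": "T0", "panel": "A", "z": 5.0, "p": 1e-8},
                {"gene": "g1", "tissue": "T1", "panel": "B", "z": 2.0, "p": 1e-3},
                {"gene": "g2", "tissue": "T0", "panel": "A", "z": 1.0, "p": 0.3},
            ]
        )
        out = twas_genes(merged, p_threshold=1e-6)
        out = out.set_index("gene")
        assert out.loc["g1", "min_p"] == 1e-8
        assert bool(out.loc["g1", "significant"])
        assert not bool(out.loc["g2", "significant"])
        assert out.loc["g1", "best_tissues"] == "T0"
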