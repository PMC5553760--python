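"""Marker filters (MAF, Hardy-Weinberg) and variant-to-feature mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gfblup import (
    SimulationConfig,
    apply_qc,
    combine_features,
    compute_maf,
    hwe_test,
    map_variants_to_features,
    simulate_genotypes,
)
from gfblup.qc import hwe_test_panel
from tests.conftest import make_panel


class TestMaf:
    @pytest.mark.parametrize(
        "dosages,expected",
        [
            ([0, 0, 0, 0], 0.0),        # monomorphic
            ([1, 1, 1, 1], 0.5),        # all heterozygous
            ([0, 1, 2, 2], 0.375),      # folded from 5/8
        ],
    )
    def test_examples(self, dosages, expected):
        panel = make_panel(np.array(dosages)[:, None])
        assert compute_maf(panel)[0] == pytest.approx(expected)

    def test_zero_individuals_rejected(self):
        panel = make_panel(np.zeros((1, 2)))
        panel.dosages = panel.dosages[:0]
        panel.ids = panel.ids[:0]
        panel.populations = panel.populations[:0]
        with pytest.raises(ValueError):
            compute_maf(panel)


class TestHwe:
    def test_exact_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_test((50, 0, 0)) == 1.0
        assert hwe_test((0, 0, 50)) == 1.0

    def test_chi_square_oracle(self):
        # counts (30, 40, 30): p=0.5, expected (25, 50, 25), chi2 = 1+2+1 = 4
        p = hwe_test((30, 40, 30))
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-12)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((-1, 2, 3))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(100, 20)).astype(float)
        panel = make_panel(dos)
        vec = hwe_test_panel(panel)
        for j in range(20):
            counts = ((dos[:, j] == 2).sum(), (dos[:, j] == 1).sum(), (dos[:, j] == 0).sum())
            assert vec[j] == pytest.approx(hwe_test(counts), rel=1e-10)


class TestApplyQc:
    def test_monomorphic_removed(self):
        dos = np.array(
            [[0, 1, 2, 1, 0], [0, 2, 1, 1, 2], [0, 1, 0, 2, 1], [0, 0, 1, 0, 1]]
        ).astype(float)
        filtered, report = apply_qc(make_panel(dos), maf_min=0.01, hwe_min=0.0)
        assert filtered.n_variants == 4
        assert report.n_removed_maf == 1

    def test_zero_thresholds_are_identity(self, small_cohort):
        panel = small_cohort["panel"]
        filtered, report = apply_qc(panel, maf_min=0.0, hwe_min=0.0)
        assert filtered.n_variants == panel.n_variants
        assert report.n_kept == panel.n_variants

    def test_matches_per_variant_loop_oracle(self):
        cfg = SimulationConfig(n_individuals=120, n_variants=500, n_populations=1,
                               ancestral_maf_range=(0.005, 0.5), seed=77)
        panel = simulate_genotypes(cfg)["popA"]
        filtered, _ = apply_qc(panel, maf_min=0.05, hwe_min=1e-3)
        keep = []
        for j in range(panel.n_variants):
            x = panel.dosages[:, j]
            p = x.mean() / 2
            maf = min(p, 1 - p)
            counts = ((x == 2).sum(), (x == 1).sum(), (x == 0).sum())
            if maf >= 0.05 and hwe_test(counts) >= 1e-3:
                keep.append(panel.variants["id"].iloc[j])
        assert list(filtered.variants["id"]) == keep

    def test_order_independence(self, small_cohort):
        panel = small_cohort["panel"]
        maf_then_hwe, _ = apply_qc(apply_qc(panel, 0.05, 0.0)[0], 0.0, 1e-3)
        hwe_then_maf, _ = apply_qc(apply_qc(panel, 0.0, 1e-3)[0], 0.05, 0.0)
        assert maf_then_hwe.variants.equals(hwe_then_maf.variants)

    def test_all_removed_raises(self):
        panel = make_panel(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            apply_qc(panel, maf_min=0.01, hwe_min=0.0)


class TestFeatureMapping:
    def _toy(self):
        panel = make_panel(np.ones((3, 5)), pos=[99, 100, 150, 200, 201])
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": [1], "start": [100], "end": [200]}
        )
        return panel, genes

    def test_inclusive_boundaries(self):
        panel, genes = self._toy()
        fmap = map_variants_to_features(panel, genes, {"t": ["g1"]})
        # 99 excluded, 100/150/200 included, 201 excluded
        assert list(fmap.genes["g1"]) == [1, 2, 3]

    def test_unknown_chromosome_warns_and_skips(self):
        panel, genes = self._toy()
        genes2 = pd.concat(
            [genes, pd.DataFrame({"gene_id": ["g2"], "chrom": [9], "start": [1], "end": [5]})]
        )
        with pytest.warns(UserWarning):
            fmap = map_variants_to_features(panel, genes2, {"t": ["g1", "g2"]})
        assert "g2" not in fmap.genes

    def test_union_counts_match_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(np.arange(100, 5000), size=60, replace=False))
        panel = make_panel(np.ones((2, 60)), pos=pos)
        genes = pd.DataFrame(
            {
                "gene_id": ["ga", "gb", "gc"],
                "chrom": [1, 1, 1],
                "start": [200, 1000, 1100],
                "end": [1200, 2500, 4000],
            }
        )
        sets = {"t1": ["ga", "gb"], "t2": ["gb", "gc"]}
        fmap = map_variants_to_features(panel, genes, sets)
        for term, members in sets.items():
            brute = set()
            for i, p in enumerate(pos):
                for g in members:
                    row = genes[genes["gene_id"] == g].iloc[0]
                    if row["start"] <= p <= row["end"]:
                        brute.add(i)
            assert set(fmap.variant_indices(term).tolist()) == brute

    def test_indices_valid_after_requalification(self, small_cohort):
        """Re-mapping against the filtered panel yields in-range indices."""
        panel, fmap0 = small_cohort["panel"], small_cohort["fmap"]
        filtered, _ = apply_qc(panel, maf_min=0.1, hwe_min=0.0)
        gene_table = small_cohort["gene_table"]
        fmap = map_variants_to_features(filtered, gene_table, dict(fmap0.terms))
        for term in fmap.term_ids:
            idx = fmap.variant_indices(term)
            assert idx.size == 0 or idx.max() < filtered.n_variants
        # mapped positions still fall inside their gene intervals
        g = gene_table.set_index("gene_id")
        pos = filtered.variants["pos"].to_numpy()
        for gene, idx in fmap.genes.items():
            if idx.size:
                assert pos[idx].min() >= g.loc[gene, "start"]
                assert pos[idx].max() <= g.loc[gene, "end"]


class TestCombineFeatures:
    def test_idempotent(self, small_cohort):
        fmap = small_cohort["fmap"]
        t = fmap.term_ids[0]
        combined = combine_features(fmap, [t, t], new_id="u")
        assert combined.m_f("u") == fmap.m_f(t)

    def test_disjoint_terms_add(self):
        from gfblup.panel import FeatureMap

        fmap = FeatureMap(terms={"a": ["g1"], "b": ["g2"]},
                          genes={"g1": [0, 1], "g2": [2, 3, 4]})
        combined = combine_features(fmap, ["a", "b"], new_id="u")
        assert combined.m_f("u") == 5

    def test_overlap_matches_set_union_oracle(self, small_cohort):
        fmap = small_cohort["fmap"]
        t1, t2 = fmap.term_ids[:2]
        combined = combine_features(fmap, [t1, t2], new_id="u")
        oracle = set(fmap.variant_indices(t1)) | set(fmap.variant_indices(t2))
        assert set(combined.variant_indices("u").tolist()) == oracle
        assert combined.m_f("u") <= fmap.m_f(t1) + fmap.m_f(t2)

    def test_empty_list_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            combine_features(small_cohort["fmap"], [])
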