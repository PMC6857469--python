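import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from caseinhap import (
    haplotype_em as hem,
    protein_variants as pv,
    synthetic_data as sd,
    tables,
)


def expand_to_dosage(labels, probs, n, rng, positions=None):
    positions = positions or tables.core_positions()
    alt = {s.pos: s.alt for s in tables.CORE_SNPS}
    vec = {}
    for lab in labels:
        alleles = sd.expand_haplotype(lab)
        vec[lab] = np.array([int(alleles[p] == alt[p]) for p in positions])
    draws = rng.choice(len(labels), size=(n, 2), p=probs)
    return np.array([vec[labels[a]] + vec[labels[b]] for a, b in draws])


class TestEnumeratePairs:
    def test_homozygous_single_pair(self):
        assert hem.enumerate_pairs([0, 2, 0]) == [((0, 1, 0), (0, 1, 0))]

    def test_two_het_loci_two_pairs(self):
        assert len(hem.enumerate_pairs([1, 1])) == 2

    def test_three_het_loci_four_pairs(self):
        assert len(hem.enumerate_pairs([1, 1, 1])) == 4

    @settings(max_examples=20, deadline=None)
    @given(st.integers(1, 7))
    def test_k_het_loci_gives_2_to_k_minus_1(self, k):
        assert len(hem.enumerate_pairs([1] * k)) == 2 ** (k - 1)

    def test_missing_locus_expands(self):
        # one missing locus alone: 00, 01, 11 as unordered pairs
        assert len(hem.enumerate_pairs([-1])) == 3

    def test_ambiguity_cap(self):
        with pytest.raises(hem.AmbiguityCapExceeded):
            hem.enumerate_pairs([1] * 13, max_ambiguity=12)


class TestEmFit:
    def test_matches_counting_on_unambiguous_data(self):
        # at most one het locus per individual: phase is unambiguous and
        # the MLE is plain haplotype counting
        rng = np.random.default_rng(5)
        haps = [(0, 0, 0), (1, 0, 0), (1, 1, 1)]
        counts = {}
        genotypes = []
        for _ in range(40):
            i, j = rng.integers(0, 3, size=2)
            h1, h2 = haps[i], haps[j]
            if sum(a != b for a, b in zip(h1, h2)) > 1:
                continue
            genotypes.append([a + b for a, b in zip(h1, h2)])
            counts[h1] = counts.get(h1, 0) + 1
            counts[h2] = counts.get(h2, 0) + 1
        res = hem.em_fit(np.array(genotypes))
        total = sum(counts.values())
        for hap, freq in zip(res.haplotypes, res.frequencies):
            assert freq == pytest.approx(counts.get(hap, 0) / total, abs=1e-6)

    def test_double_heterozygote_symmetric_fixed_point(self):
        res = hem.em_fit([[1, 1]])
        np.testing.assert_allclose(res.frequencies, 0.25, atol=1e-12)
        assert res.converged

    def test_loglik_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            G = rng.integers(0, 3, size=(rng.integers(2, 12),
                                         rng.integers(2, 5)))
            res = hem.em_fit(G)
            trace = np.array(res.loglik_trace)
            assert (np.diff(trace) >= -1e-10).all()

    def test_frequencies_on_simplex(self):
        rng = np.random.default_rng(13)
        G = rng.integers(0, 3, size=(20, 4))
        res = hem.em_fit(G)
        assert res.frequencies.min() >= 0
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_allele_frequency_consistency_no_missing(self):
        rng = np.random.default_rng(17)
        G = rng.integers(0, 3, size=(50, 3))
        res = hem.em_fit(G)
        implied = res.implied_allele_frequencies()
        direct = G.mean(axis=0) / 2
        np.testing.assert_allclose(implied, direct, atol=1e-6)

    def test_excludes_over_ambiguous_individuals(self):
        G = np.array([[1] * 14, [0] * 14])
        res = hem.em_fit(G, max_ambiguity=12)
        assert res.n_individuals == 1
        assert res.excluded == [0]

    def test_excludes_mostly_missing_individuals(self):
        G = np.array([[-1, -1, -1, 0], [0, 0, 0, 0]])
        res = hem.em_fit(G, max_missing_frac=0.5)
        assert res.n_individuals == 1

    def test_no_individuals_left_error(self):
        with pytest.raises(hem.EMError):
            hem.em_fit(np.array([[1] * 20]), max_ambiguity=5)

    def test_oracle_equivalence_small_instances(self):
        """EM log-likelihood equals the directly maximized likelihood
        (Dirichlet random search + simplex polish) on tiny instances."""
        rng = np.random.default_rng(23)
        for _ in range(4):
            G = rng.integers(0, 3, size=(rng.integers(2, 7),
                                         rng.integers(2, 4)))
            res = hem.em_fit(G, tol=1e-12, max_iter=10_000, n_restarts=20)
            haps = res.haplotypes
            best = max(hem.block_loglik(G, haps,
                                        rng.dirichlet(np.ones(len(haps))))
                       for _ in range(1000))
            assert res.loglik >= best - 1e-6

            def nll(x):
                p = np.exp(x - x.max())
                return -hem.block_loglik(G, haps, p / p.sum())

            opt = minimize(nll, np.zeros(len(haps)), method="Nelder-Mead",
                           options={"maxiter": 20_000, "fatol": 1e-12,
                                    "xatol": 1e-10})
            assert abs(res.loglik - (-opt.fun)) < 1e-6


class TestPerBreed:
    def test_single_haplotype_breed_returns_it_fixed(self, core_only_matrix):
        pass  # covered via degenerate config below

    def test_degenerate_breed(self):
        import caseinhap.genotype_io as gio
        G = np.zeros((8, 7), dtype=int)
        res = hem.em_fit(G)
        assert len(res.haplotypes) == 1
        assert res.frequencies[0] == pytest.approx(1.0)

    def test_per_breed_and_pooled(self, core_only_matrix):
        em = hem.per_breed_frequencies(core_only_matrix,
                                       tables.core_positions())
        assert set(em) == {"DSN", "Holstein", hem.POOLED}
        for res in em.values():
            assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert res.converged

    def test_pooled_is_sample_size_weighted_mixture_at_large_n(self, tmp_path):
        cfg = sd.SimConfig(
            breeds=[("DSN", 2000), ("Holstein", 2000)], seed=31,
            category_counts={"missense": 7})
        bundle = sd.simulate_cohort(cfg, tmp_path)
        em = hem.per_breed_frequencies(bundle.matrix,
                                       tables.core_positions())
        pooled = em[hem.POOLED].as_series()
        mix = (em["DSN"].as_series().reindex(pooled.index, fill_value=0)
               + em["Holstein"].as_series().reindex(pooled.index,
                                                    fill_value=0)) / 2
        assert (pooled - mix).abs().max() < 0.03

    def test_parameter_recovery_table_frequencies(self, tmp_path):
        # every generated haplotype frequency recovered within 0.02 at n=5000
        cfg = sd.SimConfig(breeds=[("DSN", 5000)], seed=37,
                           category_counts={"missense": 7})
        bundle = sd.simulate_cohort(cfg, tmp_path)
        em = hem.per_breed_frequencies(bundle.matrix, tables.core_positions())
        est = em["DSN"].as_series()
        alt = {s.pos: s.alt for s in tables.CORE_SNPS}
        positions = tables.core_positions()
        for label, freq in bundle.generating_freqs["DSN"].items():
            alleles = sd.expand_haplotype(label)
            key = "".join(alleles[p] for p in positions)
            assert est.get(key, 0.0) == pytest.approx(freq, abs=0.02)


@pytest.fixture(scope="module")
def em_results(core_only_matrix):
    return hem.per_breed_frequencies(core_only_matrix,
                                     tables.core_positions())


class TestComprehensiveHaplotypes:
    def test_dsn_modal_label(self, em_results):
        table = hem.comprehensive_haplotypes(em_results, pv.builtin_rules())
        named = table.drop(index=hem.RESIDUAL)
        assert named["DSN"].idxmax() == "B-A1-A-A"

    def test_holstein_modal_label(self, em_results):
        table = hem.comprehensive_haplotypes(em_results, pv.builtin_rules())
        named = table.drop(index=hem.RESIDUAL)
        assert named["Holstein"].idxmax() == "B-A2-A-A"

    def test_columns_sum_to_one(self, em_results):
        table = hem.comprehensive_haplotypes(em_results, pv.builtin_rules())
        for col in table.columns:
            assert table[col].sum() == pytest.approx(1.0, abs=1e-6)

    def test_no_residual_when_everything_common(self):
        # two-haplotype population, both far above threshold
        rng = np.random.default_rng(41)
        G = expand_to_dosage(["B-A1-A-A", "B-A2-A-A"], np.array([0.5, 0.5]),
                             200, rng)
        positions = tables.core_positions()
        snps = {s.pos: s for s in tables.CORE_SNPS}
        alleles = [(snps[p].ref, snps[p].alt) for p in positions]
        res = hem.em_fit(G, positions=positions, alleles=alleles)
        table = hem.comprehensive_haplotypes({"X": res}, pv.builtin_rules())
        assert table.loc[hem.RESIDUAL, "X"] == pytest.approx(0.0, abs=1e-9)


class TestTheoreticalCount:
    def test_published_dsn_gives_nine(self):
        table = tables.builtin_variant_frequencies()
        assert hem.theoretical_haplotype_count(table, "DSN") == 9

    def test_single_variant_everywhere_gives_one(self):
        idx = pd.MultiIndex.from_tuples(
            [(g, "A") for g in tables.GENE_ORDER], names=["gene", "variant"])
        table = pd.DataFrame({"X": [1.0] * 4}, index=idx)
        assert hem.theoretical_haplotype_count(table, "X") == 1

    def test_two_variants_per_gene_gives_sixteen(self):
        rows = [(g, v) for g in tables.GENE_ORDER for v in ("A", "B")]
        idx = pd.MultiIndex.from_tuples(rows, names=["gene", "variant"])
        table = pd.DataFrame({"X": [0.5] * 8}, index=idx)
        assert hem.theoretical_haplotype_count(table, "X") == 16
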