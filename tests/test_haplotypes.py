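"""EM haplotype-frequency estimation against exhaustive-likelihood oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breedline.genotypes import MISSING, DataError, PopulationLabels
from breedline.haplotypes import (
    EmSettings,
    compatible_pairs,
    em_haplotype_frequencies,
    max_likelihood_oracle,
    poll_style_report,
)
from breedline.simulate import (
    DriftConfig,
    HaplotypeBlockConfig,
    inject_haplotype_block,
    simulate_balding_nichols,
)
from tests.conftest import make_genotypes


def em_on_codes(codes, **settings_kw):
    g = make_genotypes(codes)
    settings = EmSettings(**settings_kw) if settings_kw else None
    return em_haplotype_frequencies(
        g, list(g.snps.snp_ids), list(g.samples), settings
    )


class TestCompatiblePairs:
    def test_homozygote_has_single_pair(self):
        assert compatible_pairs(np.array([2, 0, 2])) == [(0b101, 0b101)]

    def test_het_count_doubles_pairs(self):
        pairs = compatible_pairs(np.array([1, 1]))
        assert len(pairs) == 4  # ordered pairs
        assert set(pairs) == {(0b10, 0b01), (0b01, 0b10), (0b11, 0b00), (0b00, 0b11)}


class TestEm:
    def test_fully_homozygous_sample_set_is_direct_count(self):
        codes = np.array([[2, 2], [0, 0], [2, 2], [2, 0]], np.int8)
        res = em_on_codes(codes)
        # gametes: 11 x4 ... sample4 is hom 2 / hom 0 => haplotype 10 x2
        expected = {0b11: 4 / 8, 0b00: 2 / 8, 0b10: 2 / 8}
        for h, f in expected.items():
            assert res.frequencies[h] == pytest.approx(f, abs=1e-9)
        assert res.n_iterations <= 2

    def test_classic_two_individual_instance_matches_analytic_maximum(self):
        """Hom (2,2) plus double heterozygote: the likelihood maximizer puts
        3/4 on the doubly-derived haplotype and 1/4 on the ancestral one."""
        codes = np.array([[2, 2], [1, 1]], np.int8)
        res = em_on_codes(codes)
        assert res.frequencies[0b11] == pytest.approx(0.75, abs=1e-6)
        assert res.frequencies[0b00] == pytest.approx(0.25, abs=1e-6)
        f_o, ll_o = max_likelihood_oracle(codes)
        assert res.log_likelihood == pytest.approx(ll_o, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_maximizer_on_tiny_instances(self, seed):
        """EM log-likelihood equals the oracle's maximum (m <= 3, n <= 4)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 4))
        n = int(rng.integers(2, 5))
        codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        res = em_on_codes(codes, seed=seed)
        _, ll_o = max_likelihood_oracle(codes, seed=seed + 1)
        assert res.log_likelihood == pytest.approx(ll_o, abs=1e-6)

    def test_log_likelihood_monotone_within_run(self):
        # monotonicity is asserted inside the EM loop; a run on an ambiguous
        # instance exercises many iterations without tripping the assertion
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        res = em_on_codes(codes, tol=1e-12, max_iter=500)
        assert np.isfinite(res.log_likelihood)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=(12, 3)).astype(np.int8)
        a = em_on_codes(codes, seed=0)
        b = em_on_codes(codes[::-1], seed=0)
        np.testing.assert_allclose(a.frequencies, b.frequencies, atol=1e-6)

    def test_allele_label_swap_permutes_frequencies(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(15, 2)).astype(np.int8)
        a = em_on_codes(codes, seed=0)
        swapped = codes.copy()
        swapped[:, 0] = 2 - swapped[:, 0]  # swap labels at SNP 1
        b = em_on_codes(swapped, seed=0)
        # haplotype index bit 0 (MSB) flips
        perm = [h ^ 0b10 for h in range(4)]
        # agreement limited by the EM stopping rule, not the permutation
        np.testing.assert_allclose(a.frequencies, b.frequencies[perm], atol=1e-4)

    def test_missing_window_calls_excluded_and_counted(self):
        codes = np.array([[2, 2], [1, MISSING], [0, 0]], np.int8)
        res = em_on_codes(codes)
        assert res.n_used == 2
        assert res.n_excluded == 1

    def test_no_complete_samples_errors(self):
        codes = np.array([[MISSING, 0]], np.int8)
        with pytest.raises(DataError, match="complete"):
            em_on_codes(codes)

    def test_recovers_published_florida_vector(self):
        """Genotypes simulated from frequencies 0.49/0.03/0.39/other 0.09 at
        n = 35 are re-estimated within 3 binomial SE."""
        cfg = DriftConfig(
            n_pops=1, drift_c=[0.05], n_snps=50, samples_per_pop=[35], seed=44,
            chromosomes=[("10", 50)],
        )
        g, m, labels, truth = simulate_balding_nichols(cfg)
        window = list(m.snp_ids[:4])
        vec = np.zeros(16)
        vec[0b0000], vec[0b0101], vec[0b0011] = 0.49, 0.03, 0.39
        rest = vec == 0
        vec[rest] = 0.09 / rest.sum()
        block = HaplotypeBlockConfig(window, {"POP1": vec})
        g2, _ = inject_haplotype_block(g, truth, labels, block, seed=45)
        res = em_haplotype_frequencies(g2, window, labels.samples_in("POP1"))
        n_gametes = 2 * 35
        for h, f in [(0b0000, 0.49), (0b0101, 0.03), (0b0011, 0.39)]:
            se = np.sqrt(f * (1 - f) / n_gametes)
            assert abs(res.frequencies[h] - f) <= 3 * se + 1e-9


class TestPollStyleReport:
    def window_alleles_em(self, vec_by_pop, n_by_pop, seed=50):
        """Simulate, inject, and EM-estimate a 4-SNP window per population."""
        pops = list(vec_by_pop)
        cfg = DriftConfig(
            n_pops=len(pops),
            drift_c=[0.05] * len(pops),
            n_snps=30,
            samples_per_pop=[n_by_pop[p] for p in pops],
            pop_names=pops,
            seed=seed,
            chromosomes=[("10", 30)],
        )
        g, m, labels, truth = simulate_balding_nichols(cfg)
        window = list(m.snp_ids[:4])
        block = HaplotypeBlockConfig(window, dict(vec_by_pop))
        g2, _ = inject_haplotype_block(g, truth, labels, block, seed=seed + 1)
        tables = {
            p: em_haplotype_frequencies(g2, window, labels.samples_in(p))
            for p in pops
        }
        idx = m.index_of(window)
        alleles = [
            (m.table["allele_a"].iloc[i], m.table["allele_b"].iloc[i]) for i in idx
        ]
        return tables, alleles

    def test_single_fixed_haplotype(self):
        vec = np.zeros(16)
        vec[0] = 1.0
        tables, alleles = self.window_alleles_em({"P": vec}, {"P": 20})
        h1 = "".join(a for a, _ in alleles)
        report = poll_style_report(tables, [("H1", h1)])
        row = report.iloc[0]
        assert row["H1"] == 1.00
        assert row["Other"] == 0.00
        assert row["n_haplotypes"] == 1

    def test_named_plus_other_conserve_mass(self):
        rng = np.random.default_rng(9)
        vec = rng.dirichlet(np.ones(16) * 0.5)
        tables, alleles = self.window_alleles_em({"P": vec}, {"P": 40})
        res = tables["P"]
        named = [(f"H{k+1}", res.allele_strings[k]) for k in range(3)]
        report = poll_style_report(tables, named)
        row = report.iloc[0]
        total = row["H1"] + row["H2"] + row["H3"] + row["Other"]
        assert total == pytest.approx(1.0, abs=0.011)

    def test_duplicate_labels_rejected(self):
        vec = np.zeros(16)
        vec[0] = 1.0
        tables, alleles = self.window_alleles_em({"P": vec}, {"P": 5})
        h1 = "".join(a for a, _ in alleles)
        with pytest.raises(DataError, match="duplicate"):
            poll_style_report(tables, [("H1", h1), ("H1", h1)])
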