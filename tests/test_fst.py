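"""Hudson-form F_ST components, bootstrap SD, ranking, enrichment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breedline.fst import (
    bootstrap_sd,
    chromosome_enrichment,
    fst_components,
    format_fst_table,
    global_fst,
    pairwise_fst_matrix,
    rank_top_fraction,
)
from breedline.genotypes import MISSING, PopulationLabels
from breedline.simulate import DriftConfig, simulate_balding_nichols
from tests.conftest import make_genotypes, make_snp_map


def two_pop_labels(g, n1):
    return PopulationLabels(
        {s: ("P1" if i < n1 else "P2") for i, s in enumerate(g.samples)}
    )


def brute_force_components(codes, idx1, idx2):
    """Straight per-locus recomputation from raw codes."""
    nums, dens = [], []
    for j in range(codes.shape[1]):
        c1 = [codes[i, j] for i in idx1 if codes[i, j] != MISSING]
        c2 = [codes[i, j] for i in idx2 if codes[i, j] != MISSING]
        n1, n2 = 2 * len(c1), 2 * len(c2)
        if n1 < 2 or n2 < 2:
            nums.append(np.nan)
            dens.append(np.nan)
            continue
        p1, p2 = sum(c1) / n1, sum(c2) / n2
        nums.append(
            (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        )
        dens.append(p1 * (1 - p2) + p2 * (1 - p1))
    return np.array(nums), np.array(dens)


class TestComponents:
    def test_fixed_difference_gives_one(self):
        codes = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], np.int8)
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 2), ("P1", "P2"))
        np.testing.assert_allclose(comp.numerator, 1.0)
        np.testing.assert_allclose(comp.denominator, 1.0)
        np.testing.assert_allclose(comp.per_snp_fst, 1.0)

    def test_balanced_heterozygosity_arithmetic(self):
        """p1 = p2 = 0.5 at n = 50 chromosomes: N = -2*(0.25/49), D = 0.5."""
        half = [0] * 12 + [2] * 12 + [1]  # 25 diploids, p = 0.5
        codes = np.array([half + half], np.int8).reshape(1, 50).T  # 50 samples x 1 SNP
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 25), ("P1", "P2"))
        assert comp.n1[0] == 50 and comp.n2[0] == 50
        assert comp.numerator[0] == pytest.approx(-2 * 0.25 / 49)
        assert comp.denominator[0] == pytest.approx(0.5)
        assert comp.per_snp_fst[0] == pytest.approx(-0.0204, abs=1e-4)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        codes = rng.integers(0, 3, size=(30, 80)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.1] = MISSING
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 15), ("P1", "P2"))
        num, den = brute_force_components(codes, range(15), range(15, 30))
        np.testing.assert_allclose(comp.numerator, num, equal_nan=True)
        np.testing.assert_allclose(comp.denominator, den, equal_nan=True)

    def test_population_swap_invariance(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        a = fst_components(g, labels, ("POP1", "POP2"))
        b = fst_components(g, labels, ("POP2", "POP1"))
        np.testing.assert_allclose(a.numerator, b.numerator, equal_nan=True)
        assert global_fst(a) == pytest.approx(global_fst(b))

    def test_monomorphic_snp_flagged_uninformative(self):
        codes = np.zeros((6, 2), np.int8)
        codes[:, 1] = [0, 1, 2, 0, 1, 2]
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 3), ("P1", "P2"))
        assert not comp.informative[0]
        assert comp.informative[1]


class TestGlobalFst:
    def test_all_fixed_differences(self):
        codes = np.array([[0] * 5, [0] * 5, [2] * 5, [2] * 5], np.int8)
        g = make_genotypes(codes)
        assert global_fst(fst_components(g, two_pop_labels(g, 2), ("P1", "P2"))) == 1.0

    def test_null_split_of_one_population(self):
        """One panmictic population split in half: |global F_ST| < 0.01."""
        cfg = DriftConfig(
            n_pops=1, drift_c=[0.1], n_snps=5000, samples_per_pop=[60], seed=13
        )
        g, _, _, _ = simulate_balding_nichols(cfg)
        labels = two_pop_labels(g, 30)
        comp = fst_components(g, labels, ("P1", "P2"))
        assert abs(global_fst(comp)) < 0.01

    def test_ratio_of_sums_not_mean_of_ratios(self):
        codes = np.array(
            [[0, 0], [0, 1], [2, 0], [2, 1]], np.int8
        )
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 2), ("P1", "P2"))
        ratio_of_sums = np.nansum(comp.numerator[comp.informative]) / np.nansum(
            comp.denominator[comp.informative]
        )
        assert global_fst(comp) == pytest.approx(ratio_of_sums)

    def test_invariant_to_duplicating_every_snp(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        comp = fst_components(g, labels, ("POP1", "POP2"))
        doubled = make_genotypes(
            np.hstack([g.codes, g.codes]),
        )
        doubled.samples = list(g.samples)
        labels2 = PopulationLabels(dict(labels.assignments))
        comp2 = fst_components(doubled, labels2, ("POP1", "POP2"))
        assert global_fst(comp2) == pytest.approx(global_fst(comp))

    def test_recovers_drift_parameter(self):
        """c = 0.062 each side: estimate within 3 bootstrap SD of 0.062."""
        cfg = DriftConfig(
            n_pops=2, drift_c=[0.062, 0.062], n_snps=10_000,
            samples_per_pop=[50, 50], seed=20,
        )
        g, _, labels, _ = simulate_balding_nichols(cfg)
        comp = fst_components(g, labels, ("POP1", "POP2"))
        est = global_fst(comp)
        sd = bootstrap_sd(comp, n_boot=1000, seed=21)
        assert abs(est - 0.062) < 3 * sd


class TestBootstrapSd:
    def test_identical_components_give_zero(self):
        codes = np.array([[0] * 10, [0] * 10, [2] * 10, [2] * 10], np.int8)
        g = make_genotypes(codes)
        comp = fst_components(g, two_pop_labels(g, 2), ("P1", "P2"))
        assert bootstrap_sd(comp, n_boot=50, seed=0) == 0.0

    def test_tiny_n_boot_matches_enumerated_draws(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        comp = fst_components(g, labels, ("POP1", "POP2"))
        sd = bootstrap_sd(comp, n_boot=3, seed=99)
        num = comp.numerator[comp.informative]
        den = comp.denominator[comp.informative]
        rng = np.random.default_rng(99)
        reps = []
        for _ in range(3):
            idx = rng.integers(0, len(num), size=len(num))
            reps.append(num[idx].sum() / den[idx].sum())
        assert sd == pytest.approx(np.std(reps, ddof=1))

    def test_sd_scales_with_inverse_sqrt_panel_size(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        comp = fst_components(g, labels, ("POP1", "POP2"))
        quadrupled = make_genotypes(np.hstack([g.codes] * 4))
        quadrupled.samples = list(g.samples)
        comp4 = fst_components(quadrupled, PopulationLabels(dict(labels.assignments)), ("POP1", "POP2"))
        sd1 = bootstrap_sd(comp, n_boot=400, seed=1)
        sd4 = bootstrap_sd(comp4, n_boot=400, seed=2)
        assert sd4 == pytest.approx(sd1 / 2, rel=0.25)


class TestPairwiseMatrix:
    def test_two_populations_one_pair(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        results = pairwise_fst_matrix(g, labels, n_boot=10, seed=0)
        assert len(results) == 1

    def test_pair_count_is_k_choose_2(self):
        cfg = DriftConfig(
            n_pops=6, drift_c=[0.05] * 6, n_snps=200, samples_per_pop=[8] * 6, seed=30
        )
        g, _, labels, _ = simulate_balding_nichols(cfg)
        results = pairwise_fst_matrix(g, labels, n_boot=5, seed=0)
        assert len(results) == 15

    def test_low_drift_pair_smallest_in_most_replicates(self):
        """c = (0.02, 0.02, 0.10): the (1,2) pair has the smallest F_ST in
        >= 9 of 10 replicates (expectation (c_i + c_j)/2)."""
        wins = 0
        for rep in range(10):
            cfg = DriftConfig(
                n_pops=3, drift_c=[0.02, 0.02, 0.10], n_snps=1500,
                samples_per_pop=[25, 25, 25], seed=400 + rep,
            )
            g, _, labels, _ = simulate_balding_nichols(cfg)
            results = pairwise_fst_matrix(g, labels, n_boot=2, seed=rep)
            smallest = min(results, key=lambda p: results[p].global_fst)
            wins += smallest == ("POP1", "POP2")
        assert wins >= 9

    def test_table_layout_percent_above_sd_below(self, two_pop_panel):
        g, _, labels, _ = two_pop_panel
        results = pairwise_fst_matrix(g, labels, n_boot=50, seed=0)
        table = format_fst_table(results)
        r = next(iter(results.values()))
        assert table.loc["POP1", "POP2"] == round(r.global_fst * 100, 1)
        assert table.loc["POP2", "POP1"] == round(r.sd * 1000, 1)


class TestRankTopFraction:
    def test_chip_panel_one_percent_is_491(self):
        rng = np.random.default_rng(0)
        fst = rng.normal(size=49_034)
        ids = np.array([f"s{i:05d}" for i in range(49_034)])
        assert len(rank_top_fraction(fst, ids, 0.01)) == 491

    def test_five_of_one_hundred(self):
        fst = np.arange(100.0)
        ids = np.array([f"s{i}" for i in range(100)])
        top = rank_top_fraction(fst, ids, 0.05)
        assert top == ["s99", "s98", "s97", "s96", "s95"]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_sort_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        fst = rng.integers(0, 5, size=200) / 10.0  # heavy ties
        ids = np.array([f"m{i:03d}" for i in range(200)])
        top = rank_top_fraction(fst, ids, 0.07)
        expected = [
            i for _, i in sorted(zip(-fst, ids), key=lambda t: (t[0], t[1]))
        ][: int(np.ceil(0.07 * 200))]
        assert top == expected


class TestEnrichment:
    def test_uniform_top_ratios_near_one(self):
        m = make_snp_map(1000)
        m.table.loc[500:, "chromosome"] = "2"
        rng = np.random.default_rng(8)
        ratios = []
        for _ in range(20):
            top = list(np.array(m.snp_ids)[rng.choice(1000, 100, replace=False)])
            enr = chromosome_enrichment(top, m).set_index("chromosome")
            ratios.append(enr.loc["1", "ratio"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_published_style_ratio(self):
        """A chromosome with 3.8% of SNPs holding 9.2% of outliers: ratio 2.42."""
        n = 1000
        m = make_snp_map(n)
        m.table.loc[: 37, "chromosome"] = "10"  # 38 SNPs = 3.8%
        m.table.loc[38:, "chromosome"] = "1"
        snp_ids = np.array(m.snp_ids)
        top = list(snp_ids[:23]) + list(snp_ids[38 : 38 + 227])  # 23/250 = 9.2%
        enr = chromosome_enrichment(top, m).set_index("chromosome")
        assert enr.loc["10", "observed_fraction"] == pytest.approx(0.092)
        assert enr.loc["10", "ratio"] == pytest.approx(0.092 / 0.038, rel=1e-6)
        assert enr.loc["10", "ratio"] > 2

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        """20 SNPs on 2 chromosomes, 5 outliers: tail probability equals the
        exact count over all C(20,5) outlier subsets."""
        m = make_snp_map(20)
        m.table.loc[12:, "chromosome"] = "2"  # 12 on chr1, 8 on chr2
        snp_ids = list(m.snp_ids)
        top = snp_ids[:4] + snp_ids[12:13]  # 4 from chr1, 1 from chr2
        enr = chromosome_enrichment(top, m).set_index("chromosome")
        k_obs = 4
        count = 0
        total = 0
        for subset in itertools.combinations(range(20), 5):
            total += 1
            k = sum(1 for i in subset if i < 12)
            count += k >= k_obs
        assert enr.loc["1", "p_value"] == pytest.approx(count / total, rel=1e-9)

    def test_fractions_sum_to_one(self):
        m = make_snp_map(60)
        m.table.loc[20:39, "chromosome"] = "2"
        m.table.loc[40:, "chromosome"] = "X"
        top = list(np.array(m.snp_ids)[[0, 5, 25, 45, 50]])
        enr = chromosome_enrichment(top, m)
        assert enr["expected_fraction"].sum() == pytest.approx(1.0)
        assert enr["observed_fraction"].sum() == pytest.approx(1.0)
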