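import itertools
import math

import numpy as np
import pandas as pd
import pytest

import cwdkin as ck
from cwdkin.datasets import MISSING, DataError
from cwdkin.simulate import SimConfig, generate_mature_population, _draw_true_genotypes, \
    draw_locus_frequencies, _build_dataset
from conftest import make_dataset


class TestHeterozygosityAndDiversity:
    def test_observed_het_counts(self):
        ds = make_dataset([[(1, 1)], [(1, 2)], [(1, 2)]])
        per, mean = ck.observed_heterozygosity(ds)
        assert per["L01"] == pytest.approx(2 / 3)
        assert mean == pytest.approx(2 / 3)
        all_hom = make_dataset([[(1, 1)], [(2, 2)]])
        assert ck.observed_heterozygosity(all_hom)[1] == 0.0

    def test_observed_het_matches_counting_oracle(self, small_hwe_population):
        ds = small_hwe_population
        per, _ = ck.observed_heterozygosity(ds)
        for li, locus in enumerate(ds.loci):
            het = n = 0
            for i in range(ds.n):
                a, b = ds.genotypes[i, li]
                if a == MISSING:
                    continue
                n += 1
                het += a != b
            assert per[locus.name] == pytest.approx(het / n, abs=1e-12)

    def test_gene_diversity_hand_value(self):
        # 5 individuals, 10 genes at p = (0.5, 0.3, 0.2): H_S = (10/9)(1 - 0.38)
        ds = make_dataset(
            [[(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)], [(3, 3)]],
        )
        per, _ = ck.gene_diversity(ds)
        assert per["L01"] == pytest.approx(10 / 9 * (1 - 0.38), abs=1e-12)

    def test_gene_diversity_monomorphic_is_zero(self):
        ds = make_dataset([[(1, 1)], [(1, 1)]])
        assert ck.gene_diversity(ds)[1] == 0.0

    def test_gene_diversity_biallelic_half(self):
        geno = [[(1, 2)]] * 50
        ds = make_dataset(geno)
        assert ck.gene_diversity(ds)[1] == pytest.approx(0.5, abs=0.01)


class TestAllelicRichness:
    def test_full_sample_returns_observed_count(self):
        ds = make_dataset([[(1, 2)], [(2, 3)], [(3, 3)]])
        per, _ = ck.allelic_richness(ds, g=6)
        assert per["L01"] == pytest.approx(3.0, abs=1e-9)

    def test_monomorphic_is_one(self):
        ds = make_dataset([[(1, 1)], [(1, 1)]])
        assert ck.allelic_richness(ds, g=2)[1] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # 6 genes with allele counts (3, 2, 1); enumerate all C(6, g) subsamples
        ds = make_dataset([[(1, 1)], [(1, 2)], [(2, 3)]])
        genes = [1, 1, 1, 2, 2, 3]
        for g in (2, 3, 4):
            expected = np.mean(
                [len(set(sub)) for sub in itertools.combinations(genes, g)]
            )
            per, _ = ck.allelic_richness(ds, g=g)
            assert per["L01"] == pytest.approx(expected, abs=1e-10)

    def test_oversized_subsample_errors(self):
        ds = make_dataset([[(1, 2)], [(2, 3)]])
        with pytest.raises(DataError, match="L01"):
            ck.allelic_richness(ds, g=10)


def _brute_force_fis(ds):
    """Weir–Cockerham f via literal per-allele loops (independent oracle)."""
    sum_b = sum_c = 0.0
    for li in range(len(ds.loci)):
        rows = [tuple(g) for g in ds.genotypes[:, li, :] if g[0] != MISSING]
        alleles = sorted({a for r in rows for a in r})
        if len(alleles) < 2:
            continue
        n = len(rows)
        for a in alleles:
            p = sum(r.count(a) for r in rows) / (2 * n)
            h = sum(1 for r in rows if r[0] != r[1] and a in r) / n
            sum_b += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            sum_c += h / 2
    return 1 - sum_c / (sum_b + sum_c)


def _brute_force_theta(ds_a, ds_b):
    """Weir–Cockerham theta via literal loops over loci and alleles."""
    num = den = 0.0
    names = [l.name for l in ds_a.loci]
    for li, name in enumerate(names):
        lb = [l.name for l in ds_b.loci].index(name)
        rows1 = [tuple(g) for g in ds_a.genotypes[:, li, :] if g[0] != MISSING]
        rows2 = [tuple(g) for g in ds_b.genotypes[:, lb, :] if g[0] != MISSING]
        alleles = sorted({a for r in rows1 + rows2 for a in r})
        if len(alleles) < 2:
            continue
        n1, n2 = len(rows1), len(rows2)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        for a in alleles:
            p1 = sum(row.count(a) for row in rows1) / (2 * n1)
            p2 = sum(row.count(a) for row in rows2) / (2 * n2)
            h1 = sum(1 for row in rows1 if row[0] != row[1] and a in row) / n1
            h2 = sum(1 for row in rows2 if row[0] != row[1] and a in row) / n2
            pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
            hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
            av = nbar / nc * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
            bv = nbar / (nbar - 1) * (
                pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            cv = hbar / 2
            num += av
            den += av + bv + cv
    return num / den


class TestWeirCockerham:
    def test_all_heterozygotes_f_is_minus_one(self):
        ds = make_dataset([[(1, 2)]] * 10)
        assert ck.multilocus_fis(ds) == pytest.approx(-1.0, abs=1e-12)

    def test_hwe_simulation_near_zero(self, small_hwe_population):
        assert abs(ck.multilocus_fis(small_hwe_population)) < 0.1

    def test_fis_matches_brute_force(self, small_hwe_population):
        ds = small_hwe_population.subset(np.arange(10))
        assert ck.multilocus_fis(ds) == pytest.approx(_brute_force_fis(ds), abs=1e-10)

    def test_theta_fixed_difference_is_one(self):
        a = make_dataset([[(1, 1)]] * 5)
        b = make_dataset([[(2, 2)]] * 5)
        assert ck.weir_cockerham_theta(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_theta_matches_brute_force(self, small_hwe_population):
        ds = small_hwe_population
        a, b = ds.subset(np.arange(8)), ds.subset(np.arange(8, 16))
        assert ck.weir_cockerham_theta(a, b) == pytest.approx(
            _brute_force_theta(a, b), abs=1e-10
        )

    def test_theta_label_swap_invariant(self, small_hwe_population):
        ds = small_hwe_population
        a, b = ds.subset(np.arange(10)), ds.subset(np.arange(10, 25))
        assert ck.weir_cockerham_theta(a, b) == pytest.approx(
            ck.weir_cockerham_theta(b, a), abs=1e-12
        )


class TestPairwiseFst:
    def test_permutation_p_range_and_identity(self, small_hwe_population):
        ds = small_hwe_population
        meta = ds.meta.copy()
        meta.loc[: ds.n // 2, "stage"] = "seedling"
        meta["cwd_id"] = "log1"
        ds2 = ck.GenotypeDataset(meta, ds.genotypes, ds.loci, ds.plot_extent)
        theta, p = ck.pairwise_fst_amova(ds2, "mature", "seedling", n_perms=99, rng=1)
        assert abs(theta) < 0.05  # random split of one population
        assert 1 / 100 <= p <= 1.0


class TestHweExactTest:
    def test_extreme_heterozygote_excess(self):
        ds = make_dataset([[(1, 2)]] * 20)
        p = ck.hwe_mc_exact_test(ds, None, "L01", n_reps=500, rng=0)
        assert p < 0.01

    def test_monomorphic_returns_one(self):
        ds = make_dataset([[(1, 1)]] * 6)
        assert ck.hwe_mc_exact_test(ds, None, "L01", n_reps=10, rng=0) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # biallelic, n=8, allele counts (6, 10): enumerate all genotype tables
        genos = [(1, 1), (1, 2), (1, 2), (1, 2), (1, 2), (2, 2), (2, 2), (2, 2)]
        ds = make_dataset([[g] for g in genos])
        n, n1 = 8, sum(r.count(1) for r in genos)

        def levene(n11, n12, n22):
            het = n12
            return (
                math.lgamma(n + 1)
                - (math.lgamma(n11 + 1) + math.lgamma(n12 + 1) + math.lgamma(n22 + 1))
                + het * math.log(2)
                + math.lgamma(n1 + 1)
                + math.lgamma(2 * n - n1 + 1)
                - math.lgamma(2 * n + 1)
            )

        obs = levene(1, 4, 3)
        exact = total = 0.0
        for n12 in range(n1 % 2, min(n1, 2 * n - n1) + 1, 2):
            n11 = (n1 - n12) // 2
            n22 = n - n11 - n12
            if n11 < 0 or n22 < 0:
                continue
            prob = math.exp(levene(n11, n12, n22))
            total += prob
            if levene(n11, n12, n22) <= obs + 1e-12:
                exact += prob
        assert total == pytest.approx(1.0, abs=1e-9)
        n_reps = 4000
        p_mc = ck.hwe_mc_exact_test(ds, None, "L01", n_reps=n_reps, rng=3)
        exact = min(max(exact, 0.0), 1.0)  # guard float rounding
        se = math.sqrt(exact * (1 - exact) / n_reps)
        assert abs(p_mc - exact) < 3 * se + 1 / n_reps


class TestLinkageDisequilibrium:
    def test_duplicated_locus_detected(self):
        rng = np.random.default_rng(0)
        col = [tuple(sorted(rng.choice([1, 2, 3], 2))) for _ in range(40)]
        ds = make_dataset([[g, g] for g in col])
        p = ck.ld_permutation_test(ds, None, ("L01", "L02"), n_reps=200, rng=1)
        assert 1 / 201 <= p < 0.05  # resolution floor is 1/(n_reps + 1)

    def test_independent_loci_not_extreme(self, small_hwe_population):
        p = ck.ld_permutation_test(
            small_hwe_population, None, ("L01", "L02"), n_reps=200, rng=2
        )
        assert p > 0.01


class TestNullAlleles:
    def test_clean_hwe_near_zero(self, small_hwe_population):
        res = ck.null_allele_em(small_hwe_population, None, "L01")
        assert res.null_freq < 0.04

    def test_recovery_of_simulated_null(self):
        cfg = SimConfig(rng_seed=31, n_mature=500, n_loci=3, alleles_per_locus=(8, 12),
                        null_loci_fraction=1.0, null_freq_range=(0.15, 0.15),
                        missing_rate=0.0)
        mat = generate_mature_population(cfg)
        ests = [ck.null_allele_em(mat, None, l.name).null_freq for l in mat.loci]
        for est in ests:
            assert est == pytest.approx(0.15, abs=0.03)

    def test_monotone_in_homozygote_excess(self):
        def dataset_with_hom_excess(extra_hom):
            geno = [[(1, 2)]] * (30 - extra_hom) + [[(1, 1)]] * (15 + extra_hom) \
                + [[(2, 2)]] * 15
            return make_dataset(geno)

        ests = [
            ck.null_allele_em(dataset_with_hom_excess(k), None, "L01").null_freq
            for k in (0, 10, 20)
        ]
        assert ests[0] <= ests[1] <= ests[2]

    def test_joint_ml_clean_hwe_near_zero(self, small_hwe_population):
        f, nus = ck.fis_null_joint_ml(small_hwe_population)
        assert abs(f) < 0.06

    def test_joint_ml_recovery_and_shrinkage(self):
        cfg = SimConfig(rng_seed=9, n_mature=500, n_loci=6, alleles_per_locus=(8, 12),
                        null_loci_fraction=1.0, null_freq_range=(0.1, 0.1),
                        missing_rate=0.0)
        rng = np.random.default_rng(9)
        loci, tables = draw_locus_frequencies(cfg, rng)
        true = _draw_true_genotypes(tables, 500, rng, f=0.1)
        meta = pd.DataFrame({"id": [f"I{i}" for i in range(500)], "stage": "mature",
                             "x": 0.0, "y": 0.0})
        ds = _build_dataset(meta, true, loci, cfg, rng)
        f_hat, nus = ck.fis_null_joint_ml(ds)
        assert f_hat == pytest.approx(0.1, abs=0.05)
        assert np.mean(list(nus.values())) == pytest.approx(0.1, abs=0.05)
        # null-aware estimate strips the null-driven homozygote excess
        assert f_hat < ck.multilocus_fis(ds)
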