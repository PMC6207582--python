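import numpy as np
import pandas as pd
import pytest

import cwdkin as ck
from cwdkin.datasets import AlleleFrequencyTable, DataError
from cwdkin.fsgs import DistanceClassScheme, dataset_self_reference
from conftest import make_dataset


def biallelic_ref(n_genes=1e9):
    return AlleleFrequencyTable(
        freqs={"L01": {1: 0.5, 2: 0.5}, "L02": {1: 0.5, 2: 0.5}},
        gene_counts={"L01": n_genes, "L02": n_genes},
    )


class TestReferenceConstruction:
    def test_plain_mature_frequencies_without_unique_alleles(self):
        mat = make_dataset([[(1, 2)], [(1, 1)]])
        ado = make_dataset([[(1, 2)]], stage="seedling", cwd_id=["log1"])
        ref = ck.build_reference_frequencies(mat, ado)
        assert ref.freqs["L01"] == {1: 0.75, 2: 0.25}
        assert ref.gene_counts["L01"] == 4

    def test_unique_adolescent_allele_gets_one_gene_copy(self):
        mat = make_dataset([[(1, 2)], [(1, 1)]])
        ado = make_dataset([[(3, 3)]], stage="seedling", cwd_id=["log1"])
        ref = ck.build_reference_frequencies(mat, ado)
        assert ref.gene_counts["L01"] == 5
        assert ref.freqs["L01"][3] == pytest.approx(1 / 5)

    def test_two_unique_alleles_add_two_genes(self):
        mat = make_dataset([[(1, 2)], [(1, 1)]])
        ado = make_dataset([[(3, 4)]], stage="seedling", cwd_id=["log1"])
        ref = ck.build_reference_frequencies(mat, ado)
        assert ref.gene_counts["L01"] == 6
        assert ref.freqs["L01"][3] == pytest.approx(1 / 6)
        assert ref.freqs["L01"][4] == pytest.approx(1 / 6)


class TestLoiselleKinship:
    def test_opposite_homozygotes(self):
        ds = make_dataset([[(1, 1), (1, 2)], [(2, 2), (1, 2)]])
        f = ck.loiselle_kinship(ds, "I001", "I002", biallelic_ref(), bias_correction=False)
        # L01 contributes -1 with weight 0.5; L02 contributes 0 with weight 0.5
        assert f == pytest.approx(-0.5, abs=1e-12)

    def test_self_heterozygote_is_zero(self):
        ds = make_dataset([[(1, 2), (1, 2)]])
        f = ck.pairwise_kinship(ds, biallelic_ref(), bias_correction=False)
        assert f[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, small_hwe_population):
        ref = dataset_self_reference(small_hwe_population)
        f = ck.pairwise_kinship(small_hwe_population, ref)
        np.testing.assert_allclose(f, f.T, atol=1e-12)

    def test_matches_brute_force(self, small_hwe_population):
        ds = small_hwe_population.subset(np.arange(8))
        ref = dataset_self_reference(small_hwe_population)
        f = ck.pairwise_kinship(ds, ref, bias_correction=True)

        def brute(i, j):
            num = den = 0.0
            for li, locus in enumerate(ds.loci):
                gi, gj = ds.genotypes[i, li], ds.genotypes[j, li]
                if gi[0] < 0 or gj[0] < 0 or locus.name not in ref.freqs:
                    continue
                table = ref.freqs[locus.name]
                alleles = sorted(set(table) | set(map(int, gi)) | set(map(int, gj)))
                w = sum(table.get(a, 0.0) * (1 - table.get(a, 0.0)) for a in alleles)
                if w <= 0:
                    continue
                n_l = ref.gene_counts[locus.name]
                term = 0.0
                for a in alleles:
                    pa = table.get(a, 0.0)
                    dose_i = sum(1 for x in gi if x == a) / 2
                    dose_j = sum(1 for x in gj if x == a) / 2
                    term += (dose_i - pa) * (dose_j - pa)
                num += term + w / (n_l - 1)
                den += w
            return num / den

        for i in range(8):
            for j in range(8):
                assert f[i, j] == pytest.approx(brute(i, j), abs=1e-10)

    def test_centered_on_own_reference(self, small_hwe_population):
        # with the sample itself as reference and correction on, the mean
        # pairwise kinship over all pairs is ~0
        ds = small_hwe_population
        ref = dataset_self_reference(ds)
        f = ck.pairwise_kinship(ds, ref, bias_correction=True)
        iu, ju = np.triu_indices(ds.n, k=1)
        assert abs(np.nanmean(f[iu, ju])) < 0.01

    def test_no_shared_locus_errors(self):
        ds = make_dataset([[(1, 1), (-1, -1)], [(-1, -1), (1, 2)]])
        with pytest.raises(DataError, match="shared"):
            ck.loiselle_kinship(ds, "I001", "I002", biallelic_ref())


class TestIndividualFis:
    def test_homozygote_and_heterozygote_extremes(self):
        ds = make_dataset([[(1, 1)], [(1, 2)]])
        ref = AlleleFrequencyTable(freqs={"L01": {1: 0.5, 2: 0.5}},
                                   gene_counts={"L01": 1e9})
        fis = ck.individual_fis(ds, ref, bias_correction=False)
        assert fis[0] == pytest.approx(1.0, abs=1e-9)
        assert fis[1] == pytest.approx(-1.0, abs=1e-9)

    def test_recovers_generating_inbreeding(self):
        from cwdkin.simulate import SimConfig, draw_locus_frequencies, \
            _draw_true_genotypes, _build_dataset

        cfg = SimConfig(rng_seed=13, n_loci=8, alleles_per_locus=(6, 10),
                        null_loci_fraction=0.0, missing_rate=0.0)
        rng = np.random.default_rng(13)
        loci, tables = draw_locus_frequencies(cfg, rng)
        true = _draw_true_genotypes(tables, 600, rng, f=0.2)
        meta = pd.DataFrame({"id": [f"I{i}" for i in range(600)], "stage": "mature",
                             "x": 0.0, "y": 0.0})
        ds = _build_dataset(meta, true, loci, cfg, rng)
        ref = AlleleFrequencyTable(
            freqs={f"L{li + 1:02d}": {int(c): float(v) for c, v in zip(codes, p)}
                   for li, (codes, p, _nu) in enumerate(tables)},
            gene_counts={f"L{li + 1:02d}": 1e9 for li in range(len(tables))},
        )
        fis = ck.individual_fis(ds, ref)
        assert np.mean(fis) == pytest.approx(0.2, abs=0.03)


class TestCorrelogram:
    def test_class_scheme_validation_and_assignment(self):
        scheme = DistanceClassScheme((0.0, 10.0, 20.0))
        idx = scheme.assign(np.array([0.0, 9.999, 10.0, 19.9, 25.0]))
        assert list(idx) == [0, 0, 1, 1, -1]
        with pytest.raises(DataError):
            DistanceClassScheme((10.0, 5.0))

    def test_empty_class_reported_without_test(self, small_hwe_population):
        ds = small_hwe_population
        scheme = DistanceClassScheme((0.0, 1e-6, 10.0, 300.0))
        corr = ck.fsgs_correlogram(ds, dataset_self_reference(ds), scheme,
                                   n_perms=20, rng=0)
        row = corr.table.iloc[0]
        assert row["n_pairs"] == 0 and np.isnan(row["p"])
        assert corr.table["n_pairs"].sum() == ds.n * (ds.n - 1) // 2

    def test_min_p_resolution(self, simulated_plot):
        _, _, mat, off = simulated_plot
        ref = ck.build_reference_frequencies(mat, off)
        n_perms = 99
        corr = ck.fsgs_correlogram(off, ref, n_perms=n_perms, rng=1)
        p = corr.table["p"].dropna()
        assert (p >= 2 / (n_perms + 1) - 1e-12).all()

    def test_limited_dispersal_first_class_positive(self, simulated_plot):
        _, _, mat, off = simulated_plot
        ref = ck.build_reference_frequencies(mat, off)
        corr = ck.fsgs_correlogram(off, ref, n_perms=199, rng=2)
        first = corr.table.iloc[0]
        assert first["mean_fij"] > 0
        assert first["mean_fij"] > first["env_hi"]
        assert first["p"] < 0.05


class TestRegressionAndSp:
    def test_constant_kinship_gives_zero_slope(self):
        # identical heterozygotes everywhere: every pair F equal -> slope 0
        geno = [[(1, 2), (3, 4)]] * 8
        coords = [(float(2**i), 0.0) for i in range(8)]
        ds = make_dataset(geno, coords=coords)
        ref = AlleleFrequencyTable(
            freqs={"L01": {1: 0.5, 2: 0.5}, "L02": {3: 0.5, 4: 0.5}},
            gene_counts={"L01": 1e9, "L02": 1e9},
        )
        b_f, se, p = ck.kinship_distance_regression(ds, ref, n_perms=20, rng=0)
        assert b_f == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_independent_ols(self, simulated_plot):
        _, _, mat, off = simulated_plot
        ref = ck.build_reference_frequencies(mat, off)
        b_f, _, _ = ck.kinship_distance_regression(off, ref, n_perms=5, rng=0)
        f = ck.pairwise_kinship(off, ref)
        d = ck.pairwise_distances(off)
        iu, ju = np.triu_indices(off.n, k=1)
        ok = (d[iu, ju] > 0) & ~np.isnan(f[iu, ju])
        coef = np.polyfit(np.log(d[iu, ju][ok]), f[iu, ju][ok], 1)[0]
        assert b_f == pytest.approx(coef, abs=1e-10)

    def test_single_locus_jackknife_errors(self):
        ds = make_dataset([[(1, 2)], [(1, 1)], [(2, 2)]],
                          coords=[(0, 0), (5, 0), (0, 7)])
        ref = AlleleFrequencyTable(freqs={"L01": {1: 0.5, 2: 0.5}},
                                   gene_counts={"L01": 100})
        with pytest.raises(DataError, match="jackknife"):
            ck.kinship_distance_regression(ds, ref, n_perms=5, rng=0)

    def test_sp_values_and_errors(self):
        assert round(ck.sp_statistic(-0.013, 0.055), 3) == 0.014
        assert round(ck.sp_statistic(-0.001, -0.004), 3) == 0.001
        assert ck.sp_statistic(0.0, 0.5) == 0.0
        with pytest.raises(DataError):
            ck.sp_statistic(-0.01, 1.0)

    def test_summary_sp_invariant(self, simulated_plot):
        _, _, mat, off = simulated_plot
        ref = ck.build_reference_frequencies(mat, off)
        s = ck.fsgs_summary(off, ref, n_perms=49, rng=3)
        assert s.sp * (s.f1 - 1.0) == pytest.approx(s.b_f, abs=1e-12)


class TestMeanFisTest:
    def test_bonferroni_adjustment(self, small_hwe_population):
        ds = small_hwe_population
        res = ck.mean_fis_test(ds, dataset_self_reference(ds), n_perms=99,
                               n_stages_for_bonferroni=4, rng=1)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p * 4), abs=1e-12)

    def test_inbred_population_detected(self):
        from cwdkin.simulate import SimConfig, draw_locus_frequencies, \
            _draw_true_genotypes, _build_dataset

        cfg = SimConfig(rng_seed=29, n_loci=8, alleles_per_locus=(6, 10),
                        null_loci_fraction=0.0, missing_rate=0.0)
        rng = np.random.default_rng(29)
        loci, tables = draw_locus_frequencies(cfg, rng)
        true = _draw_true_genotypes(tables, 150, rng, f=0.25)
        meta = pd.DataFrame({"id": [f"I{i}" for i in range(150)], "stage": "mature",
                             "x": 0.0, "y": 0.0})
        ds = _build_dataset(meta, true, loci, cfg, rng)
        res = ck.mean_fis_test(ds, dataset_self_reference(ds), n_perms=199, rng=2)
        assert res.mean_fis == pytest.approx(0.25, abs=0.06)
        assert res.p < 0.05


class TestClusterSummary:
    def _dataset_and_q(self, n=80, n_above=59):
        from cwdkin.simulate import SimConfig, generate_mature_population

        cfg = SimConfig(rng_seed=41, n_mature=n, n_loci=5, alleles_per_locus=(4, 8),
                        null_loci_fraction=0.0, missing_rate=0.0)
        ds = generate_mature_population(cfg)
        q1 = np.concatenate([np.full(n_above, 0.95), np.full(n - n_above, 0.5)])
        q = pd.DataFrame({"cluster_1": q1, "cluster_2": 1 - q1},
                         index=pd.Index([str(i) for i in ds.ids], name="id"))
        return ds, q

    def test_59_members_make_1711_pairs(self):
        ds, q = self._dataset_and_q()
        ref = dataset_self_reference(ds)
        m, pairs, mean_f = ck.cluster_kinship_summary(ds, ref, q, cluster=1)
        assert m == 59
        assert pairs == 1711
        assert np.isfinite(mean_f)

    def test_strict_threshold_excludes_boundary(self):
        ds, q = self._dataset_and_q()
        ref = dataset_self_reference(ds)
        with pytest.raises(DataError, match="threshold"):
            ck.cluster_kinship_summary(ds, ref, q, cluster=1, threshold=0.95)

    def test_all_members_when_q_is_one(self):
        ds, q = self._dataset_and_q()
        q["cluster_1"] = 1.0
        q["cluster_2"] = 0.0
        ref = dataset_self_reference(ds)
        m, pairs, _ = ck.cluster_kinship_summary(ds, ref, q, cluster=1)
        assert m == ds.n


class TestDeltaK:
    def test_hand_computed_value(self):
        rows = []
        rng = np.random.default_rng(0)
        means = {1: -100.0, 2: -80.0, 3: -75.0}
        for k, mu in means.items():
            # two runs symmetric around the mean: sd is exactly |spread|
            spread = 5.0 if k == 2 else 1.0
            rows += [{"K": k, "lnP": mu - spread / np.sqrt(2)},
                     {"K": k, "lnP": mu + spread / np.sqrt(2)}]
        table = ck.evanno_delta_k(pd.DataFrame(rows))
        row = table[table["K"] == 2].iloc[0]
        # |mean(3) - 2*mean(2) + mean(1)| / sd(2) = 15 / 5
        assert row["delta_K"] == pytest.approx(3.0, abs=1e-9)

    def test_linear_lnp_gives_zero(self):
        rows = []
        for k in (1, 2, 3, 4):
            rows += [{"K": k, "lnP": -10.0 * k + 0.5}, {"K": k, "lnP": -10.0 * k - 0.5}]
        table = ck.evanno_delta_k(pd.DataFrame(rows))
        inner = table["delta_K"].iloc[1:-1]
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)

    def test_single_run_per_k_errors(self):
        runs = pd.DataFrame({"K": [1, 2, 3], "lnP": [-10, -8, -7]})
        with pytest.raises(DataError, match="2 runs"):
            ck.evanno_delta_k(runs)


class TestQMatrixReader:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "q.txt"
        path.write_text("a 0.91 0.09\nb 0.40 0.60\n")
        q = ck.read_q_matrix(path)
        assert q.loc["a", "cluster_1"] == pytest.approx(0.91)
        bad = tmp_path / "bad.txt"
        bad.write_text("a 0.9 0.2\n")
        with pytest.raises(DataError):
            ck.read_q_matrix(bad)
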