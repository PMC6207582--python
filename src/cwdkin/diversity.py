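"""Stage-wise genetic diversity and differentiation statistics.

Implements the per-stage summary statistics (observed heterozygosity H_O,
Nei's unbiased gene diversity H_S, rarefaction allelic richness R_S,
Weir–Cockerham inbreeding coefficient F_IS and its null-allele-aware
counterpart) and the supporting tests: Monte-Carlo exact Hardy–Weinberg test,
genotypic linkage-disequilibrium permutation test, and pairwise F_ST
(Weir–Cockerham theta) with a permutation test for stage differentiation.

Null alleles — non-amplifying SSR variants — inflate apparent homozygosity,
so F_IS is also estimated jointly with per-locus null frequencies by
maximum likelihood (a point-estimate approximation of the Bayesian
co-estimation approach used in the field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .datasets import MISSING, AlleleFrequencyTable, DataError, GenotypeDataset


# ---------------------------------------------------------------------------
# basic per-stage statistics


def _stage_subset(dataset: GenotypeDataset, stage: str | None) -> GenotypeDataset:
    return dataset.by_stage(stage) if stage is not None else dataset


def observed_heterozygosity(dataset: GenotypeDataset, stage: str | None = None):
    """Fraction of typed individuals heterozygous, per locus and multilocus mean."""
    sub = _stage_subset(dataset, stage)
    per_locus = {}
    for li, locus in enumerate(sub.loci):
        g = sub.genotypes[:, li, :]
        typed = g[:, 0] != MISSING
        if typed.sum() == 0:
            continue
        per_locus[locus.name] = float(np.mean(g[typed, 0] != g[typed, 1]))
    if not per_locus:
        raise DataError("no typed loci in subset")
    series = pd.Series(per_locus, name="H_O")
    return series, float(series.mean())


def gene_diversity(dataset: GenotypeDataset, stage: str | None = None):
    """Nei's unbiased gene diversity (n/(n-1))(1 - sum p^2), per locus and mean."""
    sub = _stage_subset(dataset, stage)
    per_locus = {}
    for li, locus in enumerate(sub.loci):
        copies = sub.genotypes[:, li, :].ravel()
        copies = copies[copies != MISSING]
        n = copies.size
        if n < 2:
            continue
        _, counts = np.unique(copies, return_counts=True)
        p = counts / n
        per_locus[locus.name] = float(n / (n - 1) * (1.0 - np.sum(p**2)))
    if not per_locus:
        raise DataError("no locus with >= 2 gene copies")
    series = pd.Series(per_locus, name="H_S")
    return series, float(series.mean())


def allelic_richness(dataset: GenotypeDataset, stage: str | None = None, g: int = 74):
    """Rarefaction allelic richness at a standard sample of ``g`` gene copies.

    R_S = sum over alleles of [1 - C(N - N_a, g) / C(N, g)], the expected
    number of distinct alleles in a random subsample of g gene copies.
    """
    sub = _stage_subset(dataset, stage)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    per_locus = {}
    for li, locus in enumerate(sub.loci):
        copies = sub.genotypes[:, li, :].ravel()
        copies = copies[copies != MISSING]
        n_total = copies.size
        if n_total == 0:
            continue
        if g > n_total:
            raise DataError(f"locus {locus.name!r}: only {n_total} gene copies, cannot rarefy to {g}")
        _, counts = np.unique(copies, return_counts=True)
        rs = 0.0
        for n_a in counts:
            if n_total - n_a < g:
                rs += 1.0
            else:
                rs += 1.0 - np.exp(log_comb(n_total - n_a, g) - log_comb(n_total, g))
        per_locus[locus.name] = float(rs)
    if not per_locus:
        raise DataError("no typed loci")
    series = pd.Series(per_locus, name="R_S")
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components


def _locus_stats(genos: np.ndarray, alleles: np.ndarray):
    """Per-allele frequency and heterozygote frequency among typed individuals."""
    typed = genos[:, 0] != MISSING
    g = genos[typed]
    n = len(g)
    if n == 0:
        return 0, None, None
    p = np.empty(len(alleles))
    h = np.empty(len(alleles))
    het = g[:, 0] != g[:, 1]
    for ai, a in enumerate(alleles):
        dose = (g == a).sum(axis=1)
        p[ai] = dose.sum() / (2 * n)
        h[ai] = np.mean(het & (dose == 1))
    return n, p, h


def multilocus_fis(dataset: GenotypeDataset, stage: str | None = None) -> float:
    """Weir–Cockerham inbreeding coefficient f, variance components summed over loci."""
    sub = _stage_subset(dataset, stage)
    if sub.n < 2:
        raise DataError("F_IS needs >= 2 individuals")
    sum_b = sum_c = 0.0
    informative = False
    for li in range(len(sub.loci)):
        genos = sub.genotypes[:, li, :]
        copies = genos[genos != MISSING]
        alleles = np.unique(copies)
        if alleles.size < 2:
            continue
        n, p, h = _locus_stats(genos, alleles)
        if n < 2:
            continue
        informative = True
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        sum_b += b.sum()
        sum_c += c.sum()
    if not informative:
        raise DataError("all loci monomorphic; F_IS undefined")
    denom = sum_b + sum_c
    if denom == 0:
        raise DataError("zero variance; F_IS undefined")
    return float(1.0 - sum_c / denom)


def weir_cockerham_theta(group_a: GenotypeDataset, group_b: GenotypeDataset) -> float:
    """Weir–Cockerham theta (F_ST) for two groups, components summed over loci/alleles."""
    if group_a.n < 2 or group_b.n < 2:
        raise DataError("theta needs >= 2 individuals per group")
    names_a = [l.name for l in group_a.loci]
    names_b = [l.name for l in group_b.loci]
    shared = [n for n in names_a if n in names_b]
    sum_a = sum_all = 0.0
    informative = False
    r = 2
    for name in shared:
        ga = group_a.genotypes[:, names_a.index(name), :]
        gb = group_b.genotypes[:, names_b.index(name), :]
        copies = np.concatenate([ga[ga != MISSING], gb[gb != MISSING]])
        alleles = np.unique(copies)
        if alleles.size < 2:
            continue
        n1, p1, h1 = _locus_stats(ga, alleles)
        n2, p2, h2 = _locus_stats(gb, alleles)
        if n1 < 1 or n2 < 1 or n1 + n2 < 3:
            continue
        informative = True
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = nbar / nc * (
            s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a.sum()
        sum_all += (a + b + c).sum()
    if not informative or sum_all == 0:
        raise DataError("zero total variance; theta undefined")
    return float(sum_a / sum_all)


def pairwise_fst_amova(
    dataset: GenotypeDataset,
    stage_a: str,
    stage_b: str,
    loci_subset: list[str] | None = None,
    n_perms: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Weir–Cockerham theta between two stages with a permutation p-value.

    The null distribution comes from random reassignment of individuals to the
    two groups (group sizes preserved); p is the one-sided proportion of
    permuted thetas >= observed.
    """
    rng = np.random.default_rng(rng)
    sub_a = dataset.by_stage(stage_a)
    sub_b = dataset.by_stage(stage_b)
    if loci_subset is not None:
        drop = [l.name for l in dataset.loci if l.name not in loci_subset]
        sub_a, sub_b = sub_a.drop_loci(drop), sub_b.drop_loci(drop)
    theta = weir_cockerham_theta(sub_a, sub_b)

    pooled_meta = pd.concat([sub_a.meta, sub_b.meta], ignore_index=True)
    pooled_geno = np.concatenate([sub_a.genotypes, sub_b.genotypes])
    n_a, n_tot = sub_a.n, sub_a.n + sub_b.n
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(n_tot)
        ga = GenotypeDataset(pooled_meta.iloc[perm[:n_a]], pooled_geno[perm[:n_a]],
                             list(sub_a.loci), dataset.plot_extent)
        gb = GenotypeDataset(pooled_meta.iloc[perm[n_a:]], pooled_geno[perm[n_a:]],
                             list(sub_a.loci), dataset.plot_extent)
        try:
            if weir_cockerham_theta(ga, gb) >= theta:
                count += 1
        except DataError:
            continue
    p = (count + 1) / (n_perms + 1)
    return theta, p


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test (Monte-Carlo)


def _levene_log_prob(genos: np.ndarray) -> float:
    """Log conditional probability of a genotype array given its allele counts."""
    n = len(genos)
    copies = genos.ravel()
    alleles, allele_counts = np.unique(copies, return_counts=True)
    het = int(np.sum(genos[:, 0] != genos[:, 1]))
    key = np.minimum(genos[:, 0], genos[:, 1]) * (copies.max() + 1) + np.maximum(
        genos[:, 0], genos[:, 1]
    )
    _, geno_counts = np.unique(key, return_counts=True)
    logp = (
        gammaln(n + 1)
        - gammaln(geno_counts + 1).sum()
        + het * np.log(2.0)
        + gammaln(allele_counts + 1).sum()
        - gammaln(2 * n + 1)
    )
    return float(logp)


def hwe_mc_exact_test(
    dataset: GenotypeDataset,
    stage: str | None,
    locus: str,
    n_reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy–Weinberg proportions at one locus.

    The test statistic is the Levene conditional probability of the genotype
    array given the allele counts; the null is sampled by shuffling the 2n
    gene copies into random pairs.  p is the proportion of resampled arrays
    at most as probable as the observed one (observed included).
    """
    rng = np.random.default_rng(rng)
    sub = _stage_subset(dataset, stage)
    li = sub.locus_index(locus)
    genos = sub.genotypes[:, li, :]
    genos = genos[genos[:, 0] != MISSING]
    if len(genos) < 5:
        raise DataError(f"locus {locus!r}: fewer than 5 typed individuals")
    if np.unique(genos).size < 2:
        return 1.0
    obs = _levene_log_prob(genos)
    copies = genos.ravel().copy()
    count = 0
    for _ in range(n_reps):
        rng.shuffle(copies)
        if _levene_log_prob(copies.reshape(-1, 2)) <= obs + 1e-12:
            count += 1
    return (count + 1) / (n_reps + 1)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_permutation_test(
    dataset: GenotypeDataset,
    stage: str | None,
    locus_pair: tuple[str, str],
    n_reps: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Genotypic LD test between two loci via a log-likelihood-ratio statistic.

    The statistic is the G statistic of the genotype-class contingency table;
    the null is built by permuting one locus's genotypes among individuals.
    """
    rng = np.random.default_rng(rng)
    sub = _stage_subset(dataset, stage)
    ia, ib = sub.locus_index(locus_pair[0]), sub.locus_index(locus_pair[1])
    ga, gb = sub.genotypes[:, ia, :], sub.genotypes[:, ib, :]
    typed = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    if typed.sum() < 5:
        raise DataError("fewer than 5 individuals typed at both loci")
    ga, gb = ga[typed], gb[typed]

    def codes(g):
        key = [tuple(sorted(row)) for row in g]
        uniq = sorted(set(key))
        lut = {k: i for i, k in enumerate(uniq)}
        return np.array([lut[k] for k in key]), len(uniq)

    ca, na = codes(ga)
    cb, nb = codes(gb)
    if na < 2 or nb < 2:
        raise DataError("a locus is monomorphic in genotype classes")

    def g_stat(xa, xb):
        table = np.zeros((na, nb))
        np.add.at(table, (xa, xb), 1)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows * cols / table.sum()
        mask = table > 0
        return 2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask]))

    obs = g_stat(ca, cb)
    count = 0
    perm = cb.copy()
    for _ in range(n_reps):
        rng.shuffle(perm)
        if g_stat(ca, perm) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_reps + 1)


# ---------------------------------------------------------------------------
# null alleles


@dataclass
class NullEmResult:
    null_freq: float
    failure_rate: float
    visible_freqs: dict[int, float]
    n_iter: int


def null_allele_em(
    dataset: GenotypeDataset,
    stage: str | None,
    locus: str,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> NullEmResult:
    """EM estimate of the null-allele frequency at one locus.

    Model: Hardy–Weinberg genotype proportions over visible alleles plus a
    null allele; a visible/null heterozygote is scored as a visible homozygote
    and a null homozygote as missing; each individual additionally fails
    genotyping with a co-estimated failure rate regardless of genotype.
    """
    sub = _stage_subset(dataset, stage)
    li = sub.locus_index(locus)
    genos = sub.genotypes[:, li, :]
    typed = genos[:, 0] != MISSING
    n = len(genos)
    n_miss = int(n - typed.sum())
    g = genos[typed]
    if np.unique(g).size < 2:
        raise DataError(f"locus {locus!r} is monomorphic")
    alleles = np.unique(g)
    a_index = {int(a): i for i, a in enumerate(alleles)}
    k = len(alleles)

    het_mask = g[:, 0] != g[:, 1]
    het_counts = np.zeros(k)
    for row in g[het_mask]:
        het_counts[a_index[int(row[0])]] += 1
        het_counts[a_index[int(row[1])]] += 1
    hom_counts = np.zeros(k)
    for row in g[~het_mask]:
        hom_counts[a_index[int(row[0])]] += 1

    copies = g.ravel()
    p = np.array([(copies == a).sum() for a in alleles], dtype=float)
    nu = 0.05
    p = p / p.sum() * (1 - nu)  # joint visible freqs; p.sum() + nu == 1
    beta = 0.5 * n_miss / n if n_miss else 0.0

    for it in range(max_iter):
        # E-step: expected gene-copy counts for visible alleles and the null
        counts = het_counts.copy()
        w = 2 * nu / np.maximum(p + 2 * nu, 1e-300)  # share of A/null among observed A/A
        counts += hom_counts * (2.0 - w)
        null_count = float(np.sum(hom_counts * w))
        fail_exp = 0.0
        if n_miss:
            p_nullhom = (1 - beta) * nu**2
            u = p_nullhom / max(beta + p_nullhom, 1e-300)
            null_count += 2 * n_miss * u
            fail_exp = n_miss * (1 - u)
            # failed individuals are uninformative: posterior equals prior
            counts += 2 * fail_exp * p
            null_count += 2 * fail_exp * nu
        total = counts.sum() + null_count
        new_p = counts / total
        new_nu = null_count / total
        new_beta = fail_exp / n if n_miss else 0.0
        delta = abs(new_nu - nu) + float(np.abs(new_p - p).max())
        p, nu, beta = new_p, new_nu, new_beta
        if delta < tol:
            q_cond = p / max(p.sum(), 1e-300)
            return NullEmResult(
                null_freq=float(nu),
                failure_rate=float(beta),
                visible_freqs={int(a): float(q_cond[i]) for i, a in enumerate(alleles)},
                n_iter=it + 1,
            )
    raise DataError(f"null-allele EM did not converge in {max_iter} iterations")


def fis_null_joint_ml(
    dataset: GenotypeDataset,
    stage: str | None = None,
    f_bounds: tuple[float, float] = (-0.2, 0.95),
) -> tuple[float, dict[str, float]]:
    """Joint ML point estimate of inbreeding f (shared) and per-locus null freqs.

    For each locus the observed genotype classes (heterozygote, apparent
    homozygote per allele, missing) are multinomial with probabilities that
    combine f-inflated homozygosity and null-allele masking; visible allele
    frequencies are profiled out with the EM estimator.  The shared f is found
    by grid search plus bounded refinement of the profile likelihood.
    A boundary solution (f or a null frequency pinned at its bound) is
    reported as-is; callers can flag it.
    """
    sub = _stage_subset(dataset, stage)
    polymorphic: list[int] = []
    for li in range(len(sub.loci)):
        g = sub.genotypes[:, li, :]
        if np.unique(g[g != MISSING]).size >= 2:
            polymorphic.append(li)
    if len(polymorphic) < 2:
        raise DataError("joint ML needs >= 2 polymorphic loci")

    per_locus = []
    for li in polymorphic:
        genos = sub.genotypes[:, li, :]
        typed = genos[:, 0] != MISSING
        g = genos[typed]
        n_miss = int(len(genos) - typed.sum())
        alleles = np.unique(g)
        try:
            em = null_allele_em(sub, None, sub.loci[li].name)
            q = np.array([em.visible_freqs[int(a)] for a in alleles])
            q = q / q.sum()
        except DataError:
            copies = g.ravel()
            q = np.array([(copies == a).sum() for a in alleles], dtype=float)
            q /= q.sum()
        het = g[:, 0] != g[:, 1]
        n_het = int(het.sum())
        hom = np.array([(np.all(g == a, axis=1)).sum() for a in alleles], dtype=float)
        het_logq = 0.0
        for row in g[het]:
            ia = np.searchsorted(alleles, row[0])
            ib = np.searchsorted(alleles, row[1])
            het_logq += np.log(2 * q[ia] * q[ib])
        per_locus.append((q, n_het, het_logq, hom, n_miss))

    def locus_nll(f: float, nu: float, stats) -> float:
        q, n_het, het_logq, hom, n_miss = stats
        p = (1 - nu) * q
        p_het = 1 - f  # per-pair factor; visible-freq part is het_logq (constant in f)
        if p_het <= 0:
            return np.inf
        ll = het_logq + n_het * (2 * np.log1p(-nu) + np.log(p_het))
        p_hom = p**2 * (1 - f) + f * p + 2 * p * nu * (1 - f)
        if np.any(p_hom <= 0):
            return np.inf
        ll += float(np.sum(hom * np.log(p_hom)))
        p_miss = nu**2 * (1 - f) + f * nu
        if p_miss < 0:  # invalid genotype-class distribution
            return np.inf
        if n_miss:
            ll += n_miss * np.log(max(p_miss, 1e-300))
        return -ll

    def profile_nll(f: float) -> tuple[float, list[float]]:
        total = 0.0
        nus = []
        for stats in per_locus:
            res = minimize_scalar(
                lambda nu: locus_nll(f, nu, stats), bounds=(0.0, 0.5), method="bounded",
                options={"xatol": 1e-6},
            )
            zero = locus_nll(f, 0.0, stats)
            if zero <= res.fun:
                nus.append(0.0)
                total += zero
            else:
                nus.append(float(res.x))
                total += float(res.fun)
        return total, nus

    grid = np.linspace(f_bounds[0], f_bounds[1], 24)
    vals = [profile_nll(f)[0] for f in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda f: profile_nll(f)[0], bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    f_hat = float(res.x)
    _, nus = profile_nll(f_hat)
    names = [sub.loci[li].name for li in polymorphic]
    return f_hat, dict(zip(names, nus))


# ---------------------------------------------------------------------------
# summary assembly


def diversity_summary(
    dataset: GenotypeDataset,
    stages: tuple[str, ...] = ("mature", "juvenile", "sapling", "seedling"),
    richness_genes: int | None = None,
) -> pd.DataFrame:
    """Per-stage table of H_O, H_S, F_IS, R_S and null-corrected F_IS."""
    if richness_genes is None:
        # rarefy to the smallest per-locus typed gene count across stages
        richness_genes = min(
            int(min(allele_frequencies_counts(dataset.by_stage(s)))) for s in stages
        )
    rows = {}
    for stage in stages:
        _, ho = observed_heterozygosity(dataset, stage)
        _, hs = gene_diversity(dataset, stage)
        _, rs = allelic_richness(dataset, stage, g=richness_genes)
        fis = multilocus_fis(dataset, stage)
        fis_null, _ = fis_null_joint_ml(dataset, stage)
        rows[stage] = {"H_O": ho, "H_S": hs, "F_IS": fis, "R_S": rs, "F_IS_null": fis_null}
    return pd.DataFrame.from_dict(rows, orient="index")


def allele_frequencies_counts(dataset: GenotypeDataset) -> list[float]:
    mask = dataset.typed_mask()
    return [2.0 * mask[:, li].sum() for li in range(len(dataset.loci))]


def pairwise_fst_matrix(
    dataset: GenotypeDataset,
    stages: tuple[str, ...] = ("mature", "juvenile", "sapling", "seedling"),
    loci_subset: list[str] | None = None,
    n_perms: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise stage F_ST matrix and matching permutation p-values."""
    rng = np.random.default_rng(rng)
    theta = pd.DataFrame(np.nan, index=stages, columns=stages)
    pvals = pd.DataFrame(np.nan, index=stages, columns=stages)
    for i, sa in enumerate(stages):
        for sb in stages[i + 1 :]:
            t, p = pairwise_fst_amova(dataset, sa, sb, loci_subset, n_perms, rng)
            theta.loc[sa, sb] = theta.loc[sb, sa] = t
            pvals.loc[sa, sb] = pvals.loc[sb, sa] = p
    return theta, pvals
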