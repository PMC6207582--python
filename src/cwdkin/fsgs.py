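"""Kinship-based fine-scale spatial genetic structure (FSGS).

The kinship coefficient between individuals i and j is F_ij = (Q_ij - Q_m) /
(1 - Q_m): the excess probability of identity in state of genes sampled from
i and j over that of genes sampled from a reference population.  Here it is
computed with the Loiselle et al. multiallelic estimator: per locus

    F_ij(l) = [ sum_a (p_ia - p_a)(p_ja - p_a) + corr_l ] / sum_a p_a (1 - p_a)

where p_ia in {0, 1/2, 1} is the dose of allele a in i, p_a the reference
frequency, and corr_l = sum_a p_a(1-p_a) / (n_l - 1) a small-sample bias
correction based on the reference gene count n_l (on by default).  Multilocus
values average loci weighted by the per-locus polymorphism sum_a p_a(1-p_a),
dropping loci untyped in either member of a pair.

FSGS per growth stage is summarized by the correlogram of mean F_ij over
distance classes, the regression slope b_F of F_ij on ln(distance), and the
dimensionless intensity Sp = b_F / (F_1 - 1) where F_1 is the mean kinship in
the first distance class.  Significance comes from permuting individual
locations (genotype-location links), which preserves the geometry of the
distance matrix under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import (
    MISSING,
    AlleleFrequencyTable,
    DataError,
    GenotypeDataset,
    allele_frequencies,
    pairwise_distances,
)


@dataclass(frozen=True)
class DistanceClassScheme:
    """Half-open distance intervals [lo, hi) in meters."""

    breakpoints: tuple[float, ...] = tuple(float(b) for b in range(0, 201, 10))

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if len(bp) < 2 or not np.all(np.diff(bp) > 0):
            raise DataError("breakpoints must be strictly increasing, length >= 2")

    @property
    def n_classes(self) -> int:
        return len(self.breakpoints) - 1

    def assign(self, distances: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for distances outside the range."""
        bp = np.asarray(self.breakpoints)
        idx = np.searchsorted(bp, distances, side="right") - 1
        idx[(distances < bp[0]) | (distances >= bp[-1])] = -1
        return idx

    def midpoints(self) -> np.ndarray:
        bp = np.asarray(self.breakpoints)
        return (bp[:-1] + bp[1:]) / 2


# ---------------------------------------------------------------------------
# reference population


def build_reference_frequencies(
    mature: GenotypeDataset, adolescents: GenotypeDataset | None = None
) -> AlleleFrequencyTable:
    """Reference allele frequencies from the mature cohort, augmented with
    one gene copy of every allele observed only in the adolescent stages.

    The augmentation allocates a low, nonzero frequency 1/(n_l + k) to each of
    the k adolescent-unique alleles at a locus so the kinship estimator is
    defined for every observed genotype.
    """
    if mature.n == 0:
        raise DataError("empty mature reference")
    names_m = [l.name for l in mature.loci]
    freqs: dict[str, dict[int, float]] = {}
    counts: dict[str, float] = {}
    for li, name in enumerate(names_m):
        copies = mature.genotypes[:, li, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            continue
        codes, k_codes = np.unique(copies, return_counts=True)
        tally = {int(c): float(k) for c, k in zip(codes, k_codes)}
        if adolescents is not None and name in [l.name for l in adolescents.loci]:
            la = [l.name for l in adolescents.loci].index(name)
            a_copies = adolescents.genotypes[:, la, :].ravel()
            a_codes = np.unique(a_copies[a_copies != MISSING])
            for code in a_codes:
                if int(code) not in tally:
                    tally[int(code)] = 1.0
        total = sum(tally.values())
        freqs[name] = {c: k / total for c, k in tally.items()}
        counts[name] = total
    return AlleleFrequencyTable(freqs=freqs, gene_counts=counts)


# ---------------------------------------------------------------------------
# kinship internals


def _locus_terms(dataset: GenotypeDataset, ref: AlleleFrequencyTable, bias_correction: bool):
    """Per-locus pair-numerator and denominator matrices.

    Returns (num_l, den_l) lists over informative loci: ``num_l`` is
    (Y @ Y.T + corr_l) masked to pairs typed at the locus, ``den_l`` the
    matching w_l mask, where Y are reference-centered dose vectors.
    """
    n = dataset.n
    nums: list[np.ndarray] = []
    dens: list[np.ndarray] = []
    for li, locus in enumerate(dataset.loci):
        if locus.name not in ref.freqs:
            continue
        codes, p = ref.arrays(locus.name)
        w = float(np.sum(p * (1 - p)))
        if w <= 0:  # monomorphic in the reference
            continue
        geno = dataset.genotypes[:, li, :]
        typed = geno[:, 0] != MISSING
        extra = np.setdiff1d(np.unique(geno[typed]), codes)
        if extra.size:  # alleles absent from the reference enter at frequency 0
            codes = np.concatenate([codes, extra])
            p = np.concatenate([p, np.zeros(extra.size)])
        dose = np.zeros((n, codes.size))
        for ci, code in enumerate(codes):
            dose[:, ci] = 0.5 * (geno == code).sum(axis=1)
        y = np.where(typed[:, None], dose - p, 0.0)
        corr = w / (ref.gene_counts[locus.name] - 1.0) if bias_correction else 0.0
        mask = np.outer(typed, typed)
        nums.append((y @ y.T + corr) * mask)
        dens.append(w * mask)
    return nums, dens


def pairwise_kinship(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    bias_correction: bool = True,
) -> np.ndarray:
    """Multilocus Loiselle kinship for every pair (symmetric matrix).

    Entries with no shared typed locus are NaN.  The diagonal holds the
    estimator applied to an individual against itself (not F_is).
    """
    nums, dens = _locus_terms(dataset, ref, bias_correction)
    if not nums:
        raise DataError("no locus polymorphic in the reference")
    num = np.sum(nums, axis=0)
    den = np.sum(dens, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return f


def loiselle_kinship(
    dataset: GenotypeDataset,
    id_i: str,
    id_j: str,
    ref: AlleleFrequencyTable,
    bias_correction: bool = True,
) -> float:
    """Multilocus Loiselle kinship between two named individuals."""
    ids = list(dataset.ids)
    try:
        i, j = ids.index(id_i), ids.index(id_j)
    except ValueError as exc:
        raise KeyError(str(exc)) from exc
    sub = dataset.subset([i, j])
    f = pairwise_kinship(sub, ref, bias_correction)[0, 1]
    if np.isnan(f):
        raise DataError(f"{id_i!r}/{id_j!r}: no shared typed locus")
    return float(f)


def individual_fis(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    bias_correction: bool = True,
) -> np.ndarray:
    """Individual inbreeding coefficients: kinship between the two gene
    copies within each individual (dose vectors are 0/1 per copy).

    Returns one value per individual; NaN if no informative locus is typed.
    """
    n = dataset.n
    num = np.zeros(n)
    den = np.zeros(n)
    informative = False
    for li, locus in enumerate(dataset.loci):
        if locus.name not in ref.freqs:
            continue
        codes, p = ref.arrays(locus.name)
        w = float(np.sum(p * (1 - p)))
        if w <= 0:
            continue
        informative = True
        geno = dataset.genotypes[:, li, :]
        typed = geno[:, 0] != MISSING
        lut = {int(c): float(pc) for c, pc in zip(codes, p)}
        p_u = np.array([lut.get(int(a), 0.0) for a in geno[:, 0]])
        p_v = np.array([lut.get(int(a), 0.0) for a in geno[:, 1]])
        s2 = float(np.sum(p**2))
        corr = w / (ref.gene_counts[locus.name] - 1.0) if bias_correction else 0.0
        vals = (geno[:, 0] == geno[:, 1]).astype(float) - p_u - p_v + s2 + corr
        num += np.where(typed, vals, 0.0)
        den += np.where(typed, w, 0.0)
    if not informative:
        raise DataError("no locus polymorphic in the reference")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


# ---------------------------------------------------------------------------
# correlogram and regression


@dataclass
class CorrelogramResult:
    """Mean kinship per distance class with a permutation envelope."""

    table: pd.DataFrame  # columns: lo, hi, n_pairs, mean_fij, env_lo, env_hi, p
    n_perms: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, label: str | None = None):
        """Correlogram with the permutation envelope (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mid = (self.table["lo"] + self.table["hi"]) / 2
        ax.plot(mid, self.table["mean_fij"], "o-", label=label)
        ax.plot(mid, self.table["env_lo"], "k:", lw=0.8)
        ax.plot(mid, self.table["env_hi"], "k:", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel("distance class midpoint (m)")
        ax.set_ylabel("mean $F_{ij}$")
        return ax


def _pair_arrays(dataset: GenotypeDataset, ref, bias_correction):
    f = pairwise_kinship(dataset, ref, bias_correction)
    d = pairwise_distances(dataset)
    iu, ju = np.triu_indices(dataset.n, k=1)
    return f, d, iu, ju


def fsgs_correlogram(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    scheme: DistanceClassScheme | None = None,
    n_perms: int = 1000,
    rng: np.random.Generator | int | None = None,
    bias_correction: bool = True,
) -> CorrelogramResult:
    """Correlogram of mean pairwise kinship over distance classes.

    The permutation null shuffles individual locations (the genotype-location
    link); the envelope is the 2.5/97.5 percentile band of permuted class
    means and p is the two-sided rank-based probability per class.
    """
    if dataset.n < 3:
        raise DataError("correlogram needs >= 3 individuals")
    scheme = scheme or DistanceClassScheme()
    rng = np.random.default_rng(rng)
    f, d, iu, ju = _pair_arrays(dataset, ref, bias_correction)
    cls = scheme.assign(d[iu, ju])
    fv = f[iu, ju]
    valid = ~np.isnan(fv)
    k = scheme.n_classes

    def class_means(values, ok):
        sums = np.zeros(k)
        cnts = np.zeros(k)
        use = ok & (cls >= 0)
        np.add.at(sums, cls[use], values[use])
        np.add.at(cnts, cls[use], 1)
        with np.errstate(invalid="ignore"):
            return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan), cnts

    obs_mean, counts = class_means(fv, valid)
    perm_means = np.empty((n_perms, k))
    for r in range(n_perms):
        perm = rng.permutation(dataset.n)
        pv = f[perm[iu], perm[ju]]
        perm_means[r], _ = class_means(pv, ~np.isnan(pv))

    with np.errstate(invalid="ignore"):
        env_lo = np.nanpercentile(perm_means, 2.5, axis=0)
        env_hi = np.nanpercentile(perm_means, 97.5, axis=0)
        ge = np.nansum(perm_means >= obs_mean, axis=0)
        le = np.nansum(perm_means <= obs_mean, axis=0)
    p = np.minimum(1.0, 2.0 * np.minimum(ge + 1, le + 1) / (n_perms + 1))
    p[counts == 0] = np.nan
    bp = np.asarray(scheme.breakpoints)
    table = pd.DataFrame(
        {
            "lo": bp[:-1],
            "hi": bp[1:],
            "n_pairs": counts.astype(int),
            "mean_fij": obs_mean,
            "env_lo": np.where(counts > 0, env_lo, np.nan),
            "env_hi": np.where(counts > 0, env_hi, np.nan),
            "p": p,
        }
    )
    return CorrelogramResult(table=table, n_perms=n_perms)


def kinship_distance_regression(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    n_perms: int = 1000,
    rng: np.random.Generator | int | None = None,
    bias_correction: bool = True,
) -> tuple[float, float, float]:
    """Slope b_F of pairwise kinship on ln(distance) over all pairs.

    Returns (b_F, jackknife SE over loci, one-sided permutation p for a
    negative slope).  Pairs at distance 0 are excluded (ln 0 undefined).
    """
    rng = np.random.default_rng(rng)
    nums, dens = _locus_terms(dataset, ref, bias_correction)
    if len(nums) < 2:
        raise DataError("slope jackknife needs >= 2 informative loci")
    num = np.sum(nums, axis=0)
    den = np.sum(dens, axis=0)
    d = pairwise_distances(dataset)
    iu, ju = np.triu_indices(dataset.n, k=1)
    dist = d[iu, ju]
    pos = dist > 0
    if pos.sum() < 3:
        raise DataError("need >= 3 pairs at distinct positive distances")
    x_all = np.full(dist.shape, np.nan)
    x_all[pos] = np.log(dist[pos])

    def slope(y, x):
        ok = ~np.isnan(y) & ~np.isnan(x)
        if ok.sum() < 3:
            return np.nan
        xo, yo = x[ok], y[ok]
        vx = np.var(xo)
        if vx == 0:
            raise DataError("all pairs at identical distance; slope undefined")
        return float(np.cov(xo, yo, bias=True)[0, 1] / vx)

    with np.errstate(invalid="ignore", divide="ignore"):
        fv = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)[iu, ju]
    b_f = slope(fv, x_all)

    # delete-one-locus jackknife
    pseudo = []
    total_num, total_den = np.sum(nums, axis=0), np.sum(dens, axis=0)
    for l in range(len(nums)):
        num_l = total_num - nums[l]
        den_l = total_den - dens[l]
        with np.errstate(invalid="ignore", divide="ignore"):
            fl = np.where(den_l > 0, num_l / np.where(den_l > 0, den_l, 1.0), np.nan)[iu, ju]
        s = slope(fl, x_all)
        if not np.isnan(s):
            pseudo.append(s)
    if len(pseudo) < 2:
        raise DataError("slope jackknife needs >= 2 informative loci")
    pseudo = np.asarray(pseudo)
    m = len(pseudo)
    se = float(np.sqrt((m - 1) / m * np.sum((pseudo - pseudo.mean()) ** 2)))

    fmat = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(dataset.n)
        pv = fmat[perm[iu], perm[ju]]
        if slope(pv, x_all) <= b_f:
            count += 1
    p = (count + 1) / (n_perms + 1)
    return b_f, se, p


def sp_statistic(b_f: float, f_1: float) -> float:
    """FSGS intensity Sp = b_F / (F_1 - 1)."""
    if f_1 == 1:
        raise DataError("Sp undefined for F_1 = 1")
    return b_f / (f_1 - 1.0)


@dataclass
class FsgsSummary:
    """Stage-level FSGS summary: first-class kinship, slope, and Sp."""

    f1: float
    n_pairs_first_class: int
    b_f: float
    b_f_se: float
    b_f_p: float
    sp: float

    def __post_init__(self) -> None:
        assert abs(self.sp * (self.f1 - 1.0) - self.b_f) < 1e-9


def fsgs_summary(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    scheme: DistanceClassScheme | None = None,
    n_perms: int = 1000,
    rng: np.random.Generator | int | None = None,
    bias_correction: bool = True,
) -> FsgsSummary:
    """F_1, b_F (with jackknife SE and permutation p) and Sp for one dataset."""
    scheme = scheme or DistanceClassScheme()
    rng = np.random.default_rng(rng)
    f, d, iu, ju = _pair_arrays(dataset, ref, bias_correction)
    cls = scheme.assign(d[iu, ju])
    fv = f[iu, ju]
    first = (cls == 0) & ~np.isnan(fv)
    if first.sum() == 0:
        raise DataError("no pairs in the first distance class")
    f1 = float(np.mean(fv[first]))
    b_f, se, p = kinship_distance_regression(dataset, ref, n_perms, rng, bias_correction)
    return FsgsSummary(
        f1=f1,
        n_pairs_first_class=int(first.sum()),
        b_f=b_f,
        b_f_se=se,
        b_f_p=p,
        sp=sp_statistic(b_f, f1),
    )


# ---------------------------------------------------------------------------
# mean individual inbreeding


@dataclass
class InbreedingSummary:
    mean_fis: float
    p: float
    p_bonferroni: float
    significant: bool


def mean_fis_test(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    n_perms: int = 1000,
    n_stages_for_bonferroni: int = 4,
    rng: np.random.Generator | int | None = None,
    bias_correction: bool = True,
    alpha: float = 0.05,
) -> InbreedingSummary:
    """Mean individual F_is with a gene-copy re-pairing permutation test.

    The null re-pairs gene copies at random among the stage's individuals
    within each locus (breaking within-individual association while keeping
    allele frequencies fixed); p is one-sided for an excess of inbreeding.
    """
    if dataset.n < 2:
        raise DataError("mean F_is test needs >= 2 individuals")
    rng = np.random.default_rng(rng)
    obs = individual_fis(dataset, ref, bias_correction)
    if np.isnan(obs).any():
        raise DataError("individuals with undefined F_is")
    mean_obs = float(np.mean(obs))

    n = dataset.n
    per_locus = []
    den = np.zeros(n)
    for li, locus in enumerate(dataset.loci):
        if locus.name not in ref.freqs:
            continue
        codes, p = ref.arrays(locus.name)
        w = float(np.sum(p * (1 - p)))
        if w <= 0:
            continue
        geno = dataset.genotypes[:, li, :]
        typed = np.flatnonzero(geno[:, 0] != MISSING)
        if typed.size == 0:
            continue
        lut = {int(c): float(pc) for c, pc in zip(codes, p)}
        copies = geno[typed].ravel()
        p_of = np.array([lut.get(int(a), 0.0) for a in copies])
        s2 = float(np.sum(p**2))
        corr = w / (ref.gene_counts[locus.name] - 1.0) if bias_correction else 0.0
        per_locus.append((typed, copies.copy(), p_of, s2, corr))
        den[typed] += w

    count = 0
    for _ in range(n_perms):
        num = np.zeros(n)
        for typed, copies, p_of, s2, corr in per_locus:
            order = rng.permutation(copies.size)
            u, v = copies[order[0::2]], copies[order[1::2]]
            pu, pv = p_of[order[0::2]], p_of[order[1::2]]
            num[typed] += (u == v).astype(float) - pu - pv + s2 + corr
        perm_mean = float(np.mean(num / den))
        if perm_mean >= mean_obs:
            count += 1
    p = (count + 1) / (n_perms + 1)
    p_bonf = min(1.0, p * n_stages_for_bonferroni)
    return InbreedingSummary(mean_fis=mean_obs, p=p, p_bonferroni=p_bonf,
                             significant=bool(p_bonf < alpha))


# ---------------------------------------------------------------------------
# cluster summaries and Delta K


def read_q_matrix(path: str | Path) -> pd.DataFrame:
    """Whitespace-delimited per-individual cluster membership table.

    First column: individual id; remaining columns: membership probabilities
    (one per cluster).  Rows must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None)
    q = df.set_index(0)
    q.index = q.index.astype(str)
    q.index.name = "id"
    q.columns = [f"cluster_{i + 1}" for i in range(q.shape[1])]
    sums = q.sum(axis=1)
    if (np.abs(sums - 1.0) > 1e-6).any():
        raise DataError("Q-matrix rows do not sum to 1")
    return q


def cluster_kinship_summary(
    dataset: GenotypeDataset,
    ref: AlleleFrequencyTable,
    q_matrix: pd.DataFrame,
    cluster: int | str = 1,
    threshold: float = 0.9,
    stage: str | None = None,
    bias_correction: bool = True,
) -> tuple[int, int, float]:
    """Members with cluster membership strictly above ``threshold`` and their
    pair count and mean pairwise kinship.

    Returns (n_members, n_pairs, mean_F_ij).
    """
    col = cluster if isinstance(cluster, str) else f"cluster_{cluster}"
    sub = dataset.by_stage(stage) if stage is not None else dataset
    missing = [i for i in sub.ids if str(i) not in q_matrix.index]
    if missing:
        raise DataError(f"Q-matrix lacks ids {missing[:5]}")
    q = q_matrix.loc[[str(i) for i in sub.ids], col].to_numpy(dtype=float)
    members = np.flatnonzero(q > threshold)
    m = members.size
    if m < 2:
        raise DataError(f"only {m} members above threshold {threshold}")
    msub = sub.subset(members)
    f = pairwise_kinship(msub, ref, bias_correction)
    iu, ju = np.triu_indices(m, k=1)
    vals = f[iu, ju]
    return m, int(m * (m - 1) // 2), float(np.nanmean(vals))


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Rate-of-change statistic Delta K for selecting the number of clusters.

    ``runs`` has columns ``K`` and ``lnP`` (one row per clustering run).
    Delta K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)) with the
    sample standard deviation over runs; endpoints are NaN, as is any K whose
    run standard deviation is 0 (flagged in the ``degenerate`` column).
    """
    if not {"K", "lnP"} <= set(runs.columns):
        raise DataError("runs table needs columns K and lnP")
    grouped = runs.groupby("K")["lnP"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DataError(f"need >= 2 runs per K; offending K: {bad}")
    ks = np.array(sorted(counts.index))
    if len(ks) < 3 or not np.all(np.diff(ks) == 1):
        raise DataError("Delta K needs >= 3 contiguous K values")
    mean = grouped.mean().loc[ks].to_numpy()
    sd = grouped.std(ddof=1).loc[ks].to_numpy()
    delta = np.full(len(ks), np.nan)
    degenerate = np.zeros(len(ks), dtype=bool)
    for i in range(1, len(ks) - 1):
        if sd[i] == 0:
            degenerate[i] = True
        else:
            delta[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    return pd.DataFrame(
        {"K": ks, "mean_lnP": mean, "sd_lnP": sd, "delta_K": delta, "degenerate": degenerate}
    )


def dataset_self_reference(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    """The dataset's own allele frequencies (no external reference, no
    augmentation) — the reference used for the thinning analyses."""
    return allele_frequencies(dataset)
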