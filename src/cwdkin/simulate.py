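"""Spatially explicit stage-structured SSR data generator.

Emulates the study system the analysis pipeline assumes: a 200 m x 250 m
plot strewn with fallen logs (coarse woody debris), a mature conifer
population genotyped at multiallelic SSR loci (some carrying null alleles),
and offspring cohorts established only on logs, produced under the same
seed/pollen dispersal process the neighborhood model fits — immigrant seed
and pollen pools, exponential-power kernels, dbh-dependent fecundity
exp(gamma * z), zero selfing, Mendelian inheritance, then a genotyping-error
layer (null-allele masking plus random dropout).  The true pedigree and
pre-error genotypes are recorded alongside every generated cohort, so the
downstream estimators can be validated against known truth.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import MISSING, AlleleFrequencyTable, DataError, GenotypeDataset, Locus
from .dispersal import exp_power_logpdf

#: internal allele code for a non-amplifying (null) allele in true genotypes
NULL_ALLELE = -9


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults reproduce the study conditions the pipeline targets: plot size,
    112 logs, 123 mature trees, 11 SSR loci with 3-46 alleles, a subset of
    loci carrying null alleles at 0.09-0.185, and the fitted seedling-stage
    kernel/immigration parameters as the generative truth.
    """

    plot_extent: tuple[float, float] = (200.0, 250.0)
    n_logs: int = 112
    log_length_range: tuple[float, float] = (5.0, 25.0)
    log_diameter_range: tuple[float, float] = (20.0, 80.0)
    n_mature: int = 123
    n_seedlings: int = 179
    n_saplings: int = 190
    n_juveniles: int = 39
    n_loci: int = 11
    alleles_per_locus: tuple[int, int] = (3, 46)
    null_loci_fraction: float = 5.0 / 11.0
    null_freq_range: tuple[float, float] = (0.09, 0.185)
    missing_rate: float = 0.01
    seed_kernel: tuple[float, float] = (3.823, 0.571)  # (a_s, b_s)
    pollen_kernel: tuple[float, float] = (81.816, 3.097)  # (a_p, b_p)
    m_s: float = 0.744
    m_p: float = 0.866
    gamma: float = 1.2
    selfing: float = 0.0
    background_divergence: float = 0.05
    soil_establishment: bool = False  # offspring restricted to logs by default
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.m_s, self.m_p, self.selfing, self.missing_rate,
                  self.null_loci_fraction):
            if not 0.0 <= p <= 1.0:
                raise DataError(f"probability {p} outside [0, 1]")
        for a, b in (self.seed_kernel, self.pollen_kernel):
            if a <= 0 or b <= 0:
                raise DataError("kernel parameters must be positive")


@dataclass
class Landscape:
    """Fallen-log line segments within the plot."""

    plot_extent: tuple[float, float]
    logs: pd.DataFrame  # columns: cwd_id, x0, y0, x1, y1, diameter, length

    def __post_init__(self) -> None:
        w, h = self.plot_extent
        xs = self.logs[["x0", "x1"]].to_numpy()
        ys = self.logs[["y0", "y1"]].to_numpy()
        if (xs < -1e-9).any() or (xs > w + 1e-9).any() or (ys < -1e-9).any() or (ys > h + 1e-9).any():
            raise DataError("log segments extend outside the plot")
        if (self.logs["diameter"] < 20).any():
            raise DataError("log diameters must be >= 20 cm")


def _clip_segment(p0, p1, w, h):
    """Liang–Barsky clip of segment p0-p1 to the rectangle [0,w]x[0,h]."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for dim, lim in ((0, w), (1, h)):
        for sign, q in ((-d[dim], p0[dim]), (d[dim], lim - p0[dim])):
            if sign == 0:
                if q < 0:
                    return None
                continue
            t = q / sign
            if sign < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
    if t0 > t1:
        return None
    return p0 + t0 * d, p0 + t1 * d


def generate_landscape(config: SimConfig, rng: np.random.Generator | int | None = None) -> Landscape:
    """Place ``n_logs`` randomly oriented segments uniformly, clipped to the plot."""
    if config.n_logs < 1:
        raise DataError("need at least one log")
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    w, h = config.plot_extent
    rows = []
    while len(rows) < config.n_logs:
        mid = rng.uniform((0, 0), (w, h))
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(*config.log_length_range)
        half = 0.5 * length * np.array([np.cos(angle), np.sin(angle)])
        clipped = _clip_segment(mid - half, mid + half, w, h)
        if clipped is None:
            continue
        p0, p1 = clipped
        rows.append(
            {
                "cwd_id": f"log{len(rows) + 1:03d}",
                "x0": p0[0], "y0": p0[1], "x1": p1[0], "y1": p1[1],
                "diameter": rng.uniform(*config.log_diameter_range),
                "length": float(np.hypot(*(p1 - p0))),
            }
        )
    return Landscape(plot_extent=config.plot_extent, logs=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# allele frequencies and genotype draws


def draw_locus_frequencies(config: SimConfig, rng: np.random.Generator):
    """Dirichlet-sampled allele frequencies and null frequencies per locus."""
    loci = []
    tables = []
    lo, hi = config.alleles_per_locus
    for li in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        codes = tuple(100 + 2 * li + 50 * np.arange(k))  # fragment-size-like labels
        p = rng.dirichlet(np.ones(k))
        p = np.maximum(p, 1e-4)
        p /= p.sum()
        nu = 0.0
        if rng.random() < config.null_loci_fraction:
            nu = float(rng.uniform(*config.null_freq_range))
        loci.append(Locus(name=f"L{li + 1:02d}", allele_codes=tuple(int(c) for c in codes),
                          null_freq=nu))
        tables.append((np.array(codes, dtype=np.int64), p, nu))
    return loci, tables


def _draw_true_genotypes(tables, n: int, rng: np.random.Generator, f: float = 0.0):
    """HWE (or inbred, coefficient f) true genotypes; null allele included."""
    n_loci = len(tables)
    geno = np.empty((n, n_loci, 2), dtype=np.int64)
    for li, (codes, p, nu) in enumerate(tables):
        joint_codes = np.append(codes, NULL_ALLELE)
        joint_p = np.append((1 - nu) * p, nu)
        first = rng.choice(joint_codes, size=n, p=joint_p)
        second = rng.choice(joint_codes, size=n, p=joint_p)
        if f > 0:
            ibd = rng.random(n) < f
            second = np.where(ibd, first, second)
        geno[:, li, 0] = first
        geno[:, li, 1] = second
    return geno


def apply_genotyping_errors(
    true_geno: np.ndarray, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Null-allele masking plus random dropout.

    A visible/null heterozygote reads as a visible homozygote; a null
    homozygote reads as missing; each (individual, locus) additionally drops
    out with ``missing_rate``.
    """
    obs = true_geno.copy()
    a, b = obs[..., 0], obs[..., 1]
    both_null = (a == NULL_ALLELE) & (b == NULL_ALLELE)
    a_null = (a == NULL_ALLELE) & ~both_null
    b_null = (b == NULL_ALLELE) & ~both_null
    obs[..., 0] = np.where(a_null, b, a)
    obs[..., 1] = np.where(b_null, a, b)
    obs[..., 0] = np.where(obs[..., 0] == NULL_ALLELE, MISSING, obs[..., 0])
    obs[..., 1] = np.where(obs[..., 1] == NULL_ALLELE, MISSING, obs[..., 1])
    drop = rng.random(obs.shape[:2]) < missing_rate
    obs[drop | both_null] = MISSING
    return obs


def _build_dataset(meta, true_geno, loci, config, rng) -> GenotypeDataset:
    obs = apply_genotyping_errors(true_geno, config.missing_rate, rng)
    observed_loci = []
    for li, locus in enumerate(loci):
        seen = np.unique(obs[:, li, :][obs[:, li, :] != MISSING])
        codes = tuple(int(c) for c in seen) if seen.size else (0,)
        observed_loci.append(Locus(name=locus.name, allele_codes=codes,
                                   null_freq=locus.null_freq))
    ds = GenotypeDataset(meta=meta, genotypes=obs, loci=observed_loci,
                         plot_extent=config.plot_extent)
    ds.true_genotypes = true_geno  # pre-error genotypes, null allele explicit
    return ds


def generate_mature_population(
    config: SimConfig,
    landscape: Landscape | None = None,
    rng: np.random.Generator | int | None = None,
    tables=None,
    loci=None,
) -> GenotypeDataset:
    """Mature trees placed uniformly, genotyped at HWE, dbh >= 20 cm."""
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    if tables is None or loci is None:
        loci, tables = draw_locus_frequencies(config, rng)
    w, h = config.plot_extent
    n = config.n_mature
    meta = pd.DataFrame(
        {
            "id": [f"M{i + 1:04d}" for i in range(n)],
            "stage": "mature",
            "x": rng.uniform(0, w, n),
            "y": rng.uniform(0, h, n),
            "cwd_id": pd.array([None] * n, dtype="object"),
            "dbh": 20.0 + rng.gamma(shape=2.0, scale=15.0, size=n),
            "age": np.nan,
        }
    )
    true_geno = _draw_true_genotypes(tables, n, rng)
    ds = _build_dataset(meta, true_geno, loci, config, rng)
    ds.locus_tables = tables
    return ds


def background_frequency_table(
    config: SimConfig, tables, rng: np.random.Generator
) -> AlleleFrequencyTable:
    """Immigrant gene-pool frequencies: a Dirichlet perturbation of the local
    tables with concentration 1/divergence (divergence 0 returns them unchanged)."""
    freqs = {}
    counts = {}
    for li, (codes, p, _nu) in enumerate(tables):
        if config.background_divergence > 0:
            q = rng.dirichlet(p / config.background_divergence)
            q = np.maximum(q, 1e-6)
            q /= q.sum()
        else:
            q = p
        freqs[f"L{li + 1:02d}"] = {int(c): float(v) for c, v in zip(codes, q)}
        counts[f"L{li + 1:02d}"] = 1e6  # effectively infinite pool
    return AlleleFrequencyTable(freqs=freqs, gene_counts=counts)


def _establishment_points(landscape: Landscape, n: int, rng: np.random.Generator):
    logs = landscape.logs
    weights = logs["length"].to_numpy()
    weights = weights / weights.sum()
    idx = rng.choice(len(logs), size=n, p=weights)
    t = rng.random(n)
    x = logs["x0"].to_numpy()[idx] * (1 - t) + logs["x1"].to_numpy()[idx] * t
    y = logs["y0"].to_numpy()[idx] * (1 - t) + logs["y1"].to_numpy()[idx] * t
    return x, y, logs["cwd_id"].to_numpy()[idx]


def simulate_offspring_nm(
    config: SimConfig,
    mature: GenotypeDataset,
    landscape: Landscape,
    stage: str = "seedling",
    n_offspring: int | None = None,
    background: AlleleFrequencyTable | None = None,
    rng: np.random.Generator | int | None = None,
    id_prefix: str | None = None,
) -> GenotypeDataset:
    """Offspring generated under the neighborhood dispersal model.

    Establishment points fall on random logs; the seed parent is an immigrant
    with probability ``m_s`` (genotype from the background pool) or a local
    mother drawn proportional to exp(gamma*z) times the seed kernel; pollen is
    immigrant with probability ``m_p`` or from a local father != mother
    weighted by fecundity times the pollen kernel.  Gametes are Mendelian and
    the genotyping-error layer is applied afterwards.  The true pedigree is
    attached as ``dataset.pedigree`` (mother_id/father_id or "IMM").
    """
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    tables = getattr(mature, "locus_tables", None)
    if tables is None:
        raise DataError("mature dataset lacks generating locus tables")
    if background is None:
        background = background_frequency_table(config, tables, rng)
    if n_offspring is None:
        n_offspring = {"seedling": config.n_seedlings, "sapling": config.n_saplings,
                       "juvenile": config.n_juveniles}[stage]
    prefix = id_prefix or {"seedling": "S", "sapling": "P", "juvenile": "J"}[stage]

    x, y, cwd = _establishment_points(landscape, n_offspring, rng)
    coords = np.column_stack([x, y])
    mat_xy = mature.coords
    dbh = mature.meta["dbh"].to_numpy(dtype=float)
    sd = dbh.std()
    z = (dbh - dbh.mean()) / (sd if sd > 0 else 1.0)

    a_s, b_s = config.seed_kernel
    a_p, b_p = config.pollen_kernel
    diff = coords[:, None, :] - mat_xy[None, :, :]
    d_om = np.sqrt((diff**2).sum(axis=2))
    lw = config.gamma * z[None, :] + exp_power_logpdf(d_om, a_s, b_s)
    lw -= lw.max(axis=1, keepdims=True)
    psi = np.exp(lw)
    psi /= psi.sum(axis=1, keepdims=True)

    diff = mat_xy[:, None, :] - mat_xy[None, :, :]
    d_mm = np.sqrt((diff**2).sum(axis=2))
    lp = config.gamma * z[None, :] + exp_power_logpdf(d_mm, a_p, b_p)
    np.fill_diagonal(lp, -np.inf)
    lp -= lp.max(axis=1, keepdims=True)
    phi = np.exp(lp)
    phi /= phi.sum(axis=1, keepdims=True)

    true_mat = getattr(mature, "true_genotypes", mature.genotypes)
    n_loci = len(tables)
    geno = np.empty((n_offspring, n_loci, 2), dtype=np.int64)
    mothers: list[str] = []
    fathers: list[str] = []
    mat_ids = mature.ids

    bg_codes = []
    bg_p = []
    for li, (codes, p, nu) in enumerate(tables):
        name = f"L{li + 1:02d}"
        t_codes, t_p = background.arrays(name)
        bg_codes.append(np.append(t_codes, NULL_ALLELE))
        bg_p.append(np.append((1 - nu) * t_p, nu))

    def background_gamete(li):
        return int(rng.choice(bg_codes[li], p=bg_p[li]))

    for o in range(n_offspring):
        if rng.random() < config.m_s:
            mothers.append("IMM")
            fathers.append("IMM")
            for li in range(n_loci):
                geno[o, li] = (background_gamete(li), background_gamete(li))
            continue
        j = int(rng.choice(len(mat_ids), p=psi[o]))
        mothers.append(str(mat_ids[j]))
        if rng.random() < config.m_p:
            fathers.append("IMM")
            paternal = [background_gamete(li) for li in range(n_loci)]
        else:
            k = int(rng.choice(len(mat_ids), p=phi[j]))
            fathers.append(str(mat_ids[k]))
            paternal = [true_mat[k, li, rng.integers(2)] for li in range(n_loci)]
        for li in range(n_loci):
            geno[o, li] = (true_mat[j, li, rng.integers(2)], paternal[li])

    meta = pd.DataFrame(
        {
            "id": [f"{prefix}{i + 1:04d}" for i in range(n_offspring)],
            "stage": stage,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "cwd_id": cwd,
            "dbh": np.nan,
            "age": np.nan,
        }
    )
    loci = [Locus(name=f"L{li + 1:02d}", allele_codes=tuple(int(c) for c in tables[li][0]),
                  null_freq=tables[li][2]) for li in range(n_loci)]
    ds = _build_dataset(meta, geno, loci, config, rng)
    ds.locus_tables = tables
    ds.pedigree = pd.DataFrame(
        {"offspring_id": meta["id"], "mother_id": mothers, "father_id": fathers}
    )
    ds.background = background
    return ds


# ---------------------------------------------------------------------------
# sib families (kinship validation harness)


def equifrequent_reference(n_loci: int = 10, n_alleles: int = 10) -> AlleleFrequencyTable:
    """Reference table of ``n_loci`` loci with ``n_alleles`` equifrequent alleles."""
    freqs = {
        f"L{li + 1:02d}": {100 + 10 * a: 1.0 / n_alleles for a in range(n_alleles)}
        for li in range(n_loci)
    }
    counts = {name: 1e9 for name in freqs}
    return AlleleFrequencyTable(freqs=freqs, gene_counts=counts)


def generate_sib_families(
    n_families: int = 500,
    family_size: int = 2,
    kind: str = "half",
    ref: AlleleFrequencyTable | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame, AlleleFrequencyTable]:
    """Labelled half-sib or full-sib cohorts from a known reference pool.

    Half-sib families share the mother with independent fathers; full-sib
    families share both parents.  Returns (dataset, pedigree, reference).
    """
    if family_size < 2:
        raise DataError("family sizes must be >= 2")
    if kind not in ("half", "full"):
        raise DataError("kind must be 'half' or 'full'")
    rng = np.random.default_rng(rng)
    ref = ref or equifrequent_reference()
    names = ref.locus_names
    n_loci = len(names)

    def draw_parent():
        g = np.empty((n_loci, 2), dtype=np.int64)
        for li, name in enumerate(names):
            codes, p = ref.arrays(name)
            g[li] = rng.choice(codes, size=2, p=p)
        return g

    n_total = n_families * family_size
    geno = np.empty((n_total, n_loci, 2), dtype=np.int64)
    rows = []
    ped = []
    i = 0
    for fam in range(n_families):
        mother = draw_parent()
        father = draw_parent() if kind == "full" else None
        for off in range(family_size):
            sire = father if kind == "full" else draw_parent()
            for li in range(n_loci):
                geno[i, li] = (mother[li, rng.integers(2)], sire[li, rng.integers(2)])
            oid = f"F{fam + 1:04d}O{off + 1}"
            rows.append({"id": oid, "stage": "seedling", "x": float(fam % 50),
                         "y": float(fam // 50), "cwd_id": f"log{fam + 1:04d}",
                         "dbh": np.nan, "age": np.nan})
            ped.append({"offspring_id": oid, "family": fam,
                        "mother_id": f"F{fam + 1:04d}M",
                        "father_id": f"F{fam + 1:04d}P" if kind == "full"
                        else f"F{fam + 1:04d}P{off + 1}"})
            i += 1
    loci = [Locus(name=name, allele_codes=tuple(sorted(ref.freqs[name])))
            for name in names]
    meta = pd.DataFrame(rows)
    ds = GenotypeDataset(meta=meta, genotypes=geno, loci=loci)
    return ds, pd.DataFrame(ped), ref


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    """Pedigree TSV: offspring_id, mother_id|IMM, father_id|IMM."""
    pedigree.to_csv(path, sep="\t", index=False)
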