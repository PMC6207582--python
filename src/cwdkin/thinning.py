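"""Demographic-thinning simulations on the pooled offspring cohort.

Three mortality scenarios are imposed on the pooled seedling + sapling
dataset and the FSGS statistics are recomputed for every surviving dataset:

1. inbreeding depression — keep the ``n_keep`` offspring with the lowest
   individual inbreeding coefficients (the most inbred die);
2. stochastic loss — repeated uniform subsamples without replacement;
3. local disturbance — eradicate every offspring on the most offspring-rich
   logs (top-k for k = 1..5, or every log holding more than eight offspring).

Following the thinning analyses' convention, the report statistics use each
surviving dataset's own allele frequencies as the kinship reference (no
external reference population, no augmentation); the inbreeding ranking for
scenario 1, by contrast, uses the reference supplied by the caller, since
offspring inbreeding is assessed before the simulated deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import AlleleFrequencyTable, DataError, GenotypeDataset
from .fsgs import (
    DistanceClassScheme,
    dataset_self_reference,
    fsgs_summary,
    individual_fis,
    mean_fis_test,
)


def pool_offspring(seedlings: GenotypeDataset, saplings: GenotypeDataset) -> GenotypeDataset:
    """Union of the two cohorts with stage labels retained."""
    ids_a = set(map(str, seedlings.ids))
    ids_b = set(map(str, saplings.ids))
    clash = ids_a & ids_b
    if clash:
        raise DataError(f"id collision between cohorts: {sorted(clash)[:5]}")
    if saplings.n == 0:
        return seedlings.subset(np.arange(seedlings.n))
    names_a = [l.name for l in seedlings.loci]
    names_b = [l.name for l in saplings.loci]
    if names_a != names_b:
        raise DataError("cohorts genotyped at different loci")
    loci = []
    for la, lb in zip(seedlings.loci, saplings.loci):
        codes = tuple(sorted(set(la.allele_codes) | set(lb.allele_codes)))
        loci.append(type(la)(name=la.name, allele_codes=codes, null_freq=la.null_freq))
    meta = pd.concat([seedlings.meta, saplings.meta], ignore_index=True)
    geno = np.concatenate([seedlings.genotypes, saplings.genotypes])
    return GenotypeDataset(meta=meta, genotypes=geno, loci=loci,
                           plot_extent=seedlings.plot_extent)


def thin_by_inbreeding(
    pooled: GenotypeDataset,
    ref_for_fis: AlleleFrequencyTable,
    n_keep: int = 123,
) -> GenotypeDataset:
    """Survivors are the ``n_keep`` offspring with the lowest individual F_is.

    Ranking ties are broken by position in the dataset (stable sort), and an
    individual with undefined F_is (no typed informative locus) is an error.
    """
    if pooled.n < n_keep:
        raise DataError(f"pooled size {pooled.n} below n_keep {n_keep}")
    fis = individual_fis(pooled, ref_for_fis)
    bad = np.flatnonzero(np.isnan(fis))
    if bad.size:
        raise DataError(f"undefined F_is for ids {list(pooled.ids[bad])[:5]}")
    order = np.argsort(fis, kind="stable")
    return pooled.subset(np.sort(order[:n_keep]))


def thin_random(
    pooled: GenotypeDataset,
    n_keep: int = 123,
    n_reps: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[GenotypeDataset]:
    """``n_reps`` independent uniform subsets of size ``n_keep`` without replacement."""
    if pooled.n < n_keep:
        raise DataError(f"pooled size {pooled.n} below n_keep {n_keep}")
    rng = np.random.default_rng(rng)
    return [
        pooled.subset(np.sort(rng.choice(pooled.n, size=n_keep, replace=False)))
        for _ in range(n_reps)
    ]


def thin_by_cwd(pooled: GenotypeDataset, rule: int | str) -> GenotypeDataset:
    """Remove all offspring on the most offspring-rich logs.

    ``rule`` is an integer k (eradicate the top-k logs by offspring count) or
    the string ``">8"`` (eradicate every log holding more than eight
    offspring).  Count ties at the rank boundary are broken by log id.
    """
    if "cwd_id" not in pooled.meta.columns or pooled.meta["cwd_id"].isna().any():
        raise DataError("every offspring needs a cwd_id")
    counts = pooled.meta.groupby("cwd_id").size()
    ranked = counts.iloc[np.lexsort((counts.index.astype(str), -counts.to_numpy()))]
    if rule == ">8":
        doomed = set(ranked.index[ranked > 8])
    else:
        k = int(rule)
        if k < 0:
            raise DataError("rule must be a non-negative k or '>8'")
        doomed = set(ranked.index[:k])
    keep = ~pooled.meta["cwd_id"].isin(doomed)
    return pooled.subset(keep.to_numpy())


@dataclass
class ThinningReport:
    """Per-scenario FSGS statistics for the surviving datasets."""

    table: pd.DataFrame  # dataset, n, mean_fis, fis_p, f1, b_f, b_f_se, b_f_p, sp
    survivors: dict[str, list[str]]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def thinning_fsgs_report(
    datasets: dict[str, GenotypeDataset],
    scheme: DistanceClassScheme | None = None,
    n_perms: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ThinningReport:
    """FSGS statistics per dataset, each against its own allele frequencies.

    For every dataset: mean individual F_is with its permutation p, the
    first-class mean kinship F_1, the ln-distance slope b_F with jackknife SE
    and permutation p, and Sp.
    """
    rng = np.random.default_rng(rng)
    scheme = scheme or DistanceClassScheme()
    rows = []
    survivors = {}
    for name, ds in datasets.items():
        if ds.n < 3:
            raise DataError(f"dataset {name!r} has fewer than 3 individuals")
        ref = dataset_self_reference(ds)
        fis = mean_fis_test(ds, ref, n_perms=n_perms, rng=rng)
        summ = fsgs_summary(ds, ref, scheme=scheme, n_perms=n_perms, rng=rng)
        rows.append(
            {
                "dataset": name,
                "n": ds.n,
                "mean_fis": fis.mean_fis,
                "fis_p": fis.p,
                "f1": summ.f1,
                "b_f": summ.b_f,
                "b_f_se": summ.b_f_se,
                "b_f_p": summ.b_f_p,
                "sp": summ.sp,
            }
        )
        survivors[name] = [str(i) for i in ds.ids]
    return ThinningReport(table=pd.DataFrame(rows), survivors=survivors)


def standard_scenarios(
    pooled: GenotypeDataset,
    ref_for_fis: AlleleFrequencyTable,
    n_keep: int = 123,
    n_random_reps: int = 10,
    rng: np.random.Generator | int | None = None,
) -> dict[str, GenotypeDataset]:
    """The full scenario battery: inbred removal, random removals, and the
    six CWD-eradication datasets (top-1..5 logs and the >8-offspring rule)."""
    rng = np.random.default_rng(rng)
    out: dict[str, GenotypeDataset] = {"inbred": thin_by_inbreeding(pooled, ref_for_fis, n_keep)}
    for i, ds in enumerate(thin_random(pooled, n_keep, n_random_reps, rng)):
        out[f"random_{i + 1}"] = ds
    for k in range(1, 6):
        out[f"cwd_top{k}"] = thin_by_cwd(pooled, k)
    out["cwd_gt8"] = thin_by_cwd(pooled, ">8")
    return out
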