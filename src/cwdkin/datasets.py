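"""Core data model and I/O for stage-structured, spatially referenced codominant genotypes.

The central container is :class:`GenotypeDataset`: a metadata table (one row per
individual: id, growth stage, plot coordinates in meters, optional log/CWD id,
dbh, age) plus an integer-coded genotype array of shape ``(n_individuals,
n_loci, 2)``.  Allele codes are opaque integer labels (SSR fragment sizes);
``MISSING`` (-1) marks an untyped gene copy.  A locus is treated as missing for
an individual when either of its two gene copies is missing, and estimators
downstream drop such loci pairwise.

Coordinates are plot-local meters with the origin at a plot corner; all
distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

STAGES = ("seedling", "sapling", "juvenile", "mature")

#: Stages collectively referred to as adolescents (all pre-mature stages).
ADOLESCENT_STAGES = ("seedling", "sapling", "juvenile")


class DataError(ValueError):
    """Malformed input data (parse or validation failure)."""


@dataclass(frozen=True)
class Locus:
    """A codominant marker locus.

    Parameters
    ----------
    name : str
        Locus identifier.
    allele_codes : tuple of int
        Ordered registry of observed allele labels.
    missing_code : int
        Sentinel for an untyped gene copy.
    null_freq : float, optional
        Estimated null-allele frequency in [0, 1].
    """

    name: str
    allele_codes: tuple[int, ...]
    missing_code: int = MISSING
    null_freq: float | None = None

    def __post_init__(self) -> None:
        if len(self.allele_codes) == 0:
            raise DataError(f"locus {self.name!r}: empty allele registry")
        if self.null_freq is not None and not (0.0 <= self.null_freq <= 1.0):
            raise DataError(f"locus {self.name!r}: null_freq {self.null_freq} outside [0, 1]")


@dataclass
class GenotypeDataset:
    """Stage-structured, spatially referenced multilocus genotype data.

    Attributes
    ----------
    meta : pandas.DataFrame
        One row per individual with columns ``id``, ``stage``, ``x``, ``y`` and
        optionally ``cwd_id``, ``dbh``, ``age``.
    genotypes : numpy.ndarray
        Integer array ``(n, n_loci, 2)``; ``MISSING`` marks untyped copies.
    loci : list of Locus
    plot_extent : (float, float)
        Plot width and height in meters.
    """

    meta: pd.DataFrame
    genotypes: np.ndarray
    loci: list[Locus]
    plot_extent: tuple[float, float] = (200.0, 250.0)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.shape != (len(self.meta), len(self.loci), 2):
            raise DataError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.meta)} individuals x {len(self.loci)} loci x 2"
            )
        ids = self.meta["id"].astype(str)
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise DataError(f"duplicate individual ids: {dups[:5]}")
        bad = ~self.meta["stage"].isin(STAGES)
        if bad.any():
            raise DataError(f"unknown stage labels: {sorted(self.meta.loc[bad, 'stage'].unique())}")
        if not np.all(np.isfinite(self.meta[["x", "y"]].to_numpy(dtype=float))):
            raise DataError("non-finite coordinates")
        # one missing gene copy at a locus marks the whole locus missing
        half = (self.genotypes == MISSING).any(axis=2)
        self.genotypes[half] = MISSING
        self._validate_registry()
        self._validate_stage_rules()

    def _validate_registry(self) -> None:
        for li, locus in enumerate(self.loci):
            observed = self.genotypes[:, li, :]
            typed = observed[observed != MISSING]
            unknown = np.setdiff1d(typed, np.asarray(locus.allele_codes, dtype=np.int64))
            if unknown.size:
                raise DataError(
                    f"locus {locus.name!r}: alleles {unknown[:5].tolist()} not in registry"
                )

    def _validate_stage_rules(self) -> None:
        if "dbh" in self.meta.columns:
            dbh = pd.to_numeric(self.meta["dbh"], errors="coerce")
            mature_bad = (self.meta["stage"] == "mature") & dbh.notna() & (dbh < 20)
            juv_bad = (self.meta["stage"] == "juvenile") & dbh.notna() & ~((dbh >= 5) & (dbh < 20))
            if mature_bad.any():
                raise DataError(f"mature individuals with dbh < 20 cm: "
                                f"{self.meta.loc[mature_bad, 'id'].tolist()[:5]}")
            if juv_bad.any():
                raise DataError(f"juveniles with dbh outside [5, 20) cm: "
                                f"{self.meta.loc[juv_bad, 'id'].tolist()[:5]}")
        if "cwd_id" in self.meta.columns:
            on_logs = self.meta["stage"].isin(("seedling", "sapling"))
            no_log = on_logs & self.meta["cwd_id"].isna()
            if no_log.any():
                raise DataError(f"seedlings/saplings without cwd_id: "
                                f"{self.meta.loc[no_log, 'id'].tolist()[:5]}")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def ids(self) -> np.ndarray:
        return self.meta["id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in meters."""
        return self.meta[["x", "y"]].to_numpy(dtype=float)

    def locus_index(self, name: str) -> int:
        for i, locus in enumerate(self.loci):
            if locus.name == name:
                return i
        raise KeyError(name)

    def typed_mask(self) -> np.ndarray:
        """(n, n_loci) boolean: locus fully typed for the individual."""
        return (self.genotypes != MISSING).all(axis=2)

    def subset(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            meta=self.meta.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[index].copy(),
            loci=list(self.loci),
            plot_extent=self.plot_extent,
        )

    def by_stage(self, stage: str) -> "GenotypeDataset":
        if stage not in STAGES:
            raise DataError(f"unknown stage {stage!r}")
        sub = self.subset(self.meta["stage"].to_numpy() == stage)
        if sub.n == 0:
            raise DataError(f"no individuals in stage {stage!r}")
        return sub

    def drop_loci(self, names: Iterable[str]) -> "GenotypeDataset":
        names = set(names)
        keep = [i for i, locus in enumerate(self.loci) if locus.name not in names]
        return GenotypeDataset(
            meta=self.meta.copy(),
            genotypes=self.genotypes[:, keep, :].copy(),
            loci=[self.loci[i] for i in keep],
            plot_extent=self.plot_extent,
        )


@dataclass
class AlleleFrequencyTable:
    """Per-locus reference allele frequencies with gene counts.

    ``freqs[locus_name]`` maps allele code -> frequency; ``gene_counts`` holds
    the number of sampled gene copies behind each locus.  This is the reference
    gene pool whose probability of identity centers the kinship estimator.
    """

    freqs: dict[str, dict[int, float]]
    gene_counts: dict[str, float]

    def __post_init__(self) -> None:
        for name, table in self.freqs.items():
            if not table:
                raise DataError(f"locus {name!r}: empty frequency table")
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise DataError(f"locus {name!r}: frequencies sum to {total}, not 1")
            if any(p <= 0 for p in table.values()):
                raise DataError(f"locus {name!r}: non-positive frequency")
            if self.gene_counts.get(name, 0) < 2:
                raise DataError(f"locus {name!r}: gene count below 2")

    @property
    def locus_names(self) -> list[str]:
        return list(self.freqs)

    def arrays(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Allele codes and frequencies as parallel arrays (code-sorted)."""
        table = self.freqs[name]
        codes = np.array(sorted(table), dtype=np.int64)
        p = np.array([table[c] for c in codes], dtype=float)
        return codes, p


def allele_frequencies(dataset: GenotypeDataset, stage: str | None = None) -> AlleleFrequencyTable:
    """Observed allele frequencies over non-missing gene copies.

    Loci with zero typed individuals in the subset are excluded.
    """
    sub = dataset.by_stage(stage) if stage is not None else dataset
    freqs: dict[str, dict[int, float]] = {}
    counts: dict[str, float] = {}
    for li, locus in enumerate(sub.loci):
        copies = sub.genotypes[:, li, :].ravel()
        copies = copies[copies != MISSING]
        if copies.size == 0:
            import warnings

            warnings.warn(f"locus {locus.name!r}: no typed individuals, excluded")
            continue
        codes, n_codes = np.unique(copies, return_counts=True)
        total = copies.size
        freqs[locus.name] = {int(c): k / total for c, k in zip(codes, n_codes)}
        counts[locus.name] = float(total)
    return AlleleFrequencyTable(freqs=freqs, gene_counts=counts)


def pairwise_distances(dataset: GenotypeDataset) -> np.ndarray:
    """Symmetric matrix of Euclidean distances in meters (zero diagonal)."""
    from scipy.spatial.distance import squareform, pdist

    xy = dataset.coords
    if len(xy) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(xy))


# -- tabular I/O ---------------------------------------------------------

_META_COLS = ("id", "stage", "x", "y", "cwd_id", "dbh", "age")


def read_genotype_table(
    path: str | Path,
    locus_names: Sequence[str] | None = None,
    plot_extent: tuple[float, float] = (200.0, 250.0),
    missing_codes: tuple = (MISSING, 0, "NA", ""),
    sep: str = ",",
) -> GenotypeDataset:
    """Read a genotype table (CSV/TSV) into a :class:`GenotypeDataset`.

    Expected columns: ``id``, ``stage``, ``x``, ``y``, optionally ``cwd_id``,
    ``dbh``, ``age``, and two columns per locus named ``<locus>_1`` /
    ``<locus>_2``.  ``locus_names`` restricts/orders the loci; by default every
    ``*_1``/``*_2`` pair is used in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    for col in ("id", "stage", "x", "y"):
        if col not in df.columns:
            raise DataError(f"{path.name}: missing required column {col!r}")
    if locus_names is None:
        locus_names = []
        for col in df.columns:
            if col.endswith("_1") and col[:-2] + "_2" in df.columns and col[:-2] not in _META_COLS:
                locus_names.append(col[:-2])
    n = len(df)
    geno = np.full((n, len(locus_names), 2), MISSING, dtype=np.int64)
    for li, name in enumerate(locus_names):
        for ci, col in enumerate((f"{name}_1", f"{name}_2")):
            if col not in df.columns:
                raise DataError(f"{path.name}: missing allele column {col!r}")
            vals = df[col]
            for ri, v in enumerate(vals):
                if pd.isna(v) or v in missing_codes or str(v) in map(str, missing_codes):
                    continue
                try:
                    geno[ri, li, ci] = int(v)
                except (TypeError, ValueError) as exc:
                    raise DataError(
                        f"{path.name}, line {ri + 2}: bad allele {v!r} at {col}"
                    ) from exc
    loci = []
    for li, name in enumerate(locus_names):
        observed = geno[:, li, :]
        observed = np.unique(observed[observed != MISSING])
        if observed.size == 0:
            observed = np.array([0])
        loci.append(Locus(name=name, allele_codes=tuple(int(a) for a in observed)))
    meta_cols = [c for c in _META_COLS if c in df.columns]
    return GenotypeDataset(
        meta=df[meta_cols].copy(), genotypes=geno, loci=loci, plot_extent=plot_extent
    )


def write_genotype_table(dataset: GenotypeDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset in the :func:`read_genotype_table` column schema."""
    df = dataset.meta.copy()
    for li, locus in enumerate(dataset.loci):
        df[f"{locus.name}_1"] = dataset.genotypes[:, li, 0]
        df[f"{locus.name}_2"] = dataset.genotypes[:, li, 1]
    df.to_csv(path, sep=sep, index=False)


def with_augmented_loci(dataset: GenotypeDataset, null_freqs: Mapping[str, float]) -> GenotypeDataset:
    """Return a copy whose loci carry the given estimated null-allele frequencies."""
    loci = [
        replace(locus, null_freq=float(null_freqs.get(locus.name, locus.null_freq or 0.0)))
        for locus in dataset.loci
    ]
    return GenotypeDataset(
        meta=dataset.meta.copy(),
        genotypes=dataset.genotypes.copy(),
        loci=loci,
        plot_extent=dataset.plot_extent,
    )
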