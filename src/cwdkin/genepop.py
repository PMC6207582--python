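"""GENEPOP-format reading and writing.

GENEPOP files carry one line per individual, ``name ,  aabb ccdd ...`` with
2 or 3 digits per allele (4- or 6-digit genotypes) and ``00``/``000`` for a
missing copy.  POP blocks delimit populations; here each block maps to a
growth stage via an explicit block -> stage list.  GENEPOP has no coordinate
or metadata fields, so those are merged from a sidecar table keyed by
individual id.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import MISSING, DataError, GenotypeDataset, Locus


def read_genepop(
    path: str | Path,
    stage_for_block: Sequence[str],
    sidecar: str | Path | pd.DataFrame | None = None,
    plot_extent: tuple[float, float] = (200.0, 250.0),
) -> GenotypeDataset:
    """Parse a GENEPOP file into a :class:`GenotypeDataset`.

    Parameters
    ----------
    stage_for_block : sequence of str
        Stage label for each POP block, in file order.
    sidecar : table keyed by ``id``, optional
        Per-individual ``x``, ``y`` and optional ``cwd_id``/``dbh``/``age``.
        Without it coordinates default to 0 (valid for purely non-spatial use).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise DataError(f"{path}: too short for GENEPOP")
    body = lines[1:]  # first line is a title/comment
    # locus names: either one comma-separated line or one name per line up to POP
    first_pop = next((i for i, l in enumerate(body) if l.strip().lower() == "pop"), None)
    if first_pop is None:
        raise DataError(f"{path}: no POP block")
    locus_lines = [l.strip() for l in body[:first_pop] if l.strip()]
    if len(locus_lines) == 1 and "," in locus_lines[0]:
        locus_names = [s.strip() for s in locus_lines[0].split(",") if s.strip()]
    else:
        locus_names = locus_lines
    n_loci = len(locus_names)

    rows: list[tuple[str, str, list[tuple[int, int]]]] = []
    block = -1
    width: int | None = None
    for raw in body[first_pop:]:
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            block += 1
            if block >= len(stage_for_block):
                raise DataError(f"{path}: more POP blocks than stage mappings")
            continue
        if "," not in line:
            raise DataError(f"{path}: individual line without comma: {line!r}")
        name, geno_part = line.split(",", 1)
        fields = geno_part.split()
        if len(fields) != n_loci:
            raise DataError(
                f"{path}: {name.strip()!r} has {len(fields)} genotypes, expected {n_loci}"
            )
        genos = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise DataError(f"{path}: bad genotype field {f!r} for {name.strip()!r}")
            w = len(f) // 2
            if width is None:
                width = w
            elif w != width:
                raise DataError(f"{path}: inconsistent allele-code width ({2*width} vs {2*w} digits)")
            a, b = int(f[:w]), int(f[w:])
            genos.append((a if a != 0 else MISSING, b if b != 0 else MISSING))
        rows.append((name.strip(), stage_for_block[block], genos))

    n = len(rows)
    geno = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
    for ri, (_, _, genos) in enumerate(rows):
        for li, (a, b) in enumerate(genos):
            geno[ri, li] = (a, b)
    meta = pd.DataFrame(
        {
            "id": [r[0] for r in rows],
            "stage": [r[1] for r in rows],
            "x": 0.0,
            "y": 0.0,
        }
    )
    if sidecar is not None:
        side = sidecar if isinstance(sidecar, pd.DataFrame) else pd.read_csv(sidecar)
        side = side.copy()
        side["id"] = side["id"].astype(str)
        meta = meta.drop(columns=["x", "y"]).merge(side, on="id", how="left", validate="1:1")
        if meta[["x", "y"]].isna().any().any():
            missing_ids = meta.loc[meta["x"].isna(), "id"].tolist()
            raise DataError(f"sidecar lacks coordinates for ids {missing_ids[:5]}")
    loci = []
    for li, name in enumerate(locus_names):
        observed = geno[:, li, :]
        observed = np.unique(observed[observed != MISSING])
        if observed.size == 0:
            observed = np.array([0])
        loci.append(Locus(name=name, allele_codes=tuple(int(a) for a in observed)))
    return GenotypeDataset(meta=meta, genotypes=geno, loci=loci, plot_extent=plot_extent)


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    title: str = "cwdkin export",
    digits: int = 3,
) -> list[str]:
    """Write the dataset as GENEPOP, one POP block per stage present.

    Returns the block -> stage mapping used (stage labels in block order),
    which :func:`read_genepop` needs to reconstruct stages.
    """
    if digits not in (2, 3):
        raise DataError("GENEPOP allele codes are 2 or 3 digits")
    limit = 10**digits
    for locus in dataset.loci:
        if any(a >= limit or a < 0 for a in locus.allele_codes):
            raise DataError(f"locus {locus.name!r}: allele codes exceed {digits}-digit encoding")
    stages_present = [s for s in ("seedling", "sapling", "juvenile", "mature")
                      if (dataset.meta["stage"] == s).any()]
    out = [title, ", ".join(l.name for l in dataset.loci)]
    for stage in stages_present:
        out.append("POP")
        idx = np.flatnonzero(dataset.meta["stage"].to_numpy() == stage)
        for i in idx:
            fields = []
            for li in range(len(dataset.loci)):
                a, b = dataset.genotypes[i, li]
                fields.append(f"{max(a, 0):0{digits}d}{max(b, 0):0{digits}d}")
            out.append(f"{dataset.meta['id'].iloc[i]} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")
    return stages_present
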