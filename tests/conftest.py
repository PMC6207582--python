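import numpy as np
import pandas as pd
import pytest

from cwdkin.datasets import GenotypeDataset, Locus
from cwdkin.simulate import SimConfig, generate_landscape, generate_mature_population


def make_dataset(genotypes, stage="mature", coords=None, loci_names=None, **meta_extra):
    """Small literal dataset: genotypes is a list of per-individual lists of
    (a, b) allele pairs, one per locus; -1 marks missing."""
    geno = np.asarray(genotypes, dtype=np.int64)
    n, n_loci, _ = geno.shape
    if coords is None:
        coords = [(float(i), 0.0) for i in range(n)]
    loci = []
    for li in range(n_loci):
        seen = np.unique(geno[:, li, :][geno[:, li, :] >= 0])
        loci.append(
            Locus(
                name=(loci_names[li] if loci_names else f"L{li + 1:02d}"),
                allele_codes=tuple(int(a) for a in seen) or (0,),
            )
        )
    meta = pd.DataFrame(
        {
            "id": [f"I{i + 1:03d}" for i in range(n)],
            "stage": stage,
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            **meta_extra,
        }
    )
    return GenotypeDataset(meta=meta, genotypes=geno, loci=loci)


@pytest.fixture
def small_hwe_population():
    """60 individuals, 6 loci at HWE, no nulls, no missing data."""
    cfg = SimConfig(
        rng_seed=17, n_mature=60, n_loci=6, alleles_per_locus=(4, 8),
        null_loci_fraction=0.0, missing_rate=0.0,
    )
    return generate_mature_population(cfg, None, np.random.default_rng(17))


@pytest.fixture
def simulated_plot():
    """Landscape + mature cohort + limited-dispersal seedlings (clean genotypes)."""
    cfg = SimConfig(
        rng_seed=23, seed_kernel=(5.0, 1.0), m_s=0.2, m_p=0.5,
        null_loci_fraction=0.0, missing_rate=0.0,
    )
    rng = np.random.default_rng(23)
    landscape = generate_landscape(cfg, rng)
    mature = generate_mature_population(cfg, landscape, rng)
    from cwdkin.simulate import simulate_offspring_nm

    seedlings = simulate_offspring_nm(cfg, mature, landscape, stage="seedling", rng=rng)
    return cfg, landscape, mature, seedlings
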