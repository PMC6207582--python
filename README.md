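# cwdkin

Fine-scale spatial genetic structure (FSGS) analysis for stage-structured
microsatellite data from tree populations that regenerate on coarse woody
debris (CWD) — fallen logs, stumps and snags acting as obligate "safe sites"
for seedling establishment.

`cwdkin` is aimed at population geneticists and forest ecologists who sample
a mapped plot across growth stages (seedling, sapling, juvenile, mature),
genotype the individuals at codominant SSR loci, and want to ask how spatial
genetic structure changes over the life history: is kinship clustered at
short distances in the young cohorts, does it persist into the mature stand,
and can demographic thinning (inbreeding depression, stochastic death,
disturbance that wipes out whole logs) erase it?

## What it computes

**Kinship and FSGS.** The pairwise kinship coefficient is estimated with the
Loiselle et al. multiallelic estimator of
F<sub>ij</sub> = (Q<sub>ij</sub> − Q<sub>m</sub>)/(1 − Q<sub>m</sub>),
where Q<sub>ij</sub> is the probability of identity in state of genes drawn
from individuals *i* and *j* and Q<sub>m</sub> the same probability for the
reference population (by convention the mature trees, augmented with one gene
copy of every allele found only in the younger stages). Per stage the package
reports the distance-class correlogram of mean F<sub>ij</sub> with a
location-permutation envelope, the regression slope *b*<sub>F</sub> of
F<sub>ij</sub> on ln(distance) with a delete-one-locus jackknife SE and
permutation p, and the FSGS intensity

&nbsp;&nbsp;&nbsp;&nbsp;*Sp* = *b*<sub>F</sub> / (*F*<sub>1</sub> − 1),

with *F*<sub>1</sub> the mean kinship in the first distance class. Individual
inbreeding F<sub>is</sub> (kinship between the two gene copies within an
individual) is tested by re-pairing gene copies at random.

**Diversity and differentiation.** H<sub>O</sub>, Nei's unbiased gene
diversity H<sub>S</sub>, rarefaction allelic richness R<sub>S</sub>,
Weir–Cockerham F<sub>IS</sub> and pairwise F<sub>ST</sub> (theta) with
permutation tests; a Monte-Carlo exact Hardy–Weinberg test; a genotypic LD
permutation test; EM estimation of per-locus null-allele frequencies and a
joint maximum-likelihood point estimate of inbreeding with null alleles.

**Dispersal kernels.** A neighborhood-model likelihood for offspring
genotypes: each offspring's genotype is a categorical mixture over immigrant
origin and all local mother/father pairs, weighted by 2-D exponential-power
kernels P(r) = b/(2πa²Γ(2/b))·exp(−(r/a)<sup>b</sup>), dbh-dependent
fecundity exp(γz), and immigration rates m<sub>s</sub>, m<sub>p</sub>
(selfing fixed at 0). `NeighborhoodModel(...).fit()` returns a results
object with estimates, SEs from the inverse observed information, mean
dispersal distances d = a·Γ(3/b)/Γ(2/b), and a `summary()` table.

**Thinning simulations.** Pool the seedling and sapling cohorts, impose
mortality (most-inbred removal, repeated random removal, eradication of the
most offspring-rich logs) and recompute the FSGS statistics of every
surviving dataset against its own allele frequencies.

**Synthetic data.** `cwdkin.simulate` generates the whole study system —
log landscape, mature population, and offspring produced under the same
dispersal model the likelihood fits, with null-allele masking and dropout —
with recorded pedigree, so every estimator can be validated against known
truth.

## Worked example

```python
import numpy as np
import cwdkin as ck
from cwdkin.simulate import (SimConfig, generate_landscape,
                             generate_mature_population, simulate_offspring_nm)

cfg = SimConfig(rng_seed=0, seed_kernel=(5.0, 1.0), m_s=0.3, m_p=0.7,
                null_loci_fraction=0.0, missing_rate=0.0)
rng = np.random.default_rng(0)
landscape = generate_landscape(cfg, rng)
mature = generate_mature_population(cfg, landscape, rng)
seedlings = simulate_offspring_nm(cfg, mature, landscape, stage="seedling", rng=rng)

ref = ck.build_reference_frequencies(mature, seedlings)
summary = ck.fsgs_summary(seedlings, ref, n_perms=999, rng=1)
print(f"F_1 = {summary.f1:.3f}  b_F = {summary.b_f:.4f} (SE {summary.b_f_se:.4f}, "
      f"p = {summary.b_f_p:.3f})  Sp = {summary.sp:.4f}")

res = ck.NeighborhoodModel(seedlings, mature, background=seedlings.background).fit(
    n_starts=4, rng=2)
print(res.summary())
```

prints

```
F_1 = 0.050  b_F = -0.0057 (SE 0.0012, p = 0.001)  Sp = 0.0060
Neighborhood dispersal model (exponential-power kernels)
  offspring n = 179, candidate parents = 123, log-likelihood = -5700.489
  converged: True (4 starts)

  Parameter             Seed        (SE)      Pollen        (SE)
  a                    7.959       2.349      88.458       6.146
  b                    1.224       0.200       7.322       3.144
  s                    0.000       0.000       0.000       0.000
  d                   11.389       0.969      57.981       3.408
  m                    0.341       0.035       0.703       0.042
  Sigma (dbh)          1.321       0.104       1.321       0.104
```

The seedlings were generated with strong, short-range seed dispersal (scale
5 m, exponential shape) on top of 30% seed and 70% pollen immigration, so the
correlogram slope is significantly negative (kinship declines with log
distance: real spatial family structure) and the fitted kernels recover the
generating regime — mean seed dispersal ~11 m against a true 10 m, pollen
immigration 0.70 against a true 0.7.

There is also a CLI for the same steps — `cwdkin simulate`, `cwdkin
diversity`, `cwdkin fsgs`, `cwdkin dispersal`, `cwdkin thin`, `cwdkin
deltak` — each writing TSV/JSON reports plus a manifest of parameters and
seeds.

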