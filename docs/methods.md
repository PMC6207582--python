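# Methods

This note records the statistical models implemented in `cwdkin`, the
defaults and why, the scope of the synthetic-data generator, and the
numerical choices a user auditing results will want to know.

## Kinship estimator

The pairwise kinship coefficient F_ij = (Q_ij − Q_m)/(1 − Q_m) is estimated
with the Loiselle et al. multiallelic estimator. Per locus l with reference
frequencies p_a based on n_l gene copies,

    F_ij(l) = [ Σ_a (p_ia − p_a)(p_ja − p_a) + Σ_a p_a(1−p_a)/(n_l − 1) ] / Σ_a p_a(1−p_a)

with p_ia ∈ {0, ½, 1} the allele dose in individual i. The
1/(n_l − 1) bias-correction term is **on by default** (matching standard
kinship software); a `bias_correction` flag turns it off, which is what the
sib-calibration checks use together with an effectively infinite reference
(the correction then vanishes anyway). Multilocus values average loci with
weights w_l = Σ_a p_a(1−p_a); a locus untyped in either member of a pair is
dropped from that pair only (pairwise deletion), and a locus monomorphic in
the reference is excluded. An allele observed in the sample but absent from
the reference enters the dose sums at reference frequency 0 — with the
augmented reference described next this case cannot arise in the standard
analysis, but it keeps the estimator defined for arbitrary references.

Individual inbreeding F_is applies the same estimator to the two gene copies
within one individual (0/1 indicator doses per copy).

**Reference population.** The mature cohort's allele counts, augmented with
one gene copy of each allele observed only in the younger stages, so every
such allele receives the low frequency 1/(n_l + k). The thinning analyses
instead use each surviving dataset's own frequencies (no external reference,
no augmentation); with the sample itself as reference and the correction on,
the all-pairs mean kinship is ~0, so F_1 measures purely local excess.

## Correlogram, b_F and Sp

Distance classes are half-open [lo, hi) intervals, default 0–200 m in 10 m
steps (20 classes). The permutation null shuffles individual **locations**
(the genotype–location link) rather than per-pair distances: this preserves
the geometry of the distance matrix under the null and is the standard
operationalization of permuting spatial distances among pairs. Per class the
package reports the pair count, mean F_ij, the 2.5/97.5 percentile envelope
of permuted class means (per-class, not family-wide — the narrower of the
two defensible conventions, stated here because published figures rarely say
which they use) and a two-sided rank-based p.

b_F is the OLS slope of pairwise F_ij on ln(distance) over **all** pairs
with d > 0; pairs at distance exactly 0 (same establishment point) fall in
the first distance class but are excluded from the regression because ln 0
is undefined. Its SE is a delete-one-locus jackknife (the per-locus
numerator/denominator decomposition makes leave-one-locus-out exact), which
requires ≥ 2 informative loci; its p is one-sided (observed more negative)
from the same location permutations. Sp = b_F/(F_1 − 1) with F_1 the mean
kinship in the first class; the summary object enforces
Sp·(F_1 − 1) = b_F to machine precision.

The mean-F_is test re-pairs gene copies at random among the stage's
individuals within each locus, keeping allele frequencies and each
individual's typed-locus pattern fixed; p is one-sided for inbreeding
excess, with an optional Bonferroni factor for the number of stages tested.

Cluster-restricted kinship summaries take a per-individual membership
(Q) matrix and use a **strict** threshold (membership > 0.9 by default).
ΔK for choosing the number of clusters is |L(K+1) − 2L(K) + L(K−1)|/sd(L(K))
over run means, sample sd over runs; endpoints and sd = 0 cases are flagged
rather than computed.

## Diversity statistics

H_O is the fraction of typed individuals heterozygous; H_S is Nei's unbiased
gene diversity (n/(n−1))(1 − Σp²); allelic richness is hypergeometric
rarefaction to a standard number of gene copies g (the pipeline default
rarefies to the smallest per-locus typed gene count across stages; g = 74
corresponds to the conventional 37-individual standard). F_IS and pairwise
F_ST are Weir–Cockerham variance-component estimators with components summed
over alleles and loci; F_ST significance comes from re-assigning individuals
to groups at random (one-sided). The Hardy–Weinberg test is a Monte-Carlo
exact test: the statistic is the Levene conditional probability of the
genotype array given allele counts and the null is sampled by shuffling gene
copies into random pairs — same target distribution as a Markov-chain
sampler, easier to verify by enumeration on small tables. The LD test is a
genotypic G statistic with one locus permuted among individuals.

## Null alleles

`null_allele_em` fits, by EM to tolerance 1e-8 (cap 10,000 iterations), a
Hardy–Weinberg model over visible alleles plus one null allele where a
visible/null heterozygote reads as a visible homozygote, a null homozygote
reads as missing, and each individual independently fails genotyping at a
co-estimated rate β (so missing data are a νν/failure mixture).
`fis_null_joint_ml` generalizes this to a shared inbreeding coefficient f
across loci with per-locus null frequencies: per locus the observed genotype
classes (heterozygote, apparent homozygote per allele, missing) are
multinomial with probabilities combining f-inflated homozygosity and null
masking; visible frequencies are profiled with the EM estimate, ν_l by
bounded 1-D optimization, and f by grid search plus refinement of the
profile likelihood. All class probabilities, including the unobserved
missing class, are constrained non-negative — without that constraint f and
ν trade off along an invalid ridge. This is a point-estimate approximation
of the Bayesian co-estimation approach used in the field, adequate for the
qualitative F_IS-with-nulls < naive-F_IS comparison it supports.

## Neighborhood dispersal model

For offspring o with establishment point x_o, candidate parents j with
standardized dbh z_j, the likelihood of the observed multilocus genotype is

    L_o = m_s·B(g_o) + (1 − m_s)·Σ_j ψ_j [ m_p·T(g_o | g_j, bg) + (1 − m_p)·Σ_{k≠j} φ_jk·T(g_o | g_j, g_k) ]

with mother weights ψ_j ∝ exp(γ z_j)·P_s(d(o,j)) normalized over all
candidates, father weights φ_jk ∝ exp(γ z_k)·P_p(d(j,k)) normalized over
k ≠ j (the exclusion implements selfing rate 0), and B the background
genotype probability. Kernel values enter the weights un-normalized over the
plot: the within-plot normalizer cancels in categorical weights, and
immigration absorbs out-of-plot mass. Fecundity is exp(γ·z) with z the
z-score of dbh — chosen for positivity and so that γ is a log-linear effect.
The background pool defaults to the mature-tree frequencies and is
configurable.

Genotype probabilities are computed on observed genotype classes,
marginalizing over true genotypes given per-locus null frequencies: an
observed parental homozygote A/A is truly A/A or A/null with posterior odds
p_A : 2ν; an observed offspring homozygote matches gamete pairs {A,A} and
{A,null}; a parent untyped at a locus transmits a population gamete; loci
missing in the offspring are skipped. All per-pair transition products are
precomputed once (they do not depend on the parameters), so one likelihood
evaluation is two weight matrices and an einsum.

Estimation maximizes over (logit m_s, logit m_p, ln a_s, ln b_s, ln a_p,
ln b_p, γ) with L-BFGS-B from several jittered starts (default 6, seeded),
shape b bounded in [0.05, 20] to keep Γ arguments finite, log-gamma
arithmetic throughout. SEs come from the inverse observed information
(central finite-difference Hessian, step 1e-3); confidence intervals are
Wald intervals on the transformed scale; mean distances d = a·Γ(3/b)/Γ(2/b)
get delta-method SEs (d ln d/d ln b = (2ψ(2/b) − 3ψ(3/b))/b). Immigration
rates pinned near 0 or 1 are flagged — the corresponding kernel is then
unidentified. The information-based SEs (rather than bootstrap) are a
deliberate choice: the likelihood is smooth and the bootstrap would be two
orders of magnitude more expensive; the parameter-recovery test shows the
resulting intervals hold close to nominal coverage on self-generated data.
Mothers of sampled offspring are treated as unknown (both parents inferred),
which matches offspring established on logs away from any adult.

## Thinning scenarios

Scenario 1 ranks the pooled offspring by individual F_is **under the
augmented mature reference** (inbreeding is assessed before the simulated
deaths) and keeps the lowest 123; ties break by dataset order. Scenario 2
draws 10 uniform subsets of 123 without replacement. Scenario 3 ranks logs
by offspring count (ties by log id) and eradicates the top-k logs for
k = 1..5, plus every log with strictly more than eight offspring. Report
statistics for every surviving dataset use that dataset's own frequencies as
reference.

## Synthetic-data generator

Defaults emulate the target study system: a 200 × 250 m plot, 112 fallen
logs (segments ≥ 20 cm diameter, length 5–25 m — length and dbh
distributions are config-exposed conveniences, not site estimates), 123
mature trees placed uniformly with dbh 20 + Gamma(2, 15) cm, 11 SSR loci
with 3–46 alleles at Dirichlet(1)-sampled frequencies, ~5/11 loci carrying
null alleles at 0.09–0.185, cohorts of 179 seedlings / 190 saplings / 39
juveniles established only on logs (a soil-establishment toggle exists,
default off), and the fitted seedling-stage kernel and immigration values as
generative truth (seed a = 3.823, b = 0.571; pollen a = 81.816, b = 3.097;
m_s = 0.744, m_p = 0.866; γ = 1.2; selfing 0). Offspring are produced by
exactly the categorical process the likelihood describes — same family, so
fitting recovers the generating parameters — followed by a genotyping-error
layer (null masking, then random dropout at rate 0.01; the published study
does not report how missing genotypes were distributed, so the rate is a
knob). Immigrant genotypes come from a Dirichlet perturbation of the local
frequency tables with concentration 1/divergence (default divergence 0.05),
since no external-pool frequencies are available. The true pedigree and
pre-error genotypes are recorded alongside every cohort.

What the generator does **not** emulate: multi-generation dynamics, log
decay and creation, spatially autocorrelated mortality beyond whole-log
eradication, locus-specific mutation or allele-size homoplasy, and any
clustering of mature trees beyond an optional toggle. Passing tests
therefore demonstrate estimator correctness and calibration under the
model's own assumptions, not robustness to real-data violations of them.

## Numerical and testing choices

- Permutation p-values use the +1 convention: p = (1 + #extreme)/(R + 1),
  so the attainable minimum is 1/(R+1) one-sided, 2/(R+1) two-sided.
- The categorical mother/father draws and all generators run off
  `numpy.random.Generator`; every stochastic function takes an explicit
  seed or generator, and outputs are bit-reproducible under a fixed seed.
- Rarefaction and Levene probabilities are computed with log-gamma, exact
  to ≥ 1e-10 against enumeration on small tables.
- Problem sizes in the statistical tests (e.g. 5 replicate fits of 400
  offspring for kernel recovery, 100 replicate datasets × 200 permutations
  for test calibration, 1500 sib pairs for kinship calibration) were chosen
  so Monte-Carlo error is comfortably below the tolerance being asserted
  while a full suite run stays in the single-digit minutes.

## Known limitations

- The joint f/ν estimator profiles visible frequencies from a HWE-based EM;
  under strong inbreeding this slightly biases f downward (the recovery test
  tolerances reflect this).
- Wald intervals for kernel parameters can undercover when an immigration
  rate sits near a boundary (flagged) or when a and b trade off along their
  ridge at low information; mean distance d is the better-identified
  functional.
- The correlogram envelope is per-class, so ~5% of classes are expected
  outside it under the null; family-wide statements should use b_F's
  permutation test.
- GENEPOP round-trips preserve genotypes and stage blocks but not
  coordinates (the dialect has no coordinate field); a sidecar table is the
  supported transport for metadata.
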