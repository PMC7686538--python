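# Methods

This note documents the statistical machinery of `mitonuclear`: the models
implemented, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## 1. Genotype states

All analyses operate on per-gene *state matrices* (subjects × sites):

- mitochondrial sites are haploid alternate-allele indicators in {0, 1};
  a homozygous diploid-coded call (`1|1`) is accepted as allele 1, a
  heterozygous mitochondrial call is an error (heteroplasmy is out of scope);
- nuclear sites are unordered diploid genotypes in {hom-ref, het, hom-alt};
  phase is discarded on input (`0|1` and `1|0` are one state).

Only biallelic SNVs with complete calls are used. Multiallelic records,
indels and sites with any missing call are excluded with a log message:
splitting multiallelics would change the pair-state alphabet, and the scoring
equation has no missing-data term. Sites that do not vary across the pooled
subjects are removed before analysis (`filter_invariant`, idempotent);
filtering is done on the pooled sample, not per population, so each gene has
one retained-site count.

## 2. Frequency scores

For reference population *R*, each site–state combination has an empirical
frequency `f_R`. A subject's gene score is the mean of `1 − f_R(state)` over
the gene's sites; a gene-pair score is the mean of `1 − f_R(joint state)`
over all (mt site, nuc site) pairs, where the joint state is one of the six
(mt allele) × (collapsed genotype) categories. Properties used by the tests:

- scores lie in [0, 1]; 0 iff every carried (joint) state is fixed in the
  reference, 1 iff every carried state is unseen there;
- when mt and nuc states are independent in the reference, the joint
  frequency factorizes into the product of the marginals;
- reference subjects are scored with the same table (leave-in). Their scores
  are the mean rarity of their own states — near the population's mean
  rarity, not zero.

**Computation.** The summed joint reference frequency for subject *s* equals
`mean over reference subjects r of  m(s,r) · k(s,r)`, where `m` and `k`
count matching mt and nuclear sites between *s* and *r*. Pair scoring is
therefore O(n_subjects × n_reference) per gene pair with two small matrix
products per gene, independent of the (potentially multi-million) number of
site pairs, and never materializes a per-site-pair table. The brute-force
double loop is kept in the test suite as the oracle.

## 3. Classification and feature selection

Binary population classification uses a random forest, 500 trees by default
(`n_trees`), stratified 10-fold cross-validation (`n_folds`; stratification
is a deliberate choice — plain 10-fold at ~90 subjects per class risks
degenerate folds), and mean-decrease-in-impurity importances normalized to
sum to 1. Serial selection re-evaluates the top-k feature prefixes for
k = 1…K and reports the smallest k whose accuracy is within `tolerance`
(default 0.01, read as absolute, configurable) of the curve maximum.
Importance ties are broken lexicographically by feature name so rankings are
deterministic. One pipeline seed fans out to per-stage seeds via
`numpy.random.SeedSequence.spawn`; fixed seed ⇒ bit-identical results.

Two sources of optimism are inherent to this procedure and show up on
truly undifferentiated data. First, the frequency-score encoding is computed
once on all subjects before cross-validation (the reference population's own
subjects included), so finite-sample frequency differences between two
exchangeable populations are baked into the features and remain learnable
across CV folds. Second, the optimal-k rule reports a value near the maximum
of a noisy accuracy curve (selection bias of order 1–2 CV standard errors).
Together they center the null "optimal accuracy" around 0.55–0.61 rather
than 0.5, with occasional excursions to ≈ 0.7 in the pair mode (which has
the longest curve), at any forest size. A calibrated-null reading of a
reported accuracy should therefore subtract this offset; the test suite
documents it, and single-experiment accuracies below ≈ 0.65 should not be
read as evidence of real structure.

A population's *specific* features are the intersection of the optimal lists
of every experiment involving it (four experiments per population in the
gene modes, two in the SNV-pair mode). Combination gains compare a pair's
normalized within-model rank against its constituents' ranks (importances
are normalized within each model, so raw scores are not directly comparable
across models of different size; a raw-score comparison is available via an
argument).

The SNV-pair mode encodes each (mt site, nuc site) pair as one integer
category 0–5 (`3·allele + genotype`). Forests split on thresholds, so the
ordinal encoding of a 6-category variable is an accepted approximation; the
category order is fixed. No reference population is used in this mode. The
`top_k = 100` retained pairs per experiment is a configuration constant;
when fewer features exist, all are retained and a warning is logged.

## 4. Population-genetics baselines

**LD pruning.** Greedy sliding window over sites in position order: within a
window of 50 still-kept sites, the later site of any pair with r² > 0.1 is
removed; the window advances by 10. The earlier (left) site is kept on each
conflict — note PLINK breaks ties by allele frequency, so equivalence with
PLINK output is not promised. Output is a subset of input sites and the pass
is idempotent at fixed parameters.

**Fst.** Weir–Cockerham variance components, combined across loci as a ratio
of sums. Diploid sites use the three-component decomposition (among
populations / among individuals within populations / within individuals,
with the heterozygosity terms); haploid mitochondrial sites use the
two-component haploid form. With zero heterozygosity the diploid components
reduce algebraically to the haploid ones at equal individual counts, so
recoding a haploid block as homozygous diploid is a no-op — the ploidy
branch matters exactly when heterozygotes exist. The estimator may be
slightly negative for undifferentiated populations; a pair with no
polymorphic site has no defined estimate and is reported as missing.

**Significance.** Labels of the pooled pair are permuted (group sizes
preserved) `n_perm = 200` times and the empirical p-value is
`(#{θ_perm ≥ θ_obs} + 1) / (n_perm + 1)`. Fitting a parametric density to
200 permuted values would add a distribution-family assumption the data
cannot check, so the standard tail proportion is used instead; it is
uniform on a 201-point grid under the null, which the calibration test
verifies by Kolmogorov–Smirnov. A gene is *specific* to population P when
both P-involving p-values fall below α = 0.05 and the third does not, and
discriminant for all populations when all three do.

**DAPC.** PCA retaining `n_pca` components — by default the smallest number
explaining ≥ 90% of variance, capped at n_subjects/3 (a guard against the
overfitting DAPC is known for; configurable) — followed by linear
discriminant analysis on the retained components. Three groups give at most
two discriminant axes; centroid Euclidean distances on those axes quantify
separation. Centroids of identically distributed groups coincide (the
degenerate zero-between-variance case yields zero axes and zero distances).

## 5. Synthetic data

The generator emulates the structure the pipeline consumes: three
populations (default 100/100/97 subjects, echoing the 297-subject study
design), per-gene allele-frequency divergence under the Balding–Nichols
model — population frequencies drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` around an ancestral `p`, so the
differentiation parameter F equals the expected Fst, which calibrates the
estimator tests — haploid mitochondrial Bernoulli draws and
Hardy–Weinberg nuclear genotypes within population. Ancestral frequencies
default to Uniform(0.05, 0.95). Sites are independent by default; an
optional `ld_copies` parameter appends noisy duplicates of random columns to
exercise the pruning code. Fixtures are written as uncompressed VCF v4.2
(haploid GT fields for mt records) plus panel and region tables, and
round-trip exactly through the reader.

**Interaction planting** rearranges existing nuclear genotype values among
the subjects of one population, aligned to a mitochondrial allele, so
per-site state counts are *exactly* preserved (integer equality, checked in
tests) while the joint distribution changes. Two constructions:

- `hom_swap` (default): hom-ref genotypes of mt-allele-1 carriers are
  exchanged against hom-alt genotypes of mt-allele-0 carriers; `delta` is
  the fraction of the feasible (Fréchet) maximum
  `min(#hom-ref | mt=1, #hom-alt | mt=0)` actually swapped. Near allele
  frequency 1/2 the two homozygote states have (almost) identical
  frequency, so *no per-site rarity statistic can see the coupling*: the
  single-genome scores are blind by construction, while the joint
  (mt allele, genotype class) distribution is maximally tilted. This is the
  cleanest testbed for "pairs beat singles".
- `dosage`: a fraction `delta` of subjects receives the comonotone
  assignment (descending genotype dosage to descending mt allele), the rest
  are reshuffled; `delta = 0` reproduces independence. This style produces
  an association visible at SNV level regardless of allele frequency and is
  used for the SNV-pair recovery tests.

Because both constructions permute existing values, every `delta` in [0, 1]
is feasible; the delta-infeasibility error reduces to range validation.

**What the generator does not emulate** — and hence what a green test does
not establish: linkage disequilibrium beyond the optional duplicated
columns, mitochondrial phylogeny/haplogroup structure, selection, admixture,
missing or erroneous calls, and realistic site-frequency spectra. A green
pair-beats-singles test shows the encoding detects a planted joint-only
signal; it does not certify power against the weaker, LD-confounded
interactions expected in real cohorts.

## 6. Numerical and design choices

- Scores and components in float64; the pair-score fast path agrees with
  the brute force to 1e-10 (tested on random fixtures).
- Experiments are asymmetric by design: swapping reference and target
  changes the encoding, so accuracy matrices are not symmetric.
- Empty blocks (all sites invariant, or no sites in region) are produced
  with a warning and rejected by every downstream operation by name.
- Degenerate LDA (identical group distributions) yields fewer discriminant
  axes than requested; the DAPC wrapper reports the realized axis count.
- Runtime scaling in tests: simulations use 50–150 trees instead of the
  500-tree default; the asserted quantities were checked to be
  tree-count-insensitive at these scales (including spot checks at 300 and
  500 trees for the null-calibration excursions).

## 7. Known limitations

- The SNV-pair mode materializes the full subjects × (site pairs) category
  matrix; for very large nuclear genes this is memory-bound (the study-scale
  gene-pair mode is not — it never builds per-pair tables).
- The ordinal 0–5 encoding can, in principle, hide category contrasts that
  a one-hot encoding would expose to shallow trees.
- Permutation p-values have resolution 1/(n_perm+1); with 200 permutations
  the smallest attainable p is ≈ 0.005.
- LD pruning reproduces the stated window/step/threshold procedure, not any
  specific external tool's tie-breaking.
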