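# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data model behind `hapscan`, together with the design decisions that
were genuinely open and how they were resolved.

## Haplotype network construction

Pairwise distances are plain site-count differences between aligned
nucleotide sequences; any two differing characters count as one difference,
so ambiguity codes mismatch every differing concrete base (ambiguity-aware
distances would only matter for phase-uncertain input, which is out of scope).

**Parsimony connection limit.** Haplotype pairs are connected only up to the
largest number of steps that is still credibly homoplasy-free. We model the
placement of mutational steps as uniform and independent across the m sites;
j steps are then all at distinct sites — so that the observed differences
equal the true number of steps and the parsimonious connection is the true
one — with probability

    P_j = prod_{i=1}^{j-1} (1 - i/m),      P_1 = 1,

the birthday-problem recursion. The connection limit at confidence c (default
0.95) is the largest j with P_j > c. This reconstruction of the classical
statistical-parsimony limit is deliberately simple: it is exact under the
uniform-placement model, always at least 1, and non-decreasing in m. It is
somewhat conservative relative to implementations that discount invisible
same-lineage multiple hits. For the data this package targets — every branch
a single step — the limit never binds; it matters only for diverged inputs.

**Build order and loops.** Pairs are connected level by level in ascending
distance. Within a level, every pair joining two components that were
distinct at the start of the level is added, so alternative equal-length
connections are retained as loops. With all-distinct distances this reduces
exactly to Kruskal's algorithm (tested against a minimum-spanning-tree
oracle).

**Loop resolution.** The coalescent rationale is that rare haplotypes are
recent tips, so the least credible connection in a cycle is the one joining
the rarest pair. Removal priority: (1) smallest summed endpoint frequency,
(2) fewest interior (degree ≥ 3) endpoints — interior nodes are older and
their connections more credible, (3) lexicographically greatest edge id for
determinism. Named edges can be force-broken from configuration (only when
they lie on a cycle, so connectivity is never sacrificed); all removals are
logged in the run manifest.

**Branch orientation.** The most frequent haplotype is the designated
ancestral node. For each tree edge, the side containing it is ancestral
(side_a); individuals are classed by copies of the derived-side allele.
Nonsynonymous edge labels use 1-based codon coordinates against reading frame
0 of the supplied alignment.

## Branch scan

Phenotypes are replaced by OLS residuals on the covariates plus intercept
before any testing. Constant covariates are dropped (reducing to mean
centering); genuinely collinear covariate matrices are an error. Rows with
missing phenotypes or covariates are dropped per analysis.

Each branch's statistic is the one-way ANOVA F across its retained genotype
classes; a class with fewer than `min_class_count` (default 5) individuals is
excluded together with its individuals, and a branch with fewer than two
remaining classes is skipped and logged. Significance is by permutation of
phenotype rows with the add-one estimator p = (1 + #{F* ≥ F}) / (1 + B),
which cannot return zero; B defaults to 10,000. Multivariate rows are
permuted as whole phenotype vectors, preserving the inter-phenotype
correlation.

**Multiple testing.** A single permutation index stream is shared by all
branches, and corrected p-values use step-down max-T: branches are sorted by
observed statistic; the corrected p at rank r counts permutations whose
maximum statistic over ranks r..last reaches the observed value, and
monotonicity is enforced down the list. Because the permutation distribution
of the maximum absorbs the correlation between branch tests, perfectly
correlated branches cost nothing extra. The branch statistics being compared
are F values whose degrees of freedom can differ across branches (2 vs 3
classes); the max-T procedure is applied to them directly, which is the
standard treescanning convention and is what the brute-force oracle checks.

**Multivariate scan.** The branch statistic is the Rao-F transform of Wilk's
Λ (see below); its nominal p in the scan is the permutation p on the same
stream — uniform semantics with the univariate tests, keeping the
corrected ≥ nominal invariant well defined — while the parametric p-value of
the F transformation is reported in the per-branch MANOVA summary.

**Conditional second round.** Whether the original second-round procedure
subdivides the significant allele class or treats it as a covariate is not
decidable from the available description; we implement stratified
conditioning: individuals outside the conditioning branch's retained classes
are excluded, permutations shuffle phenotype rows only within conditioning
strata, and the statistic is the partial F for the target branch in the
additive two-factor layout (computed via orthonormal bases of the reduced and
full design spaces; a branch collinear with the conditioning factor gets
F = 0, p = 1, which also covers self-conditioning). Strata contributing fewer
than two target classes simply add no information.

## MANOVA and partial Wilk's tests

For response matrix Y (N × p) and k genotype classes, E and H are the within-
and between-class SSCP matrices and Λ = det(E)/det(E+H). Determinants are
computed by triangular factorization (slogdet) with a conditioning guard:
if the condition number of E+H exceeds 1e12 the phenotypes are reported as
degenerate rather than silently inverted. Full-model significance uses Rao's
F approximation, exact in the cases that occur here (p ≤ 2 or k ≤ 3; genotype
factors have at most 3 classes).

The contribution of phenotype y_g conditional on the others is
Λ_p / Λ_{p−1}, with the exact transform F_{v_H, v_E−p+1} =
((1−Λ)/Λ)·((v_E−p+1)/v_H). The implementation satisfies the ratio identity
partial(g)·Λ_reduced(g) = Λ_full to machine precision, and the partial-F
p-value is verified against an independent ANCOVA model-comparison oracle
(regressing y_g on the other phenotypes with and without the class factor).
Partial p-values are parametric; permutation is reserved for the branch-level
scan. Note that a phenotype that exactly duplicates another column makes E
singular (reported), and a near-duplicate's partial test is null-distributed
— the factor explains an F-distributed share of the residual noise — not
identically 1.

Total cholesterol is excluded from the default multivariate phenotype set
because it is (by construction in the generator, and in fact) a composite of
the other lipids.

## Radical-substitution scoring

Ancestral sequences are reconstructed by Hartigan's parsimony algorithm
(exact minimum-mutation reconstruction, multifurcations included), replacing
likelihood-based reconstruction: on a single-step, star-like haplotype tree
every substitution is pendant and the two approaches agree, and parsimony
needs no external tool. Downward-pass ties keep the parent's state when
optimal, else take the alphabetically first state; private (singleton)
variants are always assigned to their tip's own branch regardless of
tie-breaking, which the tests assert.

For each property, change magnitudes |value(to) − value(from)| are binned
into 8 equal-width categories spanning [0, max], where max is the largest
change achievable by a single nucleotide substitution between sense codons of
the standard genetic code. The expected category distribution weights all
such nonsynonymous codon changes uniformly ("completely random replacement");
conditioning on the observed codon composition would be a one-function swap
(`expected_distribution`) and is deliberately isolated. Category enrichment
uses one-sided z = (obs − nq)/sqrt(nq(1−q)) at threshold 1.645 (α = 0.05,
configurable); an observed event in a category with zero expected proportion
is flagged as infinite surprise without a z. Sites are flagged through the
events that land in significant categories; a flag is radical iff the
category is 6–8.

The packaged property table carries 12 physicochemical scales whose values
are reliably sourced from the standard literature (Kyte–Doolittle hydropathy,
isoelectric point, residue molecular weight, Grantham molecular volume and
polarity, Woese polar requirement, Zimmerman bulkiness, Chou–Fasman
helix/sheet/turn propensities, Hopp–Woods hydrophilicity, Eisenberg consensus
hydrophobicity). The classical radical-substitution analysis uses a larger
catalogue (31 scales); any CSV with the same schema (property, amino_acid,
value — 20 finite values per property) is accepted in its place, so users
with a preferred catalogue can drop it in.

## Predictor evaluation

The packaged annotation table records, for 27 missense variants: the
triglyceride-distribution class of carriers (High/Middle/Low) or, for common
variants, scan significance; the biological-assay outcome; the PolyPhen score
and prediction; and the radical-substitution category (none, 6–7, or 8, read
from the published per-variant property lists, where top-category properties
are distinguished typographically). The "known" functional column comprises
the 6 assay-confirmed low-tail variants plus the 2 scan-significant common
variants; the 2 high-tail variants that assayed as non-functional are
excluded from the 2×2 and reported alongside; the remaining 17 variants form
the negative column.

Seven criteria are evaluated: PolyPhen (possibly or probably damaging),
Strict PolyPhen (probably only), TreeSAAP-style (category ≥ 6), Strict
(category 8 only), the AND of the two non-strict criteria, the AND of the two
strict criteria, and their OR. For each: a two-tailed Fisher exact test
(point-probability tail rule — tables at least as extreme by probability),
and the conditional maximum-likelihood odds ratio with exact tail-inversion
CI. The conditional-MLE convention is the one consistent with the published
comparison values (its estimates differ visibly from the sample cross-product
ratio, e.g. 7.01 vs 7.78 for the Strict PolyPhen table); both the Fisher tail
rule and the OR estimate are verified against independent oracles
(exact-rational hypergeometric enumeration; the root of the conditional score
equation). Sensitivity = a/(a+c) and specificity = d/(b+d) on the fixed
column totals (8, 17); α and β are their exact complements.

One known source-table tension is worth recording: the annotation row for one
high-tail variant (P-251-T) carries no radical-substitution property in the
published per-variant list, while the published summary comparison counts
both high-tail variants as flagged by that method. The packaged fixture
follows the per-variant table; the discrepancy affects only the
separately-reported high-tail counts, never the 2×2 cells or any statistic
derived from them.

## Synthetic cohorts

The generator reproduces the structure the analysis assumes, with defaults
matching the motivating study's conditions: three populations of
1830/601/1045 individuals, 45 haplotypes over a 1218-nt coding region, the
two dominant haplotypes at frequencies 0.512 and 0.260 (together 70–80% of
every population), and five lipid phenotypes.

* **Genealogy**: a random attachment process — each new haplotype mutates one
  previously untouched site off an existing haplotype chosen with probability
  proportional to frequency. This reproduces the star-like, all-single-step
  topology of a low-diversity intragenic network without a full coalescent;
  it does not model recombination, recurrent mutation, or population
  demography. Remaining frequency mass is spread over the rare haplotypes by
  a Dirichlet(0.35) draw, giving the long tail of singletons seen in real
  frequency tables. In-frame stop codons are avoided so the sequences remain
  valid coding sequences.
* **Diplotypes**: Hardy–Weinberg random union within each population (no
  mating structure is modeled).
* **Covariates**: age ~ Uniform(18, 65), sex ~ Bernoulli(0.5),
  BMI ~ Normal(28, 5) — arbitrary but documented; only the residual structure
  after adjustment matters downstream.
* **Phenotypes** (SD units): covariate term + additive branch effect
  (effect size × derived-allele copies) + correlated Gaussian noise with
  correlation matrix defaulting to a realistic lipid structure
  (tg–vldl 0.9, tg–hdl −0.4, ldl weakly coupled). Total cholesterol is the
  deterministic composite ldl + hdl + tg/5 plus Normal(0, 0.05) noise, so its
  exclusion from the multivariate model is meaningful.
* **Seeding**: one user seed expands into fixed per-stage streams
  (haplotypes, diplotypes, phenotypes, scan) via SeedSequence keys, so each
  stage is individually reproducible and all outputs are bit-identical
  functions of (inputs, config, seed).

What passing tests on these cohorts do *not* show: robustness to
linkage-disequilibrium structure beyond a single gene, to recombination, to
non-Gaussian phenotype tails, or to population stratification — real analyses
run per population precisely to sidestep the last of these.

## Problem sizes used in the checks

The calibration suite uses the sizes at which the operating characteristics
are defined: null type-I error from 200 replicates of n = 500 with 1,000
permutations (expected nominal rate 0.05 ± 0.02); effect recovery from 50
replicates of n = 3,000 with a 0.5-SD HDL effect and 1,000 permutations
(top-ranked corrected-significant recovery with the smallest partial Λ on
HDL in ≥ 90%). The acceptance script uses 100 and 25 replicates respectively
for the same quantities. Fisher oracle equivalence is exhaustive over all
2×2 tables with total ≤ 30.

## Known limitations

* The connection-limit model ignores invisible same-lineage multiple hits
  (conservative) and rate heterogeneity across sites.
* Max-T compares F statistics across branches with unequal degrees of
  freedom; a min-p variant would equalize scale at higher computational cost.
* The conditional scan implements stratified conditioning only; covariate-
  style conditioning is deliberately not exposed until it can be verified.
* Fisher/odds-ratio machinery targets single 2×2 tables; no stratified
  (Mantel–Haenszel-style) evaluation is provided.
* Parsimony ancestral reconstruction is exact for minimum mutations but not a
  substitute for likelihood reconstruction on trees with long branches; it is
  appropriate here because every branch is a single step.
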