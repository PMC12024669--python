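# Methods

This note documents the models, estimators, parameter defaults and design
choices behind `introscreen`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Data model

Genotypes are stored as foreign-allele dosages (0 = homozygous native,
1 = heterozygous, 2 = homozygous foreign, −1 = missing) in a dense
samples × loci `int8` array with a sample → population map and an optional
per-call depth table. Allele polarity is fixed once by the diagnostic
panel and never reinterpreted: VCF sites whose REF matches the panel's
foreign allele are flipped on ingestion, and sites matching neither allele
are dropped with a warning. The genotype TSV dialect (tokens `N/H/F/.`)
exists to keep fixtures and round-trip tests byte-stable; genepop export
uses 2-digit allele codes (native 01, foreign 02, missing 0000) with one
POP block per population.

## Panel QC and validation

A locus is kept only if its mean read depth across all calls is at least
`min_locus_depth` (default 150×; strict — a mean of 149 fails).
Individuals with more than `max_missing_loci_per_individual` missing calls
(default 0, i.e. any missing locus) are then removed. Because removing
individuals changes per-locus mean depths, the two rules are iterated to a
fixed point; the first pass is the plain sequential rule, and iteration
only fires in contrived edge cases. This makes the filter idempotent,
which downstream code relies on.

Validation against reference pools computes each pool's foreign-allele
frequency by gene-copy counting (2 per homozygote, 1 per heterozygote).
The native pool may carry the foreign allele at up to
`tolerance_native_pool` (default 0.2) — low-frequency standing variation
for the "foreign" allele inside a native gene pool is real and must not
disqualify a locus — while the foreign pool must show a foreign-allele
frequency of at least 1 − `tolerance_foreign_pool` (default 0.15). With
both tolerances at 0 the rule reduces to requiring strict opposite
fixation. The defaults admit, e.g., a foreign reference pool of four with
one heterozygote (frequency 7/8) and a native pool of twenty with five
heterozygotes and one homozygous-foreign individual (frequency 0.175).

The simplified allele-ratio caller assigns HET when the foreign-read
fraction lies in [0.2, 0.8] (configurable), the corresponding homozygote
outside it, and MISSING at zero depth. It stands in for a full
amplicon-genotyping pipeline and ignores strand, base quality and
paralog checks.

## Ancestry scoring

Score = 100 × mean over loci of (1, 0.5, 0) for (hom-native, het,
hom-foreign). Missing calls are a hard error — the completeness filter
guarantees their absence. Reported values round half-away-from-zero to one
decimal; this convention is forced by the printed score lattice (raw
56.25 → 56.3 and 81.25 → 81.3, where banker's rounding would print 56.2
and 81.2). "Pure" means a raw score of exactly 100, not rounded-to-100.
Population summaries include an overall Total row; the median for an even
count is the midpoint of the central pair.

## Six-class hybrid classifier

Classes and gene-copy-origin probabilities φ = (φ_AA, φ_AB, φ_BB):
LMB (1,0,0), FB (0,0,1), F1 (0,1,0), F2 (¼,½,¼), LMB_Bx (½,½,0),
FB_Bx (0,½,½). Given native-allele frequencies p_A, p_B in the two
parental pools, the genotype law at a locus is the φ-mixture of the three
Hardy–Weinberg laws; loci are treated as unlinked, so likelihoods multiply
across loci. Only first- and second-generation categories are modeled —
later-generation backcrosses are absorbed into whichever class fits best.

With frequencies known, posteriors are computed exactly in log space
(classes with zero likelihood get exactly zero mass; a genotype vector
impossible under every class is an error). Otherwise a Gibbs sampler
augments the data with each individual's class z and each gene copy's
species-of-origin: a sweep (i) samples the origin pair per individual ×
locus given z and the current frequencies, resolving for mixed-origin
heterozygotes which species contributed the native copy, (ii) redraws
every p_A(ℓ), p_B(ℓ) from Beta posteriors given the origin-attributed
allele counts plus a Beta(0.5, 0.5) Jeffreys prior (configurable), and
(iii) redraws each z from its conditional posterior. Defaults: 10,000
burn-in, 10,000 retained sweeps, 6 independent runs; posteriors are the
across-run mean of post-burn-in class-indicator frequencies, and the
across-run SD is reported, flagging any class with SD > 0.05 as unstable.
Samples of known origin can be pinned to the corresponding pure class,
contributing to frequency updates only; pinning is off by default.

The two species labels are exchangeable, so the sampler's orientation is
broken deterministically: classes are initialized under the diagnostic
assumption p_A ≈ 1, p_B ≈ 0 — the same polarity the panel defines. For a
panel where the native allele is in fact the majority allele of species A
this pins the mode; it is a design choice, not an inference.

Labeling: posterior strictly greater than 0.8 for the top class gives a
single label; otherwise the two highest classes are joined as
"TOP/SECOND" (0.8 exactly is a dual label).

## Dataset filters

Loci must be genotyped in at least `min_presence` (default 0.8, inclusive)
of the individuals of every population; the global minor-allele count must
be at least `min_mac` (default 3, removing singletons and doubletons); and
when parent-locus ids are present, only the first SNP per parent locus is
retained to avoid tightly linked sites. Presence and MAC are independent
per-locus predicates, so their order cannot change the result; the
implementation applies presence first.

## Diversity, divergence and effective size

Per population and locus (complete-case within locus): H_O is the observed
heterozygote fraction; H_E = 2pq; π = 2pq·2n/(2n−1) with n the locus's
genotyped diploids (sample-size-corrected H_E, the convention for SNP
matrices without invariant sites); P is the major-allele frequency.
Summaries average over the dataset's analyzed loci, with across-loci
standard errors. F_IS = 1 − H_O/H_E per polymorphic locus, averaged.
Hardy–Weinberg uses the exact conditional test (enumeration over
heterozygote counts given the allele margins, summing outcomes no more
probable than observed) at α = 0.05; the out-of-HWE percentage is quoted
against all analyzed loci. Private alleles are alleles observed in exactly
one population.

Watterson's θ_W = S/(a₁M) uses k = 2n sequences, S = loci segregating
within the population, and M = the number of analyzed variant sites. On
SNP-only data θ_W (and π) are therefore per *analyzed site*, comparable
within a dataset but not across datasets with different ascertainment —
this is deliberate and matters when reading the numbers. Tajima's D uses
the standard a₁…e₂ constants with total pairwise diversity summed over
loci; S = 0 leaves D undefined (NaN).

Weir & Cockerham's θ̂ is computed from the per-locus a, b, c variance
components (sample sizes, allele frequencies, observed heterozygosity per
population) and combined as Σa/Σ(a+b+c) over loci with non-zero
denominators. Negative estimates are retained (e.g. −1/9 for two
populations of 5 AA + 5 aa each); they signal sampling noise around zero
differentiation.

The LD N̂e estimator squares the Pearson correlation of genotype dosages
(the Burrows composite measure) over all pairs of MAF-passing loci
(default threshold 0.05), skipping pairs that share a parent locus. The
drift component r²' = r² − (1/S + 3.19/S²) is inverted under random mating
as N̂e = (⅓ + √(1/9 − 2.76 r²'))/(2 r²'); r²' ≤ 0 yields ∞ — expected for
small samples where sampling noise swamps drift LD. The confidence
interval is the parametric chi-square interval on the mean r² with the
pair count as degrees of freedom. The S < 30 small-sample constants and
the jackknife interval are not implemented; with few individuals prefer
the parametric interval's width as a rough guide only. When the sample is
the entire population (S = N), the 1/S correction somewhat over-corrects
and estimates skew mildly high; the Wright–Fisher check in the test suite
shows medians near 1.3 × N under that regime, within its stated band.

## Synthetic data

`simulate_reference_pools` draws native-pool genotypes in Hardy–Weinberg
proportions from per-locus foreign-allele frequencies (default: uniform on
[0.03, 0.24], the observed range for a validated diagnostic panel with
standing variation) and a foreign pool fixed for the foreign allele; read
depths are negative binomial with per-locus means log-uniform on
[2,000, 9,500] and dispersion 5 (overdispersed, matching the order-of-
magnitude spread of real amplicon panels), split binomially by genotype
with a 0.001 per-read miscall rate. `simulate_hybrid_cohort` draws each
individual's origin pairs from its class's φ and alleles from the parental
frequencies — the exact sampling inverse of the classifier's model.
`simulate_structured_populations` uses the Balding–Nichols Beta model
around uniform ancestral frequencies. `simulate_wright_fisher` evolves a
closed, randomly mating diploid population with unlinked loci for 15
generations (ample for unlinked-locus LD to reach quasi-equilibrium, since
it halves each generation) to generate genuine drift LD.

Because cohorts are generated from the classifier's own model, class-
recovery tests demonstrate computational correctness of the inference, not
robustness to model violations (linked loci, genotyping error structure,
later-generation hybrids, population substructure within species). The
standing-variation generator models foreign alleles in natives as ancient
polymorphism, not recent admixture — precisely the confounder that makes a
naive "any foreign allele = introgression" reading wrong, and the reason
validation tolerances are configurable rather than zero.

## Numerical choices

Likelihood products are evaluated in log space with −inf allowed for
structurally zero classes; the Gibbs sampler clips Beta draws to
[1e−12, 1 − 1e−12]. Frequencies reported from count tables guard zero
denominators and return NaN for all-missing loci. The rounding helper
implements half-away-from-zero explicitly (floor(|x|·10 + 0.5)).
Chi-square CI bounds and the N̂e discriminant are clamped at zero before
the square root. Pipeline outputs contain no timestamps so reruns are
byte-identical; the manifest records a SHA-256 hash of the resolved
config.

## Problem sizes used in the test suite

Closed-form and oracle checks run on hand-sized instances. Stochastic
checks use: 20 individuals × 16 loci with 2,000/4,000 sweeps × 3 runs for
Gibbs-vs-closed-form agreement (tolerance 0.02); 100 individuals per class
× 16 diagnostic loci with 1,000/1,000 sweeps × 2 runs for ≥90% per-class
recovery; 5 populations × 30 diploids × 5,000 loci for Balding–Nichols
F_ST recovery (±0.02); and 20 Wright–Fisher replicates of N = 50 with 500
unlinked loci for the N̂e median band [35, 70]. These sizes were chosen as
the smallest at which the sampling distributions support the stated
tolerances.
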