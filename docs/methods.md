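# Methods

`polyqtl` implements QTL mapping for triploid offspring of a tetraploid x
diploid cross genotyped by low-depth sequencing, in the mould of the banana
('Musa') weevil-resistance mapping studies that motivated it. This note
documents the models, the defaults and why they were chosen, the numerical
choices, and the limits of what the synthetic-data experiments demonstrate.

## The mapping problem

A 4x x 2x cross yields triploid offspring whose genotype at a biallelic SNP
is a reference-allele dosage g in {0,1,2,3}: the tetraploid transmits a
diploid gamete (dosage 0-2) and the diploid a haploid gamete (0-1).
Genotyping-by-sequencing (DArTSeq-like) delivers per-sample reference and
alternative read counts at depths far too low for reliable integer dosage
calling in polyploids. The package therefore supports two complementary
mapping routes:

1. **Continuous mapping** — regress adjusted trait means directly on the
   per-individual reference-allele *frequency* estimate at each marker,
   skipping genotype calls entirely.
2. **Conventional linkage mapping** restricted to *simplex* markers
   (homozygous tetraploid x heterozygous diploid, e.g. AAAA x RA), which
   segregate 1:1 like a diploid backcross and can carry a standard linkage
   map and interval-mapping scan.

## Phenotype model and adjusted means

Percentage traits are analysed on the logit scale. Plant observations are
averaged to plot means, proportions are clamped to
`[delta, 1-delta]`, `delta = 1/(4 * n_plants * 100)` (= 1/1600 for 4-plant
plots), and logit-transformed; the clamp keeps 0%/100% plots usable. The
plot, not the plant, is the unit of analysis: the block structure is
randomized at plot level and plant readings within a plot share every
design effect.

The mixed model is

    y = mu + batch (fixed) + genotype_extra (fixed)
        + genotype_test (random) + block(batch) (random) + error,

fitted twice: first with the test genotypes random to estimate
`(sigma2_g, sigma2_block, sigma2_e)` by REML, then with all genotypes fixed
to obtain unshrunken generalized-least-squares means under the first-run
variance structure (least-squares means at the average batch). Broad-sense
heritability is the entry-mean form

    H2 = sigma2_g / (sigma2_g + sigma2_e / r_h),

with `r_h` the harmonic mean number of plots per test genotype. LSD
comparisons use `t(1-alpha/2, residual df) * SED` per pair with standard
insert-and-absorb letter assignment (ties broken by genotype id).

REML maximizes the profiled restricted likelihood over the two variance
*ratios* (genotype/residual, block/residual) on the log scale, by bounded
Powell search (bounds `log-ratio` in [-30, 10], `xtol` 1e-10, at most 500
iterations); the residual variance has a closed form given the ratios. On
balanced layouts the estimates agree with the ANOVA method-of-moments
closed form to 1e-6, which the tests verify.

## Dosage likelihoods and marker classification

Given reference/alternative counts (r, a) and candidate dosage g at ploidy
m, the likelihood is binomial,

    P(D | g) = Binom(r; r + a, p_g),  p_g = (g/m)(1 - eps) + (1 - g/m) eps,

with sequencing-error rate `eps` (default 0.01). A dosage is called only
when the best genotype is at least 10 times more likely than the runner-up;
otherwise the call is missing. Parental dosages use the same rule at their
own ploidy; markers are then classified into the 15 (g4, g2) combinations
and their segregation status (monomorphic, polymorphic non-segregating,
segregating in either or both parents). Marker filters: minor allele
frequency >= 0.02 (population frequency = unweighted mean of per-sample
frequencies, avoiding depth weighting) and missingness strictly below 10%.

## Continuous mapping and the depth-bias correction

At each marker, ordinary least squares of the adjusted means on the
frequency estimates gives a slope, a two-sided t-test p-value (n-2 df) and
R². Because the frequency is measured with binomial error, the slope is
attenuated; for triploid families the attenuation factor is

    lambda(S_T) = 1 / (1 + 2 / S_T),

where S_T is the sequencing depth — with variable depth, the harmonic mean
of the per-sample depths, since the error variance of a frequency estimate
scales as 1/depth. The corrected effect divides the raw slope by lambda.
S_T is computed per marker over the samples with nonzero depth (the finest
level consistent with a per-marker correction); a genome-wide S_T is
available via a flag. Effects are reported per reference-allele copy
(slope / 3 in a triploid), matching the allele-substitution-effect
convention; the per-unit-frequency slope is available via a flag. The scan
applies a fixed p < 0.001 threshold and no multiple-testing adjustment.

The correction factor is exact for 1:1 (backcross-like) segregation with
the genotypic variance of a simplex marker; for other parental classes the
true attenuation is stronger (a duplex x simplex marker attenuates by
1/(1 + 2.86/S_T), a duplex x homozygote by 1/(1 + 5.07/S_T)), and the
factor ignores the (1 - 2 eps) compression of the frequency range by
sequencing error. Under the cross's realistic marker-class mix at
harmonic-mean depth around 16, a residual downward bias of order 10%
therefore remains after correction — the parameter-recovery experiment in
the test suite quantifies it. Per-class correction factors would remove
most of it but would depart from the single published expression this
package implements.

## Linkage map and interval mapping

Simplex markers are recoded 0/1 by carrier status of the diploid parent's
segregating allele; dosages impossible under the simplex model become
missing. Markers pass a 1:1 chi-square distortion filter (alpha = 0.001)
and the missingness filter. Pairwise recombination uses mismatch counts
over complete pairs, `r = min(k, n-k)/n`, with coupling phase when
mismatches are the minority and a LOD against r = 0.5. Grouping is
single-linkage (transitive closure) at r <= 0.20, discarding groups below
10 markers. Ordering is greedy chaining seeded at the closest pair plus
2-opt refinement of the summed adjacent r (deterministic; an option adopts
the physical order instead). Map positions are cumulative Haldane distances
`d = -50 ln(1 - 2r)`; phases propagate along adjacent pairs from the group
anchor.

Interval mapping is regression-based (Haley-Knott): at every 5 cM plus all
marker positions, the phenotype means are regressed on the conditional
probability of the heterozygous class given, per individual, the nearest
non-missing flanking markers (no-interference backcross formulas; a single
flank beyond group ends; prior 0.5 with no information). At a fully
observed marker this reduces algebraically to the single-marker regression.
Composite interval mapping adds the SIM peak positions as covariates,
excluding cofactors within 10 cM (configurable) of the tested position;
collinear cofactors are dropped. Peaks are local maxima of -log10(p) at or
above 2. Mixture-model (EM) interval mapping is deliberately not
implemented: at backcross-like segregation and these effect sizes the
regression form agrees closely and matches the continuous-mapping arm.

Linkage groups whose markers map to more than one physical chromosome
(each contributing >= 5% of the group) are flagged as candidate
translocations; coupling-phase LD (r² with a decay table) supports manual
inspection of such groups.

## Synthetic cross generator

The generator emulates the motivating study's structure: 138 triploid
offspring, ~37k SNPs on 11 chromosomes (~18k segregating under the default
parental-class mix, which follows the observed 15-cell class table of the
motivating population), low variable depth, and a 4-batch x 2-block x
4-plant phenotype design with the two parents and four checks repeated in
every batch while offspring batches are disjoint.

* **Tetraploid meiosis**: the four homologs form two uniformly random
  disjoint bivalents per meiosis; each bivalent undergoes an independent
  Haldane (Poisson, no-interference) crossover process and contributes one
  chromatid. At any single marker this yields the hypergeometric gamete law
  C(g4,k) C(4-g4,2-k)/C(4,2). Double reduction is not modelled.
* **Diploid meiosis**: standard, same crossover model.
* **Reference-allele placement**: carrier homologs are uniformly random per
  marker, so marker pairs are in coupling or repulsion at random.
* **Phenotypes**: latent plot value = mu + sum of QTL effects (per
  reference-allele copy) + genotype deviation + batch + block(batch) + plot
  error on the logit scale, observed as 100 * expit(latent) with a small
  per-plant deviation. QTL positions snap to the nearest segregating marker
  (optionally restricted to a parental class) — a non-segregating QTL is
  unmappable by construction.
* **Read counts**: depth ~ negative binomial (mean, dispersion k) i.i.d.
  per site and sample, zero depth = missing; reference count ~
  Binomial(depth, p_g) with the error-adjusted reference fraction.

Defaults (chosen once, where the design itself does not fix them): depth
mean 20 with dispersion k = 10 (CV about 0.4, moderate overdispersion of a
filtered reduced-representation library), eps = 0.01, batch effects
(0, -0.2, 0.1, 0.3), variance components (0.2, 0.05, 0.8) plus per-plant
variance 0.05 — an entry-mean H2 in the 0.3-0.5 range typical of corm
damage traits — and mu = 0.25 on the logit scale. All randomness flows from
one seed through named `SeedSequence` child streams, so any run is exactly
reproducible from its config.

What the generator does **not** emulate: per-marker depth variation between
sequencing tags (depth is i.i.d. across sites, so call missingness is
nearly uniform across markers, unlike real DArTSeq where tag coverage
varies strongly); PCR/allelic bias; aneuploid or off-ploidy offspring;
linkage disequilibrium between the parents' haplotypes beyond what meiosis
creates. Passing tests therefore demonstrate correctness of the estimators
under the stated models, not robustness to those additional artefacts.

## Experiment sizes in the test suite

The acceptance-level experiments use: 200 replicates of a 2,002-marker
(1 cM spacing, 11 chromosomes), 138-offspring cross at depth 20 with one
0.8-logit QTL for effect recovery and peak localization; 20 null seeds of
5,000 unlinked markers for type-I calibration (unlinked so the binomial
reference distribution applies); and 50 seeds of two 100 cM, 50-marker
chromosomes with 200 offspring for map recovery. The map-recovery
experiment runs at mean depth 45: under the i.i.d. depth model confident
triploid dosage calling — and hence survival of the <10% missingness
filter — requires substantially more depth than frequency-based mapping,
consistent with the polyploid-genotyping literature.

## Known limitations

* The depth-bias correction uses the simplex-family factor everywhere; the
  residual downward bias at non-simplex markers and moderate depth is of
  order 10% (see above).
* Marker ordering by greedy + 2-opt is a heuristic; long groups with weak
  linkage can order locally well but globally imperfectly (map lengths
  inflate with miscalls, as genotyping error masquerades as recombination).
* The REML machinery targets the two-random-component PSEA layout and is
  dense-matrix; it is comfortable to a few thousand plots but is not a
  general sparse mixed-model solver.
* Interval mapping assumes additivity and no interference; dominance,
  epistasis and Kosambi-style interference are out of scope.
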