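# Methods

## Design

The package separates direct from indirect (genetic-nurture) effects by
splitting each genotyped parent's haplotypes into the one transmitted to
the offspring and the one not transmitted. PGS-T, built from the two
transmitted haplotypes, equals the offspring's own polygenic score and
captures direct effects plus any environmentally mediated parental effect;
PGS-NT, built from the two non-transmitted haplotypes, can only act
through the environment and is the nurture proxy. Everything below serves
that contrast: a simulator with known effects, a transmission-inference
algorithm, score assembly, outcome construction, and family-clustered
association models.

## Cohort simulator

**Genetics.** Biallelic markers are spread evenly across chromosomes at
5 kb spacing; effect-allele frequencies are uniform on a configurable
range (default 0.05–0.5). Founder haplotypes are drawn site-independently:
there is no background LD, so linkage exists only within families through
co-transmission. This is deliberate — tile matching and score arithmetic
do not require population LD, and the simplification keeps every
downstream identity analytically checkable. Consequences: the simulator
cannot probe LD-dependent behaviour (e.g. tag-SNP redundancy in scores) or
population stratification; a haplotype-block generator is out of scope.

**Meiosis.** Crossover counts per chromosome are Poisson with mean equal
to the map length in Morgans, positions uniform on the cM scale, no
interference (Haldane model), starting haplotype fair. The default map is
constant-rate, 100 cM per chromosome. Offspring haplotype 0 is the
paternal gamete and haplotype 1 the maternal one — the pedigree-phased
convention a phasing tool produces when given parents. A configurable
phase-error rate swaps the two offspring alleles independently at
heterozygous sites to emulate imperfect statistical phasing.

**Cohort shape.** Defaults follow the roughly 3:5:9 ratio of trios to
father-only to mother-only pairs seen in population biobanks where mothers
are genotyped more often (defaults 279/525/914 families; a sibling-rate
parameter adds second offspring to exercise the family random intercept).
In pair designs the second parent is simulated — so ground truth exists —
and withheld from the released panel.

**Assortative mating.** Couples are rank-matched on a noisy latent score:
each father receives a key correlated `spousal_corr` with his standardized
diploid PGS, and mothers sorted by score are assigned to fathers sorted by
key. For jointly Gaussian scores the realized spousal correlation
approaches the target (verified at r = 0.5 within ±0.05 at 5,000 couples).
The default is r = 0.02 — essentially random mating, the regime reported
for depression scores in population cohorts.

**Phenotypes.** A latent liability
`y = β_T·z(PGS-T) + β_NT·z(PGS-NT) + u_fam + ε` is built from the *true*
transmitted/non-transmitted scores (never from inference), both z-scored
with the mean and SD of the true PGS-T. Binary diagnoses threshold an
outcome-specific liability at the (1 − prevalence) quantile of its
analytic marginal distribution (variance
`β_T² + β_NT² + 2β_Tβ_NT·ρ + σ²_fam + σ²_resid`, with ρ the empirical
score correlation — deterministic given the cohort, unlike an empirical
quantile). Default prevalences mirror adult general-population rates for
MDD (18.5%), dysthymia (2.6%), GAD (11.5%), panic (3.3%), agoraphobia
(7.1%) and social phobia (4.0%); defaults β_T = 0.15, β_NT = 0,
σ²_fam = 0.2, σ²_resid = 0.8 put the direct effect in the range reported
for depression polygenic scores and make the total liability variance ≈ 1.
Symptom counts (0–9 and 0–7) are monotone Poisson-quantile transforms of a
per-wave liability; item-level scales (six 8-item neuroticism facets, a
10-item negative-affect scale) discretize noisy loadings on a shared
latent into 1–5 responses with small item missingness. A raw continuous
`trait` column exposes the liability itself, the cleanest target for
effect-recovery checks. Waves are missing completely at random at a
configurable rate, plus extra wave-1 symptom missingness emulating
conditional item administration. The per-person case status is fixed
across waves; wave-specific effects are therefore not simulated, only
wave-specific observation.

What passing tests on this generator do **not** show about real data:
robustness to LD, to genotyping error beyond phase flips, to informative
(non-random) missingness, to diagnostic-instrument quirks, or to
population structure. The generator's item scales are also more reliable
(Cronbach's alpha ≈ 0.9) than real questionnaires.

## Transmission inference

For each offspring/parent duo the offspring haplotype attributed to that
parent is compared to the parent's two haplotypes in tiles of
`tile_size = 150` adjacent markers per chromosome (final partial tile
kept). Agreement fractions are computed only over *informative* markers —
parent-heterozygous and fully observed — because homozygous sites match
both parental haplotypes and would dilute the contrast; their alleles are
still emitted in both output vectors. The better-scoring haplotype is
assigned; tiles with fewer than `min_informative = 5` informative markers
(scaled proportionally for partial tiles) or exactly tied scores are
ambiguous.

Resolution then proceeds in four deterministic steps:

1. **Smoothing** (on by default): an isolated single-tile switch whose
   score margin is below 0.2 is reverted — a tile that wins 0.51 vs 0.49
   is noise, a genuine double-crossover tile wins near 1.0 vs 0.0.
2. **Run-length fill**: ambiguous tiles flanked by agreeing assignments
   inherit them; chromosome-leading/trailing runs take the nearest
   assigned tile. A chromosome with no assigned tile stays entirely
   unassigned and contributes missing alleles.
3. **Breakpoint refinement**: each retained switch is refined inside the
   window spanning the flanking tile pair (plus ambiguous tiles between)
   to the split maximizing total agreement — the first argmax of the
   cumulative agreement difference, which is where it changes sign for a
   clean crossover. Breakpoints are emitted as half-open marker intervals
   [last marker of the old segment, first marker of the new).
4. **Double-crossover rescue**: crossover pairs closer together than a
   tile are invisible to tile-level matching (both flanking tiles keep the
   same majority assignment). Within every constant-assignment run, the
   maximum-subarray of the per-marker agreement difference finds the best
   interior interval favouring the other haplotype; it is flipped when it
   carries ≥ 10 net informative matches at ≥ 0.9 purity, thresholds high
   enough that phase-error noise (isolated flipped sites) and weak-noise
   tiles cannot trigger it. This pass cuts the allele error rate roughly
   five-fold at the benchmark scale (99.96% vs 99.67% concordance).

Transmitted alleles = the assigned haplotype's alleles; non-transmitted =
the other's; unassigned regions are missing in both. A Mendelian conflict
(offspring allele absent from the parent at an assigned marker) is counted
and masked, not raised. For an ungenotyped parent the non-transmitted side
is entirely missing while the transmitted side is read off the offspring's
own phased haplotype. Pair-mode inference for the genotyped parent is
byte-identical to trio-mode — the other parent never enters the duo
computation.

Marker indices are 0-based internally; VCF positions 1-based at I/O
boundaries. Inference contains no randomness.

## Scores

Weights are matched to the panel by variant ID with allele verification;
when the weight's effect allele is the panel's other allele the weight
sign is flipped (the additive constant this drops cancels in every
contrast the pipeline makes). Missing sites are skipped, never
mean-imputed; contributing-marker counts are reported. Key identity,
exact by construction at every assigned marker: transmitted +
non-transmitted alleles equal the parent's two alleles, so
`PGS-T + PGS-NT = father PGS + mother PGS` holds to float round-off on
complete trios. Under phase errors, mis-assigned sites swap transmitted
and non-transmitted and therefore cancel in the sum — the identity erodes
only through conflict-masked sites (≈ 0.2% of weight mass at a 0.5%
phase-error rate).

**Pair imputation.** The missing per-parent non-transmitted component of a
pair offspring is imputed as the observed parent's average haplotype
score, i.e. half that parent's diploid PGS. Two consequences, both
intentional and tested: the imputed component borrows the observed
parent's own genetics, so the pair PGS-NT partially overlaps PGS-T and
nurture estimates from imputed pairs are *attenuated* (to roughly 2/3 in
the joint model under this generator); and estimates are less precise.
This mirrors the behaviour expected of this design when pairs are
retained. A `cohort_mean` alternative (half the cohort-mean parental PGS —
a family-independent constant) is available: it leaves pair estimates
unbiased but discards all family information and shrinks the apparent
PGS-NT variance instead. The choice is a genuine design fork; the default
follows the attenuation-plus-retention trade-off.

**Standardization.** PGS-T and PGS-NT are both z-scored with the mean and
SD of PGS-T over the full analysis sample, so one unit is one SD of PGS-T
and the two coefficients are directly comparable. The four parent-of-origin
components are standardized analogously with the pooled transmitted
haplotype scores. PC residualization (OLS residuals on an intercept plus
components, collinear columns dropped with a warning) is provided for real
data; the synthetic cohorts carry no stratification, so the pipeline omits
it by default.

## Outcomes

Lifetime case = 1 if case at any observed wave, 0 if observed and never a
case, missing if never observed. Symptom scores average over observed
waves (any number of observed waves qualifies — no minimum is imposed).
Neuroticism: within each facet, missing items take the individual's mean
over that facet's observed items; a facet with no observed item nulls the
total; the default total uses 4 facets, excluding the depression and
anxiety facets so the trait is not contaminated by the disorders it is
modelled against (the 6-facet variant is available). Negative affect: a
plain 10-item sum, missing listwise — no imputation rule is defensible
without instrument documentation, so none is invented. Cronbach's alpha
uses complete rows and sample variances. Continuous outcomes are z-scored
before modelling.

## Association models

Complete-case per outcome; covariates are standardized age at first
assessment, sex, and genotyping array; family ID is the random-intercept
grouping. PGS-T and PGS-NT enter jointly by default (PGS-NT is the
nurture proxy unconfounded by direct effects; a separate-fits mode
exists). Continuous outcomes: REML linear mixed model via statsmodels
MixedLM. Binary outcomes: random-intercept logistic regression maximized
over a Gauss-Hermite quadrature marginal likelihood, 25 nodes — ample for
family-sized clusters and moderate intercept variances; it matches
`lme4::glmer(nAGQ = 25)` to 1e-3 on coefficients, SEs and the intercept
SD in the test suite's cross-check. Wald tests and normal-approximation
CIs throughout; odds ratios are per SD of PGS-T.

Degenerate cases are handled deterministically rather than raised: with
singleton-only families the intercept variance is unidentified and the
fit drops to OLS / plain logistic regression (flagged in the `model`
field — with cluster size one the mixed and marginal models coincide, and
the degenerate REML split otherwise corrupts standard errors); a variance
estimated at the boundary (SD < 0.01) likewise; separation and
non-convergence are flagged on the result. All fits are reproducible
bit-for-bit: starting values are the fixed GLM estimates and the
optimizers are deterministic.

Parent-of-origin models fit one parent's transmitted and non-transmitted
haplotype scores on the subsample with that parent genotyped, so maternal
and paternal sample sizes differ by design. The spousal check is the
Pearson correlation of parental diploid PGSs over complete couples with a
Fisher-z CI. FDR is Benjamini-Hochberg over one family pooling every
PGS-NT (and parent-of-origin non-transmitted) test across outcomes and
waves; the family is a caller-configurable mask.

## Problem sizes and numerical choices

The benchmark configuration for non-transmitted concordance is 500 trios ×
10,000 markers over 10 chromosomes of 100 cM (≈ 10 crossovers per gamete,
≈ 20 million alleles compared); it completes in well under a minute.
Replicate-based calibration studies (effect recovery, type-I error,
attenuation) use 300–1,000 markers and 1,000–4,000 offspring per
replicate — polygenic scores from a few hundred independent markers are
already effectively Gaussian, so nothing statistical is lost relative to
larger panels, and the replicate counts (20–200) keep Monte Carlo error
well inside the asserted bands. Seeds are fixed everywhere; identical
configuration implies byte-identical cohorts, inference, and fits.

## Known limitations

No background LD, multi-allelic sites, X-chromosome inheritance, de-novo
mutation, or stratification in the simulator; no statistical phasing or
genotype imputation in the pipeline (phased input is a precondition);
no diagnostic-instrument logic (the generator emits flags and sums
directly); the exact tile-resolution rules of production pipelines vary
and the ones here are validated against simulation ground truth, not
against an external phasing stack.
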