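# Methods

## Scope and data model

`arprev` analyses per-variant annotation tables for genes associated with
autosomal recessive (AR) disorders. A variant row carries: identity
(chrom:pos:ref:alt, 1-based, assumed left-aligned upstream), gene symbol,
consequence class, per-population allele count/number (AC/AN), a calling
confidence flag, a ClinVar-style assertion with an optional manual curation
override, a loss-of-function (LoF) confidence call, and the
deleterious/tolerated/missing verdicts of ten missense predictors (SIFT,
PolyPhen-2, MutationAssessor, VEST3, Eigen, CADD, DANN, MetaSVM, REVEL,
PROVEAN). The package consumes these calls; it does not run the predictors.
Frequencies are always derived on demand as AC/AN and are undefined where
AN = 0 (such variants are skipped from aggregation with a warning, since a
zero denominator carries no frequency information).

Seven ethnogeographic populations enter interethnic comparisons (AFR, LAT,
AJ, EAS, SAS, FIN, NFE); an eighth group (OTH, other/unknown ancestry)
contributes to pooled "global" AC/AN but not to cross-population contrasts.
Global frequency is the pooled-cohort estimate (summed AC over summed AN),
not an average of population frequencies.

## Triage cascade

Decision order in ensemble mode: (1) low calling confidence excludes; (2) a
curated benign/likely-benign assertion excludes (a manual override column
replaces the database label when present; "vus" and "conflicting" fall
through to computation); (3) pathogenic/likely-pathogenic keeps the variant
with database provenance; (4) LoF-class consequences (stop gain, frameshift,
start loss, canonical splice site — canonical-site eligibility is signalled
by the consequence column, decided upstream) are kept when the LoF call is
high-confidence; (5) missense variants are kept on unanimous deleterious
consensus. A missing predictor call counts as non-deleterious by default
(`missing_predictor_policy="strict"`), because stringency is the design
goal; the `lenient` policy judges consensus over the called tools only. The
required consensus count is configurable (default 10 = unanimity).

Classifier modes for head-to-head evaluation: `clinvar_only` stops after
step 3; `clinvar_plus` keeps only database-pathogenic variants that
computation independently confirms; `predictions_only` ignores pathogenic
database assertions (benign exclusions still apply). By construction the
`clinvar_plus` set is nested in the `clinvar_only` set, and lowering the
required consensus can only grow the ensemble set.

## Incidence model

Aggregated pathogenic allele frequency per gene and population:
q = 1 − Π(1 − f_i), treating pathogenic alleles as independent; this bounds
q between max f_i and min(1, Σ f_i). Under Hardy–Weinberg equilibrium
genetic incidence is q², which counts homozygotes and compound
heterozygotes alike. For the rare 2–3-gene disorders, loci combine as a
union over independent genes, 1 − Π_g(1 − q_g²); plain summation is
available as a config switch (`multi_gene_rule="sum"`) and differs only in
the q⁴ cross terms. Carrier rate is 1 − (1 − q)² (≥ 1 pathogenic allele); a
heterozygote-only definition (2pq) is an option.

Prevalence = penetrance × incidence, reported per 10,000 individuals at
disease-level penetrance 100/90/70/50% (penetrance scales linearly, so any
level is recoverable from the 100% column). Display tables round to one
decimal, half away from zero, and censor values below 0.05 per 10,000 as
"<0.1"; internal pipeline values are never censored.

Confidence intervals use a parametric binomial bootstrap: per variant,
AC\* ~ Binomial(AN, AC/AN), recomputing q, incidence and prevalence per
replicate; B = 1000 replicates, percentile 95% interval, deterministic under
a fixed seed. No method was prescribed for this step; the parametric
bootstrap was chosen because the binomial is the exact sampling model of an
allele count at fixed AN. When every variant has AN = 0 the CI is undefined
and flagged (NaN).

Interethnic variability is the fold change between the highest and lowest
population prevalence (global excluded). A population at exactly zero while
another is positive makes the fold infinite and the disease
population-limited. When recomputing folds from display tables, censored
("<0.1") entries are excluded from the minimum — they bound but do not
measure the prevalence. In the variability census, infinite folds count
toward the >100-fold cumulative tally: absence differs by more than any
finite fold.

## Informedness and founder evidence

Variants are sorted by descending MAF (ties broken lexicographically by
variant id, for determinism). P(v) = v/n; D(v) defaults to the cumulative
allele-mass share Σ_{i≤v} f_i / Σ_i f_i. The disease fraction explained by a
panel is not uniquely defined; allele-mass share is the quantity relevant to
carrier screening (the probability mass of pathogenic chromosomes the panel
interrogates), reproduces the worked single-dominant-variant value
(0.99 − 1/35 ≈ 0.96), and keeps D linear in the spectrum. A genotype-level
alternative D(v) = (q_v/q)² — the share of affected genotypes formed
entirely from panel alleles — sits behind
`disease_fraction_definition="genotype"`. I = max_v(D(v) − P(v)) is found by
a full scan; v\* is the smallest maximizing cutoff (within 1e-12 numerical
tolerance, so exact ties resolve to the smaller panel). I is 0 exactly for
an equal-mass spectrum and 1 − 1/n when one variant carries all mass.
Panel sizes for 50/75/90/99% coverage are the smallest v with D(v) ≥ level.
Profiles default to global MAFs with a per-population option.

Founder evidence is an explicit conjunction, all thresholds configurable:
population informedness ≥ 0.8, top-variant disease-mass share ≥ 0.5,
top-variant population MAF ≥ 3-fold its global (pooled) MAF, and top-variant
population AC ≥ 5. The last criterion is a plausibility floor: an allele
observed a handful of times cannot evidence a founder event, however
concentrated the gene's observed spectrum. No flagging rule was prescribed;
the conjunction makes the evidence auditable (each flag reports its
informedness, mass share, enrichment and AC). Note the enrichment criterion
is structurally bounded by the inverse of a population's cohort share, so
founder alleles in the majority population (NFE, ~46% of chromosomes) cannot
exceed ~2.2-fold global enrichment and are not detectable under this
definition.

The complexity census reports the median, Fisher–Pearson skewness
(standardized third moment) and excess kurtosis (normal = 0) of informedness
values, per-population medians, and an aggregated ROC curve obtained by
pooling all profiles' variants into one descending-MAF spectrum.

## Validation

Predicted prevalence (penetrance 100%, the common convention for rare
diseases) is paired with reported prevalence by disease and population and
correlated with Pearson's r. The default scale is log10, because prevalences
span orders of magnitude and the linear correlation would be dominated by
the few most common disorders; both scales are available, and non-positive
values are dropped under log10 with a warning. The mode comparison reruns
triage + incidence under each classifier mode against the same reported
table.

## Synthetic cohorts

The generator emulates the study conditions of a seven-population
aggregation cohort: sample sizes AFR 12,487; LAT 17,720; AJ 5,185; EAS
9,977; SAS 15,308; FIN 12,562; NFE 64,603; OTH 3,614 (141,456 individuals);
AN per variant and population is Binomial(2N, call rate 0.95), emulating
coverage dropout; every observed AC is Binomial(AN, true frequency), so
observed frequencies converge to the planted truth as AN grows.

True pathogenic MAFs follow a three-part mixture: 57% singleton-class
(point mass at 1/total-AN — the observed singleton fraction is necessarily
lower, since a mean-one binomial draw yields AC = 1 only ~37% of the time),
a log-uniform rare tail (10⁻⁶–10⁻³, 40%), and a few common alleles
(10⁻³–10⁻¹·⁵, 3%). Per-population frequencies scatter around the base value
by a mean-one lognormal (σ = 0.3, modest drift). Pathogenic variants draw
consequences from the detectable classes in empirically realistic
proportions (59% missense, 16% frameshift, 12% stop gain, the rest splice
site/start loss); benign variants are dominated by missense, intronic and
synonymous classes.

Label noise: rare true-pathogenic variants get a pathogenic database label
at rate 0.3 and common ones (global f > 10⁻³) at 0.95, with cross-errors of
1% (rare) and 0.05% (common) — label quality rising with study depth
mirrors real curation, and without it a single mislabeled common benign
allele dominates a gene's q. LoF calls are high-confidence for 85% of
pathogenic LoF-class variants (2% false-high on benign); predictors have
per-tool sensitivity 0.9 / specificity 0.95 with independent errors and 5%
missingness. The `noiseless()` config zeroes all error channels, under which
triage recovers the planted truth exactly (a calibration check).

Founder events (default 6) are planted in single-gene diseases: one variant
in one minority population is boosted until it holds 90% of the gene's
pathogenic mass there (floor 2×10⁻³, cap 0.2), and is database-labelled
pathogenic, as famous founder alleles are. Planting is restricted to
non-majority populations because of the enrichment bound noted above. The
planted mass is 0.9 rather than a bare majority because a top-variant share
of s with dispersed residual mass yields informedness s − 1/n, which must
clear the 0.8 flagging threshold.

Default problem size is 40 diseases (~50 genes, ~6,000 variants) — compact
enough for the whole suite to run in seconds while leaving dozens of genes
per structural property.

What the generator does **not** emulate: linkage disequilibrium, demography
and mutation-rate structure (frequencies are exchangeable within their
mixture class), correlated predictor errors, variant-level penetrance, and
in-utero loss. Passing tests therefore demonstrate the pipeline's
correctness and calibration under its own sampling assumptions, not the
accuracy of any particular real-world prevalence estimate.

## Numerical choices and edge cases

- Empty gene → q = 0; empty spectrum → informedness undefined (error).
- All-zero observed frequencies in a population → flat profile (D = P,
  I = 0), with a warning.
- Bootstrap with all AC = 0 degenerates to [0, 0]; with all AN = 0 it is
  undefined (NaN, flagged). Replicates below 100 are rejected.
- Correlation requires ≥ 3 usable pairs.
- The variability census reports raw counts and fractions only; it does not
  arbitrate between conflicting published summary percentages.
- Moments use biased (population) estimators of skewness and excess
  kurtosis.

## Known limitations

End-to-end incidence is deliberately conservative: stringent triage
sacrifices rare unlabeled pathogenic mass, so estimates sit ~10–20% below
planted truth at default noise, while the frequency-estimation step itself
is unbiased (<2% at pooled AN). Founder detection is frequency-based only
(no haplotype dating) and blind to majority-population founders. The VCF
reader accepts the aggregation-style INFO dialect read-only; the canonical
exchange format is TSV.
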