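# arprev

Population genetics of autosomal recessive (AR) disease from cohort-scale
allele frequencies.

AR disorders manifest only when both copies of a gene carry pathogenic
variation. Estimating how common each disorder is — and in which populations
— requires (1) deciding which variants in a disease gene are pathogenic, and
(2) converting their population allele frequencies into carrier rates and
disease incidence. `arprev` implements this pipeline for per-variant
annotation tables of the kind released by sequencing-aggregation efforts
(per-population allele counts AC and allele numbers AN, database assertions,
loss-of-function confidence calls, and the verdicts of ten missense effect
predictors), for clinical geneticists and statistical geneticists designing
population-adjusted carrier and newborn screening panels.

## The model

**Triage.** Variants are partitioned by a stringent cascade: low-confidence
calls and database-benign variants are removed; database-pathogenic variants
are kept; among the remainder, nonsense-class variants (stop gain,
frameshift, start loss, canonical splice site) are kept when the
loss-of-function caller rates them high-confidence, and missense variants
when all ten predictors unanimously call them deleterious. Alternative
classifier modes (database-only, database-confirmed-by-computation,
computation-only) support head-to-head evaluation.

**Incidence.** For gene *g* with pathogenic variant frequencies *f_i*, the
aggregated pathogenic allele frequency is, under independence,

```
q = 1 − Π_i (1 − f_i)
```

Under Hardy–Weinberg equilibrium (p² + 2pq + q² = 1) the genetic incidence
is q² — counting both homozygotes and compound heterozygotes — and the
carrier rate is 1 − (1 − q)². Multi-gene disorders combine loci as a union
over independent genes, 1 − Π_g (1 − q_g²). Clinical prevalence is penetrance
× incidence, reported per 10,000 at penetrance 100/90/70/50%, with a 95%
parametric binomial bootstrap CI. Interethnic variability is the fold change
between the highest and lowest population prevalence.

**Complexity.** For a gene's pathogenic variants sorted by descending MAF,
P(v) = v/n is the fraction of variants a size-v panel interrogates and D(v)
the fraction of disease it explains (cumulative allele-mass share).
Informedness is the Youden-style statistic

```
I = max_v ( D(v) − P(v) )
```

with maximizer v\*, the maximally effective screening panel; I = 0 means risk
is spread evenly, I → 1 means a single variant explains essentially all
disease. High population informedness plus population-specific enrichment of
the top allele flags candidate founder effects.

A synthetic cohort generator emulates the seven-population study conditions
(141,456 individuals; singleton-dominated heavy-tailed MAF spectrum; planted
pathogenic variants, founder alleles and label noise) so every stage is
testable against known ground truth.

## Worked example

```python
from arprev import (AnalysisConfig, DiseaseDefinition, GeneAggregate,
                    disease_incidence, format_per_10k,
                    informedness_from_spectrum)

cfg = AnalysisConfig()
disease = DiseaseDefinition(235200, "Hemochromatosis, type 1", ("HFE",))
agg = {"HFE": GeneAggregate(gene="HFE", population="GLOBAL", q=0.034)}
est = disease_incidence(disease, agg, "GLOBAL", cfg)
print(est.incidence)                        # 0.001156
print(format_per_10k(est.prevalence_per_10k[1.0]))   # 11.6
print(round(est.carrier_rate_per_10k, 1))   # 668.4

shares = [("rs1800562", 0.99)] + [(f"v{i:02d}", 0.01 / 34) for i in range(34)]
profile = informedness_from_spectrum(shares)
print(round(profile.informedness, 2), profile.v_star)  # 0.96 1
```

With an aggregated pathogenic allele frequency of 3.4% in *HFE*, genetic
incidence is q² ≈ 0.00116, i.e. 11.6 expected cases per 10,000 individuals
at full penetrance, and about 668 carriers per 10,000. A gene whose most
frequent variant carries 99% of the disease-allele mass over 35 pathogenic
variants has informedness 0.96 at an optimal panel of a single variant — a
one-variant screen captures nearly all risk.

A command-line interface mirrors the library
(`arprev simulate | triage | incidence | informedness | validate | compare`);
run `arprev --help`.

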