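"""Carrier rates, disease incidence and interethnic comparisons.

Under Hardy-Weinberg equilibrium (p^2 + 2pq + q^2 = 1) the genetic incidence
of a recessive disorder of a single gene is q^2, where q is the aggregated
frequency of pathogenic alleles. Treating pathogenic variants of a gene as
independent, q = 1 - prod_i(1 - f_i) over the per-variant frequencies f_i,
so q^2 counts both homozygotes and compound heterozygotes. Clinical
prevalence is obtained by scaling genetic incidence with a disease-level
penetrance, reported per 10,000 individuals. Uncertainty comes from a
parametric binomial bootstrap of the observed allele counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    AnalysisConfig,
    COMPARISON_POPULATIONS,
    DiseaseDefinition,
    GLOBAL,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("arprev")

PER_10K = 1e4


@dataclass
class GeneAggregate:
    """Aggregated pathogenic allele frequency q of one gene in one population.

    Invariant: max(f_i) <= q <= min(1, sum(f_i)); q = 0 with no variants.
    """

    gene: str
    population: str  # population code or GLOBAL
    q: float
    variant_ids: tuple[str, ...] = ()
    frequencies: tuple[float, ...] = ()


@dataclass
class IncidenceEstimate:
    """Per-disease, per-population incidence and penetrance-scaled prevalence."""

    omim_id: int
    population: str
    incidence: float  # genetic incidence (probability)
    prevalence_per_10k: dict[float, float]  # penetrance -> cases per 10,000
    carrier_rate_per_10k: float
    ci_low: Optional[float] = None  # per 10,000, at penetrance 1.0
    ci_high: Optional[float] = None
    ci_undefined: bool = False


@dataclass
class PopulationComparison:
    """Fold change between highest and lowest population prevalence."""

    omim_id: int
    fold_change: float  # >= 1 when finite; inf when population-limited
    tier: Optional[str]  # population_limited | gt_100x | gt_10x | lt_10x
    max_population: Optional[str] = None
    min_population: Optional[str] = None
    undefined: bool = False


def aggregate_allele_frequency(
    variants: Iterable[VariantRecord],
    population: Optional[str],
    gene: Optional[str] = None,
) -> GeneAggregate:
    """q = 1 - prod(1 - f_i) over one gene's pathogenic variants.

    ``population=None`` (or GLOBAL) pools AC/AN across all populations.
    Variants with AN == 0 in the population carry no frequency information
    and are skipped with a warning.
    """
    ids: list[str] = []
    freqs: list[float] = []
    gene_name = gene or ""
    for v in variants:
        gene_name = gene_name or v.gene
        if population is None or population == GLOBAL:
            f = v.global_frequency()
        else:
            f = v.frequency(population)
        if f is None:
            logger.warning(
                "variant %s has AN=0 in %s; skipped from aggregation",
                v.variant_id,
                population or GLOBAL,
            )
            continue
        if not 0.0 <= f <= 1.0:
            raise ValidationError(f"{v.variant_id}: frequency {f} outside [0,1]")
        ids.append(v.variant_id)
        freqs.append(f)
    q = 1.0 - float(np.prod([1.0 - f for f in freqs])) if freqs else 0.0
    return GeneAggregate(
        gene=gene_name,
        population=population or GLOBAL,
        q=q,
        variant_ids=tuple(ids),
        frequencies=tuple(freqs),
    )


def combine_gene_incidences(q_by_gene: Sequence[float], rule: str = "union") -> float:
    """Cross-gene genetic incidence for a multi-gene disease.

    ``union`` treats the loci as independent: 1 - prod_g(1 - q_g^2), i.e. the
    probability of being genetically affected at one or more of the genes.
    ``sum`` adds per-gene incidences (an upper-bound approximation).
    """
    if rule == "union":
        return 1.0 - float(np.prod([1.0 - q * q for q in q_by_gene]))
    if rule == "sum":
        return float(sum(q * q for q in q_by_gene))
    raise ValidationError(f"unknown multi-gene rule {rule!r}")


def carrier_rate(q: float, heterozygote_only: bool = False) -> float:
    """Carriers per 10,000: 1 - (1-q)^2 by default (>=1 pathogenic allele);
    the heterozygote-only definition 2pq is available as an option."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"frequency {q} outside [0,1]")
    p = 1.0 - q
    rate = 2.0 * p * q if heterozygote_only else 1.0 - p * p
    return rate * PER_10K


def disease_incidence(
    disease: DiseaseDefinition,
    aggregates: Mapping[str, GeneAggregate],
    population: str,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> IncidenceEstimate:
    """Genetic incidence and penetrance-scaled prevalence for one disease.

    ``aggregates`` maps gene symbol -> GeneAggregate for this population;
    every disease gene must be present (a gene without pathogenic variants
    contributes q = 0, not an absent entry).
    """
    qs = []
    for gene in disease.genes:
        if gene not in aggregates:
            raise ValidationError(
                f"OMIM {disease.omim_id}: no aggregate for gene {gene!r} "
                f"in {population}"
            )
        qs.append(aggregates[gene].q)
    incidence = combine_gene_incidences(qs, cfg.multi_gene_rule)
    prevalence = {
        pi: pi * incidence * PER_10K for pi in cfg.penetrance_levels
    }
    carrier_prob = 1.0 - float(np.prod([(1.0 - q) ** 2 for q in qs]))
    return IncidenceEstimate(
        omim_id=disease.omim_id,
        population=population,
        incidence=incidence,
        prevalence_per_10k=prevalence,
        carrier_rate_per_10k=carrier_prob * PER_10K,
    )


def bootstrap_ci(
    disease: DiseaseDefinition,
    counts_by_gene: Mapping[str, Sequence[tuple[int, int]]],
    reps: int = 1000,
    seed: int = 0,
    penetrance: float = 1.0,
    multi_gene_rule: str = "union",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of prevalence (per 10,000) for one population.

    ``counts_by_gene`` maps each disease gene to its pathogenic variants'
    observed (AC, AN) pairs. Each replicate redraws AC* ~ Binomial(AN, AC/AN)
    per variant and recomputes q, the cross-gene incidence and prevalence.
    Deterministic under a fixed seed. All-AN-zero input has no sampling
    distribution: the CI is undefined and NaNs are returned.
    """
    if reps < 100:
        raise ValidationError("bootstrap needs reps >= 100")
    rng = np.random.default_rng(seed)
    any_informative = False
    per_gene_draws = []
    for gene in disease.genes:
        pairs = [(ac, an) for ac, an in counts_by_gene.get(gene, ()) if an > 0]
        if not pairs:
            per_gene_draws.append(np.zeros(reps))
            continue
        any_informative = True
        ac = np.array([p[0] for p in pairs], dtype=float)
        an = np.array([p[1] for p in pairs], dtype=float)
        f_hat = ac / an
        ac_star = rng.binomial(an.astype(np.int64), f_hat, size=(reps, len(pairs)))
        f_star = ac_star / an
        q_star = 1.0 - np.prod(1.0 - f_star, axis=1)
        per_gene_draws.append(q_star)
    if not any_informative:
        logger.warning(
            "OMIM %d: all variants have AN=0; bootstrap CI undefined",
            disease.omim_id,
        )
        return (math.nan, math.nan)
    q_matrix = np.vstack(per_gene_draws)  # genes x reps
    if multi_gene_rule == "union":
        incidence = 1.0 - np.prod(1.0 - q_matrix**2, axis=0)
    else:
        incidence = np.sum(q_matrix**2, axis=0)
    prevalence = penetrance * incidence * PER_10K
    low, high = np.percentile(prevalence, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(low), float(high))


def interethnic_fold_change(
    prevalence_by_pop: Mapping[str, Optional[float]],
    omim_id: int = 0,
) -> PopulationComparison:
    """Fold change between highest and lowest population prevalence.

    ``None`` marks a display-censored entry, excluded from the comparison
    (only when reading back display tables; pipeline values are never
    censored internally). A population at exactly zero prevalence while
    another is positive makes the fold infinite: the disease is
    population-limited. The pooled global column must not be included.
    """
    defined = {
        pop: val
        for pop, val in prevalence_by_pop.items()
        if val is not None and pop != GLOBAL
    }
    if len(defined) < 2:
        raise ValidationError("fold change needs >= 2 populations with values")
    positives = {pop: v for pop, v in defined.items() if v > 0}
    if not positives:
        logger.warning("OMIM %d: all-zero prevalences; fold change undefined", omim_id)
        return PopulationComparison(
            omim_id=omim_id, fold_change=math.nan, tier=None, undefined=True
        )
    max_pop = max(positives, key=positives.get)
    if len(positives) < len(defined):  # some population has exactly zero
        min_pop = next(pop for pop, v in defined.items() if v == 0)
        return PopulationComparison(
            omim_id=omim_id,
            fold_change=math.inf,
            tier="population_limited",
            max_population=max_pop,
            min_population=min_pop,
        )
    min_pop = min(positives, key=positives.get)
    fold = positives[max_pop] / positives[min_pop]
    if fold > 100:
        tier = "gt_100x"
    elif fold > 10:
        tier = "gt_10x"
    else:
        tier = "lt_10x"
    return PopulationComparison(
        omim_id=omim_id,
        fold_change=fold,
        tier=tier,
        max_population=max_pop,
        min_population=min_pop,
    )


@dataclass
class VariabilityCensus:
    """Counts of diseases per interethnic-variability tier."""

    n_total: int
    tier_counts: dict[str, int]
    n_gt_10x_cumulative: int  # fold > 10, including > 100 and infinite
    n_gt_100x_cumulative: int  # fold > 100, including infinite

    def fractions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {}
        return {
            "population_limited": self.tier_counts.get("population_limited", 0)
            / self.n_total,
            "gt_100x_cumulative": self.n_gt_100x_cumulative / self.n_total,
            "gt_10x_cumulative": self.n_gt_10x_cumulative / self.n_total,
        }


def variability_census(
    comparisons: Iterable[PopulationComparison],
) -> VariabilityCensus:
    """Tier counts with cumulative >10-fold and >100-fold tallies.

    Infinite folds (population-limited diseases) count toward both cumulative
    tallies: a disease absent from a population differs more than 100-fold.
    """
    tier_counts: dict[str, int] = {}
    n_total = 0
    n10 = n100 = 0
    for comp in comparisons:
        if comp.undefined or comp.tier is None:
            continue
        n_total += 1
        tier_counts[comp.tier] = tier_counts.get(comp.tier, 0) + 1
        if comp.fold_change > 100:
            n100 += 1
        if comp.fold_change > 10:
            n10 += 1
    return VariabilityCensus(
        n_total=n_total,
        tier_counts=tier_counts,
        n_gt_10x_cumulative=n10,
        n_gt_100x_cumulative=n100,
    )


# ---------------------------------------------------------------------------
# Pipeline convenience: pathogenic set -> per-population estimates
# ---------------------------------------------------------------------------

def population_aggregates(
    pathogenic_set,
    genes: Iterable[str],
    populations: Sequence[str] = COMPARISON_POPULATIONS,
    include_global: bool = True,
) -> dict[str, dict[str, GeneAggregate]]:
    """population (or GLOBAL) -> gene -> GeneAggregate, q=0 for empty genes."""
    targets = list(populations) + ([GLOBAL] if include_global else [])
    out: dict[str, dict[str, GeneAggregate]] = {}
    for popn in targets:
        per_gene = {}
        for gene in genes:
            per_gene[gene] = aggregate_allele_frequency(
                pathogenic_set.variants(gene), popn, gene=gene
            )
        out[popn] = per_gene
    return out


def estimate_all(
    pathogenic_set,
    diseases: Sequence[DiseaseDefinition],
    cfg: AnalysisConfig = AnalysisConfig(),
    populations: Sequence[str] = COMPARISON_POPULATIONS,
    with_ci: bool = False,
) -> list[IncidenceEstimate]:
    """Incidence estimates for every disease in every population + global."""
    genes = sorted({g for d in diseases for g in d.genes})
    aggs = population_aggregates(pathogenic_set, genes, populations)
    estimates = []
    for disease in diseases:
        for popn, per_gene in aggs.items():
            est = disease_incidence(disease, per_gene, popn, cfg)
            if with_ci:
                counts = {}
                for gene in disease.genes:
                    pairs = []
                    for v in pathogenic_set.variants(gene):
                        if popn == GLOBAL:
                            pairs.append((v.global_ac, v.global_an))
                        else:
                            pairs.append((v.ac.get(popn, 0), v.an.get(popn, 0)))
                    counts[gene] = pairs
                low, high = bootstrap_ci(
                    disease,
                    counts,
                    reps=cfg.bootstrap_reps,
                    seed=cfg.rng_seed,
                    multi_gene_rule=cfg.multi_gene_rule,
                )
                est.ci_low, est.ci_high = low, high
                est.ci_undefined = math.isnan(low)
            estimates.append(est)
    return estimates
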