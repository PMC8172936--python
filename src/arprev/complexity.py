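"""Genetic complexity: informedness, screening panels, founder evidence.

For a gene's pathogenic variants sorted by descending minor allele frequency,
P(v) = v/n is the fraction of variants interrogated by a panel of size v and
D(v) the fraction of disease it explains. Informedness is the Youden-style
statistic I = max_v (D(v) - P(v)); the maximizing v* is the panel with the
largest information excess, i.e. the maximally effective screening panel.
I = 0 when risk is spread evenly across variants; I -> 1 - 1/n when a single
variant explains essentially all disease.

D(v) defaults to the cumulative pathogenic-allele mass share
sum_{i<=v} f_i / sum_i f_i — the quantity relevant to carrier screening. A
genotype-level alternative (q_v / q)^2, the share of recessive genotypes
formed entirely from panel alleles, sits behind a config switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import AnalysisConfig, GLOBAL, ValidationError, VariantRecord

logger = logging.getLogger("arprev")


@dataclass
class InformednessProfile:
    """ROC-style profile of one gene/disease in one population."""

    key: str  # gene symbol or disease id
    population: str
    variant_ids: tuple[str, ...]  # sorted by descending MAF
    frequencies: tuple[float, ...]
    P: np.ndarray  # fraction interrogated at v = 1..n
    D: np.ndarray  # fraction of disease explained at v = 1..n
    informedness: float
    v_star: int
    panel_sizes: dict[float, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.variant_ids)

    @property
    def top_mass_share(self) -> float:
        """Disease-mass share of the single most frequent variant, D(1)."""
        return float(self.D[0])

    @property
    def top_variant_id(self) -> str:
        return self.variant_ids[0]


def _sorted_spectrum(
    pairs: Sequence[tuple[str, float]]
) -> tuple[tuple[str, ...], np.ndarray]:
    """Sort by descending MAF, ties broken lexicographically by variant id."""
    ordered = sorted(pairs, key=lambda p: (-p[1], p[0]))
    ids = tuple(p[0] for p in ordered)
    freqs = np.array([p[1] for p in ordered], dtype=float)
    return ids, freqs


def informedness_from_spectrum(
    pairs: Sequence[tuple[str, float]],
    key: str = "",
    population: str = GLOBAL,
    coverage_levels: Sequence[float] = (0.5, 0.75, 0.9, 0.99),
    disease_fraction_definition: str = "allele_mass",
) -> InformednessProfile:
    """Profile from (variant_id, MAF) pairs; the core informedness scan."""
    if not pairs:
        raise ValidationError(f"{key}: informedness undefined with no variants")
    ids, freqs = _sorted_spectrum(pairs)
    n = len(ids)
    total = freqs.sum()
    if total <= 0:
        # All observed frequencies zero: no disease mass to apportion.
        logger.warning("%s/%s: zero total allele mass; flat profile", key, population)
        D = np.linspace(1 / n, 1.0, n)
    elif disease_fraction_definition == "allele_mass":
        D = np.cumsum(freqs) / total
    elif disease_fraction_definition == "genotype":
        q_v = 1.0 - np.cumprod(1.0 - freqs)
        q = q_v[-1]
        D = (q_v / q) ** 2 if q > 0 else np.linspace(1 / n, 1.0, n)
    else:
        raise ValidationError(
            f"unknown disease fraction definition {disease_fraction_definition!r}"
        )
    P = np.arange(1, n + 1) / n
    gap = D - P
    informedness = float(gap.max())
    # smallest cutoff within numerical tolerance of the maximum
    v_star = int(np.argmax(gap >= informedness - 1e-12)) + 1
    panel_sizes = {
        level: panel_size_for_coverage(D, level) for level in coverage_levels
    }
    return InformednessProfile(
        key=key,
        population=population,
        variant_ids=ids,
        frequencies=tuple(freqs),
        P=P,
        D=D,
        informedness=informedness,
        v_star=v_star,
        panel_sizes=panel_sizes,
    )


def informedness_profile(
    variants: Iterable[VariantRecord],
    population: Optional[str] = None,
    key: str = "",
    cfg: AnalysisConfig = AnalysisConfig(),
) -> InformednessProfile:
    """Profile of a gene's pathogenic variants in one population (or global).

    Variants with AN = 0 in the population are skipped (no frequency is
    defined there); at least one variant with a defined MAF is required.
    """
    pairs = []
    for v in variants:
        key = key or v.gene
        f = (
            v.global_frequency()
            if population in (None, GLOBAL)
            else v.frequency(population)
        )
        if f is None:
            continue
        pairs.append((v.variant_id, f))
    return informedness_from_spectrum(
        pairs,
        key=key,
        population=population or GLOBAL,
        coverage_levels=cfg.coverage_levels,
        disease_fraction_definition=cfg.disease_fraction_definition,
    )


def panel_size_for_coverage(D: np.ndarray, level: float) -> int:
    """Smallest panel size v with D(v) >= level; always <= n."""
    if not 0 < level <= 1:
        raise ValidationError(f"coverage level {level} outside (0,1]")
    idx = np.searchsorted(D, level - 1e-12)
    return int(min(idx, len(D) - 1)) + 1


def panel_for_coverage(profile: InformednessProfile, level: float) -> int:
    """Variants to interrogate to capture ``level`` of disease cases."""
    return panel_size_for_coverage(profile.D, level)


@dataclass
class FounderFlag:
    """Founder-effect evidence for one (disease/gene, population) pair."""

    key: str
    population: str
    flagged: bool
    informedness: float
    top_mass_share: float
    enrichment: float  # top variant population MAF / its global MAF
    top_variant_id: str
    top_variant_ac: int


def founder_flag(
    profiles_by_pop: Mapping[str, InformednessProfile],
    global_profile: InformednessProfile,
    variants: Sequence[VariantRecord],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[FounderFlag]:
    """Flag (gene, population) pairs with founder-allele evidence.

    The criterion is an explicit conjunction: population informedness >=
    ``informedness_min``, top-variant disease-mass share >= ``top_mass_min``,
    the top variant's population MAF enriched >= ``enrichment_min``-fold over
    its global MAF, and its population allele count >= ``founder_min_ac``
    (ruling out near-singleton artifacts). All thresholds are configurable.
    """
    by_id = {v.variant_id: v for v in variants}
    flags = []
    for popn, profile in profiles_by_pop.items():
        top = by_id.get(profile.top_variant_id)
        enrichment = 0.0
        top_ac = 0
        if top is not None:
            f_pop = top.frequency(popn)
            f_glob = top.global_frequency()
            top_ac = top.ac.get(popn, 0)
            if f_pop and f_glob:
                enrichment = f_pop / f_glob
        flagged = (
            profile.informedness >= cfg.informedness_min
            and profile.top_mass_share >= cfg.top_mass_min
            and enrichment >= cfg.enrichment_min
            and top_ac >= cfg.founder_min_ac
        )
        flags.append(
            FounderFlag(
                key=profile.key,
                population=popn,
                flagged=flagged,
                informedness=profile.informedness,
                top_mass_share=profile.top_mass_share,
                enrichment=enrichment,
                top_variant_id=profile.top_variant_id,
                top_variant_ac=top_ac,
            )
        )
    return flags


@dataclass
class ComplexityCensus:
    """Distribution summary of informedness across diseases."""

    n: int
    median: float
    skewness: float  # Fisher-Pearson standardized third moment
    excess_kurtosis: float  # normal distribution = 0
    aggregated_P: np.ndarray  # pooled variant-mass ROC curve
    aggregated_D: np.ndarray
    per_population_median: dict[str, float] = field(default_factory=dict)


def complexity_census(
    profiles: Sequence[InformednessProfile],
    per_population_profiles: Optional[
        Mapping[str, Sequence[InformednessProfile]]
    ] = None,
) -> ComplexityCensus:
    """Moments of the informedness distribution plus the pooled ROC curve.

    The aggregated curve pools every profile's variants into one spectrum
    sorted by descending MAF, so D is the cumulative share of total
    pathogenic-allele mass across all diseases.
    """
    values = np.array([p.informedness for p in profiles], dtype=float)
    if values.size < 3:
        raise ValidationError("complexity census needs >= 3 profiles")
    pooled = np.sort(
        np.concatenate([np.asarray(p.frequencies) for p in profiles])
    )[::-1]
    total = pooled.sum()
    if total > 0:
        agg_D = np.cumsum(pooled) / total
    else:
        agg_D = np.linspace(1 / pooled.size, 1.0, pooled.size)
    agg_P = np.arange(1, pooled.size + 1) / pooled.size
    per_pop_median = {}
    if per_population_profiles:
        for popn, profs in per_population_profiles.items():
            if profs:
                per_pop_median[popn] = float(
                    np.median([p.informedness for p in profs])
                )
    return ComplexityCensus(
        n=values.size,
        median=float(np.median(values)),
        skewness=float(stats.skew(values, bias=True)),
        excess_kurtosis=float(stats.kurtosis(values, fisher=True, bias=True)),
        aggregated_P=agg_P,
        aggregated_D=agg_D,
        per_population_median=per_pop_median,
    )
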