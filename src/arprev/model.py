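"""Domain types for autosomal-recessive disease genetics analyses.

The package models cohort-level variant data in the shape released by large
exome/genome aggregation efforts: per-variant allele counts (AC) and allele
numbers (AN) stratified by ethnogeographic population, together with the
evidence used to triage variants into pathogenic and non-pathogenic —
database assertions, loss-of-function confidence calls, and the verdicts of
ten missense effect predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import yaml

logger = logging.getLogger("arprev")

#: Canonical population codes. OTH (other/unknown ancestry) contributes to
#: pooled global AC/AN but is excluded from interethnic comparisons.
POPULATION_CODES = ("AFR", "LAT", "AJ", "EAS", "SAS", "FIN", "NFE", "OTH")

#: Populations entering interethnic (cross-population) comparisons.
COMPARISON_POPULATIONS = ("AFR", "LAT", "AJ", "EAS", "SAS", "FIN", "NFE")

#: Sentinel for pooled-cohort ("global") quantities.
GLOBAL = "GLOBAL"

CONSEQUENCES = (
    "missense",
    "stop_gain",
    "frameshift",
    "start_lost",
    "splice_site",
    "intronic",
    "synonymous",
    "other",
)

#: Consequence classes eligible for the high-confidence LoF rule.
LOF_CONSEQUENCES = ("stop_gain", "frameshift", "start_lost", "splice_site")

CLINVAR_ASSERTIONS = (
    "pathogenic",
    "likely_pathogenic",
    "benign",
    "likely_benign",
    "vus",
    "conflicting",
    "absent",
)

#: The ten missense effect predictors whose calls are consumed as input.
PREDICTOR_TOOLS = (
    "SIFT",
    "PolyPhen-2",
    "MutationAssessor",
    "VEST3",
    "Eigen",
    "CADD",
    "DANN",
    "MetaSVM",
    "REVEL",
    "PROVEAN",
)

PREDICTOR_CALLS = ("deleterious", "tolerated", "missing")

CLASSIFIER_MODES = ("ensemble", "clinvar_only", "clinvar_plus", "predictions_only")


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass(frozen=True)
class Population:
    """An ethnogeographic group with its cohort sample size (individuals)."""

    code: str
    label: str = ""
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.code not in POPULATION_CODES:
            raise ValidationError(f"unknown population code {self.code!r}")
        if self.n_samples < 0:
            raise ValidationError(f"{self.code}: n_samples must be >= 0")


#: Cohort sample sizes of the seven ethnogeographic groups plus the
#: other/unknown remainder (141,456 individuals in total).
DEFAULT_PANEL = (
    Population("AFR", "Africans", 12487),
    Population("LAT", "Latinos", 17720),
    Population("AJ", "Ashkenazi Jews", 5185),
    Population("EAS", "East Asians", 9977),
    Population("SAS", "South Asians", 15308),
    Population("FIN", "Finns", 12562),
    Population("NFE", "Non-Finnish Europeans", 64603),
    Population("OTH", "Other/unknown", 3614),
)


def panel_codes(panel: Sequence[Population]) -> tuple[str, ...]:
    codes = tuple(p.code for p in panel)
    if len(set(codes)) != len(codes):
        raise ValidationError("population codes must be unique within a panel")
    return codes


@dataclass
class VariantRecord:
    """One annotated variant with per-population counts and triage evidence.

    Frequencies are never stored: ``frequency(pop)`` derives AC/AN on demand
    and is defined only where AN > 0.
    """

    variant_id: str  # chrom:pos:ref:alt
    gene: str
    consequence: str
    ac: dict[str, int] = field(default_factory=dict)  # population -> AC
    an: dict[str, int] = field(default_factory=dict)  # population -> AN
    call_confidence: str = "pass"  # pass | low_confidence
    clinvar_assertion: str = "absent"
    curation_override: Optional[str] = None
    lof_confidence: str = "not_applicable"  # high | low | not_applicable
    predictor_calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.clinvar_assertion not in CLINVAR_ASSERTIONS:
            raise ValidationError(
                f"{self.variant_id}: unknown assertion {self.clinvar_assertion!r}"
            )
        if self.curation_override is not None and (
            self.curation_override not in CLINVAR_ASSERTIONS
        ):
            raise ValidationError(
                f"{self.variant_id}: unknown override {self.curation_override!r}"
            )
        if self.call_confidence not in ("pass", "low_confidence"):
            raise ValidationError(
                f"{self.variant_id}: unknown call confidence {self.call_confidence!r}"
            )
        if self.lof_confidence not in ("high", "low", "not_applicable"):
            raise ValidationError(
                f"{self.variant_id}: unknown LoF confidence {self.lof_confidence!r}"
            )
        for pop, count in self.ac.items():
            an = self.an.get(pop, 0)
            if count < 0 or an < 0:
                raise ValidationError(f"{self.variant_id}: negative AC/AN in {pop}")
            if count > an:
                raise ValidationError(
                    f"{self.variant_id}: AC={count} exceeds AN={an} in {pop}"
                )
        for tool, call in self.predictor_calls.items():
            if call not in PREDICTOR_CALLS:
                raise ValidationError(
                    f"{self.variant_id}: bad predictor call {tool}={call!r}"
                )

    @property
    def effective_assertion(self) -> str:
        """Curated assertion: manual override wins over the database label."""
        return self.curation_override or self.clinvar_assertion

    def frequency(self, population: str) -> Optional[float]:
        """Allele frequency AC/AN in one population; None where AN == 0."""
        an = self.an.get(population, 0)
        if an == 0:
            return None
        return self.ac.get(population, 0) / an

    @property
    def global_ac(self) -> int:
        return sum(self.ac.values())

    @property
    def global_an(self) -> int:
        return sum(self.an.values())

    def global_frequency(self) -> Optional[float]:
        """Pooled-cohort frequency: summed AC over summed AN, all populations."""
        an = self.global_an
        if an == 0:
            return None
        return self.global_ac / an

    @property
    def is_singleton(self) -> bool:
        """A variant observed on exactly one chromosome cohort-wide."""
        return self.global_ac == 1


@dataclass(frozen=True)
class DiseaseDefinition:
    """A recessive disorder and its 1-3 causative genes."""

    omim_id: int
    name: str
    genes: tuple[str, ...]
    # population code or GLOBAL -> reported cases per 10,000
    reported_prevalence: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.genes) <= 3:
            raise ValidationError(
                f"OMIM {self.omim_id}: diseases must map to 1-3 genes, "
                f"got {len(self.genes)}"
            )


@dataclass
class AnalysisConfig:
    """Tunable knobs for the whole pipeline.

    classifier_mode
        ``ensemble`` (database assertions + high-confidence LoF + unanimous
        missense consensus), ``clinvar_only`` (assertions alone),
        ``clinvar_plus`` (assertions confirmed by computation) or
        ``predictions_only`` (computation alone).
    required_consensus
        Number of deleterious predictor calls needed for the missense rule
        (default 10 = unanimity across all tools).
    missing_predictor_policy
        ``strict`` counts a missing call as non-deleterious (breaks
        unanimity); ``lenient`` judges consensus over the called tools only.
    """

    classifier_mode: str = "ensemble"
    required_consensus: int = 10
    missing_predictor_policy: str = "strict"  # strict | lenient
    penetrance_levels: tuple[float, ...] = (1.0, 0.9, 0.7, 0.5)
    bootstrap_reps: int = 1000
    rng_seed: int = 0
    censor_display_threshold: float = 0.1  # cases per 10,000
    coverage_levels: tuple[float, ...] = (0.5, 0.75, 0.9, 0.99)
    multi_gene_rule: str = "union"  # union | sum
    disease_fraction_definition: str = "allele_mass"  # allele_mass | genotype
    # Founder-evidence thresholds (conjunction; all must hold).
    informedness_min: float = 0.8
    top_mass_min: float = 0.5
    enrichment_min: float = 3.0
    founder_min_ac: int = 5

    def __post_init__(self) -> None:
        if self.classifier_mode not in CLASSIFIER_MODES:
            raise ValidationError(f"unknown classifier mode {self.classifier_mode!r}")
        if not 1 <= self.required_consensus <= len(PREDICTOR_TOOLS):
            raise ValidationError("required_consensus must be between 1 and 10")
        for level in self.penetrance_levels:
            if not 0 < level <= 1:
                raise ValidationError("penetrance levels must lie in (0, 1]")
        for level in self.coverage_levels:
            if not 0 < level <= 1:
                raise ValidationError("coverage levels must lie in (0, 1]")
        if self.missing_predictor_policy not in ("strict", "lenient"):
            raise ValidationError("missing_predictor_policy: strict or lenient")
        if self.multi_gene_rule not in ("union", "sum"):
            raise ValidationError("multi_gene_rule: union or sum")
        if self.disease_fraction_definition not in ("allele_mass", "genotype"):
            raise ValidationError(
                "disease_fraction_definition: allele_mass or genotype"
            )

    def with_mode(self, mode: str) -> "AnalysisConfig":
        return replace(self, classifier_mode=mode)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("penetrance_levels", "coverage_levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def setup_logging(level: str = "INFO") -> None:
    """Console logging for CLI runs; library use leaves handlers alone."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
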