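"""Synthetic cohort generator with known ground truth.

Emulates the shape of a multi-population sequencing-aggregation release
joined to a clinical variant database: seven ethnogeographic populations
(plus an other/unknown remainder) at realistic sample sizes, a heavy-tailed
allele-frequency spectrum dominated by singleton-class alleles, planted
pathogenic variants, planted founder alleles concentrated in chosen
populations, and noisy database assertions and predictor calls. Every
observed allele count is a Binomial(AN, true frequency) draw, so pipeline
estimates converge to the planted truth as AN grows.

The generator underpins the test suite: triage, incidence, bootstrap
coverage and founder detection are all evaluated against the planted truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    COMPARISON_POPULATIONS,
    DEFAULT_PANEL,
    DiseaseDefinition,
    GLOBAL,
    LOF_CONSEQUENCES,
    Population,
    PREDICTOR_TOOLS,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("arprev")

# Consequence mixes, conditioned on true pathogenicity. Pathogenic variants
# are confined to classes the triage cascade can in principle detect.
PATHOGENIC_CONSEQUENCES = ("missense", "frameshift", "stop_gain", "splice_site", "start_lost")
PATHOGENIC_CONSEQUENCE_PROBS = (0.594, 0.162, 0.12, 0.094, 0.03)
BENIGN_CONSEQUENCES = (
    "missense", "intronic", "synonymous", "splice_site",
    "stop_gain", "frameshift", "start_lost", "other",
)
BENIGN_CONSEQUENCE_PROBS = (0.34, 0.35, 0.16, 0.045, 0.02, 0.02, 0.005, 0.06)

BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Population sample sizes default to the seven ethnogeographic groups of
    the emulated 141,456-individual aggregation cohort; the singleton-class
    fraction defaults to the 57% observed among pathogenic variants there.
    Cohort size (diseases, variants per gene) is desk-scale.
    """

    panel: tuple[Population, ...] = DEFAULT_PANEL
    n_diseases: int = 40
    gene_multiplicity_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)
    mean_pathogenic_per_gene: float = 40.0
    mean_benign_per_gene: float = 80.0
    dispersion: float = 3.0  # negative-binomial shape for per-gene counts

    # True-MAF mixture for pathogenic variants.
    singleton_fraction: float = 0.57
    common_fraction: float = 0.03
    rare_log10_range: tuple[float, float] = (-6.0, -3.0)
    common_log10_range: tuple[float, float] = (-3.0, -1.5)
    pop_scatter_sigma: float = 0.3  # lognormal per-population drift

    # Founder events.
    n_founder_events: int = 6
    founder_mass: float = 0.9  # target disease-mass share of the founder allele
    founder_f_floor: float = 2e-3
    founder_f_cap: float = 0.2

    # Observation model.
    call_rate: float = 0.95  # per-variant fraction of chromosomes genotyped
    low_confidence_rate: float = 0.01

    # Database-label noise.
    clinvar_label_rate: float = 0.3  # rare true-pathogenic labelled pathogenic
    clinvar_label_rate_common: float = 0.95  # well-studied common alleles
    benign_label_rate: float = 0.2
    benign_label_rate_common: float = 0.95
    vus_rate: float = 0.1
    conflicting_rate: float = 0.05
    clinvar_error_rate: float = 0.01  # rare variants; label quality rises
    clinvar_error_rate_common: float = 0.0005  # ... with study depth

    # In-silico caller noise.
    loftee_sensitivity: float = 0.85
    loftee_false_high_rate: float = 0.02
    predictor_sensitivity: float = 0.9
    predictor_specificity: float = 0.95
    predictor_missing_rate: float = 0.05

    reported_noise_sigma: float = 0.25  # lognormal noise on reported prevalence

    def __post_init__(self) -> None:
        if not 0 < self.founder_mass < 1:
            raise ValidationError("founder_mass must lie in (0,1)")
        if self.singleton_fraction + self.common_fraction > 1:
            raise ValidationError("MAF mixture fractions exceed 1")
        for rate in (
            self.call_rate, self.low_confidence_rate, self.clinvar_label_rate,
            self.benign_label_rate, self.vus_rate, self.conflicting_rate,
            self.clinvar_error_rate, self.loftee_sensitivity,
            self.loftee_false_high_rate, self.predictor_sensitivity,
            self.predictor_specificity, self.predictor_missing_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValidationError(f"rate {rate} outside [0,1]")
        if self.n_diseases < 1:
            raise ValidationError("need at least one disease")

    def noiseless(self) -> "SimulationConfig":
        """All labels and predictor calls exactly reflect the planted truth."""
        return replace(
            self,
            low_confidence_rate=0.0,
            clinvar_error_rate=0.0,
            vus_rate=0.0,
            conflicting_rate=0.0,
            loftee_sensitivity=1.0,
            loftee_false_high_rate=0.0,
            predictor_sensitivity=1.0,
            predictor_specificity=1.0,
            predictor_missing_rate=0.0,
            reported_noise_sigma=0.0,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth matched to the emitted variant table by id."""

    variants: pd.DataFrame  # one row per variant: pathogenicity, true f per pop
    disease_incidence: dict  # (omim_id, population|GLOBAL) -> true incidence
    founder_events: set  # {(gene, population)}
    founder_diseases: set  # {(omim_id, population)}
    config: SimulationConfig = field(repr=False, default=None)
    seed: int = 0


def _sample_counts(rng, mean: float, k: float, size: int, floor: int) -> np.ndarray:
    p = k / (k + mean)
    return np.maximum(rng.negative_binomial(k, p, size=size), floor)


def _variant_id(rng, used: set) -> str:
    while True:
        chrom = int(rng.integers(1, 23))
        pos = int(rng.integers(1, 250_000_000))
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        vid = f"chr{chrom}:{pos}:{BASES[ref]}:{BASES[alt]}"
        if vid not in used:
            used.add(vid)
            return vid


def _clinvar_label(rng, pathogenic: bool, common: bool, cfg: SimulationConfig) -> str:
    u = rng.random()
    error_rate = cfg.clinvar_error_rate_common if common else cfg.clinvar_error_rate
    if pathogenic:
        label_rate = cfg.clinvar_label_rate_common if common else cfg.clinvar_label_rate
        if u < error_rate:
            return "benign" if rng.random() < 0.5 else "likely_benign"
        if u < error_rate + label_rate:
            return "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
    else:
        label_rate = cfg.benign_label_rate_common if common else cfg.benign_label_rate
        if u < error_rate:
            return "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
        if u < error_rate + label_rate:
            return "benign" if rng.random() < 0.5 else "likely_benign"
    u2 = rng.random()
    if u2 < cfg.vus_rate:
        return "vus"
    if u2 < cfg.vus_rate + cfg.conflicting_rate:
        return "conflicting"
    return "absent"


def _predictor_calls(rng, consequence: str, pathogenic: bool, cfg: SimulationConfig) -> dict:
    if consequence != "missense":
        return {tool: "missing" for tool in PREDICTOR_TOOLS}
    calls = {}
    for tool in PREDICTOR_TOOLS:
        if rng.random() < cfg.predictor_missing_rate:
            calls[tool] = "missing"
        elif pathogenic:
            calls[tool] = (
                "deleterious"
                if rng.random() < cfg.predictor_sensitivity
                else "tolerated"
            )
        else:
            calls[tool] = (
                "tolerated"
                if rng.random() < cfg.predictor_specificity
                else "deleterious"
            )
    return calls


def generate_cohort(
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> tuple[list[VariantRecord], list[DiseaseDefinition], SyntheticTruth]:
    """Draw a complete synthetic cohort: variants, disease map, truth.

    Deterministic under a fixed seed: identical (config, seed) yields
    byte-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    pops = [p.code for p in cfg.panel]
    comparison_pops = [p for p in pops if p != "OTH"]
    expected_an = {p.code: 2 * p.n_samples * cfg.call_rate for p in cfg.panel}
    total_expected_an = sum(expected_an.values())

    # Disease map and gene roster.
    diseases: list[DiseaseDefinition] = []
    gene_counter = 0
    multiplicities = rng.choice(
        [1, 2, 3], size=cfg.n_diseases, p=cfg.gene_multiplicity_probs
    )
    gene_to_disease: dict[str, int] = {}
    for i, mult in enumerate(multiplicities):
        genes = []
        for _ in range(int(mult)):
            gene_counter += 1
            genes.append(f"GENE{gene_counter:04d}")
        omim = 600000 + i
        diseases.append(
            DiseaseDefinition(omim_id=omim, name=f"Synthetic disorder {i + 1}", genes=tuple(genes))
        )
        for g in genes:
            gene_to_disease[g] = omim
    genes = sorted(gene_to_disease)

    n_path = _sample_counts(rng, cfg.mean_pathogenic_per_gene, cfg.dispersion, len(genes), 3)
    n_ben = _sample_counts(rng, cfg.mean_benign_per_gene, cfg.dispersion, len(genes), 1)

    # Founder events: distinct genes of single-gene diseases, one population
    # each. Founders are planted only in minority populations: enrichment of
    # a population MAF over the pooled global MAF is structurally bounded by
    # the inverse of the population's cohort share, so a founder allele in
    # the majority group cannot show meaningful global enrichment.
    single_gene = [d.genes[0] for d in diseases if len(d.genes) == 1]
    n_events = min(cfg.n_founder_events, len(single_gene))
    founder_genes = list(rng.choice(single_gene, size=n_events, replace=False))
    founder_candidates = [
        p for p in comparison_pops if expected_an[p] / total_expected_an < 0.35
    ]
    founder_pops = {
        g: founder_candidates[int(rng.integers(len(founder_candidates)))]
        for g in founder_genes
    }

    used_ids: set[str] = set()
    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    singleton_f = 1.0 / total_expected_an

    for gene, npath, nben in zip(genes, n_path, n_ben):
        plan = [True] * int(npath) + [False] * int(nben)
        gene_true_f: list[dict[str, float]] = []
        gene_meta: list[dict] = []
        for pathogenic in plan:
            if pathogenic:
                consequence = str(
                    rng.choice(PATHOGENIC_CONSEQUENCES, p=PATHOGENIC_CONSEQUENCE_PROBS)
                )
                u = rng.random()
                if u < cfg.singleton_fraction:
                    base_f = singleton_f
                elif u < cfg.singleton_fraction + cfg.common_fraction:
                    lo, hi = cfg.common_log10_range
                    base_f = 10 ** rng.uniform(lo, hi)
                else:
                    lo, hi = cfg.rare_log10_range
                    base_f = 10 ** rng.uniform(lo, hi)
            else:
                consequence = str(
                    rng.choice(BENIGN_CONSEQUENCES, p=BENIGN_CONSEQUENCE_PROBS)
                )
                u = rng.random()
                if u < 0.5:
                    base_f = singleton_f
                elif u < 0.9:
                    base_f = 10 ** rng.uniform(-6.0, -3.0)
                else:
                    base_f = 10 ** rng.uniform(-3.0, -1.0)
            sigma = cfg.pop_scatter_sigma
            drift = rng.lognormal(-sigma**2 / 2, sigma, size=len(pops))
            f_by_pop = {
                pop: float(min(0.5, base_f * drift[j])) for j, pop in enumerate(pops)
            }
            gene_true_f.append(f_by_pop)
            gene_meta.append({"pathogenic": pathogenic, "consequence": consequence})

        # Plant the founder allele: boost one pathogenic variant in the target
        # population until it carries ``founder_mass`` of the gene's mass there.
        founder_idx: Optional[int] = None
        if gene in founder_pops:
            fpop = founder_pops[gene]
            path_idx = [i for i, m in enumerate(gene_meta) if m["pathogenic"]]
            founder_idx = path_idx[int(rng.integers(len(path_idx)))]
            other_mass = sum(
                gene_true_f[i][fpop] for i in path_idx if i != founder_idx
            )
            target = cfg.founder_mass / (1.0 - cfg.founder_mass) * other_mass
            f_founder = float(
                np.clip(target, cfg.founder_f_floor, cfg.founder_f_cap)
            )
            gene_true_f[founder_idx][fpop] = f_founder

        for i, (f_by_pop, meta) in enumerate(zip(gene_true_f, gene_meta)):
            pathogenic = meta["pathogenic"]
            consequence = meta["consequence"]
            vid = _variant_id(rng, used_ids)
            is_founder = founder_idx is not None and i == founder_idx
            f_global_true = (
                sum(expected_an[pop] * f_by_pop[pop] for pop in pops)
                / total_expected_an
            )
            an = {
                pop: int(rng.binomial(2 * p.n_samples, cfg.call_rate))
                for pop, p in zip(pops, cfg.panel)
            }
            ac = {pop: int(rng.binomial(an[pop], f_by_pop[pop])) for pop in pops}

            common = f_global_true > 1e-3
            clinvar = (
                "pathogenic"
                if is_founder
                else _clinvar_label(rng, pathogenic, common, cfg)
            )
            if consequence in LOF_CONSEQUENCES:
                if pathogenic:
                    lof = "high" if rng.random() < cfg.loftee_sensitivity else "low"
                else:
                    lof = "high" if rng.random() < cfg.loftee_false_high_rate else "low"
            else:
                lof = "not_applicable"
            records.append(
                VariantRecord(
                    variant_id=vid,
                    gene=gene,
                    consequence=consequence,
                    ac=ac,
                    an=an,
                    call_confidence=(
                        "low_confidence"
                        if rng.random() < cfg.low_confidence_rate
                        else "pass"
                    ),
                    clinvar_assertion=clinvar,
                    lof_confidence=lof,
                    predictor_calls=_predictor_calls(rng, consequence, pathogenic, cfg),
                )
            )
            row = {
                "variant_id": vid,
                "gene": gene,
                "true_pathogenic": pathogenic,
                "founder": is_founder,
                "founder_population": founder_pops.get(gene, "") if is_founder else "",
                "true_f_global": f_global_true,
            }
            for pop in pops:
                row[f"true_f_{pop}"] = f_by_pop[pop]
            truth_rows.append(row)

    truth_df = pd.DataFrame(truth_rows)

    # True per-disease incidence from planted frequencies.
    disease_incidence: dict = {}
    path_df = truth_df[truth_df.true_pathogenic]
    for disease in diseases:
        for popn in comparison_pops + [GLOBAL]:
            col = "true_f_global" if popn == GLOBAL else f"true_f_{popn}"
            inc = 1.0
            for g in disease.genes:
                f = path_df.loc[path_df.gene == g, col].to_numpy()
                q = 1.0 - np.prod(1.0 - f) if f.size else 0.0
                inc *= 1.0 - q * q
            disease_incidence[(disease.omim_id, popn)] = 1.0 - inc

    founder_events = {(g, p) for g, p in founder_pops.items()}
    founder_diseases = {(gene_to_disease[g], p) for g, p in founder_pops.items()}
    truth = SyntheticTruth(
        variants=truth_df,
        disease_incidence=disease_incidence,
        founder_events=founder_events,
        founder_diseases=founder_diseases,
        config=cfg,
        seed=seed,
    )
    logger.info(
        "generated %d variants in %d genes (%d diseases, %d founder events)",
        len(records), len(genes), len(diseases), len(founder_events),
    )
    return records, diseases, truth


def reported_prevalence_from_truth(
    truth: SyntheticTruth,
    seed: int = 0,
    min_prevalence_per_10k: float = 1e-4,
) -> dict[tuple[int, str], float]:
    """A noisy 'clinically reported' prevalence table (per 10,000).

    Lognormal noise on the true global prevalence, mimicking the error of
    epidemiological surveys; diseases with negligible true prevalence have
    no reported literature value and are omitted.
    """
    rng = np.random.default_rng(seed)
    sigma = truth.config.reported_noise_sigma
    reported = {}
    for (omim, popn), inc in sorted(truth.disease_incidence.items()):
        if popn != GLOBAL:
            continue
        prev = inc * 1e4
        if prev < min_prevalence_per_10k:
            continue
        noise = rng.lognormal(0.0, sigma) if sigma > 0 else 1.0
        reported[(omim, GLOBAL)] = prev * noise
    return reported


@dataclass
class RecoveryReport:
    """How well the pipeline recovered the planted truth."""

    triage_sensitivity: Optional[float] = None
    triage_specificity: Optional[float] = None
    incidence_relative_bias: Optional[float] = None  # end-to-end, mean over diseases
    incidence_rmse: Optional[float] = None
    founder_precision: Optional[float] = None
    founder_recall: Optional[float] = None


def evaluate_recovery(
    truth: SyntheticTruth,
    calls=None,
    estimates=None,
    founder_flags=None,
    min_true_incidence: float = 1e-8,
) -> RecoveryReport:
    """Score pipeline outputs against the planted truth.

    ``calls``: iterable of PathogenicCall; ``estimates``: IncidenceEstimates
    (penetrance 1.0 is compared); ``founder_flags``: FounderFlags keyed by
    gene. Any output referencing an unknown id is an error.
    """
    report = RecoveryReport()
    truth_df = truth.variants.set_index("variant_id")

    if calls is not None:
        tp = fn = tn = fp = 0
        for call in calls:
            if call.variant_id not in truth_df.index:
                raise ValidationError(f"call for unknown variant {call.variant_id}")
            true_path = bool(truth_df.loc[call.variant_id, "true_pathogenic"])
            called_path = call.verdict == "pathogenic"
            if true_path and called_path:
                tp += 1
            elif true_path:
                fn += 1
            elif called_path:
                fp += 1
            else:
                tn += 1
        report.triage_sensitivity = tp / (tp + fn) if tp + fn else None
        report.triage_specificity = tn / (tn + fp) if tn + fp else None

    if estimates is not None:
        rel_errors = []
        sq_errors = []
        for est in estimates:
            key = (est.omim_id, est.population)
            if key not in truth.disease_incidence:
                raise ValidationError(f"estimate for unknown disease/population {key}")
            true_inc = truth.disease_incidence[key]
            if true_inc < min_true_incidence:
                continue
            rel_errors.append((est.incidence - true_inc) / true_inc)
            sq_errors.append((est.incidence - true_inc) ** 2)
        if rel_errors:
            report.incidence_relative_bias = float(np.mean(rel_errors))
            report.incidence_rmse = float(np.sqrt(np.mean(sq_errors)))

    if founder_flags is not None:
        flagged = {
            (flag.key, flag.population) for flag in founder_flags if flag.flagged
        }
        true_set = truth.founder_events
        tp_f = len(flagged & true_set)
        report.founder_precision = tp_f / len(flagged) if flagged else None
        report.founder_recall = tp_f / len(true_set) if true_set else None
    return report
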