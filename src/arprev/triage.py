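"""Pathogenic variant triage.

Partitions every variant in recessive-disease genes into pathogenic (with
provenance) and non-pathogenic. The decision cascade in ensemble mode:

1. low calling confidence          -> excluded_low_confidence
2. curated assertion benign/likely -> excluded_benign
3. curated assertion pathogenic/likely -> pathogenic (clinvar)
4. LoF-class consequence with high-confidence LoF call
                                   -> pathogenic (lof_high_confidence)
5. missense with unanimous deleterious predictor consensus
                                   -> pathogenic (missense_consensus)
else                               -> not_pathogenic

Alternative classifier modes restrict the cascade: ``clinvar_only`` stops
after step 3; ``clinvar_plus`` keeps only database-pathogenic variants that
computation independently confirms; ``predictions_only`` skips step 3.
Assertions of "vus" or "conflicting" are always routed to computation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    AnalysisConfig,
    LOF_CONSEQUENCES,
    PREDICTOR_TOOLS,
    ValidationError,
    VariantRecord,
)

logger = logging.getLogger("arprev")

VERDICTS = (
    "pathogenic",
    "excluded_benign",
    "excluded_low_confidence",
    "not_pathogenic",
)
PROVENANCES = ("clinvar", "lof_high_confidence", "missense_consensus", "none")

MAF_BIN_EDGES_PCT = (0.001, 0.01, 0.1, 1.0)  # percent
MAF_BIN_LABELS = ("<0.001%", "0.001-0.01%", "0.01-0.1%", "0.1-1%", ">=1%")


@dataclass(frozen=True)
class PathogenicCall:
    """The triage verdict for one variant under one classifier mode."""

    variant_id: str
    verdict: str
    provenance: str
    mode: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if (self.provenance == "none") != (self.verdict != "pathogenic"):
            raise ValidationError(
                f"{self.variant_id}: provenance {self.provenance!r} inconsistent "
                f"with verdict {self.verdict!r}"
            )


@dataclass
class PathogenicSet:
    """Pathogenic variants grouped by gene, plus the per-stage tally."""

    by_gene: dict[str, list[tuple[VariantRecord, PathogenicCall]]] = field(
        default_factory=dict
    )
    tally: Counter = field(default_factory=Counter)

    def variants(self, gene: str) -> list[VariantRecord]:
        return [v for v, _ in self.by_gene.get(gene, [])]

    def all_variants(self) -> list[VariantRecord]:
        return [v for pairs in self.by_gene.values() for v, _ in pairs]

    @property
    def n_pathogenic(self) -> int:
        return sum(len(pairs) for pairs in self.by_gene.values())


def _missense_consensus(v: VariantRecord, cfg: AnalysisConfig) -> bool:
    """Unanimous (or configured) deleterious consensus across predictors."""
    calls = [v.predictor_calls.get(tool, "missing") for tool in PREDICTOR_TOOLS]
    deleterious = sum(c == "deleterious" for c in calls)
    tolerated = sum(c == "tolerated" for c in calls)
    if tolerated > 0:
        return False
    if cfg.missing_predictor_policy == "strict":
        return deleterious >= cfg.required_consensus
    # lenient: judge the called tools only, still requiring at least one call
    n_called = deleterious + tolerated
    return n_called > 0 and deleterious >= min(cfg.required_consensus, n_called)


def _lof_pass(v: VariantRecord) -> bool:
    return v.consequence in LOF_CONSEQUENCES and v.lof_confidence == "high"


def classify_variant(v: VariantRecord, cfg: AnalysisConfig) -> PathogenicCall:
    """Apply the triage cascade to one variant under ``cfg.classifier_mode``."""
    mode = cfg.classifier_mode

    def call(verdict: str, provenance: str = "none") -> PathogenicCall:
        return PathogenicCall(v.variant_id, verdict, provenance, mode)

    if v.call_confidence == "low_confidence":
        return call("excluded_low_confidence")
    assertion = v.effective_assertion
    if assertion in ("benign", "likely_benign"):
        return call("excluded_benign")

    clinvar_path = assertion in ("pathogenic", "likely_pathogenic")
    computational = _lof_pass(v) or _missense_consensus(v, cfg)

    if mode == "clinvar_only":
        if clinvar_path:
            return call("pathogenic", "clinvar")
        return call("not_pathogenic")
    if mode == "clinvar_plus":
        if clinvar_path and computational:
            return call("pathogenic", "clinvar")
        return call("not_pathogenic")
    if mode == "ensemble" and clinvar_path:
        return call("pathogenic", "clinvar")
    # ensemble fall-through and predictions_only: computational assessment
    if _lof_pass(v):
        return call("pathogenic", "lof_high_confidence")
    if v.consequence == "missense" and _missense_consensus(v, cfg):
        return call("pathogenic", "missense_consensus")
    return call("not_pathogenic")


def build_pathogenic_set(
    variants: Iterable[VariantRecord], cfg: AnalysisConfig
) -> PathogenicSet:
    """Classify every variant and group the pathogenic ones by gene.

    The tally mirrors the selection-funnel box counts: total input, removals
    by stage, and pathogenic counts by provenance.
    """
    result = PathogenicSet()
    tally = result.tally
    seen: dict[str, set[str]] = {}
    for v in variants:
        tally["total"] += 1
        pcall = classify_variant(v, cfg)
        if pcall.verdict == "excluded_low_confidence":
            tally["removed_low_confidence"] += 1
            continue
        if pcall.verdict == "excluded_benign":
            tally["removed_benign"] += 1
            continue
        if pcall.verdict != "pathogenic":
            tally["not_pathogenic"] += 1
            continue
        gene_seen = seen.setdefault(v.gene, set())
        if v.variant_id in gene_seen:
            raise ValidationError(
                f"duplicate variant {v.variant_id} in gene {v.gene}"
            )
        gene_seen.add(v.variant_id)
        tally["pathogenic"] += 1
        tally[pcall.provenance] += 1
        result.by_gene.setdefault(v.gene, []).append((v, pcall))
    return result


def _maf_bin(freq_pct: float) -> str:
    for edge, label in zip(MAF_BIN_EDGES_PCT, MAF_BIN_LABELS):
        if freq_pct < edge:
            return label
    return MAF_BIN_LABELS[-1]


@dataclass
class LandscapeSummary:
    """Descriptive summary of the pathogenic-variation landscape."""

    consequence_counts_all: Counter
    consequence_counts_pathogenic: Counter
    maf_bin_counts: Counter  # pathogenic variants, global MAF bins (percent)
    n_singletons: int  # pathogenic with global AC == 1
    per_gene_counts: Counter  # pathogenic variants per gene
    per_gene_q: dict[str, float]  # aggregated pathogenic frequency per gene

    def consequence_fractions(self, pathogenic: bool = False) -> dict[str, float]:
        counts = (
            self.consequence_counts_pathogenic
            if pathogenic
            else self.consequence_counts_all
        )
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()} if total else {}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "n_pathogenic": n, "aggregated_q": self.per_gene_q.get(g)}
            for g, n in self.per_gene_counts.most_common()
        ]
        return pd.DataFrame(rows)


def variant_landscape_summary(
    variants: Sequence[VariantRecord],
    pathogenic_set: PathogenicSet,
) -> LandscapeSummary:
    """Counts and fractions behind the variant-landscape figures."""
    from .epi import aggregate_allele_frequency

    all_counts = Counter(v.consequence for v in variants)
    path_variants = pathogenic_set.all_variants()
    path_counts = Counter(v.consequence for v in path_variants)

    maf_bins: Counter = Counter()
    n_singletons = 0
    for v in path_variants:
        if v.is_singleton:
            n_singletons += 1
        freq = v.global_frequency()
        if freq is not None:
            maf_bins[_maf_bin(freq * 100.0)] += 1

    per_gene_counts = Counter(
        {g: len(pairs) for g, pairs in pathogenic_set.by_gene.items()}
    )
    per_gene_q = {
        g: aggregate_allele_frequency(pathogenic_set.variants(g), population=None).q
        for g in pathogenic_set.by_gene
    }
    return LandscapeSummary(
        consequence_counts_all=all_counts,
        consequence_counts_pathogenic=path_counts,
        maf_bin_counts=maf_bins,
        n_singletons=n_singletons,
        per_gene_counts=per_gene_counts,
        per_gene_q=per_gene_q,
    )


def calls_frame(
    variants: Iterable[VariantRecord], cfg: AnalysisConfig
) -> pd.DataFrame:
    """One triage call per variant as a tidy table (CLI output)."""
    rows = []
    for v in variants:
        pcall = classify_variant(v, cfg)
        rows.append(
            {
                "variant_id": v.variant_id,
                "gene": v.gene,
                "verdict": pcall.verdict,
                "provenance": pcall.provenance,
                "mode": pcall.mode,
            }
        )
    return pd.DataFrame(rows)
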