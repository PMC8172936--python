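"""Validation of predicted prevalence against reported clinical prevalence.

Model-predicted prevalence (per 10,000, penetrance 100% by default) is paired
with clinically reported prevalence per disease and population, and the two
are correlated. Because prevalences span several orders of magnitude the
default correlation scale is log10; the linear scale is also available.
The mode comparison reruns triage + incidence under each classifier mode to
rank database-only, computation-only and ensemble classification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import AnalysisConfig, CLASSIFIER_MODES, GLOBAL, ValidationError

logger = logging.getLogger("arprev")


@dataclass(frozen=True)
class ValidationPair:
    """Predicted vs reported prevalence for one disease and population."""

    omim_id: int
    population: str
    predicted: float  # cases per 10,000
    reported: float


def correlate_prevalence(
    pairs: Sequence[ValidationPair],
    scale: str = "log10",
) -> tuple[float, float, int]:
    """Pearson correlation of predicted vs reported prevalence.

    Returns (r, two-sided p, n used). Under log10, non-positive values carry
    no usable information and their pairs are dropped with a warning.
    """
    if scale not in ("log10", "linear"):
        raise ValidationError(f"unknown scale {scale!r}")
    xs, ys = [], []
    for pair in pairs:
        x, y = pair.predicted, pair.reported
        if scale == "log10":
            if x <= 0 or y <= 0:
                logger.warning(
                    "OMIM %d/%s: non-positive prevalence dropped under log10",
                    pair.omim_id,
                    pair.population,
                )
                continue
            x, y = math.log10(x), math.log10(y)
        xs.append(x)
        ys.append(y)
    n = len(xs)
    if n < 3:
        raise ValidationError(f"correlation needs >= 3 usable pairs, got {n}")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p), n


def build_pairs(
    estimates,
    reported: Mapping[tuple[int, str], float],
    penetrance: float = 1.0,
) -> list[ValidationPair]:
    """Match incidence estimates to a reported-prevalence table.

    A reported GLOBAL entry pairs with the pooled estimate; population
    entries pair population-to-population. Pairs where either side is
    non-positive are excluded from correlation by convention.
    """
    by_key = {(est.omim_id, est.population): est for est in estimates}
    pairs = []
    for (omim, popn), rep in reported.items():
        est = by_key.get((omim, popn or GLOBAL))
        if est is None:
            continue
        pairs.append(
            ValidationPair(
                omim_id=omim,
                population=popn or GLOBAL,
                predicted=est.prevalence_per_10k[penetrance],
                reported=rep,
            )
        )
    return pairs


def mode_comparison(
    variants,
    diseases,
    reported: Mapping[tuple[int, str], float],
    cfg: AnalysisConfig = AnalysisConfig(),
    scale: str = "log10",
    modes: Sequence[str] = CLASSIFIER_MODES,
) -> dict[str, tuple[float, float, int]]:
    """Correlation per classifier mode: rerun triage + incidence under each.

    Quantifies how database assertions, stringent computational predictions
    and their ensemble each track reported disease frequencies.
    """
    from .epi import estimate_all
    from .triage import build_pathogenic_set

    if not reported:
        raise ValidationError("reported-prevalence table is empty")
    results = {}
    for mode in modes:
        mode_cfg = cfg.with_mode(mode)
        pset = build_pathogenic_set(variants, mode_cfg)
        estimates = estimate_all(pset, diseases, mode_cfg)
        pairs = build_pairs(estimates, reported)
        try:
            results[mode] = correlate_prevalence(pairs, scale=scale)
        except ValidationError as exc:
            logger.warning("mode %s: %s", mode, exc)
            results[mode] = (math.nan, math.nan, 0)
    return results
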