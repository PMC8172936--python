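"""Shared fixtures: synthetic cohorts and a variant-record factory."""

from __future__ import annotations

import logging

import pytest

from arprev import (
    AnalysisConfig,
    DEFAULT_PANEL,
    SimulationConfig,
    VariantRecord,
    generate_cohort,
)
from arprev.model import PREDICTOR_TOOLS

# Expected per-population diagnostics (AN=0 skips, zero-mass profiles) are
# noisy at WARNING level during whole-cohort sweeps.
logging.getLogger("arprev").setLevel(logging.ERROR)


def make_variant(
    variant_id="chr1:1000:A:T",
    gene="GENE1",
    consequence="missense",
    ac=None,
    an=None,
    clinvar="absent",
    lof="not_applicable",
    n_deleterious=0,
    n_tolerated=0,
    call_confidence="pass",
    curation_override=None,
) -> VariantRecord:
    """Single-population variant with a configurable predictor profile."""
    calls = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if i < n_deleterious:
            calls[tool] = "deleterious"
        elif i < n_deleterious + n_tolerated:
            calls[tool] = "tolerated"
        else:
            calls[tool] = "missing"
    return VariantRecord(
        variant_id=variant_id,
        gene=gene,
        consequence=consequence,
        ac=ac if ac is not None else {"NFE": 10},
        an=an if an is not None else {"NFE": 10000},
        call_confidence=call_confidence,
        clinvar_assertion=clinvar,
        curation_override=curation_override,
        lof_confidence=lof,
        predictor_calls=calls,
    )


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact noisy cohort for fast structural tests."""
    sim = SimulationConfig(
        n_diseases=12, mean_pathogenic_per_gene=15, mean_benign_per_gene=25
    )
    return generate_cohort(sim, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the generator's default study conditions."""
    return generate_cohort(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL
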