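"""Readers and writers for the canonical exchange tables.

The canonical format is TSV with one row per variant, AC_<POP>/AN_<POP>
column pairs per population, and one column per missense predictor. A
read-only VCF reader maps the gnomAD-style INFO dialect (AC_afr, AN_afr, ...)
onto the same records. Result tables render prevalence per 10,000 to one
decimal, censoring values below the display threshold as "<0.1".
"""

from __future__ import annotations

import decimal
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    DEFAULT_PANEL,
    DiseaseDefinition,
    GLOBAL,
    Population,
    PREDICTOR_TOOLS,
    ValidationError,
    VariantRecord,
    panel_codes,
)

logger = logging.getLogger("arprev")

MANDATORY_COLUMNS = (
    "variant_id",
    "gene",
    "consequence",
    "call_confidence",
    "clinvar_assertion",
    "lof_confidence",
)

#: gnomAD INFO-key suffix for each canonical population code.
VCF_POP_KEYS = {
    "AFR": "afr",
    "LAT": "amr",
    "AJ": "asj",
    "EAS": "eas",
    "SAS": "sas",
    "FIN": "fin",
    "NFE": "nfe",
    "OTH": "oth",
}


class FormatError(ValueError):
    """Raised when a table lacks the mandatory structure."""


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variant_table(
    path,
    panel: Sequence[Population] = DEFAULT_PANEL,
    on_error: str = "raise",
) -> list[VariantRecord]:
    """Parse a canonical variant TSV into records.

    Parsing is total: every row yields exactly one record or one
    line-numbered diagnostic. With ``on_error="raise"`` the first bad row
    aborts; with ``on_error="skip"`` bad rows are logged and dropped.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    codes = panel_codes(panel)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    for code in codes:
        for prefix in ("AC_", "AN_"):
            if prefix + code not in df.columns:
                missing.append(prefix + code)
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")

    records: list[VariantRecord] = []
    for idx, row in enumerate(df.to_dict("records"), start=2):  # line 1 = header
        try:
            records.append(_row_to_record(row, codes))
        except (ValidationError, ValueError) as exc:
            if on_error == "raise":
                raise ValidationError(f"{path}:{idx}: {exc}") from exc
            logger.warning("%s:%d: skipped row: %s", path, idx, exc)
    return records


def _row_to_record(row: Mapping[str, str], codes: Sequence[str]) -> VariantRecord:
    ac: dict[str, int] = {}
    an: dict[str, int] = {}
    for code in codes:
        ac[code] = int(row[f"AC_{code}"])
        an[code] = int(row[f"AN_{code}"])
    predictor_calls = {
        tool: (row.get(tool) or "missing") for tool in PREDICTOR_TOOLS if tool in row
    }
    override = row.get("curation_override") or None
    return VariantRecord(
        variant_id=row["variant_id"],
        gene=row["gene"],
        consequence=row["consequence"],
        ac=ac,
        an=an,
        call_confidence=row["call_confidence"] or "pass",
        clinvar_assertion=row["clinvar_assertion"] or "absent",
        curation_override=override,
        lof_confidence=row["lof_confidence"] or "not_applicable",
        predictor_calls=predictor_calls,
    )


def write_variant_table(
    records: Iterable[VariantRecord],
    path,
    panel: Sequence[Population] = DEFAULT_PANEL,
) -> Path:
    """Emit records as a canonical TSV (inverse of :func:`read_variant_table`)."""
    codes = panel_codes(panel)
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "variant_id": rec.variant_id,
            "gene": rec.gene,
            "consequence": rec.consequence,
            "call_confidence": rec.call_confidence,
            "clinvar_assertion": rec.clinvar_assertion,
            "curation_override": rec.curation_override or "",
            "lof_confidence": rec.lof_confidence,
        }
        for code in codes:
            row[f"AC_{code}"] = rec.ac.get(code, 0)
            row[f"AN_{code}"] = rec.an.get(code, 0)
        for tool in PREDICTOR_TOOLS:
            row[tool] = rec.predictor_calls.get(tool, "missing")
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_vcf(
    path,
    panel: Sequence[Population] = DEFAULT_PANEL,
) -> list[VariantRecord]:
    """Read variants from a VCF carrying the gnomAD INFO dialect.

    Per-population counts come from ``AC_afr``/``AN_afr``-style INFO keys;
    triage evidence from ``GENE``, ``CSQ_CLASS``, ``CLNSIG``, ``LOF``,
    ``PRED_<tool>`` keys. Coordinates are 1-based; variants are identified as
    chrom:pos:ref:alt (left-alignment is assumed done upstream).
    """
    import pysam

    codes = panel_codes(panel)
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            for alt_idx, alt in enumerate(site.alts or ()):
                info = site.info
                ac: dict[str, int] = {}
                an: dict[str, int] = {}
                def info_get(key, default=None):
                    # pysam raises on keys absent from the VCF header
                    try:
                        return info.get(key, default)
                    except (KeyError, ValueError):
                        return default

                for code in codes:
                    suffix = VCF_POP_KEYS[code]
                    raw_ac = info_get(f"AC_{suffix}", 0)
                    if isinstance(raw_ac, tuple):
                        raw_ac = raw_ac[alt_idx]
                    ac[code] = int(raw_ac or 0)
                    an[code] = int(info_get(f"AN_{suffix}", 0) or 0)
                predictor_calls = {}
                for tool in PREDICTOR_TOOLS:
                    key = "PRED_" + tool.replace("-", "").upper()
                    call = info_get(key)
                    predictor_calls[tool] = str(call) if call else "missing"
                records.append(
                    VariantRecord(
                        variant_id=f"{site.chrom}:{site.pos}:{site.ref}:{alt}",
                        gene=str(info_get("GENE", "")),
                        consequence=str(info_get("CSQ_CLASS", "other")),
                        ac=ac,
                        an=an,
                        call_confidence=(
                            "pass"
                            if not site.filter or "PASS" in site.filter
                            else "low_confidence"
                        ),
                        clinvar_assertion=str(info_get("CLNSIG", "absent")),
                        lof_confidence=str(info_get("LOF", "not_applicable")),
                        predictor_calls=predictor_calls,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Disease map and reported prevalence
# ---------------------------------------------------------------------------

def read_disease_map(path) -> list[DiseaseDefinition]:
    """TSV with columns omim_id, name, genes (comma-separated, 1-3 symbols)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("omim_id", "name", "genes"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    diseases = []
    seen: set[int] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        omim = int(row.omim_id)
        if omim in seen:
            raise ValidationError(f"{path}:{idx}: duplicate omim_id {omim}")
        seen.add(omim)
        genes = tuple(g.strip() for g in row.genes.split(",") if g.strip())
        diseases.append(DiseaseDefinition(omim_id=omim, name=row.name, genes=genes))
    return diseases


def read_reported_prevalence(path) -> dict[tuple[int, str], float]:
    """TSV columns omim_id, population (code or GLOBAL), reported_per_10000."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("omim_id", "population", "reported_per_10000"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return {
        (int(row.omim_id), row.population or GLOBAL): float(row.reported_per_10000)
        for row in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Result rendering
# ---------------------------------------------------------------------------

def format_per_10k(value: float, censor_threshold: float = 0.1) -> str:
    """Render a per-10,000 rate for display tables.

    One decimal, rounding half away from zero; values below half the censor
    threshold (i.e. < 0.05 for the default 0.1) render as "<0.1".
    """
    if value < censor_threshold / 2:
        return f"<{censor_threshold:g}"
    quantized = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return str(quantized)


def parse_per_10k(text: str) -> Optional[float]:
    """Inverse of :func:`format_per_10k`; censored entries become None."""
    text = text.strip()
    if text.startswith("<"):
        return None
    return float(text)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
) -> dict[str, Path]:
    """Write each result DataFrame as <name>.tsv with a stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


def render_prevalence_table(
    estimates: Iterable,
    diseases: Mapping[int, DiseaseDefinition],
    censor_threshold: float = 0.1,
    penetrance: float = 1.0,
) -> pd.DataFrame:
    """Display table of per-population prevalence with censored rendering.

    One row per disease; per-population columns hold formatted per-10,000
    strings ("<0.1" below threshold), mirroring the convention of published
    population-prevalence tables.
    """
    from .model import COMPARISON_POPULATIONS

    by_disease: dict[int, dict[str, float]] = {}
    for est in estimates:
        by_disease.setdefault(est.omim_id, {})[est.population] = (
            est.prevalence_per_10k[penetrance]
        )
    rows = []
    for omim, per_pop in sorted(by_disease.items()):
        disease = diseases.get(omim)
        row: dict[str, object] = {
            "omim_id": omim,
            "name": disease.name if disease else "",
            "genes": ",".join(disease.genes) if disease else "",
        }
        if GLOBAL in per_pop:
            row["Global"] = format_per_10k(per_pop[GLOBAL], censor_threshold)
        for code in COMPARISON_POPULATIONS:
            if code in per_pop:
                row[code] = format_per_10k(per_pop[code], censor_threshold)
        rows.append(row)
    return pd.DataFrame(rows)
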