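"""Reading case/genotype inputs and writing the consult ledger.

The case file is YAML with ``patient``, ``medications``, ``comedications``
and optionally ``genotypes`` blocks; genotype reports are two-column TSV
(``gene<TAB>diplotype``, ``#`` comments ignored). Reports are written as
CSV (the spreadsheet ledger plus summary lines), JSON (the full structured
result with provenance) or Markdown (a consult-note section). Regenerating
a report from the same inputs yields byte-identical canonical content; the
timestamp lives only in the JSON provenance block and is excluded from the
canonical form.
"""

from __future__ import annotations

import csv
import datetime
import hashlib
import io
import json
import logging
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__ as engine_version
from .knowledge_base import KnowledgeBase
from .scoring import ConsultResult, GenotypeRecord, PatientCase

logger = logging.getLogger(__name__)

LEDGER_COLUMNS = [
    "medication",
    "guideline",
    "adequate_trial",
    "outcome",
    "congruency",
    "rationale",
]


class CaseFormatError(ValueError):
    """A case or genotype file does not match the documented schema."""


class Provenance(BaseModel):
    kb_version: str = "unversioned"
    engine_version: str = engine_version
    timestamp: str = ""
    input_digests: dict[str, str] = Field(default_factory=dict)


class ConsultReport(BaseModel):
    """A consult result plus the provenance recorded alongside it."""

    result: ConsultResult
    provenance: Provenance


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_case(path: Path | str) -> PatientCase:
    """Load and schema-validate a YAML patient case file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise CaseFormatError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise CaseFormatError(f"{path}: expected a mapping at the top level")
    if "medications" in raw:
        meds = raw["medications"]
        if not isinstance(meds, list):
            raise CaseFormatError(f"{path}: 'medications' must be a list")
        raw = {
            **raw,
            "medications": [
                {**m, "drug_name": m.get("drug_name", m.get("name"))}
                if isinstance(m, dict)
                else m
                for m in meds
            ],
        }
        for m in raw["medications"]:
            if isinstance(m, dict):
                m.pop("name", None)
    try:
        return PatientCase.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise CaseFormatError(f"{path}: {details}") from exc


def read_genotypes(path: Path | str, kb: Optional[KnowledgeBase] = None) -> list[GenotypeRecord]:
    """Load a two-column TSV genotype report.

    An empty file is a valid untested patient. With a knowledge base given,
    genes it does not define are warned about (they will be carried as
    indeterminate by the scorer, never dropped).
    """
    path = Path(path)
    records: list[GenotypeRecord] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise CaseFormatError(
                f"{path}:{lineno}: expected 'gene<TAB>diplotype', got {line!r}"
            )
        gene, diplotype = (f.strip() for f in fields)
        if kb is not None and gene not in kb.genes:
            logger.warning(
                "%s:%d: gene %s not in knowledge base; phenotype will be indeterminate",
                path, lineno, gene,
            )
        records.append(GenotypeRecord(gene=gene, diplotype=diplotype))
    return records


def build_report(
    result: ConsultResult,
    kb: Optional[KnowledgeBase] = None,
    input_paths: Optional[dict[str, Path | str]] = None,
    timestamp: Optional[str] = None,
) -> ConsultReport:
    """Attach provenance (KB/engine versions, input digests, timestamp)."""
    digests = {
        name: _sha256(Path(p)) for name, p in (input_paths or {}).items() if Path(p).is_file()
    }
    return ConsultReport(
        result=result,
        provenance=Provenance(
            kb_version=kb.version if kb is not None else "unversioned",
            timestamp=timestamp
            if timestamp is not None
            else datetime.datetime.now(datetime.timezone.utc).isoformat(),
            input_digests=digests,
        ),
    )


def _ledger_cells(result: ConsultResult) -> list[list]:
    return [
        [
            row.drug_name,
            row.guideline_flag,
            row.adequacy_flag,
            row.outcome_flag,
            row.score,
            row.rationale,
        ]
        for row in result.rows
    ]


def render_csv(result: ConsultResult) -> str:
    """Canonical spreadsheet form: ledger rows then summary lines.

    Comma-separated, UTF-8, LF line endings, strings quoted; byte-identical
    across runs for identical inputs.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_NONNUMERIC, lineterminator="\n")
    writer.writerow(LEDGER_COLUMNS)
    for cells in _ledger_cells(result):
        writer.writerow(cells)
    writer.writerow(["PGxBS", result.pgxbs])
    writer.writerow(["interpretation", result.interpretation.value])
    writer.writerow(["testing_recommended", str(result.testing_recommended).lower()])
    writer.writerow(["n_guideline_meds", result.n_guideline_meds])
    return buf.getvalue()


def render_markdown(result: ConsultResult) -> str:
    """Human-readable consult-note section."""
    lines = ["## Pharmacogenomics consult ledger", ""]
    lines.append("| " + " | ".join(LEDGER_COLUMNS) + " |")
    lines.append("|" + "---|" * len(LEDGER_COLUMNS))
    for cells in _ledger_cells(result):
        lines.append("| " + " | ".join(str(c) for c in cells) + " |")
    lines += [
        "",
        f"**PGxBS: {result.pgxbs}** — "
        + (
            "a possible pharmacogenomic contribution to the medication-related problems"
            if result.interpretation.value == "possible_pgx_contribution"
            else "pharmacogenomics is less likely to be important for this patient"
        ),
    ]
    if not result.genotyped:
        lines += [
            "",
            f"Patient untested; {result.n_guideline_meds} medication(s) with PGx "
            "guidelines — reactive PGx testing "
            + ("recommended." if result.testing_recommended else "not indicated."),
        ]
    lines.append("")
    return "\n".join(lines)


def render_json(report: ConsultReport) -> str:
    return json.dumps(report.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"


def load_json_report(path: Path | str) -> ConsultReport:
    """Reload a JSON report; round-trips losslessly."""
    return ConsultReport.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))


def write_report(
    result: ConsultResult | ConsultReport,
    format: str,
    path: Path | str,
    kb: Optional[KnowledgeBase] = None,
) -> Path:
    """Write the consult in the requested format (csv, json or markdown)."""
    report = (
        result if isinstance(result, ConsultReport) else build_report(result, kb=kb)
    )
    path = Path(path)
    if format == "csv":
        content = render_csv(report.result)
    elif format == "json":
        content = render_json(report)
    elif format == "markdown":
        content = render_markdown(report.result)
    else:
        raise ValueError(f"unknown report format {format!r}")
    path.write_text(content, encoding="utf-8", newline="")
    return path
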