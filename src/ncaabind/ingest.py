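"""Reading and filtering IEDB-style MHC ligand export tables.

The export is a wide CSV; only five logical columns matter here: the peptide
``Name`` (which may carry modification notation), the qualitative and
quantitative measurements, the assay type (``Response Measured``) and the
restricting ``HLA`` allele.  :func:`filter_dataset` applies the modeling
filter chain — quantitative value present, single HLA allele, single assay
type, peptide length 9 or 10 — and reports the row count after every stage.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PeptideParseError
from . import tokenizer

logger = logging.getLogger(__name__)

#: logical name -> default physical CSV header
DEFAULT_COLUMNS: dict[str, str] = {
    "name": "Name",
    "qualitative": "Qualitative Measurement",
    "quantitative": "Quantitative Measurement",
    "response": "Response Measured",
    "hla": "HLA",
}


@dataclass(frozen=True)
class EpitopeRecord:
    """One row of an IEDB-style export (the five columns of interest)."""

    name_field: str
    qualitative: str | None
    quantitative_nM: float | None
    response_measured: str
    hla_allele: str


@dataclass
class FilterReport:
    """Row counts after each stage of the filter chain, in application order."""

    rows_in: int = 0
    rows_after_quantitative: int = 0
    rows_after_hla: int = 0
    rows_after_response: int = 0
    rows_after_length: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def rows_out(self) -> int:
        return self.rows_after_length

    def to_json(self) -> str:
        d = asdict(self)
        d["rows_out"] = self.rows_out
        return json.dumps(d, indent=1)


def _parse_quantitative(cell, row_index: int) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str):
        cell = cell.strip().replace(",", "")
        if not cell:
            return None
    try:
        value = float(cell)
    except (TypeError, ValueError):
        logger.warning("row %d: unparseable quantitative value %r treated as absent", row_index, cell)
        return None
    if not math.isfinite(value) or value <= 0:
        logger.warning("row %d: non-positive IC50 %r treated as absent", row_index, cell)
        return None
    return value


def read_iedb_export(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[EpitopeRecord]:
    """Read an IEDB-style CSV into :class:`EpitopeRecord` rows.

    *column_map* overrides the default physical header per logical column
    (keys of :data:`DEFAULT_COLUMNS`).  Extra columns are ignored; blank or
    unparseable quantitative cells map to an absent value.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    columns = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(columns)
        if unknown:
            raise ConfigurationError(f"unknown logical columns in column_map: {sorted(unknown)}")
        columns.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [phys for phys in columns.values() if phys not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) missing: {missing}; present: {list(df.columns)}"
        )
    records: list[EpitopeRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        # itertuples mangles headers containing spaces; index positionally
        vals = {logical: row[df.columns.get_loc(phys)] for logical, phys in columns.items()}
        qualitative = vals["qualitative"].strip() or None
        records.append(
            EpitopeRecord(
                name_field=vals["name"].strip(),
                qualitative=qualitative,
                quantitative_nM=_parse_quantitative(vals["quantitative"], i),
                response_measured=vals["response"].strip(),
                hla_allele=vals["hla"].strip(),
            )
        )
    logger.info("read %d records from %s", len(records), path)
    return records


def _base_length(record: EpitopeRecord) -> int | None:
    try:
        base, _ = tokenizer.parse_name(record.name_field)
    except PeptideParseError:
        return None
    return len(base)


def filter_dataset(
    records: Sequence[EpitopeRecord],
    hla: str,
    response: str,
    lengths: Iterable[int] = (9, 10),
) -> tuple[list[EpitopeRecord], FilterReport]:
    """Apply the four-stage modeling filter and count every stage.

    Stages, in order: (i) quantitative IC50 present; (ii) HLA allele equals
    *hla* (exact string equality after trimming); (iii) assay label equals
    *response* (case-insensitive after trimming); (iv) base-sequence length
    in *lengths*.  Records whose ``Name`` field does not parse are dropped at
    the length stage with a warning.
    """
    if not hla.strip() or not response.strip():
        raise ConfigurationError("hla and response filters must be non-empty")
    lengths = set(lengths)
    report = FilterReport(rows_in=len(records))

    stage1 = [r for r in records if r.quantitative_nM is not None]
    report.rows_after_quantitative = len(stage1)

    hla = hla.strip()
    stage2 = [r for r in stage1 if r.hla_allele.strip() == hla]
    report.rows_after_hla = len(stage2)

    response_cf = response.strip().casefold()
    stage3 = [r for r in stage2 if r.response_measured.strip().casefold() == response_cf]
    report.rows_after_response = len(stage3)

    stage4: list[EpitopeRecord] = []
    for r in stage3:
        n = _base_length(r)
        if n is None:
            report.warnings.append(f"unparseable Name dropped: {r.name_field!r}")
        elif n in lengths:
            stage4.append(r)
    report.rows_after_length = len(stage4)

    if not stage4:
        report.warnings.append("filter produced an empty dataset")
    logger.info(
        "filter chain: %d -> %d -> %d -> %d -> %d",
        report.rows_in,
        report.rows_after_quantitative,
        report.rows_after_hla,
        report.rows_after_response,
        report.rows_after_length,
    )
    return stage4, report


def aggregate_duplicates(records: Sequence[EpitopeRecord]) -> list[EpitopeRecord]:
    """Optional hygiene: collapse repeated measurements of one peptide.

    Rows sharing a ``Name`` field are merged into a single record whose IC50
    is the geometric mean of the individual measurements (IC50 error is
    multiplicative, so the geometric mean is the natural centre).
    """
    groups: dict[str, list[EpitopeRecord]] = {}
    for r in records:
        groups.setdefault(r.name_field, []).append(r)
    out: list[EpitopeRecord] = []
    for name, grp in groups.items():
        if len(grp) == 1:
            out.append(grp[0])
            continue
        values = [r.quantitative_nM for r in grp if r.quantitative_nM is not None]
        gm = float(np.exp(np.mean(np.log(values)))) if values else None
        out.append(
            EpitopeRecord(
                name_field=name,
                qualitative=grp[0].qualitative,
                quantitative_nM=gm,
                response_measured=grp[0].response_measured,
                hla_allele=grp[0].hla_allele,
            )
        )
    return out


def write_dataset(records: Sequence[EpitopeRecord], path: str | Path) -> None:
    """Write records back out with the five standard headers."""
    df = pd.DataFrame(
        {
            "Name": [r.name_field for r in records],
            "Qualitative Measurement": [r.qualitative or "" for r in records],
            "Quantitative Measurement": [
                "" if r.quantitative_nM is None else r.quantitative_nM for r in records
            ],
            "Response Measured": [r.response_measured for r in records],
            "HLA": [r.hla_allele for r in records],
        }
    )
    df.to_csv(path, index=False)
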