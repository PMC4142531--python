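"""Readers and writers for AERS quarterly ASCII tables (DEMO, DRUG, REAC).

The legacy AERS distribution ships each table as a delimiter-separated flat
file ("$" by convention) with a single header line. Only the three tables
the normalization pipeline consumes are supported:

* DEMO — one row per submitted report version (ISR), carrying the CASE
  number and the date FDA received the report (FDA_DT, ``YYYYMMDD``).
* DRUG — one row per drug mention within a report, keyed by
  (ISR, DRUG_SEQ), with the verbatim DRUGNAME, ROUTE and DOSE_VBM text.
* REAC — one row per reported adverse event, a MedDRA Preferred Term.

Files are read line by line so that malformed rows can be counted and
reported instead of silently dropped: for every table,
``records + malformed == data_lines``. Legacy AERS files are not reliably
UTF-8; decoding falls back to Latin-1 per file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

DEFAULT_DELIMITER = "$"

DateTriple = tuple[int, int, int]


@dataclass(frozen=True)
class DemoRecord:
    """One DEMO row: a report version and its FDA receipt date.

    ``fda_dt`` is a (year, month, day) triple, or None when the field was
    missing or unparseable (the record is retained and flagged, because the
    de-duplication rule can still fall back to the ISR tie-break).
    """

    isr: int
    case_id: int
    fda_dt: DateTriple | None


@dataclass(frozen=True)
class DrugRecord:
    """One DRUG row: a verbatim drug mention within a report."""

    isr: int
    drug_seq: int
    drugname: str
    route: str = ""
    dose_vbm: str = ""


@dataclass(frozen=True)
class ReacRecord:
    """One REAC row: a verbatim MedDRA Preferred Term for a report."""

    isr: int
    pt_term: str


@dataclass
class TableReadResult:
    """Records from one table plus per-line accounting.

    Iterating the result yields the records, so it can be passed anywhere a
    record sequence is expected while keeping the bookkeeping attached.
    """

    records: list
    malformed_count: int = 0
    flagged_dates: int = 0
    data_lines: int = 0
    columns: dict[str, int] = field(default_factory=dict)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]


class MissingColumnError(ValueError):
    """A required column is absent from the table header."""


def _read_lines(path: str | Path) -> list[str]:
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return text.splitlines()


def _header_map(header: str, delimiter: str, required: Sequence[str], path) -> dict[str, int]:
    names = [c.strip().upper() for c in header.split(delimiter)]
    columns = {name: i for i, name in enumerate(names)}
    for col in required:
        if col not in columns:
            raise MissingColumnError(f"{path}: required column {col!r} not in header {names}")
    return columns


def parse_fda_dt(text: str) -> DateTriple | None:
    """Parse a YYYYMMDD date field; None for missing/invalid values.

    Triples compare lexicographically, matching YYYYMMDD string order.
    """
    text = text.strip()
    if len(text) != 8 or not text.isdigit():
        return None
    y, m, d = int(text[:4]), int(text[4:6]), int(text[6:8])
    if not (1 <= m <= 12 and 1 <= d <= 31):
        return None
    return (y, m, d)


def _int_field(fields: list[str], idx: int) -> int | None:
    if idx >= len(fields):
        return None
    text = fields[idx].strip()
    if not text.isdigit():
        return None
    return int(text)


def _text_field(fields: list[str], idx: int | None) -> str:
    if idx is None or idx >= len(fields):
        return ""
    return fields[idx].strip()


def read_demo(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> TableReadResult:
    """Read a DEMO table into :class:`DemoRecord` rows.

    A missing ISR or CASE makes the line malformed; a bad FDA_DT only flags
    the record (``fda_dt=None``) and retains it.
    """
    lines = _read_lines(path)
    if not lines:
        raise MissingColumnError(f"{path}: empty file, no header")
    columns = _header_map(lines[0], delimiter, ("ISR", "CASE", "FDA_DT"), path)
    result = TableReadResult(records=[], columns=columns)
    for line in lines[1:]:
        if not line.strip():
            continue
        result.data_lines += 1
        fields = line.split(delimiter)
        isr = _int_field(fields, columns["ISR"])
        case_id = _int_field(fields, columns["CASE"])
        if isr is None or case_id is None:
            result.malformed_count += 1
            continue
        fda_dt = parse_fda_dt(_text_field(fields, columns["FDA_DT"]))
        if fda_dt is None:
            result.flagged_dates += 1
        result.records.append(DemoRecord(isr=isr, case_id=case_id, fda_dt=fda_dt))
    return result


def read_drug(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> TableReadResult:
    """Read a DRUG table; ROUTE and DOSE_VBM are optional columns."""
    lines = _read_lines(path)
    if not lines:
        raise MissingColumnError(f"{path}: empty file, no header")
    columns = _header_map(lines[0], delimiter, ("ISR", "DRUG_SEQ", "DRUGNAME"), path)
    result = TableReadResult(records=[], columns=columns)
    for line in lines[1:]:
        if not line.strip():
            continue
        result.data_lines += 1
        fields = line.split(delimiter)
        isr = _int_field(fields, columns["ISR"])
        drug_seq = _int_field(fields, columns["DRUG_SEQ"])
        drugname = _text_field(fields, columns["DRUGNAME"])
        if isr is None or drug_seq is None:
            result.malformed_count += 1
            continue
        result.records.append(
            DrugRecord(
                isr=isr,
                drug_seq=drug_seq,
                drugname=drugname,
                route=_text_field(fields, columns.get("ROUTE")),
                dose_vbm=_text_field(fields, columns.get("DOSE_VBM")),
            )
        )
    return result


def read_reac(path: str | Path, delimiter: str = DEFAULT_DELIMITER) -> TableReadResult:
    """Read a REAC table; PT terms are whitespace-trimmed, empty PTs are malformed."""
    lines = _read_lines(path)
    if not lines:
        raise MissingColumnError(f"{path}: empty file, no header")
    columns = _header_map(lines[0], delimiter, ("ISR", "PT"), path)
    result = TableReadResult(records=[], columns=columns)
    for line in lines[1:]:
        if not line.strip():
            continue
        result.data_lines += 1
        fields = line.split(delimiter)
        isr = _int_field(fields, columns["ISR"])
        pt_term = _text_field(fields, columns["PT"])
        if isr is None or not pt_term:
            result.malformed_count += 1
            continue
        result.records.append(ReacRecord(isr=isr, pt_term=pt_term))
    return result


def _fmt_date(fda_dt: DateTriple | None) -> str:
    if fda_dt is None:
        return ""
    y, m, d = fda_dt
    return f"{y:04d}{m:02d}{d:02d}"


def write_demo(records: Sequence[DemoRecord], path: str | Path,
               delimiter: str = DEFAULT_DELIMITER) -> None:
    _write(path, delimiter, ("ISR", "CASE", "FDA_DT"),
           ((r.isr, r.case_id, _fmt_date(r.fda_dt)) for r in records))


def write_drug(records: Sequence[DrugRecord], path: str | Path,
               delimiter: str = DEFAULT_DELIMITER) -> None:
    _write(path, delimiter, ("ISR", "DRUG_SEQ", "DRUGNAME", "ROUTE", "DOSE_VBM"),
           ((r.isr, r.drug_seq, r.drugname, r.route, r.dose_vbm) for r in records))


def write_reac(records: Sequence[ReacRecord], path: str | Path,
               delimiter: str = DEFAULT_DELIMITER) -> None:
    _write(path, delimiter, ("ISR", "PT"), ((r.isr, r.pt_term) for r in records))


def _write(path, delimiter, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n",
                            quoting=csv.QUOTE_NONE, quotechar=None)
        writer.writerow(header)
        writer.writerows(rows)
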