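"""MedDRA Preferred Term lookup and PT -> System Organ Class rollup.

MedDRA is licensed and never shipped; its content is consumed either as a
simple TSV (``pt_term  pt_code  soc_code  soc_name  primary_flag``, one
row per PT/SOC link) or, for license holders, as the MedDRA ascii
distribution files (``pt.asc`` / ``soc.asc``, "$"-delimited).

AERS REAC entries are already MedDRA PTs, so term lookup is exact after
case folding and whitespace normalization — no fuzzy matching. Each PT
rolls up to exactly one primary SOC; aggregation uses the primary link
only, so SOC-level counts partition the record set instead of
double-counting PTs linked to several SOCs.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path


class MeddraValidationError(ValueError):
    """The loaded hierarchy violates a structural invariant."""


@dataclass
class MeddraTables:
    """PT lexicon plus PT->SOC links (one primary per PT) and SOC labels."""

    pt_lexicon: dict[str, int] = field(default_factory=dict)  # normalized term -> pt_code
    pt_to_soc: dict[int, list[tuple[int, bool]]] = field(default_factory=dict)
    soc_names: dict[int, str] = field(default_factory=dict)
    pt_names: dict[int, str] = field(default_factory=dict)

    def soc_name(self, soc_code: int) -> str:
        # label falls back to the code when no name was supplied
        return self.soc_names.get(soc_code) or str(soc_code)


def _norm_term(term: str) -> str:
    return " ".join(term.casefold().split())


def _validate(tables: MeddraTables, source: str) -> MeddraTables:
    for pt_code, socs in tables.pt_to_soc.items():
        if not socs:
            raise MeddraValidationError(f"{source}: PT {pt_code} has no SOC link")
        if sum(1 for _, primary in socs if primary) != 1:
            raise MeddraValidationError(
                f"{source}: PT {pt_code} must have exactly one primary SOC")
    return tables


def load_meddra(source: str | Path) -> MeddraTables:
    """Load MedDRA content from a TSV file or an ascii distribution directory."""
    source = Path(source)
    if source.is_dir():
        return _load_ascii(source)
    return _load_tsv(source)


def _load_tsv(path: Path) -> MeddraTables:
    tables = MeddraTables()
    links: dict[int, dict[int, bool]] = defaultdict(dict)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            pt_code = int(rec["pt_code"])
            soc_code = int(rec["soc_code"])
            tables.pt_lexicon[_norm_term(rec["pt_term"])] = pt_code
            tables.pt_names.setdefault(pt_code, rec["pt_term"].strip())
            primary = str(rec.get("primary_flag", "")).strip().lower() in ("y", "1", "true")
            # duplicate (pt, soc) rows collapse; a primary flag sticks
            links[pt_code][soc_code] = links[pt_code].get(soc_code, False) or primary
            soc_name = (rec.get("soc_name") or "").strip()
            if soc_name:
                tables.soc_names[soc_code] = soc_name
    tables.pt_to_soc = {
        pt: sorted(socs.items(), key=lambda kv: (not kv[1], kv[0]))
        for pt, socs in links.items()
    }
    return _validate(tables, str(path))


def _load_ascii(directory: Path) -> MeddraTables:
    """MedDRA ascii files: pt.asc (pt_code$pt_name$..$primary_soc) + soc.asc.

    Only the primary SOC link carried by pt.asc is consumed; the
    HLGT/HLT hierarchy chain is out of scope.
    """
    tables = MeddraTables()
    soc_path = directory / "soc.asc"
    if soc_path.exists():
        for line in soc_path.read_text(encoding="utf-8").splitlines():
            f = line.split("$")
            if len(f) >= 2 and f[0].isdigit():
                tables.soc_names[int(f[0])] = f[1].strip()
    pt_path = directory / "pt.asc"
    if not pt_path.exists():
        raise FileNotFoundError(f"{directory}: pt.asc not found")
    for line in pt_path.read_text(encoding="utf-8").splitlines():
        f = line.split("$")
        if len(f) < 4 or not (f[0].isdigit() and f[3].isdigit()):
            continue
        pt_code, soc_code = int(f[0]), int(f[3])
        tables.pt_lexicon[_norm_term(f[1])] = pt_code
        tables.pt_names.setdefault(pt_code, f[1].strip())
        tables.pt_to_soc[pt_code] = [(soc_code, True)]
    return _validate(tables, str(directory))


def map_pt(term: str, tables: MeddraTables) -> int | None:
    """Exact case-folded lookup of a verbatim PT; None on a miss."""
    return tables.pt_lexicon.get(_norm_term(term))


def pt_to_soc(pt_code: int, tables: MeddraTables) -> int:
    """The primary SOC of a mapped PT code."""
    for soc_code, primary in tables.pt_to_soc[pt_code]:
        if primary:
            return soc_code
    raise MeddraValidationError(f"PT {pt_code} has no primary SOC")  # pragma: no cover
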