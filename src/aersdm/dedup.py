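"""De-duplication of AERS reports by CASE number.

Spontaneous reports arrive in versions: follow-ups to one patient case
share a CASE number but get a fresh ISR. The FDA-recommended rule keeps,
for each CASE, the report with the latest FDA_DT, breaking date ties by
the highest ISR. The retained ISR set is then propagated to the DRUG and
REAC tables so the whole corpus speaks about one version per case.

Reports with a missing or unparseable FDA_DT sort before any dated report;
if every version of a case is undated, the highest ISR wins (the rule
degrades gracefully to its own tie-breaker).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TypeVar

from .aers_io import DemoRecord

_R = TypeVar("_R")

# sorts before the smallest real (year, month, day) triple
_UNDATED = (-1, 0, 0)


@dataclass(frozen=True)
class KeepSet:
    """The retained ISRs plus which ISR was kept for each CASE."""

    retained_isrs: frozenset[int]
    provenance: dict[int, int]  # case_id -> retained isr

    def __contains__(self, isr: int) -> bool:
        return isr in self.retained_isrs


def deduplicate(demo: Iterable[DemoRecord]) -> KeepSet:
    """Select one ISR per CASE: latest FDA_DT, ties broken by highest ISR.

    Order independent; duplicate (isr, case) lines collapse. The retained
    set has exactly one member per distinct case_id.
    """
    best: dict[int, tuple[tuple, int]] = {}
    for rec in demo:
        key = (rec.fda_dt if rec.fda_dt is not None else _UNDATED, rec.isr)
        if rec.case_id not in best or key > best[rec.case_id][0]:
            best[rec.case_id] = (key, rec.isr)
    provenance = {case: isr for case, (_, isr) in best.items()}
    return KeepSet(retained_isrs=frozenset(provenance.values()), provenance=provenance)


def filter_table(records: Sequence[_R], keep: KeepSet) -> list[_R]:
    """Keep only records whose ISR was retained, preserving input order.

    Applies to any record type with an ``isr`` field (DEMO, DRUG, REAC).
    ISRs never seen in the DEMO table are dropped along with the
    superseded report versions.
    """
    return [r for r in records if r.isr in keep.retained_isrs]
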