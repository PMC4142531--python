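"""The two output tables: normalized Drug-ADE records and aggregated pairs.

A normalized Drug-ADE record is one (ISR, RxCUI, PT, SOC) co-occurrence:
for every retained report, each matched drug mention is paired with each
mapped reaction — the within-report cross product. Aggregation then
replaces the drug side with its NDF-RT class memberships on a chosen axis
and the event side with either the PT code or its primary SOC, summing
co-occurrences. The two tables connect through the RxNorm codes.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from ._util import pct
from .aers_io import ReacRecord
from .dedup import KeepSet
from .drug_normalizer import DrugMention
from .meddra_map import MeddraTables, map_pt, pt_to_soc
from .ndfrt_classify import AXES, ClassMembership

PT_LEVEL = "PT"
SOC_LEVEL = "SOC"


@dataclass(frozen=True)
class NormalizedDrugAde:
    """One drug/event co-occurrence in one retained report."""

    isr: int
    rxcui: int
    pt_code: int
    soc_code: int


@dataclass(frozen=True)
class AggregatedPair:
    """Co-occurrence count of one drug class with one adverse-event code."""

    axis: str
    class_code: str
    ade_level: str  # PT_LEVEL or SOC_LEVEL
    ade_code: int
    count: int


@dataclass
class DrugAdeBuild:
    """Built records plus counts of what contributed nothing."""

    records: list[NormalizedDrugAde]
    n_unmatched_drugs: int = 0
    n_unmapped_pts: int = 0
    n_dropped_isrs: int = 0  # rows outside the keep set

    def __iter__(self) -> Iterator[NormalizedDrugAde]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def build_drug_ade_records(drug_mentions: Iterable[DrugMention],
                           reac_records: Iterable[ReacRecord],
                           keep: KeepSet,
                           meddra: MeddraTables,
                           distinct_per_report: bool = False) -> DrugAdeBuild:
    """Cross each retained report's matched drugs with its mapped reactions.

    Occurrence pairs by default: a drug listed twice doubles its pairs.
    ``distinct_per_report`` collapses to distinct (rxcui, pt) per report
    instead. Unmatched mentions and unmapped PTs are counted, not errors.
    """
    build = DrugAdeBuild(records=[])
    drugs_by_isr: dict[int, list[int]] = defaultdict(list)
    for m in drug_mentions:
        if m.isr is None or m.isr not in keep.retained_isrs:
            build.n_dropped_isrs += 1
            continue
        if m.matched_rxcui is None:
            build.n_unmatched_drugs += 1
            continue
        drugs_by_isr[m.isr].append(m.matched_rxcui)

    reacs_by_isr: dict[int, list[int]] = defaultdict(list)
    for r in reac_records:
        if r.isr not in keep.retained_isrs:
            build.n_dropped_isrs += 1
            continue
        pt_code = map_pt(r.pt_term, meddra)
        if pt_code is None:
            build.n_unmapped_pts += 1
            continue
        reacs_by_isr[r.isr].append(pt_code)

    for isr in sorted(drugs_by_isr.keys() & reacs_by_isr.keys()):
        pairs: Iterable[tuple[int, int]] = (
            (rxcui, pt) for rxcui in drugs_by_isr[isr] for pt in reacs_by_isr[isr])
        if distinct_per_report:
            pairs = sorted(set(pairs))
        for rxcui, pt_code in pairs:
            build.records.append(NormalizedDrugAde(
                isr=isr, rxcui=rxcui, pt_code=pt_code,
                soc_code=pt_to_soc(pt_code, meddra)))
    return build


def _ade_code(record: NormalizedDrugAde, level: str) -> int:
    if level == PT_LEVEL:
        return record.pt_code
    if level == SOC_LEVEL:
        return record.soc_code
    raise ValueError(f"unknown ADE level: {level!r}")


def count_unique_pairs(records: Iterable[NormalizedDrugAde], level: str = PT_LEVEL) -> int:
    """Distinct (rxcui, ADE code) pairs at PT or SOC level."""
    return len({(r.rxcui, _ade_code(r, level)) for r in records})


def aggregate_pairs(records: Iterable[NormalizedDrugAde],
                    classifications: Mapping[int, Iterable[ClassMembership]],
                    axis: str,
                    level: str = PT_LEVEL) -> list[AggregatedPair]:
    """Class-by-ADE co-occurrence table for one axis, count-descending.

    Each record contributes once per class membership of its drug on the
    axis (a drug in two classes increments both). Ties order by
    (class_code, ade_code) for determinism.
    """
    if axis not in AXES:
        raise ValueError(f"unknown class axis: {axis!r}")
    counts: Counter[tuple[str, int]] = Counter()
    axis_classes: dict[int, list[str]] = {}
    for record in records:
        if record.rxcui not in axis_classes:
            axis_classes[record.rxcui] = sorted(
                {m.class_code for m in classifications.get(record.rxcui, ())
                 if m.axis == axis})
        code = _ade_code(record, level)
        for class_code in axis_classes[record.rxcui]:
            counts[(class_code, code)] += 1
    return [
        AggregatedPair(axis=axis, class_code=cc, ade_level=level, ade_code=ac, count=n)
        for (cc, ac), n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass(frozen=True)
class SocRow:
    soc_code: int
    soc_name: str
    n_pt_codes: int
    n_records: int
    pct: float | None  # share of all records, one decimal


def soc_distribution(records: Sequence[NormalizedDrugAde],
                     meddra: MeddraTables) -> list[SocRow]:
    """Record counts per SOC (primary rollup), largest share first.

    Because each record carries exactly one primary SOC, the n_records
    column partitions the record total.
    """
    total = len(records)
    by_soc: dict[int, int] = Counter()
    pts_by_soc: dict[int, set[int]] = defaultdict(set)
    for r in records:
        by_soc[r.soc_code] += 1
        pts_by_soc[r.soc_code].add(r.pt_code)
    rows = [
        SocRow(soc_code=soc, soc_name=meddra.soc_name(soc),
               n_pt_codes=len(pts_by_soc[soc]), n_records=n,
               pct=pct(n, total, 1))
        for soc, n in by_soc.items()
    ]
    rows.sort(key=lambda row: (-row.n_records, row.soc_code))
    return rows


@dataclass(frozen=True)
class ClassProfileRow:
    class_code: str
    class_name: str
    n_reports: int  # distinct ISRs containing >=1 drug of the class
    n_drugs: int    # distinct RxCUIs of the class present in the records


def class_profile(records: Iterable[NormalizedDrugAde],
                  classifications: Mapping[int, Iterable[ClassMembership]],
                  axis: str) -> list[ClassProfileRow]:
    """Report/drug counts per class on one axis, most-reported first."""
    if axis not in AXES:
        raise ValueError(f"unknown class axis: {axis!r}")
    reports: dict[tuple[str, str], set[int]] = defaultdict(set)
    drugs: dict[tuple[str, str], set[int]] = defaultdict(set)
    for record in records:
        for m in classifications.get(record.rxcui, ()):
            if m.axis != axis:
                continue
            key = (m.class_code, m.class_name)
            reports[key].add(record.isr)
            drugs[key].add(record.rxcui)
    rows = [
        ClassProfileRow(class_code=code, class_name=name,
                        n_reports=len(isrs), n_drugs=len(drugs[(code, name)]))
        for (code, name), isrs in reports.items()
    ]
    rows.sort(key=lambda row: (-row.n_reports, row.class_code))
    return rows
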