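"""Greedy NDF-RT classification of RxNorm concepts.

NDF-RT (the VA's National Drug File – Reference Terminology) organizes
drugs along multiple class axes — mechanism of action, physiologic effect,
therapeutic intent, chemical structure, pharmacokinetics, the legacy VA
drug classes, and others. Inside RxNorm, NDF-RT contributes ingredient and
clinical-drug concepts; a normalized AERS drug can therefore be classified
by walking RxNorm's own relations until an NDF-RT-sourced concept is
reached.

The traversal is greedy in the minimal-hop sense: if the query RxCUI is
itself NDF-RT-sourced, it anchors itself at depth 0; otherwise a
breadth-first search expands over a configurable set of
ingredient/clinical-drug relations (both edge directions), stops at the
first depth where at least one NDF-RT-sourced ingredient-like (IN/PIN) or
clinical-drug-like (SCD/SCDC) concept appears, and collects every such
concept at that depth. Minimal depth keeps anchors semantically closest to
the query; collecting all of them maximizes class recall.

Class memberships are then read off a class table — either supplied as a
TSV or extracted from NDF-RT-labelled role relations in the RRF — and
clinical-drug anchors additionally inherit the classes of their
ingredients, mirroring how NDF-RT's role relations are inherited down to
clinical drug concepts.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import pct
from .rxgraph import RxGraph, UnknownConceptError, is_ndfrt_concept

#: The nine class axes reported for AERS drug coverage.
AXES = (
    "Generic Ingredient Combinations",
    "Chemical Ingredients Class",
    "Therapeutic Intent",
    "Mechanism of Action",
    "Physiologic Effect",
    "VA Class",
    "FDA Established Pharmacologic Class",
    "Therapeutic Category",
    "Pharmacokinetics",
)

#: Relations walked by the traversal: the ingredient / clinical-drug
#: pathway of the RxNorm relation model. Both members of each inverse
#: pair are listed because traversal is direction-agnostic per edge.
DEFAULT_RELATIONS = frozenset({
    "has_ingredient", "ingredient_of",
    "has_precise_ingredient", "precise_ingredient_of",
    "tradename_of", "has_tradename",
    "consists_of", "constitutes",
    "has_form", "form_of",
    "isa",
})

#: NDF-RT role-relation labels (as they appear in RRF RELA fields) mapped
#: onto the nine axes. This default is configurable: NDF-RT hierarchy
#: names do not line up one-to-one with the axis labels used in coverage
#: reports, and distributions differ in which labels they carry.
DEFAULT_ROLE_TO_AXIS = {
    "has_ingredients": "Generic Ingredient Combinations",
    "has_chemical_structure": "Chemical Ingredients Class",
    "has_structural_class": "Chemical Ingredients Class",
    "may_treat": "Therapeutic Intent",
    "has_mechanism_of_action": "Mechanism of Action",
    "has_physiologic_effect": "Physiologic Effect",
    "has_va_class": "VA Class",
    "has_epc": "FDA Established Pharmacologic Class",
    "has_therapeutic_class": "Therapeutic Category",
    "has_pharmacokinetics": "Pharmacokinetics",
    "has_pk": "Pharmacokinetics",
}

INGREDIENT_TTYS = frozenset({"IN", "PIN"})
CLINICAL_TTYS = frozenset({"SCD", "SCDC"})
ANCHOR_TTYS = INGREDIENT_TTYS | CLINICAL_TTYS
_INHERIT_TTYS = frozenset({"SCD", "SCDC", "SBD"})
_INGREDIENT_RELAS = frozenset({"has_ingredient", "ingredient_of",
                               "has_precise_ingredient", "precise_ingredient_of"})


@dataclass(frozen=True)
class ClassMembership:
    """One (anchor concept, axis, class) row of the classification."""

    anchor_rxcui: int
    axis: str
    class_code: str
    class_name: str

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"unknown class axis: {self.axis!r}")


@dataclass(frozen=True)
class TraversalResult:
    """Anchors found for one query, the hop depth, and the labels walked."""

    query_rxcui: int
    anchors: frozenset[int]
    depth: int | None  # None when no anchor was reachable
    path_log: tuple[str, ...]


#: class table: NDF-RT-sourced rxcui -> set of (axis, class_code, class_name)
ClassTable = Mapping[int, frozenset[tuple[str, str, str]]]


def _is_anchor(graph: RxGraph, rxcui: int) -> bool:
    con = graph.concepts[rxcui]
    return (any(s.upper() == "NDFRT" for s in con.sources)
            and bool(con.term_types & ANCHOR_TTYS))


def find_ndfrt_anchors(graph: RxGraph, rxcui: int, max_depth: int = 3,
                       relations: frozenset[str] = DEFAULT_RELATIONS) -> TraversalResult:
    """Greedy minimal-hop search for NDF-RT anchor concepts.

    Raises :class:`UnknownConceptError` for an RxCUI absent from the graph
    — distinct from a present concept with no reachable anchor, which
    returns an empty anchor set.
    """
    if rxcui not in graph:
        raise UnknownConceptError(rxcui)
    if is_ndfrt_concept(graph, rxcui):
        return TraversalResult(rxcui, frozenset({rxcui}), 0, ())
    visited = {rxcui}
    frontier = [rxcui]
    walked: list[str] = []
    for depth in range(1, max_depth + 1):
        nxt: set[int] = set()
        for node in frontier:
            for rela, other in graph.neighbors(node, relations):
                if other not in visited:
                    nxt.add(other)
                    walked.append(rela)
        if not nxt:
            break
        anchors = frozenset(n for n in nxt if _is_anchor(graph, n))
        if anchors:
            return TraversalResult(rxcui, anchors, depth, tuple(sorted(set(walked))))
        visited |= nxt
        frontier = sorted(nxt)
    return TraversalResult(rxcui, frozenset(), None, tuple(sorted(set(walked))))


def classify(graph: RxGraph, anchors: Iterable[int],
             class_table: ClassTable) -> set[ClassMembership]:
    """Union of class memberships over all anchors, with inheritance.

    A clinical-drug anchor contributes its own class rows plus those of
    its immediate ingredient concepts (IN/PIN across ingredient
    relations), because NDF-RT attaches mechanism/effect/intent roles to
    ingredients and clinical drugs inherit them. Anchors with no class
    rows contribute nothing.
    """
    out: set[ClassMembership] = set()

    def add_rows(owner: int, anchor: int) -> None:
        for axis, code, name in class_table.get(owner, frozenset()):
            out.add(ClassMembership(anchor_rxcui=anchor, axis=axis,
                                    class_code=code, class_name=name))

    for anchor in anchors:
        add_rows(anchor, anchor)
        if graph.concepts[anchor].term_types & _INHERIT_TTYS:
            for rela, other in graph.neighbors(anchor, _INGREDIENT_RELAS):
                if graph.concepts[other].term_types & INGREDIENT_TTYS:
                    add_rows(other, anchor)
    return out


def classify_concept(graph: RxGraph, rxcui: int, class_table: ClassTable,
                     max_depth: int = 3,
                     relations: frozenset[str] = DEFAULT_RELATIONS) -> set[ClassMembership]:
    """Traverse then classify: the full per-concept classification step."""
    result = find_ndfrt_anchors(graph, rxcui, max_depth=max_depth, relations=relations)
    return classify(graph, result.anchors, class_table)


def load_class_table(path: str | Path) -> dict[int, frozenset[tuple[str, str, str]]]:
    """Read a class-membership TSV: ndfrt_rxcui, axis, class_code, class_name.

    A header line is required; axis labels must come from the nine-axis set.
    """
    rows: dict[int, set[tuple[str, str, str]]] = defaultdict(set)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            axis = rec["axis"].strip()
            if axis not in AXES:
                raise ValueError(f"unknown class axis in {path}: {axis!r}")
            rows[int(rec["ndfrt_rxcui"])].add(
                (axis, rec["class_code"].strip(), rec["class_name"].strip()))
    return {k: frozenset(v) for k, v in rows.items()}


def class_table_from_graph(graph: RxGraph,
                           role_to_axis: Mapping[str, str] = DEFAULT_ROLE_TO_AXIS,
                           ) -> dict[int, frozenset[tuple[str, str, str]]]:
    """Extract class rows from NDF-RT role relations embedded in the RRF.

    Each relation ``drug --role--> class-concept`` whose label appears in
    ``role_to_axis`` becomes a membership; the class concept's RxCUI is
    the class code and its first name the label.
    """
    rows: dict[int, set[tuple[str, str, str]]] = defaultdict(set)
    for rel in graph.relations:
        axis = role_to_axis.get(rel.rela)
        if axis is None:
            continue
        names = graph.concepts[rel.to_rxcui].names
        class_name = min(names) if names else str(rel.to_rxcui)
        rows[rel.from_rxcui].add((axis, str(rel.to_rxcui), class_name))
    return {k: frozenset(v) for k, v in rows.items()}


@dataclass(frozen=True)
class AxisCoverage:
    """One coverage row: how much of the classified corpus an axis covers."""

    axis: str
    n_classes: int
    n_rxcuis: int
    a_pct: float | None  # % of all classified concepts carrying this axis
    b_pct: float | None  # % of classified reports containing a drug of this axis


def coverage_report(classified: Mapping[int, Iterable[ClassMembership]],
                    reports: Iterable[tuple[int, int]] = (),
                    ) -> list[AxisCoverage]:
    """Per-axis coverage over classified concepts and (optionally) reports.

    ``classified`` maps each RxCUI to its memberships; ``reports`` is an
    iterable of (isr, rxcui) drug occurrences. Denominators are concepts
    with at least one membership on any axis, and reports containing at
    least one classified drug. Percentages are half-up integers. Rows come
    back in fixed axis order with empty axes included (n_rxcuis 0).
    """
    axis_rxcuis: dict[str, set[int]] = {axis: set() for axis in AXES}
    axis_classes: dict[str, set[str]] = {axis: set() for axis in AXES}
    any_classified: set[int] = set()
    for rxcui, memberships in classified.items():
        for m in memberships:
            axis_rxcuis[m.axis].add(rxcui)
            axis_classes[m.axis].add(m.class_code)
            any_classified.add(rxcui)

    axis_reports: dict[str, set[int]] = {axis: set() for axis in AXES}
    classified_reports: set[int] = set()
    for isr, rxcui in reports:
        if rxcui in any_classified:
            classified_reports.add(isr)
            for m in classified[rxcui]:
                axis_reports[m.axis].add(isr)

    return [
        AxisCoverage(
            axis=axis,
            n_classes=len(axis_classes[axis]),
            n_rxcuis=len(axis_rxcuis[axis]),
            a_pct=pct(len(axis_rxcuis[axis]), len(any_classified), 0),
            b_pct=pct(len(axis_reports[axis]), len(classified_reports), 0),
        )
        for axis in AXES
    ]
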