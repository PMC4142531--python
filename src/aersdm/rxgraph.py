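"""RxNorm concept graph loaded from Rich Release Format (RRF) tables.

Two pipe-delimited tables are consumed:

* ``RXNCONSO`` — one row per atom (a name of a concept in one source
  vocabulary). Atoms sharing an RxCUI are folded into one
  :class:`RxConcept` carrying the union of names, term types (TTY: IN,
  PIN, BN, SCD, SBD, SCDC, ...) and source vocabularies (SAB).
* ``RXNREL`` — typed relations between concepts. A row is stored as the
  directed edge ``RXCUI2 --RELA--> RXCUI1`` (NLM defines the relationship
  as that of the second concept to the first); a reverse index makes
  traversal direction-agnostic.

A concept "is an NDF-RT concept" when NDF-RT appears among its source
vocabularies — that membership is what anchors the drug-class traversal.
Suppressed atoms keep their concept in the graph but are excluded from the
name lexicon used for drug-string matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

NDFRT_SAB = "NDFRT"

# RXNCONSO.RRF column positions (RxNorm technical documentation)
_C_RXCUI, _C_SAB, _C_TTY, _C_STR, _C_SUPPRESS = 0, 11, 12, 14, 16
# RXNREL.RRF column positions
_R_RXCUI1, _R_RXCUI2, _R_RELA, _R_SAB = 0, 5, 7, 9


@dataclass
class RxConcept:
    """One RxNorm concept: all its names, term types and sources."""

    rxcui: int
    names: set[str] = field(default_factory=set)
    term_types: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    lexicon_names: set[str] = field(default_factory=set)  # non-suppressed atoms only


@dataclass(frozen=True)
class RxRelation:
    """Directed typed edge between two concepts (RELA label, source SAB)."""

    from_rxcui: int
    to_rxcui: int
    rela: str
    sab: str = ""


class UnknownConceptError(KeyError):
    """Query RxCUI is not present in the loaded graph."""


class RxGraph:
    """Concepts keyed by RxCUI plus forward/reverse RELA-typed adjacency."""

    def __init__(self) -> None:
        self.concepts: dict[int, RxConcept] = {}
        self.relations: set[RxRelation] = set()
        self._fwd: dict[int, set[tuple[str, int]]] = {}
        self._rev: dict[int, set[tuple[str, int]]] = {}
        self.dropped_relations = 0  # rows referencing unknown concepts or lacking RELA

    def __contains__(self, rxcui: int) -> bool:
        return rxcui in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def concept(self, rxcui: int) -> RxConcept:
        try:
            return self.concepts[rxcui]
        except KeyError:
            raise UnknownConceptError(rxcui) from None

    def add_concept(self, rxcui: int, name: str, tty: str, sab: str,
                    suppressed: bool = False) -> None:
        con = self.concepts.setdefault(rxcui, RxConcept(rxcui=rxcui))
        con.names.add(name)
        con.term_types.add(tty)
        con.sources.add(sab)
        if not suppressed:
            con.lexicon_names.add(name)

    def add_relation(self, from_rxcui: int, to_rxcui: int, rela: str, sab: str = "") -> bool:
        """Add a typed edge; returns False (and counts) if an endpoint is unknown."""
        if not rela or from_rxcui not in self.concepts or to_rxcui not in self.concepts:
            self.dropped_relations += 1
            return False
        rel = RxRelation(from_rxcui, to_rxcui, rela, sab)
        if rel not in self.relations:
            self.relations.add(rel)
            self._fwd.setdefault(from_rxcui, set()).add((rela, to_rxcui))
            self._rev.setdefault(to_rxcui, set()).add((rela, from_rxcui))
        return True

    def neighbors(self, rxcui: int, relas: frozenset[str] | set[str] | None = None,
                  ) -> set[tuple[str, int]]:
        """(rela, other) pairs reachable in either edge direction.

        ``relas`` restricts to the given labels; labels are not rewritten
        to their inverses — callers include both members of each inverse
        pair when they care about both readings.
        """
        out = self._fwd.get(rxcui, set()) | self._rev.get(rxcui, set())
        if relas is not None:
            out = {(rela, other) for rela, other in out if rela in relas}
        return out


def _split_rrf(line: str) -> list[str]:
    return line.rstrip("\n").split("|")


def load_rrf(conso_path: str | Path, rel_path: str | Path) -> RxGraph:
    """Load RXNCONSO/RXNREL-style pipe-delimited files into an :class:`RxGraph`.

    Relation rows referencing an RxCUI absent from the concept table, or
    with an empty RELA, are dropped and counted in ``dropped_relations``.
    Loading is row-order independent.
    """
    graph = RxGraph()
    with open(conso_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            f = _split_rrf(line)
            if len(f) <= _C_STR or not f[_C_RXCUI].isdigit():
                continue
            suppressed = len(f) > _C_SUPPRESS and f[_C_SUPPRESS] in ("Y", "O", "E")
            graph.add_concept(int(f[_C_RXCUI]), f[_C_STR], f[_C_TTY], f[_C_SAB], suppressed)
    with open(rel_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            f = _split_rrf(line)
            if len(f) <= _R_SAB or not (f[_R_RXCUI1].isdigit() and f[_R_RXCUI2].isdigit()):
                graph.dropped_relations += 1
                continue
            # RELA expresses the relationship of RXCUI2 to RXCUI1
            graph.add_relation(int(f[_R_RXCUI2]), int(f[_R_RXCUI1]), f[_R_RELA], f[_R_SAB])
    return graph


def is_ndfrt_concept(graph: RxGraph, rxcui: int) -> bool:
    """True iff NDF-RT is among the concept's source vocabularies."""
    return any(sab.upper() == NDFRT_SAB for sab in graph.concept(rxcui).sources)
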