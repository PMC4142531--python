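"""Deterministic synthetic fixtures: mini-RxNorm, mini-MedDRA, mini-AERS.

Real inputs to the pipeline are either huge (AERS quarterly files, RxNorm
RRF) or licensed (MedDRA). This module fabricates miniature versions of
all of them with the structure the pipeline exercises — tradename /
ingredient / clinical-drug wiring, NDF-RT source flags and multi-axial
class rows, duplicate report versions with date ties, decorated and
corrupted drug strings, a PT/SOC hierarchy — and records the ground truth
for every planted fact, so each stage's output can be checked exactly.

Everything is driven by one integer seed: the same blueprint yields
byte-identical files. Corrupted drug strings are validated at generation
time by an exhaustive prefix scan over the generated lexicon, so a string
planted as "unmatched" can never accidentally match.

The generator emulates structure, not epidemiology: drug/event
co-occurrences are uniform, so passing on fixtures demonstrates pipeline
correctness, not statistical realism of ADE frequencies.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from itertools import product
from pathlib import Path

from .aers_io import DemoRecord, DrugRecord, ReacRecord
from .drug_normalizer import norm_tokens
from .ndfrt_classify import (ANCHOR_TTYS, DEFAULT_RELATIONS, INGREDIENT_TTYS)

# worked-example concepts, always planted
KCL_INGREDIENT_RXCUI = 8591
KCL_INGREDIENT_NAME = "Potassium Chloride"
KCL_SCD_RXCUI = 198116
KCL_SCD_NAME = "Potassium Chloride 20 MEQ Extended Release Tablet"

_IN_AXES = ("Mechanism of Action", "Physiologic Effect", "Therapeutic Intent",
            "Chemical Ingredients Class", "Generic Ingredient Combinations",
            "Pharmacokinetics")
_SCD_AXES = ("VA Class", "FDA Established Pharmacologic Class", "Therapeutic Category")

_AXIS_TO_ROLE = {
    "Generic Ingredient Combinations": "has_ingredients",
    "Chemical Ingredients Class": "has_chemical_structure",
    "Therapeutic Intent": "may_treat",
    "Mechanism of Action": "has_mechanism_of_action",
    "Physiologic Effect": "has_physiologic_effect",
    "VA Class": "has_va_class",
    "FDA Established Pharmacologic Class": "has_epc",
    "Therapeutic Category": "has_therapeutic_class",
    "Pharmacokinetics": "has_pharmacokinetics",
}

_AXIS_POOL_SIZE = {
    "Generic Ingredient Combinations": 4,
    "Chemical Ingredients Class": 4,
    "Therapeutic Intent": 5,
    "Mechanism of Action": 4,
    "Physiologic Effect": 4,
    "VA Class": 5,
    "FDA Established Pharmacologic Class": 6,
    "Therapeutic Category": 4,
    "Pharmacokinetics": 2,
}

_INGREDIENT_RELAS = frozenset({"has_ingredient", "ingredient_of",
                               "has_precise_ingredient", "precise_ingredient_of"})

_DOSE_DECOR = ("", "ONE TABLET BID", "AS NEEDED", "2 TABLETS DAILY")
_ROUTE_DECOR = ("", "ORAL", "INTRAVENOUS")


@dataclass
class FixtureBlueprint:
    """All knobs of the synthetic study corpus.

    Defaults are the standing test conditions: ~200 RxNorm concepts and
    500 cases — enough to exercise tie-breaks, traversal fan-out and
    multi-axis classes while keeping a full pipeline run sub-second.
    """

    seed: int = 0
    n_ingredients: int = 40
    n_clinical_drugs: int = 80
    n_brands: int = 40
    n_branded_drugs: int = 40
    ndfrt_ingredient_fraction: float = 0.6
    ndfrt_clinical_fraction: float = 0.5
    n_cases: int = 500
    duplicate_rate: float = 0.1
    unmatched_rate: float = 0.1
    n_pts: int = 30
    n_socs: int = 6


@dataclass
class RxNormFixture:
    """Generated concept/relation content plus the planted truth."""

    conso_rows: list[tuple]            # (rxcui, name, tty, sab, suppressed)
    rel_rows: list[tuple]              # directed (from, to, rela, sab)
    class_rows: dict[int, set[tuple[str, str, str]]]
    ndfrt_rxcuis: set[int]
    tty_of: dict[int, str]             # primary term type per concept
    name_to_rxcui: dict[str, int]      # lexicon names (non-suppressed)
    drug_rxcuis: list[int]             # queryable drug concepts (not class concepts)
    anchor_truth: dict[int, tuple[int | None, frozenset[int]]]
    membership_truth: dict[int, set[tuple[str, str, str]]]
    conso_path: Path | None = None
    rel_path: Path | None = None
    class_tsv_path: Path | None = None

    def lexicon_keys(self) -> dict[tuple[str, ...], int]:
        return {norm_tokens(name): rxcui for name, rxcui in self.name_to_rxcui.items()}


@dataclass
class MeddraFixture:
    rows: list[tuple[str, int, int, str, bool]]  # term, pt, soc, soc_name, primary
    pt_of_term: dict[str, int]
    primary_soc: dict[int, int]
    path: Path | None = None


@dataclass
class AersFixture:
    demo: list[DemoRecord]
    drug: list[DrugRecord]
    reac: list[ReacRecord]
    retained_isrs: set[int]
    n_distinct_cases: int
    tie_case: tuple[int, int]                       # (case_id, expected retained isr)
    mention_truth: dict[tuple[int, int], int | None]  # (isr, drug_seq) -> rxcui
    input_truth: dict[tuple[int, int], str]
    mapped_pts: dict[int, list[int]]                # retained isr -> pt codes in row order
    planted_records: list[tuple[int, int, int, int]]  # (isr, rxcui, pt, soc) expected
    n_unique_inputs: int = 0       # over retained DRUG rows
    n_unique_matched: int = 0
    demo_path: Path | None = None
    drug_path: Path | None = None
    reac_path: Path | None = None


# ---------------------------------------------------------------------------
# RxNorm fixture


def _drug_names(n: int, prefixes: tuple[str, ...], suffixes: tuple[str, ...]) -> list[str]:
    combos = ["".join(p) for p in product(prefixes, suffixes)]
    return [combos[i] if i < len(combos) else f"{combos[i % len(combos)]}{i}"
            for i in range(n)]


def _exhaustive_anchor_search(fx: RxNormFixture, query: int,
                              max_depth: int = 3) -> tuple[int | None, frozenset[int]]:
    """Independent breadth-first search used to record the planted anchors."""
    if query in fx.ndfrt_rxcuis:
        return 0, frozenset({query})
    adj: dict[int, set[int]] = {}
    for a, b, rela, _sab in fx.rel_rows:
        if rela in DEFAULT_RELATIONS:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    visited = {query}
    frontier = {query}
    for depth in range(1, max_depth + 1):
        frontier = {n for node in frontier for n in adj.get(node, ())} - visited
        if not frontier:
            return None, frozenset()
        anchors = frozenset(
            n for n in frontier
            if n in fx.ndfrt_rxcuis and fx.tty_of.get(n) in ANCHOR_TTYS)
        if anchors:
            return depth, anchors
        visited |= frontier
    return None, frozenset()


def _planted_memberships(fx: RxNormFixture, anchors: frozenset[int]) -> set:
    """Expected classification for a set of anchors, with inheritance."""
    rows: set[tuple[str, str, str]] = set()
    for anchor in anchors:
        rows |= fx.class_rows.get(anchor, set())
        if fx.tty_of.get(anchor) in ("SCD", "SCDC", "SBD"):
            for a, b, rela, _sab in fx.rel_rows:
                if rela not in _INGREDIENT_RELAS:
                    continue
                other = b if a == anchor else (a if b == anchor else None)
                if other is not None and fx.tty_of.get(other) in INGREDIENT_TTYS:
                    rows |= fx.class_rows.get(other, set())
    return rows


def generate_rxnorm_fixture(blueprint: FixtureBlueprint,
                            out_dir: str | Path | None = None) -> RxNormFixture:
    """Build (and optionally write) the mini-RxNorm RRF pair and class TSV."""
    rng = random.Random(blueprint.seed * 1_000_003 + 11)
    fx = RxNormFixture(conso_rows=[], rel_rows=[], class_rows={}, ndfrt_rxcuis=set(),
                       tty_of={}, name_to_rxcui={}, drug_rxcuis=[],
                       anchor_truth={}, membership_truth={})
    next_rxcui = [1000]

    def new_concept(name: str, tty: str, ndfrt: bool, rxcui: int | None = None,
                    queryable: bool = True) -> int:
        if rxcui is None:
            rxcui = next_rxcui[0]
            next_rxcui[0] += 1
        fx.conso_rows.append((rxcui, name, tty, "RXNORM", False))
        if ndfrt:
            fx.conso_rows.append((rxcui, name, tty, "NDFRT", False))
            fx.ndfrt_rxcuis.add(rxcui)
        fx.tty_of[rxcui] = tty
        fx.name_to_rxcui[name] = rxcui
        if queryable:
            fx.drug_rxcuis.append(rxcui)
        return rxcui

    # class axis pools: numeric class concepts in their own rxcui range
    class_pool: dict[str, list[tuple[str, str]]] = {}
    class_rxcui = 900_000
    for axis, pool_size in _AXIS_POOL_SIZE.items():
        pool = []
        for k in range(pool_size):
            name = f"{axis} class {k + 1}"
            fx.conso_rows.append((class_rxcui, name, "FN", "NDFRT", False))
            fx.ndfrt_rxcuis.add(class_rxcui)
            fx.tty_of[class_rxcui] = "FN"
            pool.append((str(class_rxcui), name))
            class_rxcui += 1
        class_pool[axis] = pool

    def assign_classes(rxcui: int, axes: tuple[str, ...], n_axes: int) -> None:
        rows = set()
        for axis in rng.sample(axes, min(n_axes, len(axes))):
            code, name = rng.choice(class_pool[axis])
            rows.add((axis, code, name))
        fx.class_rows[rxcui] = rows

    # ingredients
    in_names = _drug_names(blueprint.n_ingredients,
                           ("Alfa", "Beta", "Cori", "Dexa", "Enzo", "Fluro", "Gami",
                            "Halo", "Ivo", "Juno", "Keto", "Lami", "Mino", "Novo",
                            "Oxi", "Pari", "Quino", "Rilo", "Sulfa", "Tervo"),
                           ("micin", "pril", "olol", "statin", "zole",
                            "mab", "cillin", "dryl", "phene", "caine"))
    ingredients = []
    for i, name in enumerate(in_names):
        ndfrt = rng.random() < blueprint.ndfrt_ingredient_fraction or i == 0
        ingredients.append(new_concept(name, "IN", ndfrt))
    # worked-example ingredient, always NDF-RT sourced
    kcl_in = new_concept(KCL_INGREDIENT_NAME, "IN", True, rxcui=KCL_INGREDIENT_RXCUI)
    ingredients.append(kcl_in)
    for rxcui in ingredients:
        if rxcui in fx.ndfrt_rxcuis:
            assign_classes(rxcui, _IN_AXES, rng.randint(2, 4))

    # precise ingredients for every 4th ingredient: salt form of the base
    pins: dict[int, int] = {}
    for i, base in enumerate(ingredients[:blueprint.n_ingredients]):
        if i % 4 == 0:
            base_name = next(n for n, r in fx.name_to_rxcui.items() if r == base)
            pin = new_concept(f"{base_name} Hydrochloride", "PIN", False)
            fx.rel_rows.append((pin, base, "precise_ingredient_of", "RXNORM"))
            pins[base] = pin

    # clinical drugs: ingredient + dose + form
    # the worked-example ingredient gets no generated clinical drugs, so the
    # planted 20 MEQ concept stays the unique potassium-chloride clinical drug
    scd_bases = ingredients[:blueprint.n_ingredients]
    doses = (10, 25, 50, 100, 250)
    scds = []
    for i in range(blueprint.n_clinical_drugs):
        base = scd_bases[i % len(scd_bases)]
        dose = doses[(i // len(scd_bases)) % len(doses)]
        base_name = next(n for n, r in fx.name_to_rxcui.items() if r == base)
        ndfrt = rng.random() < blueprint.ndfrt_clinical_fraction
        scd = new_concept(f"{base_name} {dose} MG Oral Tablet", "SCD", ndfrt)
        fx.rel_rows.append((scd, base, "has_ingredient", "RXNORM"))
        if base in pins:
            fx.rel_rows.append((scd, pins[base], "has_precise_ingredient", "RXNORM"))
        if ndfrt:
            assign_classes(scd, _SCD_AXES, rng.randint(1, 3))
        scds.append(scd)
    kcl_scd = new_concept(KCL_SCD_NAME, "SCD", False, rxcui=KCL_SCD_RXCUI)
    fx.rel_rows.append((kcl_scd, kcl_in, "has_ingredient", "RXNORM"))
    scds.append(kcl_scd)

    # brand names over ingredients, branded drugs over clinical drugs
    bn_names = _drug_names(blueprint.n_brands,
                           ("Vel", "Zor", "Axi", "Lum", "Pax", "Nev", "Tor", "Quil"),
                           ("tra", "dex", "vio", "max", "lin"))
    brands = []
    for j, name in enumerate(bn_names):
        bn = new_concept(name, "BN", False)
        fx.rel_rows.append((bn, ingredients[j % len(ingredients)], "tradename_of", "RXNORM"))
        brands.append(bn)
    for j in range(blueprint.n_branded_drugs):
        scd = scds[j % len(scds)]
        brand_name = bn_names[j % len(bn_names)]
        scd_name = next(n for n, r in fx.name_to_rxcui.items() if r == scd)
        dose_form = scd_name.split(" ", 1)[1] if " " in scd_name else "Oral Tablet"
        sbd = new_concept(f"{brand_name} {dose_form}"
                          if j < len(bn_names) else f"{brand_name} {dose_form} {j}",
                          "SBD", False)
        fx.rel_rows.append((sbd, scd, "tradename_of", "RXNORM"))

    # a suppressed alias exercises lexicon exclusion without losing the name
    first_in = ingredients[0]
    first_name = next(n for n, r in fx.name_to_rxcui.items() if r == first_in)
    fx.conso_rows.append((first_in, f"{first_name} (obsolete)", "SY", "RXNORM", True))

    # NDF-RT class memberships embedded as role relations (drug -> class concept)
    for rxcui, rows in fx.class_rows.items():
        for axis, code, _name in rows:
            fx.rel_rows.append((rxcui, int(code), _AXIS_TO_ROLE[axis], "NDFRT"))

    # planted traversal + classification truth via the generator's own BFS
    for rxcui in fx.drug_rxcuis:
        depth, anchors = _exhaustive_anchor_search(fx, rxcui)
        fx.anchor_truth[rxcui] = (depth, anchors)
        fx.membership_truth[rxcui] = _planted_memberships(fx, anchors)

    if out_dir is not None:
        write_rxnorm_fixture(fx, out_dir)
    return fx


def write_rxnorm_fixture(fx: RxNormFixture, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx.conso_path = out_dir / "RXNCONSO.RRF"
    fx.rel_path = out_dir / "RXNREL.RRF"
    fx.class_tsv_path = out_dir / "ndfrt_classes.tsv"
    with open(fx.conso_path, "w", encoding="utf-8") as fh:
        for i, (rxcui, name, tty, sab, suppressed) in enumerate(fx.conso_rows):
            f = [""] * 18
            f[0], f[1], f[7] = str(rxcui), "ENG", str(i + 1)
            f[11], f[12], f[14] = sab, tty, name
            f[16] = "Y" if suppressed else "N"
            fh.write("|".join(f) + "\n")
    with open(fx.rel_path, "w", encoding="utf-8") as fh:
        # loader reads an edge as RXCUI2 --RELA--> RXCUI1
        for a, b, rela, sab in fx.rel_rows:
            f = [""] * 16
            f[0], f[2], f[4], f[5] = str(b), "CUI", "CUI", str(a)
            f[7], f[9] = rela, sab
            fh.write("|".join(f) + "\n")
    with open(fx.class_tsv_path, "w", encoding="utf-8") as fh:
        fh.write("ndfrt_rxcui\taxis\tclass_code\tclass_name\n")
        for rxcui in sorted(fx.class_rows):
            for axis, code, name in sorted(fx.class_rows[rxcui]):
                fh.write(f"{rxcui}\t{axis}\t{code}\t{name}\n")


# ---------------------------------------------------------------------------
# MedDRA fixture


def generate_meddra_fixture(blueprint: FixtureBlueprint,
                            out_dir: str | Path | None = None) -> MeddraFixture:
    """PT/SOC table with one primary SOC per PT and some secondary links."""
    rng = random.Random(blueprint.seed * 1_000_003 + 29)
    socs = [(10_005_000 + j, f"System organ class {j + 1}")
            for j in range(blueprint.n_socs)]
    rows: list[tuple[str, int, int, str, bool]] = []
    pt_of_term: dict[str, int] = {}
    primary_soc: dict[int, int] = {}
    for i in range(blueprint.n_pts):
        pt_code = 10_100_000 + i
        term = f"Adverse reaction {i + 1:03d}"
        soc_code, soc_name = socs[i % len(socs)]  # round-robin: >=3 PTs per SOC
        rows.append((term, pt_code, soc_code, soc_name, True))
        pt_of_term[term] = pt_code
        primary_soc[pt_code] = soc_code
        if i % 5 == 0:  # secondary link exercises primary-only rollup
            sec_code, sec_name = socs[(i + 1) % len(socs)]
            rows.append((term, pt_code, sec_code, sec_name, False))
    rng.shuffle(rows)
    fx = MeddraFixture(rows=rows, pt_of_term=pt_of_term, primary_soc=primary_soc)
    if out_dir is not None:
        write_meddra_fixture(fx, out_dir)
    return fx


def write_meddra_fixture(fx: MeddraFixture, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx.path = out_dir / "meddra.tsv"
    with open(fx.path, "w", encoding="utf-8") as fh:
        fh.write("pt_term\tpt_code\tsoc_code\tsoc_name\tprimary_flag\n")
        for term, pt, soc, soc_name, primary in fx.rows:
            fh.write(f"{term}\t{pt}\t{soc}\t{soc_name}\t{'Y' if primary else 'N'}\n")


# ---------------------------------------------------------------------------
# AERS fixture


def _corrupt(name: str, rng: random.Random, mode: str, salt: int) -> str:
    if mode == "foreign":
        return f"ZUVREXOL{salt}"
    # typo: damage the head token so no prefix can anchor
    head, _, rest = name.partition(" ")
    chars = list(head)
    pos = rng.randrange(len(chars))
    chars[pos] = "x" if chars[pos] != "x" else "q"
    chars.insert(pos, "z")
    damaged = "".join(chars)
    return f"{damaged} {rest}".strip()


def _scan_match(tokens: tuple[str, ...],
                entries: list[tuple[tuple[str, ...], int, str, str]]) -> int | None:
    """Exhaustive generation-time scan mirroring the documented match rule.

    ``entries`` rows are (normalized key, rxcui, tty, name). A verbatim
    key wins outright; otherwise longest common prefix, ties by term-type
    priority then lowest rxcui. Independent of the matcher's index
    structures so planted truths double as an oracle.
    """
    from .drug_normalizer import TTY_PRIORITY
    best: tuple | None = None
    for key, rxcui, tty, name in entries:
        if key == tokens:
            return rxcui
        k = 0
        for a, b in zip(tokens, key):
            if a != b:
                break
            k += 1
        if k == 0:
            continue
        rank = (-k, TTY_PRIORITY.get(tty, len(TTY_PRIORITY)), rxcui, name)
        if best is None or rank < best[0]:
            best = (rank, rxcui)
    return best[1] if best is not None else None


def generate_aers_fixture(blueprint: FixtureBlueprint,
                          rxnorm: RxNormFixture,
                          meddra: MeddraFixture,
                          out_dir: str | Path | None = None) -> AersFixture:
    """DEMO/DRUG/REAC tables with planted duplicates, ties and corruptions.

    Every drug string's fate (its RxCUI or "unmatched") is verified at
    generation time by an exhaustive longest-prefix scan over the
    generated lexicon, and recorded; the expected de-duplicated Drug-ADE
    record list is derived from that bookkeeping.
    """
    rng = random.Random(blueprint.seed * 1_000_003 + 47)
    entries = [(norm_tokens(name), rxcui, rxnorm.tty_of[rxcui], name)
               for name, rxcui in sorted(rxnorm.name_to_rxcui.items())]
    lexicon_names = sorted(rxnorm.name_to_rxcui)
    pt_terms = sorted(meddra.pt_of_term)

    fx = AersFixture(demo=[], drug=[], reac=[], retained_isrs=set(),
                     n_distinct_cases=blueprint.n_cases, tie_case=(0, 0),
                     mention_truth={}, input_truth={}, mapped_pts={},
                     planted_records=[])
    next_isr = [4_000_000]

    def fresh_isr() -> int:
        next_isr[0] += rng.randint(1, 7)
        return next_isr[0]

    foreign_salt = [0]
    undated_allowed = blueprint.n_cases > 1  # a 1-case corpus stays dated

    for case_idx in range(blueprint.n_cases):
        case_id = 5_000_000 + case_idx
        n_versions = 1
        if rng.random() < blueprint.duplicate_rate:
            n_versions = 3 if rng.random() < 0.25 else 2
        if case_idx == 0:
            n_versions = max(n_versions, 2)
        base_date = (rng.randint(2004, 2011), rng.randint(1, 12), rng.randint(1, 28))
        dates: list[tuple[int, int, int] | None] = [base_date]
        for _ in range(n_versions - 1):
            roll = rng.random()
            if case_idx == 0 or roll < 0.3:
                dates.append(base_date)  # exact-date tie -> ISR tie-break
            elif roll < 0.35 and undated_allowed:
                dates.append(None)       # missing FDA_DT, sorts below any date
            else:
                dates.append((base_date[0], base_date[1],
                              min(28, base_date[2] + rng.randint(1, 10))))
        isrs = sorted(fresh_isr() for _ in range(n_versions))
        rng.shuffle(dates)  # higher ISR is not always the later version

        def sort_key(pair: tuple[int, tuple | None]) -> tuple:
            isr, date = pair
            return (date if date is not None else (-1, 0, 0), isr)

        retained = max(zip(isrs, dates), key=sort_key)[0]
        fx.retained_isrs.add(retained)
        if case_idx == 0:
            fx.tie_case = (case_id, retained)

        for isr, date in zip(isrs, dates):
            fx.demo.append(DemoRecord(isr=isr, case_id=case_id, fda_dt=date))
            # drug rows
            for seq in range(1, rng.randint(1, 3) + 1):
                dose_vbm = rng.choice(_DOSE_DECOR)
                route = rng.choice(_ROUTE_DECOR)
                if rng.random() < blueprint.unmatched_rate:
                    mode = rng.choice(("typo", "foreign"))
                    for _attempt in range(20):
                        foreign_salt[0] += 1
                        drugname = _corrupt(rng.choice(lexicon_names).upper(),
                                            rng, mode, foreign_salt[0])
                        parts = [p for p in (drugname, dose_vbm, route) if p.strip()]
                        text = " ".join(" ".join(p.split()) for p in parts)
                        if _scan_match(norm_tokens(text), entries) is None:
                            break
                    else:  # pragma: no cover - corruption never this sticky
                        raise RuntimeError("could not build an unmatched string")
                    truth = None
                else:
                    name = rng.choice(lexicon_names)
                    drugname = name.upper()
                    parts = [p for p in (drugname, dose_vbm, route) if p.strip()]
                    text = " ".join(" ".join(p.split()) for p in parts)
                    truth = _scan_match(norm_tokens(text), entries)
                    assert truth is not None  # head token is a lexicon name head
                fx.drug.append(DrugRecord(isr=isr, drug_seq=seq, drugname=drugname,
                                          route=route, dose_vbm=dose_vbm))
                fx.mention_truth[(isr, seq)] = truth
                fx.input_truth[(isr, seq)] = text
            # reaction rows
            mapped: list[int] = []
            for _ in range(rng.randint(1, 3)):
                if rng.random() < 0.05:
                    fx.reac.append(ReacRecord(isr=isr, pt_term="Unlisted event XQ"))
                    continue
                term = rng.choice(pt_terms)
                written = term.upper() if rng.random() < 0.3 else term
                fx.reac.append(ReacRecord(isr=isr, pt_term=written))
                mapped.append(meddra.pt_of_term[term])
            if isr == retained:
                fx.mapped_pts[isr] = mapped

    # expected de-duplicated Drug-ADE records: within-report cross product
    for isr in sorted(fx.retained_isrs):
        drugs = [fx.mention_truth[(i, s)] for (i, s) in sorted(fx.mention_truth)
                 if i == isr and fx.mention_truth[(i, s)] is not None]
        for rxcui in drugs:
            for pt in fx.mapped_pts.get(isr, ()):
                fx.planted_records.append((isr, rxcui, pt, meddra.primary_soc[pt]))

    retained_inputs = {fx.input_truth[(i, s)] for (i, s) in fx.input_truth
                       if i in fx.retained_isrs}
    fx.n_unique_inputs = len(retained_inputs)
    fx.n_unique_matched = len({fx.input_truth[(i, s)] for (i, s) in fx.input_truth
                               if i in fx.retained_isrs
                               and fx.mention_truth[(i, s)] is not None})

    if out_dir is not None:
        write_aers_fixture(fx, out_dir)
    return fx


def write_aers_fixture(fx: AersFixture, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx.demo_path = out_dir / "DEMO.txt"
    fx.drug_path = out_dir / "DRUG.txt"
    fx.reac_path = out_dir / "REAC.txt"
    with open(fx.demo_path, "w", encoding="utf-8") as fh:
        fh.write("ISR$CASE$FDA_DT\n")
        for r in fx.demo:
            date = "" if r.fda_dt is None else "{:04d}{:02d}{:02d}".format(*r.fda_dt)
            fh.write(f"{r.isr}${r.case_id}${date}\n")
    with open(fx.drug_path, "w", encoding="utf-8") as fh:
        fh.write("ISR$DRUG_SEQ$DRUGNAME$ROUTE$DOSE_VBM\n")
        for r in fx.drug:
            fh.write(f"{r.isr}${r.drug_seq}${r.drugname}${r.route}${r.dose_vbm}\n")
    with open(fx.reac_path, "w", encoding="utf-8") as fh:
        fh.write("ISR$PT\n")
        for r in fx.reac:
            fh.write(f"{r.isr}${r.pt_term}\n")


# ---------------------------------------------------------------------------
# convenience: the whole corpus in one call


@dataclass
class FixtureSet:
    blueprint: FixtureBlueprint
    rxnorm: RxNormFixture
    meddra: MeddraFixture
    aers: AersFixture


def generate_fixture_set(blueprint: FixtureBlueprint,
                         out_dir: str | Path | None = None) -> FixtureSet:
    """Generate all three fixtures (and their files when ``out_dir`` given)."""
    rxnorm = generate_rxnorm_fixture(blueprint, out_dir)
    meddra = generate_meddra_fixture(blueprint, out_dir)
    aers = generate_aers_fixture(blueprint, rxnorm, meddra, out_dir)
    if out_dir is not None:
        blueprint_path = Path(out_dir) / "blueprint.json"
        summary = {
            "seed": blueprint.seed,
            "n_cases": blueprint.n_cases,
            "duplicate_rate": blueprint.duplicate_rate,
            "unmatched_rate": blueprint.unmatched_rate,
            "retained_isrs": sorted(aers.retained_isrs),
            "n_distinct_cases": aers.n_distinct_cases,
            "n_planted_records": len(aers.planted_records),
            "n_unique_inputs": aers.n_unique_inputs,
            "n_unique_matched": aers.n_unique_matched,
            "mention_truth": {f"{isr}:{seq}": rxcui
                              for (isr, seq), rxcui in sorted(aers.mention_truth.items())},
        }
        blueprint_path.write_text(json.dumps(summary, indent=1), encoding="utf-8")
    return FixtureSet(blueprint=blueprint, rxnorm=rxnorm, meddra=meddra, aers=aers)
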