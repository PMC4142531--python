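# Methods

This note documents the models and procedural choices behind `aersdm`: how
raw spontaneous-report data are turned into normalized and aggregated
Drug-ADE tables, which knobs matter, and what the synthetic test corpus
does and does not demonstrate.

## Input model

Three AERS tables are consumed, as "$"-delimited flat files with one
header line: DEMO (one row per submitted report version: ISR, CASE,
FDA_DT), DRUG (verbatim DRUGNAME/ROUTE/DOSE_VBM per drug mention, keyed by
ISR and DRUG_SEQ) and REAC (one MedDRA Preferred Term per reported event).
The delimiter is configurable per file; decoding tries UTF-8 and falls
back to Latin-1, because legacy AERS files are not UTF-8 clean. Parsing is
line-level so that malformed rows are counted rather than silently
dropped: for every file, `records + malformed = data_lines`. ISR and CASE
are stored as integers (leading zeros are not semantic); FDA_DT is kept as
a (year, month, day) triple whose lexicographic order matches YYYYMMDD
string order, with missing/invalid dates flagged as absent but the record
retained.

## De-duplication

Follow-up reports share a CASE number; the retention rule keeps, per CASE,
the report with the latest FDA_DT and breaks date ties by the highest ISR.
Two decisions the rule itself does not settle:

* A report with a missing date never beats a dated report; if every
  version of a case is undated, the highest ISR wins. This lets the rule
  degrade gracefully to its own tie-breaker.
* The keep-set is defined solely on DEMO. DRUG/REAC rows whose ISR never
  appears in DEMO are dropped by the propagation filter along with
  superseded versions.

The operation is idempotent, order-independent and retains exactly one ISR
per distinct CASE; those properties are tested under randomized inputs.

## Drug normalization

For each DRUG row one input string is built: `DRUGNAME`, `DOSE_VBM`,
`ROUTE`, joined in that order with single spaces, empty fields skipped,
internal whitespace collapsed. The dose and route text frequently carry
the dose-form words that distinguish a clinical drug from its bare
ingredient, which is why they are appended rather than discarded.

Matching is a transparent lexicon matcher over the non-suppressed concept
names in the RxNorm RRF. Both sides are case-folded,
punctuation-stripped and tokenized. Ranking:

1. An input equal to a lexicon entry verbatim maps to that entry.
2. Otherwise each entry sharing the input's head token is scored by the
   length of the common token prefix (the match is anchored at token 0 on
   both sides); the longest wins.
3. Ties break by term-type priority — SCD, SCDC, SBD, BN, PIN, IN — then
   lowest RxCUI, then name. The priority prefers the most specific
   concept, which is what lets a concatenated string whose dose tokens
   appear out of order relative to the concept name still reach the
   clinical drug instead of stopping at the ingredient.

Head anchoring is deliberate: unanchored substring matching maps
parenthesized salt names ("... (CARBAZOCROME SODIUM SULFONATE)") to
unrelated ingredient concepts, a documented failure mode of partial-name
matching. The matcher is deterministic by construction (ties cannot
survive rule 3), monotone under lexicon growth (adding entries can never
unmatch a matched string), and exact-name complete (every lexicon name fed
verbatim maps to its own concept). "Unmatched" is a value, not an error;
no fuzzy matching or spelling correction is attempted.

Externally produced normalizations (e.g. MedEx output) can be ingested as
a two-column TSV; RxCUIs absent from the loaded graph are demoted to
unmatched with a warning count. The headline statistic is the fraction of
unique input strings matched, reported as a half-up integer percent.

## The RxNorm graph and NDF-RT classification

Only RXNCONSO and RXNREL are required. Atoms sharing an RxCUI fold into
one concept carrying the union of names, term types and source
vocabularies; suppressed atoms stay in the graph but are excluded from the
matcher lexicon. Relation rows are stored as directed RELA-labelled edges
(RXCUI2 → RXCUI1, the documented reading of the relationship direction)
with a reverse index, so traversal is direction-agnostic; rows with an
empty RELA or an endpoint missing from the concept table are dropped and
counted. A concept "is NDF-RT" when NDF-RT appears among its source
vocabularies (matched case-insensitively).

Classification is a greedy minimal-hop search. A query that is itself
NDF-RT-sourced anchors itself at depth 0. Otherwise breadth-first
expansion proceeds over a configurable relation set — by default the
ingredient / clinical-drug pathway: `has_ingredient`/`ingredient_of`,
`has_precise_ingredient`/`precise_ingredient_of`,
`tradename_of`/`has_tradename`, `consists_of`/`constitutes`,
`has_form`/`form_of`, `isa` — and stops at the first depth (default cap 3)
where at least one NDF-RT-sourced concept with an ingredient-like (IN,
PIN) or clinical-drug-like (SCD, SCDC) term type appears. All such
concepts at that depth are collected: minimal depth keeps anchors
semantically closest to the query, collect-all maximizes class recall. A
visited set makes the search cycle-safe; an RxCUI absent from the graph is
an error distinct from "no anchor reachable".

Class memberships are read from a class table mapping NDF-RT concepts to
(axis, class code, class name) rows on nine axes: Generic Ingredient
Combinations, Chemical Ingredients Class, Therapeutic Intent, Mechanism of
Action, Physiologic Effect, VA Class, FDA Established Pharmacologic Class,
Therapeutic Category, Pharmacokinetics. The table comes either from a
user TSV or from NDF-RT role relations embedded in the RRF
(`has_mechanism_of_action`, `has_physiologic_effect`, `may_treat`,
`has_va_class`, ...), via a configurable label→axis dictionary — the
mapping between role labels and the nine reporting axes is a convention of
this package, not something the terminologies define uniquely. Because
NDF-RT attaches mechanism/effect/intent roles to ingredients and clinical
drugs inherit them, a clinical-drug anchor also contributes the class rows
of its immediate ingredient concepts.

Coverage reporting computes, per axis, the number of classified concepts
and two percentages: share of all classified concepts (a%) and share of
reports containing at least one drug classified on that axis, over reports
containing at least one classified drug (b%). The b% denominator uses
classified reports rather than all retained reports — the narrower, more
interpretable base.

## MedDRA rollup

REAC entries are already MedDRA PTs, so term lookup is exact after case
folding and whitespace normalization; fuzzy matching would add risk
without recall. Each PT must carry exactly one primary SOC (validated
fatally at load). Aggregation uses the primary SOC only, so SOC-level
record counts partition the record total instead of double-counting
multi-SOC terms. Content is consumed as a TSV
(`pt_term, pt_code, soc_code, soc_name, primary_flag`) or, for license
holders, from `pt.asc`/`soc.asc` of the ascii distribution (where only the
primary SOC field is used; secondary links via the HLGT/HLT chain are out
of scope).

## The two output tables

A normalized Drug-ADE record is one (ISR, RxCUI, PT, SOC) occurrence pair:
within each retained report, matched drug mentions are crossed with mapped
reactions. The cross product is the definition of a co-occurrence here —
occurrence pairs by default, with a flag to collapse to distinct pairs per
report. Unmatched drugs and unmapped PTs contribute nothing and are
counted. Aggregation replaces the drug side with its class memberships on
one axis (a drug in two classes increments both; a class reached through
two anchors still counts once per record) and the event side with the PT
or primary-SOC code, and orders pairs by descending count with
deterministic tie order. SOC distributions and per-class report/drug
profiles come from the same record list.

Percentages are printed half-up — integer for coverage columns, one
decimal for distribution and evaluation outputs — with all internal
arithmetic at full precision; F-measure is computed from unrounded P and
R. An undefined metric (zero denominator) raises rather than reporting 0,
except F at P = R = 0, which is 0 by convention.

Evaluation against a gold annotation scores unique input strings: a
prediction agreeing with the gold code is a TP; a differing code is one FP
plus one FN (the gold string was not recovered); a prediction where the
annotators said "no code" is an FP; a gold-coded string left unmatched is
an FN.

## Synthetic fixtures

The generator fabricates all three inputs from one seed, byte-identically
across runs. Defaults — about 200 RxNorm concepts (40 ingredients, 80
clinical drugs, 40 brands, 40 branded drugs, plus the planted
potassium-chloride pair), 500 cases, 10% duplicate rate, 10% unmatched
rate, 30 PTs over 6 SOCs — are large enough to exercise date ties,
traversal fan-out and multi-axis classes while keeping a full pipeline run
sub-second. Structure planted on purpose:

* tradename/ingredient/clinical-drug wiring mirroring the RxNorm relation
  model, with NDF-RT source flags on a fraction of ingredients (60%) and
  clinical drugs (50%) and class rows across all nine axes, emitted both
  as a TSV and as role relations in the RRF;
* duplicate report versions including exact-date ties and occasional
  missing dates, with the expected survivor recorded per case;
* drug strings decorated with route/dose text, and a controlled fraction
  corrupted by head-token typos or foreign-brand-style renames — each
  corruption is verified unmatched by an exhaustive prefix scan over the
  generated lexicon at generation time, so planted fates are never
  accidental;
* a PT/SOC table with one primary SOC per PT and secondary links to
  exercise primary-only rollup.

Every planted fact (per-mention RxCUI, retained ISRs, anchor sets, class
memberships, the full expected Drug-ADE record list) is recorded in the
blueprint, so tests compare pipeline output to ground truth exactly. The
corpus emulates structure, not epidemiology: event frequencies are
uniform, names are synthetic, and MedDRA content is invented. Passing on
fixtures therefore demonstrates correctness of the mechanics, not
real-data match rates or class coverage.

## Problem sizes used in checks

The traversal property suite compares the greedy search against an
exhaustive breadth-first oracle on 50 random typed graphs of 30–150 nodes
(plus 12 more up to 200 nodes in the unit suite), covering every node as a
query. End-to-end recovery runs the full pipeline on 150-case corpora with
duplicate and unmatched rates swept over {0, 0.1, 0.3}². The published
full-corpus statistics (millions of reports) require the licensed and
archival source releases and are out of scope; the published worked
examples are reproduced exactly.

## Known limitations

* The matcher resolves only what head-anchored lexicon matching can:
  foreign brand names, misspellings and unspecified names ("BLINDED
  PLACEBO") stay unmatched by design.
* The NDF-RT role→axis dictionary is a documented default, configurable
  because distributions differ in the role labels they carry.
* MedDRA multi-SOC fan-out is intentionally not performed; analyses that
  need secondary SOC links must extend the rollup.
* Only DEMO/DRUG/REAC are parsed; the other AERS tables (OUTC, RPSR,
  THER, INDI) are not consumed.
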