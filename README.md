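# aersdm

Tools for standardizing spontaneous adverse-drug-event reports from the FDA
Adverse Event Reporting System (AERS/FAERS) into an analysis-ready,
ontology-linked data set.

Raw AERS quarterly files are hard to mine: one patient case appears as
several report versions, drug names are free text ("trade names,
abbreviations, and even typographical errors"), and adverse events are
MedDRA Preferred Terms (PTs) with no grouping. `aersdm` turns this into two
flat tables — normalized Drug-ADE records and aggregated class-by-event
co-occurrence counts — by:

1. **De-duplication** — for each CASE keep the report with the latest
   FDA_DT, breaking date ties by the highest ISR, and propagate the kept
   ISRs to the DRUG and REAC tables.
2. **Drug normalization** — concatenate `DRUGNAME + DOSE_VBM + ROUTE`,
   and map the string to an RxNorm concept (RxCUI) with a deterministic,
   head-anchored lexicon matcher built from the RxNorm RRF files (or
   ingest the output of an external medication-extraction tool such as
   MedEx).
3. **Drug classification** — greedy minimal-hop traversal of RxNorm
   relations (`has_ingredient`, `tradename_of`, `consists_of`, ...) from
   each RxCUI to NDF-RT-sourced ingredient / clinical-drug anchors, then
   extraction of multi-axial class memberships (mechanism of action,
   physiologic effect, therapeutic intent, VA class, pharmacokinetics, ...).
4. **Event aggregation** — map verbatim PTs to MedDRA PT codes and roll
   each PT up to its primary System Organ Class (SOC).
5. **Evaluation** — precision / recall / F-measure of normalizations
   against a gold annotation: `P = TP/(TP+FP)`, `R = TP/(TP+FN)`,
   `F = 2PR/(P+R)`.

MedDRA is licensed and is never shipped; it is consumed as a simple TSV or
as the licensed ascii distribution. A seeded synthetic-fixture generator
(`aersdm.fixtures`) fabricates miniature RxNorm/MedDRA/AERS inputs with
recorded ground truth, so the whole pipeline is testable offline.

## Worked example

Generate a synthetic corpus (200 cases) and run the full pipeline from the
shell:

```sh
aersdm fixtures  --seed 42 --out-dir fx --n-cases 200
aersdm dedup     --demo fx/DEMO.txt --drug fx/DRUG.txt --reac fx/REAC.txt --out-dir dd
aersdm normalize --drug-table dd/DRUG.txt --rrf-dir fx --out mentions.tsv
aersdm build-records --demo fx/DEMO.txt --reac fx/REAC.txt \
    --mentions mentions.tsv --meddra fx/meddra.tsv --out records.tsv
aersdm classify  --rrf-dir fx --class-table fx/ndfrt_classes.tsv \
    --rxcuis "$(cut -f2 records.tsv | tail -n +2 | sort -u | paste -sd, -)" \
    --out classes.tsv
aersdm aggregate --records records.tsv --classes classes.tsv \
    --axis "Therapeutic Category" --level PT --out pairs.tsv
```

which prints, stage by stage:

```
{"input_reports": 233, "retained_reports": 200, "distinct_cases": 200}
{"unique_inputs": 380, "unique_matched": 332, "unique_rxcuis": 131, "pct_matched": 87.0}
{"records": 650, "unmatched_drugs": 48, "unmapped_pts": 24}
classified 130 concepts -> 418 membership rows
{"total_records": 650, "unique_pairs_pt": 584, "unique_pairs_soc": 409}
```

Reading: 233 report versions collapse to 200 (one per case); 332 of 380
unique drug strings (87%) normalize to 131 RxNorm concepts; crossing each
retained report's matched drugs with its mapped reactions yields 650
normalized Drug-ADE records, 584 distinct (drug, PT) pairs and 409
distinct (drug, SOC) pairs; `pairs.tsv` then holds the per-class
co-occurrence counts on the chosen axis, largest first.

The same steps are available as library calls (`deduplicate`,
`build_lexicon`, `normalize_drug_records`, `classify_concept`,
`build_drug_ade_records`, `aggregate_pairs`, ...); see the module
docstrings under `src/aersdm/`.

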