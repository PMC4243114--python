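# openlbd

Open literature-based discovery (LBD) with supervised filtering of linking
concepts. Starting from a concept C, the pipeline finds linking concepts B
that co-occur with C in the MeSH field of MEDLINE-style records, represents
each (C, B) pair by two mutual-information scores and five textual Boolean
features, classifies linking concepts as relevant or irrelevant with a
linear SVM, then discovers and ranks target concepts A (the C→B→A model)
by their useful linking-term count under two textual evidence rules. The
percentage-of-useful-LTC metric evaluates each configuration.

## What's inside

| Module | Role |
| --- | --- |
| `openlbd.medline_io` | MEDLINE flat-file parsing/writing, sentence segmentation, mention and abbreviation resolution |
| `openlbd.lexicon` | Semantic-type map, linking/target type filters, interaction-word lexicon |
| `openlbd.cooccurrence` | Document-level occurrence/co-occurrence indices at four scopes (MeSH field, title+abstract, sentence, adjacent-sentence window) |
| `openlbd.features` | Mutual-information scores and the 7-feature pair vector |
| `openlbd.linking_classifier` | Rule-based training-set construction and the SVM relevance classifier |
| `openlbd.discovery` | Target discovery, useful-linking rules, tie-aware dense ranking, evaluation |
| `openlbd.synthetic_corpus` | Seeded MEDLINE-like corpus generator with planted C–B–A chains and full ground truth |

## CLI

```bash
# generate a synthetic corpus with ground truth and semantic types
openlbd simulate --seed 3 --out corpus.txt --truth truth.json \
    --semantic-types types.tsv

# train the linking-concept classifier from the labeling rules
openlbd train corpus.txt --start startconcept --seed 3 --model-out model.joblib

# run open discovery and rank targets
openlbd discover corpus.txt --start startconcept --rule rule2 \
    --semantic-types types.tsv --model model.joblib \
    --designated-target targetcand0 --out report

# evaluate against a designated known target
openlbd evaluate corpus.txt --start startconcept \
    --designated-target targetcand0 --mode rule1 --semantic-types types.tsv
```

`discover` writes `<prefix>.tsv` (concept, LTC, useful LTC, rank, type
rank) and `<prefix>.json` (run summary with the evaluation result).
Useful-linking rules: `rule1` = linking and target co-occur in the
title/abstract text; `rule2` = they share one sentence that also contains
an interaction word; `plain` = raw linking-term count.

Interaction lexicon, semantic-type map and stop-concept list are plain
text inputs (`--lexicon`, `--semantic-types`); a small default verb
lexicon ships with the package for experimentation, but replication work
should supply the domain lexicon.

## File formats

- **Corpus**: tag-prefixed MEDLINE flat file (`PMID- `, `DP  - `,
  `TI  - `, `AB  - `, `MH  - `; continuation lines indented).
- **Semantic types**: 2-column TSV `concept<TAB>type`.
- **Interaction lexicon / stop concepts**: one entry per line, `#` comments.
- **Index cache**: 3-section TSV (`#scope` header, `#occ`, `#cooc`).
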