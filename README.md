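# picoscreen

A two-stage (title–abstract, then full-text) systematic-review screening
pipeline driven by PICOS-decomposed chained eligibility tasks over a pluggable
language-model backend, with complete offline evaluation machinery.

Eligibility is decomposed into four sequential dimensions —
interventions/comparators → populations → outcomes → study designs — each
backed by a prompt assembled from role text, domain definitions, stepwise
reasoning instructions, few-shot examples, and a JSON output contract. The
first failing task short-circuits the chain and supplies a traceable exclusion
reason, supporting PRISMA-style flow accounting.

## Components

| Module | Role |
| --- | --- |
| `picoscreen.corpus_io` | RIS / CSV / MEDLINE / corpus-XML reading, text cleaning, title+year deduplication |
| `picoscreen.pdf_structure` | page streams → canonically sectioned articles (heading vocabulary, caption diversion, OCR contract) |
| `picoscreen.criteria_prompt` | PICOS criteria config, exclusion-reason taxonomy, prompt assembly, response parsing |
| `picoscreen.llm_backend` | completion contract: deterministic offline mock (seedable noise), response cache, thin vendor adapters |
| `picoscreen.screening` | chained task execution per stage, decision traces, PRISMA counts |
| `picoscreen.evaluation` | accuracy/precision/recall, exclusion-reason concordance, Pearson chi-square model comparison |
| `picoscreen.synthetic_corpus` | seeded labeled corpora, stratified splits, duplicate injection, sectioned full-text fixtures |
| `picoscreen.cli` | end-to-end command-line surface |

The test suite and all offline runs use the deterministic mock backend, which
answers from machine-readable sentinels («INC» / «EXC:dimension») embedded in
synthetic documents and can flip a seed-determined fraction of records to
emulate an imperfect model. Vendor HTTP adapters (OpenAI-compatible dialects)
ship but are never required.

## CLI

```bash
# generate a labeled synthetic corpus (records.csv + gold.csv [+ fulltext/])
picoscreen fixtures --n 1000 --prevalence 0.1 --seed 7 --outdir fx --fulltext

# clean + deduplicate + write corpus XML
picoscreen preprocess --input fx/records.csv --format csv \
    --out-xml corpus.xml --report-json dedup.json

# title–abstract screening with the mock backend
picoscreen screen-ta --corpus fx/records.csv --backend mock --out ta.jsonl

# page streams → structured articles → full-text screening
picoscreen structure --pages-dir fx/fulltext --out-dir articles
picoscreen screen-ft --articles-dir articles --out ft.jsonl

# score against the gold standard (multiple --decisions compare backends)
picoscreen evaluate --gold fx/gold.csv --decisions ta.jsonl --out report.json
```

Exit codes: 0 success, 1 validation/configuration error, 2 runtime error.
One JSON log line per screened record goes to stderr. Identical config + seed
reproduce byte-identical decision files.

Criteria configs are YAML/JSON with a `picos:` block and optional
`exclusion_reasons:` overrides; see `src/picoscreen/data/rsv_criteria.yaml`
for the bundled default scenario.

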