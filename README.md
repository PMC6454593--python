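# genx

Gender requirement extraction and summarization from unstructured clinical
trial text.

Registry websites only offer *Male*, *Female* and *All* as structured sex
options, so trials recruiting transgender participants routinely carry
incorrect structured gender information. `genx` reads the free text of a
trial (study description plus inclusion/exclusion criteria), detects gender
mentions with a lexicon plus heuristic rules and automatically learned
token-window patterns, verifies them against partner/negation context, and
summarizes the evidence into a 13-type gender model:

- a **transgender component** (Male / Female / All) crossed with a
  **biological component** (none / Male / Female / All) — 12 labels — plus
- the single collapsed **`Biological`** label for trials with no
  transgender requirement.

Each final label also maps back to a conventional registry value
(Male/Female/All), by gender identity by default.

## Layout

| module | what it does |
| --- | --- |
| `genx.gender_model` | the 13-type model, 4 meta gender types, judgement and transformation functions (split/merge/trans-constrain) |
| `genx.preprocessing` | rule-based sentence splitting for criteria text, lowercasing tokenizer with protected tokens (`m/f`, `msm/w`, ...) |
| `genx.pattern_learning` | windowed pattern candidates around annotated spans (window ≤ β per side), support/confidence scoring and filtering |
| `genx.extraction` | per-sentence mention detection (patterns first, then lexicon rules), partner/negation verification, exclusion-section polarity flip |
| `genx.summarization` | meta-gender frequency counting, majority-rule pruning (`Pred = MG_{i+1}/MG_i × μ`, prune below 1), final label composition |
| `genx.evaluation` | macro-averaged P/R/F harness, stratified k-fold CV, bootstrap resampling, μ grid tuning |
| `genx.corpus_io` | trial JSONL / registry-XML / plain-dir readers, annotated-corpus round-trip, synthetic fixture generator |

The lexicon, composition gaps, verification windows and section header
regexes are data, shipped in `src/genx/data/rules.yaml`; sentence-splitter
abbreviations and protected tokens live in
`src/genx/data/preprocessing.yaml`. Both can be copied, edited, and passed
back via the config loaders or CLI flags.

## CLI

```sh
# build a synthetic dataset with known gold labels + an annotated corpus
genx --seed 7 gen-fixtures --n-positive 134 --n-negative 5000 \
     --out-trials trials.jsonl --out-corpus corpus.txt

# learn windowed patterns from the annotated corpus
genx learn-patterns --corpus corpus.txt --beta 7 --support 4 \
     --confidence 0.7 --out patterns.jsonl

# extract verified mentions / summarize to final labels
genx extract   --trials trials.jsonl --patterns patterns.jsonl --out mentions.jsonl
genx summarize --trials trials.jsonl --patterns patterns.jsonl --mu 5 --out summaries.jsonl

# macro-averaged evaluation with 10-fold CV and mu tuning over 1..10
genx --seed 17 evaluate --trials trials.jsonl --patterns patterns.jsonl \
     --k 10 --tune --out eval.json
```

Annotated corpora accept two inline dialects:
`[span text|LABEL]` or `<TG_Start>span text<TG_End>`.

Trial JSONL schema: one object per line with `nct_id`, `description`,
`inclusion`, `exclusion`, `registered_sex` (`Male|Female|All|Unknown`) and
optional `gold_label` (one of the 13 label strings).

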