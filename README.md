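# genorm

Multi-stage gene normalization (GN) for full-text articles, with
context-based species filtering for dynamic dictionary-entry selection and a
TAP-k evaluator for ranked gene-identifier lists.

The package normalizes gene/protein mentions in structured full-text articles
to database identifiers in three stages — richest context first
(introduction → abstract → title), then propagation of the normalized memory
across the whole article, then mention recognition over the remaining
sections and captions. Inter-species ambiguity is reduced by enabling only
dictionary entries for a configurable common-species list (static strategy)
or for the union of that list and the species detected by keyword in the
article or each section (dynamic strategies). Normalized identifiers are
ranked by a linear margin classifier over matching, vote, frequency,
location and known-information features.

## Layout

| module | role |
|---|---|
| `genorm.corpus` | article data model, JSON I/O, sentence segmentation, range expansion, abbreviation (long-form/short-form) extraction |
| `genorm.lexicon` | gene-name dictionary, orthographic variants, exact/partial matching, species keywords, entry-selection strategies |
| `genorm.mention` | tagger contract + dictionary tagger, boundary adjustment, blacklist filtering |
| `genorm.disambig` | 13 rule-based vote classifiers, weighted linear vote, candidate selection |
| `genorm.pipeline` | three-stage orchestration, focus species, cross-stage memory |
| `genorm.ranking` | feature extraction, trainable ranker, confidence calibration |
| `genorm.tapk` | threshold average precision (TAP-k), E_k threshold search, improvement reporting |
| `genorm.synthio` | deterministic synthetic corpora (dictionary, KB, species table, articles, gold lists) |

## CLI

```bash
# generate a synthetic corpus (articles/, dict.tsv, kb.json, species.tsv, gold.tsv)
genorm simulate --seed 1 --out corpus/

# preprocessing report: abbreviations + expanded collapsed ranges
genorm preprocess corpus/articles/SYN0000.json

# run the pipeline on one article; strategies: static | article | section | oracle
genorm normalize --article corpus/articles/SYN0000.json \
    --dict corpus/dict.tsv --kb corpus/kb.json --species corpus/species.tsv \
    --strategy article --out ranked.tsv

# score a ranked list with TAP-k (optionally vs a baseline run)
genorm eval --gold gold.tsv --pred ranked.tsv --k 5,10,20 [--baseline other.tsv]

# variant-expanded dictionary
genorm build-dict names.tsv --variants --out expanded.tsv
```

Article JSON schema:
`{"article_id": str, "keywords": [str], "sections": [{"kind": str, "heading": str, "text": str}]}`
where `kind` is one of `title, abstract, introduction, results, conclusion,
other, figure_caption, table_caption, appendix, section_title` (omitted kinds
are inferred from the heading). Dictionary TSV columns:
`gene_id, taxon_id, name, name_type`. Species keyword TSV columns:
`taxon_id, pattern, case_sensitive`.

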