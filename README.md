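# litnet

A rule-cascade machine-reading library for biomedical text.  litnet
extracts typed, grounded entity mentions and biochemical events — simple
conversions (the nine covalent additions and their removal mirrors,
binding, hydrolysis, translocation) plus nested, polarity-corrected
regulations and activations — resolves entity/event coreference with a
deterministic sieve cascade, and assembles everything into an
evidence-counted interaction network that can be merged with a curated
prior in SIF form.

The extraction grammar is a compact inventory of **154 named rule
templates** in two dialects (dependency-pattern "syntax" rules and
token-window "surface" rules), organized so that ten reusable syntactic
variations (declarative, passive, three nominalizations, two relative
clause forms, two appositions, paraphrastic causative) are shared across
all event types, each instantiated with a per-event trigger lexicon.

## Layout

| module | role |
|---|---|
| `litnet.preprocess` | sentence/token segmentation (biomedical dash/slash splitting), CoNLL-U read/write, pluggable parser-provider contract |
| `litnet.entities` | KB TSV loading, dictionary + pattern NER, grounding (uniprot > interpro > chebi > hmdb), PTM/mutant/wild-type state attachment |
| `litnet.grammar` | template representation, compilation and both matchers; shipped grammar in `grammar/data/` |
| `litnet.events` | two-step bottom-up event extraction, coordination cross-product expansion, binding binarization, negation |
| `litnet.polarity` | reversal-cue scan along trigger–argument dependency paths, parity sign correction |
| `litnet.coref` | anaphor detection and the 4-sieve cascade (exact match, mutant alias, event label, nearest type) |
| `litnet.pipeline` | document-level orchestration incl. coref re-extraction to a fixpoint |
| `litnet.assembly` | event → interaction-record normalization, paper-level evidence aggregation, redundancy filter, SIF prior merge |
| `litnet.fixtures` | synthetic gold corpus generator (sentences + hand-built trees + gold annotations) and verbatim hand-annotated fixtures |
| `litnet.scoring` | approximate-span / recursive-argument event scorer |

## CLI

```sh
# generate the synthetic gold corpus (CoNLL-U + gold JSON + KB TSV)
litnet fixtures --out corpus/ --seed 7

# run the cascade over pre-parsed documents
litnet extract --kb corpus/kb.tsv --conllu corpus/corpus.conllu --out events.json

# score predictions against gold
litnet score --pred events.json --gold corpus/gold.json --mode approximate

# aggregate, filter by redundancy and merge with a curated prior
litnet merge --prior prior.sif --extracted events.json --min-evidence 2 --out merged.sif

# per-category template counts of the shipped grammar
litnet inventory
```

Plain text can be fed with `litnet extract --text doc.txt ...`; without
a dependency parse only the surface fallback rules fire.  A live parser
can be plugged in through `litnet.preprocess.register_provider` (a
callable from token lists to per-token `(pos, lemma, head, label)`).

## Grammar files

`src/litnet/grammar/data/grammar.yaml` lists every template (name,
category, dialect, variation tag, pattern).  Syntax patterns are paths
of dependency steps, e.g. `>nsubj >appos?` (head→dependent hop,
optional hop) or `<obj@causative >nsubj` (dependent→head hop gated on
an auxiliary lexicon).  Surface patterns are bracketed token specs,
e.g. `[re=^[A-Z]\d+[A-Z]$ as=variant] [t=mutant]`.  Trigger lexicons
live in `grammar/data/lexicons/triggers.tsv` (label, form, POS prefix)
and are config-extensible.
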