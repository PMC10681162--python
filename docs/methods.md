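# Methods

## Model

`gdlink` treats document-level gene–disease extraction as two coupled
problems over one shared contextual encoding.

**Encoding.** Text is whitespace pre-tokenized and split into byte-pair
subwords learned on the training corpus (greedy merges by pair frequency,
lexicographic tie-break, so training is deterministic). Every subword
carries half-open character offsets; character-offset annotations map to
the minimal covering token interval, snapping outward when a mention
boundary splits a subword. Two encoders satisfy the same contract: a tiny
trainable transformer (token + learned positional embeddings, pre-norm
blocks, final layer norm; defaults H=64, 2 layers, 2 heads) and an adapter
slot for an externally supplied pretrained model. All shipped training and
tests use the tiny encoder; documents longer than the positional table are
processed with a half-window-stride sliding window and mean-merged overlaps.

The neural substrate is a compact reverse-mode autodiff engine over numpy
(`gdlink.nn`) implementing exactly the operations the model needs. It is
single-threaded and bitwise deterministic for a fixed seed and platform.

**Span-based NER.** All token intervals up to `max_width` subwords
(default 10 — longer spans are decreasingly likely to be entities) are
candidates. A candidate is represented as elementwise max over its token
vectors ⧺ a learned width embedding (dimension 25; widths beyond the table
clamp to its last row), classified by a shallow ReLU network into the 12
entity types plus non-entity. The loss is the summed cross-entropy
−Σ_o Σ_t y_{o,t} log p_{o,t}; a mean reduction is available for gentler
steps but the sum is the default. At training time the gold spans are
scored together with up to 100 sampled non-entity spans per document
(scoring all ~10n spans every step would dominate the cost for no
measurable gain at this scale). At prediction time all spans are scored;
overlapping predictions of different extents are retained, and identical
spans with conflicting types keep the higher-probability type, tie-breaking
toward the lowest class index.

**Relation extraction.** Candidates are all (gene, disease) mention cross
pairs of a document, gene first, deduplicated by span coordinates. The
feature vector concatenates (1–2) the two span representations, (3) the
elementwise max over tokens strictly between the spans (zero vector when
the spans are adjacent or overlap — the identity of an empty max pool),
and (4) an attention context Σ w_i x_i with softmaxed scaled-dot-product
weights. The attention query is a linear projection of the two pooled span
vectors; keys and values are the token encodings, either passed through
unchanged (default, and what the fast test paths use) or via one
bidirectional Elman-style recurrent layer (`seq2seq="birnn"`). The link
head is a 2-class softmax whose positive probability feeds binary
cross-entropy; this is mathematically identical to a sigmoid-BCE head. A
pair is predicted linked iff p_link exceeds 0.5 strictly. Gene–disease
pairs without a gold edge are negatives, capped at 50 per document.

**Joint training.** The total loss is the exact sum of the NER and RE
components, so gradients from both heads reach the shared encoder.
Optimization is AdamW with linear warmup over the first 10% of steps and
linear decay to zero. The learning-rate default (6e-5) matches the
fine-tuning regime for large pretrained encoders; the tiny encoder trains
from random initialization, so the shipped tests and the acceptance script
use 1e-3 to 3e-3, the package's own from-scratch choice. The `only_re`
mode supplies gold mentions and skips the NER loss entirely.

## Direct-edge augmentation

For each gene mention g and disease mention d joined in the annotation
graph by a path whose interior nodes are all triggers (any type outside
{Gene, Disease}), augmentation adds LinkedOf(g, d, direct=true). The
implementation generalizes from the single-trigger case to any-length
trigger-interior paths (breadth-first search from each gene, expanding only
through trigger nodes; optional `max_path_len`), is idempotent and
monotone, and stores the gene as e0. Protein is deliberately not a DE
endpoint by default — the endpoint set is configurable — because proteins
are handled downstream by linking them to their encoding gene's identifier.

## Evaluation

Gold and predicted annotations are compared as graphs. Entity matching is
exact on (document, span, type); relaxing to overlap matching is a
possible extension, not currently shipped. Relation matching is undirected
over edges whose endpoints both match gold nodes. Precision with zero
predictions is reported as 0 (not NaN) so fold averaging stays total; F1 is
0 whenever TP is 0. For relation-level scoring of gene–disease link
predictions, the gold edge set is taken by default as the *direct-edge
closure* (every trigger-mediated pair made explicit) rather than the raw
annotated edges; otherwise switching DE augmentation on would change the
task itself rather than just the training signal. Both modes are exposed
(`eval_target="raw"|"closure"`). Cross-validation splits at document level
into k=5 folds whose sizes differ by at most one; the split, negative
sampling and initialization all derive their streams from one seed by
seed-sequence keying.

## Synthetic corpus

The generator emulates the statistical structure of a trigger-annotated
gene–disease corpus: 12 entity types in two categories, gene+disease
mentions at a configurable fraction of all entities (default 0.4, matching
the reported composition of such corpora), Poisson relation counts
(default 1.5 links per positive document), and a fraction of relation-free
negative documents (default 0.2). Linked pairs are realized in one of two
sentence patterns: a trigger-mediated chain "GENE trigger [trigger]
DISEASE" annotated Gene→trigger→Disease (with a 0.2 chance of a two-trigger
chain), or — with probability 0.5 — a directly annotated edge realized as
"GENE is associated with DISEASE" through an unannotated connective. The
split matters: a model trained *without* DE augmentation only receives
positive signal from the direct pattern, while DE augmentation also turns
every trigger-mediated pair into a positive example. Because the two
patterns differ at the surface, the without-DE model cannot generalize to
trigger-mediated pairs, and the recall gap between the two arms is a real
property of the training signal, not an artifact of the evaluator.

Background genes and diseases appear only in trigger-free sentences, so
they are genuine unlinked distractors. Several lexicon entries are shared
across types (e.g. "p53 signal" as a Pathway alongside Gene "TP53") so the
NER head must use context, not surface lookup; an optional train/heldout
lexicon split puts unseen surfaces in evaluation documents. Document i
draws from a substream keyed by (seed, i), so corpora are byte-identical
across runs and stable under prefix extension. The generator records the
gene–disease pairs it intends to link; tests check that DE augmentation
recovers exactly that bookkeeping. What the generator does *not* emulate:
real biomedical language statistics, discontinuous or nested gold
mentions, cross-sentence trigger chains, or annotation noise — passing at
desk scale demonstrates the machinery is correct and the training dynamics
directionally faithful, not that real-corpus F1 levels are attained.

## Entity linking and graph post-processing

Surfaces map to identifiers by cosine similarity over character-3-gram
count vectors (lowercased; strings shorter than 3 characters get one
padded gram so symbols like "AR" keep a non-empty profile). The index is a
brute-force cosine nearest-neighbour structure — exact by construction, so
it trivially meets the ≥0.99-recall-vs-exhaustive contract any replacement
index must satisfy; tests compare against an independent exhaustive oracle.
The default acceptance threshold is min_sim=0.7. Proteins query the gene
namespace. Decision rules are a registry of generic, ordered filters
(probability threshold, drop-unlinked, namespace whitelist, degree cap)
with per-rule removal logging; domain-specific rule sets are user
configuration, not package policy. Node merging collapses nodes sharing a
non-null (namespace, identifier), unioning provenance, keeping the maximum
edge probability and dropping merge-induced self-loops. Trigger reduction
removes trigger nodes and connects every gene/protein–disease pair
attached to the same trigger-connected component, with provenance unioned
over the component. Integration merges per-document graphs at identifier
level (unlinked nodes fall back to lowercased-surface identity within
their namespace), keeps gene–disease edges only (bipartite result), stores
the max per-edge probability and the full list of contributing documents,
and is order-independent up to isomorphism.

## Numerical and degenerate-case policies

- Log-probabilities come from shifted log-softmax; finite logits can never
  produce log(0), so no epsilon clamp is needed in the losses.
- Elementwise/axis max routes gradient to the first argmax on ties.
- Empty batches give loss 0; empty documents are skipped in training and
  return empty annotations at prediction.
- Attention over zero tokens is an error (no silent empty context).
- Mentions that align to no token (whitespace-only spans) are dropped from
  training with the document otherwise kept.
- Gold spans wider than `max_width` subwords cannot be enumerated and are
  excluded from the NER training signal (they still count against recall).

## Desk-scale problem sizes

The shipped tests and the acceptance script use sizes chosen so the whole
suite runs in minutes on one CPU: 20-document corpora trained to
saturation (80 epochs joint / 40 epochs onlyRE) for the overfitting sanity
checks, and a 100-document corpus with a 1-layer, 32-wide encoder and 15
epochs per fold for the paired (±DE) × (joint/onlyRE) 5-fold ablation.
These are the package's reference experimental conditions; scaling any of
them up is a configuration change, not a code change.

## Known limitations

- The tiny encoder is not a pretrained language model; absolute scores on
  real corpora require plugging a pretrained encoder into the adapter slot
  and are out of scope here.
- Only binary gene–disease `LinkedOf` relations are modeled; no relation
  subtypes, n-ary relations, or cross-document coreference.
- BIO/CRF sequence decoding is deliberately absent; the span classifier
  with overlap retention is the only NER decoder.
- The Elman BiRNN key/value encoder is a minimal stand-in for richer
  sequence-to-sequence encoders and is off (identity) by default.
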