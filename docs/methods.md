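# Methods

## Statement model

A BEL statement is represented as an ordered tree.  The root is the causal
relation (`increases`, `decreases`, `directlyIncreases`,
`directlyDecreases`); internal nodes are BEL functions (`complex`, `cat`,
`deg`, `tloc`, activity functions, and the modification functions `pmod`,
`sub`, `trunc`, `fus`); leaves are entities (`namespace:identifier` or an
anonymized placeholder) and literal parameters (modification type,
amino-acid code, sequence position).  Normalization elevates modification
functions written inside an entity term — `p(HGNC:AKT1, pmod(P, S, 21))`
becomes `pmod(p(HGNC:AKT1), P, S, 21)` — so functions always sit above
entities; rendering reverses the move.  Multiple statements attached to one
sentence are unified under an `or` root so the sentence aligns against a
single tree.  Nested relations (a statement as argument of another) are
rejected with an explicit parse error; the supported corpora do not use
them, and silently guessing a structure would corrupt training data.

Serialization is a preorder walk in which every internal node carries its
child count (`complex@2`).  The arity markers make deserialization exact:
a sequence is consumed left to right, each `label@n` claiming the next *n*
subtrees.  Serialize/deserialize and parse/render are inverse pairs,
enforced by 1,000-tree random round-trip tests.

Placeholder codes are GENE (genes/proteins, term functions `p`/`g`/`r`/`m`),
CHEM (`a`), BP (`bp`), DIS (`path`); numbering restarts per sentence in
order of first mention.

## Tokenization and grounding

Tokenization is whitespace splitting plus three rules: a trailing comma
(comma before space) becomes its own token while commas followed by a
letter or digit stay inside biomedical names (`1,25-dihydroxyvitamin`);
hyphens are split out of compounds whose final segment ends in *ed*/*ing*,
exposing the participle that usually carries the relation; amino-acid codes
fused with positions are split (`Ser727` → `Ser 727`).  The residue rule
fires only when the letter part is a one- or three-letter amino-acid code,
so `p53` stays whole.  Hyphens and commas are emitted as tokens rather than
deleted, keeping character offsets recoverable.  Stems come from a small
deterministic suffix stripper (longest-suffix-first, minimum stem length
3); any deterministic stemmer satisfies the feature contract, and avoiding
a heavyweight dependency keeps training reproducible bit-for-bit.

Entity grounding cascades three passes: precomputed NER mentions (the
package reads mention files; it never runs external taggers),
renormalization (genes pass through — Entrez/HGNC/MGI identifiers are
treated as consistent; chemicals map to CHEBI through a user-supplied
table; OMIM-linked diseases are discarded because no OMIM→MESH conversion
exists), and dictionary search for whatever remains.  Dictionary search
scans every contiguous token window up to `max_span` = 6 tokens and picks
the window minimizing character-level edit distance (lowercased, normalized
by the longer string, computed with edlib) to any symbol or synonym;
matches are accepted at distance ≤ 0.2, enough for minor morphological
variants without grabbing arbitrary text.  Ties break toward the smaller
distance, then the longer window, then leftmost, making results independent
of dictionary order.  An entity with no acceptable window is ABSENT, and
pairs with ABSENT entities are filtered out of the parallel corpus.

## Sentence simplification

Sentences are reduced to the minimal connected subgraph of their dependency
tree containing all statement entities (union of the paths from each entity
to the collective lowest common ancestor), emitted in original word order.
Parsing is external: trees arrive pre-parsed in CoNLL-U, and a hand-checked
parse of the published simplification example ships with the tests.
Function words the example drops ("the", "and") fall out of the subtree
computation; no stop-word filtering is applied.  When no parse is available
the sentence passes through unchanged with a warning, keeping the pipeline
total.

## Word alignment

The simplified sentence is the source language and the serialized node
sequence the target.  An IBM-Model-1-style EM learns t(word | node) — for
each node, a distribution over source words summing to one — so several
words may align to one node but each word aligns to at most one node, which
is what downstream tag generation consumes.  Three details matter:

* **NULL node.**  Every sentence carries a NULL target; words whose best
  candidate is NULL stay unaligned.
* **NULL weighting** (`null_weight`, default 2.0) counts NULL as two
  virtual tokens per sentence.  Plain Model 1 systematically attaches
  frequent function words ("of", "to", "with") to whatever content node
  co-occurs with them; weighting NULL is the standard corrective and is
  what lets the aligner leave prepositions unaligned, reproducing the
  published link pattern (trigger→relation, function word→nothing).  Add-n
  smoothing of the M-step is available (`smoothing`, default 0).
* **Pseudo-parallel pairs.**  Fifty single-token identity pairs per
  placeholder dominate each placeholder's row; extraction additionally
  forces placeholder words onto their identical target node (by occurrence
  order when repeated), so entity links have precision 1.

Training iterates pairs in `pair_id` order, initializes uniformly and uses
no randomness; the `seed` argument is stored for provenance.  The corpus
log-likelihood is recorded per iteration and is non-decreasing (EM
monotonicity), which the tests assert.  Ten iterations are the default —
the toy corpora involved converge in far fewer.

## Hierarchical tags

Layers are node heights: entity/parameter leaves at layer 1, every internal
node one above its highest child, the relation (or `or`) root on top.  A
node's span is the minimal contiguous interval covering its own aligned
words and all tokens covered by its descendants, tagged BIESO with the bare
node label (no arity; arity is recomputed from recognized children at
reconstruction).  Gaps inside a span are tagged I — spans are contiguous
intervals by construction.  Parameter leaves are tagged with coarse classes
P (modification type), AA (amino-acid code) and NUM (position) rather than
their literal values.  Instances where a node has no aligned word and no
descendant span, or where two same-layer spans overlap (typically
statements sharing an argument across different relations, which cannot be
unified into a well-formed tree), are rejected from training with a logged
reason.

Reconstruction runs top-down: the top-layer span becomes the root, and each
span adopts the lower-layer spans nested inside it (parent = containing
span on the lowest higher layer, narrowest first) as children in
left-to-right surface order.  For relations, the left span is the first
argument — the paper's framework does not specify how subject/object roles
are recovered when the object precedes the trigger, so surface order is the
documented choice here.  Predicted BIESO sequences are repaired
deterministically before span extraction (orphan I/E opens a block,
unterminated blocks close at their last token); orphan spans outside every
higher span are dropped with a warning; several top-layer spans are joined
under an `or` root.  On every instance whose nodes all received alignments,
reconstruction inverts generation exactly (tested over the full synthetic
corpus).

## Stacked labelers

One linear-chain CRF per layer, trained bottom-up with gold lower-layer
tags as features (teacher forcing) and decoded top-down on predicted tags.
Features are unigrams of word, stem and each lower layer's tag at offsets
−2..+2 (window 5) plus a bias; label bigrams enter through the CRF's
transition weights.  Out-of-range offsets yield boundary sentinels, so
feature extraction is position-covariant.

The CRF engine is implemented in-package (`belhier._crf`): emission weights
per (feature, label), transition and start weights, exact forward-backward
gradients, L2 penalty with coefficient `c2` = 1.0, optimized by L-BFGS from
a zero start.  Everything about training is deterministic given the corpus
order, so identical seeds and inputs reproduce identical models and
predictions — asserted in the tests.  `max_iter` defaults to 100 L-BFGS
iterations; the synthetic corpora converge well before that.  Shallower
instances are padded with all-O layers up to L so the per-layer models see
consistent layer indices.

## Evaluation

Scoring projects statements onto six levels — term (entity terms),
function-secondary (function name + argument entities, relaxed), function
(function with its inner term), relation-secondary (relation type + each
single argument), relation (type + both ordered arguments), statement (the
whole normalized statement).  `directlyIncreases ≡ increases`,
`directlyDecreases ≡ decreases`, and the activity family (`act`, `cat`,
`kin`, `tscript`, `phos`, `gtp`, `pep`, `ribo`, `tport`, `chap`) maps to
`act()` everywhere.  Matching is per sentence and multiset-aware; a
prediction never matches gold from another sentence.  The exact secondary
projections follow the shared-task evaluation descriptions as interpreted
here and are isolated inside `canonicalize`, so they can be revised without
touching the counting logic (which is verified against a brute-force
matcher).

## Synthetic corpus

The generator emulates the statistical shape of sentence/statement pairs:
a subject phrase, a causal trigger drawn from a small lexicon ("prevented"
→ `decreases`, "elevated" → `increases`, phrasal "led to"/"interfered
with"), an optional function trigger ("association"/"binding" →
`complex(x, y)`, "catalysis" → `cat(x)`, "degradation" → `deg(x)`), an
optional subject activity ("activity of X"), connector prepositions, and
filler material of two kinds: distractor adverbs attached off the entity
paths (provably removed by simplification) and subject nominalization
phrases ("Preincubation with ...") whose head sits on the path and must be
left unaligned by the aligner.  The dependency tree is built from the
template grammar, so gold parses, gold alignments and gold layered tags are
known exactly.

Default condition parameters, chosen once as a realistic mix: p_function
= 0.5 (share of statements with an object-side function), p_subject_activity
= 0.25, p_subject_prep = 0.3, p_phrasal_trigger = 0.25, p_or = 0.1
(multi-statement sentences), p_distractor = 0.3 per slot, p_noise = 0.05
(probability a trigger word is misspelled while remaining gold-aligned).
Entity vocabularies: 30 genes, 12 chemicals, 8 processes, 4 diseases,
drawn without replacement within a sentence.  `GenConfig.low_noise(n, seed)`
is the single-statement study configuration (p_or = 0, everything else at
defaults), giving trees of depth ≤ 3 — the three-layer setting used by the
end-to-end experiment (2,000 training / 200 held-out pairs).

What the generator does **not** emulate: real biomedical sentence length
and vocabulary, parser errors, NER errors, nested coordination,
discontinuous mentions, and statements sharing arguments across different
relations.  Passing the end-to-end thresholds therefore demonstrates that
the pipeline machinery is correct and self-consistent, not that it reaches
any particular accuracy on real corpora — on the shared-task data the
published setting of this framework reports statement-level F1 in the low
thirties, limited mainly by NER recall, parse quality and training-set
size.

## Numerical choices and degenerate inputs

* Edit distances are character-level on lowercased strings; the variant
  (vs. token-level) is unstated upstream and documented here.
* EM and CRF training are exactly reproducible: fixed iteration order,
  zero initialization, leftmost tie-breaking (numpy `argmax` convention in
  Viterbi).
* Empty prediction lists score P = R = F1 = 0 by convention; an all-O tag
  matrix yields "no statement extracted" rather than an error.
* Statement strings are compared after whitespace canonicalization (no
  space after commas) because gold files vary in dialect.
* A relation reconstructed with other than two children cannot be rendered
  and is dropped from the prediction list with a warning.

## Known limitations

* The full OpenBEL grammar (translocation coordinates, reactions,
  `hasMembers`, nested statements) is out of scope; only the constructs of
  the extraction task are modeled.
* One aligner direction is implemented (words conditioned on nodes); no
  fertility or distortion model, no symmetrization beyond forced entity
  links.
* Secondary-level evaluation semantics are an interpretation of the shared
  task's scorer, not a reimplementation of it.
* Dictionary search is O(sentence × max_span × names); adequate for
  sentence-scale inputs, not optimized for full-corpus sweeps.
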