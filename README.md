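# belhier

Hierarchical sequence labeling for extracting **Biological Expression
Language (BEL)** statements from biomedical sentences.

BEL captures causal findings as `subject-term relation object-term`
statements, e.g.

```
cat(p(HGNC:IL2)) increases complex(p(HGNC:LYN), p(HGNC:IL2RB))
```

for the sentence *"The association of lyn with IL-2Rbeta was markedly
elevated by IL-2 stimulation."*  Corpora such as the BioCreative BEL track
annotate statements only at the sentence level, so conventional supervised
relation extractors cannot be trained directly.  This package implements a
pipeline that turns sentence-level annotation into token-level supervision
and back:

1. **Preprocessing** — biomedical tokenization (residues `Ser727` →
   `Ser 727`, participial hyphens `progesterone-induced` → `progesterone -
   induced`), statement normalization (modification functions `pmod`/`sub`/
   `trunc` elevated above their entity term), entity grounding via a
   pluggable NER hook plus edit-distance dictionary search, and
   anonymization of mentions as typed placeholders (`GENE_1`, `CHEM_1`, ...).
2. **Parallel corpus construction** — each sentence is reduced to the words
   of the minimal dependency subtree containing its entities; each statement
   is parsed into a tree (relation root, functions, entity/parameter
   leaves), the trees of one sentence are unified under an `or` node, and
   the unified tree is serialized to its preorder node sequence with arity
   markers (`decreases@2 CHEM_1 complex@2 GENE_1 GENE_2`).
3. **Word alignment** — an IBM-Model-1-style EM aligner (NULL token,
   NULL weighting, pseudo-parallel `GENE_1 → GENE_1` pairs) links sentence
   words to statement nodes.
4. **Hierarchical tagging** — every node lives on a layer (leaves at 1,
   parents above their highest child); each node's minimal covering token
   interval becomes a BIESO span labeled at the node's layer.
5. **Stacked sequence labeling** — L linear-chain CRFs trained bottom-up;
   layer *k* consumes words, stems and the layer `1..k-1` tags in a window
   of 5.  At test time, predicted layers feed the next layer, spans are
   reassembled into a tree, and the tree is rendered back to BEL text.
6. **Evaluation** — precision/recall/F1 at Term, Function-Secondary,
   Function, Relation-Secondary, Relation and Statement levels, with
   `directlyIncreases ≡ increases` and activity functions (`kin`, `cat`,
   `tscript`, ...) collapsed to `act()`.

A seeded synthetic-corpus generator (`belhier.synth_fixtures`) produces
sentence/statement pairs with gold dependency parses, gold alignments and
gold layered tags, so every stage — and the end-to-end pipeline — is
testable without external corpora or tools.

## Worked example

```python
from belhier import parse_statement, serialize_tree, normalize_statement
from belhier.bel_core import build_placeholder_map, render_statement

tree = parse_statement(
    "a(CHEBI:castanospermine) decreases complex(p(MGI:Asgr2), p(MGI:Pdia3))"
)
print(serialize_tree(tree, build_placeholder_map(tree)))
# ['decreases@2', 'CHEM_1', 'complex@2', 'GENE_1', 'GENE_2']

norm = normalize_statement(
    parse_statement("p(HGNC:AKT1, pmod(P, S, 21)) increases p(HGNC:B)")
)
print(render_statement(norm))
# p(HGNC:AKT1,pmod(P,S,21)) increases p(HGNC:B)
```

The full pipeline on a synthetic corpus (300 training / 50 held-out pairs):

```
$ belhier run-synthetic --n-train 300 --n-test 50 --seed 7
Evaluation Level        P(%)    R(%)   F1(%)
Term                   100.0   100.0   100.0
Function-Secondary     100.0   100.0   100.0
Function               100.0   100.0   100.0
Relation-Secondary      96.0    96.0    96.0
Relation                96.0    96.0    96.0
Statement               96.0    96.0    96.0
alignment error rate       0.038
placeholder link precision 1.000
layer 1 tag accuracy       1.000
layer 2 tag accuracy       0.972
layer 3 tag accuracy       0.952
training instances         300 (0 rejected)
```

The Term row says every entity term of the gold statements was recovered;
the Statement row is the strictest check — the complete reconstructed
statement must match the gold statement.  The alignment error rate measures
the EM aligner's word→node links against the generator's gold links, and
the per-layer accuracies compare predicted BIESO tags with gold tags on the
held-out sentences.

Other CLI entry points: `belhier simulate` (write a fixture bundle:
statements TSV, CoNLL-U parses, Pharaoh alignments, layered tag files),
`belhier train` / `belhier predict` (model persistence and decoding),
`belhier align` (stand-alone aligner), `belhier score gold.tsv pred.tsv`.

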