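# rxnforge

Most published chemical reactions exist only as scheme drawings in papers and
patents. Tools that parse those images back into machine-readable reactions
need two things that are expensive to produce by hand: large **annotated
training corpora** of reaction-scheme images, and a **rigorous way to score**
a parser's output. `rxnforge` provides both, without any trained model in the
loop:

* a **synthetic dataset generator** that turns reaction SMILES
  (`reactants>agents>products`) into rendered reaction-scheme images with
  exact ground truth — component boxes with roles (reactant / condition /
  product), condition text spans with semantic roles (agent, solvent,
  temperature, time, yield, plus untyped "other" text), arrow geometry and
  per-step reaction SMILES — across four layout patterns: single-line,
  multiple-line, branch and catalytic cycle, with augmentation in font size,
  line width, molecule scale and pattern;
* a **token-sequence codec** that losslessly linearizes annotations into a
  stream with paired start–end tokens per component and numeric coordinate
  tokens (quantized to B bins per axis), and a total decoder back;
* an **evaluation framework** scoring any parser that emits the annotation
  JSON: hard/soft match precision, recall and F1 at the reaction level,
  condition role identification (CRI) confusion matrices, condition OCR
  accuracy, and reaction SMILES exact-match accuracy.

## The metrics, precisely

A predicted reaction step matches a ground-truth step when a one-to-one
correspondence exists between their components such that every pair has box
IoU ≥ τ (default 0.5) and agreeing roles. Under **hard** match roles must be
identical; under **soft** match a ground-truth molecular agent (a condition
region whose agent text parses as SMILES) may be predicted as a *reactant* —
the one relaxation that distinguishes the two criteria, so soft scores
dominate hard scores everywhere. Across a scheme, predicted and ground-truth
steps are matched by maximum-cardinality bipartite matching, and

    P = TP / n_pred,  R = TP / n_gt,  F1 = 2PR / (P + R)

with the zero conventions P = R = F1 = 0 when nothing is predicted. Two
reaction SMILES are *exactly equal* when the canonical-form molecule
multisets of their reactant, agent and product fields agree pairwise
(RDKit canonicalization; within-field order never matters).

## Worked example

Generate a 12-image dataset and score its ground truth against itself:

```
$ rxnforge generate --n 12 --seed 7 --out demo
wrote 12 images to demo (0 resample events)
$ rxnforge evaluate demo demo --mode both
 hard: P=1.000 R=1.000 F1=1.000
 soft: P=1.000 R=1.000 F1=1.000
  CRI accuracy=1.000 OCR accuracy=1.000 SMILES exact match=1.0
```

Self-evaluation is exact by construction — the useful signal appears when a
parser is imperfect. Corrupting the ground truth of a 20-image dataset with
random role relabelings, box jitter, step deletions and spurious steps, then
scoring the corrupted predictions:

```python
from rxnforge.perturb import random_corruption
preds = {k: random_corruption(s, RNGStream(99, (i,)))
         for i, (k, s) in enumerate(gts.items())}
```

prints

```
hard: P=0.627 R=0.615 F1=0.621
soft: P=0.647 R=0.635 F1=0.641
CRI accuracy=0.469
OCR accuracy=0.993
```

Soft F1 exceeds hard F1 because some corruptions were exactly the
agent-as-reactant relabeling the soft criterion forgives; OCR stays near 1
because box jitter moves text regions without changing their characters,
while role flips crush CRI accuracy.

Other subcommands: `rxnforge codec encode|decode` (token streams),
`rxnforge inspect` (box-overlay rendering of one annotation). Reaction
sources: a file of reaction SMILES (one per line) or the bundled toy source
(curated transformations plus combinatorial functional-group transforms on
alkyl/aryl scaffolds).

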