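# Methods

## Scope and model of a reaction scheme

A scheme is a canvas (pixels, origin top-left) holding role-labelled
components and the steps connecting them. Boxes are half-open,
`[x_min, x_max) × [y_min, y_max)`, so widths, areas and IoU are exact integer
arithmetic after layout rounds every box to whole pixels. Components are
either molecules (reactant/product, payload = SMILES) or condition regions
(payload = ordered text items, each with a role from agent, solvent,
temperature, time, yield, other). Arrows are straight, curved (≥1 control
point) or bidirectional, and may be crossed out; a crossed-out arrow marks a
reaction that does not occur and is therefore excluded when arrow semantics
are resolved for reaction-SMILES assembly, while a bidirectional arrow
expands into both directions as two separate steps. Validation is data, not
exceptions: `validate_scheme` returns one record per violated invariant.

In chained layouts (a single-line sequence A → B → C, or a closed cycle) one
molecule box is simultaneously the product of one step and the reactant of
the next. The component's stored `role` is the role of its first use; the
evaluator always derives a component's role *within a step* from which id
list it occupies, so shared components are scored correctly in both steps.

## Synthetic generation

Given a reaction source, each image is produced by: (1) drawing a concrete
style — font size (default 11–18 pt), line width (1–3 px), molecule scale
(0.8–1.3×), layout pattern (uniform over the four patterns by default), one
of two bundled DejaVu faces — uniformly from configured ranges; (2) planning
steps for the pattern; (3) sampling condition text; (4) laying out boxes;
(5) rasterizing with RDKit depiction for molecules and Pillow for text and
arrows.

Placement follows printed-scheme conventions: reactants, arrow, products run
left to right with "+" glyphs between co-reactants ("+" is drawn but never
annotated, since components are only reactants, conditions and products);
agent text is centred above the arrow; solvent, temperature, time and yield
stack below it in that order, followed by any untyped "other" text. This
above/below rule is applied uniformly at the arrow midpoint for *every*
arrow kind, including the curved arcs of cycles — a deliberate choice so the
positional invariant "agents above, everything else below" is assertable
from bbox centres across all four patterns rather than pattern-by-pattern.
A single-line scheme wraps onto a continuation line when content exceeds
`canvas_max_width` (default 1400 px); the canvas otherwise grows to fit, so
layout output always validates. Molecule boxes never overlap by
construction: rows and columns are spaced, and cycle radii are inflated
(×1.2 steps) until all node boxes clear each other.

Condition sampling emulates literature frequency: each of the five roles is
present with its own probability (agents 0.7, solvent 0.7, temperature 0.6,
time 0.5, yield 0.5 by default), untyped auxiliary text ("pH 10–11",
"N2 atmosphere", R-group legends) appears with probability 0.1. Name
vocabularies are chosen so no entry accidentally parses as SMILES; only
SMILES-valued agent items (including the source reaction's own agents, which
are placed above the arrow verbatim) enter the agent field when a step is
assembled back into reaction SMILES — name-only agents like "Pd/C" stay
textual metadata, since name-to-structure resolution is out of scope. As a
consequence the assembled reaction of every generated step is exactly
equivalent to its recorded source reaction, which the dataset tests assert.

Branch and cycle topologies cannot be realized from arbitrary independent
reactions, so the generator recombines molecules from the source: a branch
shares the reactant set of its group (the toy source emits genuine
shared-reactant groups; file sources fall back to grafting arms onto the
first reaction's reactants), and a cycle chains k single-molecule nodes
into a closed loop. The per-step ground truth records the recombined
reaction, keeping annotation and image consistent. This emulates the
*visual* structure of catalytic cycles; it does not claim the individual
ring steps are balanced chemistry.

After rasterization every annotation box is re-measured as the tight box of
the actually drawn pixels inside its allocated region (threshold: any
channel < 250). Tightening only shrinks boxes, so disjointness and canvas
containment survive. Rendering is fully deterministic: fonts are the two
DejaVu faces packaged with matplotlib (no system fonts), RDKit's cairo
drawer is deterministic given (SMILES, tile size, line width), and
regeneration from the same seed is byte-identical for both PNGs and
annotation JSON. Optional tilted condition text (±30°, off by default)
stores the axis-aligned box of the rotated glyphs.

What the generator does *not* emulate: journal-specific drawing styles,
hand-drawn noise, scanned-page artifacts, R-group tables, footnote linking,
and text rendered along arbitrary curves. Tests passing on this synthetic
distribution therefore certify the pipeline's bookkeeping (annotations,
metrics, codec), not parser performance on real literature images.

## Randomness

All draws flow from one root seed through hierarchical named substreams
(`numpy SeedSequence(root, spawn_key=path)`): the same `(seed, path)` always
reproduces the same draws regardless of sibling consumption, which is what
makes per-item resampling (on depiction failure) reproducible. The dataset
split is a seed-deterministic shuffle with sizes round-half-up(N·ratio) for
train and val and the remainder to test — stated explicitly because N = 7 at
8:1:1 must give (6, 1, 0) reproducibly.

## Token-sequence codec

Annotations linearize to `RXN_START … RXN_END` blocks (one per step, in the
scheme's step order, which the generator emits in reading order), each
containing component blocks in reactant, condition, product order. A
component block is its start token, four numeric coordinate tokens, for
condition blocks the per-item role token + percent-escaped text (items with
role "other" carry text but no role token), and the end token. Coordinates
quantize as `round(c / extent · (B−1))` clamped to `[0, B−1]`, so
dequantization errs by at most `extent / (2(B−1))` per coordinate; the
default B = 1000 keeps sub-pixel error on typical canvases. Item sub-boxes
are not encoded — the format fixes exactly four coordinates per component —
so decoded items inherit their component's box. Escaping guarantees a text
token can never collide with a structural token, role token or coordinate.
The decoder is total: unbalanced or truncated blocks are dropped with
diagnostics, and random token streams never raise.

## Evaluation

Component correspondence is IoU ≥ τ (default 0.5, reported in output) plus
role agreement; the soft criterion's only relaxation accepts a ground-truth
*molecular* agent — a condition region with at least one agent item whose
text parses as SMILES — predicted as a reactant. Name-only agents get no
relaxation. A step matches when component counts agree and a perfect
matching exists in the component-compatibility bigraph; scheme-level scores
come from maximum-cardinality matching over steps (Kuhn's augmenting paths,
input-order tie-breaks, verified against brute-force injection enumeration
in the tests). Precision with zero predictions is defined as 0, matching
the F1 = 0 convention. Because every hard-mode edge is also a soft-mode
edge, soft P, R and F1 dominate hard for any prediction set — the tests
check this over hundreds of random corruptions rather than assuming it.

Condition items pair greedily by highest item-box IoU within each image.
The CRI confusion matrix is 6 ground-truth roles × (6 predicted roles + a
dedicated "missed" column for unpaired ground truth); unpaired predictions
count into the "other" row; accuracy is the 6×6 trace over the total. OCR
equality normalizes with Unicode NFKC, strips whitespace and drops degree
marks (so "35C", "35 °C" and "35℃" agree). Reaction-SMILES accuracy is
per-image: the predicted reaction *set* must equal ground truth under
canonical multiset equality, order-insensitive across steps; whether the
agent field participates is a flag (`compare_agents`, default on), because
both conventions are defensible and downstream users disagree.

## Numerical and degenerate-input choices

* Quantization at the canvas edge clamps into the last bin; a box outside
  its canvas is a hard error at encode time but only a diagnostic at decode.
* χ²-based pattern-frequency checks run at α = 0.01 with 4000 draws.
* Layout raises on unsatisfiable inputs (a molecule wider than
  `canvas_max_width` at the drawn scale, a cycle with < 3 steps or
  multi-molecule nodes) rather than silently clipping.
* Empty prediction sets, empty condition lists, zero-item pairings and
  empty token streams all take defined zero paths, asserted in tests.

## Problem sizes

The test suite and the acceptance script size their simulations for a
single-CPU run: 1000 layout-only schemes for generator validity (layout
needs no rasterization, so this is seconds), a 40–60 image rendered dataset
for the self-evaluation identities, 500 corrupted prediction sets for the
ordering law, 300 schemes × three bin counts for codec round trips, and
1000 random token streams for decoder totality.
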