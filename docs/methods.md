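# Methods

`rinmut` turns a protein structure into a residue interaction network
(RIN), annotates each residue with a structural and an evolutionary
attribute, and classifies single-residue mutations with a subgraph-based
graph-attention classifier.  This note records the model, its assumptions,
the numerical choices, and what the synthetic benchmark does and does not
establish.

## Residue interaction network

Nodes are residues of a single prepared chain; "legacy" numbering (the
1-based mature-protein numbering, negatives for a signal peptide) is kept
alongside contiguous 0-based node ids through every stage, because
mutation tables quote legacy positions.  Excision plans (closed intervals
in legacy numbering) remove segments — e.g. the activated coagulation
factor VIII convention of dropping the signal peptide (−19..−1), the
a1/a2 acidic linkers (336–372, 711–740) and the B domain (741–1689) —
and the survivor map is the single source of truth for placing mutations
on nodes.

Edges connect residues with at least one heavy-atom pair within 5.0 Å
(peptide-bond neighbors, |Δlegacy| ≤ 1, are excluded: the network models
non-covalent contacts).  Each edge is typed by the contacting atom
classes — main-chain (N, CA, C, O, OXT) vs side-chain — and scored by the
number of qualifying atom pairs, a monotone proxy for probe-contact
scores; only relative order survives the later min–max normalization, so
the proxy choice is immaterial downstream.  `simplify` keeps the single
highest-scoring edge per residue pair (score ties broken by the fixed
priority sc_sc > mc_sc > mc_mc); `normalize_weights` min–max scales
weights to [0, 1], optionally reversing them so that rarer (lower-count)
contacts score higher, and maps an all-equal score set to 1.0.  Networks
computed externally by probe-rolling tools can be imported from edge
lists (plain positions or `Chain:Pos:_:RES` labels) instead; unresolvable
endpoints are skipped and counted.

## Residue attributes

*Relative surface exposure.*  Solvent-accessible surface area is computed
by the Shrake–Rupley method with probe radius 1.4 Å.  Test points are a
golden-spiral lattice (default 960 points per atom), which makes the
computation deterministic without a seed; per-atom accessible area is the
lattice fraction outside all neighboring expanded spheres, and residue
area sums its atoms, so structure totals are additive by construction.
The area is divided by the same residue type's maximum area in an
extended Gly-X-Gly reference tripeptide (packaged published table,
user-overridable).  Ratios are not clipped — chain termini can slightly
exceed 1 — and values above 1.2 are flagged.

*Conservation.*  Either imported from a per-position table (9-step grade
scales and continuous rate scores are both recognized; the internal
convention is always "higher = more conserved", so rate-convention inputs
are flipped on load), or computed from a multiple sequence alignment as
1 − H/ln 20 per focus-row column, with H the Shannon entropy of the
column's amino-acid distribution (gaps excluded).  Missing positions are
mean-imputed and flagged.  This entropy score is a deliberately simple
stand-alone measure; it ignores phylogeny and sequence weighting.

Features are min–max scaled to [0, 1].  Inside cross-validation the
scaling statistics come from the training split's instance nodes only.

## Mutation datasets

Records (position, wild-type, substitution, label) are cleaned by four
ordered rules — multi-phenotype labels (e.g. "Mild/Moderate"), wild-type
mismatches against the retained sequence, stop-codon substitutions,
positions outside the network — each drop logged under the first rule it
violates, so record counts always reconcile.  Phenotypes at the same
position are reduced by majority vote and ties are dropped; an instance
is therefore a position, not a patient report.  Severity labels collapse
mild/moderate to class 0 and severe to class 1 (the clinically salient
positive class).  Percent-of-wild-type values binarize at 50%, with the
exactly-50% boundary assigned to the retained class by convention (the
assay definition's strict inequalities leave it open); the threshold is
configurable.

## Subgraph extraction

The classifier is decoupled: each labeled node is classified from its own
shallow subgraph.  Two extractors are provided with the defaults used
throughout: L-HOP (breadth-first ball of depth L = 2 with a per-node
fan-out budget b = 20, sampled uniformly without replacement from a
generator seeded by (seed, target)), and personalized PageRank (restart
probability 1 − 0.85 at the target; power iteration stopped when the L1
step change falls below ε = 1e−5; the K = 150 highest-scoring reachable
nodes are kept, ties broken by ascending node id).  The damping factor
0.85 is the standard PageRank default; the random walk is
degree-normalized and unweighted by default, with a weighted-walk flag.

## Classifier

Stacked graph-attention layers (4 heads, hidden width 256 split 4×64)
over each subgraph: per destination node and head, attention logits are
the standard additive form (shared linear map, source + destination
terms, LeakyReLU slope 0.2) softmax-normalized over incoming edges
including a self edge.  Head outputs are concatenated between layers and
averaged at the last; ReLU follows every layer.  Each layer combines its
attention message with a skip connection (identity when dimensions
match, a learned projection otherwise) through a scalar residual gate
initialized at zero.  Both pieces are load-bearing.  The skip: in
additive attention the destination term is constant within a softmax, so
attention cannot single out the self edge, and without a skip path the
stack would irreversibly average a node's own attributes — exactly the
signal that determines its label — into the neighborhood mean.  The
gate: with it a deep stack starts out as its skip chain and blends the
attention term in as training proceeds, removing the long
majority-class plateau that 5-layer stacks otherwise spend their first
dozen epochs in.  The target node's
embedding (optionally concatenated with a subgraph mean-pool and/or a
substitution one-hot) feeds a one-hidden-layer MLP (width 256, ReLU) that
emits two logits.

Training: Adam at learning rate 1e−3, batch size 128, cross-entropy
(optional class weighting for imbalanced sets), dropout 0.35 on hidden
representations and the MLP hidden layer (raw input attributes — just a
few scores wide — are not dropped), drop-edge 0.1 removing both
directions of sampled subgraph edges, both active only in training.
Early stopping monitors a stratified 15% validation split with a
configurable patience; the best parameters are restored.  All randomness
flows from one seeded generator: a fixed seed reproduces the training
history bit-for-bit on the same platform.  The forward and backward
passes are written directly in NumPy/SciPy over packed batches of
disjoint subgraphs (block-diagonal edges, segmented softmax per
destination, per-head sparse aggregation); gradients are verified against
central finite differences in the test suite.

## Evaluation

Accuracy, precision, recall and F1 come from the 2×2 contingency table;
0/0 ratios are defined as 0.  Cross-validation is stratified 6-fold with
seeded shuffling (6 folds rather than the more common 10 because the
datasets of interest are small); headline metrics are pooled
(micro-averaged) over the union of held-out predictions, with per-fold
metrics reported alongside.  The pooled accuracy equals the
instance-weighted mean of fold accuracies.  A constant majority-class
predictor scores accuracy equal to the majority ratio and F1 = 0, which
is the floor every model must beat.

## Synthetic benchmark

The generator emulates the statistical structure of curated clinical and
alanine-scan datasets without any real sequence content.  Structures are
idealized chains (3.8 Å consecutive CA distance): extended, helical, or a
self-avoiding random walk confined to a sphere allotting ~110 Å³ per
residue, which produces a realistic burial gradient; side chains carry
the residue type's heavy-atom count as short outward-pointing chains so
surface residues reach realistic relative exposures.  Alignments plant a
conserved column fraction (default 0.45) over 40 rows with a 0.5 per-row
substitution rate in mutable columns.  Mutation labels follow the
burial-and-conservation rule — deleterious iff exposure below its median
AND conservation above its median, medians keeping the rule scale-free —
flipped with probability `label_noise` (default 0.1), subsampled to a
0.66 majority ratio and capped at 300 instances (defaults: 420 residues
so that the subsample is met).  Deliberately malformed rows
(multi-phenotype, wild-type mismatch, stop codon) can be injected to
exercise the sanitation rules.

Because the labels are recoverable from the two node attributes by a
depth-2 rule with accuracy ≥ 1 − noise, the benchmark establishes that
the training pipeline can extract a known signal through the full
structure → network → features → subgraph → classifier path, and that
permuted labels reduce it to the majority-class floor.  It does not
establish clinical performance: real severity labels carry diagnostic
inconsistencies, real conservation is phylogeny-weighted, and real
structures have side-chain packing and contact topology that the
idealized chains only coarsely imitate.

## Problem sizes and budgets

Default test and acceptance runs use the 300-instance benchmark (420
residues), 6-fold cross-validation, and a training schedule of 15 epochs
— with the gated residual all four variants converge well within it —
keeping a full four-variant comparison (3/5 layers × L-HOP/PPR) desk
scale.  The spec-level hyperparameters (heads 4, hidden 256, dropout
0.35, drop-edge 0.1, lr 1e−3, batch 128, L = 2/b = 20, K = 150/ε = 1e−5)
are never changed by the tests.

## Known limitations

- The heavy-atom 5 Å contact criterion replaces probe-rolling with
  hydrogen placement; imported edge lists restore full fidelity.
- Glycine has no side-chain heavy atoms, so sc-typed edges cannot involve
  it; no pseudo-atom is invented.
- Entropy conservation ignores phylogeny; grade-scale imports are mapped
  affinely.
- The classifier is CPU-only NumPy; it is sized for hundreds of labeled
  nodes per dataset, not millions.
- Multi-residue variants, indels and insertion-coded structures are out
  of scope.
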