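# rinmut

Residue interaction networks and subgraph graph-attention classifiers for
predicting the effect of single-residue mutations from protein structure.

## The problem

Missense mutations in large proteins — the motivating case is coagulation
factor VIII, where single substitutions cause hemophilia A of mild,
moderate or severe grade — disrupt function in ways that track two residue
properties: how deeply the residue is buried and how strongly evolution
has conserved it.  `rinmut` operationalizes this as node classification on
a residue interaction network (RIN): the structure becomes a graph
G = (V, ξ) with one node per residue and an edge whenever two residues'
heavy atoms lie within 5 Å, each node carries its relative surface
exposure (solvent-accessible area over the residue type's Gly-X-Gly
reference maximum) and a conservation score, and a classifier f: G → Y
predicts a binary label per mutated residue (severe vs mild/moderate
disease, or disrupted vs retained in-vitro activity).

The classifier follows the decoupled shallow-subgraph design: for each
target residue an extractor pulls a small subgraph — either the L-hop
breadth-first ball (L = 2, fan-out budget b = 20) or the top-K
personalized-PageRank neighborhood (K = 150, ε = 1e−5) — and a graph
attention network (4 heads, hidden width 256, skip connections, dropout
0.35, drop-edge 0.1) embeds it; the target node's embedding feeds an MLP
that emits class logits.  Training uses Adam (lr 1e−3, batch 128) with
early stopping, and evaluation is stratified 6-fold cross-validation with
pooled accuracy/precision/recall/F1.  The forward and backward passes are
implemented directly in NumPy/SciPy (numba-accelerated edge kernels) and
verified against finite differences.

Audience: structural bioinformaticians who want a transparent,
CPU-friendly, fully seeded pipeline from a PDB/mmCIF file (or an imported
edge list plus a conservation table) to per-residue mutation-effect
scores, with every curation step logged.

## Worked example

Everything below runs offline on a synthetic fixture whose mutation
labels are planted by a known rule (buried + conserved ⇒ deleterious,
10% label noise, 0.66 class imbalance), so the expected outcome is known
in advance:

```bash
rinmut make-fixture --out-dir demo --n-residues 120 --n-instances 100 --seed 3
rinmut evaluate \
    --network demo/network.tsv --node-map demo/node_map.tsv \
    --features demo/features.tsv --dataset demo/dataset.tsv \
    --extractor lhop --layers 3 --max-epochs 60 --patience 60 \
    --seed 1 --out-dir demo/eval
```

which prints, for this fixture and seed (about a minute on one CPU):

```
fixture: 120 residues, 523 edges, 97 instances
pooled accuracy 0.804  F1 0.642 (majority ratio 0.660)
```

Reading: a majority-class predictor would score accuracy 0.660 with
F1 = 0; the classifier recovers most of the planted signal (whose noise
ceiling is 0.90) from structure-derived features alone.  The full
metrics report, including per-fold breakdowns and the run manifest, is
in `demo/eval/metrics.json`.  The same
commands accept real inputs: `rinmut build-rin --structure protein.pdb
--chain A --excise "-19:-1,336:372,711:740,741:1689"` parses a structure,
removes the listed legacy segments, and builds the network;
`featurize` accepts an MSA (FASTA) or a precomputed conservation table;
`prepare-data` ingests curated mutation CSVs, logging every dropped
record with its reason.

The same pipeline is available as a library; see `rinmut.cross_validate`,
`rinmut.train_classifier`, `rinmut.predict_nodes`.

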