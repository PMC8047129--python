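# sebiograph

Few-shot knowledge transfer for sparsely labeled biomedical graphs.

Biomedical networks — drug–drug interaction graphs, protein–protein
interaction maps, disease–symptom co-occurrence graphs — are expensive to
annotate: a typical graph carries labels for only a small fraction of its
nodes. `sebiograph` implements a semi-supervised, prototype-based graph
neural network that compensates by *transferring* structure learned on a
bank of related auxiliary graphs to a sparsely labeled target graph. It is
aimed at computational biologists and method developers who need node
classification or link prediction to work with tens, not thousands, of
labels per graph.

## The model

Each graph is `G = (A, N)` with a symmetric adjacency `A ∈ {0,1}^{m×m}` and
node features `N ∈ ℝ^{m×h}`. Four components are trained jointly,
episodically, across the auxiliary graphs:

1. **Gated encoder** `f_θ`. A two-layer graph convolution using the
   renormalized propagation rule `Â = D̃^{-1/2}(A+I)D̃^{-1/2}`. The output
   layer's weight block `α` is shared globally across graphs but modulated
   per graph: `α_i = g_i ∘ α`.
2. **Hierarchical representation gate.** The graph is coarsened level by
   level: a one-layer assignment convolution produces a row-stochastic
   matrix `P` (softmax over community logits), then
   `A^{d+1} = PᵀA^dP`, `N^{d+1} = Pᵀ·FGNN(A^d, N^d)`. Level summaries
   (coordinate-wise max over coarsened rows) are combined by attention
   against a learnable query `q`, and a sigmoid head yields the gate
   `g_i = σ(W_g h_i + b_g) ∈ (0,1)`. Similar graphs thus steer the shared
   encoder toward similar metric spaces — the transfer mechanism.
3. **Structured prototypes.** The support nodes of class `k` are linked
   into an intra-class relation graph weighted by inverse shortest-path
   distance plus shared k-hop-neighborhood overlap; a one-layer prototype
   convolution propagates their embeddings over it and the prototype
   `c^k` is the coordinate-wise max over members. Queries are scored by a
   softmax over negated squared Euclidean distances, giving the episode
   loss `L_i = −Σ_{(n,y)∈Q} log p(y | f_θ(n), {c^k})`.
4. **Reconstruction constraint.** A one-layer decoder convolution maps
   embeddings to `Z` and `L_d = ‖A − ZZᵀ‖²_F` regularizes embedding
   quality. The joint update is `Φ ← Φ − γ∇_Φ [Σ_i L_i + β L_d]`.

At evaluation time the meta-learned parameters are frozen; prototypes are
built from the target's few labeled support nodes and the remaining labeled
nodes are classified by nearest prototype (Micro-/Macro-F1). Link
prediction classifies Hadamard products of endpoint embeddings into
edge/non-edge with the same prototype machinery on an 80/20 edge split.

A seeded synthetic-bank generator (stochastic-block-model topology with a
balanced planted partition, class-conditional Gaussian features with class
means shared across the bank) provides the study conditions: presets
`easy` (separation 5σ, strong communities) and `hard` (1.5σ, weak
communities).

## Worked example

```
$ sebiograph simulate --preset easy --out bank --seed 7
wrote 6 graphs (5 auxiliary + 1 target) to bank

$ echo '{"optimizer": "adam", "gamma": 0.01}' > cfg.json
$ sebiograph train --config cfg.json --bank bank --out model.npz --seed 7
trained 5 epochs (final mean total loss 0.0396); checkpoint -> model.npz, log -> model.log.jsonl

$ sebiograph eval --task node --ckpt model.npz --target bank/target_000 --shots 10
{"task": "node", "micro_f1": 0.99, "macro_f1": 0.98989898989899}

$ sebiograph eval --task link --ckpt model.npz --target bank/target_000
{"task": "link", "accuracy": 0.7660818713450293}

$ sebiograph embed --ckpt model.npz --graph bank/target_000 --out target_emb.tsv
wrote 200x32 embeddings to target_emb.tsv
```

The training loss (mean episode negative log-likelihood plus the weighted
per-entry reconstruction error) falls from ≈1.4 at initialization to
≈0.04. With 10 labeled support nodes per class the frozen model classifies
99% of the target's held-out labeled nodes correctly — the easy preset's
5σ class separation is fully recovered. Link accuracy of ≈0.77 reflects
that edges in a stochastic block model are only probabilistically related
to class structure. The same library calls are available in Python
(`sebiograph.train`, `sebiograph.evaluate_node_classification`, …); the
CLI is a thin wrapper.

On-disk formats are plain TSV: an edge list `u<TAB>v[<TAB>w]`, a feature
table `id<TAB>f1…fh` whose row order fixes the node order, and a label
table `id<TAB>class` with positive-integer classes (absent ids are
unlabeled).

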