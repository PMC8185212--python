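# Methods

## Problem and model

`gatedock` scores rigid-body protein–protein docking models
("decoys"). Given a decoy with a receptor and a ligand subunit, the
question is whether the pose is of CAPRI-acceptable quality — close
enough to the (unknown, at scoring time) native complex in terms of
interface RMSD, ligand RMSD and preserved native contacts.

The scorer represents the decoy's interface as a pair of atom graphs
and learns to read the *intermolecular* geometry:

1. **Interface extraction.** A residue belongs to the interface when
   its minimum heavy-atom distance to any residue of the partner
   subunit is ≤ 10 Å. All heavy atoms of interface residues become
   graph nodes (receptor block first, then ligand, in file order).
2. **Node features.** Each heavy atom carries a 23-dimensional binary
   vector: atom-type one-hot over (C, N, O, S, H) — the H slot is kept
   for shape compatibility but never set, because nodes are heavy
   atoms — then one-hot degree (0–5), attached hydrogens (0–4),
   implicit valence (0–5) and an aromatic flag. Degree, hydrogen
   counts and aromaticity come from a fixed amino-acid template table;
   implicit valence is element valence (C 4, N 3, O 2, S 2) minus the
   observed heavy-atom degree, clamped to 0–5. Decoys are treated as
   unprotonated; file hydrogens are parsed but never featurized.
3. **Two adjacencies.** A¹ holds covalent bonds within each subunit
   (template bonds, peptide bonds C(i)–N(i+1) under 2.0 Å, unit
   diagonal). A² equals A¹ within a subunit and adds, for
   cross-subunit atom pairs within 10 Å, the Gaussian weight
   exp(−(d−μ)²/σ) with learnable scalars μ (init 0.0) and σ (init
   1.0, clamped ≥ 1e-6). Because μ and σ train, the graph object
   stores the raw cross-distance matrix and A² is rebuilt inside
   every forward pass so gradients reach both parameters.
4. **Gate-augmented attention (GAT).** Per layer: transformed
   features x′ = Wx; symmetric bilinear logits
   e_ij = x′ᵢᵀE x′ⱼ + x′ⱼᵀE x′ᵢ on the support of A; attention
   a_ij = softmax over the neighborhood N_i = {j : A_ij > 0}
   multiplied afterwards by A_ij (so binary rows sum to 1 and
   weighted rows sum to ≤ 1); aggregation x″ᵢ = Σ a_ij x′ⱼ; and a
   learned convex gate out = c·x + (1−c)·x″ with
   c = logistic(D·(x‖x″) + b). There is no multi-head splitting and
   no LeakyReLU — the attention is deliberately the symmetric
   bilinear form, and no extra activation is applied inside the layer
   beyond the gate.
5. **Network.** 23→140 affine embedding (no activation); four GAT
   layers, each run with A¹ and A² under *shared* layer parameters;
   after every layer the passed-on embedding is GAT(x, A²) −
   GAT(x, A¹), which cancels all signal except what cross-molecular
   edges contribute; sum pooling over nodes; a 140→128→128→128→1
   fully connected head with rectifiers and a logistic output.
   Dropout 0.3 applies in training mode after the embedding, after
   each subtracted GAT layer and after FC layers 1–3 (every layer
   except the last FC).
6. **Training.** Binary cross-entropy on the logit (stable softplus
   form), Adam with learning rate 0.002 and weight decay 0, batch
   size 32, Glorot-uniform weights and zero biases. Batches are
   exactly class-balanced; an epoch is one pass over the incorrect
   decoys with correct ones resampled (with replacement when scarce).
   Validation accuracy at threshold 0.5 selects the retained
   checkpoint; AUC is reported alongside. Fine-tuning restarts from a
   checkpoint at 0.0002 (or 0.00002 for a second stage).

### Numerical core

No tensor framework is used: `gatedock.autodiff` is a small
reverse-mode engine on float64 numpy arrays (broadcast-aware
arithmetic, batched matmul, the needed nonlinearities, reductions,
masked selection) plus Adam. It exists so that gradients can flow
into the adjacency itself (μ, σ); it is validated against central
finite differences in the test-suite, including the path through A².
Graphs with equal node counts are stacked and processed as one
batched pass; mixed sizes are grouped internally.

Softmax logits are max-subtracted and clipped to ±50 before
exponentiation; entries off the adjacency support get exactly zero
attention. The forward pass shares x′ and the bilinear logits between
the A¹ and A² passes of a layer (they do not depend on the adjacency),
which is an algebraic identity, not an approximation.

## CAPRI metrics

* **Kabsch superposition** via SVD with the determinant sign
  correction, so reflections are never returned.
* **iRMSD**: interface residues are defined on the *native* (10 Å
  rule), matched to the decoy by (chain, residue number, insertion
  code), and the Cα sets are superposed before the RMSD. Residues
  missing a Cα are dropped with a warning; fewer than 3 matched Cα is
  an error.
* **lRMSD**: Kabsch on receptor Cα only; the transform is applied to
  the decoy and the ligand Cα RMSD is reported with no further
  fitting. A translation-only decoy therefore gives exactly ‖t‖.
* **fnat**: native contacts are cross-subunit residue pairs with any
  heavy-atom pair ≤ 5 Å; the decoy preserves a contact if the same
  residue pair (by key) is in contact. A native without contacts is
  an error, not fnat = 0.
* **Quality ladder** (evaluated top-down, RMSD conditions are an OR):
  high if fnat ≥ 0.5 and (lRMSD ≤ 1 or iRMSD ≤ 1); medium if
  fnat ≥ 0.3 and (lRMSD ≤ 5 or iRMSD ≤ 2); acceptable if fnat ≥ 0.1
  and (lRMSD ≤ 10 or iRMSD ≤ 4); else incorrect. The table is data
  (`CAPRI_THRESHOLDS`) so alternative schemes are testable. This is
  the standard CAPRI combination; it is monotone in each metric.
  "Correct" throughout the package means acceptable or better.

## Synthetic decoy generator

Real decoy archives are multi-gigabyte downloads, so the package
fabricates desk-scale benchmarks. A native is two idealized
poly-alanine strands (N, CA, C, O, CB per residue; exact peptide-bond
geometry; C-betas of the two chains facing each other at a 6 Å
backbone separation, ≥ 3 native contacts enforced). Chain lengths per
target are drawn from 6–8 (receptor) and 5–6 (ligand) residues, with
±0.04 Å coordinate jitter for diversity — sizes chosen to keep an
interface of ~55–70 atoms, large enough to exercise every code path
while a full train/evaluate cycle stays in the minutes range on one
CPU core.

Decoys are rigid-body ligand perturbations (rotation about a random
axis through the ligand centroid, then a translation). Quality is
controlled by sampling magnitudes from two regimes — near-native
(≤ 6°, ≤ 0.8 Å) and far (30–150°, 3–8 Å) — and each decoy's label is
*recomputed* from its CAPRI metrics, with bounded resampling when the
realized class misses the requested one, so stored labels always
equal `classify_quality` of the stored metrics, and the positive
fraction (default 0.1, mimicking the ~9% imbalance of real decoy
pools) is met to binomial tolerance.

What the generator does *not* emulate: side-chain chemistry and
packing, clash relaxation, sequence diversity, and the conformational
(non-rigid) component of real decoy error. Passing the learning
experiment therefore demonstrates that the architecture extracts and
learns intermolecular geometric signal end-to-end — not that the
trained toy model transfers to real complexes, which requires
training on real archives via the manifest-driven CLI.

## The learning experiment

`run_synthetic_experiment` generates 8 targets × 60 decoys, trains
for 30 epochs on 6 targets (with a random 15% decoy-level validation
split for checkpoint selection) and scores the 2 held-out targets.
Reported: pooled held-out AUC, top-5/top-10 hit rates, per-target
first-hit ranks and the learned μ, σ. The 30-epoch budget matches
where training converges on this data. Under these conditions the
held-out AUC is expected ≥ 0.85 with a correct decoy in the top 5 of
every held-out target for most seeds; μ and σ move visibly from their
inits, confirming the gradient path through the adjacency.

## Design choices where the design was open

* **Subtraction per layer:** the A²−A¹ difference is taken after
  every one of the four GAT layers (the subtracted embedding is the
  next layer's input), not only at the end.
* **μ, σ are global scalars** shared by all cross edges and all
  layers: the edge model defines a single A².
* **Softmax support** includes the self-loop (unit diagonal); with a
  weighted A² the A_ij multiplier applies after normalization, so
  weighted rows need not sum to 1 — documented behavior, not a bug.
* **Node order** is fixed (receptor first, file order) for
  reproducible serialization; the network is order-invariant anyway
  (tested to 1e-6).
* **Altloc** resolution keeps the first-listed conformer; only the
  first MODEL of multi-model files is read; HETATM and waters are
  skipped; non-template residues fall back to a 1.9 Å distance bond
  rule with element-based typing and aromatic = 0.
* **Tie-breaking** in rankings is stable (input order preserved).

## Known limitations

* Heavy-atom-only graphs; protonation states and file hydrogens are
  ignored by design.
* No symmetry-aware chain mapping for homodimers in the metrics; the
  residue-key correspondence must hold.
* Single-pair (receptor, ligand) complexes only; no mmCIF input.
* The engine is CPU/numpy; throughput is adequate for interface
  graphs of a few thousand atoms but it is not a GPU training stack.
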