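# geoprot

Hybrid sequence–structure protein property prediction: geometric residue
graphs, GVP/GAT graph networks, protein language-model fine-tuning, and three
analysis procedures — integrated-gradients residue saliency, masked-marginal
zero-shot variant scoring, and attention-map contact probing.

## The problem

Protein function is written twice: in the sequence (evolutionary context a
protein language model can read) and in the 3D backbone (the geometry that
actually carries out the function). `geoprot` implements a framework that
combines both. A protein chain becomes a directed k-nearest-neighbour residue
graph (k = 30 by default): node features carry the backbone dihedrals
φ, ψ, ω as sin/cos pairs, a 21-letter one-hot identity, and three unit
direction vectors (to the next Cα, to the previous Cα, toward an ideal Cβ);
edge features carry a 16-component Gaussian radial-basis encoding of the
Cα–Cα distance, a 16-component sinusoidal encoding of the sequence offset,
and the unit Cα→Cα direction.

Two message-passing cores consume this graph:

* **GVP** (geometric vector perceptron) layers operate on tuples `(s, V)` of
  scalar and 3-vector channels so that scalar outputs are invariant and
  vector outputs equivariant under rotations — messages
  `M = GVP(concat(h_n^(j), h_e^(j→i)))`, update
  `U = LayerNorm(h + mean_j Dropout(M))`;
* **GAT** layers use softmax attention over each node's in-neighbourhood
  plus itself, `M = α_ij W h_j`, `U = α_ii W h_i + Σ_j M`.

Five model families share this machinery: a sequence-only classifier on the
language model's pooled [CLS] token; structure-only GVP/GAT networks; and
hybrids whose node scalars are per-residue LM embeddings (`lm_only` for GAT,
`concat(t_i, s_i)` for GVP), trained either **2-stage** (LM frozen) or
**end-to-end** with gradual unfreezing — the head and graph network train to
convergence with the LM frozen, then the LM's transformer layers unfreeze.
Multi-label losses weight each label by inverse positive frequency,
`w_j = max(1, min(10, Σ N_i⁺ / (l·N_j⁺)))`; evaluation reports micro-AUPR,
CAFA protein-centric Fmax and Spearman ρ.

The analysis procedures:

* **Saliency** — integrated gradients along the straight path from the
  embedding of an all-[SEP] ("neutral") sequence to the real embedding,
  summed over the embedding width per residue, compared with binding-site
  annotations by AUROC;
* **Zero-shot variant scoring** — mask all mutated positions in one forward
  pass and score `Σ_{i∈M} log p(mt_i | x_\M) − log p(wt_i | x_\M)`, evaluated
  by Spearman ρ against assay values;
* **Contact probing** — an L1-penalised logistic regression from symmetrized
  per-(layer, head) attention values to true contacts (Cα distance ≤ 10 Å,
  |i−j| ≥ 6), scored by precision over the top-L ranked pairs.

Everything differentiable runs on a compact NumPy reverse-mode autodiff
engine inside the package, in float64 and single-device, so fixed seeds
reproduce training bitwise. A deterministic mini-transformer stub
(`StubProteinLM`) satisfies the full embedder contract offline; an adapter
for HuggingFace masked protein LMs is provided behind the optional `lm`
extra.

## Worked example

```python
from geoprot import (ProteinPropertyPredictor, make_structure_task,
                     residue_saliency)

task = make_structure_task(260, seed=42)        # synthetic helix-content task
est = ProteinPropertyPredictor(
    family="gvp", task="multilabel", hidden_scalar=24, hidden_vector=4,
    learning_rate=1e-3, batch_size=16, max_epochs=50, patience=10, seed=0)
est.fit(task.structures[:200], task.labels[:200])
print("held-out micro-AUPR:", est.score(task.structures[200:], task.labels[200:]))

prof = residue_saliency(est, task.structures[0], target_index=0, steps=64)
print("top residue:", int(prof.scores.argmax()) + 1,
      "completeness gap:", prof.completeness_gap)
```

Output from this exact run:

```
held-out micro-AUPR: 0.9936974789915966
top residue: 13 completeness gap: 0.0018631271388073042
```

AUPR 0.994 says the structure-only GVP almost perfectly ranks held-out
chains by whether their helix content crosses the 0.5 threshold — the
dihedral features carry that signal directly, so this is a sanity scale, not
a benchmark. The completeness gap (relative difference between the summed
attributions and F(x) − F(x′)) near 2e-3 confirms the integrated-gradients
quadrature has converged at 64 steps.

A thin CLI wraps the same library calls:

```bash
geoprot synth task --seed 1 --n 20 --out demo/
geoprot parse demo/protein_0000.pdb --chain A --out demo/p0.json
geoprot featurize demo/protein_0000.pdb --mode lm_concat --out demo/p0.npz
geoprot zeroshot demo_scan/wildtype.fasta demo_scan/scan.tsv --out scores.tsv
```

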