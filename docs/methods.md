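# Methods

This note records the scientific and numerical choices behind `geoprot`:
what the models assume, which parameters matter, what the synthetic data
emulates (and does not), and where the design was genuinely open.

## Residue graphs

A chain of L residues becomes a directed graph in which node *i* receives
edges from its min(k, L−1) nearest residues by Cα Euclidean distance
(k = 30 default). Distances are computed in double precision and quantized
to 1e-6 Å before the stable sort, so exact geometric ties — common in
idealized chains — break by residue index and the edge set is invariant
under rigid transforms despite float noise. For L ≤ a few hundred an
exhaustive all-pairs sort is cheaper and simpler than a spatial index.

Node scalars (width 27 in `onehot` mode): sin/cos of φ, ψ, ω (IUPAC signs;
φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N–Cα–C–N(i+1), ω(i) = Cα–C–N–Cα(i+1))
plus a 21-letter one-hot (20 standard residues + X for anything else).
Undefined angles — the first φ, the last ψ/ω, degenerate quadruples — are
encoded as (0, 0) rather than dropping residues, so node count always equals
sequence length; the (0, 0) pair is outside the unit circle that defined
angles live on, which lets a network distinguish "undefined" from any real
angle. Terminal direction vectors are likewise exact zero vectors with a
defined-mask.

Node vectors (ν = 3): unit vectors to the next Cα, to the previous Cα, and
from Cα toward an *ideal* Cβ reconstructed from the local N–Cα–C frame
(bond 1.522 Å, N–Cα–Cβ angle 110.4°, C–N–Cα–Cβ torsion −122.5°). Using the
imputed direction rather than an observed Cβ makes the feature a pure
function of the backbone, defined for glycine, and chirality-aware (the
frame construction uses a cross product, so mirror images featurize
differently in the vector channel while scalar features are insensitive to
handedness only through the dihedral signs, which do flip under reflection
— the networks' invariance claims therefore concern transforms of the
vector channel and proper rigid motions of coordinates).

Edge scalars (width 32): 16 Gaussian RBFs of the Cα–Cα distance with
centers evenly spaced on [0, 20] Å and width equal to the center spacing
(20/15 Å; matching the spacing gives ≈50 % overlap between neighbouring
basis functions, the usual choice); 16
sinusoidal positional-encoding dimensions of the signed offset j − i
(the Transformer recipe; 16 dims suffice to make all offsets in ±30
distinct). Edge vector (μ = 1): the unit Cα→Cα direction.

## Backbone parsing

PDB files are read with biotite: first model only, altlocs resolved by
highest occupancy then first-listed, HETATM amino acids (e.g.
selenomethionine) accepted, non-standard residues mapped to X. Residues
missing any of N/Cα/C are dropped with a warning because every feature
needs the full frame; missing O is tolerated (unused downstream). These
conventions are this package's own — selection rules for multi-model or
multi-altloc entries are rarely stated by structure-based models.

## The GVP and GAT cores

The GVP transform follows the row-norm construction: vectors pass through a
learned map over the vector-count axis, their row norms join the scalar
channel, the scalar output takes a pointwise ReLU, and the vector output is
a second learned map gated by a sigmoid of a scalar-derived signal. Scalars
therefore see the vector channel only through norms (rotation-invariant);
vector outputs are linear maps of vector inputs scaled by invariants
(rotation-equivariant by construction). One GVP per message by default, matching the single application in the
message equation; the depth is configurable since stacked variants exist.

The convolution layer computes messages from the concatenation of
source-node and edge features, averages over incoming messages, applies
dropout (rate 0.1; whole vector rows are dropped so equivariance survives),
and updates with residual + normalisation. "LayerNorm" on the vector
channel is undefined in the update equation as written; here the vector
channel is rescaled by the reciprocal of its mean row norm — an invariant
per-node scalar, the simplest normalisation that cannot break equivariance.

GAT uses the original recipe — shared linear map, additive pairwise score
through LeakyReLU (slope 0.2), softmax over the in-neighbourhood including
self — with a single head by default (configurable). Its update `α_ii W h_i + Σ_j α_ij W h_j` is exactly
the softmax-including-self form.

Readouts concatenate per-node features across the three layers, then pool
over residues: sum for GAT, mean for GVP, with vector row norms appended as
invariant scalars so the pooled representation is flat. A dense layer maps
the pooled vector to a 400-wide penultimate representation before the task
head.

## Language-model embedders

The embedder contract: per-residue embeddings with special tokens stripped;
a tanh-pooled [CLS] vector; masked-position amino-acid distributions with
*all* requested positions masked in a single forward pass; row-stochastic
per-(layer, head) attention maps, stripped of special tokens and
renormalised (the stripping convention is this package's bookkeeping
choice). The reference implementation is a 2-layer, 2-head, width-16
transformer with seed-fixed random weights — deterministic, CPU-cheap
(L = 200 forward ≪ 0.1 s), and sufficient for every contract property the
downstream analyses rely on. It is *not* pretrained: its distributions
carry no biology, which is exactly why the synthetic mutational scans plant
the stub's own scores as ground truth (below). The token-embedding table is
excluded from gradient flow permanently; fine-tuning touches transformer
layers and heads only.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), MSE for regression, label-weighted BCE on
logits for multi-label (weights `max(1, min(10, ΣN⁺/(l·N_j⁺)))`, applied to
both the positive and negative terms of label j, computed on the training
split). Early stopping on validation loss with patience 10 and a 200-epoch
cap; the benchmark-scale hyper-parameter grid is {1e-4, 1e-5, 1e-6} ×
{16, 32} selected by validation loss, while desk-scale experiments use a
single point (1e-3, 16) since the tiny networks would not move in 50 epochs
at 1e-6.

Gradual unfreezing: phase 1 trains the graph network and head with the LM
frozen, "until convergence" operationalized as the same early-stopping
criterion; phase 2 unfreezes the LM's transformer layers, re-initialises
the optimizer (logged in the history), and runs a second early-stopped
phase with the same per-phase epoch budget. The best-validation state is
carried across phases as the incumbent, so the model selected by the
schedule can only improve on phase 1 — which also makes the 2-stage
configuration *exactly* phase 1 of end-to-end: at a fixed seed their
histories coincide epoch for epoch.

While the LM is frozen its embeddings are computed outside the autodiff
graph; this is numerically identical to freezing via masked gradients and
substantially cheaper. All arithmetic is float64 single-device NumPy, so
fixed seeds reproduce entire training histories bitwise.

## Analyses

**Integrated gradients** uses midpoint quadrature (steps default 64; the attribution is defined as an
integral, and the quadrature rule is this package's numerical choice). The attribution surface is the
L×h embedding matrix for sequence-bearing models (baseline: embedding of an
all-[SEP] sequence of the same length) and the residue-identity channel
with a zero baseline for structure-only models; coordinates are never
interpolated. The logit, not the probability, is attributed for multilabel
outputs. The completeness gap is reported *relative* to F(x) − F(x′); on an
untrained network that difference can be near zero and the relative gap
ill-conditioned, so completeness checks run on fitted models, where the gap
at 256 steps is well under 1 %. The sequence-only family's pooled-[CLS]
output is not a function of the stripped embedding matrix, so its
attribution surface is the mean-pooled embedding — a documented surrogate.

**Zero-shot scoring** masks all mutated positions jointly (the scoring
formula conditions every term on x_\M, which requires the joint mask; for
multi-mutants this genuinely differs from summing single-mask scores, and a
test asserts that difference). Substitution notation "A123G", semicolons
for multi-mutants; insertions/deletions are rejected.

**Contact probing** defines contacts as Cα distance ≤ 10 Å at |i−j| ≥ 6,
symmetrizes attention as (A[i,j] + A[j,i])/2 (average-product correction
is available behind a flag, off by default),
pools pairs across training proteins into one regression, and selects the
L1 strength on a held-out split by log-loss. The penalty is interpreted
against the per-sample-averaged loss (solver C divided by n), so
duplicating rows leaves the fit unchanged. Precision is reported @L
(top-L ranked eligible pairs, L = protein length), the field's standard
convention; proteins with fewer than L eligible
pairs use all of them, flagged.

## Synthetic data: what it shows and what it cannot

`build_chain` places backbone atoms sequentially from internal coordinates
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard bond angles), so a chain
built from stated torsions re-measures to < 1e-3°; chirality matches
L-amino acids (the ideal-Cβ construction lands within 0.01 Å of the
standard reconstruction coefficients on an ideal frame). The labeled task
mixes helix (φ = −57°, ψ = −47°), strand (−139°, 135°) and coil segments;
the binary label is helix fraction ≥ 0.5, with sequences coupled to
secondary structure through residue-propensity pools so sequence models
also carry signal. Segment lengths 4–8 and a uniform helix-content target
keep label balance within [0.3, 0.7] at n ≥ 50. Mutational scans plant
`assay = stub masked-marginal score + N(0, σ)` with σ = 0.1 by default —
a parameter-recovery design in which the true ranking is known exactly.

Passing tests on these fixtures demonstrate the *mechanics* — equivariance,
oracle-exact featurization, optimisation, attribution convergence, signal
recovery — not biological performance. The chains are idealized (no packing,
no sidechains, no crystallographic noise), the stub LM knows no evolution,
and the desk-scale tasks are nearly separable by construction. Benchmark
conclusions (relative orderings of the model families on real GO/TAPE data)
are mirrored only directionally: on the synthetic hybrid task the
end-to-end schedule's median final validation loss over 3 seeds is no worse
than the 2-stage schedule's, which the incumbent-carrying design in fact
guarantees whenever phase 2 does not help and strictly improves when it
does.

## Problem sizes used

The reported experiments use n = 200 training / 60 held-out chains of
length 25–35 for the structure-only task (hidden widths 24 scalar /
4 vector, 3 layers, ≤ 50 epochs); n = 60 chains of length 20–28 for the
3-seed schedule comparison (16/4, per-phase cap 15, patience 5); 100 random
chains of L ≤ 40 for featurizer oracle agreement; 20 structures × ~3
transforms × random-weight models for the invariance suite; 256 quadrature
steps for the completeness check; 200-record scans for zero-shot recovery.
These sizes were chosen so the full pipeline exercises every component in
minutes on one CPU core.

## Known limitations

* No mmCIF input, no multi-chain complexes, no sidechain torsions or
  solvent accessibility features.
* The pretrained-LM adapter requires the optional `transformers`/`torch`
  stack and local weights; it shares the stub's conformance contract but is
  not exercised by the offline test suite.
* The NumPy autodiff engine is tuned for these architectures (graph
  gathers, segment reductions, GVP algebra), not a general DL framework;
  very deep or very wide configurations will be slow.
* Fmax follows the CAFA protein-centric convention (precision averaged over
  proteins with ≥1 prediction at the threshold); published numbers computed
  under other conventions are not directly comparable.
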