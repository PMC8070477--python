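# Methods

## Model

The package scores protein–ligand binding affinity, expressed as
pKa = −log10 K (K a dissociation/inhibition constant in molar), from
the covalent topology of the binding pocket and the ligand alone. Both
molecules are featurized as graphs — atoms as nodes, chemical bonds as
edges — and concatenated into one complex graph with *no* cross edges:
the non-covalent interface is deliberately not encoded, so the model is
applicable to protein/ligand pairs that have never been docked, and no
3D conformation is required anywhere.

Each atom carries a 75-dimensional feature vector in a fixed layout:

| group | width | encoding |
|---|---|---|
| element | 44 | one-hot over 43 named elements + "unknown" |
| degree | 11 | one-hot, bins 0–10 |
| explicit valence | 7 | one-hot, bins 0–6 |
| formal charge | 1 | raw signed value |
| radical electrons | 1 | raw value |
| hybridization | 5 | one-hot over SP, SP2, SP3, SP3D, SP3D2 |
| aromaticity | 1 | flag |
| total hydrogens | 5 | one-hot, bins 0–4 |

Counts above a bin's top value clamp to the top bin with a logged
warning; unlisted hybridizations clamp to SP3. Each bond carries a
6-dim indicator: [single, double, triple, aromatic, conjugated,
in-ring]; every undirected bond is stored as two directed edges with
identical features so neighbor aggregation is one pass over incoming
edges.

The network is a cascade:

1. **Linear embedding** X′ = XW + b (75 → m₁, no activation). Its only
   job is densifying the sparse one-hot input.
2. **ARMA stage.** With L = D^{−1/2}AD^{−1/2} and L̃ = I − L, each of K
   parallel stacks runs T recursion steps
   X̄⁽ᵗ⁺¹⁾ = σ(L̃ X̄⁽ᵗ⁾ Wₜ + X Vₜ), X̄⁽⁰⁾ = X,
   and the K final states are averaged (the average itself is linear).
   σ is ReLU; weights are per-stack, per-step (no sharing). Zero-degree
   nodes get zero rows in L, no self-loops are added — the +XVₜ skip
   term plays that role.
3. **MPNN stage.** One (configurable) edge-conditioned convolution
   x_i′ = x_i + Σ_{j∈N(i)} Θ(e_ij)·x_j, where Θ is a small dense
   network (6 → 32 → d²; ReLU) mapping the bond vector to a d×d message
   matrix. Stacked layers get fresh parameters with ReLU between;
   no activation sits between the ARMA and MPNN stages.
4. **Global add pool** (per-graph sum of node states) followed by a
   dense head m₁ → m₁/2 → 1 (ReLU between, linear output).

Ablation variants `arma_only` and `mpnn_only` drop one stage via
config; `arma_only` is numerically identical to `mpnn_layers: 0`.

## Defaults and training

Defaults follow the best grid-search cell of the architecture study:
embedding width m₁ = 128, T = 5 ARMA steps, 1 MPNN layer. The number
of parallel stacks K is a free hyperparameter (default 3), as is the
edge-network hidden width (32) and the head shape. Training uses
smooth-L1 loss (Huber, β = 1), Adam, Glorot-uniform initialization with
zero biases, initial learning rate 1e−4 halved every 20 epochs
(the decay factor 0.5, batch size 32 and 200 epochs are package
choices, config-exposed). When a validation set is supplied, the
checkpoint with the best validation RMSE is returned, otherwise the
final parameters. All randomness (init, shuffling, synthetic data) is
driven by explicit seeds; repeated CPU runs reproduce loss traces
exactly.

The tensor machinery is an in-package reverse-mode autodiff tape over
numpy (float64): dense matmuls, gathers, segment sums and a batched
matrix-vector product cover every layer above, and gradients are
verified against central finite differences in the test suite.
Batches are disjoint unions of complex graphs with a per-node graph id;
because L is block-diagonal across graphs, batched forward equals
per-graph forward to float precision.

## Evaluation

`evaluate` reports RMSE, Pearson R, MAE and SD. SD — the CASF
dispersion statistic — is not given a formula in most scoring-function
papers; here it is the standard deviation of prediction residuals
about the least-squares line of predictions on labels, normalized by
n − 1. Ranking power takes clusters of three complexes of one target:
*high-level* success requires the full predicted order to match the
true order, *low-level* only that the top-affinity complex is ranked
first. Ties in predictions count as failures (conservative; the
convention is otherwise undefined). Dataset splitting mirrors the
PDBbind protocol: the core set is the test set, a seeded random sample
of the remainder is validation, and ids overlapping an external test
set (the CASF dedup rule) are removed from training.

## Synthetic data

`fixtures` generates random connected molecules (spanning tree plus
ring-closing edges, simple degree ≤ 4, valence capped per element over
the alphabet C/N/O/S/P) with self-consistent attributes: hydrogens fill
the default valence, double bonds are only placed where both atoms have
spare valence, hybridization is SP2 at double bonds. All attribute
values fall inside the featurization bins, so clamping never fires on
generated data.

Each complex's label is *planted*: pKa = 1.0 + Σ_e w_e·count(e) over
the pocket-plus-ligand element composition (w = C 0.12, N 0.25, O 0.20,
S 0.35, P 0.30), optionally + 0.4 per independent ring when the
topology-dependent variant is enabled, plus Gaussian noise (default
SD 0.1 pKa), clipped to [0, 14]. A composition-linear target is exactly
representable from the pooled graph representation, so end-to-end
learnability tests the wiring (featurization → convolution → pooling →
head → gradients) rather than model expressiveness. Default problem
sizes are desk-scale: pockets of 16–32 atoms (real pockets are larger),
ligands of 6–16, 250 complexes.

What the generator does **not** emulate: real residue chemistry and
protonation states, aromatic systems, charged or metal-containing
pockets, the size and redundancy structure of PDBbind, and — most
importantly — any physical relationship between structure and affinity.
A passing learnability test therefore demonstrates a correctly wired,
trainable implementation, not benchmark-level accuracy on real data;
the published benchmark figures require the full PDBbind/CASF downloads
and GPU-scale training and are out of scope here.

The learnability experiment (200 train / 50 held-out complexes,
noise off) uses a reduced configuration — embedding 32, K = 2, T = 3,
1 MPNN layer, lr 1e−3 halved every 50 of 150 epochs — chosen once as a
desk-scale setting; it reaches train RMSE < 0.1 and held-out
Pearson R > 0.9.

## Numerical choices and edge cases

- Float64 throughout; layer forwards agree with their per-node loop
  oracles to ~1e−15, far inside the 1e−6 contract.
- Empty molecules are rejected at graph construction; structures rdkit
  cannot sanitize raise a parse error carrying the complex id, and
  dataset assembly discards exactly those entries (logged).
- Zero-variance prediction or label vectors make Pearson R undefined
  and raise rather than return NaN.
- mol2 ligands are converted to PDB with the openbabel CLI and then
  read with rdkit, falling back to rdkit's native mol2 reader when
  obabel is not on PATH. PDB parsing trusts CONECT records and disables
  proximity-based bond perception, which suits fixture-written files
  and pocket files with explicit connectivity.
- Graph caches and checkpoints are npz containers; checkpoints embed
  the full model config (JSON) and its hash.

## Known limitations

- Dense n×n normalized adjacency per batch: fine up to a few thousand
  nodes per batch, not intended for full-protein graphs.
- CPU-only and numpy-based: throughput is desk-scale; the contract
  (identical results to the loop oracles) would carry over unchanged to
  a GPU implementation.
- Conjugation/hybridization perceived by rdkit on file round-trips can
  legitimately differ from the generator's simple assignments (e.g.
  amide nitrogens perceived SP2); topology, elements, valences and
  hydrogen counts are the round-trip-stable attributes.
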