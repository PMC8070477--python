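# apmnet

Cascade graph-convolutional scoring of protein–ligand binding affinity.

Predicting how tightly a small molecule binds a protein target — the
binding affinity, reported as pKa = −log₁₀ K for a dissociation or
inhibition constant K — is a core step in structure-based drug
discovery. This package implements a scoring function that needs only
the covalent topology of the binding pocket and the ligand: both are
represented as molecular graphs (75-dim one-hot atom features, 6-dim
bond features), concatenated without cross edges, and passed through a
two-stage graph network

1. a linear embedding X′ = XW (densifying the sparse one-hot input),
2. an **ARMA** graph filter, K parallel stacks of the recursion
   X̄⁽ᵗ⁺¹⁾ = σ(L̃ X̄⁽ᵗ⁾ Wₜ + X Vₜ) with L̃ = I − D^(−1/2)AD^(−1/2),
   averaged over stacks,
3. an **edge-conditioned message-passing** layer
   x_i′ = x_i + Σ_{j∈N(i)} Θ(e_ij)·x_j, where a small network Θ turns
   each bond vector into a message matrix,
4. a global add pool Σᵢ x_i′ and a dense head producing the scalar pKa.

Training uses smooth-L1 loss, Adam, Glorot initialization and a stepped
learning-rate schedule. Evaluation reports RMSE, Pearson R, MAE, the
CASF dispersion statistic SD, and CASF-style ranking power (fraction of
three-ligand clusters ordered correctly). Everything runs on CPU: the
layers are implemented on numpy with an in-package autodiff tape, and
each graph convolution ships with an independent per-node loop oracle
it is tested against.

Because the full PDBbind/CASF benchmarks require large downloads and
GPU-scale training, the package is exercised end to end on synthetic
pocket–ligand complexes with a *planted*, composition-linear affinity
function that a correctly wired model can learn — see
`docs/methods.md` for what this does and does not demonstrate.

## Worked example

```python
import numpy as np
from apmnet import (SyntheticSpec, make_synthetic_dataset, ApmnetConfig,
                    TrainConfig, train, forward, evaluate)

spec = SyntheticSpec(n_complexes=250, noise_sd=0.0, seed=7)
data = make_synthetic_dataset(spec)
train_set, test_set = data[:200], data[200:]

model_cfg = ApmnetConfig(embed_dim=32, arma_layers=3, arma_stacks=2,
                         mpnn_layers=1, edge_hidden=16)
train_cfg = TrainConfig(lr=1e-3, epochs=150, batch_size=32, seed=7,
                        lr_step=50, lr_gamma=0.5)
params, trace = train(train_set, model_cfg, train_cfg)

preds = forward(test_set, params, model_cfg)
labels = np.array([cg.label for cg in test_set])
report = evaluate(preds, labels)
print(f"held-out RMSE {report.rmse:.3f}  Pearson R {report.pearson_r:.3f}")
```

Output:

```
held-out RMSE 0.315  Pearson R 0.991
```

The 250 complexes carry a noise-free label linear in their element
composition; after 150 epochs the model predicts held-out affinities
with Pearson R ≈ 0.99 and RMSE ≈ 0.32 pKa units (train RMSE ≈ 0.07),
confirming that featurization, both convolution stages, pooling and
the training loop are wired correctly.

The same pipeline is available from the shell on PDBbind-layout
directories (real or synthetic):

```sh
apmnet --config run.yaml --seed 7 synth     # write a fixture dataset
apmnet --config run.yaml --seed 7 prepare   # parse + cache graphs, split
apmnet --config run.yaml --seed 7 train     # checkpoint + loss trace
apmnet --config run.yaml --seed 7 evaluate --split test
```

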