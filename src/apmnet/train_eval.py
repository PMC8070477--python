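"""Training loop, regression metrics, CASF-style ranking power and
PDBbind-style dataset splitting.

Training minimizes the smooth-L1 (Huber, beta=1) loss with Adam and a
stepped learning-rate schedule (initial 1e-4, multiplied by a decay
factor every 20 epochs by default). Runs are fully seeded: data order
comes from a seeded RNG and parameter initialization from the model
seed, so two runs with the same configuration produce identical loss
traces on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._autodiff import Tensor, smooth_l1_loss
from .model import ApmnetConfig, ApmnetParams, forward, forward_tensor, init_params
from .molgraph import ComplexGraph


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_step: int = 20
    lr_gamma: float = 0.5
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not self.lr >= 0:
            raise ValueError("lr must be >= 0")
        if self.lr_step < 1:
            raise ValueError("lr_step must be >= 1")


@dataclass
class EvalReport:
    rmse: float
    pearson_r: float
    mae: float
    sd: float
    n: int

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "pearson_r": self.pearson_r,
                "mae": self.mae, "sd": self.sd, "n": self.n}


@dataclass
class RankingReport:
    high_level_rate: float
    low_level_rate: float
    n_clusters: int

    def to_dict(self) -> dict:
        return {"high_level_rate": self.high_level_rate,
                "low_level_rate": self.low_level_rate,
                "n_clusters": self.n_clusters}


@dataclass
class SplitSpec:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    extra_test_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        groups = [set(self.train_ids), set(self.val_ids),
                  set(self.test_ids), set(self.extra_test_ids)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be pairwise disjoint")


def smooth_l1(pred: np.ndarray, true: np.ndarray) -> float:
    """Mean smooth-L1 loss: 0.5 r^2 for |r| < 1, |r| - 0.5 otherwise."""
    pred = np.asarray(pred, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("inputs must be non-empty and of equal length")
    r = pred - true
    return float(np.where(np.abs(r) < 1, 0.5 * r * r,
                          np.abs(r) - 0.5).mean())


class Adam:
    """Adam on the autodiff parameter tensors (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def train(dataset: Sequence[ComplexGraph], model_cfg: ApmnetConfig,
          train_cfg: TrainConfig,
          val_dataset: Optional[Sequence[ComplexGraph]] = None,
          params: Optional[ApmnetParams] = None,
          ) -> tuple[ApmnetParams, list[float]]:
    """Train on labelled complexes; returns (params, per-epoch loss trace).

    With a validation set, the returned parameters are the checkpoint
    with the best validation RMSE; otherwise the final parameters.
    Raises :class:`TrainingDivergedError` on a non-finite loss.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training set")
    if any(cg.label is None for cg in dataset):
        raise ValueError("all training complexes must carry labels")
    rng = np.random.default_rng(train_cfg.seed)
    if params is None:
        params = init_params(model_cfg, seed=train_cfg.seed)
    opt = Adam(params.parameters(), lr=train_cfg.lr)
    trace: list[float] = []
    best_val = np.inf
    best_values = None
    for epoch in range(train_cfg.epochs):
        opt.lr = train_cfg.lr * train_cfg.lr_gamma ** (epoch // train_cfg.lr_step)
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(dataset), train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            batch = [dataset[i] for i in idx]
            labels = np.array([cg.label for cg in batch])
            opt.zero_grad()
            preds = forward_tensor(batch, params, model_cfg)
            loss = smooth_l1_loss(preds, labels)
            if not np.isfinite(loss.value):
                raise TrainingDivergedError(epoch)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value)
            n_batches += 1
        trace.append(epoch_loss / n_batches)
        if val_dataset:
            val_preds = forward(list(val_dataset), params, model_cfg)
            val_labels = np.array([cg.label for cg in val_dataset])
            val_rmse = float(np.sqrt(np.mean((val_preds - val_labels) ** 2)))
            if val_rmse < best_val:
                best_val = val_rmse
                best_values = params.copy_values()
    if best_values is not None:
        params.load_values(best_values)
    return params, trace


def evaluate(preds: np.ndarray, labels: np.ndarray) -> EvalReport:
    """RMSE, Pearson R, MAE and the CASF dispersion statistic SD.

    SD is the standard deviation of prediction residuals about the
    least-squares line of predictions on labels (normalized by n-1).
    Raises on zero variance in either vector (Pearson undefined).
    """
    preds = np.asarray(preds, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if preds.size == 0 or preds.shape != labels.shape:
        raise ValueError("inputs must be non-empty and of equal length")
    n = preds.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.std(preds) == 0 or np.std(labels) == 0:
        raise ValueError("zero variance: Pearson R undefined")
    resid = preds - labels
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    r = float(np.corrcoef(labels, preds)[0, 1])
    slope, intercept = np.polyfit(labels, preds, 1)
    line_resid = preds - (slope * labels + intercept)
    sd = float(np.sqrt(np.sum(line_resid ** 2) / (n - 1)))
    return EvalReport(rmse=rmse, pearson_r=r, mae=mae, sd=sd, n=n)


def ranking_power(clusters: Sequence[Sequence[tuple[float, float]]]
                  ) -> RankingReport:
    """CASF ranking power over clusters of three (true, predicted) pairs.

    High-level success: the predicted order of all three complexes
    matches the true order. Low-level success: the complex with the
    highest true affinity also has the highest prediction, regardless
    of how the other two are ordered. Ties in predictions count as
    failures. Rates are percentages over clusters.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters supplied")
    high = low = 0
    for c, members in enumerate(clusters):
        if len(members) != 3:
            raise ValueError(f"cluster {c} has {len(members)} members, "
                             "expected 3")
        true = np.array([m[0] for m in members], dtype=np.float64)
        pred = np.array([m[1] for m in members], dtype=np.float64)
        if len(np.unique(true)) != 3:
            raise ValueError(f"cluster {c} has tied true affinities")
        if len(np.unique(pred)) != 3:
            continue  # tied predictions: failure at both levels
        true_order = np.argsort(true)
        pred_order = np.argsort(pred)
        if np.array_equal(true_order, pred_order):
            high += 1
        if true_order[-1] == pred_order[-1]:
            low += 1
    n = len(clusters)
    return RankingReport(high_level_rate=100.0 * high / n,
                         low_level_rate=100.0 * low / n, n_clusters=n)


def make_splits(index_ids: Sequence[str], core_ids: Sequence[str],
                casf_ids: Sequence[str] = (), n_val: int = 1000,
                seed: int = 0) -> SplitSpec:
    """PDBbind-style split: test = core set; validation = seeded random
    sample from the remainder; train = what is left minus any overlap
    with the extra (CASF) test set."""
    index_ids = sorted(set(index_ids))
    core = set(core_ids)
    if not core <= set(index_ids):
        raise ValueError("core ids must be a subset of the index")
    pool = sorted(set(index_ids) - core)
    if n_val > len(pool):
        raise ValueError(f"n_val={n_val} exceeds {len(pool)} available "
                         "non-core complexes")
    rng = np.random.default_rng(seed)
    val = sorted(rng.choice(pool, size=n_val, replace=False).tolist())
    casf = set(casf_ids)
    train = sorted(set(pool) - set(val) - casf)
    return SplitSpec(train_ids=train, val_ids=val, test_ids=sorted(core),
                     extra_test_ids=sorted(casf & set(index_ids)))
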