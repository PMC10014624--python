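"""Fivefold cross-validation training, soft-voting ensemble, cycle protocol.

The training set is split into five stratified folds; each fold trains one
model (four parts train, one validates) and the independent test set is
scored by all five.  The five positive-class probabilities per test record
are averaged (soft voting) and thresholded at 0.5 - a tie at exactly 0.5
is called positive.  The stability protocol repeats the whole procedure
for several cycles with fresh fold assignments and initializations and
summarizes each metric as mean +/- population standard deviation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _autodiff as ad
from .encoders import encode_dataset
from .metrics import MetricsReport, summarize
from .network import NetworkConfig, build_model
from .seq_io import LabeledDataset

logger = logging.getLogger(__name__)

N_FOLDS = 5

#: the six architecture variants of the ablation study
ABLATION_BACKBONES = (
    "resnet",
    "densenet",
    "densenet+channel",
    "densenet+spatial",
    "densenet+serial_cbam",
    "densenet+parallel_cbam",
)


@dataclass
class TrainConfig:
    """Optimization settings (Adam; best-validation-accuracy selection)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 8          # early stop after this many epochs without val improvement
    min_epochs: int = 1
    scheme: str = "onehot+ncp"
    vote: str = "soft"         # or "hard": majority of per-fold labels
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldPlan:
    """Stratified fold index per training record, reproducible from seed."""

    fold_assignments: np.ndarray
    seed: int
    n_folds: int = N_FOLDS

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, validation indices) for one fold."""
        val = np.flatnonzero(self.fold_assignments == fold)
        trn = np.flatnonzero(self.fold_assignments != fold)
        return trn, val


@dataclass
class PredictionRecord:
    """Per-test-record fold probabilities and the soft-voted call."""

    record_id: str
    fold_probs: list[float]
    mean_prob: float
    label_pred: int


@dataclass
class EnsembleModel:
    fold_models: list
    cfg: NetworkConfig
    train_cfg: TrainConfig
    layer: int = 1
    backbone: str = "densenet"


def make_folds(dataset: LabeledDataset, n_folds: int = N_FOLDS, seed: int = 0) -> FoldPlan:
    """Stratified partition into n_folds; sizes differ by at most one."""
    if len(dataset) == 0:
        raise ValueError("cannot fold an empty dataset")
    y = np.asarray(dataset.labels)
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError(f"fewer than {n_folds} records in one class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assign = np.empty(len(y), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assign[val_idx] = fold
    return FoldPlan(fold_assignments=assign, seed=seed, n_folds=n_folds)


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _accuracy(model, x, y) -> float:
    if len(x) == 0:
        return float("nan")
    probs = model.predict_proba(x)
    return float(((probs[:, 1] >= 0.5).astype(int) == y).mean())


def train_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: NetworkConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
    backbone: str = "densenet",
):
    """Train one fold model; returns (model at best val accuracy, history).

    Mini-batch Adam with shuffling; the parameter snapshot with the best
    validation accuracy across epochs is restored at the end.  Training
    stops early after ``patience`` epochs without improvement.  A NaN loss
    aborts with a diagnostic.
    """
    model_cfg = NetworkConfig.from_dict({**cfg.to_dict(), "seed": seed})
    model = build_model(model_cfg, c_in=x_train.shape[1], backbone=backbone)
    params = model.params()
    opt = _Adam(params, train_cfg.learning_rate)
    rng = np.random.default_rng(seed)
    best_acc, best_state, best_epoch = -1.0, model.get_state(), -1
    history = []
    n = len(x_train)
    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i : i + train_cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm train mode needs real batch statistics
            logits = model.forward(x_train[idx], train=True)
            loss, _ = ad.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            ad.backward(loss)
            opt.step()
            losses.append(float(loss.data))
        val_acc = _accuracy(model, x_val, y_val)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_acc": val_acc})
        logger.info("epoch %d: loss %.4f val_acc %.4f", epoch, history[-1]["loss"], val_acc)
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, model.get_state(), epoch
        elif epoch - best_epoch >= train_cfg.patience and epoch + 1 >= train_cfg.min_epochs:
            logger.info("early stop at epoch %d (best %.4f @ %d)", epoch, best_acc, best_epoch)
            break
    model.set_state(best_state)
    return model, history


def train_ensemble(
    train_ds: LabeledDataset,
    cfg: NetworkConfig,
    train_cfg: TrainConfig,
    seed: int = 0,
    backbone: str = "densenet",
    n_folds: int = N_FOLDS,
) -> EnsembleModel:
    """Fivefold CV: one model per fold, all sharing the architecture config."""
    x = encode_dataset(train_ds.records, train_cfg.scheme)
    y = np.asarray(train_ds.labels)
    plan = make_folds(train_ds, n_folds, seed)
    models = []
    for fold in range(n_folds):
        trn, val = plan.indices(fold)
        logger.info("training fold %d (%d train / %d val)", fold, len(trn), len(val))
        model, _ = train_fold(
            x[trn], y[trn], x[val], y[val], cfg, train_cfg,
            seed=seed * n_folds + fold + 1, backbone=backbone,
        )
        models.append(model)
    return EnsembleModel(
        fold_models=models, cfg=cfg, train_cfg=train_cfg,
        layer=train_ds.layer, backbone=backbone,
    )


def ensemble_predict(em: EnsembleModel, test_ds: LabeledDataset) -> list[PredictionRecord]:
    """Score every test record with all five fold models and soft-vote.

    mean_prob is the arithmetic mean of the five positive-class
    probabilities; label 1 iff mean_prob >= 0.5 (ties positive).  With
    vote="hard" the call is the majority of per-fold thresholded labels.
    """
    x = encode_dataset(test_ds.records, em.train_cfg.scheme)
    fold_probs = np.stack(
        [m.predict_proba(x)[:, 1] for m in em.fold_models], axis=1
    )  # (N, 5)
    mean_probs = fold_probs.mean(axis=1)
    if em.train_cfg.vote == "hard":
        labels = ((fold_probs >= 0.5).sum(axis=1) * 2 >= fold_probs.shape[1]).astype(int)
    else:
        labels = (mean_probs >= 0.5).astype(int)
    return [
        PredictionRecord(
            record_id=rec.id,
            fold_probs=[float(p) for p in fold_probs[i]],
            mean_prob=float(mean_probs[i]),
            label_pred=int(labels[i]),
        )
        for i, rec in enumerate(test_ds.records)
    ]


def evaluate_ensemble(em: EnsembleModel, test_ds: LabeledDataset) -> MetricsReport:
    preds = ensemble_predict(em, test_ds)
    return MetricsReport.from_predictions(
        test_ds.labels,
        [p.label_pred for p in preds],
        scores=[p.mean_prob for p in preds],
    )


def _assert_disjoint(train_ds: LabeledDataset, test_ds: LabeledDataset) -> None:
    overlap = {r.id for r in train_ds.records} & {r.id for r in test_ds.records}
    if overlap:
        raise ValueError(f"train/test record ids overlap: {sorted(overlap)[:5]} ...")


def run_cycle_protocol(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    cfg: NetworkConfig,
    train_cfg: TrainConfig,
    n_cycles: int = 10,
    base_seed: int = 0,
    backbone: str = "densenet",
) -> dict:
    """Repeat the fivefold + soft-vote protocol n_cycles times.

    Cycle c reseeds both fold assignment and model initialization with
    base_seed + c.  Returns per-cycle reports plus mean and population
    standard deviation of each metric.
    """
    reports = []
    for c in range(n_cycles):
        _assert_disjoint(train_ds, test_ds)
        em = train_ensemble(train_ds, cfg, train_cfg, seed=base_seed + c, backbone=backbone)
        rep = evaluate_ensemble(em, test_ds)
        logger.info("cycle %d: Acc %.2f MCC %.4f", c, rep.acc, rep.mcc)
        reports.append(rep)
    summary = {}
    for key in ("sn", "sp", "acc", "mcc", "auc"):
        mean, std = summarize([getattr(r, key) for r in reports])
        summary[key] = {"mean": mean, "std": std}
    return {"cycles": [r.to_dict() for r in reports], "summary": summary}


def _backbone_to_build(name: str) -> tuple[str, dict]:
    """Map an ablation registry name to (backbone, config overrides)."""
    if name == "resnet":
        return "resnet", {"use_attention": False}
    if name == "densenet":
        return "densenet", {"use_attention": False}
    variants = {
        "densenet+channel": "channel",
        "densenet+spatial": "spatial",
        "densenet+serial_cbam": "serial",
        "densenet+parallel_cbam": "parallel",
    }
    if name not in variants:
        raise ValueError(f"unknown backbone {name!r}; registry: {ABLATION_BACKBONES}")
    return "densenet", {"use_attention": True, "attention_variant": variants[name]}


def run_ablation(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    cfg: NetworkConfig,
    train_cfg: TrainConfig,
    backbones=ABLATION_BACKBONES,
    seed: int = 0,
) -> dict:
    """One metrics row per architecture variant under an identical protocol."""
    rows = {}
    for name in backbones:
        backbone, overrides = _backbone_to_build(name)
        variant_cfg = NetworkConfig.from_dict({**cfg.to_dict(), **overrides})
        em = train_ensemble(train_ds, variant_cfg, train_cfg, seed=seed, backbone=backbone)
        rows[name] = evaluate_ensemble(em, test_ds).to_dict()
    return rows


# ---------------------------------------------------------------------------
# checkpoints


def save_ensemble(em: EnsembleModel, out_dir) -> Path:
    """Serialize the ensemble: one .npz of arrays per fold + a JSON config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "network": em.cfg.to_dict(),
        "train": em.train_cfg.to_dict(),
        "layer": em.layer,
        "backbone": em.backbone,
        "n_folds": len(em.fold_models),
    }
    with open(out_dir / "ensemble.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    for i, model in enumerate(em.fold_models):
        arrays = {f"a{j}": a for j, a in enumerate(model.state_arrays())}
        np.savez(out_dir / f"fold{i}.npz", **arrays)
    return out_dir


def load_ensemble(out_dir, c_in: int = 1) -> EnsembleModel:
    out_dir = Path(out_dir)
    with open(out_dir / "ensemble.json") as fh:
        meta = json.load(fh)
    cfg = NetworkConfig.from_dict(meta["network"])
    tcfg = TrainConfig(**meta["train"])
    models = []
    for i in range(meta["n_folds"]):
        model = build_model(cfg, c_in=c_in, backbone=meta["backbone"])
        with np.load(out_dir / f"fold{i}.npz") as z:
            state = [z[f"a{j}"] for j in range(len(z.files))]
        model.set_state(state)
        models.append(model)
    return EnsembleModel(
        fold_models=models, cfg=cfg, train_cfg=tcfg,
        layer=meta["layer"], backbone=meta["backbone"],
    )
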