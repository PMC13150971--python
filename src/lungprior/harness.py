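"""Training and evaluation harness for the fusion segmentation models.

Provides pixelwise segmentation metrics, seed-reproducible hold-out and
k-fold split plans, a deterministic CPU training loop (Adam on logit
binary cross-entropy), cross-dataset evaluation and the 16-combination
channel-ablation sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import fusion
from .fusion import ChannelSet, Combination
from .nn import Adam, FusionModel, Tensor, bce_with_logits

__all__ = ["ModelSpec", "TrainConfig", "MetricsReport", "SplitPlan",
           "TrainedSegmenter", "pixel_metrics", "aggregate_metrics",
           "split_holdout", "kfold", "train_model", "evaluate_model",
           "cross_dataset_eval", "ablation_sweep"]


@dataclass
class ModelSpec:
    family: str = "unet"
    depth: int = 3
    base_filters: int = 8


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 4
    input_size: int = 256
    seed: int = 0
    model: ModelSpec = field(default_factory=ModelSpec)
    max_steps: int | None = None      # caps epochs * batches when set
    threshold: float = 0.5            # probability cut for predicted masks

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs and batch_size must be positive")


@dataclass
class MetricsReport:
    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    n_images: int = 1

    def as_dict(self) -> dict:
        return {"dice": self.dice, "iou": self.iou, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall,
                "n_images": self.n_images}


@dataclass
class SplitPlan:
    train_ids: list
    test_ids: list
    folds: List[list] | None = None
    seed: int = 0
    holdout_fraction: float = 0.2
    k: int = 5


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pixel_metrics(pred: np.ndarray, ref: np.ndarray) -> MetricsReport:
    """Pixelwise overlap metrics for one prediction/reference mask pair.

    Empty-vs-empty pairs score 1.0 on dice, IoU, precision and recall.
    """
    p = np.asarray(pred, dtype=bool)
    r = np.asarray(ref, dtype=bool)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = p.size - tp - fp - fn
    if tp + fp + fn == 0:
        return MetricsReport(1.0, 1.0, 1.0, 1.0, 1.0)
    dice = 2 * tp / (2 * tp + fp + fn)
    iou = tp / (tp + fp + fn)
    acc = (tp + tn) / p.size
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return MetricsReport(dice, iou, acc, prec, rec)


def aggregate_metrics(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean of per-image reports."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return MetricsReport(
        dice=float(np.mean([r.dice for r in reports])),
        iou=float(np.mean([r.iou for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        n_images=sum(r.n_images for r in reports))


# ---------------------------------------------------------------------------
# split protocols
# ---------------------------------------------------------------------------

def split_holdout(ids: Sequence, fraction: float = 0.2,
                  seed: int = 0) -> SplitPlan:
    """Seeded shuffle split; ``round(fraction * n)`` ids go to the test set."""
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError("need at least 5 ids to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(np.floor(fraction * n + 0.5))
    test = [ids[i] for i in order[:n_test]]
    train = [ids[i] for i in order[n_test:]]
    return SplitPlan(train_ids=train, test_ids=test, seed=seed,
                     holdout_fraction=fraction)


def kfold(train_ids: Sequence, k: int = 5, seed: int = 0) -> List[list]:
    """Seeded partition into k folds whose sizes differ by at most one."""
    ids = list(train_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError("need at least k ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    return [[ids[i] for i in chunk] for chunk in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack_dataset(data: Sequence[Tuple[ChannelSet, np.ndarray]],
                   size: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for cs, mask in data:
        x = cs.stack()
        if x.shape[-1] != size:
            x = np.stack([
                np.clip(resize(x[0], (size, size), order=1, anti_aliasing=False,
                               preserve_range=True), 0, 1)]
                + [(resize(plane, (size, size), order=0, anti_aliasing=False,
                           preserve_range=True) > 0.5).astype(np.float64)
                   for plane in x[1:]])
        m = np.asarray(mask, dtype=np.float64)
        if m.shape != (size, size):
            m = resize(m, (size, size), order=0, anti_aliasing=False,
                       preserve_range=True) > 0.5
        xs.append(x.astype(np.float32))
        ys.append(np.asarray(m, np.float32)[None])
    return np.stack(xs), np.stack(ys)


@dataclass
class TrainedSegmenter:
    """A trained fusion model plus the combination it was trained under."""

    model: FusionModel
    combo: Combination
    config: TrainConfig
    loss_history: List[float] = field(default_factory=list)

    def predict_proba(self, stacks: np.ndarray) -> np.ndarray:
        x = fusion.apply_selection(np.asarray(stacks, np.float64), self.combo)
        return self.model.predict_proba(x.astype(np.float32))

    def predict(self, stacks: np.ndarray) -> np.ndarray:
        return self.predict_proba(stacks) > self.config.threshold


def train_model(cfg: TrainConfig,
                data: Sequence[Tuple[ChannelSet, np.ndarray]],
                combo: Combination) -> TrainedSegmenter:
    """Deterministic CPU training of mixer + network on one combination.

    The pipeline is channel selection -> trainable 1x1 mixer -> network,
    optimized with Adam on logit binary cross-entropy.  Batch order is a
    seeded per-epoch shuffle; a NaN loss aborts with diagnostics.
    """
    if not data:
        raise ValueError("empty training set")
    X, Y = _stack_dataset(data, cfg.input_size)
    X = fusion.apply_selection(X, combo).astype(np.float32)
    n = X.shape[0]

    model = FusionModel(cfg.model.family, cfg.model.depth,
                        cfg.model.base_filters, seed=cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    order_rng = np.random.default_rng(cfg.seed + 1)

    total_steps = cfg.epochs * int(np.ceil(n / cfg.batch_size))
    if cfg.max_steps is not None:
        total_steps = min(total_steps, cfg.max_steps)

    losses: List[float] = []
    step = 0
    while step < total_steps:
        order = order_rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            if step >= total_steps:
                break
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(X[idx])
            logits = model.forward(xb)
            loss = bce_with_logits(logits, Y[idx])
            val = float(loss.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"NaN/inf loss at step {step} "
                    f"(combo={combo.label}, lr={cfg.learning_rate})")
            losses.append(val)
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
    return TrainedSegmenter(model=model, combo=combo, config=cfg,
                            loss_history=losses)


def evaluate_model(seg: TrainedSegmenter,
                   data: Sequence[Tuple[ChannelSet, np.ndarray]]
                   ) -> MetricsReport:
    """Per-image metrics on a dataset, aggregated by unweighted mean."""
    if not data:
        raise ValueError("empty evaluation set")
    X, Y = _stack_dataset(data, seg.config.input_size)
    preds = seg.predict(X)
    reports = [pixel_metrics(preds[i], Y[i, 0] > 0.5) for i in range(len(data))]
    return aggregate_metrics(reports)


def cross_dataset_eval(seg: TrainedSegmenter,
                       test_sets: Dict[str, Sequence[Tuple[ChannelSet, np.ndarray]]]
                       ) -> Dict[str, MetricsReport]:
    """Evaluate a model trained on one source against named held-out sets."""
    out = {}
    for name, data in test_sets.items():
        if not data:
            raise ValueError(f"empty target set {name!r}")
        out[name] = evaluate_model(seg, data)
    return out


def ablation_sweep(cfg: TrainConfig,
                   data: Sequence[Tuple[ChannelSet, np.ndarray]],
                   eval_data: Sequence[Tuple[ChannelSet, np.ndarray]] | None = None
                   ) -> pd.DataFrame:
    """Train and evaluate all 16 channel combinations under identical settings.

    Returns one row per combination with the five metrics and delta columns
    against the grayscale-only baseline (first row).
    """
    rows = []
    eval_on = eval_data if eval_data is not None else data
    for combo in fusion.enumerate_combinations():
        seg = train_model(replace(cfg), data, combo)
        rep = evaluate_model(seg, eval_on)
        rows.append({"combo": combo.label, **rep.as_dict()})
    df = pd.DataFrame(rows)
    base = df.iloc[0]
    df["delta_dice"] = df["dice"] - base["dice"]
    df["delta_iou"] = df["iou"] - base["iou"]
    return df
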