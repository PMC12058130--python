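"""Data splitting, training with early stopping on validation AUC, metrics.

The split protocol takes 10% of the data as validation, then 10% of the
remaining 90% as test (9% of the whole), stratified by label.  Training
minimizes binary cross-entropy with Adam (lr 5e-4, batch 64, up to 20
epochs), evaluates validation ROC AUC on a fixed batch cadence, keeps the
best checkpoint, and stops early when a patience budget of batches elapses
without improvement.  Evaluation reports ROC AUC (Mann-Whitney rank
statistic), PR AUC (step interpolation), and the five threshold metrics
plus MCC at a fixed 0.5 operating point.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split

from . import nn
from .embedding import TokenizerSpec, encode_indices
from .io_formats import DatasetManifest, EmbeddingTable, LabeledSequence
from .model import BindingSiteNetwork, ModelConfig, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "EvalReport",
    "stratified_split",
    "train",
    "evaluate",
    "evaluate_scores",
    "roc_auc_rank",
    "run_ablation",
]


@dataclass(frozen=True)
class SplitSpec:
    val_fraction: float = 0.10
    test_fraction_of_remainder: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for f in (self.val_fraction, self.test_fraction_of_remainder):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 64
    max_epochs: int = 20
    early_stop_batches: int = 5000
    eval_every: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.early_stop_batches, self.eval_every) <= 0:
            raise ValueError("all training parameters must be positive")


@dataclass
class EvalReport:
    """The seven reported metrics plus the confusion counts behind them."""

    roc_auc: float
    pr_auc: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    mcc: float
    threshold: float = 0.5
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(d.pop("metadata"))
        return d


def stratified_split(data: DatasetManifest, spec: SplitSpec
                     ) -> tuple[list[LabeledSequence], list[LabeledSequence],
                                list[LabeledSequence]]:
    """Disjoint, exhaustive (train, val, test) preserving class proportions."""
    seqs = data.sequences
    labels = data.labels()
    for cls in (0, 1):
        if (labels == cls).sum() < 3:
            raise ValueError(
                f"class {cls} has fewer than 3 members; cannot fill 3 splits")
    idx = np.arange(len(seqs))
    rest, val = train_test_split(idx, test_size=spec.val_fraction,
                                 stratify=labels, random_state=spec.seed)
    train_idx, test = train_test_split(
        rest, test_size=spec.test_fraction_of_remainder,
        stratify=labels[rest], random_state=spec.seed)
    return ([seqs[i] for i in train_idx], [seqs[i] for i in val],
            [seqs[i] for i in test])


def _split_checksum(*splits: list[LabeledSequence]) -> str:
    h = hashlib.sha256()
    for part in splits:
        for s in part:
            h.update(s.id.encode())
        h.update(b"|")
    return h.hexdigest()[:12]


# -- metrics ------------------------------------------------------------------

def roc_auc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic with tie correction."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined: test set has a single class")
    ranks = rankdata(s)  # average ranks handle ties
    r_pos = ranks[y == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray,
                    threshold: float = 0.5) -> EvalReport:
    """Seven-metric report from scores in [0, 1] at a fixed threshold."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    auc = roc_auc_rank(y, s)
    pr = float(average_precision_score(y, s))  # step interpolation
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    accuracy = (tp + tn) / len(y)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    return EvalReport(roc_auc=auc, pr_auc=pr, precision=precision,
                      recall=recall, accuracy=accuracy, f1=f1, mcc=float(mcc),
                      threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn)


def _encode(model: BindingSiteNetwork, seqs: list[LabeledSequence]):
    spec = TokenizerSpec(model.config.kmer_size, model.config.stride)
    idx = encode_indices(seqs, spec)
    y = np.array([s.label for s in seqs], dtype=np.float64)
    return idx, y


def evaluate(model: BindingSiteNetwork, test: list[LabeledSequence],
             threshold: float = 0.5) -> EvalReport:
    """Score the test split and report the seven metrics at ``threshold``."""
    if not test:
        raise ValueError("test set is empty")
    idx, y = _encode(model, test)
    if len(np.unique(y)) < 2:
        raise ValueError("test set has a single class; AUC undefined")
    scores = model.predict_proba(idx)
    return evaluate_scores(y, scores, threshold)


# -- training -----------------------------------------------------------------

def train(model: BindingSiteNetwork, train_set: list[LabeledSequence],
          val_set: list[LabeledSequence], config: TrainConfig
          ) -> tuple[BindingSiteNetwork, list[dict]]:
    """Fit with Adam + BCE; early-stop on validation ROC AUC.

    Returns the model holding its best-validation-AUC parameters and a
    history of per-evaluation (batch, epoch, mean train loss, val AUC).
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    idx, y = _encode(model, train_set)
    val_idx, val_y = _encode(model, val_set)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    n = idx.shape[0]
    history: list[dict] = []
    best_auc = -np.inf
    best_state: dict | None = None
    best_batch = 0
    batches_done = 0
    loss_acc: list[float] = []
    stop = False

    def run_validation(epoch: int) -> None:
        nonlocal best_auc, best_state, best_batch, stop
        val_auc = roc_auc_rank(val_y, model.predict_proba(val_idx))
        history.append({"batch": batches_done, "epoch": epoch,
                        "train_loss": float(np.mean(loss_acc)) if loss_acc else np.nan,
                        "val_auc": val_auc})
        loss_acc.clear()
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            best_batch = batches_done
        elif batches_done - best_batch >= config.early_stop_batches:
            stop = True
        logger.info("batch %d epoch %d val_auc %.4f (best %.4f)",
                    batches_done, epoch, val_auc, best_auc)

    model.train()
    for epoch in range(config.max_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = perm[start:start + config.batch_size]
            logits = model.forward(idx[sel])
            loss = nn.bce_with_logits(logits, y[sel])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at batch {batches_done} "
                    f"(lr={config.learning_rate}, epoch={epoch})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            loss_acc.append(loss.item())
            batches_done += 1
            if batches_done % config.eval_every == 0:
                run_validation(epoch)
                if stop:
                    break
                model.train()
        if stop:
            break

    # final check so short runs always record at least one evaluation,
    # and the returned model is never worse than the best checkpoint
    if not history or history[-1]["batch"] != batches_done:
        run_validation(config.max_epochs - 1)
    if best_state is not None and history[-1]["val_auc"] < best_auc:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def run_ablation(data: DatasetManifest, variants: dict[str, ModelConfig],
                 config: TrainConfig, split: SplitSpec | None = None,
                 table: EmbeddingTable | None = None,
                 threshold: float = 0.5) -> pd.DataFrame:
    """Train and score each variant on identical splits and seeds.

    One row per variant, seven metric columns, a shared split checksum,
    and a status column; a variant that fails to build is marked failed
    and the run continues.
    """
    if len(variants) < 2:
        raise ValueError("an ablation needs at least two variants")
    split = split if split is not None else SplitSpec(seed=config.seed)
    tr, val, test = stratified_split(data, split)
    checksum = _split_checksum(tr, val, test)
    rows = []
    for name, mconfig in variants.items():
        row: dict = {"model": name, "split_checksum": checksum}
        try:
            model = build_model(mconfig, seed=config.seed, table=table)
            model, _ = train(model, tr, val, config)
            report = evaluate(model, test, threshold)
            row.update({k: getattr(report, k)
                        for k in ("roc_auc", "pr_auc", "precision", "recall",
                                  "accuracy", "f1", "mcc")})
            row["status"] = "ok"
            row["n_parameters"] = model.num_parameters()
        except Exception as exc:  # noqa: BLE001 - row-level isolation
            logger.error("variant %s failed: %s", name, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
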