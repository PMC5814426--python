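"""Network training, subject-level evaluation, and chance calibration.

Training follows the original recipe: Adamax (lr 0.002, beta1 0.9,
beta2 0.999), categorical cross-entropy on one-hot labels, batches of 70
epochs, stopping when (a) training accuracy reaches 100%, (b) the
training loss stops decreasing, or (c) the run budget is exhausted.
Subject-level sex calls average the per-epoch male probability over a
subject's epochs and threshold strictly at 0.5.

The significance threshold is calibrated by Monte-Carlo simulation:
labels are assigned at random with the cohort's prior male fraction and
scored against the fixed true labels; the maximum accuracy over the
simulations (100,000 by default, i.e. p < 1e-5) is the chance-level
threshold, reported as a whole percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .errors import ConfigurationError, DataError
from .model import Network
from .preprocess import EpochSet

__all__ = [
    "TrainConfig", "TrainResult", "NullSimResult",
    "split_cohort", "train", "predict_subjects", "subject_accuracy",
    "epoch_accuracy", "simulate_null_threshold", "stack_epochsets",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 70
    max_runs: int = 150
    plateau_patience: int = 10
    plateau_delta: float = 1e-4
    seed: int = 0
    shuffle: bool = True

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.max_runs < 1:
            raise ConfigurationError("max_runs must be >= 1")


@dataclass
class TrainResult:
    network: Network
    history: pd.DataFrame   # columns: run, loss, train_acc[, test_acc]
    stop_reason: str        # train_acc_100 | loss_plateau | max_runs


@dataclass
class NullSimResult:
    n_subjects: int
    true_male_fraction: float
    assigned_male_fraction: float
    n_sims: int
    threshold_percent: int
    seed: int
    accuracies: np.ndarray = field(repr=False)

    @property
    def max_accuracy(self) -> float:
        return float(self.accuracies.max())


def split_cohort(cohort: list, n_train: int, seed: int = 0):
    """Disjoint subject-level split: seeded shuffle, first ``n_train``
    subjects train, the rest test."""
    if n_train >= len(cohort):
        raise DataError(
            f"n_train={n_train} must be below the cohort size {len(cohort)}")
    order = np.random.default_rng(
        np.random.SeedSequence([seed, 0x591])).permutation(len(cohort))
    train_set = [cohort[i] for i in order[:n_train]]
    test_set = [cohort[i] for i in order[n_train:]]
    return train_set, test_set


def stack_epochsets(epochsets: list[EpochSet]):
    """Concatenate per-subject epoch stacks into (X, y) training arrays."""
    X = np.concatenate([es.epochs for es in epochsets], axis=0)
    y = np.concatenate([np.full(es.n_epochs, es.sex, dtype=int)
                        for es in epochsets])
    return X, y


def train(net: Network, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None,
          eval_data: tuple[np.ndarray, np.ndarray] | None = None) -> TrainResult:
    """Optimize ``net`` in place; returns the per-run history.

    ``X`` is (n_epochs_total, time, channels) (or net layout), ``y`` the
    binary labels (1=male).  Training accuracy is accumulated from the
    pre-update forward passes of each batch, as is conventional.
    Deterministic given ``cfg.seed`` and a fixed BLAS configuration.
    """
    from .model import _to_net_layout

    cfg = cfg if cfg is not None else TrainConfig()
    cfg.validate()
    X = _to_net_layout(X, net.input_shape)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise DataError(f"{X.shape[0]} epochs but {y.shape[0]} labels")
    onehot = np.zeros((y.size, 2), dtype=np.float32)
    onehot[np.arange(y.size), y] = 1.0

    opt = _nn.Adamax(lr=cfg.learning_rate, beta1=cfg.beta1,
                     beta2=cfg.beta2, eps=cfg.eps)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7124]))
    n = X.shape[0]
    rows = []
    best_loss = np.inf
    stall = 0
    stop_reason = "max_runs"
    for run in range(1, cfg.max_runs + 1):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = net.forward_logits(X[idx], train=True, rng=rng)
            loss, dlogits, proba = _nn.softmax_xent(logits, onehot[idx])
            losses.append(loss * idx.size)
            correct += int((proba.argmax(axis=1) == y[idx]).sum())
            net.backward(dlogits)
            opt.step(net.parameters())
        run_loss = float(np.sum(losses) / n)
        train_acc = correct / n
        row = {"run": run, "loss": run_loss, "train_acc": train_acc}
        if eval_data is not None:
            Xe, ye = eval_data
            proba = net.predict_proba(Xe)
            pred = (proba[:, 1] > 0.5).astype(int)
            row["test_acc"] = float((pred == np.asarray(ye)).mean())
        rows.append(row)

        if train_acc >= 1.0:
            stop_reason = "train_acc_100"
            break
        if run_loss < best_loss - cfg.plateau_delta:
            best_loss = run_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                stop_reason = "loss_plateau"
                break
    return TrainResult(network=net, history=pd.DataFrame(rows),
                       stop_reason=stop_reason)


def predict_subjects(net: Network, epochsets: list[EpochSet]) -> pd.DataFrame:
    """Subject-level prediction table.

    One row per subject: true sex, mean male probability over the
    subject's epochs, and the thresholded call (male iff p > 0.5, so a
    mean of exactly 0.5 is called female).
    """
    rows = []
    for es in epochsets:
        if es.n_epochs == 0:
            raise DataError(f"subject {es.subject_id} has no epochs")
        proba = net.predict_proba(es.epochs)
        p_male = float(proba[:, 1].mean())
        rows.append({"subject_id": es.subject_id, "true_sex": es.sex,
                     "mean_male_probability": p_male,
                     "predicted_sex": int(p_male > 0.5)})
    return pd.DataFrame(rows)


def subject_accuracy(table: pd.DataFrame) -> float:
    """Percent of correct subject-level calls."""
    if len(table) == 0:
        raise DataError("empty prediction table")
    return 100.0 * float(
        (table["predicted_sex"] == table["true_sex"]).mean())


def epoch_accuracy(net: Network, epochsets: list[EpochSet]) -> float:
    """Percent of correct per-epoch calls (no subject aggregation)."""
    correct = 0
    total = 0
    for es in epochsets:
        proba = net.predict_proba(es.epochs)
        correct += int(((proba[:, 1] > 0.5).astype(int) == es.sex).sum())
        total += es.n_epochs
    return 100.0 * correct / total


def simulate_null_threshold(n_subjects: int, true_male_fraction: float,
                            assigned_male_fraction: float,
                            n_sims: int = 100_000,
                            seed: int = 0) -> NullSimResult:
    """Chance-level accuracy threshold by Monte-Carlo label assignment.

    True labels are held fixed at exactly ``round(true_male_fraction *
    n_subjects)`` males (a fixed test cohort); each simulation assigns
    every subject male independently with probability
    ``assigned_male_fraction`` and is scored against the true labels.
    The threshold is the maximum accuracy over simulations, rounded to a
    whole percent — with 100,000 simulations this estimates the p < 1e-5
    chance level.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be >= 1")
    for name, frac in (("true_male_fraction", true_male_fraction),
                       ("assigned_male_fraction", assigned_male_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1]")
    n_male = int(round(true_male_fraction * n_subjects))
    truth = np.zeros(n_subjects, dtype=bool)
    truth[:n_male] = True
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7811]))
    accs = np.empty(n_sims, dtype=np.float32)
    chunk = max(1, min(n_sims, 20_000))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        assigned = rng.random((m, n_subjects)) < assigned_male_fraction
        accs[done:done + m] = (assigned == truth).mean(axis=1)
        done += m
    threshold = int(round(100.0 * float(accs.max())))
    return NullSimResult(
        n_subjects=n_subjects, true_male_fraction=true_male_fraction,
        assigned_male_fraction=assigned_male_fraction, n_sims=n_sims,
        threshold_percent=threshold, seed=seed, accuracies=accs)
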