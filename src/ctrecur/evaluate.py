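"""Cross-validation orchestration, optimizer schedule, and the six-metric
evaluator.

The protocol is patient-level, stratified five-fold cross-validation shared
by every base network and every ensemble: a patient's prediction is always
made by the fold model that never saw them. Metrics (accuracy, AUC, F1,
precision, recall on the percent scale; MCC in [-1, 1]) are computed per
test fold and summarized as mean +/- sd over the five folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

METRIC_NAMES = ("accuracy", "auc", "f1", "precision", "recall", "mcc")

# The training protocol (epoch counts, 50-epoch LR decay) was designed for a
# ~530-patient cohort, i.e. ~13 optimizer steps per epoch at batch 32.
REF_STEPS_PER_EPOCH = 530 * 0.8 / 32


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters: mini-batch 32, SGD at 5e-3 decaying by 0.7
    every 50 epochs with momentum 0.5, binary cross-entropy loss; 500 epochs
    for base CNNs and 300 for the fusion network."""

    batch_size: int = 32
    epochs_base: int = 500
    epochs_fusion: int = 300
    lr0: float = 5e-3
    decay: float = 0.7
    decay_every: int = 50
    momentum: float = 0.5

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs_base, self.epochs_fusion,
               self.decay_every) <= 0:
            raise ValueError("sizes and epoch counts must be positive")
        if self.lr0 <= 0 or not 0 < self.decay <= 1 or not 0 <= self.momentum < 1:
            raise ValueError("invalid optimizer hyperparameters")


def lr_schedule(epoch: int, hp: Hyperparams | None = None) -> float:
    """Step-decayed learning rate: lr0 * decay^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if hp is None:
        hp = Hyperparams()
    return hp.lr0 * hp.decay ** (epoch // hp.decay_every)


def match_fusion_steps(hp: Hyperparams, n_train: int) -> Hyperparams:
    """Rescale the fusion stage's epoch counts so a smaller cohort sees the
    same number of SGD steps — and the same learning-rate-versus-step
    trajectory — as the reference protocol.

    An 'epoch' on the reference cohort is ~13 mini-batches; on a 40-patient
    training fold it is just one or two, which starves the optimizer if epoch
    counts are kept verbatim. The factor multiplies both ``epochs_fusion``
    and ``decay_every``.
    """
    steps_per_epoch = max(1, int(np.ceil(n_train / hp.batch_size)))
    factor = max(1, round(REF_STEPS_PER_EPOCH / steps_per_epoch))
    if factor == 1:
        return hp
    return replace(hp, epochs_fusion=hp.epochs_fusion * factor,
                   decay_every=hp.decay_every * factor)


@dataclass
class FoldAssignment:
    """patient_id -> fold index, with every patient in exactly one fold."""

    assignment: dict
    n_folds: int = 5

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if not folds.issubset(range(self.n_folds)):
            raise ValueError("fold indices out of range")

    def fold_of(self, patient_id) -> int:
        return self.assignment[patient_id]

    def members(self, fold: int) -> list:
        return [p for p, f in self.assignment.items() if f == fold]

    def splits(self, patient_ids) -> list[tuple[np.ndarray, np.ndarray]]:
        """(train_idx, test_idx) pairs over ``patient_ids`` for each fold."""
        fold_vec = np.array([self.assignment[p] for p in patient_ids])
        out = []
        for f in range(self.n_folds):
            test = np.flatnonzero(fold_vec == f)
            train = np.flatnonzero(fold_vec != f)
            out.append((train, test))
        return out


def make_folds(labels, k: int = 5, seed: int = 0, patient_ids=None) -> FoldAssignment:
    """Stratified k-fold split at the patient level, deterministic in ``seed``.

    Falls back to an unstratified split (with a warning) when a class has
    fewer members than k.
    """
    labels = np.asarray(labels).ravel()
    n = labels.size
    if n < k:
        raise ValueError(f"need at least {k} patients for {k}-fold CV")
    if patient_ids is None:
        patient_ids = list(range(n))
    counts = np.bincount(labels.astype(int), minlength=2)
    if counts.min() < k:
        warnings.warn(f"a class has fewer than {k} members; folds will not be "
                      "fully stratified", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    assignment = {}
    for f, (_, test_idx) in enumerate(split_iter):
        for i in test_idx:
            assignment[patient_ids[i]] = f
    return FoldAssignment(assignment, n_folds=k)


def roc_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic, ties counted half.

    Returns NaN when only one class is present (AUC undefined).
    """
    y_true = np.asarray(y_true).ravel().astype(int)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(np.asarray(y_prob).ravel())
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(y_true, y_prob, threshold: float = 0.5) -> dict[str, float]:
    """Six classification metrics from probabilities binarized at ``threshold``.

    Accuracy/AUC/F1/precision/recall are on the percent scale; MCC in [-1, 1].
    Ratios with an empty denominator are reported as 0 (a degenerate
    predictor is no better than chance).
    """
    y_true = np.asarray(y_true).ravel().astype(int)
    y_prob = np.asarray(y_prob).ravel().astype(float)
    if y_true.size != y_prob.size or y_true.size == 0:
        raise ValueError("y_true and y_prob must be equal-length, non-empty")
    y_pred = (y_prob >= threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    n = y_true.size
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = roc_auc(y_true, y_prob)
    return {"accuracy": 100 * accuracy,
            "auc": 100 * auc if np.isfinite(auc) else float("nan"),
            "f1": 100 * f1,
            "precision": 100 * precision,
            "recall": 100 * recall,
            "mcc": float(mcc)}


@dataclass
class MetricsReport:
    """Per-fold metric values with mean +/- sd summaries."""

    fold_metrics: list[dict[str, float]] = field(default_factory=list)

    def add(self, metrics: dict[str, float]) -> None:
        self.fold_metrics.append(metrics)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fold_metrics)

    def mean(self) -> dict[str, float]:
        df = self.to_frame()
        return {m: float(np.nanmean(df[m])) for m in df.columns}

    def sd(self) -> dict[str, float]:
        df = self.to_frame()
        return {m: float(np.nanstd(df[m], ddof=1)) if len(df) > 1 else 0.0
                for m in df.columns}

    def summary_row(self) -> dict[str, str]:
        mean, sd = self.mean(), self.sd()
        fmt = {m: f"{mean[m]:.2f} ± {sd[m]:.2f}" for m in mean}
        return fmt


@dataclass
class ExperimentConfig:
    """What to train and ensemble on a preprocessed cohort.

    ``inputs`` are patch keys (five slice names and/or 'scale50'/'scale150'),
    trained with the 3 x 3 kernel; ``kernels`` adds multi-kernel networks
    (2/4/5/6) on the medium slice; ``combos`` are ensemble combinations such
    as '3slices+5/6'.
    """

    inputs: tuple = ("second_before", "first_before", "medium",
                     "first_after", "second_after", "scale50", "scale150")
    kernels: tuple = (2, 4, 5, 6)
    combos: tuple = ("3slices+5/6",)
    hp: Hyperparams = field(default_factory=Hyperparams)
    epochs_base: int | None = None  # override hp.epochs_base (e.g. quick runs)
    seed: int = 0


def base_model_specs(config: ExperimentConfig) -> list[tuple[str, str, int]]:
    """(model_name, patch_key, kernel) for every requested base network."""
    specs = [(name, name, 3) for name in config.inputs]
    specs += [(f"kernel{k}", "medium", k) for k in config.kernels]
    return specs


def train_base_oof(patches: np.ndarray, labels: np.ndarray, folds: FoldAssignment,
                   patient_ids, kernel: int, hp: Hyperparams, seed: int,
                   epochs: int | None = None) -> tuple[np.ndarray, MetricsReport, list]:
    """Five-fold out-of-fold predictions for one base CNN.

    Returns (oof probabilities aligned with ``patient_ids``, per-fold metrics,
    the trained per-fold models).
    """
    from .models import ModelConfig, build_cnn, predict, train_cnn

    labels = np.asarray(labels).ravel().astype(int)
    oof = np.full(labels.size, np.nan)
    report = MetricsReport()
    fold_models = []
    for f, (train_idx, test_idx) in enumerate(folds.splits(patient_ids)):
        fold_seed = int(np.random.SeedSequence([seed, kernel, f]).generate_state(1)[0]
                        % (2 ** 31))
        model = build_cnn(ModelConfig(kernel=kernel), seed=fold_seed)
        train_cnn(model, patches[train_idx], labels[train_idx], hp=hp,
                  seed=fold_seed, epochs=epochs, augment=True)
        probs = predict(model, patches[test_idx])
        oof[test_idx] = probs
        report.add(compute_metrics(labels[test_idx], probs))
        fold_models.append(model)
    assert not np.isnan(oof).any()
    return oof, report, fold_models


def run_experiment(patchsets: dict, config: ExperimentConfig,
                   return_models: bool = False):
    """Train every requested base model and ensemble over shared folds.

    ``patchsets`` maps patient_id -> PatchSet. Returns (results DataFrame in
    the rows-by-metrics layout, out-of-fold prediction DataFrame) and, when
    ``return_models`` is set, the per-model trained fold networks.
    """
    from .ensemble import assemble_predictions, train_fusion

    patient_ids = list(patchsets)
    labels = np.array([patchsets[p].label for p in patient_ids], dtype=int)
    folds = make_folds(labels, k=5, seed=config.seed, patient_ids=patient_ids)

    oof_cols: dict[str, np.ndarray] = {}
    rows = []
    all_models = {}
    for name, patch_key, kernel in base_model_specs(config):
        patches = np.stack([getattr(patchsets[p], patch_key) for p in patient_ids])
        oof, report, fold_models = train_base_oof(
            patches, labels, folds, patient_ids, kernel, config.hp,
            seed=config.seed, epochs=config.epochs_base)
        oof_cols[name] = oof
        all_models[name] = fold_models
        rows.append({"model": name, "kind": "base", **report.summary_row(),
                     "mean_accuracy": report.mean()["accuracy"],
                     "mean_auc": report.mean()["auc"]})

    hp_fusion = match_fusion_steps(config.hp, int(round(0.8 * len(patient_ids))))
    for combo in config.combos:
        pm = assemble_predictions(oof_cols, patient_ids, labels, order=combo)
        result = train_fusion(pm, folds, hp_fusion, seed=config.seed)
        report = MetricsReport()
        for _, test_idx in folds.splits(patient_ids):
            report.add(compute_metrics(labels[test_idx], result.oof[test_idx]))
        oof_cols[f"fusion[{combo}]"] = result.oof
        rows.append({"model": f"fusion[{combo}]", "kind": "ensemble",
                     **report.summary_row(),
                     "mean_accuracy": report.mean()["accuracy"],
                     "mean_auc": report.mean()["auc"]})

    results = pd.DataFrame(rows)
    preds = pd.DataFrame({"patient_id": patient_ids, "label": labels,
                          "fold": [folds.fold_of(p) for p in patient_ids],
                          **oof_cols})
    if return_models:
        return results, preds, all_models
    return results, preds


def quick_hyperparams(epochs_base: int, epochs_fusion: int = 300) -> Hyperparams:
    """Hyperparams with shortened training, for small synthetic cohorts."""
    return replace(Hyperparams(), epochs_base=epochs_base,
                   epochs_fusion=epochs_fusion)
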