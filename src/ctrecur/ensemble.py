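"""Stacked-generalization fusion of base-model predictions.

The out-of-fold probabilities of the base CNNs are concatenated into an
n_patients x k_models matrix — the second-stage dataset. The fusion model is
a five-layer fully connected network (hidden widths 16, 32, 64, 16, PReLU
after each hidden layer, sigmoid output) trained under the same five-fold
split as the base models, so no patient is ever scored by a model that saw
them. Majority voting and standard classifiers (RF/LR/SVM/GB/GNB/LDA/QDA)
are provided as comparators over the same matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .evaluate import FoldAssignment, Hyperparams, lr_schedule

FUSION_WIDTHS = (16, 32, 64, 16)

# Combination vocabulary used in ensemble experiments: token -> model names
_COMBO_TOKENS = {
    "3slices": ("first_before", "medium", "first_after"),
    "5slices": ("second_before", "first_before", "medium",
                "first_after", "second_after"),
}
_SCALE_TOKENS = {"50": "scale50", "100": "medium", "150": "scale150"}


def parse_combo(combo: str) -> list[str]:
    """Expand a combination label like '3slices+5/6' or '50,100,150' into the
    ordered base-model names it denotes."""
    names: list[str] = []
    for token in combo.replace(" ", "").split("+"):
        if not token:
            continue
        if token in _COMBO_TOKENS:
            names.extend(_COMBO_TOKENS[token])
        elif "/" in token:  # kernel list, e.g. "2/4/6"
            names.extend(f"kernel{k}" for k in token.split("/"))
        elif "," in token:  # scale list, e.g. "50,150"
            names.extend(_SCALE_TOKENS[s] for s in token.split(","))
        elif token in _SCALE_TOKENS:
            names.append(_SCALE_TOKENS[token])
        else:
            names.append(token)
    if len(names) < 2:
        raise ValueError(f"combination {combo!r} names fewer than two models")
    return names


@dataclass
class PredictionMatrix:
    """n_patients x k_models out-of-fold probabilities plus labels."""

    values: np.ndarray
    model_names: list[str]
    patient_ids: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels).ravel().astype(int)
        n, k = self.values.shape
        if len(self.model_names) != k:
            raise ValueError("model_names length does not match columns")
        if len(self.patient_ids) != n or self.labels.size != n:
            raise ValueError("patient_ids/labels length does not match rows")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("prediction matrix has missing entries")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_models(self) -> int:
        return self.values.shape[1]


def assemble_predictions(columns, patient_ids, labels,
                         order=None) -> PredictionMatrix:
    """Concatenate per-model out-of-fold probability vectors into a matrix.

    ``columns`` maps model name -> probability vector (all aligned with
    ``patient_ids``); ``order`` is an explicit name sequence or a combination
    label understood by :func:`parse_combo`.
    """
    if order is None:
        names = list(columns)
    elif isinstance(order, str):
        names = parse_combo(order)
    else:
        names = list(order)
    missing = [m for m in names if m not in columns]
    if missing:
        raise KeyError(f"missing prediction columns: {missing}")
    n = len(patient_ids)
    vecs = []
    for m in names:
        v = np.asarray(columns[m], dtype=float).ravel()
        if v.size != n:
            raise ValueError(f"column {m!r} has length {v.size}, expected {n}")
        vecs.append(v)
    return PredictionMatrix(np.column_stack(vecs), names, list(patient_ids), labels)


@dataclass
class FusionNet:
    """The five-layer fusion network over k base-model probabilities."""

    net: nn.Sequential
    k: int

    @property
    def trainable_parameter_count(self) -> int:
        return self.net.count_parameters()


def build_fusion_net(k: int, seed: int) -> FusionNet:
    """FC(k->16) -> PReLU -> FC(16->32) -> PReLU -> FC(32->64) -> PReLU ->
    FC(64->16) -> PReLU -> FC(16->1) -> sigmoid."""
    if k < 2:
        raise ValueError("fusion needs at least two base models")
    rng = np.random.default_rng(seed)
    widths = (k, *FUSION_WIDTHS)
    layers: list[nn.Layer] = []
    for cin, cout in zip(widths[:-1], widths[1:]):
        layers += [nn.Linear(cin, cout, rng), nn.PReLU()]
    layers.append(nn.Linear(FUSION_WIDTHS[-1], 1, rng))
    return FusionNet(net=nn.Sequential(layers), k=k)


def fusion_predict(fnet: FusionNet, values: np.ndarray) -> np.ndarray:
    logits = fnet.net.forward(np.asarray(values, dtype=np.float32), train=False)
    return nn.sigmoid(logits.ravel())


def _train_fusion_net(fnet: FusionNet, x: np.ndarray, y: np.ndarray,
                      hp: Hyperparams, seed: int) -> None:
    rng = np.random.default_rng(seed)
    opt = nn.SGD(fnet.net.params(), momentum=hp.momentum)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    n = x.shape[0]
    for epoch in range(hp.epochs_fusion):
        lr = lr_schedule(epoch, hp)
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            logits = fnet.net.forward(x[idx], train=True)
            _, dlogits = nn.bce_with_logits(logits, y[idx])
            fnet.net.backward(dlogits)
            opt.step(lr)


@dataclass
class FusionResult:
    """Out-of-fold ensemble probabilities with full CV bookkeeping."""

    oof: np.ndarray
    fold_models: list[FusionNet] = field(default_factory=list)
    train_ids: list[list] = field(default_factory=list)  # per fold
    test_ids: list[list] = field(default_factory=list)


def train_fusion(pm: PredictionMatrix, folds: FoldAssignment,
                 hp: Hyperparams | None = None, seed: int = 0) -> FusionResult:
    """Train the fusion network per fold on the other four subsets and score
    the held-out subset; every patient receives exactly one out-of-fold
    probability."""
    if hp is None:
        hp = Hyperparams()
    missing = [p for p in pm.patient_ids if p not in folds.assignment]
    if missing:
        raise ValueError(f"patients missing from fold assignment: {missing[:5]}")
    oof = np.full(len(pm.patient_ids), np.nan)
    result = FusionResult(oof=oof)
    ids = np.asarray(pm.patient_ids, dtype=object)
    for f, (train_idx, test_idx) in enumerate(folds.splits(pm.patient_ids)):
        fold_seed = int(np.random.SeedSequence([seed, 97, f]).generate_state(1)[0]
                        % (2 ** 31))
        fnet = build_fusion_net(pm.n_models, seed=fold_seed)
        _train_fusion_net(fnet, pm.values[train_idx], pm.labels[train_idx],
                          hp, fold_seed)
        oof[test_idx] = fusion_predict(fnet, pm.values[test_idx])
        result.fold_models.append(fnet)
        result.train_ids.append(list(ids[train_idx]))
        result.test_ids.append(list(ids[test_idx]))
    assert not np.isnan(oof).any()
    return result


def majority_vote(pm: PredictionMatrix, threshold: float = 0.5) -> np.ndarray:
    """Per patient: binarize every column at ``threshold`` and take the modal
    class; ties go positive iff the mean probability is >= 0.5."""
    if pm.n_models < 2:
        raise ValueError("voting needs at least two models")
    votes = (pm.values >= threshold).astype(int)
    pos = votes.sum(axis=1)
    neg = pm.n_models - pos
    out = (pos > neg).astype(int)
    tie = pos == neg
    out[tie] = (pm.values[tie].mean(axis=1) >= 0.5).astype(int)
    return out


_CLASSICAL = ("RF", "LR", "SVM", "GB", "GNB", "LDA", "QDA")


def _make_classifier(method: str, seed: int):
    from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                               QuadraticDiscriminantAnalysis)
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    if method == "RF":
        return RandomForestClassifier(random_state=seed)
    if method == "LR":
        return LogisticRegression(max_iter=1000)
    if method == "SVM":
        return SVC(probability=True, random_state=seed)
    if method == "GB":
        return GradientBoostingClassifier(random_state=seed)
    if method == "GNB":
        return GaussianNB()
    if method == "LDA":
        return LinearDiscriminantAnalysis()
    if method == "QDA":
        return QuadraticDiscriminantAnalysis()
    raise ValueError(f"unknown method {method!r}; choose from {_CLASSICAL}")


def classical_ensemble(pm: PredictionMatrix, folds: FoldAssignment,
                       method: str, seed: int = 0) -> np.ndarray:
    """Out-of-fold probabilities from a standard classifier (default
    hyperparameters) fitted per fold on the prediction matrix."""
    oof = np.full(len(pm.patient_ids), np.nan)
    for train_idx, test_idx in folds.splits(pm.patient_ids):
        clf = _make_classifier(method, seed)
        clf.fit(pm.values[train_idx], pm.labels[train_idx])
        oof[test_idx] = clf.predict_proba(pm.values[test_idx])[:, 1]
    assert not np.isnan(oof).any()
    return oof
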