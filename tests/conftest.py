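"""Shared fixtures: tiny synthetic cohorts and patch sets, generated on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from ctrecur.phantom import PhantomParams


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_disc_patches(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly separable toy patches: bright discs (label 1) vs dark discs
    (label 0) on a dim background, with jittered centers and radii."""
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    patches = np.empty((n, 100, 100), dtype=np.float32)
    yy, xx = np.mgrid[0:100, 0:100]
    for i, lab in enumerate(labels):
        cy, cx = rng.integers(35, 65, size=2)
        r = rng.integers(14, 22)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img = np.full((100, 100), 30.0, dtype=np.float32)
        img += rng.normal(0, 5, (100, 100)).astype(np.float32)
        img[disc] = 200.0 if lab == 1 else 80.0
        patches[i] = np.clip(img, 0, 255)
    return patches, labels.astype(int)


def brute_force_metrics(y_true, y_pred_binary, y_prob):
    """Independent loop-based confusion-matrix evaluation."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred_binary):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    n = len(y_true)
    acc = (tp + tn) / n
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / denom ** 0.5 if denom else 0.0
    # AUC: pairwise comparisons, ties count half
    pos = [s for t, s in zip(y_true, y_prob) if t == 1]
    neg = [s for t, s in zip(y_true, y_prob) if t == 0]
    if pos and neg:
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
                   for p in pos for q in neg)
        auc = wins / (len(pos) * len(neg))
    else:
        auc = float("nan")
    return {"accuracy": 100 * acc, "auc": 100 * auc, "f1": 100 * f1,
            "precision": 100 * prec, "recall": 100 * rec, "mcc": mcc}
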