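"""Protocol-of-origin classification from a single bias score.

The workflow mirrors the leakage-safe design: cells are split into train
and test sets, the module score is recomputed independently within each
split (expression bins and control draws use only that split's cells), a
one-feature logistic regression is fit on training scores, and test-set
discrimination is summarized by ROC/AUC. A random-signature baseline of
matched size calibrates how much of the AUC the planted biology explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .annotation import SignatureSet
from .scoring import ScoringParams, module_score

__all__ = [
    "SplitSpec",
    "LogisticModel",
    "ROCResult",
    "split_train_test",
    "score_per_split",
    "fit_score_classifier",
    "predict_proba",
    "roc_auc",
    "random_signature_baseline",
    "score_classifier_auc",
]


@dataclass
class SplitSpec:
    train_fraction: float = 0.5
    stratify: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class LogisticModel:
    intercept: float
    slope: float
    converged: bool
    n_iter: int


@dataclass
class ROCResult:
    auc: float
    curve: list = field(default_factory=list)  # (fpr, tpr) points


def split_train_test(labels: pd.Series, spec: SplitSpec | None = None):
    """Seeded disjoint, exhaustive train/test split of the cells.

    ``labels`` is any per-cell series indexed by barcode; stratified mode
    splits each label level separately so class balance carries over.
    Returns (train_barcodes, test_barcodes) as Index objects.
    """
    spec = spec or SplitSpec()
    rng = substream(spec.seed, "split")
    train_idx: list[np.ndarray] = []
    if spec.stratify:
        for level in sorted(labels.unique()):
            members = np.flatnonzero((labels == level).to_numpy())
            if len(members) < 2:
                raise ValueError(f"class {level!r} has fewer than 2 cells")
            rng.shuffle(members)
            n_train = int(round(spec.train_fraction * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx.append(members[:n_train])
    else:
        members = rng.permutation(len(labels))
        n_train = min(max(int(round(spec.train_fraction * len(members))), 1),
                      len(members) - 1)
        train_idx.append(members[:n_train])
    train_mask = np.zeros(len(labels), dtype=bool)
    train_mask[np.concatenate(train_idx)] = True
    return labels.index[train_mask], labels.index[~train_mask]


def score_per_split(
    norm: ad.AnnData,
    signature: SignatureSet,
    params: ScoringParams,
    split,
) -> pd.Series:
    """Module scores computed independently within each split.

    Bin construction and control draws for a split see only that split's
    cells, so test cells can never influence training scores.
    """
    train_ids, test_ids = split
    parts = []
    for ids in (train_ids, test_ids):
        if len(ids) == 0:
            continue
        parts.append(module_score(norm[list(ids)].copy(), signature, params))
    return pd.concat(parts)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def fit_score_classifier(
    scores, labels, max_iter: int = 100, tol: float = 1e-8
) -> LogisticModel:
    """Unpenalized logistic regression of a binary label on one score.

    Newton/IRLS with an iteration cap; under complete separation (expected
    when the bias score cleanly splits nuclei from cells) the likelihood has
    no finite maximum, so the fit stops at the cap with ``converged=False``
    — predicted probabilities remain a monotone function of the score, which
    is all ROC/AUC consumes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) < 2:
            raise ValueError("both classes must be present")
        raise ValueError("labels must be binary 0/1")
    X = np.column_stack([np.ones_like(s), s])
    beta = np.zeros(2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ beta)
        w = np.maximum(p * (1 - p), 1e-12)
        H = (X * w[:, None]).T @ X
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    return LogisticModel(float(beta[0]), float(beta[1]), converged, it)


def predict_proba(model: LogisticModel, scores) -> np.ndarray:
    return _sigmoid(model.intercept + model.slope * np.asarray(scores, float))


def roc_auc(labels, scores) -> ROCResult:
    """ROC curve and AUC with the Mann-Whitney tie convention.

    AUC = U / (n_pos * n_neg) computed from midranks, i.e. the probability a
    random positive outranks a random negative with half credit for ties;
    the curve thresholds at every distinct score, from (0,0) to (1,1).
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    order = np.argsort(-s, kind="mergesort")
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[order[j]] == s[order[i]]:
            tp += y[order[j]] == 1
            fp += y[order[j]] == 0
            j += 1
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCResult(float(auc), curve)


def score_classifier_auc(
    norm: ad.AnnData,
    signature: SignatureSet,
    labels: pd.Series,
    spec: SplitSpec | None = None,
    scoring: ScoringParams | None = None,
) -> dict:
    """Full split -> per-split score -> logistic fit -> test AUC pipeline.

    ``labels`` is a binary series (1 = positive class) indexed by barcode.
    Returns the model, per-split scores, and train/test ROC results.
    """
    spec = spec or SplitSpec()
    scoring = scoring or ScoringParams()
    split = split_train_test(labels, spec)
    scores = score_per_split(norm, signature, scoring, split)
    train_ids, test_ids = split
    model = fit_score_classifier(scores.loc[train_ids], labels.loc[train_ids])
    proba_test = predict_proba(model, scores.loc[test_ids])
    roc_test = roc_auc(labels.loc[test_ids], proba_test)
    roc_train = roc_auc(
        labels.loc[train_ids], predict_proba(model, scores.loc[train_ids])
    )
    return {
        "model": model,
        "scores": scores,
        "split": split,
        "train_roc": roc_train,
        "test_roc": roc_test,
        "test_auc": roc_test.auc,
    }


def random_signature_baseline(
    norm: ad.AnnData,
    size: int,
    labels: pd.Series,
    spec: SplitSpec | None = None,
    scoring: ScoringParams | None = None,
    n_reps: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Test AUCs of ``n_reps`` size-matched random signatures.

    Each repetition draws a fresh random gene set, a fresh split, and runs
    the identical split/score/fit/AUC pipeline; the returned AUC sample is
    the null reference the real signature is compared against.
    """
    if size < 1:
        raise ValueError("signature size must be >= 1")
    if size > norm.n_vars:
        raise ValueError("signature size exceeds the gene universe")
    spec = spec or SplitSpec()
    scoring = scoring or ScoringParams()
    aucs = np.empty(n_reps)
    for r in range(n_reps):
        rng = substream(seed, "baseline", r)
        genes = rng.choice(norm.var_names.to_numpy(), size=size, replace=False)
        sig = SignatureSet(f"random_{r}", list(genes))
        rep_spec = SplitSpec(spec.train_fraction, spec.stratify,
                             seed=int(substream(seed, "baseline-split", r).integers(2**31)))
        rep_scoring = ScoringParams(
            scoring.n_bins, scoring.n_ctrl,
            seed=int(substream(seed, "baseline-score", r).integers(2**31)),
            exclude_signature_from_controls=scoring.exclude_signature_from_controls,
        )
        aucs[r] = score_classifier_auc(norm, sig, labels, rep_spec, rep_scoring)[
            "test_auc"
        ]
    return aucs
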