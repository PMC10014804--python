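"""Linear-SVM population decoding with leave-one-out cross-validation.

Each trial is summarized as a vector of per-unit baseline-subtracted
Go-phase mean rates; a linear SVM (one-vs-rest, so each class carries a
decision value usable for Top-N ranking) is trained on all other trials and
scored on the held-out one.  Decoders: 8-direction unimanual, 16-configuration
bimanual, and two 4-direction bimanual decoders obtained by relabeling the
same trials by each arm's direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .preprocess import BinnedRates, go_phase_means

__all__ = [
    "FeatureMatrix",
    "DecodeResult",
    "build_features",
    "loocv_decode",
    "topn_accuracy",
    "bimanual_per_arm_decode",
]


@dataclass
class FeatureMatrix:
    """Trials x units feature matrix for one block, plus configuration labels."""

    X: np.ndarray
    labels: np.ndarray
    unit_ids: list[str]
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("X must be (n_trials, n_units) matching labels")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing entries")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def _config_label(row) -> str:
    if row.block_type == "ipsi":
        return f"{row.ipsi_dir_deg:g}"
    if row.block_type == "contra":
        return f"{row.contra_dir_deg:g}"
    return f"i{row.ipsi_dir_deg:g}|c{row.contra_dir_deg:g}"


def build_features(
    rates: BinnedRates,
    trials: pd.DataFrame,
    baseline: pd.DataFrame,
    block_id: int | None = None,
    block_type: str | None = None,
) -> FeatureMatrix:
    """Per-trial features for one block: mean Go-phase rate minus unit baseline.

    Select the block by ``block_id`` or by ``block_type`` (which must be
    unique in the session).  Labels are configuration identifiers: the target
    direction for unimanual blocks, the ``i<dir>|c<dir>`` pair for bimanual.
    """
    if (block_id is None) == (block_type is None):
        raise ValueError("pass exactly one of block_id or block_type")
    sel = trials["block_id"] == block_id if block_id is not None else trials["block_type"] == block_type
    block = trials[sel]
    if len(block) == 0:
        raise ValueError("no trials in the requested block")
    if block["block_id"].nunique() > 1:
        raise ValueError("block_type selects multiple blocks; pass block_id instead")
    base = baseline.set_index("unit_id")["mean_hz"]
    missing = [u for u in rates.unit_ids if u not in base.index]
    if missing:
        raise ValueError(f"units absent from baseline: {missing}")
    go = go_phase_means(rates, block)
    X = go.to_numpy() - base[rates.unit_ids].to_numpy()[None, :]
    labels = np.array([_config_label(r) for r in block.itertuples(index=False)])
    return FeatureMatrix(X=X, labels=labels, unit_ids=list(rates.unit_ids),
                         trial_ids=block["trial_id"].to_numpy())


@dataclass
class DecodeResult:
    """LOOCV outcome: confusion matrix, Top-N accuracies and per-fold scores."""

    classes: np.ndarray
    confusion_pct: np.ndarray  # rows = true class, row-normalized to percent
    topn_pct: dict[int, float]
    fold_true: np.ndarray
    fold_pred: np.ndarray
    fold_scores: np.ndarray  # (n_folds, n_classes), columns follow `classes`
    score_ties: bool

    @property
    def top1_pct(self) -> float:
        return self.topn_pct[1]

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion_pct, index=self.classes, columns=self.classes)

    def to_dict(self) -> dict:
        return dict(
            classes=self.classes.tolist(),
            confusion_pct=self.confusion_pct.tolist(),
            topn_pct={str(k): v for k, v in self.topn_pct.items()},
            fold_true=self.fold_true.tolist(),
            fold_pred=self.fold_pred.tolist(),
            fold_scores=self.fold_scores.tolist(),
            score_ties=self.score_ties,
        )

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def topn_accuracy(
    score_vectors: np.ndarray, true_labels: np.ndarray, n: int, classes: np.ndarray
) -> float:
    """Percent of folds whose true label ranks within the ``n`` highest scores.

    Exact score ties are broken by fixed class order (earlier class wins the
    higher rank).
    """
    scores = np.asarray(score_vectors, dtype=float)
    n_classes = scores.shape[1]
    if not (1 <= n <= n_classes):
        raise ValueError(f"N must be in [1, {n_classes}], got {n}")
    if len(classes) != n_classes:
        raise ValueError("classes must match the score vector width")
    class_idx = {c: i for i, c in enumerate(classes)}
    true_idx = np.array([class_idx[t] for t in true_labels])
    # rank descending by score, ties resolved by class order
    order = np.lexsort((np.arange(n_classes)[None, :].repeat(len(scores), 0), -scores), axis=1)
    hits = (order[:, :n] == true_idx[:, None]).any(axis=1)
    return float(100.0 * hits.mean())


def loocv_decode(
    features: FeatureMatrix, C: float = 1.0, standardize: bool = True
) -> DecodeResult:
    """Leave-one-out decoding with a linear one-vs-rest SVM.

    Each fold holds out one trial, optionally z-scores features with
    statistics fit on the training folds only, trains ``LinearSVC`` and
    records the held-out trial's per-class decision values.  The primal
    squared-hinge objective is strictly convex, so converged results do not
    depend on trial ordering.
    """
    classes = features.classes
    counts = pd.Series(features.labels).value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"classes with a single trial cannot be cross-validated: {list(thin.index)}; "
            "merge classes or record more repetitions"
        )
    n = len(features.labels)
    scores = np.empty((n, len(classes)))
    preds = np.empty(n, dtype=features.labels.dtype)
    for k in range(n):
        train = np.arange(n) != k
        Xtr, Xte = features.X[train], features.X[~train]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            # a unit constant across training trials carries no information
            scaler.scale_[scaler.scale_ == 0] = 1.0
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = LinearSVC(C=C, dual=False, tol=1e-6, max_iter=20000)
        clf.fit(Xtr, features.labels[train])
        dv = np.atleast_2d(clf.decision_function(Xte))
        if dv.shape[1] == 1:  # binary: expand to per-class scores
            dv = np.hstack([-dv, dv])
        # align to the global class order (every class is in training by construction)
        col = {c: i for i, c in enumerate(clf.classes_)}
        scores[k] = dv[0, [col[c] for c in classes]]
        preds[k] = classes[np.argmax(scores[k])]

    ties = bool(np.any([len(np.unique(s)) < len(s) for s in scores]))
    conf = np.zeros((len(classes), len(classes)))
    ci = {c: i for i, c in enumerate(classes)}
    for t, p in zip(features.labels, preds):
        conf[ci[t], ci[p]] += 1
    conf = 100.0 * conf / conf.sum(axis=1, keepdims=True)
    topn = {k: topn_accuracy(scores, features.labels, k, classes) for k in range(1, len(classes) + 1)}
    return DecodeResult(
        classes=classes,
        confusion_pct=conf,
        topn_pct=topn,
        fold_true=features.labels.copy(),
        fold_pred=preds,
        fold_scores=scores,
        score_ties=ties,
    )


def _split_bimanual_label(label: str) -> tuple[str, str]:
    ipsi, contra = label.split("|")
    if not (ipsi.startswith("i") and contra.startswith("c")):
        raise ValueError(f"not a bimanual configuration label: {label!r}")
    return ipsi[1:], contra[1:]


def bimanual_per_arm_decode(
    features: FeatureMatrix, C: float = 1.0, standardize: bool = True
) -> tuple[DecodeResult, DecodeResult]:
    """Decode each arm's 4 directions from the same bimanual trials.

    The 16-configuration feature rows are relabeled by the ipsilateral and
    contralateral target directions and decoded independently; returns
    ``(ipsi_result, contra_result)``.
    """
    pairs = [_split_bimanual_label(l) for l in features.labels]
    out = []
    for arm_labels in zip(*pairs):
        fm = FeatureMatrix(
            X=features.X,
            labels=np.array(arm_labels),
            unit_ids=features.unit_ids,
            trial_ids=features.trial_ids,
        )
        out.append(loocv_decode(fm, C=C, standardize=standardize))
    return out[0], out[1]
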