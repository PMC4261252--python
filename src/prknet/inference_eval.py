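"""Pairwise SVM on precomputed kernels, cross-validated ROC evaluation,
AUC confidence intervals, and McNemar comparison of paired classifiers.

The classifier is a soft-margin SVM trained on a precomputed pairwise Gram
matrix; its decision function on a query pair q is

    f(q) = Σ_p α_p d_p K(p, q) + b,

with support coefficients α ∈ [0, C], training labels d ∈ {+1, -1} and
offset b.  f(q) >= 0 classifies q as interacting (+1); exact zero maps to +1.
Evaluation uses stratified k-fold cross-validation with the ROC AUC in its
Mann-Whitney form (probability that a random positive outranks a random
negative, ties counted one half).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from prknet.rational_kernels import GramMatrix


@dataclass
class TrainedModel:
    """Pairwise SVM in dual form: α, b, training pair ids and labels.

    The feature map never materializes; everything flows through the kernel.
    ``alpha`` is dense over training pairs (zero off the support vectors).
    """

    alpha: np.ndarray
    labels: np.ndarray
    b: float
    pair_ids: list[str]
    C: float
    kernel_spec: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "alpha": {pid: float(a) for pid, a in zip(self.pair_ids, self.alpha)},
            "labels": {pid: int(d) for pid, d in zip(self.pair_ids, self.labels)},
            "b": float(self.b),
            "C": float(self.C),
            "kernel_spec": self.kernel_spec,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        pair_ids = list(doc["alpha"])
        return cls(
            alpha=np.array([doc["alpha"][p] for p in pair_ids]),
            labels=np.array([doc["labels"][p] for p in pair_ids]),
            b=float(doc["b"]),
            pair_ids=pair_ids,
            C=float(doc["C"]),
            kernel_spec=doc.get("kernel_spec", {}),
        )


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold AUCs, mean, CI and error count."""

    fold_aucs: list[float]
    mean_auc: float
    ci: tuple[float, float]
    n_errors: int
    n_pos: int
    n_neg: int
    seed: int
    folds: int

    def summary_rows(self) -> list[dict]:
        rows = [
            {"fold": i + 1, "auc": auc} for i, auc in enumerate(self.fold_aucs)
        ]
        rows.append({"fold": "mean", "auc": self.mean_auc})
        return rows


def train_svm(k: GramMatrix, labels: Sequence[int], c: float = 1.0) -> TrainedModel:
    """Fit the soft-margin dual on a precomputed (pairwise) kernel matrix.

    Delegates the quadratic program to the SMO solver of scikit-learn's SVC
    with ``kernel="precomputed"`` and recovers (α, d, b) so the decision
    function is reproducible from the model document alone.
    """
    if c <= 0:
        raise ValueError("C must be positive")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(k.ids),):
        raise ValueError("labels must align one-to-one with the kernel ids")
    if set(np.unique(labels)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded +1/-1")

    svc = SVC(kernel="precomputed", C=c)
    svc.fit(k.values, labels)

    alpha = np.zeros(len(labels))
    # dual_coef_ stores d_i * alpha_i over the support vectors
    alpha[svc.support_] = svc.dual_coef_[0] * labels[svc.support_]
    return TrainedModel(
        alpha=alpha,
        labels=labels,
        b=float(svc.intercept_[0]),
        pair_ids=list(k.ids),
        C=float(c),
    )


def decide(model: TrainedModel, k_row: Sequence[float]) -> float:
    """f(q) = Σ_p α_p d_p K(p, q) + b for one query pair.

    ``k_row`` holds the pairwise kernel values of the query against every
    training pair, in training order.
    """
    k_row = np.asarray(k_row, dtype=float)
    if k_row.shape != model.alpha.shape:
        raise ValueError(
            f"kernel row length {k_row.shape[0]} does not match {model.alpha.shape[0]} training pairs"
        )
    return float(np.dot(model.alpha * model.labels, k_row) + model.b)


def classify(score: float) -> int:
    """+1 when the decision score is >= 0 (interacting), else -1."""
    return 1 if score >= 0 else -1


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC in Mann-Whitney form.

    The fraction of (positive, negative) pairs where the positive scores
    higher, counting ties one half -- computed from midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_confidence_interval(
    auc: float,
    n_pos: int,
    n_neg: int,
    n_errors: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Distribution-free normal-approximation confidence interval for an AUC.

    The default variance estimate is the distribution-free bound on the
    variance of the Mann-Whitney statistic, Var(Â) <= Â(1 − Â)/min(m, n)
    for m positives and n negatives, giving a deliberately conservative
    interval that requires no assumption on the score distributions.  When
    the point estimate sits at 0 or 1 the bound degenerates, and the error
    rate k/(m+n) (k = classification errors at the decision threshold)
    supplies the spread instead, floored at 1/(m+n) so the interval never
    collapses on finite data.  The result is clipped to [0, 1].
    """
    if not (0 < level < 1):
        raise ValueError("confidence level must be in (0, 1)")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("positive and negative counts must be positive")
    if not (0.0 <= auc <= 1.0):
        raise ValueError("auc must lie in [0, 1]")
    if not (0 <= n_errors <= n_pos + n_neg):
        raise ValueError("error count must lie in [0, n_pos + n_neg]")

    m = min(n_pos, n_neg)
    var = auc * (1.0 - auc) / m
    if var == 0.0:
        r = n_errors / (n_pos + n_neg)
        var = max(r * (1.0 - r), 1.0 / (n_pos + n_neg)) / m
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * var ** 0.5
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def cross_validate(
    k: GramMatrix,
    labels: Sequence[int],
    c: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    level: float = 0.95,
) -> EvalReport:
    """Stratified k-fold cross-validation of the pairwise SVM.

    Folds are a seeded stratified random partition, so every test fold
    contains both classes on (near-)balanced data; each fold's AUC comes
    from decision scores of a model trained on the remaining folds, and the
    reported value is the average across folds.  Classification errors at
    the f >= 0 threshold accumulate over all test folds and parameterize
    the confidence interval.
    """
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    counts = {lab: int((labels == lab).sum()) for lab in (-1, 1)}
    if min(counts.values()) < folds:
        raise ValueError(
            f"cannot stratify: class counts {counts} are smaller than {folds} folds"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    n_errors = 0
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        sub = GramMatrix(
            [k.ids[i] for i in train_idx],
            k.values[np.ix_(train_idx, train_idx)],
            normalized=k.normalized,
        )
        model = train_svm(sub, labels[train_idx], c=c)
        rows = k.values[np.ix_(test_idx, train_idx)]
        scores = rows @ (model.alpha * model.labels) + model.b
        fold_aucs.append(roc_auc(scores, labels[test_idx]))
        preds = np.where(scores >= 0, 1, -1)
        n_errors += int((preds != labels[test_idx]).sum())

    mean_auc = float(np.mean(fold_aucs))
    ci = auc_confidence_interval(mean_auc, counts[1], counts[-1], n_errors, level=level)
    return EvalReport(
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=mean_auc,
        ci=ci,
        n_errors=n_errors,
        n_pos=counts[1],
        n_neg=counts[-1],
        seed=seed,
        folds=folds,
    )


def disagreement_counts(
    preds_a: Sequence[int], preds_b: Sequence[int], truth: Sequence[int]
) -> tuple[int, int]:
    """(n_fs, n_sf): counts where A failed/B succeeded and A succeeded/B failed."""
    preds_a = np.asarray(preds_a, dtype=int)
    preds_b = np.asarray(preds_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction and truth vectors must have equal length")
    a_ok = preds_a == truth
    b_ok = preds_b == truth
    n_fs = int((~a_ok & b_ok).sum())
    n_sf = int((a_ok & ~b_ok).sum())
    return n_fs, n_sf


def mcnemar_z(n_fs: int, n_sf: int, continuity: bool = False) -> float:
    """Signed McNemar statistic z = (n_fs − n_sf) / sqrt(n_fs + n_sf).

    ``n_fs`` counts items classifier A got wrong and B got right, ``n_sf``
    the reverse; positive z therefore favors B, and z = 0 means the two
    classifiers disagree symmetrically.  ``continuity`` applies the usual
    continuity correction (|d| − 1 in the numerator, keeping the sign).
    """
    if n_fs < 0 or n_sf < 0:
        raise ValueError("disagreement counts must be non-negative")
    total = n_fs + n_sf
    if total == 0:
        raise ValueError("both disagreement counts are zero: z is undefined")
    d = n_fs - n_sf
    if continuity:
        num = max(abs(d) - 1, 0) * (1 if d >= 0 else -1)
    else:
        num = d
    return float(num / total ** 0.5)
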