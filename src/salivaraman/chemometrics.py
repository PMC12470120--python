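"""PCA-LDA classification of subject spectra with leave-one-out validation.

The diagnostic model is the classical chemometric two-stage reduction:
principal components are extracted from the mean-centered subjects x
wavenumbers matrix, the top *k* component scores feed a two-class Fisher
discriminant, and each subject's projection on the single canonical axis is
their canonical-variable (CV) score. Validation is leave-one-out: PCA
centering, loadings and the discriminant are refit on every fold, so the
held-out subject never leaks into its own model.

Conventions
-----------
* The canonical axis is oriented so the control (CTR) class mean is
  positive; disease (OSAS) scores are therefore negative.
* The fold threshold is the midpoint of the two class mean scores (equal
  priors).
* The overall error is the *balanced* error: the unweighted mean of the two
  per-class misclassification fractions.

The public surface is both functional (``fit_pca``/``fit_lda``/``loocv``...)
and object-based: :class:`RamanPCALDA` is a statsmodels-style model whose
``fit()`` returns a :class:`RamanPCALDAResults` with estimates, diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, FitError

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "OSAS"
NEGATIVE_LABEL = "CTR"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centered singular value decomposition of the data matrix."""

    center: np.ndarray                      # (p,) feature means
    loadings: np.ndarray                    # (k, p) orthonormal rows
    explained_variance_fraction: np.ndarray  # (k,)
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.center) @ self.loadings.T


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA by SVD of the mean-centered matrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_k = min(n - 1, p)
    if not 1 <= n_components <= max_k:
        raise FitError(
            f"n_components must lie in 1..{max_k} for a {n}x{p} matrix, "
            f"got {n_components}"
        )
    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PCAModel(
        center=center,
        loadings=Vt[:n_components],
        explained_variance_fraction=frac[:n_components],
        n_components=n_components,
    )


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Two-class Fisher discriminant in PC-score space.

    ``direction`` is the unit canonical axis (proportional to
    ``Sw^-1 (m_pos - m_neg)``), signed so the negative-class (CTR) mean
    score is positive. ``threshold`` is the midpoint of the class means.
    """

    direction: np.ndarray
    group_means_on_cv: dict
    threshold: float
    positive_label: str = POSITIVE_LABEL
    negative_label: str = NEGATIVE_LABEL
    ridge_applied: bool = False

    def score(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(scores, dtype=float)) @ self.direction

    def predict(self, scores: np.ndarray) -> np.ndarray:
        cv = self.score(scores)
        pos_side = self.group_means_on_cv[self.positive_label] - self.threshold
        if pos_side < 0:
            is_pos = cv < self.threshold
        else:
            is_pos = cv > self.threshold
        return np.where(is_pos, self.positive_label, self.negative_label)


def fit_lda(
    scores: np.ndarray,
    labels: Sequence[str],
    positive_label: str = POSITIVE_LABEL,
    negative_label: str = NEGATIVE_LABEL,
) -> LDAModel:
    """Closed-form two-class Fisher discriminant ``Sw^-1 (m1 - m2)``.

    A ridge of ``1e-8 * trace(Sw)`` is added (and logged) when the pooled
    within-class scatter is numerically singular.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    classes = set(labels)
    if classes != {positive_label, negative_label}:
        raise DegenerateDataError(
            f"need exactly the two classes {positive_label}/{negative_label}, "
            f"got {sorted(classes)}"
        )
    pos = scores[labels == positive_label]
    neg = scores[labels == negative_label]
    m_pos, m_neg = pos.mean(axis=0), neg.mean(axis=0)
    Sw = (pos - m_pos).T @ (pos - m_pos) + (neg - m_neg).T @ (neg - m_neg)
    Sw = np.atleast_2d(Sw)
    ridge = False
    try:
        cond = np.linalg.cond(Sw)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        Sw = Sw + 1e-8 * np.trace(Sw) * np.eye(Sw.shape[0])
        ridge = True
        logger.info("LDA: ridge 1e-8*trace added to singular within scatter")
    try:
        direction = np.linalg.solve(Sw, m_pos - m_neg)
    except np.linalg.LinAlgError:
        Sw = Sw + 1e-8 * max(np.trace(Sw), 1e-30) * np.eye(Sw.shape[0])
        ridge = True
        direction = np.linalg.solve(Sw, m_pos - m_neg)
    norm = np.linalg.norm(direction)
    if norm < 1e-12 or not np.isfinite(norm):
        raise DegenerateDataError(
            "degenerate discriminant direction (identical class means?)"
        )
    direction = direction / norm
    # orient: CTR (negative label) mean positive on the canonical axis
    if float(m_neg @ direction) < 0:
        direction = -direction
    mu_pos = float(m_pos @ direction)
    mu_neg = float(m_neg @ direction)
    return LDAModel(
        direction=direction,
        group_means_on_cv={positive_label: mu_pos, negative_label: mu_neg},
        threshold=0.5 * (mu_pos + mu_neg),
        positive_label=positive_label,
        negative_label=negative_label,
        ridge_applied=ridge,
    )


# ---------------------------------------------------------------------------
# confusion / metrics
# ---------------------------------------------------------------------------

class Confusion(NamedTuple):
    """Two-class confusion counts; OSAS is the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float


def compute_metrics(confusion: Confusion) -> ClassificationMetrics:
    """Standard metrics from confusion counts; undefined margins raise."""
    tp, fn, tn, fp = confusion
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateDataError("a true-class margin is empty")
    if tp + fp == 0:
        raise DegenerateDataError("no positive predictions: precision undefined")
    return ClassificationMetrics(
        accuracy=(tp + tn) / (tp + fn + tn + fp),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        precision=tp / (tp + fp),
    )


def balanced_error(confusion: Confusion) -> float:
    """Unweighted mean of the two per-class error fractions."""
    tp, fn, tn, fp = confusion
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateDataError("a true-class margin is empty")
    return 0.5 * (fn / (tp + fn) + fp / (tn + fp))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    asymptotic_p: float


def roc_of_scores(
    scores: Sequence[float],
    labels: Sequence[str],
    positive_label: str = POSITIVE_LABEL,
) -> ROCResult:
    """ROC over all thresholds of `scores` (larger = more positive-class).

    The area equals the Mann-Whitney U statistic of the two score samples
    divided by ``n1*n2`` (ties counted one half); the asymptotic p-value is
    the tie-corrected normal approximation of the rank-sum null (AUC = 0.5),
    two-sided.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_label]
    neg = scores[labels != positive_label]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both classes must be present for ROC")
    if np.all(scores == scores[0]):
        return ROCResult(
            fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]), auc=0.5,
            asymptotic_p=1.0,
        )
    fpr, tpr, _ = roc_curve(labels == positive_label, scores)
    mw = stats.mannwhitneyu(
        pos, neg, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    )
    auc = float(mw.statistic) / (pos.size * neg.size)
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, asymptotic_p=float(mw.pvalue))


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    """Per-subject held-out canonical scores and derived error structure."""

    subject_ids: list
    labels: np.ndarray
    cv_scores: np.ndarray
    predicted: np.ndarray
    confusion: Confusion
    per_group_error: dict
    overall_error: float
    n_components_used: int

    @property
    def metrics(self) -> ClassificationMetrics:
        return compute_metrics(self.confusion)

    def roc(self) -> ROCResult:
        # canonical scores are CTR-positive; negate so larger = more OSAS
        return roc_of_scores(-self.cv_scores, self.labels, POSITIVE_LABEL)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "cv_score": self.cv_scores,
                "predicted": self.predicted,
                "truth": self.labels,
            }
        )


def _confusion_from(labels: np.ndarray, predicted: np.ndarray) -> Confusion:
    pos, neg = POSITIVE_LABEL, NEGATIVE_LABEL
    return Confusion(
        tp=int(np.sum((labels == pos) & (predicted == pos))),
        fn=int(np.sum((labels == pos) & (predicted == neg))),
        tn=int(np.sum((labels == neg) & (predicted == neg))),
        fp=int(np.sum((labels == neg) & (predicted == pos))),
    )


def _loocv_fold_scores(
    X: np.ndarray,
    labels: np.ndarray,
    ks: Sequence[int],
    refit_pca: bool = True,
) -> dict:
    """Held-out CV score and prediction per subject for every k in `ks`.

    The per-fold PCA is computed once at ``max(ks)`` components; the LDA for
    a smaller k uses the leading k fold scores, so the whole error-vs-k
    profile costs one SVD per fold.
    """
    n = X.shape[0]
    k_max = max(ks)
    out = {k: (np.empty(n), np.empty(n, dtype=object)) for k in ks}
    fixed_pca = None if refit_pca else fit_pca(X, k_max)
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X[keep], labels[keep]
        if len(set(y_tr)) < 2:
            raise DegenerateDataError(
                "a LOOCV training fold contains a single class"
            )
        pca = fit_pca(X_tr, min(k_max, X_tr.shape[0] - 1)) if refit_pca else fixed_pca
        tr_scores = pca.transform(X_tr)
        held = pca.transform(X[i : i + 1])
        for k in ks:
            lda = fit_lda(tr_scores[:, :k], y_tr)
            out[k][0][i] = lda.score(held[:, :k])[0]
            out[k][1][i] = lda.predict(held[:, :k])[0]
    return out


def loocv(
    X: np.ndarray,
    labels: Sequence[str],
    n_components: int,
    subject_ids: Optional[Sequence[str]] = None,
    refit_pca: bool = True,
) -> CrossValResult:
    """Leave-one-out cross-validation of the PCA-LDA classifier.

    With ``refit_pca=True`` (default) centering, loadings and discriminant
    are re-estimated on every fold; ``refit_pca=False`` reuses whole-data
    loadings (the leaky shortcut, kept only for comparison).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    for cls in (POSITIVE_LABEL, NEGATIVE_LABEL):
        if np.sum(labels == cls) < 2:
            raise DegenerateDataError(f"need >= 2 subjects in class {cls}")
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n)]
    scores, predicted = _loocv_fold_scores(X, labels, [n_components], refit_pca)[
        n_components
    ]
    predicted = predicted.astype(str)
    confusion = _confusion_from(labels, predicted)
    per_group = {
        POSITIVE_LABEL: confusion.fn / (confusion.tp + confusion.fn),
        NEGATIVE_LABEL: confusion.fp / (confusion.tn + confusion.fp),
    }
    return CrossValResult(
        subject_ids=list(subject_ids),
        labels=labels,
        cv_scores=scores,
        predicted=predicted,
        confusion=confusion,
        per_group_error=per_group,
        overall_error=balanced_error(confusion),
        n_components_used=n_components,
    )


class ComponentSelection(NamedTuple):
    n_components: int
    error_profile: np.ndarray  # balanced LOOCV error for k = 1..k_max


def select_n_components(
    X: np.ndarray,
    labels: Sequence[str],
    k_max: int,
    refit_pca: bool = True,
) -> ComponentSelection:
    """Smallest k in 1..k_max minimizing the balanced LOOCV error."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    limit = min(X.shape[0] - 2, X.shape[1])
    if not 1 <= k_max <= limit:
        raise FitError(f"k_max must lie in 1..{limit}, got {k_max}")
    ks = list(range(1, k_max + 1))
    folds = _loocv_fold_scores(X, labels, ks, refit_pca)
    errors = np.empty(k_max)
    for k in ks:
        predicted = folds[k][1].astype(str)
        errors[k - 1] = balanced_error(_confusion_from(labels, predicted))
    best = int(np.argmin(errors)) + 1  # argmin takes the first (smallest) k
    return ComponentSelection(n_components=best, error_profile=errors)


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects
# ---------------------------------------------------------------------------

class RamanPCALDA:
    """PCA-LDA diagnostic model over a subjects x wavenumbers matrix.

    Parameters
    ----------
    X : (n_subjects, n_features) array or DataFrame
        Preprocessed (averaged, normalized) subject spectra.
    labels : sequence of str
        Group label per subject (``OSAS``/``CTR``).
    n_components : int or None
        Number of principal components; ``None`` selects the smallest k
        in ``1..k_max`` minimizing the balanced LOOCV error.
    k_max : int
        Search limit for component selection.
    refit_pca_per_fold : bool
        Refit PCA inside every LOOCV fold (default, leakage-free).
    """

    def __init__(
        self,
        X,
        labels,
        n_components: Optional[int] = 6,
        k_max: int = 10,
        refit_pca_per_fold: bool = True,
    ):
        if isinstance(X, pd.DataFrame):
            self.subject_ids = list(X.index.astype(str))
            self.X = X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(X, dtype=float)
            self.subject_ids = [f"s{i}" for i in range(self.X.shape[0])]
        self.labels = np.asarray(labels).astype(str)
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels length must match the number of rows")
        self.n_components = n_components
        self.k_max = k_max
        self.refit_pca_per_fold = refit_pca_per_fold

    @classmethod
    def from_preprocessed(cls, result, **kwargs) -> "RamanPCALDA":
        """Build from a :class:`~salivaraman.preprocess.PreprocessResult`."""
        return cls(result.matrix, result.labels.to_numpy(), **kwargs)

    def fit(self) -> "RamanPCALDAResults":
        selection = None
        k = self.n_components
        if k is None:
            k_max = min(self.k_max, self.X.shape[0] - 2, self.X.shape[1])
            selection = select_n_components(
                self.X, self.labels, k_max, self.refit_pca_per_fold
            )
            k = selection.n_components
        pca = fit_pca(self.X, k)
        lda = fit_lda(pca.transform(self.X)[:, :k], self.labels)
        crossval = loocv(
            self.X, self.labels, k, self.subject_ids, self.refit_pca_per_fold
        )
        return RamanPCALDAResults(
            model=self, pca=pca, lda=lda, crossval=crossval, selection=selection
        )


@dataclass
class RamanPCALDAResults:
    """Fitted PCA-LDA model plus its leave-one-out validation."""

    model: RamanPCALDA
    pca: PCAModel
    lda: LDAModel
    crossval: CrossValResult
    selection: Optional[ComponentSelection] = None
    _roc: Optional[ROCResult] = field(default=None, repr=False)

    @property
    def metrics(self) -> ClassificationMetrics:
        return self.crossval.metrics

    @property
    def roc(self) -> ROCResult:
        if self._roc is None:
            self._roc = self.crossval.roc()
        return self._roc

    def summary(self) -> str:
        cv, m, roc = self.crossval, self.metrics, self.roc
        lines = [
            "PCA-LDA diagnosis of OSAS vs CTR (leave-one-out validation)",
            "=" * 60,
            f"subjects: {len(cv.subject_ids)}  "
            f"(OSAS {int(np.sum(cv.labels == POSITIVE_LABEL))}, "
            f"CTR {int(np.sum(cv.labels == NEGATIVE_LABEL))})",
            f"principal components used: {cv.n_components_used}",
        ]
        if self.selection is not None:
            profile = ", ".join(
                f"k={i + 1}: {e:.4f}" for i, e in enumerate(self.selection.error_profile)
            )
            lines.append(f"balanced LOOCV error vs k: {profile}")
        t = cv.confusion
        lines += [
            f"confusion: TP={t.tp} FN={t.fn} TN={t.tn} FP={t.fp}",
            f"per-group error: OSAS {cv.per_group_error[POSITIVE_LABEL]:.2%}, "
            f"CTR {cv.per_group_error[NEGATIVE_LABEL]:.2%}",
            f"overall (balanced) error: {cv.overall_error:.2%}",
            f"accuracy {m.accuracy:.2%}  sensitivity {m.sensitivity:.2%}  "
            f"specificity {m.specificity:.2%}  precision {m.precision:.2%}",
            f"ROC AUC of the canonical variable: {roc.auc:.4f} "
            f"(asymptotic p = {roc.asymptotic_p:.3g})",
        ]
        return "\n".join(lines)
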