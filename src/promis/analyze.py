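"""Statistics layer: normalization, classification, ordination, precision.

The readout analysis follows the standard serum-profiling recipe: per-sample
median normalization to put sequencing depths on a common scale, log2
transform (with a pseudocount to guard zero counts), supervised two-group
classification with a linear-kernel SVM under leave-one-out cross-validation
summarized as a ROC-AUC, unsupervised PCA for 3-D visualization, and
intra-assay precision as the per-scFv coefficient of variation over technical
replicates (CV% = 100 * sd / mean).

AUC is the tie-corrected Mann-Whitney pair statistic: over all (case, control)
score pairs, the fraction with case > control, ties counted as 1/2 — 1.0 is a
perfect classifier, 0.5 a random one.  LOO decision values are pooled across
folds into a single ROC, the only construction consistent with one held-out
score per sample; feature standardization is computed on each training fold
only, so no information leaks from the held-out sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "AnalysisParams",
    "ClassificationResult",
    "PCAResult",
    "StudyReport",
    "AnalysisError",
    "median_normalize",
    "log2_transform",
    "svm_loo_scores",
    "roc_auc",
    "pca",
    "replicate_cv",
    "run_study",
]

CASE, CONTROL = "case", "control"


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisParams:
    pseudocount: float = 1.0
    svm_cost: float = 1.0
    scale_features: bool = True
    pca_components: int = 3
    pca_scale: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise AnalysisError("pseudocount must be >= 0")
        if self.svm_cost <= 0:
            raise AnalysisError("svm_cost must be > 0")


@dataclass
class ClassificationResult:
    decision_values: pd.Series  # per-sample LOO decision value
    labels: pd.Series  # case/control per sample
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # fractions, nonincreasing, sum <= 1
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class StudyReport:
    classification: ClassificationResult
    pca: PCAResult
    expression: pd.DataFrame  # normalized, log2-transformed matrix


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))


def median_normalize(counts) -> pd.DataFrame:
    """Scale each sample so its per-scFv median equals the grand median.

    Sample j's counts are multiplied by M / m_j where m_j is the median of
    sample j's counts across scFvs and M is the median of the m_j over
    samples.  Idempotent: renormalizing a normalized matrix is a no-op.
    """
    X = _as_frame(counts).astype(float)
    m = X.median(axis=1)
    zero = m[m <= 0]
    if len(zero):
        raise AnalysisError(
            f"sample(s) with nonpositive median count: {list(zero.index)}"
        )
    M = float(m.median())
    return X.mul(M / m, axis=0)


def log2_transform(matrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """x -> log2(x + pseudocount); requires x >= 0 and rejects a zero
    pseudocount when zeros are present (log2(0) is not representable)."""
    X = _as_frame(matrix).astype(float)
    if (X.to_numpy() < 0).any():
        raise AnalysisError("negative values cannot be log2 transformed")
    if pseudocount == 0 and (X.to_numpy() == 0).any():
        raise AnalysisError("zero values require a positive pseudocount")
    return np.log2(X + pseudocount)


def _binary_labels(labels, n: int) -> np.ndarray:
    y = np.asarray([1 if str(l) == CASE else 0 for l in labels])
    if len(y) != n:
        raise AnalysisError("label length does not match sample count")
    if y.sum() == 0 or y.sum() == n:
        raise AnalysisError("both classes must be present")
    return y


def svm_loo_scores(X, labels, params: AnalysisParams | None = None) -> pd.Series:
    """Leave-one-out decision values from a linear-kernel soft-margin SVM.

    For each sample, an SVM (cost = ``svm_cost``) is fit on all other samples
    using every feature (no pre-selection); features are z-scored with
    training-fold statistics only when ``scale_features``.  Returns the signed
    distance of each held-out sample from its fold's hyperplane, oriented so
    positive means case-like.
    """
    params = params or AnalysisParams()
    Xf = _as_frame(X)
    y = _binary_labels(labels, len(Xf))
    A = Xf.to_numpy(dtype=float)
    n = len(A)
    scores = np.empty(n)
    for i in range(n):
        train = np.arange(n) != i
        ytr = y[train]
        if ytr.min() == ytr.max():
            raise AnalysisError(
                f"leaving out sample {Xf.index[i]!r} yields a one-class training fold"
            )
        Xtr, Xte = A[train], A[i : i + 1]
        if params.scale_features:
            scaler = StandardScaler().fit(Xtr)
            # constant features carry no training information; scaler maps
            # them to 0, which is the correct no-op
            with np.errstate(invalid="ignore"):
                Xtr = scaler.transform(Xtr)
                Xte = scaler.transform(Xte)
            Xtr = np.nan_to_num(Xtr)
            Xte = np.nan_to_num(Xte)
        clf = SVC(kernel="linear", C=params.svm_cost)
        clf.fit(Xtr, ytr)
        d = float(clf.decision_function(Xte)[0])
        # SVC orients by class order {0,1}; positive = class 1 = case
        scores[i] = d
    return pd.Series(scores, index=Xf.index, name="decision_value")


def roc_auc(scores, labels) -> ClassificationResult:
    """ROC curve and tie-corrected Mann-Whitney AUC from pooled scores.

    AUC = P(case score > control score) + 0.5 * P(tie), computed via midranks
    (exactly the all-pairs enumeration, without the quadratic loop).
    """
    s = pd.Series(scores).astype(float)
    y = _binary_labels(labels, len(s))
    pos, neg = int(y.sum()), int(len(y) - y.sum())
    ranks = rankdata(s.to_numpy())  # midranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - pos * (pos + 1) / 2) / (pos * neg)
    fpr, tpr, _ = roc_curve(y, s.to_numpy())
    return ClassificationResult(
        decision_values=s,
        labels=pd.Series(list(labels), index=s.index, name="group_label"),
        fpr=fpr,
        tpr=tpr,
        auc=float(auc),
    )


def pca(X, params: AnalysisParams | None = None) -> PCAResult:
    """Centered (and by default unit-variance scaled) principal components.

    Zero-variance features are dropped with a warning when scaling (they have
    no direction to contribute).  Returns sample scores on the first
    ``pca_components`` axes, feature loadings, and variance-explained
    fractions (nonincreasing, summing to <= 1).
    """
    params = params or AnalysisParams()
    Xf = _as_frame(X)
    if len(Xf) < 2:
        raise AnalysisError("PCA requires >= 2 samples")
    dropped: list[str] = []
    if params.pca_scale:
        var = Xf.var(axis=0, ddof=0)
        dropped = [str(c) for c in Xf.columns[var == 0]]
        if dropped:
            warnings.warn(f"dropping zero-variance feature(s) for scaled PCA: {dropped}")
            Xf = Xf.loc[:, var > 0]
        Xs = (Xf - Xf.mean(axis=0)) / Xf.std(axis=0, ddof=1)
    else:
        Xs = Xf - Xf.mean(axis=0)
    k = min(params.pca_components, Xs.shape[1], len(Xs) - 1)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Xs.to_numpy())
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=Xf.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=Xf.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_.copy(),
        dropped_features=dropped,
    )


def replicate_cv(replicates, as_percent: bool = True) -> pd.Series:
    """Per-scFv coefficient of variation across technical replicates.

    CV = sd / mean with the sample (n-1) standard deviation, reported in %
    by default.  A zero mean makes the CV undefined; those entries are NaN.
    Requires >= 2 replicates (rows).
    """
    R = _as_frame(replicates).astype(float)
    if len(R) < 2:
        raise AnalysisError("CV requires >= 2 technical replicates")
    mean = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return (100.0 * cv if as_percent else cv).rename("cv")


def run_study(counts, labels, params: AnalysisParams | None = None) -> StudyReport:
    """Full analysis: median normalize -> log2 -> LOO-SVM ROC-AUC, plus PCA
    on the same expression matrix."""
    params = params or AnalysisParams()
    expr = log2_transform(median_normalize(counts), params.pseudocount)
    scores = svm_loo_scores(expr, labels, params)
    classification = roc_auc(scores, labels)
    ordination = pca(expr, params)
    return StudyReport(classification=classification, pca=ordination, expression=expr)
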