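"""Pattern recognition: NIPALS PCA, Hotelling's T², and LDA on PC scores.

The decomposition is the classical NIPALS (Nonlinear Iterative Partial
Least Squares) sequential power iteration with deflation, which extracts
principal components one at a time from the mean-centered data matrix.  On
a matrix with distinct singular values it coincides with the truncated SVD
up to per-component sign; the sign convention here makes each loading's
largest-magnitude element positive so runs are comparable.

Classification follows the distance-to-class-mean family: the *linear*
classifier uses Mahalanobis distance under the pooled within-class
covariance of the PC scores, the *mahalanobis* classifier uses per-class
covariances.  Accuracy is reported both on a stratified held-out split and
on all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import extract_region, vector_normalize
from .spectrum import SpectrumSet

__all__ = [
    "PCAModel",
    "LDAModel",
    "ConfusionMatrix",
    "pca_nipals",
    "hotelling_t2",
    "lda_fit",
    "discriminate_groups",
    "DiscriminationReport",
]


@dataclass
class PCAModel:
    scores: np.ndarray            # n × k
    loadings: np.ndarray          # k × p, rows orthonormal
    explained_variance: np.ndarray  # percent of total, length k
    column_means: np.ndarray      # p, used for centering
    converged: np.ndarray         # bool per component
    iterations: np.ndarray        # iteration count per component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.column_means) @ self.loadings.T


def pca_nipals(X: np.ndarray, k: int, tol: float = 1e-9,
               max_iter: int = 1000, center: bool = True) -> PCAModel:
    """NIPALS principal component analysis.

    Components are extracted sequentially; each is converged when the
    relative change of the score vector between iterations falls below
    ``tol``.  Non-convergence raises a warning and returns the partial
    estimate for that component.  ``X`` is mean-centered first unless
    ``center=False`` (then it must already be centered).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples × variables)")
    n, p = X.shape
    kmax = min(n - 1, p)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}] for a {n}×{p} matrix")
    mu = X.mean(axis=0) if center else np.zeros(p)
    E = X - mu
    total_ss = float((E**2).sum())
    # relative threshold: centering identical rows leaves numerical dust
    if total_ss <= 1e-20 * max(float((X**2).sum()), 1e-300):
        raise ValueError("matrix has zero variance after centering")

    scores = np.zeros((n, k))
    loadings = np.zeros((k, p))
    expl = np.zeros(k)
    converged = np.zeros(k, dtype=bool)
    iters = np.zeros(k, dtype=int)
    for j in range(k):
        col_ss = (E**2).sum(axis=0)
        if col_ss.max() <= 1e-30 * total_ss:
            # residual exhausted: truncate the model
            scores, loadings = scores[:, :j], loadings[:j]
            expl, converged, iters = expl[:j], converged[:j], iters[:j]
            break
        t = E[:, int(np.argmax(col_ss))].copy()
        it = 0
        for it in range(1, max_iter + 1):
            pvec = E.T @ t / float(t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = E @ pvec
            delta = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new),
                                                    1e-30)
            t = t_new
            if delta < tol:
                converged[j] = True
                break
        iters[j] = it
        if not converged[j]:
            warnings.warn(
                f"NIPALS component {j + 1} did not converge in {max_iter} "
                "iterations; returning partial estimate", RuntimeWarning)
        # sign convention: largest-|.| loading element positive
        imax = int(np.argmax(np.abs(pvec)))
        if pvec[imax] < 0:
            pvec, t = -pvec, -t
        scores[:, j] = t
        loadings[j] = pvec
        expl[j] = 100.0 * float(t @ t) / total_ss
        E = E - np.outer(t, pvec)
    return PCAModel(scores, loadings, expl, mu, converged, iters)


def hotelling_t2(model: PCAModel, alpha: float = 0.05
                 ) -> tuple[np.ndarray, float, np.ndarray]:
    """Hotelling's T² of each sample in PC-score space.

    T²(i) = Σ_j scores(i,j)² / λ_j with λ_j the (n−1)-denominator variance
    of score column j; the control limit is k(n−1)/(n−k) · F(1−α; k, n−k).
    Returns (T² values, limit, boolean outlier flags).
    """
    T = model.scores
    n, k = T.shape
    if k < 1:
        raise ValueError("model has no components")
    if n <= k:
        raise ValueError(f"threshold undefined: need n > k (n={n}, k={k})")
    lam = T.var(axis=0, ddof=1)
    if np.any(lam <= 0):
        raise ValueError("zero-variance score column")
    t2 = (T**2 / lam).sum(axis=1)
    limit = k * (n - 1) / (n - k) * sps.f.ppf(1 - alpha, k, n - k)
    return t2, float(limit), t2 > limit


@dataclass
class ConfusionMatrix:
    classes: tuple
    counts: np.ndarray  # true × predicted

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return 100.0 * float(np.trace(self.counts)) / float(total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               classes: Sequence) -> ConfusionMatrix:
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(tuple(classes), counts)


def _ridge_inv(cov: np.ndarray) -> np.ndarray:
    m = cov.shape[0]
    try:
        # reject near-singular even when formally invertible
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        lam = 1e-8 * np.trace(cov) / m
        if lam <= 0:
            lam = 1e-12
        warnings.warn(f"singular covariance: ridge-regularized with "
                      f"lambda={lam:.3e}", RuntimeWarning)
        cov = cov + lam * np.eye(m)
    return np.linalg.inv(cov)


@dataclass
class LDAModel:
    classes: tuple
    kind: str                      # "linear" or "mahalanobis"
    means: np.ndarray              # classes × m
    pooled_cov: np.ndarray         # m × m
    class_covs: dict = field(default_factory=dict)
    priors: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = np.zeros((X.shape[0], len(self.classes)))
        for i, c in enumerate(self.classes):
            cov = (self.class_covs.get(c, self.pooled_cov)
                   if self.kind == "mahalanobis" else self.pooled_cov)
            inv = _ridge_inv(cov)
            diff = X - self.means[i]
            d2[:, i] = np.einsum("ij,jk,ik->i", diff, inv, diff)
        picks = np.argmin(d2, axis=1)
        return np.array([self.classes[i] for i in picks])


def _stratified_split(labels: np.ndarray, train_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in pd.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(train_fraction * idx.size)))
        if n_train >= idx.size:
            n_train = idx.size - 1  # keep at least one held-out sample
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def lda_fit(scores: np.ndarray, labels: Sequence, kind: str = "linear",
            split: float = 2 / 3, seed: int = 0
            ) -> tuple[LDAModel, pd.DataFrame, ConfusionMatrix,
                       ConfusionMatrix]:
    """Fit a distance-to-mean classifier on PC scores.

    A stratified random ``split`` fraction (per class) trains the model;
    the rest is held out.  Returns (model, per-sample prediction table,
    held-out confusion matrix, all-samples confusion matrix).
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("scores must be n × m with one label per row")
    if kind not in ("linear", "mahalanobis"):
        raise ValueError(f"unknown classifier kind {kind!r}")
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y, split, rng)
    Xtr, ytr = X[train_idx], y[train_idx]

    means = np.vstack([Xtr[ytr == c].mean(axis=0) for c in classes])
    # pooled within-class covariance
    dof = 0
    S = np.zeros((m, m))
    for i, c in enumerate(classes):
        G = Xtr[ytr == c] - means[i]
        S += G.T @ G
        dof += G.shape[0] - 1
    pooled = S / max(dof, 1)

    class_covs: dict = {}
    if kind == "mahalanobis":
        for i, c in enumerate(classes):
            G = Xtr[ytr == c]
            if G.shape[0] <= m:
                warnings.warn(
                    f"class {c!r}: {G.shape[0]} training samples <= {m} "
                    "dimensions; falling back to pooled covariance",
                    RuntimeWarning)
                class_covs[c] = pooled
            else:
                class_covs[c] = np.cov(G, rowvar=False, ddof=1)

    priors = np.full(len(classes), 1.0 / len(classes))
    model = LDAModel(classes, kind, means, pooled, class_covs, priors)
    y_pred = model.predict(X)
    table = pd.DataFrame({
        "label": y,
        "predicted": y_pred,
        "role": np.where(np.isin(np.arange(y.size), train_idx),
                         "train", "test"),
    })
    cm_holdout = _confusion(y[test_idx], y_pred[test_idx], classes)
    cm_all = _confusion(y, y_pred, classes)
    return model, table, cm_holdout, cm_all


@dataclass
class DiscriminationReport:
    pca: PCAModel
    lda: LDAModel
    predictions: pd.DataFrame
    confusion_holdout: ConfusionMatrix
    confusion_all: ConfusionMatrix
    t2: np.ndarray
    t2_limit: float
    region: tuple[float, float]
    labels: np.ndarray

    @property
    def holdout_accuracy(self) -> float:
        return self.confusion_holdout.accuracy

    @property
    def training_accuracy(self) -> float:
        cm = self.predictions[self.predictions["role"] == "train"]
        return 100.0 * float((cm["label"] == cm["predicted"]).mean())

    @property
    def overall_accuracy(self) -> float:
        return self.confusion_all.accuracy

    def scores_frame(self) -> pd.DataFrame:
        k = self.pca.n_components
        df = pd.DataFrame(self.pca.scores,
                          columns=[f"PC{i + 1}" for i in range(k)])
        df.insert(0, "label", self.labels)
        df["T2"] = self.t2
        return df


def discriminate_groups(
    spectra: SpectrumSet,
    region: tuple[float, float] = (650.0, 4000.0),
    label_key: str = "dose",
    k: int | None = None,
    m: int | None = None,
    kind: str = "linear",
    split: float = 2 / 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> DiscriminationReport:
    """Region PCA + PC-score LDA of a labelled spectrum set.

    Pipeline: extract ``region`` → vector-normalize → mean-center →
    NIPALS PCA (``k`` components, default min(10, rank)) → LDA on the
    first ``m`` scores.  The default ``m`` is min(10, k) further capped at
    half the pooled-covariance degrees of freedom (training samples minus
    classes), so the distance metric stays well conditioned at small n.
    """
    labels = np.array([s.metadata.get(label_key) for s in spectra])
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    regioned = spectra.map(lambda s: vector_normalize(
        extract_region(s, region)))
    X = regioned.matrix()
    n, p = X.shape
    if k is None:
        k = min(10, n - 1, p)
    pca = pca_nipals(X, k)
    if m is None:
        n_train = sum(min(max(1, int(round(split * c))), c - 1)
                      for c in counts)
        dof = n_train - len(counts)
        m = max(1, min(10, pca.n_components, dof // 2))
    m = min(m, pca.n_components)
    t2, limit, _ = hotelling_t2(pca)
    lda, preds, cm_holdout, cm_all = lda_fit(pca.scores[:, :m], labels,
                                             kind=kind, split=split,
                                             seed=seed)
    return DiscriminationReport(pca, lda, preds, cm_holdout, cm_all,
                                t2, limit, region, labels)
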