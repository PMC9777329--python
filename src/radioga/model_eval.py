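"""Logistic classification and cross-validated evaluation.

`LogisticRegressionModel` follows the model/fit/results idiom: the model
is built from data, ``fit()`` maximizes the Bernoulli likelihood by
iteratively reweighted least squares and returns a
:class:`LogisticResults` carrying coefficients, standard errors,
log-likelihood, AIC and a ``summary()`` table. ``kfold_cv`` evaluates a
whole processing pipeline (whitening, optional feature re-selection,
logistic fit) under stratified k-fold cross-validation and reports AUC,
sensitivity, specificity and accuracy per fold and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .io import ValidationError
from .tables import FeatureTable


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))  # overflow-safe logistic


class LogisticRegressionModel:
    """Binary logistic regression P(Y=1|x) = 1 / (1 + exp(-θ₀ - θᵀx)).

    Parameters
    ----------
    X : (n, p) array of finite predictor values.
    y : (n,) array of 0/1 labels; both classes must be present.
    feature_names : optional names aligned to the columns of X.
    """

    def __init__(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite predictor values")
        if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
            raise ValidationError("labels must contain both classes, coded 0/1")
        if X.shape[0] != y.size:
            raise ValidationError("X and y lengths differ")
        self.X = X
        self.y = y
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i + 1}" for i in range(X.shape[1])]
        )
        if len(self.feature_names) != X.shape[1]:
            raise ValidationError("feature name count mismatch")

    @classmethod
    def from_table(cls, table: FeatureTable, genes: Sequence[str] | None = None):
        sub = table.subset(genes) if genes is not None else table
        return cls(sub.values, sub.labels, sub.feature_names)

    def loglike(self, params: np.ndarray) -> float:
        """Bernoulli log-likelihood at [θ₀, θ₁..θ_p]."""
        eta = params[0] + self.X @ params[1:]
        # log L = Σ y·η − log(1+e^η), computed stably
        return float((self.y * eta - np.logaddexp(0.0, eta)).sum())

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "LogisticResults":
        """Maximum likelihood via IRLS (Newton-Raphson).

        Converged when max |Δθ| < ``tol``; under perfect separation the
        likelihood has no finite maximum, the iteration cap is reached and
        the results carry ``converged=False`` (a warning, not a failure).
        """
        n, p = self.X.shape
        Z = np.column_stack([np.ones(n), self.X])
        theta = np.zeros(p + 1)
        converged = False
        for _ in range(max_iter):
            mu = _sigmoid(Z @ theta)
            w = mu * (1.0 - mu)
            grad = Z.T @ (self.y - mu)
            H = (Z * np.maximum(w, 1e-12)[:, None]).T @ Z
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            theta = theta + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        mu = _sigmoid(Z @ theta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        cov = np.linalg.pinv((Z * w[:, None]).T @ Z)
        return LogisticResults(
            model=self,
            params=theta,
            bse=np.sqrt(np.diag(cov)),
            llf=self.loglike(theta),
            converged=converged,
        )


@dataclass
class LogisticResults:
    """Fitted coefficients and diagnostics of a logistic model."""

    model: LogisticRegressionModel
    params: np.ndarray  # [intercept, coefs...]
    bse: np.ndarray
    llf: float
    converged: bool

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.model.feature_names, self.params[1:].tolist()))

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        """Akaike information criterion, 2k − 2·logL."""
        return 2.0 * self.n_params - 2.0 * self.llf

    def _align(self, x) -> np.ndarray:
        if isinstance(x, dict):
            missing = [n for n in self.model.feature_names if n not in x]
            if missing:
                raise ValidationError(f"missing features: {missing}")
            x = [x[n] for n in self.model.feature_names]
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[-1] != len(self.model.feature_names):
            raise ValidationError("feature count mismatch")
        return x

    def predict_prob(self, x) -> np.ndarray:
        """P(Y=1|x); accepts an array or a name->value mapping."""
        x = self._align(x)
        return _sigmoid(self.params[0] + x @ self.params[1:])

    def classify(self, x, threshold: float = 0.5) -> np.ndarray:
        """1 iff predicted probability >= threshold (boundary inclusive)."""
        return (self.predict_prob(x) >= threshold).astype(int)

    def summary(self) -> str:
        lines = [
            "Logistic regression (maximum likelihood, IRLS)",
            f"  n = {self.model.X.shape[0]}, params = {self.n_params}, "
            f"converged = {self.converged}",
            f"  log-likelihood = {self.llf:.4f}   AIC = {self.aic:.4f}",
            f"  {'term':<32}{'coef':>12}{'std err':>12}{'z':>9}{'P>|z|':>9}",
        ]
        terms = ["(intercept)"] + list(self.model.feature_names)
        for name, b, se in zip(terms, self.params, self.bse):
            z = b / se if se > 0 else np.inf
            pv = 2 * (1 - stats.norm.cdf(abs(z)))
            lines.append(f"  {name:<32}{b:>12.4f}{se:>12.4f}{z:>9.3f}{pv:>9.3f}")
        return "\n".join(lines)


def fit_logistic(X, y, feature_names=None) -> LogisticResults:
    """Convenience wrapper: build the model and fit it."""
    return LogisticRegressionModel(X, y, feature_names).fit()


def aic(results: LogisticResults) -> float:
    return results.aic


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic: (concordant + 0.5·ties) / (n1·n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes required for AUC")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size))


def confusion_metrics(pred, labels) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from binary predictions."""
    pred = np.asarray(pred).astype(int)
    labels = np.asarray(labels).astype(int)
    if pred.shape != labels.shape:
        raise ValidationError("length mismatch")
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(labels)
    return sens, spec, acc


@dataclass
class FoldMetrics:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    test_indices: list[int]


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation metrics.

    Pooled values are the arithmetic mean over folds. ``full_fit_aic`` and
    the ``full_*`` metrics come from a single refit on all samples (the
    genes of that refit are re-derived on the full data when selection is
    part of the evaluated pipeline).
    """

    folds: list[FoldMetrics]
    seed: int
    k: int
    full_fit_aic: float
    full_genes: list[str]
    full_auc: float
    full_accuracy: float

    def _pool(self, attr: str) -> float:
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    @property
    def auc(self) -> float:
        return self._pool("auc")

    @property
    def sensitivity(self) -> float:
        return self._pool("sensitivity")

    @property
    def specificity(self) -> float:
        return self._pool("specificity")

    @property
    def accuracy(self) -> float:
        return self._pool("accuracy")

    @property
    def aic(self) -> float:
        return self.full_fit_aic

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "pooled": {
                "AUC": self.auc,
                "Sensitivity": self.sensitivity,
                "Specificity": self.specificity,
                "Accuracy": self.accuracy,
                "AIC": self.full_fit_aic,
            },
            "full_refit": {
                "AUC": self.full_auc,
                "Accuracy": self.full_accuracy,
                "genes": self.full_genes,
            },
            "folds": [
                {
                    "AUC": f.auc,
                    "Sensitivity": f.sensitivity,
                    "Specificity": f.specificity,
                    "Accuracy": f.accuracy,
                    "test_indices": f.test_indices,
                }
                for f in self.folds
            ],
        }

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold cross-validation (seed {self.seed})",
            f"  pooled AUC         {self.auc:.4f}",
            f"  pooled Sensitivity {self.sensitivity:.4f}",
            f"  pooled Specificity {self.specificity:.4f}",
            f"  pooled Accuracy    {self.accuracy:.4f}",
            f"  AIC (full refit)   {self.full_fit_aic:.2f}",
            f"  genes (full refit) {', '.join(self.full_genes)}",
        ]
        return "\n".join(lines)


def kfold_cv(
    table: FeatureTable,
    select: Callable[[FeatureTable], list[str]] | Sequence[str],
    k: int = 3,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold evaluation of whiten -> select -> logistic fit.

    ``select`` is either a fixed gene list or a callable re-run on every
    training fold (and once on the full data for the reported model), so
    selection never sees the held-out fold. Whitening statistics are
    likewise fit per training fold. Pooled metrics are means over folds.
    """
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes required")
    if counts.min() < k:
        raise ValidationError(f"each class needs at least k={k} samples")

    from .selection import whiten

    def _genes_for(sub: FeatureTable) -> list[str]:
        if callable(select):
            return list(select(sub))
        return list(select)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldMetrics] = []
    for tr, te in skf.split(table.values, y):
        train = table.rows(tr)
        mu = train.values.mean(axis=0)
        sd = train.values.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        train_w = FeatureTable(
            (train.values - mu) / sd, list(train.feature_names), train.labels
        )
        genes = _genes_for(train_w)
        res = LogisticRegressionModel.from_table(train_w, genes).fit()
        test_w = (table.values[te] - mu) / sd
        idx = [table.feature_names.index(g) for g in genes]
        probs = res.predict_prob(test_w[:, idx])
        pred = (probs >= threshold).astype(int)
        sens, spec, acc = confusion_metrics(pred, y[te])
        folds.append(
            FoldMetrics(
                auc=roc_auc(probs, y[te]),
                sensitivity=sens,
                specificity=spec,
                accuracy=acc,
                test_indices=[int(i) for i in te],
            )
        )

    full_w = whiten(table)
    full_genes = _genes_for(full_w)
    full_res = LogisticRegressionModel.from_table(full_w, full_genes).fit()
    full_probs = full_res.predict_prob(full_w.subset(full_genes).values)
    _, _, full_acc = confusion_metrics((full_probs >= threshold).astype(int), y)
    return CVReport(
        folds=folds,
        seed=seed,
        k=k,
        full_fit_aic=full_res.aic,
        full_genes=full_genes,
        full_auc=roc_auc(full_probs, y),
        full_accuracy=full_acc,
    )
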