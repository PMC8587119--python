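"""Pooled-covariance linear discriminant classification and reference
selection.

The motion decoder is classical LDA: one Gaussian per motion class with a
shared covariance, giving a linear discriminant score per class.  The same
fitted model exposes the top-2 discriminant directions used to draw reduced
feature maps.  ``ReferenceSelector`` reproduces the calibration procedure:
three independent stratified 3:1 splits, the split whose model attains the
highest macro-averaged held-out sensitivity wins, and that split's held-out
predictions are retained for the per-state performance screening.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

MODEL_SCHEMA_VERSION = 1


class PooledCovarianceLDA(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Linear discriminant analysis with a shared (pooled) class covariance.

    The discriminant score of class c for a vector x is

        delta_c(x) = x' S^-1 m_c - m_c' S^-1 m_c / 2 + log pi_c

    with m_c the class mean, S the pooled within-class covariance and pi_c
    the empirical class prior.  Prediction is the argmax; ties break toward
    the earlier class in ``classes_`` order.  A (near-)singular pooled
    covariance is ridge-regularized by ``reg * trace(S)/d * I`` with a
    warning.

    ``transform`` projects onto the top-2 discriminant directions
    (``scalings_``), the axes maximizing between- over within-class scatter,
    used for 2-D feature maps.

    Parameters
    ----------
    reg : float
        Relative ridge added to a singular pooled covariance (default 1e-6).
    """

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        n, d = X.shape
        self.classes_ = classes
        self.priors_ = np.bincount(y_idx, minlength=classes.size) / n
        self.means_ = np.vstack([X[y_idx == k].mean(axis=0) for k in range(classes.size)])

        centered = X - self.means_[y_idx]
        dof = max(n - classes.size, 1)
        cov = centered.T @ centered / dof
        cov = (cov + cov.T) / 2.0
        # ridge only when genuinely ill-conditioned (relative to the spectrum)
        eigs = linalg.eigvalsh(cov)
        if eigs[0] <= 1e-10 * max(eigs[-1], 1e-300):
            lam = self.reg * np.trace(cov) / d
            warnings.warn("singular pooled covariance; ridge regularization applied")
            cov = cov + max(lam, 1e-12) * np.eye(d)
        self.covariance_ = cov

        self._cov_inv_means = linalg.solve(cov, self.means_.T, assume_a="pos").T
        self._const = (
            -0.5 * np.einsum("kd,kd->k", self.means_, self._cov_inv_means)
            + np.log(np.clip(self.priors_, 1e-300, None))
        )
        self.scalings_ = self._discriminant_axes(X, y_idx)
        self.n_features_in_ = d
        return self

    def _discriminant_axes(self, X, y_idx) -> np.ndarray:
        """Top-2 generalized eigenvectors of between- vs within-class scatter."""
        d = X.shape[1]
        overall = X.mean(axis=0)
        sb = np.zeros((d, d))
        for k in range(self.classes_.size):
            diff = (self.means_[k] - overall)[:, None]
            sb += self.priors_[k] * (diff @ diff.T)
        evals, evecs = linalg.eigh(sb, self.covariance_ + 1e-12 * np.eye(d))
        order = np.argsort(evals)[::-1]
        axes = evecs[:, order[:2]].T
        if self.classes_.size < 3:
            warnings.warn(
                "fewer than 3 classes: only one discriminant axis exists; "
                "second axis padded with the next principal direction"
            )
            resid = X - overall
            # principal direction orthogonalized against the discriminant axis
            _, _, vt = np.linalg.svd(resid, full_matrices=False)
            cand = vt[0]
            a0 = axes[0] / np.linalg.norm(axes[0])
            cand = cand - (cand @ a0) * a0
            if np.linalg.norm(cand) < 1e-12:
                cand = vt[min(1, vt.shape[0] - 1)]
                cand = cand - (cand @ a0) * a0
            axes = np.vstack([axes[0], cand / np.linalg.norm(cand)])
        return axes

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        X = np.asarray(X, dtype=float)
        one = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        scores = X @ self._cov_inv_means.T + self._const
        return scores[0] if one else scores

    def predict(self, X):
        scores = np.atleast_2d(self.decision_function(X))
        # argmax returns the first (lowest class index) maximum: deterministic ties
        idx = np.argmax(scores, axis=1)
        out = self.classes_[idx]
        return out[0] if np.asarray(X).ndim == 1 else out

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scalings_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.means_.mean(axis=0)) @ self.scalings_.T

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "means_")
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "reg": self.reg,
            "classes": [str(c) for c in self.classes_],
            "priors": self.priors_.tolist(),
            "means": self.means_.tolist(),
            "covariance": self.covariance_.tolist(),
            "scalings": self.scalings_.tolist(),
            "training_meta": getattr(self, "training_meta_", {}),
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PooledCovarianceLDA":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        model = cls(reg=payload["reg"])
        model.classes_ = np.asarray(payload["classes"])
        model.priors_ = np.asarray(payload["priors"])
        model.means_ = np.asarray(payload["means"])
        model.covariance_ = np.asarray(payload["covariance"])
        model.scalings_ = np.asarray(payload["scalings"])
        model.training_meta_ = payload.get("training_meta", {})
        model.n_features_in_ = model.means_.shape[1]
        model._cov_inv_means = linalg.solve(
            model.covariance_, model.means_.T, assume_a="pos"
        ).T
        model._const = (
            -0.5 * np.einsum("kd,kd->k", model.means_, model._cov_inv_means)
            + np.log(np.clip(model.priors_, 1e-300, None))
        )
        return model


def macro_sensitivity(y_true, y_pred, classes=None) -> float:
    """Unweighted mean over classes of per-class recall (classes with no
    true samples are skipped)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = np.unique(y_true) if classes is None else np.asarray(classes)
    vals = []
    for c in classes:
        mask = y_true == c
        if mask.any():
            vals.append(float(np.mean(y_pred[mask] == c)))
    return float(np.mean(vals)) if vals else float("nan")


class ReferenceSelector(ClassifierMixin, BaseEstimator):
    """Select the calibration reference model over repeated stratified splits.

    ``n_splits`` independent stratified train/test splits (3:1 by default)
    are drawn from one seed; a base LDA is fitted on each training part and
    scored by macro-averaged sensitivity on the held-out part.  The
    highest-scoring split wins (ties break toward the lowest split index).
    The winner's held-out truth/prediction pairs — and any side annotations
    passed via ``heldout`` — are kept for per-state performance screening.

    Attributes (after fit)
    ----------------------
    model_ : PooledCovarianceLDA fitted on the winning training part.
    scores_ : per-split macro sensitivities.
    best_split_ : winning split index.
    heldout_true_, heldout_pred_ : winning split's held-out labels.
    heldout_meta_ : dict of side annotation arrays restricted to the
        winning held-out part (e.g. pose labels).
    """

    def __init__(
        self,
        base_estimator: PooledCovarianceLDA | None = None,
        n_splits: int = 3,
        test_size: float = 0.25,
        seed: int = 0,
        max_redraws: int = 10,
    ):
        self.base_estimator = base_estimator
        self.n_splits = n_splits
        self.test_size = test_size
        self.seed = seed
        self.max_redraws = max_redraws

    def fit(self, X, y, heldout: dict[str, np.ndarray] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        heldout = {k: np.asarray(v) for k, v in (heldout or {}).items()}
        classes = np.unique(y)
        rng = np.random.RandomState(self.seed)
        best = None
        self.scores_ = []
        for split in range(self.n_splits):
            tr_idx = te_idx = None
            for _ in range(self.max_redraws):
                state = rng.randint(0, 2**31 - 1)
                tr, te = train_test_split(
                    np.arange(len(y)), test_size=self.test_size,
                    random_state=state, stratify=y,
                )
                if np.isin(classes, y[te]).all():
                    tr_idx, te_idx = tr, te
                    break
            if tr_idx is None:
                raise RuntimeError(
                    "could not draw a split with every class in the test part"
                )
            base = self.base_estimator or PooledCovarianceLDA()
            model = clone(base).fit(X[tr_idx], y[tr_idx])
            pred = model.predict(X[te_idx])
            score = macro_sensitivity(y[te_idx], pred, classes)
            self.scores_.append(score)
            if best is None or score > best[0]:
                best = (score, split, model, te_idx, pred)
        score, split, model, te_idx, pred = best
        model.training_meta_ = {
            "seed": self.seed, "fold": split, "score": score,
            "n_train": int(len(y) - len(te_idx)),
        }
        self.model_ = model
        self.best_split_ = split
        self.best_score_ = score
        self.heldout_true_ = y[te_idx]
        self.heldout_pred_ = pred
        self.heldout_meta_ = {k: v[te_idx] for k, v in heldout.items()}
        self.classes_ = model.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(X)


def train_lda(X, y, reg: float = 1e-6) -> PooledCovarianceLDA:
    """Fit a pooled-covariance LDA (thin functional wrapper)."""
    return PooledCovarianceLDA(reg=reg).fit(X, y)


def select_reference(X, y, *, n_splits: int = 3, test_size: float = 0.25,
                     seed: int = 0, heldout=None) -> ReferenceSelector:
    """Run the repeated-split reference-model selection (thin wrapper)."""
    return ReferenceSelector(n_splits=n_splits, test_size=test_size, seed=seed).fit(
        X, y, heldout=heldout
    )
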