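"""Elastic-net feature selection on the flattened encoding.

Binary labels are regressed on the 328 features with the penalized
least-squares elastic net

    min_b  ||y - X b||^2  +  l1 ||b||_1  +  l2 ||b||_2^2 ,

fit on the training partition only.  Features with exactly nonzero
coefficients are retained, and the same index set (plus the training-set
standardization) is applied unchanged to held-out data — the train-fitted
selector travels with the model, so no test information leaks into the fit.

The penalty pair (l1, l2) maps onto scikit-learn's per-sample
parameterization via  alpha*rho = l1/(2n)  and  alpha*(1-rho) = l2/n.
When no penalties are given, the default is an equal L1/L2 mix with overall
strength 0.05 * alpha_max, where alpha_max is the smallest penalty that
zeroes every coefficient — a fixed point on the standard regularization
path that adapts to the data's scale.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, LinearRegression

logger = logging.getLogger("sixmanet")

SOLVER_TOL = 1e-6
SOLVER_MAX_ITER = 10_000
DEFAULT_MIXING = 0.5  # l1 fraction of the default penalty mix
DEFAULT_STRENGTH = 0.05  # fraction of alpha_max used when penalties are unset


class SelectionError(ValueError):
    """Raised when the fit is ill-posed or the selection is unusable."""


@dataclass
class SelectorModel:
    """A fitted elastic net plus everything needed to replay its transform."""

    coefficients: np.ndarray  # length-p vector on standardized features
    intercept: float
    l1: float
    l2: float
    n: int
    selected_indices: np.ndarray  # strictly increasing nonzero-coefficient set
    mean: np.ndarray  # training-feature means
    scale: np.ndarray  # training-feature standard deviations (0 -> 1)

    @property
    def n_features_in(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_selected(self) -> int:
        return self.selected_indices.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "l1": self.l1,
                "l2": self.l2,
                "n": self.n,
                "selected_indices": self.selected_indices.tolist(),
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectorModel":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            l1=float(d["l1"]),
            l2=float(d["l2"]),
            n=int(d["n"]),
            selected_indices=np.asarray(d["selected_indices"], dtype=int),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SelectorModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"selector file not found: {path}")
        return cls.from_json(path.read_text())


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant columns pass through
    return (X - mean) / scale, mean, scale


def _alpha_max(Xs: np.ndarray, y: np.ndarray, rho: float) -> float:
    # Smallest per-sample penalty that zeroes all coefficients on the
    # standardized, centered problem.
    n = Xs.shape[0]
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * rho))


def fit_selector(
    X: np.ndarray,
    y: np.ndarray,
    l1: float | None = None,
    l2: float | None = None,
) -> SelectorModel:
    """Fit the elastic net on training data and record the nonzero set.

    ``l1``/``l2`` are the L1 and L2 weights of the summed-squares objective;
    both None selects the data-driven default described in the module
    docstring.  ``l1 = l2 = 0`` is the ordinary least-squares limit, in
    which every feature is retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise SelectionError(f"shape mismatch: X {X.shape}, y {y.shape}")
    n, p = X.shape
    if n < 2:
        raise SelectionError(f"need at least 2 training rows, got {n}")
    if not np.all(np.isfinite(X)):
        raise SelectionError("X contains non-finite values")
    if np.unique(y).size < 2:
        raise SelectionError("training labels contain a single class")
    if (l1 is None) != (l2 is None):
        raise SelectionError("give both l1 and l2, or neither")
    if l1 is not None and (l1 < 0 or l2 < 0):
        raise SelectionError("penalties must be non-negative")

    Xs, mean, scale = _standardize(X)

    if l1 is None:
        rho = DEFAULT_MIXING
        alpha = DEFAULT_STRENGTH * _alpha_max(Xs, y, rho)
        # report back in the summed-squares parameterization
        l1 = 2.0 * n * alpha * rho
        l2 = n * alpha * (1.0 - rho)
    if l1 == 0.0 and l2 == 0.0:
        ols = LinearRegression().fit(Xs, y)
        coef, intercept = ols.coef_, float(ols.intercept_)
    else:
        alpha = l1 / (2.0 * n) + l2 / n
        rho = (l1 / (2.0 * n)) / alpha
        model = ElasticNet(
            alpha=alpha,
            l1_ratio=rho,
            tol=SOLVER_TOL,
            max_iter=SOLVER_MAX_ITER,
            fit_intercept=True,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            model.fit(Xs, y)
        for w in caught:
            logger.warning("elastic-net solver: %s", w.message)
        coef, intercept = model.coef_, float(model.intercept_)

    selected = np.flatnonzero(coef != 0.0)
    logger.info(
        "elastic net: l1=%.6g l2=%.6g n=%d -> %d/%d features selected",
        l1, l2, n, selected.size, p,
    )
    return SelectorModel(
        coefficients=np.asarray(coef, dtype=float),
        intercept=intercept,
        l1=float(l1),
        l2=float(l2),
        n=n,
        selected_indices=selected,
        mean=mean,
        scale=scale,
    )


def apply_selector(model: SelectorModel, X: np.ndarray) -> np.ndarray:
    """Standardize with training stats and gather the selected columns.

    No refitting occurs: the transform is fully determined by the training
    partition the selector was fit on.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in:
        raise SelectionError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns; "
            f"selector expects {model.n_features_in}"
        )
    Xs = (X - model.mean) / model.scale
    return Xs[:, model.selected_indices]


def select_top_k(model: SelectorModel, k: int) -> SelectorModel:
    """Compatibility mode: keep the k largest-|coefficient| features.

    Lets users force a fixed dimensionality instead of the elastic net's
    native nonzero set.  Ties broken by lower index.
    """
    if not 1 <= k <= model.n_features_in:
        raise SelectionError(f"k={k} outside [1, {model.n_features_in}]")
    order = np.lexsort((np.arange(model.n_features_in), -np.abs(model.coefficients)))
    top = np.sort(order[:k])
    return SelectorModel(
        coefficients=model.coefficients,
        intercept=model.intercept,
        l1=model.l1,
        l2=model.l2,
        n=model.n,
        selected_indices=top,
        mean=model.mean,
        scale=model.scale,
    )


def selector_report(model: SelectorModel) -> dict:
    """Summary record serialized alongside the model."""
    if model.n_selected == 0:
        logger.warning("selector retained zero features")
    mags = np.abs(model.coefficients[model.selected_indices])
    return {
        "n_selected": int(model.n_selected),
        "n_features_in": int(model.n_features_in),
        "l1": model.l1,
        "l2": model.l2,
        "n_train": model.n,
        "max_abs_coefficient": float(mags.max()) if mags.size else 0.0,
        "min_abs_coefficient": float(mags.min()) if mags.size else 0.0,
    }


def enet_objective(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float,
    l1: float, l2: float,
) -> float:
    """Value of the summed-squares elastic-net objective at (coef, intercept)."""
    resid = y - intercept - X @ coef
    return float(resid @ resid + l1 * np.abs(coef).sum() + l2 * coef @ coef)
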