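"""Neural-network surrogate of the agent-based simulator.

A Latin-hypercube design over the 13 simulation parameters is executed with
replicate runs, median emergent statistics are recorded, and one
feed-forward network per output statistic learns the parameter → statistic
mapping. A trained surrogate evaluates in microseconds, making population-
scale multiobjective optimization over the simulator tractable.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted


@dataclass
class LHCDesign:
    """Latin-hypercube sample: one point per equal-width stratum per column."""

    matrix: np.ndarray  # (n_samples, d) in physical units
    ranges: np.ndarray  # (d, 2) [lo, hi]
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.matrix)

    def unit_matrix(self) -> np.ndarray:
        lo, hi = self.ranges[:, 0], self.ranges[:, 1]
        return (self.matrix - lo) / (hi - lo)


def latin_hypercube(n: int, ranges, seed: int = 0) -> LHCDesign:
    """Stratified one-per-bin sampling per dimension with random pairing."""
    ranges = np.asarray(ranges, float).reshape(-1, 2)
    if n < 1:
        raise ValueError("n must be >= 1")
    if (ranges[:, 0] >= ranges[:, 1]).any():
        raise ValueError("each range needs lo < hi")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n)
    mat = qmc.scale(unit, ranges[:, 0], ranges[:, 1])
    return LHCDesign(matrix=mat, ranges=ranges, seed=seed)


class ExtrapolationWarning(UserWarning):
    """Emitted when the surrogate is queried outside its trained box."""


class StatisticEmulator(BaseEstimator, RegressorMixin):
    """Feed-forward surrogate for one emergent statistic.

    Sklearn-style estimator: three sigmoidal (logistic) hidden layers, a
    single linear output, min–max normalization of inputs and output.
    One emulator is trained per simulator output.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Hidden-layer widths.
    max_iter : int
        Gradient-descent iteration cap.
    random_state : int
        Weight-initialization seed.
    """

    def __init__(self, hidden_sizes=(24, 16, 8), max_iter=4000, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite training data")
        self.x_min_ = X.min(axis=0)
        self.x_max_ = X.max(axis=0)
        self.y_min_ = float(y.min())
        self.y_max_ = float(y.max())
        Xn = self._norm_x(X)
        yn = self._norm_y(y)
        self.net_ = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_sizes),
            activation="logistic",
            solver="adam",
            max_iter=self.max_iter,
            random_state=self.random_state,
            tol=1e-7,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.net_.fit(Xn, yn)
        if not np.isfinite(self.net_.loss_):
            raise RuntimeError(f"training diverged (loss={self.net_.loss_})")
        self.n_features_in_ = X.shape[1]
        return self

    # -- normalization -------------------------------------------------------
    def _norm_x(self, X):
        span = np.where(self.x_max_ > self.x_min_, self.x_max_ - self.x_min_, 1.0)
        return (X - self.x_min_) / span

    def _norm_y(self, y):
        span = self.y_max_ - self.y_min_
        return (y - self.y_min_) / span if span > 0 else y - self.y_min_

    def _denorm_y(self, yn):
        span = self.y_max_ - self.y_min_
        return yn * span + self.y_min_ if span > 0 else yn + self.y_min_

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        if (X < self.x_min_ - 1e-12).any() or (X > self.x_max_ + 1e-12).any():
            warnings.warn(
                "query outside the trained parameter box; extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        return self._denorm_y(self.net_.predict(self._norm_x(X)))

    # -- serialization -------------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "net_")
        return {
            "hidden_sizes": list(self.hidden_sizes),
            "random_state": self.random_state,
            "max_iter": self.max_iter,
            "x_min": self.x_min_.tolist(),
            "x_max": self.x_max_.tolist(),
            "y_min": self.y_min_,
            "y_max": self.y_max_,
            "coefs": [w.tolist() for w in self.net_.coefs_],
            "intercepts": [b.tolist() for b in self.net_.intercepts_],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def from_json_dict(cls, d: dict) -> "StatisticEmulator":
        em = cls(
            hidden_sizes=tuple(d["hidden_sizes"]),
            max_iter=d["max_iter"],
            random_state=d["random_state"],
        )
        em.x_min_ = np.asarray(d["x_min"], float)
        em.x_max_ = np.asarray(d["x_max"], float)
        em.y_min_ = float(d["y_min"])
        em.y_max_ = float(d["y_max"])
        coefs = [np.asarray(w, float) for w in d["coefs"]]
        intercepts = [np.asarray(b, float) for b in d["intercepts"]]
        net = MLPRegressor(
            hidden_layer_sizes=tuple(d["hidden_sizes"]), activation="logistic"
        )
        # rebuild a predict-ready sklearn net from stored weights
        net.coefs_ = coefs
        net.intercepts_ = intercepts
        net.n_layers_ = len(coefs) + 1
        net.n_outputs_ = 1
        net.out_activation_ = "identity"
        net.n_features_in_ = coefs[0].shape[0]
        em.net_ = net
        em.n_features_in_ = coefs[0].shape[0]
        return em

    @classmethod
    def load(cls, path: str | Path) -> "StatisticEmulator":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainingReport:
    """Hold-out errors of a trained surrogate."""

    train_rmse: float
    test_rmse: float
    validation_rmse: float
    cv_rmse_by_architecture: dict
    chosen_hidden_sizes: tuple


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def train_emulator(
    design: LHCDesign,
    responses,
    hidden_sizes_grid=((24, 16, 8), (16, 16, 16), (8, 8, 8)),
    k: int = 5,
    seed: int = 0,
    max_iter: int = 4000,
) -> tuple[StatisticEmulator, TrainingReport]:
    """Train one surrogate on replicate-median responses.

    The design is split 75/15/10 into train/test/validation; hidden-layer
    widths are chosen by k-fold cross-validated RMSE on the training split.
    """
    y = np.asarray(responses, float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("responses must be finite")
    if k < 2:
        raise ValueError("k must be >= 2")
    X = design.matrix
    n = len(X)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(0.75 * n))
    n_test = int(round(0.15 * n))
    tr, te, va = (
        order[:n_train],
        order[n_train : n_train + n_test],
        order[n_train + n_test :],
    )

    cv_scores: dict = {}
    best_arch, best_score = None, np.inf
    n_folds = min(k, len(tr))
    for arch in hidden_sizes_grid:
        errs = []
        for fold_tr, fold_va in KFold(n_splits=n_folds, shuffle=True,
                                      random_state=seed).split(tr):
            em = StatisticEmulator(hidden_sizes=arch, random_state=seed,
                                   max_iter=max_iter)
            em.fit(X[tr[fold_tr]], y[tr[fold_tr]])
            errs.append(_rmse(em.predict(X[tr[fold_va]]), y[tr[fold_va]]))
        score = float(np.mean(errs))
        cv_scores[str(arch)] = score
        if score < best_score:
            best_arch, best_score = arch, score

    em = StatisticEmulator(hidden_sizes=best_arch, random_state=seed,
                           max_iter=max_iter)
    em.fit(X[tr], y[tr])
    report = TrainingReport(
        train_rmse=_rmse(em.predict(X[tr]), y[tr]),
        test_rmse=_rmse(em.predict(X[te]), y[te]) if len(te) else float("nan"),
        validation_rmse=_rmse(em.predict(X[va]), y[va]) if len(va) else float("nan"),
        cv_rmse_by_architecture=cv_scores,
        chosen_hidden_sizes=tuple(best_arch),
    )
    return em, report
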