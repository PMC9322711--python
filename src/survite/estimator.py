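"""Scikit-learn style estimator for individual treatment effects on survival time.

:class:`CounterfactualSurvivalITE` wraps the representation network, the
censored/balancing/treatment-head/prior-knowledge objective and the minibatch
training loop behind ``fit`` / ``predict``.  ``predict`` returns the
estimated individual effect ``Delta Y(x) = yhat(x, treated) - yhat(x,
control)`` in the time units of the training data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .data import Dataset, split_dataset, standardize as _standardize
from .knowledge import KnowledgeBase
from .network import CounterfactualSurvivalNet, ModelConfig
from .training import TrainConfig, precompute_memberships, train

__all__ = ["CounterfactualSurvivalITE"]


def _parse_y(y, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract (time, event, treatment) from a DataFrame, structured array
    or dict-like."""
    if isinstance(y, pd.DataFrame):
        cols = {c.lower(): c for c in y.columns}
        try:
            return (y[cols["time"]].to_numpy(float),
                    y[cols["event"]].to_numpy(int),
                    y[cols["treatment"]].to_numpy(int))
        except KeyError as e:
            raise ValueError("y must provide 'time', 'event' and 'treatment' "
                             "columns") from e
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = {n_.lower(): n_ for n_ in y.dtype.names}
        return (np.asarray(y[names["time"]], float),
                np.asarray(y[names["event"]], int),
                np.asarray(y[names["treatment"]], int))
    if isinstance(y, dict):
        return (np.asarray(y["time"], float), np.asarray(y["event"], int),
                np.asarray(y["treatment"], int))
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 2 and arr.shape == (n, 3):
        return arr[:, 0], arr[:, 1].astype(int), arr[:, 2].astype(int)
    raise ValueError("y must be a DataFrame/structured array/dict with fields "
                     "time, event, treatment, or an (n, 3) array in that order")


class CounterfactualSurvivalITE(BaseEstimator):
    """Counterfactual survival regressor with optional prior-knowledge penalties.

    Parameters
    ----------
    mode : {"csa", "csa_dragonnet", "cdnepk"}
        ``csa`` balances treated/control representations and handles
        censoring; ``csa_dragonnet`` adds a treatment-prediction head that
        discourages balancing non-confounders; ``cdnepk`` further adds bound
        penalties on counterfactual predictions for patients covered by the
        knowledge base.
    knowledge_base : KnowledgeBase or None
        Required (may be empty) in ``cdnepk`` mode.
    alpha, beta : float
        Weights of the representation-balancing IPM and of the treatment
        cross-entropy.
    epochs, batch_size, learning_rate
        Adam training-loop settings.
    standardize : bool
        Shift/scale continuous covariates by the training mean/sd before the
        encoder.  Knowledge-region membership is always evaluated on raw
        covariates.
    validation_fraction : float
        Share of the fitting data held out (seeded) for epoch selection by
        validation factual loss.

    Attributes
    ----------
    net_ : the trained network.
    history_ : per-epoch loss breakdowns.
    selected_epoch_ : epoch whose parameters were kept.
    scaler_ : location/scale table (or None).
    """

    def __init__(self, mode: str = "cdnepk",
                 knowledge_base: KnowledgeBase | None = None,
                 rep_layers: tuple[int, ...] = (100, 100),
                 branch_layers: tuple[int, ...] = (100, 100),
                 noise_dim: int = 10, noise_draws_for_ite: int = 100,
                 dropout_p: float = 0.2, alpha: float = 1000.0,
                 beta: float = 100.0, ipm_kind: str = "mmd_rbf",
                 mmd_bandwidth: float | str = "median-heuristic",
                 normalized_omega: bool = True, epochs: int = 80,
                 batch_size: int = 850, learning_rate: float = 3e-3,
                 standardize: bool = True, validation_fraction: float = 0.15,
                 random_state: int = 0):
        self.mode = mode
        self.knowledge_base = knowledge_base
        self.rep_layers = rep_layers
        self.branch_layers = branch_layers
        self.noise_dim = noise_dim
        self.noise_draws_for_ite = noise_draws_for_ite
        self.dropout_p = dropout_p
        self.alpha = alpha
        self.beta = beta
        self.ipm_kind = ipm_kind
        self.mmd_bandwidth = mmd_bandwidth
        self.normalized_omega = normalized_omega
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.standardize = standardize
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config assembly ------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(rep_layers=tuple(self.rep_layers),
                           branch_layers=tuple(self.branch_layers),
                           noise_dim=self.noise_dim,
                           noise_draws_for_ite=self.noise_draws_for_ite,
                           dropout_p=self.dropout_p, alpha=self.alpha,
                           beta=self.beta, ipm_kind=self.ipm_kind,
                           mmd_bandwidth=self.mmd_bandwidth,
                           normalized_omega=self.normalized_omega,
                           seed=self.random_state)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           learning_rate=self.learning_rate, mode=self.mode,
                           seed=self.random_state)

    # -- fitting --------------------------------------------------------------
    def fit(self, X, y, validation_data: tuple | None = None):
        if self.mode == "cdnepk" and self.knowledge_base is None:
            raise ValueError("cdnepk mode requires a knowledge_base "
                             "(it may be empty)")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = check_array(X, dtype=float)
            names = [f"x{j}" for j in range(X.shape[1])]
        self.n_features_in_ = X.shape[1]
        time, event, treatment = _parse_y(y, len(X))
        full = Dataset(np.arange(len(X)), X, names, treatment, time, event)

        if validation_data is not None:
            Xv, yv = validation_data
            names_v = list(Xv.columns) if isinstance(Xv, pd.DataFrame) else names
            Xv = np.asarray(Xv, dtype=float)
            tv, ev, trv = _parse_y(yv, len(Xv))
            train_set = full
            val_set = Dataset(np.arange(len(Xv)), Xv, names_v, trv, tv, ev)
        elif self.validation_fraction > 0 and full.n >= 3:
            train_set, val_set, _ = split_dataset(
                full, (1.0 - self.validation_fraction, self.validation_fraction,
                       0.0), seed=self.random_state)
        else:
            train_set, val_set = full, None

        # membership on raw covariates, before any scaling
        memberships = precompute_memberships(train_set, self.knowledge_base)

        if self.standardize:
            if val_set is not None:
                (train_std, val_std), table = _standardize(train_set, val_set)
            else:
                (train_std,), table = _standardize(train_set)
                val_std = None
            self.scaler_ = table
        else:
            train_std, val_std = train_set, val_set
            self.scaler_ = None

        result = train(train_std, val_std, self.knowledge_base,
                       self._model_config(), self._train_config(),
                       memberships=memberships)
        self.net_ = result.net
        self.history_ = result.history
        self.selected_epoch_ = result.selected_epoch
        return self

    # -- prediction -----------------------------------------------------------
    def _transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} features, expected "
                             f"{self.n_features_in_}")
        if self.scaler_ is not None:
            loc = self.scaler_["loc"].to_numpy()
            scale = self.scaler_["scale"].to_numpy()
            X = (X - loc) / scale
        return X

    def predict(self, X) -> np.ndarray:
        """Estimated individual treatment effect for each row of X."""
        check_is_fitted(self, "net_")
        return self.net_.predict_ite(self._transform(X),
                                     n_draws=self.noise_draws_for_ite,
                                     seed=self.random_state)

    def predict_survival(self, X, arm: int, seed: int | None = None
                         ) -> np.ndarray:
        """Mean predicted survival time under the given arm."""
        check_is_fitted(self, "net_")
        Xs = self._transform(X)
        rng = np.random.default_rng(self.random_state if seed is None else seed)
        rep = self.net_.represent(Xs, training=False)
        total = np.zeros(len(Xs))
        for _ in range(self.noise_draws_for_ite):
            eps = rng.standard_normal((len(Xs), self.noise_dim))
            total += self.net_.survival(rep, arm, eps, training=False).data
        return total / self.noise_draws_for_ite

    def predict_treatment_proba(self, X) -> np.ndarray:
        """Estimated propensity (probability of treatment 1)."""
        check_is_fitted(self, "net_")
        return self.net_.predict_treatment(self._transform(X))
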