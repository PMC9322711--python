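"""The three-head representation network for counterfactual survival prediction.

Eight fully connected networks: a shared encoder ``phi`` mapping the baseline
into a representation space; a single-layer softmax treatment head ``psi``; and
per-arm survival branches in which ``g_j`` refines the representation,
``u_j`` transforms a Gaussian noise vector (the stochastic component of the
survival-time model), and a single affine layer ``h_j`` with exponential
output maps the concatenation to a strictly positive survival time.

A patient's factual prediction routes through the arm actually received;
the counterfactual prediction routes the same representation through the
opposite arm's branch.  Both use the same eight networks, so parameter counts
do not depend on whether the prior-knowledge penalties are in use.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat
from ._layers import MLP, Linear

__all__ = ["ModelConfig", "CounterfactualSurvivalNet"]


@dataclass
class ModelConfig:
    """Architecture and loss-weight configuration.

    ``rep_layers``/``branch_layers`` are the hidden widths of ``phi`` and
    ``g`` (two hidden layers of 100 by default); ``noise_dim`` the dimension
    of the noise inputs; ``noise_draws_for_ite`` the number S of paired noise
    samples averaged when predicting an individual effect; ``alpha``/``beta``
    weight the representation-balancing IPM and the treatment cross-entropy.
    """

    rep_layers: tuple[int, ...] = (100, 100)
    branch_layers: tuple[int, ...] = (100, 100)
    noise_dim: int = 10
    noise_draws_for_ite: int = 100
    dropout_p: float = 0.2
    alpha: float = 1000.0
    beta: float = 100.0
    ipm_kind: str = "mmd_rbf"
    mmd_bandwidth: float | str = "median-heuristic"
    #: divide the positive-region penalties by their group sizes so the
    #: penalty, like every other objective term, is a mean and its weight is
    #: batch-size independent; set False for the bare-sum variant.
    normalized_omega: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.noise_draws_for_ite < 1:
            raise ValueError("noise_draws_for_ite must be >= 1")
        if not all(w >= 1 for w in (*self.rep_layers, *self.branch_layers)):
            raise ValueError("layer widths must be positive")


class CounterfactualSurvivalNet:
    """The eight networks with factual / counterfactual routing."""

    def __init__(self, cfg: ModelConfig, m: int, seed: int | None = None):
        if m < 1:
            raise ValueError("need at least one covariate")
        self.cfg = cfg
        self.m = m
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        rep = list(cfg.rep_layers)
        branch = list(cfg.branch_layers)
        hidden = rep[-1]
        self.phi = MLP([m, *rep], "leaky_relu", rng,
                       batch_norm=True, dropout=cfg.dropout_p)
        self.psi = Linear(hidden, 2, rng)
        self.g = {j: MLP([hidden, *branch], "leaky_relu", rng,
                         batch_norm=True, dropout=cfg.dropout_p)
                  for j in (1, 0)}
        # u: two-layer tanh MLP from noise to a noise_dim-sized code
        self.u = {j: MLP([cfg.noise_dim, hidden, cfg.noise_dim], "tanh", rng)
                  for j in (1, 0)}
        # h: one affine layer with exponential output (strictly positive time)
        self.h = {j: Linear(branch[-1] + cfg.noise_dim, 1, rng) for j in (1, 0)}

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = self.phi.parameters() + self.psi.parameters()
        for j in (1, 0):
            params += self.g[j].parameters() + self.u[j].parameters() \
                + self.h[j].parameters()
        return params

    def _batchnorms(self):
        mods = list(self.phi.bns or [])
        for j in (1, 0):
            mods += list(self.g[j].bns or [])
        return mods

    def state_dict(self) -> list[np.ndarray]:
        """Weights plus batch-norm running statistics (both are model state)."""
        state = [p.data.copy() for p in self.parameters()]
        for bn in self._batchnorms():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, arr in zip(params, state):
            p.data = arr.copy()
        rest = state[len(params):]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = rest[2 * i].copy()
            bn.running_var = rest[2 * i + 1].copy()

    def copy(self) -> "CounterfactualSurvivalNet":
        return copy.deepcopy(self)

    # -- forward passes -------------------------------------------------------
    def represent(self, x, training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        return self.phi(x, training=training, rng=rng)

    def treatment_logits(self, rep: Tensor) -> Tensor:
        return self.psi(rep)

    def treatment_proba(self, rep: Tensor) -> Tensor:
        """Softmax probability of treatment 1; strictly inside (0, 1)."""
        logits = self.treatment_logits(rep)
        z = logits - Tensor(np.max(logits.data, axis=1, keepdims=True))
        ez = z.exp()
        return ez.take_cols(1) / ez.sum(axis=1)

    def survival(self, rep: Tensor, arm: int, eps,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """``h_arm(g_arm(rep) (+) u_arm(eps))`` — strictly positive."""
        if arm not in (0, 1):
            raise ValueError("arm must be 0 or 1")
        eps = eps if isinstance(eps, Tensor) else Tensor(np.atleast_2d(eps))
        code = self.g[arm](rep, training=training, rng=rng)
        noise = self.u[arm](eps)
        pre = self.h[arm](concat([code, noise], axis=1))
        return pre.exp().reshape(-1)

    def predict_survival(self, x, arm: int, eps) -> np.ndarray:
        """Deterministic evaluation-mode survival prediction."""
        rep = self.represent(x, training=False)
        return self.survival(rep, arm, eps, training=False).data

    def predict_treatment(self, x) -> np.ndarray:
        rep = self.represent(x, training=False)
        return self.treatment_proba(rep).data

    def predict_ite(self, x, n_draws: int | None = None,
                    seed: int = 0) -> np.ndarray:
        """Monte-Carlo individual-effect estimate.

        Averages ``yhat(x, 1, eps_s) - yhat(x, 0, eps_s)`` over S paired
        standard-normal noise draws (pairing removes the shared noise
        component of the variance and makes the difference exactly zero when
        the two branches have identical parameters).  Evaluation mode
        throughout; seeded and reproducible.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        S = n_draws or self.cfg.noise_draws_for_ite
        rng = np.random.default_rng(seed)
        rep = self.represent(x, training=False)
        total = np.zeros(x.shape[0])
        for _ in range(S):
            eps = rng.standard_normal((x.shape[0], self.cfg.noise_dim))
            y1 = self.survival(rep, 1, eps, training=False).data
            y0 = self.survival(rep, 0, eps, training=False).data
            total += y1 - y0
        return total / S
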