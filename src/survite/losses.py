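"""Loss components for counterfactual survival representation learning.

The full objective combines
  * a censored factual error per arm: absolute error where the event was
    observed, a hinge below the censoring time otherwise, each arm normalized
    by its own size;
  * an integral probability metric between the treated and control
    representation samples (squared RBF-kernel MMD by default, entropic
    Wasserstein optionally), weighted by ``alpha``;
  * a softmax cross-entropy on the treatment head, weighted by ``beta``; and
  * five prior-knowledge constraint penalties on the counterfactual
    predictions of patients inside the positive-effect union Omega or the
    zero-effect union Gamma.

All functions accept plain arrays or autodiff tensors and return a tensor, so
the same code path serves hand-value tests and gradient-based training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .knowledge import Effect

__all__ = ["LossBreakdown", "factual_loss", "ipm_distance", "mmd2_rbf",
           "sinkhorn_wasserstein", "treatment_ce", "prior_losses",
           "total_loss", "uncensored_squared_loss"]


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


@dataclass
class LossBreakdown:
    """All loss components of one batch, as plain floats for logging."""

    factual: float = 0.0
    ipm: float = 0.0
    treatment_ce: float = 0.0
    l11: float = 0.0
    l12: float = 0.0
    l13: float = 0.0
    l21: float = 0.0
    l22: float = 0.0
    lcp: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("factual", "ipm", "treatment_ce", "l11", "l12", "l13",
                 "l21", "l22", "lcp", "total")}


def factual_loss(time, event, treatment, y_pred) -> Tensor:
    """Censored factual error, each arm normalized by its own size.

    ``sum_j (1/N_j) sum_{i in arm j} [ delta|gamma - yhat| +
    (1-delta) max(0, gamma - yhat) ]``; an empty arm contributes 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    y = _t(y_pred)
    weights = np.zeros(len(time))
    for j in (0, 1):
        mask = treatment == j
        if mask.any():
            weights[mask] = 1.0 / mask.sum()
    resid = Tensor(time) - y
    per = Tensor(event) * resid.abs() + Tensor(1.0 - event) * resid.relu()
    return (Tensor(weights) * per).sum()


def _sq_dists(a: Tensor, b: Tensor) -> Tensor:
    """Pairwise squared Euclidean distances between rows of a and b."""
    aa = (a * a).sum(axis=1, keepdims=True)          # (n, 1)
    bb = (b * b).sum(axis=1, keepdims=True)          # (m, 1)
    d = aa + bb.reshape(1, -1) - 2.0 * _matmul_t(a, b)
    # numerical noise can push tiny distances below zero
    return d.relu()


def _matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """a @ b.T with gradients to both arguments."""

    def bw(g):
        if a.requires_grad:
            a._accum(g @ b.data)
        if b.requires_grad:
            b._accum(g.T @ a.data)

    data = a.data @ b.data.T
    req = a.requires_grad or b.requires_grad
    return Tensor(data, requires_grad=req, parents=(a, b) if req else (),
                  backward=bw if req else None)


def median_heuristic_bandwidth(rep1, rep0) -> float:
    """Median pairwise distance of the pooled sample (a standard kernel width)."""
    pooled = np.vstack([np.atleast_2d(np.asarray(rep1, dtype=float)),
                        np.atleast_2d(np.asarray(rep0, dtype=float))])
    d2 = (np.square(pooled[:, None, :] - pooled[None, :, :]).sum(-1))
    tri = d2[np.triu_indices(len(pooled), k=1)]
    med = float(np.sqrt(np.median(tri))) if tri.size else 1.0
    return med if med > 0 else 1.0


def mmd2_rbf(rep1, rep0, bandwidth: float | str = "median-heuristic") -> Tensor:
    """Squared maximum mean discrepancy, RBF kernel, biased V-statistic.

    ``MMD^2 = mean K(x1, x1) + mean K(x0, x0) - 2 mean K(x1, x0)`` with
    ``K(a, b) = exp(-|a - b|^2 / (2 sigma^2))``.  Symmetric; 0 for identical
    samples.
    """
    a = rep1 if isinstance(rep1, Tensor) else _t(np.atleast_2d(np.asarray(rep1, dtype=float)))
    b = rep0 if isinstance(rep0, Tensor) else _t(np.atleast_2d(np.asarray(rep0, dtype=float)))
    if a.ndim == 1:
        a = a.reshape(-1, 1)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if bandwidth == "median-heuristic":
        sigma = median_heuristic_bandwidth(a.data, b.data)
    else:
        sigma = float(bandwidth)
    gamma = 1.0 / (2.0 * sigma**2)

    def kmean(u, v):
        return ((_sq_dists(u, v) * (-gamma)).exp()).mean()

    return kmean(a, a) + kmean(b, b) - 2.0 * kmean(a, b)


def sinkhorn_wasserstein(rep1, rep0, reg: float = 0.1,
                         n_iter: int = 200) -> Tensor:
    """Entropic-regularized Wasserstein-1 between two representation samples.

    The transport plan is solved by Sinkhorn iterations on the Euclidean cost
    and then held constant in the gradient (envelope approximation), so the
    returned tensor is differentiable in the sample coordinates.
    """
    a = rep1 if isinstance(rep1, Tensor) else _t(np.atleast_2d(rep1))
    b = rep0 if isinstance(rep0, Tensor) else _t(np.atleast_2d(rep0))
    cost = _sq_dists(a, b).sqrt()
    C = cost.data
    n, m = C.shape
    mu = np.full(n, 1.0 / n)
    nu = np.full(m, 1.0 / m)
    K = np.exp(-C / max(reg, 1e-12))
    u = np.ones(n)
    for _ in range(n_iter):
        v = nu / (K.T @ u + 1e-300)
        u = mu / (K @ v + 1e-300)
    plan = u[:, None] * K * v[None, :]
    return (Tensor(plan) * cost).sum()


def ipm_distance(rep1, rep0, kind: str = "mmd_rbf",
                 bandwidth: float | str = "median-heuristic") -> Tensor:
    """IPM between the two arms' representation samples; 0 if one is empty."""
    n1 = (rep1.data if isinstance(rep1, Tensor) else np.asarray(rep1)).shape[0]
    n0 = (rep0.data if isinstance(rep0, Tensor) else np.asarray(rep0)).shape[0]
    if n1 == 0 or n0 == 0:
        warnings.warn("one arm is empty in this batch; IPM term set to 0",
                      stacklevel=2)
        return Tensor(0.0)
    if kind == "mmd_rbf":
        return mmd2_rbf(rep1, rep0, bandwidth)
    if kind == "wasserstein_sinkhorn":
        return sinkhorn_wasserstein(rep1, rep0)
    raise ValueError(f"unknown IPM kind {kind!r}")


def treatment_ce(probabilities, treatments) -> Tensor:
    """Mean binary cross-entropy between predicted and actual treatment."""
    p = _t(probabilities)
    t = np.asarray(treatments, dtype=float)
    return -(Tensor(t) * p.log() + Tensor(1.0 - t) * (1.0 - p).log()).mean()


def prior_losses(time, event, treatment, y_counterfactual, membership,
                 n_total: int | None = None, normalized_omega: bool = False
                 ) -> dict[str, Tensor]:
    """The five prior-knowledge constraint penalties and their sum.

    ``y_counterfactual`` holds the opposite-arm prediction ``yhat^{T=1-t}``
    per record (entries for records outside Omega u Gamma are ignored).
    ``membership`` is a sequence of :class:`~survite.knowledge.Effect` tags.

    As printed in the source formulation the Omega terms are scaled only by
    ``N_Omega / N`` with no inner group mean, while the Gamma terms carry an
    inner per-arm mean; ``normalized_omega=True`` additionally divides each
    Omega sum by its group size.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    ycf = _t(y_counterfactual)
    mem = np.asarray([m if isinstance(m, Effect) else Effect(m)
                      for m in membership], dtype=object)
    n = len(time) if n_total is None else int(n_total)
    omega = mem == Effect.POSITIVE
    gamma_set = mem == Effect.ZERO
    n_omega = int(omega.sum())
    n_gamma = int(gamma_set.sum())

    t_time = Tensor(time)
    zero = Tensor(0.0)

    def _sum(mask, expr) -> Tensor:
        if not mask.any():
            return zero
        return (Tensor(mask.astype(float)) * expr).sum()

    under = (t_time - ycf).relu()          # max(0, gamma - yhat^cf)
    over = (ycf - t_time).relu()           # max(0, yhat^cf - gamma)
    w_omega = n_omega / n
    w_gamma = n_gamma / n

    m110 = omega & (treatment == 0)
    m111 = omega & (treatment == 1)
    s11 = _sum(m110, Tensor(event) * under)
    s12 = _sum(m110, Tensor(1.0 - event) * under)
    s13 = _sum(m111, Tensor(event) * over)
    if normalized_omega:
        s11 = s11 / max(int(m110.sum()), 1)
        s12 = s12 / max(int(m110.sum()), 1)
        s13 = s13 / max(int(m111.sum()), 1)
    l11 = w_omega * s11
    l12 = w_omega * s12
    l13 = w_omega * s13

    l21 = zero
    l22 = zero
    for j in (0, 1):
        mj = gamma_set & (treatment == j)
        nj = int(mj.sum())
        if nj == 0:
            continue
        l21 = l21 + (w_gamma / nj) * _sum(mj, Tensor(event) * (t_time - ycf).abs())
        l22 = l22 + (w_gamma / nj) * _sum(mj, Tensor(1.0 - event) * under)

    lcp = l11 + l12 + l13 + l21 + l22
    return {"l11": l11, "l12": l12, "l13": l13, "l21": l21, "l22": l22,
            "lcp": lcp}


def uncensored_squared_loss(time, treatment, y_pred) -> Tensor:
    """Per-arm mean squared error for fully observed outcomes.

    Utility for uncensored data only (the squared-error head of the
    treatment-aware objective); not a training mode of this package.
    """
    time = np.asarray(time, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    y = _t(y_pred)
    weights = np.zeros(len(time))
    for j in (0, 1):
        mask = treatment == j
        if mask.any():
            weights[mask] = 1.0 / mask.sum()
    return (Tensor(weights) * (Tensor(time) - y) ** 2).sum()


def total_loss(factual: Tensor, ipm: Tensor, ce: Tensor, lcp: Tensor,
               alpha: float, beta: float, mode: str) -> Tensor:
    """Assemble the mode's objective from its parts.

    ``csa``: factual + alpha*ipm.  ``csa_dragonnet``: + beta*ce.
    ``cdnepk``: + the prior-knowledge penalty sum.
    """
    if mode == "csa":
        return factual + alpha * ipm
    if mode == "csa_dragonnet":
        return factual + alpha * ipm + beta * ce
    if mode == "cdnepk":
        return factual + alpha * ipm + beta * ce + lcp
    raise ValueError(f"unknown mode {mode!r}")
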