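"""Minibatch gradient training of the counterfactual survival network.

Each epoch reshuffles the training set (seeded), partitions it into
``ceil(N / b)`` batches, computes the selected mode's objective per batch and
applies one Adam step per batch.  The per-epoch validation factual loss picks
the returned parameters.

Modes: ``csa`` (censored factual error + representation balancing),
``csa_dragonnet`` (adds the treatment cross-entropy head) and ``cdnepk``
(adds the prior-knowledge counterfactual penalties).  With an empty knowledge
base the penalty term vanishes and ``cdnepk`` training is step-for-step
identical to ``csa_dragonnet`` under the same seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, scatter_rows
from ._layers import Adam
from .data import Dataset
from .knowledge import Effect, InconsistencyError, KnowledgeBase
from .losses import (LossBreakdown, factual_loss, ipm_distance, prior_losses,
                     total_loss, treatment_ce)
from .network import CounterfactualSurvivalNet, ModelConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainResult", "train", "precompute_memberships"]

MODES = ("csa", "csa_dragonnet", "cdnepk")


@dataclass
class TrainConfig:
    epochs: int = 80
    batch_size: int = 850
    learning_rate: float = 3e-3
    mode: str = "cdnepk"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass
class TrainResult:
    net: CounterfactualSurvivalNet
    history: list[dict] = field(default_factory=list)
    selected_epoch: int = 0


def precompute_memberships(dataset: Dataset, kb: KnowledgeBase | None
                           ) -> np.ndarray:
    """Knowledge-region tag per record, on RAW (unstandardized) covariates.

    Region thresholds are stated in clinical units, so membership must be
    resolved before any covariate scaling.
    """
    if kb is None or kb.empty:
        return np.full(dataset.n, Effect.UNKNOWN, dtype=object)
    tags = np.empty(dataset.n, dtype=object)
    bad: list = []
    names = list(dataset.covariate_names)
    for i, row in enumerate(dataset.covariates):
        try:
            tags[i] = kb.classify(row, names)
        except InconsistencyError:
            bad.append(dataset.ids[i])
            tags[i] = Effect.UNKNOWN
    if bad:
        raise InconsistencyError(
            f"patients {bad} satisfy both positive- and zero-effect regions")
    return tags


def _batch_loss(net: CounterfactualSurvivalNet, X, time, event, treatment,
                membership, mcfg: ModelConfig, mode: str,
                training: bool, rng: np.random.Generator | None
                ) -> tuple[Tensor, LossBreakdown]:
    """Objective of one batch; also returns the component breakdown."""
    n = len(time)
    rep = net.represent(X, training=training, rng=rng)

    # Route each arm's network once per batch: factual rows (t = j) and, in
    # knowledge mode, counterfactual rows (t = 1-j with a region tag) share a
    # single forward pass, so batch-norm statistics and dropout masks are
    # computed over the combined flow exactly as in the two-branch diagram.
    eps_rng = rng if rng is not None else np.random.default_rng(0)
    use_cf = mode == "cdnepk"
    known = np.array([m is not Effect.UNKNOWN for m in membership])
    fact_parts: list[tuple[Tensor, np.ndarray]] = []
    cf_parts: list[tuple[Tensor, np.ndarray]] = []
    for j in (1, 0):
        fidx = np.flatnonzero(treatment == j)
        cidx = (np.flatnonzero(known & (treatment == 1 - j))
                if use_cf and known.any() else np.array([], dtype=int))
        rows = np.concatenate([fidx, cidx])
        if rows.size == 0:
            continue
        eps = eps_rng.standard_normal((rows.size, mcfg.noise_dim))
        out = net.survival(rep.take_rows(rows), j, eps,
                           training=training, rng=rng)
        if fidx.size:
            fact_parts.append((out.take_rows(np.arange(fidx.size)), fidx))
        if cidx.size:
            cf_parts.append((out.take_rows(np.arange(fidx.size, rows.size)),
                             cidx))
    y_fact = sum((scatter_rows(y, idx, n) for y, idx in fact_parts),
                 Tensor(np.zeros(n)))

    fact = factual_loss(time, event, treatment, y_fact)

    if (treatment == 1).any() and (treatment == 0).any():
        ipm = ipm_distance(rep.take_rows(treatment == 1),
                           rep.take_rows(treatment == 0),
                           kind=mcfg.ipm_kind, bandwidth=mcfg.mmd_bandwidth)
    else:
        warnings.warn("single-arm batch: IPM term skipped", stacklevel=2)
        ipm = Tensor(0.0)

    zero = Tensor(0.0)
    ce = zero
    if mode in ("csa_dragonnet", "cdnepk"):
        ce = treatment_ce(net.treatment_proba(rep), treatment)

    priors = {k: zero for k in ("l11", "l12", "l13", "l21", "l22", "lcp")}
    if use_cf and cf_parts:
        y_cf = sum((scatter_rows(y, idx, n) for y, idx in cf_parts),
                   Tensor(np.zeros(n)))
        priors = prior_losses(time, event, treatment, y_cf, membership,
                              normalized_omega=mcfg.normalized_omega)

    total = total_loss(fact, ipm, ce, priors["lcp"], mcfg.alpha, mcfg.beta, mode)
    breakdown = LossBreakdown(
        factual=fact.item(), ipm=ipm.item(), treatment_ce=ce.item(),
        l11=priors["l11"].item(), l12=priors["l12"].item(),
        l13=priors["l13"].item(), l21=priors["l21"].item(),
        l22=priors["l22"].item(), lcp=priors["lcp"].item(), total=total.item())
    return total, breakdown


def _validation_factual(net: CounterfactualSurvivalNet, val: Dataset,
                        mcfg: ModelConfig, seed: int) -> float:
    """Evaluation-mode censored factual loss on the validation fold."""
    if val.n == 0:
        return np.nan
    rng = np.random.default_rng(seed)  # same draws every epoch
    rep = net.represent(val.covariates, training=False)
    y = np.zeros(val.n)
    for j in (1, 0):
        mask = val.treatment == j
        if not mask.any():
            continue
        eps = rng.standard_normal((int(mask.sum()), mcfg.noise_dim))
        y[mask] = net.survival(rep.take_rows(mask), j, eps, training=False).data
    return factual_loss(val.time, val.event, val.treatment, y).item()


def train(train_set: Dataset, val_set: Dataset | None,
          kb: KnowledgeBase | None, mcfg: ModelConfig,
          tcfg: TrainConfig, memberships: np.ndarray | None = None
          ) -> TrainResult:
    """Run the minibatch training loop and return the selected parameters.

    ``memberships`` may be supplied precomputed (tags on raw covariates);
    otherwise they are derived here from ``kb``.  The test fold is never an
    argument: model selection uses only the validation factual loss.
    """
    if train_set.n == 0:
        raise ValueError("training set is empty")
    if tcfg.mode == "cdnepk" and (kb is None or kb.empty) and memberships is None:
        logger.info("cdnepk mode with empty knowledge base: penalty term is 0")
    if memberships is None:
        memberships = precompute_memberships(train_set, kb)

    net = CounterfactualSurvivalNet(mcfg, train_set.m, seed=mcfg.seed)
    # start both survival heads at the cohort's mean observed time: the
    # exponential output otherwise begins near 1, and the large one-sided
    # hinge losses of the catch-up phase destabilize the arms asymmetrically
    base = float(np.log(np.mean(train_set.time)))
    for j in (0, 1):
        net.h[j].b.data[:] = base
    opt = Adam(net.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    n = train_set.n
    n_batches = int(np.ceil(n / tcfg.batch_size))

    history: list[dict] = []
    best = (np.inf, 0, net.state_dict())
    for epoch in range(tcfg.epochs):
        perm = rng.permutation(n)
        sums: dict[str, float] = {}
        for b in range(n_batches):
            idx = perm[b * tcfg.batch_size: (b + 1) * tcfg.batch_size]
            total, breakdown = _batch_loss(
                net, train_set.covariates[idx], train_set.time[idx],
                train_set.event[idx], train_set.treatment[idx],
                memberships[idx], mcfg, tcfg.mode, training=True, rng=rng)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b}: "
                    f"{breakdown.as_dict()}")
            opt.zero_grad()
            total.backward()
            opt.step()
            for k, v in breakdown.as_dict().items():
                sums[k] = sums.get(k, 0.0) + v
        record = {k: v / n_batches for k, v in sums.items()}
        record["epoch"] = epoch
        val_loss = (_validation_factual(net, val_set, mcfg, tcfg.seed)
                    if val_set is not None and val_set.n else record["factual"])
        record["val_factual"] = val_loss
        history.append(record)
        if val_loss < best[0]:
            best = (val_loss, epoch, net.state_dict())

    net.load_state(best[2])
    return TrainResult(net=net, history=history, selected_epoch=best[1])
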