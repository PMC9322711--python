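"""Ground-truth metrics and the multi-method comparison harness.

Both metrics need the true individual effects, which exist only for simulated
cohorts: on real data one potential outcome is always counterfactual.  PEHE
is reported as the mean squared effect-estimation error (no square root), the
convention of the benchmark this package reproduces; :func:`sqrt_pehe` is
provided for comparison with literature that reports the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, split_dataset, standardize as _standardize
from .knowledge import KnowledgeBase
from .network import ModelConfig
from .training import TrainConfig, precompute_memberships, train

__all__ = ["EvaluationResult", "pehe", "sqrt_pehe", "ate_error",
           "evaluate_ite", "compare_methods"]


@dataclass
class EvaluationResult:
    pehe: float
    ate_error: float
    per_patient_ite: np.ndarray
    n: int


def _check_pair(true_ite, est_ite) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(true_ite, dtype=float)
    b = np.asarray(est_ite, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: true {a.shape} vs est {b.shape}")
    if a.size == 0:
        raise ValueError("need at least one patient")
    return a, b


def pehe(true_ite, est_ite) -> float:
    """Mean squared error of the individual-effect estimates (no square root)."""
    a, b = _check_pair(true_ite, est_ite)
    return float(np.mean((a - b) ** 2))


def sqrt_pehe(true_ite, est_ite) -> float:
    return float(np.sqrt(pehe(true_ite, est_ite)))


def ate_error(true_ite, est_ite) -> float:
    """Absolute difference between the mean estimated and mean true effect."""
    a, b = _check_pair(true_ite, est_ite)
    return float(abs(b.mean() - a.mean()))


def evaluate_ite(true_ite, est_ite) -> EvaluationResult:
    a, b = _check_pair(true_ite, est_ite)
    return EvaluationResult(pehe=pehe(a, b), ate_error=ate_error(a, b),
                            per_patient_ite=b, n=a.size)


def compare_methods(dataset: Dataset, truth: pd.DataFrame | None,
                    modes=("csa", "csa_dragonnet", "cdnepk"),
                    seeds=(0, 1, 2, 3, 4), kb: KnowledgeBase | None = None,
                    mcfg: ModelConfig | None = None,
                    tcfg: TrainConfig | None = None,
                    ratios=(0.70, 0.15, 0.15),
                    standardize: bool = True) -> pd.DataFrame:
    """Train each mode per seed on identical splits; aggregate test-fold metrics.

    Returns one row per mode with mean and standard deviation of PEHE and the
    ATE error across seeds.  ``truth`` must be the simulator's ground-truth
    frame (``patient_id``, ``delta_Y``).
    """
    if truth is None:
        raise ValueError(
            "ground-truth effects are required: PEHE/ATE cannot be computed on "
            "real data, where one potential outcome is always counterfactual")
    truth_by_id = truth.set_index("patient_id")["delta_Y"]
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    rows = []
    per_mode: dict[str, dict[str, list[float]]] = {
        m: {"pehe": [], "ate": []} for m in modes}
    for seed in seeds:
        train_set, val_set, test_set = split_dataset(dataset, ratios, seed=seed)
        memberships = precompute_memberships(train_set, kb)
        if standardize:
            (train_std, val_std, test_std), _ = _standardize(
                train_set, val_set, test_set)
        else:
            train_std, val_std, test_std = train_set, val_set, test_set
        true_test = truth_by_id.loc[test_set.ids].to_numpy()
        for mode in modes:
            m = ModelConfig(**{**mcfg.__dict__, "seed": seed})
            t = TrainConfig(epochs=tcfg.epochs, batch_size=tcfg.batch_size,
                            learning_rate=tcfg.learning_rate, mode=mode,
                            seed=seed)
            result = train(train_std, val_std, kb, m, t,
                           memberships=memberships)
            est = result.net.predict_ite(test_std.covariates, seed=seed)
            per_mode[mode]["pehe"].append(pehe(true_test, est))
            per_mode[mode]["ate"].append(ate_error(true_test, est))
    for mode in modes:
        p = np.asarray(per_mode[mode]["pehe"])
        a = np.asarray(per_mode[mode]["ate"])
        rows.append({"mode": mode, "pehe_mean": p.mean(),
                     "pehe_sd": p.std(ddof=1) if p.size > 1 else 0.0,
                     "ate_mean": a.mean(),
                     "ate_sd": a.std(ddof=1) if a.size > 1 else 0.0,
                     "n_seeds": p.size})
    return pd.DataFrame(rows)
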