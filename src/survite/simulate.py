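"""Semi-synthetic survival benchmark with known individual treatment effects.

The generator follows the standard scheme for benchmarking counterfactual
survival estimators: covariates are drawn from an HIV-cohort-like sampler,
treatment is assigned by a logistic model of AGE and CD4 count (inducing
selection bias), and both potential survival times come from a Gompertz
proportional-hazards model by inverse-transform sampling,

    Y = (1/kappa) * log(1 - kappa * log(z) / (chi * exp(x' eta))),  z ~ U(0,1),

with a lognormal censoring time.  The same uniform draw ``z`` feeds both arms
of one patient, so region-wise parameter overrides give exact sign control of
the effect: in zero-effect regions the treated arm reuses the control
parameters (Delta Y = 0 exactly), and in positive-effect regions the treated
arm's baseline hazard scale is reduced to ``rho * chi`` with 0 < rho < 1,
which at fixed ``z`` guarantees a strictly longer treated survival time.
Outside the knowledge regions the arms use independent parameter sets and the
effect takes both signs.

Ground truth (both potential outcomes, their difference, the region label) is
returned separately from the observational table and never leaks into it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import Dataset
from .knowledge import KnowledgeBase, builtin_knowledge_bases, is_member

logger = logging.getLogger(__name__)

__all__ = ["SimulationParameters", "default_parameters", "generate_covariates",
           "treatment_probability", "gompertz_time", "sample_potential_outcomes",
           "generate_semi_synthetic"]

#: default per-covariate sampling spec for the synthetic HIV-like cohort.
#: AGE is a truncated normal in years; the CD4/CD8 counts are lognormal with
#: medians near typical cohort values; the four binary covariates share a
#: latent Gaussian factor (loading sqrt(0.45)) because demographic and
#: treatment-history indicators cluster in real cohorts.
DEFAULT_COVARIATE_SPEC: dict[str, dict] = {
    "AGE": {"dist": "truncnorm", "mean": 35.0, "sd": 8.0, "low": 18.0, "high": 70.0},
    "CD40": {"dist": "lognormal", "median": 350.0, "sigma": 0.45},
    "CD80": {"dist": "lognormal", "median": 800.0, "sigma": 0.50},
    "Z30": {"dist": "bernoulli", "p": 0.40},
    "RACE": {"dist": "bernoulli", "p": 0.40},
    "GENDER": {"dist": "bernoulli", "p": 0.50},
    "STE": {"dist": "bernoulli", "p": 0.35},
}

#: shared-latent correlation between the Bernoulli covariates.
DEFAULT_BINARY_CORRELATION = 0.45


@dataclass
class SimulationParameters:
    """The parameter set Lambda of the generator.

    ``lambda_t``/``mu_t`` are the CD4 weights of the logistic treatment model
    (renamed from the generator's lambda/mu to avoid collision with the
    knowledge-region thresholds).  ``eta1``/``eta0`` map covariate names to
    log-hazard coefficients applied to raw covariate values.  ``rho`` is the
    treated-arm hazard-scale multiplier used inside positive-effect regions.
    """

    d1: float = 2.0
    d2: float = 0.5
    lambda_t: float = 0.004
    mu_t: float = 0.004
    kappa1: float = 0.08
    kappa0: float = 0.05
    chi1: float = 0.010
    chi0: float = 0.010
    eta1: dict[str, float] = field(default_factory=lambda: {"AGE": -0.010, "CD40": 0.0005})
    eta0: dict[str, float] = field(default_factory=lambda: {"AGE": 0.020, "CD40": -0.001})
    mu_c: float = 4.0
    sigma2_c: float = 0.6
    rho: float = 0.5
    covariate_spec: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_SPEC.items()})
    binary_correlation: float = DEFAULT_BINARY_CORRELATION
    seed: int = 0

    def __post_init__(self):
        if self.chi1 <= 0 or self.chi0 <= 0:
            raise ValueError("baseline hazard scales chi must be positive")
        if self.sigma2_c < 0:
            raise ValueError("censoring log-variance must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def default_parameters(seed: int = 0, **overrides) -> SimulationParameters:
    return SimulationParameters(seed=seed, **overrides)


def _eta_vector(eta: dict[str, float], names: list[str]) -> np.ndarray:
    unknown = set(eta) - set(names)
    if unknown:
        raise KeyError(f"eta references unknown covariates {sorted(unknown)}")
    return np.array([eta.get(name, 0.0) for name in names])


def generate_covariates(n: int, spec: dict[str, dict] | None = None,
                        seed: int = 0,
                        binary_correlation: float = DEFAULT_BINARY_CORRELATION
                        ) -> pd.DataFrame:
    """Draw ``n`` covariate rows from the configured sampler (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or DEFAULT_COVARIATE_SPEC
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    load = np.sqrt(binary_correlation)
    cols: dict[str, np.ndarray] = {}
    for name, cfg in spec.items():
        dist = cfg.get("dist")
        if dist == "truncnorm":
            a = (cfg["low"] - cfg["mean"]) / cfg["sd"]
            b = (cfg["high"] - cfg["mean"]) / cfg["sd"]
            cols[name] = stats.truncnorm.rvs(a, b, loc=cfg["mean"], scale=cfg["sd"],
                                             size=n, random_state=rng)
        elif dist == "lognormal":
            mu = np.log(cfg["median"])
            cols[name] = rng.lognormal(mu, cfg["sigma"], size=n)
        elif dist == "bernoulli":
            z = load * latent + np.sqrt(1.0 - binary_correlation) * rng.standard_normal(n)
            cols[name] = (stats.norm.cdf(z) < cfg["p"]).astype(float)
        else:
            raise ValueError(f"unknown distribution {dist!r} for covariate {name!r}")
    return pd.DataFrame(cols)


def treatment_probability(X: pd.DataFrame | np.ndarray, params: SimulationParameters,
                          mean_age: float | None = None,
                          mean_cd40: float | None = None) -> np.ndarray:
    """Logistic-model treatment probability, clipped to [0, 1].

    ``p = (1/d1) * (d2 + sigmoid(AGE - mean(AGE) + lambda*CD40 - mu*mean(CD40)))``.
    The affine transform of the sigmoid can exit the unit interval for some
    (d1, d2); values are clipped with a logged warning.
    """
    if params.d1 == 0:
        raise ValueError("d1 must be nonzero")
    if isinstance(X, pd.DataFrame):
        age = X["AGE"].to_numpy()
        cd40 = X["CD40"].to_numpy()
    else:
        age, cd40 = np.asarray(X)[:, 0], np.asarray(X)[:, 1]
    mean_age = float(np.mean(age)) if mean_age is None else mean_age
    mean_cd40 = float(np.mean(cd40)) if mean_cd40 is None else mean_cd40
    raw = (params.d2 + expit(age - mean_age + params.lambda_t * cd40
                             - params.mu_t * mean_cd40)) / params.d1
    if (raw < 0).any() or (raw > 1).any():
        logger.warning("treatment probabilities outside [0, 1] were clipped")
        warnings.warn("treatment probabilities outside [0, 1] were clipped",
                      stacklevel=2)
    return np.clip(raw, 0.0, 1.0)


def gompertz_time(x, kappa: float, chi: float, eta, z) -> np.ndarray:
    """Inverse-transform Gompertz proportional-hazards survival time.

    ``x`` is a covariate row or matrix, ``eta`` the matching coefficient
    vector; ``z`` a U(0,1) draw (scalar or per-row).  For |kappa| < 1e-10 the
    exponential limit ``-log(z) / (chi * exp(x' eta))`` is used.
    """
    if chi <= 0:
        raise ValueError("chi must be positive")
    z = np.asarray(z, dtype=float)
    if np.any((z <= 0) | (z >= 1)):
        raise ValueError("z must lie strictly inside (0, 1)")
    lin = np.asarray(x, dtype=float) @ np.asarray(eta, dtype=float)
    rate = chi * np.exp(lin)
    if abs(kappa) < 1e-10:
        return -np.log(z) / rate
    bracket = 1.0 - kappa * np.log(z) / rate
    if np.any(bracket <= 0):
        raise ValueError("Gompertz bracket nonpositive; kappa too negative "
                         "for this draw")
    return np.log(bracket) / kappa


def sample_potential_outcomes(x, region: str, params: SimulationParameters,
                              z: float, names: list[str]) -> tuple[float, float]:
    """Both potential survival times for one patient from a shared draw ``z``.

    ``region`` is one of D1/D2 (positive effect), D3 (zero effect), D4
    (unconstrained); see the module docstring for the override mechanism.
    """
    eta0 = _eta_vector(params.eta0, names)
    y0 = float(gompertz_time(x, params.kappa0, params.chi0, eta0, z))
    if region == "D3":
        return y0, y0
    if region in ("D1", "D2"):
        if not 0 < params.rho < 1:
            raise ValueError("rho must lie in (0, 1) for positive-effect regions")
        y1 = float(gompertz_time(x, params.kappa0, params.rho * params.chi0, eta0, z))
        return y1, y0
    if region == "D4":
        eta1 = _eta_vector(params.eta1, names)
        y1 = float(gompertz_time(x, params.kappa1, params.chi1, eta1, z))
        return y1, y0
    raise ValueError(f"unknown region {region!r}")


def _assign_regions(X: pd.DataFrame, kb: KnowledgeBase) -> np.ndarray:
    """Map each row to D1..D4 by first-match over the benchmark regions."""
    names = list(X.columns)
    pos = kb.positive_regions
    zero = kb.zero_regions
    out = np.empty(len(X), dtype=object)
    values = X.to_numpy()
    for i, row in enumerate(values):
        if pos and is_member(row, pos[0], names):
            out[i] = "D1"
        elif len(pos) > 1 and is_member(row, pos[1], names):
            out[i] = "D2"
        elif any(is_member(row, r, names) for r in zero):
            out[i] = "D3"
        else:
            out[i] = "D4"
    return out


def generate_semi_synthetic(n: int, params: SimulationParameters | None = None,
                            kb: KnowledgeBase | None = None
                            ) -> tuple[Dataset, pd.DataFrame]:
    """Generate an observational cohort plus its counterfactual ground truth.

    Returns the :class:`~survite.data.Dataset` (covariates, treatment,
    observed time, event indicator) and a ground-truth frame with columns
    ``Y1, Y0, delta_Y, region`` aligned by patient id.  The ground truth is
    never embedded in the dataset.
    """
    params = params or default_parameters()
    kb = kb or builtin_knowledge_bases()["actg_semi_synthetic"]
    rng = np.random.default_rng(params.seed)
    X = generate_covariates(n, params.covariate_spec,
                            seed=int(rng.integers(2**31)),
                            binary_correlation=params.binary_correlation)
    names = list(X.columns)
    values = X.to_numpy()
    regions = _assign_regions(X, kb)

    prob = treatment_probability(X, params)
    treatment = rng.binomial(1, prob)

    z = rng.uniform(size=n)
    # keep z strictly interior (z=0 or 1 occurs with probability 0 anyway)
    z = np.clip(z, 1e-15, 1.0 - 1e-15)
    y1 = np.empty(n)
    y0 = np.empty(n)
    for i in range(n):
        y1[i], y0[i] = sample_potential_outcomes(values[i], regions[i], params,
                                                 z[i], names)
    y_fact = np.where(treatment == 1, y1, y0)
    y_cen = np.exp(rng.normal(params.mu_c, np.sqrt(params.sigma2_c), size=n))
    gamma = np.minimum(y_fact, y_cen)
    delta = (y_fact < y_cen).astype(int)

    ids = np.arange(n)
    dataset = Dataset(ids, values, names, treatment, gamma, delta)
    truth = pd.DataFrame({"patient_id": ids, "Y1": y1, "Y0": y0,
                          "delta_Y": y1 - y0, "region": regions})
    return dataset, truth
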