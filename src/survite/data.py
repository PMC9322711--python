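"""Censored observational survival tables: I/O, splitting, standardization.

A record is one patient: an ``m``-vector of baseline covariates, a binary
treatment ``t``, an observed time ``gamma`` (the survival time when the event
was observed, otherwise the censoring time) and an event indicator ``delta``
(1 = death observed, 0 = censored).  Categorical covariates must arrive
numerically pre-encoded so that covariate indices referenced by knowledge
regions stay stable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Dataset", "SchemaError", "ValidationError", "load_dataset",
           "save_dataset", "split_dataset", "standardize"]


class SchemaError(ValueError):
    """A required column is missing from the table."""


class ValidationError(ValueError):
    """A row violates the data-model invariants."""


@dataclass
class Dataset:
    """An ordered cohort of censored survival records.

    Attributes
    ----------
    ids : object array of patient identifiers (row order preserved).
    covariates : float array, shape (N, m).
    covariate_names : list of m column labels.
    treatment : int array in {0, 1}.
    time : float array of observed times (> 0).
    event : int array in {0, 1}; 1 means the survival time was observed.
    """

    ids: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str]
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray
    standardization: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.treatment = np.asarray(self.treatment, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.validate()

    # -- invariants -----------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ids)
        if self.covariates.shape != (n, len(self.covariate_names)):
            raise ValidationError(
                f"covariate matrix shape {self.covariates.shape} does not match "
                f"{n} records x {len(self.covariate_names)} names")
        for name, arr, ok in (("treatment", self.treatment, {0, 1}),
                              ("event", self.event, {0, 1})):
            bad = ~np.isin(arr, list(ok))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{name} must be in {sorted(ok)}; row {row} has {arr[row]}")
        bad = ~(self.time > 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"observed time must be > 0; row {row} has {self.time[row]}")

    # -- conveniences ----------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.covariate_names)

    def __len__(self) -> int:
        return self.n

    def subset(self, index) -> "Dataset":
        return Dataset(self.ids[index], self.covariates[index],
                       list(self.covariate_names), self.treatment[index],
                       self.time[index], self.event[index],
                       standardization=self.standardization)

    def arm(self, t: int) -> "Dataset":
        """The treated (t=1) or control (t=0) subset."""
        return self.subset(self.treatment == t)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=self.covariate_names)
        df.insert(0, "id", self.ids)
        df["treatment"] = self.treatment
        df["time"] = self.time
        df["event"] = self.event
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   schema: dict[str, object] | None = None) -> "Dataset":
        schema = dict(schema or {})
        id_col = schema.get("id", "id")
        t_col = schema.get("treatment", "treatment")
        time_col = schema.get("time", "time")
        ev_col = schema.get("event", "event")
        for role, col in (("id", id_col), ("treatment", t_col),
                          ("time", time_col), ("event", ev_col)):
            if col not in df.columns:
                raise SchemaError(f"missing {role} column {col!r}")
        cov_cols = schema.get("covariates")
        if cov_cols is None:
            cov_cols = [c for c in df.columns
                        if c not in {id_col, t_col, time_col, ev_col}]
        else:
            for c in cov_cols:
                if c not in df.columns:
                    raise SchemaError(f"missing covariate column {c!r}")
        t = pd.to_numeric(df[t_col]).to_numpy()
        ev = pd.to_numeric(df[ev_col]).to_numpy()
        for role, arr in (("treatment", t), ("event", ev)):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                raise ValidationError(
                    f"non-binary {role} in row {int(np.flatnonzero(bad)[0])}")
        return cls(df[id_col].to_numpy(), df[list(cov_cols)].to_numpy(dtype=float),
                   list(cov_cols), t.astype(int),
                   pd.to_numeric(df[time_col]).to_numpy(dtype=float),
                   ev.astype(int))


def load_dataset(path, schema: dict[str, object] | None = None) -> Dataset:
    """Read a CSV with a header row into a :class:`Dataset`.

    ``schema`` maps the roles ``id``, ``treatment``, ``time``, ``event`` to
    column names and may list ``covariates`` explicitly; by default every
    remaining column is a covariate.
    """
    return Dataset.from_frame(pd.read_csv(path), schema)


def save_dataset(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def split_dataset(dataset: Dataset, ratios=(0.70, 0.15, 0.15),
                  seed: int = 0) -> tuple[Dataset, Dataset, Dataset]:
    """Seeded random train/validation/test partition.

    Validation and test receive ``floor(N * ratio)`` records each; the
    remainder goes to the training share.  Subsets are disjoint and exhaustive.
    """
    r = np.asarray(ratios, dtype=float)
    if r.shape != (3,) or (r < 0).any() or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be three nonnegative reals summing to 1")
    if dataset.n < 3:
        raise ValueError("need at least 3 records to split")
    n_val = int(np.floor(dataset.n * r[1]))
    n_test = int(np.floor(dataset.n * r[2]))
    perm = np.random.default_rng(seed).permutation(dataset.n)
    train_idx = perm[: dataset.n - n_val - n_test]
    val_idx = perm[dataset.n - n_val - n_test: dataset.n - n_test]
    test_idx = perm[dataset.n - n_test:]
    return dataset.subset(train_idx), dataset.subset(val_idx), dataset.subset(test_idx)


def _is_binary(col: np.ndarray) -> bool:
    return bool(np.isin(np.unique(col), (0.0, 1.0)).all())


def standardize(train: Dataset, *others: Dataset
                ) -> tuple[list[Dataset], pd.DataFrame]:
    """Shift/scale continuous covariates by the training mean and sd.

    Binary (0/1-valued in the training set) covariates are left untouched.
    Returns the transformed datasets (train first) and an invertible
    location/scale table indexed by covariate name.  A zero-variance
    continuous covariate gets scale 1 with a logged warning.
    """
    if train.n == 0:
        raise ValueError("training set is empty")
    loc = np.zeros(train.m)
    scale = np.ones(train.m)
    binary = np.zeros(train.m, dtype=bool)
    for j in range(train.m):
        col = train.covariates[:, j]
        if _is_binary(col):
            binary[j] = True
            continue
        loc[j] = col.mean()
        sd = col.std(ddof=0)
        if sd == 0:
            msg = (f"covariate {train.covariate_names[j]!r} has zero variance; "
                   "scale set to 1")
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            sd = 1.0
        scale[j] = sd
    table = pd.DataFrame({"loc": loc, "scale": scale, "binary": binary},
                         index=train.covariate_names)
    out = []
    for ds in (train, *others):
        cov = (ds.covariates - loc) / scale
        out.append(Dataset(ds.ids, cov, list(ds.covariate_names), ds.treatment,
                           ds.time, ds.event, standardization=table))
    return out, table


def unstandardize(dataset: Dataset, table: pd.DataFrame) -> Dataset:
    """Invert :func:`standardize` using its location/scale table."""
    loc = table["loc"].to_numpy()
    scale = table["scale"].to_numpy()
    return Dataset(dataset.ids, dataset.covariates * scale + loc,
                   list(dataset.covariate_names), dataset.treatment,
                   dataset.time, dataset.event)
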