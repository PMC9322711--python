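"""Prior subgroup-effect knowledge as indicator-sum regions.

Conclusions from randomized controlled trials or retrospective cohort studies
typically read "patients satisfying <inclusion criterion> benefit (or do not
benefit) from the treatment".  Both criterion styles seen in practice —
direct covariate conditions and clinical scores summed from per-covariate
sub-scores (e.g. the Child-Pugh score) — can be written in one form: a region

    Theta = { x : sum_j sum_l  o_{j,l} * I(lambda_{j,l} <= x_j <= mu_{j,l})  in V }

with weighting coefficients ``o``, closed interval thresholds and a finite
admissible value set ``V``.  A knowledge base is a union Omega of regions whose
members have a strictly positive individual treatment effect on survival time
(Delta Y > 0) and a union Gamma of regions with no effect (Delta Y = 0).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Effect", "IndicatorTerm", "KnowledgeRegion", "KnowledgeBase",
           "InconsistencyError", "indicator_sum", "is_member", "classify",
           "cp_score", "cp_grade", "builtin_knowledge_bases",
           "load_knowledge_base"]

#: absolute tolerance for membership of the indicator sum in V; the region
#: coefficients used in practice are half-integers, so this is float-safe
#: exact semantics.
V_ATOL = 1e-9

_UP = np.inf
_EPS0 = np.nextafter(0.0, 1.0)


def _above(v: float) -> float:
    """Smallest float strictly greater than ``v`` (open lower bound)."""
    return float(np.nextafter(v, np.inf))


def _below(v: float) -> float:
    """Largest float strictly less than ``v`` (open upper bound)."""
    return float(np.nextafter(v, -np.inf))


class Effect(enum.Enum):
    POSITIVE = "positive"   # member of Omega: Delta Y > 0
    ZERO = "zero"           # member of Gamma: Delta Y = 0
    UNKNOWN = "unknown"


class InconsistencyError(ValueError):
    """A patient satisfies both a positive-effect and a zero-effect region."""


@dataclass(frozen=True)
class IndicatorTerm:
    """One weighted interval indicator ``coeff * I(lower <= x[j] <= upper)``.

    ``covariate`` may be an integer index into the covariate vector or a
    covariate name resolved against the dataset's covariate labels.
    """

    covariate: int | str
    coefficient: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")

    def resolve(self, names: list[str] | None) -> int:
        if isinstance(self.covariate, str):
            if names is None:
                raise ValueError(
                    f"term references covariate {self.covariate!r} by name but "
                    "no covariate names were supplied")
            try:
                return names.index(self.covariate)
            except ValueError:
                raise KeyError(f"unknown covariate {self.covariate!r}") from None
        return int(self.covariate)


@dataclass(frozen=True)
class KnowledgeRegion:
    terms: tuple[IndicatorTerm, ...]
    admissible_values: frozenset[float]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "admissible_values",
                           frozenset(float(v) for v in self.admissible_values))
        if not self.admissible_values:
            raise ValueError("admissible_values must be nonempty")


def indicator_sum(x, region: KnowledgeRegion,
                  names: list[str] | None = None) -> float:
    """Evaluate the weighted indicator sum of ``region`` at covariate vector x."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for term in region.terms:
        j = term.resolve(names)
        if not 0 <= j < x.shape[-1]:
            raise IndexError(f"covariate index {j} out of range for m={x.shape[-1]}")
        if term.lower <= x[j] <= term.upper:
            total += term.coefficient
    return total


def is_member(x, region: KnowledgeRegion,
              names: list[str] | None = None) -> bool:
    s = indicator_sum(x, region, names)
    return any(abs(s - v) <= V_ATOL for v in region.admissible_values)


@dataclass
class KnowledgeBase:
    """Positive-effect regions (union Omega) and zero-effect regions (Gamma)."""

    positive_regions: list[KnowledgeRegion] = field(default_factory=list)
    zero_regions: list[KnowledgeRegion] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.positive_regions and not self.zero_regions

    def matching_regions(self, x, names=None) -> tuple[list[str], list[str]]:
        pos = [r.label or f"positive[{i}]"
               for i, r in enumerate(self.positive_regions)
               if is_member(x, r, names)]
        zero = [r.label or f"zero[{i}]"
                for i, r in enumerate(self.zero_regions)
                if is_member(x, r, names)]
        return pos, zero

    def classify(self, x, names: list[str] | None = None) -> Effect:
        pos, zero = self.matching_regions(x, names)
        if pos and zero:
            raise InconsistencyError(
                f"patient satisfies both positive-effect regions {pos} and "
                f"zero-effect regions {zero}")
        if pos:
            return Effect.POSITIVE
        if zero:
            return Effect.ZERO
        return Effect.UNKNOWN

    def classify_all(self, X, names: list[str] | None = None) -> np.ndarray:
        return np.array([self.classify(row, names) for row in np.asarray(X)],
                        dtype=object)


def classify(x, kb: KnowledgeBase, names: list[str] | None = None) -> Effect:
    return kb.classify(x, names)


# ---------------------------------------------------------------------------
# Child-Pugh score
# ---------------------------------------------------------------------------

def cp_score(he_grade: float, ascites_grade: float, tbil: float, alb: float,
             pt: float) -> int:
    """Child-Pugh liver-function score: sum of five sub-scores, each 1-3.

    Sub-scores follow the standard clinical table (hepatic encephalopathy
    grade, ascites grade, total bilirubin in g/L, albumin in g/L, prothrombin
    time prolongation in s).  Values on a shared row boundary take the middle
    score (tie rule: TBIL=51 scores 2, not 3).
    """

    def he(v):
        if v == 0:
            return 1
        if v in (1, 2):
            return 2
        if v in (3, 4):
            return 3
        raise ValueError(f"hepatic encephalopathy grade {v} not in 0..4")

    def ac(v):
        if v == 0:
            return 1
        if v == 1:
            return 2
        if v in (2, 3):
            return 3
        raise ValueError(f"ascites grade {v} not in 0..3")

    def tb(v):
        if 0 < v < 34:
            return 1
        if 34 <= v <= 51:
            return 2
        if v > 51:
            return 3
        raise ValueError(f"total bilirubin {v} must be > 0")

    def al(v):
        if v > 35:
            return 1
        if 28 <= v <= 35:
            return 2
        if 0 < v < 28:
            return 3
        raise ValueError(f"albumin {v} must be > 0")

    def pt_(v):
        if 0 < v < 4:
            return 1
        if 4 <= v <= 6:
            return 2
        if v > 6:
            return 3
        raise ValueError(f"prothrombin time {v} must be > 0")

    return he(he_grade) + ac(ascites_grade) + tb(tbil) + al(alb) + pt_(pt)


def cp_grade(score: int) -> str:
    """Child-Pugh grade band: 5-6 -> 'A', 7-9 -> 'B', 10-15 -> 'OTHER'."""
    if not 5 <= score <= 15:
        raise ValueError(f"Child-Pugh score {score} outside [5, 15]")
    if score <= 6:
        return "A"
    if score <= 9:
        return "B"
    return "OTHER"


# ---------------------------------------------------------------------------
# Built-in knowledge bases
# ---------------------------------------------------------------------------

def _cp_grade_a_region() -> KnowledgeRegion:
    """Child-Pugh grade A as an indicator-sum region over the five raw labs.

    Three indicators per covariate with coefficients 1/2/3 reproduce the
    sub-score; grade A is a total in {5, 6}.  Interval endpoints adjacent to
    the middle row are shaved by one float ulp so each value maps to exactly
    one sub-score (boundary ties take score 2, as in :func:`cp_score`).
    """
    rows = {
        "HE":   [(0.0, 0.0), (1.0, 2.0), (3.0, 4.0)],
        "AC":   [(0.0, 0.0), (1.0, 1.0), (2.0, 3.0)],
        "TBIL": [(_EPS0, _below(34.0)), (34.0, 51.0), (_above(51.0), _UP)],
        "ALB":  [(_above(35.0), _UP), (28.0, 35.0), (_EPS0, _below(28.0))],
        "PT":   [(_EPS0, _below(4.0)), (4.0, 6.0), (_above(6.0), _UP)],
    }
    terms = [IndicatorTerm(name, float(score), lo, hi)
             for name, intervals in rows.items()
             for score, (lo, hi) in enumerate(intervals, start=1)]
    return KnowledgeRegion(tuple(terms), frozenset({5.0, 6.0}),
                           label="child_pugh_grade_A")


def _small_hcc_region() -> KnowledgeRegion:
    """Single tumor < 2 cm, no distant metastasis/vascular invasion/ascites."""
    terms = (IndicatorTerm("diameter", 1.0, -np.inf, 2.0),
             IndicatorTerm("number", 1.0, 1.0, 1.0),
             IndicatorTerm("DM", 1.0, 0.0, 0.0),
             IndicatorTerm("VI", 1.0, 0.0, 0.0),
             IndicatorTerm("AC", 1.0, 0.0, 0.0))
    return KnowledgeRegion(terms, frozenset({5.0}), label="small_hcc_single_tumor")


def _actg_regions() -> tuple[KnowledgeRegion, KnowledgeRegion, KnowledgeRegion]:
    """The three semi-synthetic HIV-cohort regions over AGE/CD80/Z30/RACE/GENDER/STE."""
    graded = (IndicatorTerm("AGE", 0.5, _above(30.0), _UP),
              IndicatorTerm("AGE", 1.0, _above(40.0), _UP),
              IndicatorTerm("CD80", 0.5, _above(500.0), _UP),
              IndicatorTerm("CD80", 1.0, _above(800.0), _UP),
              IndicatorTerm("Z30", 1.0, 1.0, 1.0),
              IndicatorTerm("RACE", 1.0, 1.0, 1.0),
              IndicatorTerm("GENDER", 1.0, 1.0, 1.0),
              IndicatorTerm("STE", 1.0, 1.0, 1.0))
    theta1 = KnowledgeRegion(graded, frozenset({5.0, 5.5, 6.0}), label="theta1")
    theta2 = KnowledgeRegion(
        (IndicatorTerm("AGE", 1.0, _above(30.0), _UP),
         IndicatorTerm("CD80", 1.0, _above(500.0), _UP),
         IndicatorTerm("Z30", 1.0, _above(0.5), _UP),
         IndicatorTerm("RACE", 1.0, 1.0, 1.0),
         IndicatorTerm("GENDER", 1.0, 1.0, 1.0),
         IndicatorTerm("STE", 1.0, 1.0, 1.0)),
        frozenset({6.0}), label="theta2")
    theta3 = KnowledgeRegion(graded, frozenset({0.0, 0.5, 1.0, 1.5, 2.0}),
                             label="theta3")
    return theta1, theta2, theta3


def _hcc_study_regions(all_criteria: bool = False
                       ) -> tuple[KnowledgeRegion, KnowledgeRegion, KnowledgeRegion]:
    """Hepatectomy-benefit regions over diameter/number/DM/VI/AC.

    The source prints an admissible value set {4} over five unit indicators;
    that is reproduced verbatim by default.  ``all_criteria=True`` switches to
    {5} (all five conditions required), matching the small-tumor criterion's
    own earlier encoding.
    """
    v = frozenset({5.0}) if all_criteria else frozenset({4.0})
    base = (IndicatorTerm("DM", 1.0, 0.0, 0.0),
            IndicatorTerm("VI", 1.0, 0.0, 0.0),
            IndicatorTerm("AC", 1.0, 0.0, 0.0))
    theta1 = KnowledgeRegion(
        (IndicatorTerm("diameter", 1.0, -np.inf, 2.0),
         IndicatorTerm("number", 1.0, 1.0, 1.0)) + base, v, label="hcc_theta1")
    theta2 = KnowledgeRegion(
        (IndicatorTerm("diameter", 1.0, -np.inf, 2.0),
         IndicatorTerm("number", 1.0, 2.0, 3.0)) + base, v, label="hcc_theta2")
    theta3 = KnowledgeRegion(
        (IndicatorTerm("diameter", 1.0, 5.0, 10.0),
         IndicatorTerm("number", 1.0, 1.0, 1.0)) + base, v, label="hcc_theta3")
    return theta1, theta2, theta3


def builtin_knowledge_bases(hcc_all_criteria: bool = False
                            ) -> dict[str, KnowledgeBase]:
    """Named knowledge-base fixtures used across the package.

    ``actg_semi_synthetic`` drives the semi-synthetic benchmark
    (Omega = theta1 u theta2, Gamma = theta3); ``hcc_study`` is the
    hepatectomy study configuration (Gamma = theta1 u theta2, Omega = theta3);
    ``sorafenib_child_pugh`` and ``small_hcc`` encode the two literature
    examples.
    """
    t1, t2, t3 = _actg_regions()
    h1, h2, h3 = _hcc_study_regions(all_criteria=hcc_all_criteria)
    return {
        "sorafenib_child_pugh": KnowledgeBase([_cp_grade_a_region()], []),
        "small_hcc": KnowledgeBase([], [_small_hcc_region()]),
        "actg_semi_synthetic": KnowledgeBase([t1, t2], [t3]),
        "hcc_study": KnowledgeBase([h3], [h1, h2]),
    }


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

def _parse_bound(v, default: float) -> float:
    if v is None:
        return default
    if isinstance(v, str):
        s = v.strip().lower()
        if s in {"inf", "+inf", "infinity"}:
            return np.inf
        if s == "-inf":
            return -np.inf
        return float(v)
    return float(v)


def load_knowledge_base(path) -> KnowledgeBase:
    """Load a knowledge base from YAML or JSON.

    Expected structure::

        regions:
          - label: my_region
            effect: positive        # or "zero"
            admissible_values: [5, 6]
            terms:
              - {covariate: AGE, coeff: 1.0, low: 30, high: inf}
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    kb = KnowledgeBase()
    for spec in doc.get("regions", []):
        terms = tuple(
            IndicatorTerm(t["covariate"], float(t.get("coeff", 1.0)),
                          _parse_bound(t.get("low"), -np.inf),
                          _parse_bound(t.get("high"), np.inf))
            for t in spec["terms"])
        region = KnowledgeRegion(terms, frozenset(spec["admissible_values"]),
                                 label=spec.get("label", ""))
        effect = spec.get("effect", "positive").lower()
        if effect == "positive":
            kb.positive_regions.append(region)
        elif effect == "zero":
            kb.zero_regions.append(region)
        else:
            raise ValueError(f"effect must be 'positive' or 'zero', got {effect!r}")
    return kb
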