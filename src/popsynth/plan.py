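"""Synthesis plans: variable schemas, per-variable model specs, validation, ordering.

A synthesis plan declares the low-disclosure-risk *seed variables* (whose joint
counts are exported verbatim) and an ordered sequence of outcome variables, each
with a regression model specification.  The sequential constraint — the k-th
outcome may be predicted only from the seed variables and outcomes 1..k-1 — is
what makes the chain of predictive equations a valid factorisation of the joint
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

VTYPES = ("categorical", "binary", "continuous", "probability")
FAMILIES = ("gaussian", "logistic", "multinomial")

#: which model family fits which outcome type
FAMILY_FOR_VTYPE = {
    "continuous": "gaussian",
    "probability": "gaussian",
    "binary": "logistic",
    "categorical": "multinomial",
}


@dataclass
class VariableSpec:
    """Declared type and scope of one variable.

    ``source_scope`` is ``"population"`` for variables observed for everyone
    (registry-like) and ``"survey"`` for variables carried only by the survey
    subsample (lifestyle-like).
    """

    name: str
    vtype: str
    levels: Optional[list] = None
    source_scope: str = "population"
    missing_allowed: bool = False

    @property
    def is_categorical(self) -> bool:
        return self.vtype in ("categorical", "binary")


@dataclass
class ModelSpec:
    """Regression model for one outcome in the sequence."""

    outcome: str
    family: str
    predictors: list = field(default_factory=list)
    stratify_by: list = field(default_factory=list)
    age_spline_df: Optional[int] = None
    missing_indicator_predictors: list = field(default_factory=list)
    fit_on: str = "population"


@dataclass
class SynthesisPlan:
    """Seed variables plus the ordered model sequence.

    ``age_range`` bounds the ages admitted into the seed strata; the default
    0–105 is the range conventionally covered by micro-simulation models.
    """

    seed_vars: list  # list[VariableSpec]
    outcome_vars: list  # list[VariableSpec], one per sequence entry
    sequence: list  # list[ModelSpec]
    age_var: str = "age"
    age_range: tuple = (0, 105)

    @property
    def seed_names(self) -> list:
        return [v.name for v in self.seed_vars]

    @property
    def outcome_names(self) -> list:
        return [m.outcome for m in self.sequence]

    def variable(self, name: str) -> VariableSpec:
        for v in list(self.seed_vars) + list(self.outcome_vars):
            if v.name == name:
                return v
        raise KeyError(f"variable {name!r} not declared in plan")


def validate_plan(plan: SynthesisPlan) -> list:
    """Return a list of human-readable invariant violations (empty iff valid).

    Violations are returned, never raised, so a caller can report them all at
    once.  Each message names the offending variable or model and the rule.
    """
    out: list = []
    all_specs = list(plan.seed_vars) + list(plan.outcome_vars)
    names = [v.name for v in all_specs]
    for n in names:
        if names.count(n) > 1:
            msg = f"variable {n!r}: name declared more than once"
            if msg not in out:
                out.append(msg)
    for v in all_specs:
        if v.vtype not in VTYPES:
            out.append(f"variable {v.name!r}: unknown vtype {v.vtype!r}")
            continue
        if v.is_categorical:
            if not v.levels or len(v.levels) < 2:
                out.append(
                    f"variable {v.name!r}: {v.vtype} requires >= 2 levels"
                )
        elif v.levels:
            out.append(
                f"variable {v.name!r}: {v.vtype} must not declare levels"
            )

    outcome_names = [m.outcome for m in plan.sequence]
    for n in outcome_names:
        if outcome_names.count(n) > 1:
            msg = f"model {n!r}: outcome appears more than once in sequence"
            if msg not in out:
                out.append(msg)
    declared_outcomes = {v.name for v in plan.outcome_vars}
    seed_names = set(plan.seed_names)

    for k, m in enumerate(plan.sequence):
        tag = f"model {m.outcome!r} (position {k + 1})"
        if m.outcome not in declared_outcomes:
            out.append(f"{tag}: outcome has no VariableSpec")
            continue
        ospec = plan.variable(m.outcome)
        if m.family not in FAMILIES:
            out.append(f"{tag}: unknown family {m.family!r}")
        elif FAMILY_FOR_VTYPE.get(ospec.vtype) != m.family:
            out.append(
                f"{tag}: family {m.family!r} does not match outcome vtype "
                f"{ospec.vtype!r}"
            )
        allowed = seed_names | set(outcome_names[:k])
        for p in list(m.predictors) + list(m.stratify_by):
            if p not in allowed:
                out.append(
                    f"{tag}: predictor {p!r} violates the sequential "
                    "constraint (must be a seed variable or an earlier "
                    "outcome)"
                )
        overlap = set(m.predictors) & set(m.stratify_by)
        for p in sorted(overlap):
            out.append(
                f"{tag}: {p!r} appears in both predictors and stratify_by"
            )
        for p in m.missing_indicator_predictors:
            if p not in m.predictors:
                out.append(
                    f"{tag}: missing_indicator predictor {p!r} not in "
                    "predictors"
                )
        if m.fit_on not in ("population", "survey"):
            out.append(f"{tag}: unknown fit_on {m.fit_on!r}")

    lo, hi = plan.age_range
    if not (0 <= lo < hi):
        out.append(f"plan: invalid age_range {plan.age_range!r}")
    return out


# ---------------------------------------------------------------------------
# Variable ordering by association strength
# ---------------------------------------------------------------------------

def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def _cramers_v(a: pd.Series, b: pd.Series) -> float:
    tab = pd.crosstab(a, b)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return 0.0
    chi2 = sps.chi2_contingency(tab.to_numpy(), correction=False)[0]
    n = tab.to_numpy().sum()
    k = min(tab.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if k > 0 else 0.0


def _eta(numeric: pd.Series, grouping: pd.Series) -> float:
    """Correlation ratio: sqrt(between-group SS / total SS)."""
    x = numeric.to_numpy(dtype=float)
    tot = np.sum((x - x.mean()) ** 2)
    if tot == 0:
        return 0.0
    between = 0.0
    for _, grp in pd.Series(x).groupby(grouping.to_numpy()):
        between += len(grp) * (grp.mean() - x.mean()) ** 2
    return float(np.sqrt(between / tot))


def association(a: pd.Series, b: pd.Series) -> float:
    """Mixed-type association on a common [0, 1] scale.

    Pearson |r| for two numeric columns, Cramer's V for two categoricals,
    and the correlation ratio (eta) for a numeric-categorical pair.
    """
    mask = a.notna() & b.notna()
    a, b = a[mask], b[mask]
    if len(a) < 2:
        return 0.0
    na, nb = _is_numeric(a), _is_numeric(b)
    if na and nb:
        sa, sb = a.to_numpy(float), b.to_numpy(float)
        if sa.std() == 0 or sb.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(sa, sb)[0, 1]))
    if not na and not nb:
        return _cramers_v(a, b)
    return _eta(a if na else b, b if na else a)


def rank_variables(
    data: pd.DataFrame, seed_vars: Sequence[str], candidates: Sequence[str]
) -> list:
    """Order candidate outcomes by decreasing association with what precedes.

    Greedy top-down ranking: at each step the candidate with the largest
    maximum association against the current conditioning set (seed variables
    plus already-ranked candidates) is appended.  Ties break lexicographically
    so the ordering is deterministic.
    """
    for c in list(seed_vars) + list(candidates):
        if c not in data.columns:
            raise KeyError(f"variable {c!r} not present in data")
    remaining = sorted(set(candidates))
    conditioning = list(seed_vars)
    ranked: list = []
    while remaining:
        scores = {
            c: max(association(data[c], data[s]) for s in conditioning)
            if conditioning
            else 0.0
            for c in remaining
        }
        # remaining is kept sorted, so max() returns the lexicographically
        # first candidate among score ties
        best = max(remaining, key=lambda c: scores[c])
        ranked.append(best)
        remaining.remove(best)
        conditioning.append(best)
    return ranked


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def plan_to_dict(plan: SynthesisPlan) -> dict:
    d = asdict(plan)
    d["age_range"] = list(plan.age_range)
    return d


def plan_from_dict(d: dict) -> SynthesisPlan:
    return SynthesisPlan(
        seed_vars=[VariableSpec(**v) for v in d["seed_vars"]],
        outcome_vars=[VariableSpec(**v) for v in d["outcome_vars"]],
        sequence=[ModelSpec(**m) for m in d["sequence"]],
        age_var=d.get("age_var", "age"),
        age_range=tuple(d.get("age_range", (0, 105))),
    )


def save_plan(plan: SynthesisPlan, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=False)


def load_plan(path) -> SynthesisPlan:
    with open(path) as fh:
        return plan_from_dict(yaml.safe_load(fh))
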