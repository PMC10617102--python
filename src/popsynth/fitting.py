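"""Secure-zone fitting: the sequential chain of per-variable, per-stratum
regressions and the disclosure-safe export bundle.

Only two things ever leave the fitting environment: the joint counts of the
seed-variable strata (coarse, low-risk) and per-model coefficient vectors
with their covariance matrices.  No row-level data is stored in the bundle,
which is asserted structurally in the test suite.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

from . import __version__
from .design import DesignSpec, Term, encode, make_term, split_strata
from .plan import ModelSpec, SynthesisPlan, validate_plan

PROB_EPS = 1e-6  # clamp for logit transform of probability-type outcomes
MIN_CELL_DEFAULT = 10  # minimum persons sharing a seed-variable combination


class FitError(RuntimeError):
    pass


def canon(v):
    """Canonical python value for stratum keys (survives JSON round trips)."""
    if isinstance(v, np.generic):
        v = v.item()
    if isinstance(v, float) and float(v).is_integer():
        return int(v)
    return v


def canon_key(key) -> tuple:
    return tuple(canon(v) for v in key)


# ---------------------------------------------------------------------------
# Seed strata
# ---------------------------------------------------------------------------

@dataclass
class SeedStrataTable:
    seed_vars: list
    table: pd.DataFrame  # seed columns + "count" + "waived"
    min_cell: int
    policy: str  # waive | drop

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())

    @property
    def n_waived(self) -> int:
        return int(self.table["waived"].sum())


def extract_seed_strata(
    data: pd.DataFrame,
    seed_vars: list,
    min_cell: int = MIN_CELL_DEFAULT,
    policy: str = "waive",
) -> SeedStrataTable:
    """Count individuals per seed-variable combination.

    Combinations with fewer than ``min_cell`` members are either retained
    with an explicit waiver flag (``policy="waive"``, the default, matching
    the low sensitivity of purely demographic cells) or removed
    (``policy="drop"``).
    """
    if policy not in ("waive", "drop"):
        raise ValueError(f"unknown min-cell policy {policy!r}")
    for c in seed_vars:
        if data[c].isna().any():
            raise ValueError(f"missing values in seed variable {c!r}")
    if len(data) == 0:
        tab = pd.DataFrame(columns=list(seed_vars) + ["count", "waived"])
        return SeedStrataTable(list(seed_vars), tab, min_cell, policy)
    tab = (
        data.groupby(list(seed_vars), observed=True, sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    tab["waived"] = tab["count"] < min_cell
    if policy == "drop":
        tab = tab[~tab["waived"]].reset_index(drop=True)
        tab["waived"] = False
    return SeedStrataTable(list(seed_vars), tab, min_cell, policy)


# ---------------------------------------------------------------------------
# Fitted models
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    outcome: str
    family: str  # gaussian | logistic | multinomial
    stratify_by: list
    stratum: tuple
    design: Optional[DesignSpec]
    coef: Optional[np.ndarray]  # (p,) or (J-1, p) for multinomial
    cov: Optional[np.ndarray]  # flattened-coef covariance
    residual_sd: Optional[float]
    n_fit: int
    categories: Optional[list]  # outcome levels, reference first
    transform: Optional[str] = None  # "logit" for probability outcomes
    degenerate: bool = False
    constant: object = None
    pooled_m: Optional[int] = None  # imputations pooled into this fit

    def coef_flat(self) -> np.ndarray:
        return np.asarray(self.coef).ravel()

    def with_coef_flat(self, flat: np.ndarray) -> "FittedModel":
        new = FittedModel(**{**self.__dict__})
        new.coef = flat.reshape(np.asarray(self.coef).shape)
        return new


SCORE_TOL = 1e-3  # max |penalized score| accepted as converged
RIDGE_ALPHA = 1e-4  # L2 penalty weight on the max-abs-scaled design
MAX_NEWTON_ITER = 200


def _symmetrize(m: np.ndarray) -> np.ndarray:
    return (m + m.T) / 2.0


def _ridge_newton(mod, n_params: int, what: str, alpha: float = RIDGE_ALPHA):
    """Maximize loglike(b) - alpha/2 ||b||^2 by damped Newton from zero.

    The penalized log-likelihood is strictly concave (its Hessian is at most
    -alpha I), so it has a unique maximum even under quasi-complete
    separation, where the unpenalized MLE does not exist; backtracking
    guarantees monotone ascent.  Returns (b, cov) with cov the inverse
    penalized observed information at the solution.
    """
    b = np.zeros(n_params)
    eye = np.eye(n_params)

    def objective(p):
        # extreme line-search probes can overflow to -inf loglike; the
        # backtracking loop rejects those, so the warnings are spurious
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            return mod.loglike(p) - 0.5 * alpha * float(p @ p)

    fb = objective(b)
    H = None
    for _ in range(MAX_NEWTON_ITER):
        g = mod.score(b) - alpha * b
        H = np.asarray(mod.hessian(b)) - alpha * eye
        if float(np.abs(g).max()) < SCORE_TOL:
            break
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        while t >= 2.0 ** -40:
            bn = b - t * step
            fn = objective(bn)
            if np.isfinite(fn) and fn >= fb:
                break
            t /= 2.0
        else:
            raise FitError(f"{what}: optimizer made no progress "
                           f"(max |score| {np.abs(g).max():.3g})")
        b, fb = bn, fn
    else:
        raise FitError(f"{what}: optimizer did not converge in "
                       f"{MAX_NEWTON_ITER} iterations")
    if not np.all(np.isfinite(b)):
        raise FitError(f"{what}: non-finite coefficient estimates")
    cov = _symmetrize(np.linalg.inv(-H))
    return b, cov


def _fit_family(y, X, family, levels, what):
    """Fit one stratum; returns (coef, cov, residual_sd, categories).

    Likelihood fits run on a column-rescaled design (max-abs 1 per column)
    with a weak ridge penalty for existence and numerical stability;
    coefficients and covariances are mapped back to the raw design scale
    before returning.
    """
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        return (
            np.asarray(res.params),
            _symmetrize(np.asarray(res.cov_params())),
            float(np.sqrt(res.scale)),
            None,
        )
    scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
    X = X / scale
    if family == "logistic":
        try:
            mod = sm.Logit(y, X)
            b, cov = _ridge_newton(mod, X.shape[1], what)
        except FitError:
            raise
        except Exception as e:
            raise FitError(f"{what}: {e}") from e
        return (
            b / scale,
            cov / np.outer(scale, scale),
            None,
            list(levels),
        )
    if family == "multinomial":
        # baseline-category logit; statsmodels' flat parameter vector (and
        # hence the covariance) is equation-major, matching the C-order
        # ravel of a (J-1, p) coefficient matrix
        try:
            mod = sm.MNLogit(y, X)
            n_eq = len(np.unique(y)) - 1
            b, cov = _ridge_newton(mod, X.shape[1] * n_eq, what)
        except FitError:
            raise
        except Exception as e:
            raise FitError(f"{what}: {e}") from e
        coef = b.reshape(n_eq, X.shape[1]) / scale  # (J-1, p)
        s_flat = np.tile(scale, n_eq)  # equation-major flat order
        cov = cov / np.outer(s_flat, s_flat)
        return coef, cov, None, list(levels)
    raise ValueError(f"unknown family {family!r}")


def build_design(
    data: pd.DataFrame, spec: ModelSpec, plan: SynthesisPlan
) -> DesignSpec:
    """Freeze the encoding of every predictor from fit-time data."""
    terms = []
    for p in spec.predictors:
        vs = plan.variable(p)
        mi = p in spec.missing_indicator_predictors
        if vs.is_categorical:
            terms.append(
                make_term(
                    data, p, categorical=True, missing_indicator=mi,
                    levels=vs.levels,
                )
            )
        else:
            df = spec.age_spline_df if p == plan.age_var else None
            terms.append(
                make_term(
                    data, p, categorical=False, spline_df=df,
                    missing_indicator=mi,
                )
            )
    return DesignSpec(terms=terms)


def _outcome_vector(col: pd.Series, family: str, vtype: str, levels):
    """Map the outcome column to the numeric vector the family expects.

    Returns (y, categories) where categories is the level order used
    (reference first) for categorical families.
    """
    if family == "gaussian":
        y = col.to_numpy(dtype=float)
        if vtype == "probability":
            y = _logit(np.clip(y, PROB_EPS, 1 - PROB_EPS))
        return y, None
    counts = col.value_counts()
    present = [lv for lv in levels if lv in counts.index]
    if len(present) <= 1:
        return None, present  # degenerate: constant outcome
    ref = max(present, key=lambda lv: counts[lv])
    ordered = [ref] + [lv for lv in present if lv != ref]
    if family == "logistic" and len(present) == 2:
        # keep the declared level order: model P(outcome == levels[1])
        ordered = [lv for lv in levels if lv in present]
        y = (col == ordered[1]).to_numpy(dtype=float)
        return y, ordered
    codes = pd.Categorical(col, categories=ordered).codes.astype(int)
    return codes, ordered


def fit_variable(
    data: pd.DataFrame,
    spec: ModelSpec,
    plan: SynthesisPlan,
    design: Optional[DesignSpec] = None,
    strata: Optional[dict] = None,
) -> list:
    """Fit one outcome's model in every stratum of ``data``.

    ``data`` must already be restricted to the fitting scope (population or
    survey rows) and must have a complete outcome column; chained-equation
    imputation upstream handles survey nonresponse.  A stratum in which the
    outcome is constant yields a flagged degenerate model that emits the
    constant.
    """
    vs = plan.variable(spec.outcome)
    if data[spec.outcome].isna().any():
        raise FitError(
            f"outcome {spec.outcome!r} has missing values; impute before "
            "fitting (survey nonresponse) or fix the scope"
        )
    if design is None:
        design = build_design(data, spec, plan)
    if strata is None:
        strata = split_strata(data, spec.stratify_by)
    models = []
    for key, idx in strata.items():
        sub = data.iloc[idx]
        what = f"outcome {spec.outcome!r}, stratum {key!r}"
        y, cats = _outcome_vector(
            sub[spec.outcome], spec.family, vs.vtype, vs.levels
        )
        if y is None or (spec.family == "gaussian" and len(sub) < 2):
            const = cats[0] if cats else canon(sub[spec.outcome].iloc[0])
            models.append(
                FittedModel(
                    spec.outcome, spec.family, list(spec.stratify_by),
                    canon_key(key), None, None, None, None, len(sub),
                    cats, degenerate=True, constant=canon(const),
                )
            )
            continue
        X = encode(design, sub)
        coef, cov, rsd, _ = _fit_family(y, X, spec.family, cats, what)
        models.append(
            FittedModel(
                spec.outcome, spec.family, list(spec.stratify_by),
                canon_key(key), design, coef, cov, rsd, len(sub), cats,
                transform="logit" if vs.vtype == "probability" else None,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    plan: SynthesisPlan
    strata: SeedStrataTable
    models: list = field(default_factory=list)  # FittedModel, sequence order
    provenance: dict = field(default_factory=dict)

    def models_for(self, outcome: str) -> dict:
        return {
            m.stratum: m for m in self.models if m.outcome == outcome
        }


def _data_hash(data: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(str(data.shape).encode())
    h.update(",".join(map(str, data.columns)).encode())
    for c in data.columns[: min(len(data.columns), 64)]:
        h.update(
            pd.util.hash_pandas_object(data[c], index=False).to_numpy().tobytes()
        )
    return h.hexdigest()[:16]


def fit_sequence(
    data: pd.DataFrame,
    plan: SynthesisPlan,
    survey_flag: str = "survey",
    min_cell: int = MIN_CELL_DEFAULT,
    min_cell_policy: str = "waive",
    m_imputations: int = 5,
    mice_iterations: int = 10,
    mice_seed: int = 0,
) -> ModelBundle:
    """Fit the whole sequential chain and assemble the export bundle.

    Survey-scope outcomes with item nonresponse are fitted on ``m_imputations``
    chained-equation completions of the survey rows and pooled with Rubin's
    rules before export, so the bundle carries (Q-bar, T) per model.
    """
    from .mi import default_impute_specs, mice_impute, pool_fitted_models

    violations = validate_plan(plan)
    if violations:
        raise ValueError("invalid plan:\n  " + "\n  ".join(violations))

    lo, hi = plan.age_range
    ages = data[plan.age_var]
    in_range = (ages >= lo) & (ages <= hi)
    n_age_dropped = int((~in_range).sum())
    data = data[in_range].reset_index(drop=True)

    strata = extract_seed_strata(data, plan.seed_names, min_cell, min_cell_policy)

    if survey_flag in data.columns:
        survey_rows = data[data[survey_flag] == 1].reset_index(drop=True)
    else:
        survey_rows = data

    survey_outcomes = [
        m.outcome
        for m in plan.sequence
        if plan.variable(m.outcome).source_scope == "survey"
    ]
    needs_mi = [
        v for v in survey_outcomes if survey_rows[v].isna().any()
    ]
    completed = [survey_rows]
    if needs_mi:
        specs = default_impute_specs(plan, needs_mi)
        imp = mice_impute(
            survey_rows, specs, plan, M=m_imputations,
            iterations=mice_iterations, rng_seed=mice_seed,
        )
        completed = imp.tables

    models: list = []
    for k, mspec in enumerate(plan.sequence):
        try:
            if mspec.fit_on == "survey":
                fits = [
                    fit_variable(tbl, mspec, plan,
                                 design=build_design(completed[0], mspec, plan),
                                 strata=split_strata(completed[0], mspec.stratify_by))
                    for tbl in completed
                ]
                models += pool_fitted_models(fits)
            else:
                models += fit_variable(data, mspec, plan)
        except FitError as e:
            raise FitError(f"sequence position {k + 1}: {e}") from e

    prov = {
        "fitted_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "software": f"popsynth {__version__}",
        "data_hash": _data_hash(data),
        "n_rows": int(len(data)),
        "n_age_dropped": n_age_dropped,
        "min_cell": min_cell,
        "min_cell_policy": min_cell_policy,
        "m_imputations": m_imputations if needs_mi else None,
    }
    return ModelBundle(plan, strata, models, prov)


# ---------------------------------------------------------------------------
# Bundle (de)serialization: JSON, lossless float round trip via repr
# ---------------------------------------------------------------------------

def _term_to_dict(t: Term) -> dict:
    return {k: v for k, v in t.__dict__.items() if v not in (None, False)}


def _model_to_dict(m: FittedModel) -> dict:
    d = {
        "outcome": m.outcome,
        "family": m.family,
        "stratify_by": m.stratify_by,
        "stratum": list(m.stratum),
        "n_fit": m.n_fit,
    }
    if m.degenerate:
        d["degenerate"] = True
        d["constant"] = m.constant
        d["categories"] = m.categories
        return d
    d["design"] = [_term_to_dict(t) for t in m.design.terms]
    d["coef"] = np.asarray(m.coef).tolist()
    d["cov"] = np.asarray(m.cov).tolist()
    if m.residual_sd is not None:
        d["residual_sd"] = m.residual_sd
    if m.categories is not None:
        d["categories"] = m.categories
    if m.transform:
        d["transform"] = m.transform
    if m.pooled_m:
        d["pooled_m"] = m.pooled_m
    return d


def _model_from_dict(d: dict) -> FittedModel:
    if d.get("degenerate"):
        return FittedModel(
            d["outcome"], d["family"], d["stratify_by"],
            canon_key(d["stratum"]), None, None, None, None, d["n_fit"],
            d.get("categories"), degenerate=True, constant=d.get("constant"),
        )
    coef = np.asarray(d["coef"], dtype=float)
    cov = np.asarray(d["cov"], dtype=float)
    if not np.array_equal(cov, cov.T):
        raise ValueError(
            f"bundle model {d['outcome']!r} stratum {d['stratum']!r}: "
            "covariance matrix is not symmetric"
        )
    if cov.shape[0] != coef.size:
        raise ValueError(
            f"bundle model {d['outcome']!r}: covariance dimension "
            f"{cov.shape} does not match coefficient count {coef.size}"
        )
    design = DesignSpec(terms=[Term(**t) for t in d["design"]])
    return FittedModel(
        d["outcome"], d["family"], d["stratify_by"], canon_key(d["stratum"]),
        design, coef, cov, d.get("residual_sd"), d["n_fit"],
        d.get("categories"), transform=d.get("transform"),
        pooled_m=d.get("pooled_m"),
    )


def write_bundle(bundle: ModelBundle, path) -> None:
    from .plan import plan_to_dict

    strata = bundle.strata
    doc = {
        "format": "popsynth-bundle-v1",
        "plan": plan_to_dict(bundle.plan),
        "strata": {
            "seed_vars": strata.seed_vars,
            "min_cell": strata.min_cell,
            "policy": strata.policy,
            "columns": list(strata.table.columns),
            "dtypes": {v: str(strata.table[v].dtype) for v in strata.seed_vars
                       if v in strata.table},
            "rows": [
                [canon(v) for v in row]
                for row in strata.table.itertuples(index=False)
            ],
        },
        "models": [_model_to_dict(m) for m in bundle.models],
        "provenance": bundle.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_bundle(path) -> ModelBundle:
    from .plan import plan_from_dict

    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"malformed bundle file {path}: {e}") from e
    if doc.get("format") != "popsynth-bundle-v1":
        raise ValueError(f"{path}: not a popsynth model bundle")
    s = doc["strata"]
    tab = pd.DataFrame(s["rows"], columns=s["columns"])
    if len(tab):
        tab["count"] = tab["count"].astype(int)
        tab["waived"] = tab["waived"].astype(bool)
        for col, dt in s.get("dtypes", {}).items():
            if col in tab:
                tab[col] = tab[col].astype(dt)
    strata = SeedStrataTable(s["seed_vars"], tab, s["min_cell"], s["policy"])
    return ModelBundle(
        plan_from_dict(doc["plan"]),
        strata,
        [_model_from_dict(m) for m in doc["models"]],
        doc.get("provenance", {}),
    )
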