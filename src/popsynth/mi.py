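"""Item nonresponse: chained-equation multiple imputation and Rubin pooling.

Survey-scope outcomes carry item nonresponse.  Rather than dropping
incomplete rows (complete-case analysis is biased when nonresponse depends
on age), the survey rows are completed M times by sequential conditional
draws and every downstream model is fitted once per completion; the M
coefficient vectors are then pooled with Rubin's rules,
``T = W + (1 + 1/M) B``, and the pooled (Q-bar, T) is what the export
bundle carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .design import DesignSpec, encode, make_term
from .plan import FAMILY_FOR_VTYPE, SynthesisPlan

M_DEFAULT = 5  # replications of completed risk-factor data
ITERATIONS_DEFAULT = 10  # chained-equation sweeps per completion


@dataclass
class ImputeSpec:
    """Conditional imputation model for one partially observed variable."""

    variable: str
    vtype: str
    predictors: list
    levels: Optional[list] = None
    age_spline_df: Optional[int] = None

    @property
    def family(self) -> str:
        return FAMILY_FOR_VTYPE[self.vtype]


@dataclass
class ImputationSet:
    M: int
    tables: list  # M completed copies of the survey rows
    chain_specs: list
    iterations: int
    rng_seed: int


@dataclass
class PooledEstimate:
    q_bar: np.ndarray
    W: np.ndarray  # within-imputation covariance
    B: Optional[np.ndarray]  # between-imputation covariance (None if M=1)
    T: np.ndarray  # total covariance
    M: int


def pool_rubin(estimates: list) -> PooledEstimate:
    """Rubin's combining rules for M (coefficient, covariance) pairs.

    Q-bar is the mean estimate, W the mean within covariance, B the
    empirical between covariance (divisor M-1) and T = W + (1+1/M) B.
    With M = 1, B is undefined and T = W.
    """
    if not estimates:
        raise ValueError("pool_rubin needs at least one estimate")
    qs = [np.atleast_1d(np.asarray(q, dtype=float)) for q, _ in estimates]
    ws = [np.atleast_2d(np.asarray(w, dtype=float)) for _, w in estimates]
    d = qs[0].shape[0]
    for q, w in zip(qs, ws):
        if q.shape != (d,) or w.shape != (d, d):
            raise ValueError(
                f"dimension mismatch in pooled estimates: expected ({d},) "
                f"and ({d}, {d}), got {q.shape} and {w.shape}"
            )
    M = len(qs)
    q_bar = np.mean(qs, axis=0)
    W = np.mean(ws, axis=0)
    if M == 1:
        return PooledEstimate(q_bar, W, None, W.copy(), 1)
    dev = np.stack(qs) - q_bar
    B = dev.T @ dev / (M - 1)
    T = W + (1.0 + 1.0 / M) * B
    return PooledEstimate(q_bar, W, B, (T + T.T) / 2.0, M)


# ---------------------------------------------------------------------------
# Chained-equation imputation
# ---------------------------------------------------------------------------

def default_impute_specs(plan: SynthesisPlan, variables: list) -> list:
    """Conditional models for the chained equations.

    Each partially observed survey variable is imputed from the seed
    variables and the other survey variables (current completions).  The
    nonresponse mechanism is missing-at-random given age and gender, so
    conditioning on the seeds is what makes the draws unbiased; the other
    chain variables preserve the mutual associations of the lifestyle
    block.  Keeping the conditional models small also keeps them estimable
    on a few thousand survey rows.
    """
    specs = []
    survey_outcomes = [
        v.name for v in plan.outcome_vars if v.source_scope == "survey"
    ]
    spline_df = {
        m.outcome: m.age_spline_df for m in plan.sequence
    }
    for v in variables:
        vs = plan.variable(v)
        predictors = (
            plan.seed_names + [s for s in survey_outcomes if s != v]
        )
        specs.append(
            ImputeSpec(
                v, vs.vtype, predictors, levels=vs.levels,
                age_spline_df=spline_df.get(v, 4),
            )
        )
    return specs


def _impute_design(data: pd.DataFrame, spec: ImputeSpec, plan: SynthesisPlan):
    terms = []
    for p in spec.predictors:
        vs = plan.variable(p)
        if vs.is_categorical:
            terms.append(make_term(data, p, categorical=True, levels=vs.levels))
        else:
            df = spec.age_spline_df if p == plan.age_var else None
            terms.append(make_term(data, p, categorical=False, spline_df=df))
    return DesignSpec(terms=terms)


def _draw_gaussian(y_obs, X_obs, X_mis, rng):
    """Bayesian-proper normal draw: sigma* from the scaled inverse chi-square
    posterior, beta* | sigma* from its normal posterior, then the predictive."""
    n, p = X_obs.shape
    beta, res, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta
    df = max(n - rank, 1)
    ssr = float(resid @ resid)
    sigma2 = ssr / sps.chi2.rvs(df, random_state=rng)
    xtx_inv = np.linalg.pinv(X_obs.T @ X_obs)
    cov = sigma2 * (xtx_inv + xtx_inv.T) / 2.0
    beta_star = rng.multivariate_normal(beta, cov, method="svd")
    return X_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2), len(X_mis))


def _draw_categorical_model(col_obs, X_obs, X_mis, levels, rng):
    """Fit a (multinomial) logit on observed rows, perturb the coefficients
    by their estimation uncertainty, then draw categories for missing rows."""
    from .fitting import _fit_family, _outcome_vector

    counts = col_obs.value_counts()
    present = [lv for lv in levels if lv in counts.index]
    if len(present) == 1:
        return np.repeat(present[0], len(X_mis))
    family = "logistic" if len(present) == 2 else "multinomial"
    y, cats = _outcome_vector(col_obs, family, "categorical", levels)
    coef, cov, _, _ = _fit_family(y, X_obs, family, cats, "imputation model")
    flat = rng.multivariate_normal(np.asarray(coef).ravel(), cov, method="svd")
    if family == "logistic":
        p1 = expit(X_mis @ flat)
        draw = rng.random(len(X_mis)) < p1
        return np.where(draw, cats[1], cats[0])
    B = flat.reshape(len(cats) - 1, X_mis.shape[1])
    lp = np.column_stack([np.zeros(len(X_mis)), X_mis @ B.T])
    lp -= lp.max(axis=1, keepdims=True)
    pr = np.exp(lp)
    pr /= pr.sum(axis=1, keepdims=True)
    cum = np.cumsum(pr, axis=1)
    idx = (rng.random((len(X_mis), 1)) > cum).sum(axis=1)
    return np.asarray(cats, dtype=object)[idx]


def mice_impute(
    data: pd.DataFrame,
    chain_specs: list,
    plan: SynthesisPlan,
    M: int = M_DEFAULT,
    iterations: int = ITERATIONS_DEFAULT,
    rng_seed: int = 0,
) -> ImputationSet:
    """Multiple imputation by chained equations on the survey rows.

    Missing cells are first filled by random draws from the observed
    marginal of each variable; then ``iterations`` full sweeps of
    conditional draws are run per completion.  Observed cells are never
    altered.  With no missing cells the M tables are identical copies of
    the input.
    """
    data = data.reset_index(drop=True)
    chain_vars = [s.variable for s in chain_specs]
    for c in data.columns:
        if data[c].isna().any() and c not in chain_vars:
            raise ValueError(
                f"column {c!r} has missing values but no imputation model"
            )
    for s in chain_specs:
        if data[s.variable].notna().sum() == 0:
            raise ValueError(
                f"variable {s.variable!r} is missing for all rows; its "
                "conditional distribution is inestimable"
            )
    masks = {s.variable: data[s.variable].isna().to_numpy() for s in chain_specs}
    tables = []
    for m in range(M):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(rng_seed), m])
        )
        tbl = data.copy()
        # initial fill: marginal draws from the observed values
        for s in chain_specs:
            miss = masks[s.variable]
            if not miss.any():
                continue
            obs = tbl.loc[~miss, s.variable].to_numpy()
            tbl.loc[miss, s.variable] = rng.choice(obs, size=int(miss.sum()))
        for _ in range(iterations if any(m.any() for m in masks.values()) else 0):
            for s in chain_specs:
                miss = masks[s.variable]
                if not miss.any():
                    continue
                design = _impute_design(tbl, s, plan)
                X = encode(design, tbl)
                X_obs, X_mis = X[~miss], X[miss]
                if s.vtype in ("continuous", "probability"):
                    y_obs = tbl.loc[~miss, s.variable].to_numpy(float)
                    drawn = _draw_gaussian(y_obs, X_obs, X_mis, rng)
                    if s.vtype == "probability":
                        drawn = np.clip(drawn, 0.0, 1.0)
                    tbl.loc[miss, s.variable] = drawn
                else:
                    drawn = _draw_categorical_model(
                        tbl.loc[~miss, s.variable], X_obs, X_mis,
                        s.levels or [0, 1], rng,
                    )
                    tbl.loc[miss, s.variable] = drawn
        tables.append(tbl)
    return ImputationSet(M, tables, chain_specs, iterations, rng_seed)


# ---------------------------------------------------------------------------
# Pooling fitted models across imputations
# ---------------------------------------------------------------------------

def pool_fitted_models(fits_per_imputation: list) -> list:
    """Pool per-stratum FittedModels fitted on M completed tables.

    Coefficients are pooled flat (multinomial matrices are unravelled in the
    same equation-major order as their covariances); the gaussian residual
    standard deviation is pooled as the root mean residual variance.
    """
    from .fitting import FitError, FittedModel

    M = len(fits_per_imputation)
    if M == 1:
        return list(fits_per_imputation[0])
    by_stratum = [
        {m.stratum: m for m in fits} for fits in fits_per_imputation
    ]
    keys = list(by_stratum[0].keys())
    out = []
    for key in keys:
        ms = [b[key] for b in by_stratum]
        first = ms[0]
        if any(m.degenerate for m in ms):
            if not all(m.degenerate and m.constant == first.constant for m in ms):
                raise FitError(
                    f"outcome {first.outcome!r} stratum {key!r}: degenerate "
                    "in some imputations only; cannot pool"
                )
            out.append(first)
            continue
        if any(m.categories != first.categories for m in ms):
            raise FitError(
                f"outcome {first.outcome!r} stratum {key!r}: category sets "
                "differ across imputations; cannot pool"
            )
        pooled = pool_rubin([(m.coef_flat(), m.cov) for m in ms])
        rsd = first.residual_sd
        if rsd is not None:
            rsd = float(np.sqrt(np.mean([m.residual_sd ** 2 for m in ms])))
        out.append(
            FittedModel(
                first.outcome, first.family, first.stratify_by, key,
                first.design,
                pooled.q_bar.reshape(np.asarray(first.coef).shape),
                pooled.T, rsd, first.n_fit, first.categories,
                transform=first.transform, pooled_m=M,
            )
        )
    return out
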