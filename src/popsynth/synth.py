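"""Open-zone synthesis: expand the exported seed-strata counts into a seed
population, then draw every outcome in sequence from the bundle's predictive
equations.

The seed-variable joint distribution of the synthetic population equals the
exported counts *exactly* (expansion, not sampling); every other column is a
probabilistic draw.  Optional extras reproduce two of the bundle's design
affordances: coefficient redraws from N(Q, T) per replicate (parameter
uncertainty propagation) and marginal calibration of probabilities against a
known population prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import encode
from .fitting import FittedModel, ModelBundle, canon


@dataclass
class SyntheticPopulation:
    data: pd.DataFrame
    replicate: int
    provenance: dict = field(default_factory=dict)


def expand_seed(strata) -> pd.DataFrame:
    """One row per counted individual; exact counts, deterministic order
    (stratum order, then index within stratum)."""
    tab = strata.table
    if len(tab) == 0:
        return pd.DataFrame(columns=strata.seed_vars)
    counts = tab["count"].to_numpy(int)
    reps = np.repeat(np.arange(len(tab)), counts)
    out = tab.loc[:, strata.seed_vars].iloc[reps].reset_index(drop=True)
    assert len(out) == strata.total
    return out


def _stream(seed: int, replicate: int, position: int, stratum_idx: int,
            salt: int = 0) -> np.random.Generator:
    """Independent substream keyed by (replicate, sequence position, stratum)
    so adding a variable never perturbs earlier draws."""
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), replicate, position, stratum_idx, salt]
        )
    )


def _category_probs(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-row category probabilities, columns ordered as model.categories."""
    if model.family == "logistic":
        p1 = expit(X @ np.asarray(model.coef))
        return np.column_stack([1.0 - p1, p1])
    B = np.asarray(model.coef)  # (J-1, p); reference has lp 0
    lp = np.column_stack([np.zeros(len(X)), X @ B.T])
    lp -= lp.max(axis=1, keepdims=True)
    pr = np.exp(lp)
    pr /= pr.sum(axis=1, keepdims=True)
    return pr


def draw_outcome(
    model: FittedModel,
    covariate_rows: pd.DataFrame,
    rng: np.random.Generator,
    probabilities: Optional[np.ndarray] = None,
):
    """Draw one outcome vector for the rows of one stratum.

    gaussian: linear predictor + N(0, residual_sd) (inverse-logit applied
    for probability-scale outcomes); logistic: Bernoulli(expit(lp));
    multinomial: softmax draw with implicit zero reference equation.
    ``probabilities`` overrides the model-implied category probabilities
    (used by marginal calibration).
    """
    n = len(covariate_rows)
    if model.degenerate:
        return np.repeat(model.constant, n)
    X = encode(model.design, covariate_rows)
    if X.shape[1] != np.asarray(model.coef).shape[-1]:
        raise ValueError(
            f"covariate matrix ({X.shape[1]} columns) does not match the "
            f"design of model {model.outcome!r}"
        )
    if model.family == "gaussian":
        lp = X @ np.asarray(model.coef)
        y = lp + (rng.normal(0.0, model.residual_sd, n)
                  if model.residual_sd > 0 else 0.0)
        return expit(y) if model.transform == "logit" else y
    pr = probabilities if probabilities is not None else _category_probs(model, X)
    cum = np.cumsum(pr, axis=1)
    idx = (rng.random((n, 1)) > cum).sum(axis=1)
    idx = np.minimum(idx, pr.shape[1] - 1)
    return np.asarray(model.categories, dtype=object)[idx]


def calibrate_marginal(
    probabilities: np.ndarray, target_mean: float, tol: float = 1e-10
) -> tuple:
    """Scale probabilities by one common factor c (capped at 1) so their
    mean hits ``target_mean``; returns (adjusted, c).

    The capped mean is monotone in c, so c is solved by bisection to
    ``tol``.  A target at or above 1, or above the attainable supremum
    (the fraction of nonzero probabilities), is an error.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if not (0.0 < target_mean < 1.0):
        raise ValueError(f"calibration target {target_mean} not in (0, 1)")
    sup = float(np.mean(p > 0))
    if target_mean > sup + tol:
        raise ValueError(
            f"calibration target {target_mean} exceeds the attainable "
            f"maximum {sup} (fraction of nonzero probabilities)"
        )

    def capped_mean(c):
        return float(np.mean(np.minimum(c * p, 1.0)))

    if abs(capped_mean(1.0) - target_mean) <= tol:
        return p.copy(), 1.0
    lo, hi = 0.0, 1.0
    while capped_mean(hi) < target_mean and hi < 1e12:
        lo, hi = hi, hi * 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if capped_mean(mid) < target_mean:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    c = 0.5 * (lo + hi)
    return np.minimum(c * p, 1.0), c


def _redraw_coefficients(model: FittedModel, rng) -> FittedModel:
    flat = rng.multivariate_normal(model.coef_flat(), model.cov, method="svd")
    return model.with_coef_flat(flat)


def _route_strata(frame: pd.DataFrame, stratify_by: list) -> dict:
    if not stratify_by:
        return {(): np.arange(len(frame))}
    groups = frame.groupby(stratify_by, observed=True, sort=True).indices
    out = {}
    for key, idx in groups.items():
        if not isinstance(key, tuple):
            key = (key,)
        out[tuple(canon(v) for v in key)] = np.asarray(idx)
    return out


def synthesize_population(
    bundle: ModelBundle,
    rng_seed: int = 0,
    n_replicates: int = 1,
    draw_parameters: bool = False,
    calibration_targets: Optional[dict] = None,
    stratum_fallback: str = "error",  # error | nearest
    keep_probabilities: Sequence[str] = (),
) -> list:
    """Generate ``n_replicates`` synthetic populations from a bundle.

    Outcomes are drawn in sequence order, each conditioned on the seed
    columns and all previously synthesized columns, routed per row to the
    fitted model of its stratum.  With ``draw_parameters`` every model's
    coefficients are redrawn once per replicate from N(Q, T).  Calibration
    targets (variable -> population mean) rescale the per-row probabilities
    of logistic outcomes, or the values of probability-scale outcomes, by a
    single reported factor.  Binary/categorical outcomes named in
    ``keep_probabilities`` additionally emit a ``p_<name>`` column with the
    per-row category-1 probability used for the draw.
    """
    calibration_targets = dict(calibration_targets or {})
    for v in calibration_targets:
        if v not in bundle.plan.outcome_names:
            raise KeyError(f"calibration target {v!r} is not in the sequence")
    seed_frame = expand_seed(bundle.strata)
    out = []
    for r in range(n_replicates):
        frame = seed_frame.copy()
        factors: dict = {}
        for k, mspec in enumerate(bundle.plan.sequence):
            models = bundle.models_for(mspec.outcome)
            strata = _route_strata(frame, mspec.stratify_by)
            values = np.empty(len(frame), dtype=object)
            prob_col = (
                np.full(len(frame), np.nan)
                if mspec.outcome in keep_probabilities else None
            )
            target = calibration_targets.get(mspec.outcome)
            stratum_keys = sorted(models.keys(), key=str)
            calib_probs, calib_rows = [], []
            for key, idx in strata.items():
                model = models.get(key)
                if model is None:
                    if stratum_fallback == "nearest" and models:
                        model = models[
                            min(stratum_keys,
                                key=lambda s: sum(a != b for a, b in zip(s, key)))
                        ]
                    else:
                        raise KeyError(
                            f"no fitted model for outcome {mspec.outcome!r} "
                            f"in stratum {key!r}"
                        )
                s_idx = stratum_keys.index(model.stratum)
                rng = _stream(rng_seed, r, k, s_idx)
                rows = frame.iloc[idx]
                if (
                    target is not None
                    and model.family == "logistic"
                    and not model.degenerate
                ):
                    # defer the draw: calibrate probabilities jointly over
                    # all strata, then draw with a per-stratum stream
                    X = encode(model.design, rows)
                    m = (_redraw_coefficients(model, _stream(rng_seed, r, k, s_idx, 7))
                         if draw_parameters else model)
                    calib_probs.append(_category_probs(m, X)[:, 1])
                    calib_rows.append((key, idx, m))
                    continue
                if draw_parameters and not model.degenerate:
                    model = _redraw_coefficients(
                        model, _stream(rng_seed, r, k, s_idx, 7)
                    )
                drawn = draw_outcome(model, rows, rng)
                if prob_col is not None and not model.degenerate:
                    X = encode(model.design, rows)
                    pr = _category_probs(model, X)
                    prob_col[idx] = pr[:, 1] if pr.shape[1] == 2 else pr.max(1)
                values[idx] = drawn
            if calib_rows:
                p_all = np.concatenate(calib_probs)
                adj, c = calibrate_marginal(p_all, target)
                factors[mspec.outcome] = c
                pos = 0
                for (key, idx, model), p_str in zip(calib_rows, calib_probs):
                    s_idx = stratum_keys.index(model.stratum)
                    rng = _stream(rng_seed, r, k, s_idx)
                    p1 = adj[pos:pos + len(idx)]
                    pos += len(idx)
                    pr = np.column_stack([1.0 - p1, p1])
                    drawn = draw_outcome(
                        model, frame.iloc[idx], rng, probabilities=pr
                    )
                    if prob_col is not None:
                        prob_col[idx] = p1
                    values[idx] = drawn
            col = pd.Series(values, index=frame.index, name=mspec.outcome)
            vs = bundle.plan.variable(mspec.outcome)
            if not vs.is_categorical:
                col = col.astype(float)
            else:
                col = col.infer_objects(copy=False)
            if target is not None and vs.vtype == "probability":
                adj, c = calibrate_marginal(col.to_numpy(float), target)
                factors[mspec.outcome] = c
                col = pd.Series(adj, index=frame.index, name=mspec.outcome)
            frame[mspec.outcome] = col
            if prob_col is not None:
                frame[f"p_{mspec.outcome}"] = prob_col
        prov = {
            "rng_seed": int(rng_seed),
            "replicate": r,
            "draw_parameters": bool(draw_parameters),
            "calibration_factors": factors,
            "bundle_provenance": bundle.provenance,
            "n": int(len(frame)),
        }
        out.append(SyntheticPopulation(frame, r, prov))
    return out


def implied_vs_realized(bundle: ModelBundle, synthetic: pd.DataFrame) -> pd.DataFrame:
    """Self-consistency audit of the drawing step.

    For every outcome, the fitted-model-implied marginal (mean per-row
    category probability / linear predictor on the synthetic ancestors) is
    compared with the realized draw frequency / mean; the Monte-Carlo
    standard error of the realized quantity given the implied probabilities
    is reported alongside.
    """
    rows = []
    n = len(synthetic)
    for mspec in bundle.plan.sequence:
        models = bundle.models_for(mspec.outcome)
        strata = _route_strata(synthetic, mspec.stratify_by)
        vs = bundle.plan.variable(mspec.outcome)
        if vs.is_categorical:
            levels = list(vs.levels)
            implied = np.zeros(len(levels))
            var_sum = np.zeros(len(levels))
            for key, idx in strata.items():
                model = models[key]
                if model.degenerate:
                    j = levels.index(model.constant)
                    implied[j] += len(idx)
                    continue
                pr = _category_probs(model, encode(model.design, synthetic.iloc[idx]))
                for jm, lv in enumerate(model.categories):
                    j = levels.index(lv)
                    implied[j] += pr[:, jm].sum()
                    var_sum[j] += (pr[:, jm] * (1 - pr[:, jm])).sum()
            implied /= n
            se = np.sqrt(var_sum) / n
            freq = synthetic[mspec.outcome].value_counts(normalize=True)
            for j, lv in enumerate(levels):
                rows.append(
                    dict(outcome=mspec.outcome, level=str(lv),
                         implied=implied[j],
                         realized=float(freq.get(lv, 0.0)), mc_se=se[j])
                )
        else:
            tot_lp, tot_var = 0.0, 0.0
            for key, idx in strata.items():
                model = models[key]
                if model.degenerate:
                    tot_lp += float(model.constant) * len(idx)
                    continue
                X = encode(model.design, synthetic.iloc[idx])
                lp = X @ np.asarray(model.coef)
                if model.transform == "logit":
                    # E[expit(lp + sigma Z)] and its variance per row via
                    # Gauss-Hermite quadrature (20 nodes)
                    nodes, weights = np.polynomial.hermite_e.hermegauss(20)
                    weights = weights / weights.sum()
                    vals = expit(lp[:, None] + model.residual_sd * nodes[None, :])
                    m1 = vals @ weights
                    m2 = (vals ** 2) @ weights
                    tot_lp += m1.sum()
                    tot_var += np.maximum(m2 - m1 ** 2, 0.0).sum()
                else:
                    tot_lp += lp.sum()
                    tot_var += len(idx) * model.residual_sd ** 2
            rows.append(
                dict(outcome=mspec.outcome, level=None,
                     implied=tot_lp / n,
                     realized=float(synthetic[mspec.outcome].mean()),
                     mc_se=np.sqrt(tot_var) / n)
            )
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["z"] = np.where(
            out["mc_se"] > 0,
            (out["realized"] - out["implied"]) / out["mc_se"],
            np.where(out["realized"] == out["implied"], 0.0, np.inf),
        )
    return out
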