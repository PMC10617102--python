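"""Ground-truth population simulator.

The real inputs to this kind of synthesis — registry microdata for a whole
country linked to a non-representative health survey — are confidential, so
the pipeline is exercised against a simulated "confidential" population with
the same statistical structure: a registry-like table of demographic and
socio-economic variables for everyone, a small biased survey subsample
(oversampling the elderly) carrying lifestyle variables with item
nonresponse, and rare binary disease outcomes.

The generator is itself a sequential conditional chain with *known*
coefficients, which makes it usable as an oracle: :func:`true_marginals`
returns exact (total-probability) or high-precision Monte-Carlo marginals of
any generated variable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.special import expit


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SeedSpec:
    """Marginal distribution of one seed variable (discrete levels)."""

    name: str
    levels: list
    probs: list

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.levels):
            raise ValueError(f"seed {self.name!r}: probs/levels length mismatch")
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"seed {self.name!r}: probs must be a distribution")


# Linear-predictor term kinds.  ``fn`` terms take the current frame and
# return a per-row contribution; they are how interaction misspecification
# is injected into the truth while the fitted models stay main-effects.
def eval_terms(terms: list, frame: pd.DataFrame) -> np.ndarray:
    lp = np.zeros(len(frame), dtype=float)
    for t in terms:
        kind = t["kind"]
        if kind == "const":
            lp += t["value"]
        elif kind == "linear":
            x = frame[t["var"]].to_numpy(dtype=float)
            lp += t["coef"] * (x - t.get("center", 0.0))
        elif kind == "cat":
            col = frame[t["var"]]
            coefs = t["coefs"]
            lp += col.map(lambda lv: coefs.get(lv, 0.0)).to_numpy(dtype=float)
        elif kind == "cat_linear":
            # categorical-specific slope on a numeric variable
            slopes = t["slopes"]
            s = frame[t["catvar"]].map(
                lambda lv: slopes.get(lv, 0.0)
            ).to_numpy(dtype=float)
            x = frame[t["var"]].to_numpy(dtype=float)
            lp += s * (x - t.get("center", 0.0))
        elif kind == "fn":
            lp += np.asarray(t["fn"](frame), dtype=float)
        else:
            raise ValueError(f"unknown term kind {kind!r}")
    return lp


@dataclass
class TrueModel:
    """One generating conditional model in the truth chain.

    For ``multinomial`` outcomes ``equations`` maps each non-reference level
    to its term list (reference level has linear predictor 0); for
    ``logistic`` / ``gaussian`` / ``probability`` a single ``terms`` list is
    used.  ``dist`` selects the gaussian noise shape: ``normal``,
    ``lognormal`` (y = exp(lp + noise), right-skewed), or ``uniform_rank``
    (latent gaussian rank-transformed to an exact Uniform(0, 100) marginal —
    the shape of percentile-group variables).
    """

    name: str
    vtype: str  # categorical | binary | continuous | probability
    scope: str = "population"  # population | survey
    levels: Optional[list] = None
    reference: Optional[object] = None
    equations: Optional[dict] = None  # multinomial: level -> terms
    terms: Optional[list] = None
    residual_sd: float = 1.0
    dist: str = "normal"

    def predictors_used(self) -> set:
        names: set = set()
        term_lists = (
            list(self.equations.values()) if self.equations else [self.terms or []]
        )
        for terms in term_lists:
            for t in terms:
                for key in ("var", "catvar"):
                    if key in t:
                        names.add(t[key])
                if t["kind"] == "fn":
                    names |= set(t.get("uses", ()))
        return names


@dataclass
class TruthConfig:
    n_population: int
    seeds: list  # list[SeedSpec]; first one conventionally the age variable
    true_models: list  # list[TrueModel], chain order
    survey_fraction: float = 0.03
    survey_age_bias: float = 1.0  # odds-style multiplier per decade of age
    nonresponse: dict = field(default_factory=dict)
    # nonresponse[var] = {"rate": r, "age_slope": s, "gender_coef": g}
    age_var: str = "age"
    gender_var: str = "gender"
    rng_seed: int = 0

    def model(self, name: str) -> TrueModel:
        for m in self.true_models:
            if m.name == name:
                return m
        raise KeyError(f"variable {name!r} not defined in truth config")

    def validate(self) -> None:
        defined = {s.name for s in self.seeds}
        for m in self.true_models:
            missing = m.predictors_used() - defined
            if missing:
                raise ValueError(
                    f"generating model {m.name!r} references undefined "
                    f"variable(s) {sorted(missing)}"
                )
            defined.add(m.name)
        if not (0 < self.survey_fraction <= 1):
            raise ValueError("survey_fraction must be in (0, 1]")


@dataclass
class TruthData:
    """Simulated population plus oracles the pipeline must not see.

    ``data`` is what the secure-zone fit consumes (survey columns masked
    outside the survey, nonresponse injected); ``complete`` retains every
    latent pre-masking value and is used only as a test oracle.
    """

    data: pd.DataFrame
    complete: pd.DataFrame
    config: TruthConfig
    provenance: dict


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _draw_categorical(rng, probs: np.ndarray, levels: list):
    """Vectorised draw of one level per row from per-row probabilities."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random((len(probs), 1))
    idx = (u > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


def _softmax_probs(model: TrueModel, frame: pd.DataFrame) -> tuple:
    levels = list(model.levels)
    ref = model.reference if model.reference is not None else levels[0]
    lps = []
    for lv in levels:
        if lv == ref:
            lps.append(np.zeros(len(frame)))
        else:
            lps.append(eval_terms(model.equations[lv], frame))
    lp = np.column_stack(lps)
    lp -= lp.max(axis=1, keepdims=True)
    p = np.exp(lp)
    p /= p.sum(axis=1, keepdims=True)
    return p, levels


def _simulate_chain(config: TruthConfig, n: int, rng) -> pd.DataFrame:
    """Draw seeds and every truth variable for every row (no masking)."""
    cols = {}
    for s in config.seeds:
        cols[s.name] = rng.choice(
            np.asarray(s.levels, dtype=object), size=n, p=np.asarray(s.probs)
        )
    frame = pd.DataFrame(cols)
    for s in config.seeds:
        if all(isinstance(lv, (int, float, np.number)) for lv in s.levels):
            frame[s.name] = frame[s.name].astype(float)

    for m in config.true_models:
        if m.vtype == "categorical":
            p, levels = _softmax_probs(m, frame)
            frame[m.name] = _draw_categorical(rng, p, levels)
        elif m.vtype == "binary":
            p = expit(eval_terms(m.terms, frame))
            levels = m.levels or [0, 1]
            draw = rng.random(n) < p
            frame[m.name] = np.where(draw, levels[1], levels[0])
            if all(isinstance(lv, (int, np.integer)) for lv in levels):
                frame[m.name] = frame[m.name].astype(int)
        elif m.vtype in ("continuous", "probability"):
            lp = eval_terms(m.terms, frame)
            noise = rng.normal(0.0, m.residual_sd, size=n) if m.residual_sd > 0 else 0.0
            latent = lp + noise
            if m.vtype == "probability":
                frame[m.name] = expit(latent)
            elif m.dist == "lognormal":
                frame[m.name] = np.exp(latent)
            elif m.dist == "uniform_rank":
                # rank-transform to an exact Uniform(0, 100) marginal while
                # preserving the dependence ordering of the latent draw
                order = np.argsort(latent, kind="stable")
                ranks = np.empty(n)
                ranks[order] = np.arange(n)
                frame[m.name] = 100.0 * (ranks + 0.5) / n
            else:
                frame[m.name] = latent
        else:
            raise ValueError(f"unknown vtype {m.vtype!r} for {m.name!r}")
    return frame


def survey_inclusion_probs(config: TruthConfig, age: np.ndarray) -> np.ndarray:
    """Per-row survey inclusion probability.

    Weights scale as ``survey_age_bias ** (age / 10)`` (a per-decade
    multiplier) and are normalised so the expected sampled fraction equals
    ``survey_fraction`` exactly; with bias 1 every row gets the plain
    fraction.
    """
    w = np.power(config.survey_age_bias, np.asarray(age, float) / 10.0)
    p = config.survey_fraction * w / w.mean()
    return np.clip(p, 0.0, 1.0)


def simulate_truth(config: TruthConfig, survey_flag: str = "survey") -> TruthData:
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_population
    frame = _simulate_chain(config, n, rng)

    age = frame[config.age_var].to_numpy(float)
    p_inc = survey_inclusion_probs(config, age)
    in_survey = rng.random(n) < p_inc
    frame[survey_flag] = in_survey.astype(int)

    complete = frame.copy()

    survey_vars = [m.name for m in config.true_models if m.scope == "survey"]
    for v in survey_vars:
        frame.loc[~in_survey, v] = np.nan

    # item nonresponse (MAR given age and gender) among survey rows only
    for v, spec in config.nonresponse.items():
        if v not in survey_vars:
            raise ValueError(
                f"nonresponse configured for non-survey variable {v!r}"
            )
        rate = spec.get("rate", 0.0)
        if rate <= 0:
            continue
        logit = np.log(rate / (1 - rate)) * np.ones(n)
        logit += spec.get("age_slope", 0.0) * (age - 50.0) / 10.0
        gcoef = spec.get("gender_coef", 0.0)
        if gcoef and config.gender_var in frame:
            gender = frame[config.gender_var]
            nonref = gender != gender.mode().iloc[0]
            logit += gcoef * nonref.to_numpy(float)
        p_miss = expit(logit)
        miss = (rng.random(n) < p_miss) & in_survey
        frame.loc[miss, v] = np.nan

    prov = {
        "rng_seed": config.rng_seed,
        "n_population": n,
        "config_hash": config_hash(config),
        "n_survey": int(in_survey.sum()),
    }
    return TruthData(frame, complete, config, prov)


def config_hash(config: TruthConfig) -> str:
    def default(o):
        if isinstance(o, Callable):
            return getattr(o, "__name__", "fn")
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(config, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Marginal oracle
# ---------------------------------------------------------------------------

@dataclass
class MarginalEstimate:
    variable: str
    kind: str  # "exact" | "mc"
    probs: Optional[dict] = None  # categorical/binary: level -> probability
    mean: Optional[float] = None  # continuous/probability
    sd: Optional[float] = None
    mc_n: Optional[int] = None


def _ancestor_closure(config: TruthConfig, variable: str) -> list:
    """Truth-chain ancestors of ``variable`` in chain order."""
    needed: set = set()
    order = []
    by_name = {m.name: m for m in config.true_models}

    def visit(name):
        if name in by_name and name not in needed:
            for p in by_name[name].predictors_used():
                visit(p)
            needed.add(name)

    for p in config.model(variable).predictors_used():
        visit(p)
    for m in config.true_models:
        if m.name in needed:
            order.append(m.name)
    return order


def true_marginals(
    config: TruthConfig,
    variable: str,
    mc_n: int = 500_000,
    mc_seed: int = 987_654_321,
    max_grid: int = 2_000_000,
) -> MarginalEstimate:
    """Exact or Monte-Carlo marginal of one generated variable.

    Exact mode enumerates the joint distribution of the variable's discrete
    ancestors (law of total probability over the generating chain); it is
    used whenever every ancestor is a seed or a categorical/binary outcome
    and the enumeration grid stays below ``max_grid`` rows.  Otherwise a
    fresh simulation at ``mc_n`` rows (independent seed) provides a
    high-precision Monte-Carlo estimate, flagged as such.
    """
    names = {m.name for m in config.true_models}
    if variable not in names:
        raise KeyError(f"variable {variable!r} not defined in truth config")
    model = config.model(variable)
    ancestors = _ancestor_closure(config, variable)
    discrete_ok = all(
        config.model(a).vtype in ("categorical", "binary") for a in ancestors
    )
    if discrete_ok and model.vtype in ("categorical", "binary"):
        grid = _seed_grid(config, model, ancestors)
        if grid is not None and len(grid) <= max_grid:
            return _exact_marginal(config, model, ancestors, grid)

    # Monte-Carlo fallback on an independent stream
    cfg = TruthConfig(**{**config.__dict__, "n_population": mc_n, "rng_seed": mc_seed})
    rng = np.random.default_rng(mc_seed)
    frame = _simulate_chain(cfg, mc_n, rng)
    col = frame[variable]
    if model.vtype in ("categorical", "binary"):
        probs = col.value_counts(normalize=True).to_dict()
        return MarginalEstimate(variable, "mc", probs=probs, mc_n=mc_n)
    return MarginalEstimate(
        variable, "mc", mean=float(col.mean()), sd=float(col.std()), mc_n=mc_n
    )


def _seed_grid(config, model, ancestors):
    """Cartesian product of the seed variables actually needed."""
    used: set = set(model.predictors_used())
    for a in ancestors:
        used |= config.model(a).predictors_used()
    seed_specs = [s for s in config.seeds if s.name in used]
    frames = [
        pd.DataFrame({s.name: s.levels, f"_p_{s.name}": s.probs})
        for s in seed_specs
    ]
    if not frames:
        return pd.DataFrame({"_w": [1.0]})
    grid = frames[0]
    for f in frames[1:]:
        grid = grid.merge(f, how="cross")
        if len(grid) > 5_000_000:
            return None
    w = np.ones(len(grid))
    for s in seed_specs:
        w *= grid.pop(f"_p_{s.name}").to_numpy(float)
        if pd.api.types.is_numeric_dtype(pd.Series(s.levels)):
            grid[s.name] = grid[s.name].astype(float)
    grid["_w"] = w
    return grid


def _exact_marginal(config, model, ancestors, grid):
    for a in ancestors:
        am = config.model(a)
        if am.vtype == "binary":
            p = expit(eval_terms(am.terms, grid))
            levels = am.levels or [0, 1]
            lo = grid.assign(**{a: levels[0], "_w": grid["_w"] * (1 - p)})
            hi = grid.assign(**{a: levels[1], "_w": grid["_w"] * p})
            grid = pd.concat([lo, hi], ignore_index=True)
        else:
            p, levels = _softmax_probs(am, grid)
            parts = [
                grid.assign(**{a: lv, "_w": grid["_w"] * p[:, j]})
                for j, lv in enumerate(levels)
            ]
            grid = pd.concat(parts, ignore_index=True)
        grid = grid[grid["_w"] > 0].reset_index(drop=True)

    if model.vtype == "binary":
        p = expit(eval_terms(model.terms, grid))
        levels = model.levels or [0, 1]
        p1 = float(np.sum(grid["_w"].to_numpy() * p))
        probs = {levels[0]: 1.0 - p1, levels[1]: p1}
    else:
        p, levels = _softmax_probs(model, grid)
        w = grid["_w"].to_numpy()
        probs = {lv: float(np.sum(w * p[:, j])) for j, lv in enumerate(levels)}
    return MarginalEstimate(model.name, "exact", probs=probs)
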