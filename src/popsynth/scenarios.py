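"""Canned truth-simulator scenarios and matching synthesis plans.

These are the fixed study conditions the package is validated under:

* ``demo``      — a toy-scale analogue of a national registry linked to a
                  ~3% lifestyle survey: 4 seed variables, a 14-level income
                  source, two percentile (uniform-marginal) variables,
                  household type/size, 7-level migration background, three
                  survey lifestyle variables with MAR item nonresponse, two
                  rare cancers and four chronic-disease probability columns.
* ``recovery``  — a minimal, exactly-specified chain for coefficient
                  recovery checks (fitted design == generating design).
* ``misspec``   — a chain with a pure age x region interaction that the
                  main-effects models cannot represent, so synthesis error
                  accumulates along the sequence.
* ``mi``        — a survey variable with strong MAR-by-age nonresponse, for
                  which complete-case estimates are biased by construction.

Marginal targets for the income source and migration background levels are
national registry frequencies (per cent); they serve as generator inputs.
"""

from __future__ import annotations

import numpy as np

from .plan import ModelSpec, SynthesisPlan, VariableSpec
from .truth import SeedSpec, TrueModel, TruthConfig

# ---------------------------------------------------------------------------
# Shared seed distributions
# ---------------------------------------------------------------------------

AGES = list(range(0, 106))


def _age_probs() -> list:
    """Roughly realistic single-year age weights: flat to 45, declining to
    near zero at 105 (population mean ~40 years)."""
    w = np.where(
        np.array(AGES) <= 45,
        1.0,
        np.maximum(1.0 - (np.array(AGES) - 45) / 62.0, 0.02),
    )
    return list(w / w.sum())


def _seed_age() -> SeedSpec:
    return SeedSpec("age", AGES, _age_probs())


def _seed_gender() -> SeedSpec:
    return SeedSpec("gender", ["M", "F"], [0.497, 0.503])


REGIONS = ["north", "east", "west", "south"]
URBAN = ["low", "medium", "high"]

INCOME_LEVELS = [
    "employee", "civil_servant", "director", "other_labour",
    "company_owner", "property", "unemployment", "disability",
    "retirement", "social_assistance", "other_social", "study_grant",
    "other", "no_income",
]
# registry frequencies (per cent) used as generator targets
INCOME_PCT = [47, 7.4, 2.4, 0.3, 14.7, 0.4, 1, 2.9, 17.8, 3.2, 1, 0.8, 0.1, 1]

ETHNICITY_LEVELS = [
    "dutch", "moroccan", "turkish", "surinam", "antilles",
    "other_nonwest", "other_west",
]
ETHNICITY_PCT = [78.9, 2.2, 2.4, 2.1, 0.9, 4.2, 9.4]

HH_SIZE_LEVELS = ["1", "2", "3", "4", "5", "6plus"]
HH_SIZE_PCT = [17.5, 29.7, 16.4, 23.1, 9.4, 3.9]

SMOKING_LEVELS = ["never", "past", "light", "heavy"]
SMOKING_PCT = [41.6, 41.4, 13.3, 3.7]


def _const_logits(levels, pcts, ref_index=0):
    p = np.asarray(pcts, float)
    p = p / p.sum()
    return {
        lv: float(np.log(p[i] / p[ref_index]))
        for i, lv in enumerate(levels) if i != ref_index
    }


# ---------------------------------------------------------------------------
# Demo scenario
# ---------------------------------------------------------------------------

def demo_truth_config(
    n_population: int = 100_000, rng_seed: int = 0
) -> TruthConfig:
    age = {"kind": "linear", "var": "age", "center": 40.0}

    income_eq = {}
    slopes = {  # per-year age slopes on the log-odds vs 'employee'
        "retirement": 0.11, "study_grant": -0.12, "disability": 0.03,
        "company_owner": 0.01, "no_income": -0.04,
    }
    base = _const_logits(INCOME_LEVELS, INCOME_PCT)
    for lv, c in base.items():
        terms = [{"kind": "const", "value": c}]
        if lv in slopes:
            terms.append({**age, "coef": slopes[lv]})
        if lv == "civil_servant":
            terms.append({"kind": "cat", "var": "region",
                          "coefs": {"west": 0.3}})
        if lv == "company_owner":
            terms.append({"kind": "cat", "var": "urban",
                          "coefs": {"low": 0.3, "high": -0.2}})
        terms.append({"kind": "cat", "var": "gender",
                      "coefs": {"F": 0.15 if lv in ("no_income", "social_assistance") else 0.0}})
        income_eq[lv] = terms

    hh_eq = {}
    hh_base = _const_logits(HH_SIZE_LEVELS, HH_SIZE_PCT, ref_index=1)
    for lv, c in hh_base.items():
        terms = [{"kind": "const", "value": c}]
        if lv == "1":
            terms += [{**age, "coef": 0.015},
                      {"kind": "cat", "var": "hh_type",
                       "coefs": {"institutional": 2.5}}]
        if lv in ("4", "5", "6plus"):
            terms.append({"kind": "cat_linear", "catvar": "gender",
                          "var": "age", "center": 40.0,
                          "slopes": {"M": -0.01, "F": -0.01}})
        hh_eq[lv] = terms

    eth_eq = {}
    for lv, c in _const_logits(ETHNICITY_LEVELS, ETHNICITY_PCT).items():
        terms = [{"kind": "const", "value": c},
                 {**age, "coef": -0.01}]
        if lv in ("moroccan", "turkish", "surinam", "antilles"):
            terms.append({"kind": "cat", "var": "urban",
                          "coefs": {"high": 0.8, "low": -0.8}})
        eth_eq[lv] = terms

    smoke_eq = {}
    for lv, c in _const_logits(SMOKING_LEVELS, SMOKING_PCT).items():
        terms = [{"kind": "const", "value": c}]
        if lv == "past":
            terms.append({**age, "coef": 0.045})
        if lv in ("light", "heavy"):
            terms += [{**age, "coef": -0.012},
                      {"kind": "cat", "var": "gender", "coefs": {"M": 0.25}}]
        smoke_eq[lv] = terms

    def disease_prob(name, const, age_coef, smoke_heavy, bmi_coef):
        return TrueModel(
            name, "probability", scope="population",
            terms=[
                {"kind": "const", "value": const},
                {**age, "coef": age_coef},
                {"kind": "cat", "var": "smoking",
                 "coefs": {"heavy": smoke_heavy, "light": smoke_heavy * 0.6,
                           "past": smoke_heavy * 0.3}},
                {"kind": "linear", "var": "bmi", "coef": bmi_coef,
                 "center": 25.0},
            ],
            residual_sd=0.25,
        )

    models = [
        TrueModel("income_source", "categorical", levels=INCOME_LEVELS,
                  reference="employee", equations=income_eq),
        TrueModel(
            "income_pct", "continuous", dist="uniform_rank", residual_sd=1.0,
            terms=[
                {"kind": "cat", "var": "income_source",
                 "coefs": {"director": 2.0, "company_owner": 0.8,
                           "civil_servant": 0.6, "property": 1.0,
                           "unemployment": -1.2, "disability": -1.0,
                           "social_assistance": -1.8, "study_grant": -1.5,
                           "no_income": -2.0, "retirement": -0.3}},
                {**age, "coef": 0.012},
            ],
        ),
        TrueModel(
            "property_pct", "continuous", dist="uniform_rank", residual_sd=1.0,
            terms=[
                {"kind": "linear", "var": "income_pct", "coef": 0.025,
                 "center": 50.0},
                {"kind": "cat", "var": "income_source",
                 "coefs": {"company_owner": 0.8, "property": 2.0,
                           "social_assistance": -1.0}},
                {**age, "coef": 0.03},
            ],
        ),
        TrueModel(
            "hh_type", "binary", levels=["non_institutional", "institutional"],
            terms=[{"kind": "const", "value": -6.3}, {**age, "coef": 0.085}],
        ),
        TrueModel("hh_size", "categorical", levels=HH_SIZE_LEVELS,
                  reference="2", equations=hh_eq),
        TrueModel("ethnicity", "categorical", levels=ETHNICITY_LEVELS,
                  reference="dutch", equations=eth_eq),
        TrueModel(
            "bmi", "continuous", scope="survey", dist="lognormal",
            residual_sd=0.21,
            terms=[
                {"kind": "const", "value": 3.20},
                {**age, "coef": 0.0012},
                {"kind": "cat", "var": "gender", "coefs": {"M": 0.01}},
            ],
        ),
        TrueModel("smoking", "categorical", scope="survey",
                  levels=SMOKING_LEVELS, reference="never",
                  equations=smoke_eq),
        TrueModel(
            "activity", "binary", scope="survey", levels=["no", "yes"],
            terms=[
                {"kind": "const", "value": 0.75},
                {**age, "coef": -0.015},
                {"kind": "cat", "var": "smoking",
                 "coefs": {"heavy": -0.6, "light": -0.3}},
                {"kind": "linear", "var": "bmi", "coef": -0.03,
                 "center": 25.0},
            ],
        ),
        TrueModel(
            "lung_cancer", "binary", levels=[0, 1],
            terms=[
                {"kind": "const", "value": -7.3},
                {"kind": "linear", "var": "age", "coef": 0.075,
                 "center": 50.0},
                {"kind": "cat", "var": "smoking",
                 "coefs": {"heavy": 1.3, "light": 0.9, "past": 0.5}},
                {"kind": "cat", "var": "gender", "coefs": {"M": 0.3}},
            ],
        ),
        TrueModel(
            "pancreas_cancer", "binary", levels=[0, 1],
            terms=[
                {"kind": "const", "value": -7.4},
                {"kind": "linear", "var": "age", "coef": 0.06,
                 "center": 50.0},
            ],
        ),
        disease_prob("p_chd", -3.6, 0.065, 0.5, 0.03),
        disease_prob("p_stroke", -4.2, 0.07, 0.4, 0.02),
        disease_prob("p_diabetes", -3.3, 0.05, 0.2, 0.09),
        disease_prob("p_copd", -4.0, 0.06, 1.0, -0.01),
    ]

    return TruthConfig(
        n_population=n_population,
        seeds=[
            _seed_age(), _seed_gender(),
            SeedSpec("region", REGIONS, [0.10, 0.21, 0.47, 0.22]),
            SeedSpec("urban", URBAN, [0.3, 0.4, 0.3]),
        ],
        true_models=models,
        survey_fraction=0.03,
        survey_age_bias=1.3,  # elderly oversampled
        nonresponse={
            "bmi": {"rate": 0.12, "age_slope": 0.35},
            "smoking": {"rate": 0.08, "age_slope": 0.2},
            "activity": {"rate": 0.10, "age_slope": 0.25, "gender_coef": 0.1},
        },
        rng_seed=rng_seed,
    )


def demo_plan() -> SynthesisPlan:
    seeds = [
        VariableSpec("age", "continuous"),
        VariableSpec("gender", "binary", levels=["M", "F"]),
        VariableSpec("region", "categorical", levels=REGIONS),
        VariableSpec("urban", "categorical", levels=URBAN),
    ]
    outcomes = [
        VariableSpec("income_source", "categorical", levels=INCOME_LEVELS),
        VariableSpec("income_pct", "continuous"),
        VariableSpec("property_pct", "continuous"),
        VariableSpec("hh_type", "binary",
                     levels=["non_institutional", "institutional"]),
        VariableSpec("hh_size", "categorical", levels=HH_SIZE_LEVELS),
        VariableSpec("ethnicity", "categorical", levels=ETHNICITY_LEVELS),
        VariableSpec("bmi", "continuous", source_scope="survey",
                     missing_allowed=True),
        VariableSpec("smoking", "categorical", levels=SMOKING_LEVELS,
                     source_scope="survey", missing_allowed=True),
        VariableSpec("activity", "binary", levels=["no", "yes"],
                     source_scope="survey", missing_allowed=True),
        VariableSpec("lung_cancer", "binary", levels=[0, 1]),
        VariableSpec("pancreas_cancer", "binary", levels=[0, 1]),
        VariableSpec("p_chd", "probability"),
        VariableSpec("p_stroke", "probability"),
        VariableSpec("p_diabetes", "probability"),
        VariableSpec("p_copd", "probability"),
    ]
    seeds_pred = ["age", "region", "urban"]  # gender is the stratifier

    def ms(outcome, family, predictors, **kw):
        return ModelSpec(outcome, family, predictors,
                         stratify_by=["gender"], age_spline_df=4, **kw)

    sequence = [
        ms("income_source", "multinomial", seeds_pred),
        ms("income_pct", "gaussian", seeds_pred + ["income_source"]),
        ms("property_pct", "gaussian",
           seeds_pred + ["income_source", "income_pct"]),
        ms("hh_type", "logistic",
           seeds_pred + ["income_source", "income_pct", "property_pct"]),
        ms("hh_size", "multinomial",
           seeds_pred + ["income_source", "income_pct", "property_pct",
                         "hh_type"]),
        ms("ethnicity", "multinomial",
           seeds_pred + ["income_source", "income_pct", "property_pct",
                         "hh_type", "hh_size"]),
        ms("bmi", "gaussian",
           seeds_pred + ["income_source", "income_pct"], fit_on="survey"),
        ms("smoking", "multinomial",
           seeds_pred + ["income_pct", "bmi"], fit_on="survey"),
        ms("activity", "logistic",
           seeds_pred + ["income_pct", "bmi", "smoking"], fit_on="survey"),
        ms("lung_cancer", "logistic",
           seeds_pred + ["income_pct", "bmi", "smoking"],
           missing_indicator_predictors=["bmi", "smoking"]),
        ms("pancreas_cancer", "logistic",
           seeds_pred + ["income_pct", "bmi", "smoking"],
           missing_indicator_predictors=["bmi", "smoking"]),
        ms("p_chd", "gaussian",
           seeds_pred + ["bmi", "smoking"], fit_on="survey"),
        ms("p_stroke", "gaussian",
           seeds_pred + ["bmi", "smoking"], fit_on="survey"),
        ms("p_diabetes", "gaussian",
           seeds_pred + ["bmi", "smoking"], fit_on="survey"),
        ms("p_copd", "gaussian",
           seeds_pred + ["bmi", "smoking"], fit_on="survey"),
    ]
    return SynthesisPlan(seeds, outcomes, sequence, age_var="age")


# ---------------------------------------------------------------------------
# Recovery scenario: fitted design equals the generating design
# ---------------------------------------------------------------------------

RECOVERY_TRUTH = {
    # per-gender (intercept at age 40, per-year age slope)
    "y_cont": {"M": (2.0, 0.03), "F": (2.5, 0.03), "sd": 1.0},
    "y_bin": {"M": (-0.5, 0.04), "F": (-0.2, 0.04)},
    # multinomial vs reference 'A': level -> (intercept at age 40, slope)
    "y_cat": {"B": (np.log(0.3 / 0.5), 0.02), "C": (np.log(0.2 / 0.5), -0.02)},
}


def recovery_truth_config(n_population: int = 20_000, rng_seed: int = 0) -> TruthConfig:
    age = {"kind": "linear", "var": "age", "center": 40.0}
    t = RECOVERY_TRUTH
    return TruthConfig(
        n_population=n_population,
        seeds=[_seed_age(), _seed_gender()],
        true_models=[
            TrueModel(
                "y_cont", "continuous", residual_sd=t["y_cont"]["sd"],
                terms=[
                    {"kind": "const", "value": t["y_cont"]["M"][0]},
                    {"kind": "cat", "var": "gender",
                     "coefs": {"F": t["y_cont"]["F"][0] - t["y_cont"]["M"][0]}},
                    {**age, "coef": t["y_cont"]["M"][1]},
                ],
            ),
            TrueModel(
                "y_bin", "binary", levels=[0, 1],
                terms=[
                    {"kind": "const", "value": t["y_bin"]["M"][0]},
                    {"kind": "cat", "var": "gender",
                     "coefs": {"F": t["y_bin"]["F"][0] - t["y_bin"]["M"][0]}},
                    {**age, "coef": t["y_bin"]["M"][1]},
                ],
            ),
            TrueModel(
                "y_cat", "categorical", levels=["A", "B", "C"], reference="A",
                equations={
                    lv: [
                        {"kind": "const", "value": t["y_cat"][lv][0]},
                        {**age, "coef": t["y_cat"][lv][1]},
                    ]
                    for lv in ("B", "C")
                },
            ),
        ],
        rng_seed=rng_seed,
    )


def recovery_plan() -> SynthesisPlan:
    seeds = [
        VariableSpec("age", "continuous"),
        VariableSpec("gender", "binary", levels=["M", "F"]),
    ]
    outcomes = [
        VariableSpec("y_cont", "continuous"),
        VariableSpec("y_bin", "binary", levels=[0, 1]),
        VariableSpec("y_cat", "categorical", levels=["A", "B", "C"]),
    ]
    sequence = [
        ModelSpec("y_cont", "gaussian", ["age"], stratify_by=["gender"]),
        ModelSpec("y_bin", "logistic", ["age"], stratify_by=["gender"]),
        ModelSpec("y_cat", "multinomial", ["age"], stratify_by=["gender"]),
    ]
    return SynthesisPlan(seeds, outcomes, sequence)


# ---------------------------------------------------------------------------
# Misspecification scenario: a pure interaction the main-effects fit misses
# ---------------------------------------------------------------------------

def _xor_sign(frame):
    """+1 / -1 by (region == north) XOR (age > 50): zero main effects."""
    a = frame["region"].to_numpy() == "north"
    b = frame["age"].to_numpy(float) > 50
    return np.where(a ^ b, 1.0, -1.0)


def misspec_truth_config(
    n_population: int = 50_000, rng_seed: int = 0, n_steps: int = 4,
    step: float = 0.8, noise_sd: float = 0.8,
) -> TruthConfig:
    """Chain v1..v_k with v_j = v_{j-1} + step * s + noise, where s is a
    pure age x region interaction.  Main-effects fits cannot represent s,
    and because each step adds the same hidden term, the distributional
    error of the synthetic chain grows with sequence position."""
    models = []
    prev = None
    for j in range(1, n_steps + 1):
        terms = [{"kind": "fn",
                  "fn": (lambda f, s=step: s * _xor_sign(f)),
                  "uses": ["region", "age"]}]
        if prev is not None:
            terms.append({"kind": "linear", "var": prev, "coef": 1.0})
        models.append(
            TrueModel(f"v{j}", "continuous", residual_sd=noise_sd, terms=terms)
        )
        prev = f"v{j}"
    return TruthConfig(
        n_population=n_population,
        seeds=[
            _seed_age(), _seed_gender(),
            SeedSpec("region", ["north", "south"], [0.5, 0.5]),
        ],
        true_models=models,
        rng_seed=rng_seed,
    )


def misspec_plan(n_steps: int = 4) -> SynthesisPlan:
    seeds = [
        VariableSpec("age", "continuous"),
        VariableSpec("gender", "binary", levels=["M", "F"]),
        VariableSpec("region", "categorical", levels=["north", "south"]),
    ]
    outcomes = [VariableSpec(f"v{j}", "continuous") for j in range(1, n_steps + 1)]
    sequence = []
    for j in range(1, n_steps + 1):
        preds = ["age", "region"] + [f"v{i}" for i in range(1, j)]
        sequence.append(
            ModelSpec(f"v{j}", "gaussian", preds, stratify_by=["gender"])
        )
    return SynthesisPlan(seeds, outcomes, sequence)


# ---------------------------------------------------------------------------
# MI scenario: strong MAR-by-age nonresponse on a survey variable
# ---------------------------------------------------------------------------

def mi_truth_config(n_population: int = 20_000, rng_seed: int = 0) -> TruthConfig:
    return TruthConfig(
        n_population=n_population,
        seeds=[_seed_age(), _seed_gender()],
        true_models=[
            TrueModel(
                "bmi", "continuous", scope="survey", residual_sd=2.0,
                terms=[
                    {"kind": "const", "value": 25.0},
                    {"kind": "linear", "var": "age", "coef": 0.08,
                     "center": 40.0},
                ],
            ),
        ],
        survey_fraction=0.25,
        survey_age_bias=1.0,
        nonresponse={"bmi": {"rate": 0.35, "age_slope": 0.9}},
        rng_seed=rng_seed,
    )


def mi_plan() -> SynthesisPlan:
    seeds = [
        VariableSpec("age", "continuous"),
        VariableSpec("gender", "binary", levels=["M", "F"]),
    ]
    outcomes = [
        VariableSpec("bmi", "continuous", source_scope="survey",
                     missing_allowed=True),
    ]
    sequence = [
        ModelSpec("bmi", "gaussian", ["age"], stratify_by=["gender"],
                  age_spline_df=4, fit_on="survey"),
    ]
    return SynthesisPlan(seeds, outcomes, sequence)
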