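"""Utility evaluation of a synthetic population against its source.

Univariate checks (category frequencies; the first four moments of
continuous variables), stratified multivariate contrasts over an
age-class x gender x smoking x education style grid with 95% confidence
intervals, and a disclosure-oriented exact-match rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

MIN_STRATIFIED_CELL_N = 30  # cells smaller than this are flagged, not hidden


# ---------------------------------------------------------------------------
# Age recode
# ---------------------------------------------------------------------------

def recode_age(age) -> np.ndarray:
    """Eight-level age classes: 1 = <20, 2..7 = the decades 20-29 .. 70-79,
    8 = 80+.  Ages outside [0, 105] are an error."""
    a = np.asarray(age, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    if np.any((a < 0) | (a > 105) | ~np.isfinite(a)):
        bad = a[(a < 0) | (a > 105) | ~np.isfinite(a)][0]
        raise ValueError(f"age {bad} outside the admitted range [0, 105]")
    cls = np.clip((a // 10).astype(int), 1, 8)
    cls[a < 20] = 1
    return int(cls[0]) if scalar else cls


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def four_moments(x) -> tuple:
    """(mean, sd, skewness, excess kurtosis).

    sd uses the n-1 divisor; skewness g1 = m3 / m2^1.5 and excess kurtosis
    g2 = m4 / m2^2 - 3 use population central moments m_k.  A constant
    vector has sd 0 and undefined (NaN) shape moments.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 2:
        raise ValueError("four_moments needs at least 2 observations")
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d ** 2)
    sd = float(np.sqrt(np.sum(d ** 2) / (n - 1)))
    if m2 == 0:
        return float(mean), 0.0, float("nan"), float("nan")
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return float(mean), sd, float(m3 / m2 ** 1.5), float(m4 / m2 ** 2 - 3.0)


# ---------------------------------------------------------------------------
# Univariate comparison
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    univariate: dict = field(default_factory=dict)
    stratified: Optional[pd.DataFrame] = None
    disclosure: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        uni = {}
        for v, tab in self.univariate.items():
            uni[v] = (
                tab.to_dict(orient="records")
                if isinstance(tab, pd.DataFrame) else tab
            )
        return {
            "univariate": uni,
            "stratified": (
                self.stratified.to_dict(orient="records")
                if self.stratified is not None else None
            ),
            "disclosure": self.disclosure,
            "metadata": self.metadata,
        }


def compare_univariate(
    a: pd.DataFrame,
    b: pd.DataFrame,
    variables: Sequence[str],
    labels: tuple = ("original", "synthetic"),
) -> EvalReport:
    """Side-by-side frequency tables (percent) and four-moment quadruples."""
    report = EvalReport(metadata={"n_a": len(a), "n_b": len(b)})
    for v in variables:
        if v not in a.columns or v not in b.columns:
            raise KeyError(f"variable {v!r} missing from one population")
        ca, cb = a[v].dropna(), b[v].dropna()
        if pd.api.types.is_numeric_dtype(ca) and ca.nunique() > 12:
            ma, mb = four_moments(ca), four_moments(cb)
            report.univariate[v] = pd.DataFrame(
                {
                    "statistic": ["mean", "sd", "skewness", "excess_kurtosis"],
                    labels[0]: list(ma),
                    labels[1]: list(mb),
                }
            )
        else:
            fa = ca.value_counts(normalize=True) * 100
            fb = cb.value_counts(normalize=True) * 100
            levels = sorted(set(fa.index) | set(fb.index), key=str)
            report.univariate[v] = pd.DataFrame(
                {
                    "level": [str(lv) for lv in levels],
                    labels[0]: [round(float(fa.get(lv, 0.0)), 1) for lv in levels],
                    labels[1]: [round(float(fb.get(lv, 0.0)), 1) for lv in levels],
                }
            )
    return report


# ---------------------------------------------------------------------------
# Stratified contrasts
# ---------------------------------------------------------------------------

def _cell_estimate(values: pd.Series, positive_level=None) -> dict:
    """Mean with t-based 95% CI for continuous cells, prevalence with a
    Wilson 95% CI for binary cells."""
    x = values.dropna()
    n = len(x)
    if n == 0:
        return dict(n=0, estimate=np.nan, ci_lo=np.nan, ci_hi=np.nan)
    if positive_level is not None:
        k = int((x == positive_level).sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        return dict(n=n, estimate=k / n, ci_lo=float(lo), ci_hi=float(hi))
    mean = float(x.mean())
    if n < 2 or x.std(ddof=1) == 0:
        return dict(n=n, estimate=mean, ci_lo=mean, ci_hi=mean)
    half = sps.t.ppf(0.975, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return dict(n=n, estimate=mean, ci_lo=mean - half, ci_hi=mean + half)


def stratified_compare(
    a: pd.DataFrame,
    b: pd.DataFrame,
    outcome: str,
    strata_vars: Sequence[str],
    positive_level=None,
    labels: tuple = ("original", "synthetic"),
    min_cell_n: int = MIN_STRATIFIED_CELL_N,
) -> pd.DataFrame:
    """Per-cell estimates with 95% CIs over the stratification grid.

    Rows with a missing outcome are excluded per cell and counted via the
    cell n; cells below ``min_cell_n`` are flagged ``small_cell`` but never
    hidden.
    """
    if not strata_vars:
        raise ValueError("empty stratification grid")
    rows = []
    for label, pop in zip(labels, (a, b)):
        for sv in list(strata_vars) + [outcome]:
            if sv not in pop.columns:
                raise KeyError(f"column {sv!r} missing from {label}")
        grouped = pop.groupby(list(strata_vars), observed=True, sort=True)
        for key, grp in grouped:
            if not isinstance(key, tuple):
                key = (key,)
            est = _cell_estimate(grp[outcome], positive_level)
            rows.append(
                {
                    "population": label,
                    **{sv: k for sv, k in zip(strata_vars, key)},
                    "outcome": outcome,
                    **est,
                    "small_cell": est["n"] < min_cell_n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disclosure
# ---------------------------------------------------------------------------

def disclosure_match_rate(
    original: pd.DataFrame, synthetic: pd.DataFrame, key_vars: Sequence[str]
) -> dict:
    """Fraction of synthetic rows whose key tuple occurs in the original.

    Reported with the baseline rate expected if synthetic keys were drawn
    independently from the original's per-variable marginals — the match
    level that carries no joint information at all.
    """
    key_vars = list(key_vars)
    if not key_vars:
        raise ValueError("empty disclosure key set")
    okeys = set(map(tuple, original[key_vars].itertuples(index=False)))
    skeys = list(map(tuple, synthetic[key_vars].itertuples(index=False)))
    matched = sum(1 for k in skeys if k in okeys)

    marg = [original[v].value_counts(normalize=True) for v in key_vars]
    baseline = 0.0
    for key in okeys:
        p = 1.0
        for v_marg, val in zip(marg, key):
            p *= float(v_marg.get(val, 0.0))
        baseline += p
    return {
        "key_vars": key_vars,
        "matched": matched,
        "rate": matched / len(skeys) if skeys else 0.0,
        "independent_baseline_rate": baseline,
    }


# ---------------------------------------------------------------------------
# Distributional distance (used for error-accumulation diagnostics)
# ---------------------------------------------------------------------------

def total_variation(a: pd.Series, b: pd.Series, bins: int = 30) -> float:
    """Total-variation distance between two marginals.

    Categorical variables use exact level frequencies; continuous ones are
    histogrammed on a common equal-width grid over the pooled range.
    """
    a, b = a.dropna(), b.dropna()
    if pd.api.types.is_numeric_dtype(a) and a.nunique() > 12:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        edges = np.linspace(lo, hi, bins + 1)
        pa, _ = np.histogram(a, bins=edges)
        pb, _ = np.histogram(b, bins=edges)
        pa = pa / pa.sum()
        pb = pb / pb.sum()
        return float(0.5 * np.abs(pa - pb).sum())
    fa = a.value_counts(normalize=True)
    fb = b.value_counts(normalize=True)
    levels = set(fa.index) | set(fb.index)
    return float(
        0.5 * sum(abs(fa.get(lv, 0.0) - fb.get(lv, 0.0)) for lv in levels)
    )


def plot_stratified(table: pd.DataFrame, strata_vars, out_path) -> None:
    """Small-multiple panels: age class on the x axis, one facet per
    combination of the remaining strata, both populations overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    facet_vars = [v for v in strata_vars if v != "age_class"]
    facets = (
        table.groupby(facet_vars, observed=True).groups.keys()
        if facet_vars else [()]
    )
    facets = list(facets)
    ncol = min(4, max(1, len(facets)))
    nrow = int(np.ceil(len(facets) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False
    )
    for ax, key in zip(axes.ravel(), facets):
        if not isinstance(key, tuple):
            key = (key,)
        sub = table
        for v, k in zip(facet_vars, key):
            sub = sub[sub[v] == k]
        for label, grp in sub.groupby("population"):
            grp = grp.sort_values("age_class")
            ax.errorbar(
                grp["age_class"], grp["estimate"],
                yerr=[grp["estimate"] - grp["ci_lo"],
                      grp["ci_hi"] - grp["estimate"]],
                label=str(label), marker="o", ms=3, capsize=2, lw=1,
            )
        ax.set_title(", ".join(map(str, key)), fontsize=8)
        ax.set_xlabel("age class")
    axes.ravel()[0].legend(fontsize=7)
    for ax in axes.ravel()[len(facets):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
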