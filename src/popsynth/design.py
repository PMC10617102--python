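"""Design matrices: natural cubic splines of age, one-hot encoding,
missing-indicator expansion, stratum splitting.

Every encoding decision taken at fit time (spline knots, category reference
levels, centring constants) is stored in the :class:`DesignSpec` so the exact
same matrix can be rebuilt at synthesis time from the exported model bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Natural (restricted) cubic spline basis
# ---------------------------------------------------------------------------

def spline_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Default knot placement: df-1 interior knots at equally spaced
    quantiles, boundary knots at min/max (df+1 knots in total)."""
    qs = np.linspace(0.0, 1.0, df + 1)
    knots = np.quantile(np.asarray(x, dtype=float), qs)
    knots[0] = np.min(x)
    knots[-1] = np.max(x)
    return np.unique(knots)


def build_spline_basis(
    x: np.ndarray, df: int, knots: Optional[np.ndarray] = None
) -> tuple:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Uses the truncated-power restricted-cubic-spline construction: a linear
    term plus df-1 nonlinear terms that are cubic between the knots and
    linear beyond the boundary knots (C2-continuous everywhere).  Returns
    ``(basis, knots)``; passing the stored knots back in reproduces the
    basis exactly on any new data.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError(f"spline df must be >= 2, got {df}")
    if not np.all(np.isfinite(x)):
        raise ValueError("spline input contains non-finite values")
    if knots is None:
        knots = spline_knots(x, df)
    else:
        knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k != df + 1:
        raise ValueError(
            f"need df+1={df + 1} distinct knots, got {k} (x has too few "
            "distinct values for the requested df)"
        )
    t = knots
    scale = (t[-1] - t[0]) ** 2
    cols = [x]

    def pos3(v):
        return np.where(v > 0, v, 0.0) ** 3

    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(term)
    return np.column_stack(cols), knots


# ---------------------------------------------------------------------------
# Design specification (serializable) and encoding
# ---------------------------------------------------------------------------

@dataclass
class Term:
    """One encoded predictor.

    kind:
      * ``linear``            numeric column as-is (centred at ``center``)
      * ``spline``            natural cubic spline with stored ``knots``
      * ``onehot``            categorical dummies omitting ``reference``
      * ``missing_indicator`` set → NaN filled (reference level / centre) and
                              an extra 0/1 indicator column is appended
    """

    variable: str
    kind: str  # linear | spline
    knots: Optional[list] = None
    levels: Optional[list] = None  # category levels, reference first
    center: float = 0.0
    missing_indicator: bool = False

    @property
    def is_categorical(self) -> bool:
        return self.levels is not None


@dataclass
class DesignSpec:
    terms: list = field(default_factory=list)  # list[Term]

    @property
    def column_names(self) -> list:
        names = ["intercept"]
        for t in self.terms:
            if t.is_categorical:
                names += [f"{t.variable}[{lv}]" for lv in t.levels[1:]]
            elif t.kind == "spline":
                names += [
                    f"{t.variable}_s{j}" for j in range(len(t.knots) - 1)
                ]
            else:
                names.append(t.variable)
            if t.missing_indicator:
                names.append(f"{t.variable}_missing")
        return names


def make_term(
    data: pd.DataFrame,
    variable: str,
    *,
    categorical: bool,
    spline_df: Optional[int] = None,
    missing_indicator: bool = False,
    levels: Optional[list] = None,
) -> Term:
    """Build a Term from fit-time data, freezing knots / reference / centre.

    The reference level of a categorical is its most frequent observed level
    (ties broken by level order); a continuous predictor is centred at its
    observed mean so the missing-indicator fill value 0 equals "average".
    """
    col = data[variable]
    obs = col.dropna()
    if categorical:
        counts = obs.value_counts()
        if levels is None:
            levels = list(counts.index)
        present = [lv for lv in levels if lv in counts.index]
        if not present:
            raise ValueError(f"predictor {variable!r} has no observed values")
        # keep declared-but-unobserved levels: their dummy columns are zero
        # at fit time (handled by the penalized / pinv fits) and valid at
        # synthesis time, when such levels can occur
        ref = max(present, key=lambda lv: counts[lv])
        ordered = [ref] + [lv for lv in levels if lv != ref]
        return Term(
            variable,
            "onehot",
            levels=ordered,
            missing_indicator=missing_indicator,
        )
    if len(obs) == 0:
        raise ValueError(f"predictor {variable!r} has no observed values")
    center = float(obs.mean())
    if spline_df is not None:
        _, knots = build_spline_basis(obs.to_numpy(float), spline_df)
        return Term(
            variable,
            "spline",
            knots=list(knots),
            center=center,
            missing_indicator=missing_indicator,
        )
    return Term(
        variable, "linear", center=center, missing_indicator=missing_indicator
    )


def encode(design: DesignSpec, data: pd.DataFrame) -> np.ndarray:
    """Encode rows into a numeric design matrix (intercept column first).

    Raises on NaN in a column without a missing indicator and on category
    levels unseen at fit time.
    """
    n = len(data)
    blocks = [np.ones((n, 1))]
    for t in design.terms:
        col = data[t.variable]
        miss = col.isna().to_numpy()
        if miss.any() and not t.missing_indicator:
            raise ValueError(
                f"missing values in {t.variable!r} but no missing-indicator "
                "encoding was declared"
            )
        if t.is_categorical:
            filled = col.where(~col.isna(), t.levels[0])
            unseen = set(filled.dropna().unique()) - set(t.levels)
            if unseen:
                raise ValueError(
                    f"unseen level(s) {sorted(map(str, unseen))} in "
                    f"{t.variable!r} (fit-time levels: {t.levels})"
                )
            codes = pd.Categorical(filled, categories=t.levels).codes
            dummies = np.zeros((n, len(t.levels) - 1))
            nonref = codes > 0
            dummies[np.arange(n)[nonref], codes[nonref] - 1] = 1.0
            blocks.append(dummies)
        else:
            x = col.to_numpy(dtype=float)
            x = np.where(miss, t.center, x)  # fill at centre => centred 0
            if t.kind == "spline":
                basis, _ = build_spline_basis(
                    x, len(t.knots) - 1, np.asarray(t.knots)
                )
                basis = basis - np.concatenate(
                    [[t.center], np.zeros(basis.shape[1] - 1)]
                )
                blocks.append(basis)
            else:
                blocks.append((x - t.center)[:, None])
        if t.missing_indicator:
            blocks.append(miss.astype(float)[:, None])
    X = np.concatenate(blocks, axis=1)
    assert X.shape[0] == n
    return X


def split_strata(data: pd.DataFrame, stratify_by: list) -> dict:
    """Partition row positions by the values of the stratification columns.

    Returns ``{stratum_key_tuple: integer position array}``; the empty
    stratification yields a single stratum keyed ``()``.
    """
    if not stratify_by:
        return {(): np.arange(len(data))}
    for c in stratify_by:
        if data[c].isna().any():
            raise ValueError(f"missing values in stratification column {c!r}")
    groups = data.groupby(stratify_by, observed=True, sort=True).indices
    out = {}
    for key, idx in groups.items():
        if not isinstance(key, tuple):
            key = (key,)
        out[key] = np.asarray(idx)
    return out
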