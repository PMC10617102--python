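"""Model / Results interface over the synthesis pipeline.

:class:`SequentialSynthesizer` is built from an individual-level DataFrame
plus a synthesis plan; ``fit()`` runs the secure-zone step (seed-strata
extraction, sequential per-stratum regressions, imputation + pooling where
survey nonresponse is present) and returns a :class:`SynthesisResults`
carrying the disclosure-safe model bundle.  Synthetic populations, summaries
and bundle persistence hang off the results object.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import (
    MIN_CELL_DEFAULT,
    ModelBundle,
    fit_sequence,
    read_bundle,
    write_bundle,
)
from .plan import SynthesisPlan, validate_plan
from .synth import SyntheticPopulation, implied_vs_realized, synthesize_population


class SequentialSynthesizer:
    """Sequential conditional regression synthesizer.

    Parameters
    ----------
    data : DataFrame
        The confidential individual-level table, one row per person.
    plan : SynthesisPlan
        Seed variables, ordered outcome sequence, per-variable model specs.
    survey_flag : str
        0/1 column marking survey membership (rows carrying the
        survey-scope variables).
    min_cell, min_cell_policy
        Minimum seed-stratum size gate and what to do below it
        (``waive`` keeps the stratum flagged, ``drop`` removes it).
    m_imputations, mice_iterations
        Multiple-imputation settings for survey-scope outcomes with item
        nonresponse.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        plan: SynthesisPlan,
        survey_flag: str = "survey",
        min_cell: int = MIN_CELL_DEFAULT,
        min_cell_policy: str = "waive",
        m_imputations: int = 5,
        mice_iterations: int = 10,
    ):
        violations = validate_plan(plan)
        if violations:
            raise ValueError("invalid plan:\n  " + "\n  ".join(violations))
        self.data = data
        self.plan = plan
        self.survey_flag = survey_flag
        self.min_cell = min_cell
        self.min_cell_policy = min_cell_policy
        self.m_imputations = m_imputations
        self.mice_iterations = mice_iterations

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, plan: SynthesisPlan, **kw):
        return cls(data, plan, **kw)

    def fit(self, mice_seed: int = 0) -> "SynthesisResults":
        bundle = fit_sequence(
            self.data,
            self.plan,
            survey_flag=self.survey_flag,
            min_cell=self.min_cell,
            min_cell_policy=self.min_cell_policy,
            m_imputations=self.m_imputations,
            mice_iterations=self.mice_iterations,
            mice_seed=mice_seed,
        )
        return SynthesisResults(bundle, model=self)


class SynthesisResults:
    """Fitted chain of predictive equations plus the seed-strata counts."""

    def __init__(self, bundle: ModelBundle, model: Optional[SequentialSynthesizer] = None):
        self.bundle = bundle
        self.model = model

    # -- persistence --------------------------------------------------
    def save(self, path) -> None:
        write_bundle(self.bundle, path)

    @classmethod
    def load(cls, path) -> "SynthesisResults":
        return cls(read_bundle(path))

    # -- synthesis ----------------------------------------------------
    def synthesize(
        self,
        rng_seed: int = 0,
        n_replicates: int = 1,
        draw_parameters: bool = False,
        calibration_targets: Optional[dict] = None,
        **kw,
    ):
        """Draw synthetic population(s); returns one
        :class:`SyntheticPopulation` or a list when ``n_replicates > 1``."""
        pops = synthesize_population(
            self.bundle,
            rng_seed=rng_seed,
            n_replicates=n_replicates,
            draw_parameters=draw_parameters,
            calibration_targets=calibration_targets,
            **kw,
        )
        return pops[0] if n_replicates == 1 else pops

    def consistency_audit(self, synthetic) -> pd.DataFrame:
        if isinstance(synthetic, SyntheticPopulation):
            synthetic = synthetic.data
        return implied_vs_realized(self.bundle, synthetic)

    # -- reporting ----------------------------------------------------
    def summary(self) -> str:
        b = self.bundle
        lines = [
            "Sequential synthesis results",
            "=" * 60,
            f"seed variables : {', '.join(b.strata.seed_vars)}",
            f"seed strata    : {len(b.strata.table)} "
            f"(total n = {b.strata.total}, "
            f"{b.strata.n_waived} below min cell {b.strata.min_cell}, "
            f"policy = {b.strata.policy})",
            f"sequence       : {len(b.plan.sequence)} outcomes, "
            f"{len(b.models)} stratum models",
            "",
            f"{'#':>2} {'outcome':<16} {'family':<12} {'strata':>6} "
            f"{'params':>7} {'n_fit':>9} {'pooled':>7}",
            "-" * 64,
        ]
        for k, ms in enumerate(b.plan.sequence, 1):
            models = [m for m in b.models if m.outcome == ms.outcome]
            n_par = max(
                (np.asarray(m.coef).size for m in models if not m.degenerate),
                default=0,
            )
            n_fit = sum(m.n_fit for m in models)
            pooled = next(
                (m.pooled_m for m in models if m.pooled_m), None
            )
            lines.append(
                f"{k:>2} {ms.outcome:<16} {ms.family:<12} "
                f"{len(models):>6} {n_par:>7} {n_fit:>9} "
                f"{str(pooled) if pooled else '-':>7}"
            )
        prov = b.provenance
        if prov:
            lines += ["", f"fitted {prov.get('fitted_at', '?')} "
                          f"by {prov.get('software', '?')}"]
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<SynthesisResults: {len(self.bundle.plan.sequence)} outcomes, "
            f"{len(self.bundle.models)} stratum models, "
            f"n={self.bundle.strata.total}>"
        )
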