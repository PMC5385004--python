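"""Glue between the cohort data model and the statistical modules.

Builds the per-patient analysis table that the selection pipeline consumes:
the two PK-engine predictions (PMMPV and, when requested, BEPV), the derived
renal covariates, the regimen summaries, and the lab values — partitioned
into the continuous covariates (fixed-effect candidates) and discrete
covariates (random-effect candidates).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .glmm import AnalysisDataset
from .pk import PopulationPKModel, bayes_estimate, pmm_predict
from .renal import renal_covariates

__all__ = ["patient_table", "build_dataset", "DISCRETE_COVARIATES"]

DISCRETE_COVARIATES = ("sex", "scr_adjusted", "aged_75", "age_group", "trough_day")


def patient_table(cohort: Cohort, pop: PopulationPKModel | None = None,
                  compute_bepv: bool = True, scr_floor: float = 0.6) -> pd.DataFrame:
    """One row per patient: predictions, renal covariates, labs, regimen."""
    pop = pop or PopulationPKModel()
    rows = []
    for r in cohort:
        cov = renal_covariates(r, at="planning", floor=scr_floor)
        pmm = pmm_predict(r, pop, scr_floor=scr_floor)
        dose, dur, tau = r.regimen.maintenance
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age": r.age,
            "height": r.height,
            "weight": r.weight,
            "scr": r.scr,
            "bun": r.bun,
            "alb": r.alb,
            "clcr": cov.clcr,
            "scr_adj": cov.scr_adjusted,
            "scr_adj_amt": cov.scr_adjusted_amount,
            "bun_scr": cov.bun_over_scr,
            "bun_adjscr": cov.bun_over_adjscr,
            "single_dose": dose,
            "daily_dose": r.regimen.daily_dose,
            "infusion_h": dur,
            "interval_h": tau,
            "pmmpv": pmm.pmmpv,
            "clcr_out_of_range": pmm.clcr_out_of_range,
            "scr_adjusted": "yes" if cov.scr_was_adjusted else "no",
            "aged_75": "yes" if r.age >= 75 else "no",
            "age_group": f"{int(r.age // 10) * 10}s",
            "trough_day": "" if r.trough_day is None else str(int(r.trough_day)),
            "measured_trough": r.measured_trough,
        }
        row.update(r.other_labs)
        if compute_bepv and r.measured_trough is not None:
            est = bayes_estimate(r, pop, scr_floor=scr_floor)
            row["bepv"] = est.bepv
            row["bepv_converged"] = est.converged
            row["clcr_at_trough"] = est.clcr
        rows.append(row)
    return pd.DataFrame(rows)


def build_dataset(table: pd.DataFrame,
                  extra_continuous: Sequence[str] = (),
                  response: str = "bepv") -> AnalysisDataset:
    """Wrap a patient table as an :class:`AnalysisDataset`.

    Continuous candidates are the demographic/renal/regimen columns plus any
    fully observed numeric lab columns; discrete candidates are
    ``DISCRETE_COVARIATES`` (those with at least two observed levels).
    """
    base = ["pmmpv", "age", "height", "weight", "scr", "bun", "clcr",
            "scr_adj_amt", "bun_scr", "bun_adjscr", "single_dose", "daily_dose"]
    labs = [c for c in ("alb", "ast", "alt", "crp", "ldh", "wbc", "na", "k", "tp", "hb")
            if c in table.columns]
    continuous = []
    for c in base + labs + list(extra_continuous):
        if c in table.columns and not table[c].isna().any() and c not in continuous:
            continuous.append(c)
    discrete = [c for c in DISCRETE_COVARIATES
                if c in table.columns and table[c].astype(str).nunique() >= 2]
    return AnalysisDataset(table=table, continuous=tuple(continuous),
                           discrete=tuple(discrete), response=response)
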