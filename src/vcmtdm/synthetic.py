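"""Synthetic elderly-inpatient cohorts for vancomycin TDM.

The reference dataset behind this pipeline is a small hospital cohort that
was never deposited, so this module generates cohorts with the same
*statistical structure*: marginal demographics and labs matching the
published cohort summary (age 77.37 ± 8.79 y, weight 46.66 ± 9.91 kg,
SCr 0.82 ± 0.35 mg/dL, BUN 19.15 ± 11.76 mg/dL, 14 F / 32 M, …), joined by
a Gaussian copula with documented default correlations, plus a *misfit
block* that injects the clinically documented failure mode of the
population-mean method: when BUN/SCr exceeds 20, Cockcroft-Gault
overestimates renal function, so the patient's TRUE vancomycin clearance is
lower than the population model believes —

    CL_true = CL_pop(CG CLcr) · (1 − γ·1[BUN/SCr > 20]) · m_sex
              · (1 − δ·SCr_adjust_amount) · e^η,   η ~ N(0, ω²).

The misfit enters through the true clearance, never through the observation,
so the Bayesian estimate (which sees the measured trough) partially corrects
it and a BUN/adjusted-SCr signal in the PMM prediction deviation emerges
mechanistically rather than being pasted in.

For regression-recovery studies an explicit linear truth is also provided:
the response is drawn directly from an Eq.-7-type predictor over the
mechanistically generated PMMPV and renal covariates.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, DoseRegimen, PatientRecord, write_cohort
from .pk import PKParameters, PopulationPKModel, concentration, steady_state_trough
from .renal import adjust_scr, cockcroft_gault

__all__ = [
    "Marginal",
    "SyntheticConfig",
    "SyntheticCohort",
    "LinearTruth",
    "generate_cohort",
    "linear_truth_response",
    "make_fixture",
]


@functools.lru_cache(maxsize=256)
def _moment_matched(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """(loc, scale) of the underlying normal such that the truncated
    distribution has the requested mean and sd (truncation shifts both)."""

    def eqs(p):
        loc, log_scale = p
        scale = math.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v_ = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(float(v_)) - sd]

    sol = optimize.root(eqs, [mean, math.log(sd)], method="hybr")
    if not sol.success:
        return mean, sd  # bounds too tight to match exactly; use raw parameters
    return float(sol.x[0]), float(math.exp(sol.x[1]))


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal for one continuous characteristic.

    ``mean``/``sd`` are the *target* moments of the truncated distribution;
    the underlying normal is moment-matched so truncation does not bias them.
    """

    mean: float
    sd: float
    lo: float
    hi: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        loc, scale = _moment_matched(self.mean, self.sd, self.lo, self.hi)
        a = (self.lo - loc) / scale
        b = (self.hi - loc) / scale
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


#: Cohort-summary marginals (mean, sd) with physiologic truncation bounds.
_DEFAULT_MARGINALS: dict[str, Marginal] = {
    "age": Marginal(77.37, 8.79, 40.0, 100.0),
    "height": Marginal(157.66, 8.59, 130.0, 190.0),
    "weight": Marginal(46.66, 9.91, 26.0, 95.0),
    "scr": Marginal(0.82, 0.35, 0.25, 3.5),
    "bun": Marginal(19.15, 11.76, 3.0, 90.0),
    "ast": Marginal(34.70, 24.64, 5.0, 250.0),
    "alt": Marginal(30.46, 36.94, 3.0, 300.0),
    "crp": Marginal(8.98, 7.32, 0.02, 40.0),
    "alb": Marginal(3.0, 0.6, 1.4, 5.2),
    # decoy labs with plausible elderly-inpatient marginals
    "ldh": Marginal(230.0, 80.0, 80.0, 700.0),
    "wbc": Marginal(9.5, 3.8, 1.5, 30.0),
    "na": Marginal(138.0, 4.0, 120.0, 155.0),
    "k": Marginal(4.1, 0.5, 2.5, 6.5),
    "tp": Marginal(6.2, 0.9, 3.5, 9.0),
    "hb": Marginal(11.0, 2.0, 5.0, 17.0),
}

#: Gaussian-copula correlations between characteristics (symmetric pairs).
_DEFAULT_COPULA: dict[tuple[str, str], float] = {
    ("height", "weight"): 0.6,
    ("bun", "scr"): 0.55,
    ("ast", "alt"): 0.7,
    ("age", "weight"): -0.2,
    ("tp", "alb"): 0.6,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 46
    seed: int = 0
    marginals: Mapping[str, Marginal] = field(default_factory=lambda: dict(_DEFAULT_MARGINALS))
    copula: Mapping[tuple[str, str], float] = field(default_factory=lambda: dict(_DEFAULT_COPULA))
    female_prop: float = 14.0 / 46.0
    # regimen menu: candidate doses (mg) and intervals (h); 1 h infusions
    dose_menu: tuple[float, ...] = (250.0, 500.0, 750.0, 1000.0)
    interval_menu: tuple[float, ...] = (12.0, 24.0, 48.0)
    infusion_h: float = 1.0
    target_trough: float = 15.0        # μg/mL, midpoint of the therapeutic window
    # truth block
    omega_cl: float = 0.20             # log-scale SD of true individual clearance
    omega_v1: float = 0.15
    sigma_add: float = 1.0             # μg/mL additive assay/residual SD
    sigma_prop: float = 0.10           # proportional residual CV
    # misfit block (the renal-overestimation mechanism)
    gamma: float = 0.3                 # clearance deficit when BUN/SCr > cutoff
    bun_scr_cutoff: float = 20.0
    sex_cl_mult: Mapping[str, float] = field(default_factory=lambda: {
        "female": 1.05, "male": 0.95})
    scr_adj_cl_effect: float = 0.5     # per mg/dL of SCr adjustment amount
    scr_floor: float = 0.6

    def __post_init__(self):
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        for name, m in self.marginals.items():
            if m.sd < 0:
                raise ValueError(f"negative sd for marginal {name!r}")
            if m.lo >= m.hi:
                raise ValueError(f"infeasible truncation bounds for {name!r}")
        if self.marginals["scr"].lo <= 0.2:
            raise ValueError("scr truncation must keep scr > 0.2")
        if self.marginals["weight"].lo <= 25:
            raise ValueError("weight truncation must keep weight > 25")


@dataclass(frozen=True)
class SyntheticCohort:
    cohort: Cohort
    truth: pd.DataFrame  # patient_id, true_cl, eta_cl, true_trough (hidden from the cohort file)


def _copula_matrix(names: Sequence[str], pairs: Mapping[tuple[str, str], float]) -> np.ndarray:
    k = len(names)
    r = np.eye(k)
    index = {n: i for i, n in enumerate(names)}
    for (a, b), rho in pairs.items():
        if a in index and b in index:
            r[index[a], index[b]] = r[index[b], index[a]] = rho
    # nudge to the nearest positive-definite matrix if the pairs conflict
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-8:
        w = np.clip(w, 1e-8, None)
        r = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def _choose_regimen(pop: PopulationPKModel, clcr: float, weight: float,
                    cfg: SyntheticConfig) -> tuple[float, float]:
    """Initial dose plan: the menu entry whose population-predicted trough is
    closest to the therapeutic-window midpoint (this mirrors how the initial
    plan is made in practice, and is exactly why PMM misfit matters)."""
    params = pop.params_for(clcr, weight)
    best, best_err = None, math.inf
    for tau in cfg.interval_menu:
        for dose in cfg.dose_menu:
            tr = steady_state_trough(params, (dose, cfg.infusion_h, tau))
            err = abs(tr - cfg.target_trough)
            if err < best_err:
                best, best_err = (dose, tau), err
    return best


def generate_cohort(config: SyntheticConfig,
                    pop: PopulationPKModel | None = None) -> SyntheticCohort:
    """Generate a cohort plus its hidden truth table.

    ``pop`` is the population model the *planner* uses (and the basis of the
    truth: individual parameters are the population relations at the CG CLcr,
    distorted by the misfit block and log-normal variability).  Same config
    (incl. seed) ⇒ bit-identical output.
    """
    pop = pop or PopulationPKModel()
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0x5EED]))
    n = cfg.n_patients
    names = list(cfg.marginals)
    corr = _copula_matrix(names, cfg.copula)
    z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n,
                                method="cholesky")
    u = stats.norm.cdf(z)
    draws = {name: cfg.marginals[name].ppf(u[:, j]) for j, name in enumerate(names)}
    sexes = np.where(rng.random(n) < cfg.female_prop, "female", "male")

    records, truth_rows = [], []
    for i in range(n):
        sex = str(sexes[i])
        age, height, weight = draws["age"][i], draws["height"][i], draws["weight"][i]
        scr, bun = draws["scr"][i], draws["bun"][i]
        adj = adjust_scr(scr, floor=cfg.scr_floor)
        clcr = cockcroft_gault(sex, age, weight, adj.scr_adjusted)

        dose, tau = _choose_regimen(pop, clcr, weight, cfg)
        trough_day = int(rng.integers(3, 6))
        n_doses = int((trough_day * 24.0) // tau) + 1
        regimen = DoseRegimen.regular(dose, cfg.infusion_h, tau, n_doses)

        pop_params = pop.params_for(clcr, weight)
        misfit = 1.0
        if bun / scr > cfg.bun_scr_cutoff:
            misfit *= (1.0 - cfg.gamma)
        misfit *= cfg.sex_cl_mult[sex]
        misfit *= max(1.0 - cfg.scr_adj_cl_effect * adj.scr_adjusted_amount, 0.05)
        eta_cl = rng.normal(0.0, cfg.omega_cl)
        eta_v1 = rng.normal(0.0, cfg.omega_v1)
        true_params = PKParameters(
            cl=pop_params.cl * misfit * math.exp(eta_cl),
            v1=pop_params.v1 * math.exp(eta_v1),
            q=pop_params.q, v2=pop_params.v2)

        t_obs = tau * math.floor(trough_day * 24.0 / tau)
        history = DoseRegimen.regular(dose, cfg.infusion_h, tau,
                                      max(int(t_obs // tau), 1))
        c_true = concentration(true_params, history, t_obs)
        sd = math.sqrt(cfg.sigma_add ** 2 + (cfg.sigma_prop * c_true) ** 2)
        measured = max(c_true + rng.normal(0.0, sd), 0.05)

        labs = {lab: round(float(draws[lab][i]), 2)
                for lab in ("ast", "alt", "crp", "ldh", "wbc", "na", "k", "tp", "hb")}
        records.append(PatientRecord(
            patient_id=f"S{i + 1:04d}", sex=sex,
            age=round(float(age), 1), height=round(float(height), 1),
            weight=round(float(weight), 1),
            scr=round(float(scr), 2), bun=round(float(bun), 1),
            alb=round(float(draws["alb"][i]), 1),
            regimen=regimen, other_labs=labs,
            measured_trough=round(float(measured), 2),
            trough_day=float(trough_day),
            scr_at_trough=round(float(scr), 2),
        ))
        truth_rows.append({
            "patient_id": f"S{i + 1:04d}",
            "true_cl": true_params.cl, "eta_cl": eta_cl, "eta_v1": eta_v1,
            "misfit_mult": misfit,
            "true_trough": steady_state_trough(true_params, regimen.maintenance),
        })
    return SyntheticCohort(
        cohort=Cohort(records=tuple(records), provenance=f"synthetic seed={cfg.seed}"),
        truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Explicit linear truth for regression-recovery studies


@dataclass(frozen=True)
class LinearTruth:
    """Response generated directly from a best-model-shaped linear predictor.

    ``bepv = (β1 + dev_sex)·pmmpv + β_bun·bun_adjscr + β_adj·scr_adj_amt + ε``
    with ε ~ N(0, resid_sd²).
    """

    beta_pmmpv: float = 1.0
    sex_dev: Mapping[str, float] = field(default_factory=lambda: {
        "male": 0.05, "female": -0.05})
    beta_bun_adjscr: float = 0.10
    beta_scr_adj_amt: float = -12.0
    resid_sd: float = 2.0


def linear_truth_response(table: pd.DataFrame, truth: LinearTruth,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw the response for each row of an analysis table from the linear truth."""
    beta1 = truth.beta_pmmpv + np.array([truth.sex_dev[s] for s in table["sex"]])
    mu = (beta1 * table["pmmpv"].to_numpy(float)
          + truth.beta_bun_adjscr * table["bun_adjscr"].to_numpy(float)
          + truth.beta_scr_adj_amt * table["scr_adj_amt"].to_numpy(float))
    return mu + rng.normal(0.0, truth.resid_sd, size=len(table))


# ---------------------------------------------------------------------------
# Canonical fixtures


_FIXTURE_SCALES = {"tiny": (8, 101), "paper": (46, 102), "large": (500, 103)}


def make_fixture(scale: str, out_dir: str | Path,
                 pop: PopulationPKModel | None = None) -> dict[str, Path]:
    """Write a canonical fixture cohort (cohort.csv + truth.csv + manifest).

    Scales: tiny (n=8) for unit tests, paper (n=46) matching the study size,
    large (n=500) for recovery studies.  Fixed seeds per scale, so repeated
    calls produce identical bytes.
    """
    if scale not in _FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(_FIXTURE_SCALES)}")
    n, seed = _FIXTURE_SCALES[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = generate_cohort(SyntheticConfig(n_patients=n, seed=seed), pop=pop)
    cohort_path = out / f"cohort_{scale}.csv"
    truth_path = out / f"truth_{scale}.csv"
    write_cohort(syn.cohort, cohort_path)
    syn.truth.to_csv(truth_path, index=False)
    manifest = out / f"manifest_{scale}.json"
    manifest.write_text(json.dumps({
        "scale": scale, "n_patients": n, "seed": seed,
        "files": [cohort_path.name, truth_path.name],
        "note": "synthetic cohort; truth table is hidden ground truth, "
                "never part of the public cohort file",
    }, indent=2))
    return {"cohort": cohort_path, "truth": truth_path, "manifest": manifest}
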