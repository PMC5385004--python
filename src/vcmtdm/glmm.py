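"""Mixed-model correction of population-mean trough predictions.

The response is the Bayesian-estimate predicted trough (BEPV); the basic
model is a no-intercept regression on the population-mean prediction,
``BEPV = β1·PMMPV``.  Candidate medical-data covariates enter as further
fixed effects, and a discrete variable (e.g. sex) can place grouped
deviations on any subset of the fixed-effect coefficients:

    y_i ~ Normal( Σ_k (β_k + u_{k, g(i)}) · x_ik , σ² ),
    u_{k,g} ~ Normal(0, τ_k²)   for coefficients k in the random-effect set.

Selection is staged, driven throughout by WAIC (deviance scale, lower is
better):

1. screen continuous covariates by Spearman correlation with the PMM
   prediction deviation PMMPDQ = BEPV − PMMPV (|ρ| ≥ 0.2 → candidate 1);
2. add each candidate singly to the basic model, keep those that lower WAIC
   and resolve declared/automatic near-duplicates (→ candidate 2);
3. search all non-empty candidate-2 subsets for the lowest-WAIC fixed model;
4. screen discrete variables by one-way ICC of PMMPDQ, keep the argmax;
5. try grouped deviations on every subset of fixed-effect coefficients and
   keep the overall WAIC minimiser (which may be the fixed model itself).

Posterior computation uses a blocked Gibbs sampler: coefficients are drawn
jointly from their conditional multivariate normal, and the half-Student-t(3)
priors on the residual and random-effect SDs are handled by the Huang–Wand
inverse-gamma mixture, which keeps every conditional conjugate.  Convergence
is judged by split-R̂ ≤ 1.1 on every sampled parameter; a non-converged fit
is refit once with doubled draws and otherwise excluded from selection.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "AnalysisDataset",
    "RandomEffect",
    "ModelSpec",
    "McmcSettings",
    "FitResult",
    "SelectionReport",
    "spearman_rho",
    "screen_fixed_candidate1",
    "fit_bayesian_lm",
    "waic",
    "select_fixed_candidate2",
    "search_fixed_model",
    "icc_oneway",
    "screen_random_candidate",
    "search_random_placement",
    "predict_glmmpv",
    "linear_predict",
    "run_selection",
]

RHAT_LIMIT = 1.1          # convergence rule for every selection-relevant fit
_HALF_T_NU = 3            # half-Student-t(3) priors on SDs


# ---------------------------------------------------------------------------
# Data containers


@dataclass(frozen=True)
class AnalysisDataset:
    """Per-patient analysis table: response, PMMPV and candidate covariates."""

    table: pd.DataFrame
    continuous: tuple[str, ...]
    discrete: tuple[str, ...]
    response: str = "bepv"

    def __post_init__(self):
        overlap = set(self.continuous) & set(self.discrete)
        if overlap:
            raise ValueError(f"covariates listed as both continuous and discrete: {sorted(overlap)}")
        for col in (self.response, "pmmpv", *self.continuous, *self.discrete):
            if col not in self.table.columns:
                raise ValueError(f"column {col!r} missing from analysis table")
        if self.table[self.response].isna().any():
            raise ValueError("missing values in the response column")

    @property
    def n(self) -> int:
        return len(self.table)

    def pmmpdq(self) -> np.ndarray:
        """PMM prediction deviation quantity, BEPV − PMMPV, per patient."""
        return (self.table[self.response] - self.table["pmmpv"]).to_numpy(float)


@dataclass(frozen=True)
class RandomEffect:
    grouping: str                 # discrete variable supplying group levels
    targets: tuple[str, ...]      # fixed-effect coefficients receiving deviations


@dataclass(frozen=True)
class ModelSpec:
    """One candidate trough-correction model."""

    fixed_effects: tuple[str, ...]        # always beginning with "pmmpv"
    random_effect: RandomEffect | None = None
    intercept: bool = False

    def __post_init__(self):
        if not self.fixed_effects or self.fixed_effects[0] != "pmmpv":
            raise ValueError("fixed_effects must begin with 'pmmpv'")
        if self.random_effect is not None:
            extra = set(self.random_effect.targets) - set(self.fixed_effects)
            if extra:
                raise ValueError(f"random-effect targets not among fixed effects: {sorted(extra)}")

    def label(self) -> str:
        s = " + ".join(self.fixed_effects)
        if self.random_effect:
            s += f" | {self.random_effect.grouping} on ({', '.join(self.random_effect.targets)})"
        return s


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings; draws are per chain, post-warmup, post-thinning.

    When the spec has a random effect, draws and warmup are doubled
    (mirroring the source software's doubling of iterations for mixed
    models) unless ``double_with_random`` is off.
    """

    chains: int = 3
    draws: int = 3000
    warmup: int = 1000
    thin: int = 1
    double_with_random: bool = True

    def resolved(self, has_random: bool) -> "McmcSettings":
        if has_random and self.double_with_random:
            return replace(self, draws=self.draws * 2, warmup=self.warmup * 2,
                           double_with_random=False)
        return self


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    coef_names: tuple[str, ...]              # fixed then group-deviation names
    draws: Mapping[str, np.ndarray]          # name -> (chains, draws) array
    loglik: np.ndarray                       # (total draws, n) pointwise log-likelihood
    waic: float                              # deviance scale
    p_waic: float
    rhat: Mapping[str, float]
    summary: pd.DataFrame                    # mean, sd, 2.5%, 97.5% per parameter
    group_levels: tuple[str, ...] = ()
    converged: bool = True

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def fixed_coefficients(self) -> dict[str, float]:
        return {k: self.posterior_mean(f"beta[{k}]") for k in self.spec.fixed_effects}

    def group_deviations(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        if self.spec.random_effect is None:
            return out
        for k in self.spec.random_effect.targets:
            out[k] = {g: self.posterior_mean(f"u[{k},{g}]") for g in self.group_levels}
        return out


# ---------------------------------------------------------------------------
# Elementary statistics


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation and its p-value (t approximation).

    Returns ``(nan, nan)`` when either vector has zero variance (undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def icc_oneway(values: Sequence[float], groups: Sequence,
               alpha: float = 0.05) -> tuple[float, float, float]:
    """One-way random-effects ANOVA intraclass correlation with a CI.

    ``icc = (MSB − MSW) / (MSB + (k̄ − 1)·MSW)`` where k̄ is the
    unbalanced-adjusted mean group size ``(N − Σn_i²/N)/(k − 1)``.  Negative
    estimates are legitimate (no clustering).  The confidence interval comes
    from the F distribution (Searle): with F = MSB/MSW,
    FL = F / F_{1−α/2}(k−1, N−k) and FU = F · F_{1−α/2}(N−k, k−1) transformed
    through the same functional form.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels, idx = np.unique(groups, return_inverse=True)
    k = len(levels)
    n_tot = len(values)
    if k < 2:
        raise ValueError("ICC is undefined for a single group")
    if n_tot < 3 or n_tot - k < 1:
        raise ValueError("too few observations for the one-way ANOVA estimator")
    sizes = np.bincount(idx).astype(float)
    grand = values.mean()
    gmeans = np.array([values[idx == i].mean() for i in range(k)])
    ssb = float(np.sum(sizes * (gmeans - grand) ** 2))
    ssw = float(np.sum((values - gmeans[idx]) ** 2))
    df1, df2 = k - 1, n_tot - k
    msb, msw = ssb / df1, ssw / df2
    kbar = (n_tot - np.sum(sizes ** 2) / n_tot) / df1
    if msw == 0:
        return (1.0, 1.0, 1.0)
    icc = (msb - msw) / (msb + (kbar - 1) * msw)
    f = msb / msw
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    lower = (fl - 1) / (fl + kbar - 1)
    upper = (fu - 1) / (fu + kbar - 1)
    return (float(icc), float(lower), float(upper))


def waic(loglik: np.ndarray) -> tuple[float, float]:
    """Widely applicable information criterion on the deviance scale.

    ``loglik`` is the (draws × patients) pointwise log-likelihood matrix.
    lppd_i = log mean_s exp(ll_si); p_waic_i = var_s(ll_si);
    WAIC = −2·Σ_i (lppd_i − p_waic_i).  Lower means smaller expected
    generalization error.
    """
    ll = np.asarray(loglik, float)
    if ll.ndim != 2:
        raise ValueError("loglik must be a (draws, observations) matrix")
    s = ll.shape[0]
    if s < 100:
        warnings.warn(f"WAIC from only {s} draws is noisy", stacklevel=2)
    lppd = logsumexp(ll, axis=0) - math.log(s)
    # population variance (ddof=0): the reference-implementation convention,
    # and exactly invariant under draw duplication
    p_i = ll.var(axis=0, ddof=0)
    return float(-2.0 * np.sum(lppd - p_i)), float(np.sum(p_i))


# ---------------------------------------------------------------------------
# Gibbs sampler for the Bayesian (mixed) linear model


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ for one scalar parameter from a (chains, draws) array."""
    c, d = chains.shape
    half = d // 2
    if half < 2:
        return math.nan
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    w = variances.mean()
    b = n * means.var(ddof=1)
    if w <= 1e-300:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(math.sqrt(var_hat / w))


def fit_bayesian_lm(spec: ModelSpec, dataset: AnalysisDataset,
                    mcmc: McmcSettings | None = None,
                    seed: int = 0) -> FitResult:
    """Fit one candidate model by blocked Gibbs sampling.

    Fixed coefficients get weakly-informative Normal(0, (10·sd(y)/sd(x))²)
    priors; the residual SD and each random-effect SD get half-Student-t(3)
    priors via the Huang–Wand inverse-gamma mixture.  The pointwise
    log-likelihood matrix needed for WAIC is stored with the draws, and
    split-R̂ is recorded for every sampled parameter.
    """
    mcmc = (mcmc or McmcSettings()).resolved(spec.random_effect is not None)
    df = dataset.table
    y = df[dataset.response].to_numpy(float)
    n = len(y)
    fixed = list(spec.fixed_effects)
    cols = [df[k].to_numpy(float) for k in fixed]
    names = [f"beta[{k}]" for k in fixed]
    if spec.intercept:
        cols.append(np.ones(n))
        names.append("beta[intercept]")
    X = np.column_stack(cols)
    k_fix = X.shape[1]

    sd_y = float(np.std(y)) or 1.0
    prior_sd = np.empty(k_fix)
    for j in range(k_fix):
        sd_x = float(np.std(X[:, j])) or 1.0
        prior_sd[j] = 10.0 * sd_y / sd_x

    group_levels: tuple[str, ...] = ()
    re_targets: list[int] = []
    if spec.random_effect is not None:
        g_raw = df[spec.random_effect.grouping].astype(str).to_numpy()
        levels = tuple(sorted(set(g_raw)))
        if len(levels) < 2:
            raise ValueError(f"grouping {spec.random_effect.grouping!r} has fewer than 2 levels")
        g_idx = np.array([levels.index(v) for v in g_raw])
        group_levels = levels
        z_cols, z_names = [], []
        for k in spec.random_effect.targets:
            j = fixed.index(k)
            re_targets.append(j)
            for gi, lev in enumerate(levels):
                z_cols.append(np.where(g_idx == gi, X[:, j], 0.0))
                z_names.append(f"u[{k},{lev}]")
        W = np.column_stack([X] + z_cols)
        names += z_names
    else:
        W = X
    k_tot = W.shape[1]
    n_re = len(re_targets)
    n_g = len(group_levels)

    WtW = W.T @ W
    Wty = W.T @ y
    nu = _HALF_T_NU
    a_sigma_scale = sd_y       # half-t scale for the residual SD
    a_tau_scale = 1.0          # half-t scale for coefficient-level deviations

    total_kept = mcmc.chains * mcmc.draws
    theta_store = np.empty((mcmc.chains, mcmc.draws, k_tot))
    sigma_store = np.empty((mcmc.chains, mcmc.draws))
    tau_store = np.empty((mcmc.chains, mcmc.draws, n_re)) if n_re else None

    spec_tag = zlib.crc32(spec.label().encode())  # stable across processes
    master = np.random.SeedSequence([seed & 0x7FFFFFFF, spec_tag & 0x7FFFFFFF])
    for ci, child in enumerate(master.spawn(mcmc.chains)):
        rng = np.random.default_rng(child)
        sigma2 = sd_y ** 2 * rng.uniform(0.5, 2.0)
        a_sig = 1.0
        tau2 = np.full(n_re, 0.1) if n_re else np.empty(0)
        a_tau = np.ones(n_re)
        kept = 0
        it = 0
        while kept < mcmc.draws:
            # coefficients | variances: joint multivariate normal
            prior_prec = np.empty(k_tot)
            prior_prec[:k_fix] = 1.0 / prior_sd ** 2
            pos = k_fix
            for r in range(n_re):
                prior_prec[pos:pos + n_g] = 1.0 / tau2[r]
                pos += n_g
            prec = WtW / sigma2 + np.diag(prior_prec)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Wty / sigma2)
            z = rng.standard_normal(k_tot)
            theta = mean + np.linalg.solve(chol.T, z)
            resid = y - W @ theta
            rss = float(resid @ resid)
            # residual variance (Huang–Wand mixture); floored so that exactly
            # collinear/noiseless data cannot drive sigma^2 to underflow
            sigma2 = 1.0 / rng.gamma((nu + n) / 2.0, 1.0 / (nu / a_sig + rss / 2.0))
            sigma2 = max(sigma2, 1e-12)
            a_sig = 1.0 / rng.gamma((nu + 1) / 2.0,
                                    1.0 / (nu / sigma2 + 1.0 / a_sigma_scale ** 2))
            # random-effect variances
            pos = k_fix
            for r in range(n_re):
                u = theta[pos:pos + n_g]
                tau2[r] = 1.0 / rng.gamma((nu + n_g) / 2.0,
                                          1.0 / (nu / a_tau[r] + float(u @ u) / 2.0))
                a_tau[r] = 1.0 / rng.gamma((nu + 1) / 2.0,
                                           1.0 / (nu / tau2[r] + 1.0 / a_tau_scale ** 2))
                pos += n_g
            it += 1
            if it > mcmc.warmup and (it - mcmc.warmup) % mcmc.thin == 0:
                theta_store[ci, kept] = theta
                sigma_store[ci, kept] = math.sqrt(sigma2)
                if n_re:
                    tau_store[ci, kept] = np.sqrt(tau2)
                kept += 1

    theta_flat = theta_store.reshape(total_kept, k_tot)
    sigma_flat = sigma_store.reshape(total_kept)
    mu = theta_flat @ W.T                                    # (draws, n)
    loglik = (-0.5 * ((y[None, :] - mu) / sigma_flat[:, None]) ** 2
              - np.log(sigma_flat)[:, None] - 0.5 * math.log(2 * math.pi))

    draws: dict[str, np.ndarray] = {names[j]: theta_store[:, :, j] for j in range(k_tot)}
    draws["sigma"] = sigma_store
    for r, j in enumerate(re_targets):
        draws[f"tau[{fixed[j]}]"] = tau_store[:, :, r]
    rhat = {name: _split_rhat(arr) for name, arr in draws.items()}
    converged = all((not math.isfinite(v)) or v <= RHAT_LIMIT for v in rhat.values()) and \
        all(math.isfinite(v) for v in rhat.values())

    rows = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        rows.append({"parameter": name, "mean": float(flat.mean()),
                     "sd": float(flat.std(ddof=1)),
                     "l95": float(np.percentile(flat, 2.5)),
                     "u95": float(np.percentile(flat, 97.5)),
                     "rhat": rhat[name]})
    summary = pd.DataFrame(rows).set_index("parameter")
    w, p = waic(loglik)
    return FitResult(spec=spec, coef_names=tuple(names), draws=draws, loglik=loglik,
                     waic=w, p_waic=p, rhat=rhat, summary=summary,
                     group_levels=group_levels, converged=converged)


def _fit_with_retry(spec: ModelSpec, dataset: AnalysisDataset, mcmc: McmcSettings,
                    seed: int, log: list[str]) -> FitResult | None:
    """Fit; on R̂ failure refit once with doubled draws; else drop the spec."""
    fit = fit_bayesian_lm(spec, dataset, mcmc, seed=seed)
    if fit.converged:
        return fit
    log.append(f"refit (doubled draws) after R-hat > {RHAT_LIMIT}: {spec.label()}")
    bigger = replace(mcmc, draws=mcmc.draws * 2, warmup=mcmc.warmup * 2)
    fit = fit_bayesian_lm(spec, dataset, bigger, seed=seed + 7919)
    if fit.converged:
        return fit
    log.append(f"excluded after repeated non-convergence: {spec.label()}")
    return None


# ---------------------------------------------------------------------------
# Staged selection


def screen_fixed_candidate1(dataset: AnalysisDataset, pmmpdq: np.ndarray | None = None,
                            threshold: float = 0.2) -> pd.DataFrame:
    """Stage-2 screen: Spearman correlation of each continuous covariate
    with PMMPDQ; |ρ| ≥ ``threshold`` marks a fixed-effect candidate 1.

    Returns the full correlation table (name, rho, p, kept) sorted by |ρ|
    descending; zero-variance covariates get NaN and are never kept.
    """
    if pmmpdq is None:
        pmmpdq = dataset.pmmpdq()
    rows = []
    for name in dataset.continuous:
        if name == "pmmpv":
            continue
        rho, p = spearman_rho(dataset.table[name].to_numpy(float), pmmpdq)
        kept = bool(np.isfinite(rho) and abs(rho) >= threshold)
        rows.append({"covariate": name, "rho": rho, "p_value": p, "kept": kept})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.reindex(out["rho"].abs().sort_values(ascending=False, na_position="last").index)
    return out.reset_index(drop=True)


def select_fixed_candidate2(dataset: AnalysisDataset, candidate1: Sequence[str],
                            basic_fit: FitResult, mcmc: McmcSettings | None = None,
                            seed: int = 0,
                            duplicate_pairs: Sequence[tuple[str, str]] = (),
                            auto_duplicate_rho: float = 0.9,
                            log: list[str] | None = None,
                            ) -> tuple[list[str], pd.DataFrame]:
    """Stage-3: keep single additions that lower WAIC below the basic model,
    then resolve near-duplicate covariate pairs by keeping the lower-WAIC
    member.

    Near-duplicates are the declared ``duplicate_pairs`` plus any candidate
    pair whose Spearman |ρ| exceeds ``auto_duplicate_rho``.  Returns the kept
    list and the single-addition table (covariate, coefficient, 95% bounds,
    waic, kept).
    """
    mcmc = mcmc or McmcSettings()
    log = log if log is not None else []
    rows = [{"covariate": "(basic model)", "coefficient": basic_fit.posterior_mean("beta[pmmpv]"),
             "l95": float(basic_fit.summary.loc["beta[pmmpv]", "l95"]),
             "u95": float(basic_fit.summary.loc["beta[pmmpv]", "u95"]),
             "waic": basic_fit.waic, "kept": False}]
    waics: dict[str, float] = {}
    for i, name in enumerate(candidate1):
        spec = ModelSpec(fixed_effects=("pmmpv", name))
        fit = _fit_with_retry(spec, dataset, mcmc, seed + 1000 + i, log)
        if fit is None:
            continue
        waics[name] = fit.waic
        coef = f"beta[{name}]"
        rows.append({"covariate": name, "coefficient": fit.posterior_mean(coef),
                     "l95": float(fit.summary.loc[coef, "l95"]),
                     "u95": float(fit.summary.loc[coef, "u95"]),
                     "waic": fit.waic, "kept": fit.waic < basic_fit.waic})
    kept = [n for n in candidate1 if n in waics and waics[n] < basic_fit.waic]

    pairs = {frozenset(p) for p in duplicate_pairs}
    for a, b in combinations(list(kept), 2):
        rho, _ = spearman_rho(dataset.table[a].to_numpy(float),
                              dataset.table[b].to_numpy(float))
        if np.isfinite(rho) and abs(rho) > auto_duplicate_rho:
            pairs.add(frozenset((a, b)))
    for pair in pairs:
        members = [m for m in pair if m in kept]
        if len(members) == 2:
            drop = max(members, key=lambda m: waics[m])
            kept.remove(drop)
            log.append(f"near-duplicate pair {tuple(sorted(pair))}: kept lower-WAIC member, dropped {drop}")
    table = pd.DataFrame(rows)
    table.loc[table["covariate"].isin(kept), "kept"] = True
    table.loc[~table["covariate"].isin(kept), "kept"] = False
    return kept, table


def search_fixed_model(dataset: AnalysisDataset, candidate2: Sequence[str],
                       mcmc: McmcSettings | None = None, seed: int = 0,
                       max_subsets: int = 1024,
                       log: list[str] | None = None,
                       ) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Stage-4: exhaustive WAIC search over non-empty candidate-2 subsets.

    The basic model competes too.  Ties break toward fewer covariates, then
    lexicographic order.  Returns (best spec, its fit, subset table).
    """
    mcmc = mcmc or McmcSettings()
    log = log if log is not None else []
    candidate2 = list(candidate2)
    n_subsets = 2 ** len(candidate2)
    if n_subsets > max_subsets:
        raise ValueError(
            f"{len(candidate2)} candidates give {n_subsets} subsets (> {max_subsets}); "
            "tighten the screening threshold")
    subsets: list[tuple[str, ...]] = [()]
    for r in range(1, len(candidate2) + 1):
        subsets.extend(combinations(candidate2, r))
    rows, results = [], {}
    for i, sub in enumerate(subsets):
        spec = ModelSpec(fixed_effects=("pmmpv",) + sub)
        fit = _fit_with_retry(spec, dataset, mcmc, seed + 2000 + i, log)
        if fit is None:
            continue
        results[sub] = (spec, fit)
        rows.append({"covariates": " and ".join(sub) if sub else "(basic model)",
                     "n_covariates": len(sub), "waic": fit.waic})
    if not results:
        raise RuntimeError("no fixed-effect model converged")
    best_sub = min(results, key=lambda s: (results[s][1].waic, len(s), s))
    table = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    return results[best_sub][0], results[best_sub][1], table


def screen_random_candidate(dataset: AnalysisDataset, pmmpdq: np.ndarray | None = None,
                            ) -> tuple[str, pd.DataFrame]:
    """Stage-5: one-way ICC of PMMPDQ against each discrete covariate.

    Returns the argmax covariate (there is always one: the rule is a max,
    not a threshold) and the full ICC table with 95% bounds.
    """
    if not dataset.discrete:
        raise ValueError("no discrete covariates to screen")
    if pmmpdq is None:
        pmmpdq = dataset.pmmpdq()
    rows = []
    for name in dataset.discrete:
        try:
            icc, lo, hi = icc_oneway(pmmpdq, dataset.table[name].astype(str).to_numpy())
        except ValueError:
            icc, lo, hi = math.nan, math.nan, math.nan
        rows.append({"covariate": name, "icc": icc, "l95": lo, "u95": hi})
    table = pd.DataFrame(rows).sort_values("icc", ascending=False, na_position="last")
    table = table.reset_index(drop=True)
    finite = table.dropna(subset=["icc"])
    if finite.empty:
        raise ValueError("ICC undefined for every discrete covariate")
    return str(finite.iloc[0]["covariate"]), table


def search_random_placement(dataset: AnalysisDataset, fixed_spec: ModelSpec,
                            grouping: str, fixed_fit: FitResult | None = None,
                            mcmc: McmcSettings | None = None, seed: int = 0,
                            log: list[str] | None = None,
                            ) -> tuple[ModelSpec, FitResult, pd.DataFrame]:
    """Stage-6: place grouped deviations on every subset of fixed-effect
    coefficients (plus none) and keep the overall WAIC minimiser.
    """
    mcmc = mcmc or McmcSettings()
    log = log if log is not None else []
    if fixed_fit is None:
        fixed_fit = fit_bayesian_lm(fixed_spec, dataset, mcmc, seed=seed)
    coeffs = fixed_spec.fixed_effects
    rows = [{"random_effect_on": "(fixed effect model)", "waic": fixed_fit.waic}]
    results: dict[tuple[str, ...], tuple[ModelSpec, FitResult]] = {(): (fixed_spec, fixed_fit)}
    i = 0
    for r in range(1, len(coeffs) + 1):
        for sub in combinations(coeffs, r):
            spec = replace(fixed_spec, random_effect=RandomEffect(grouping, sub))
            fit = _fit_with_retry(spec, dataset, mcmc, seed + 3000 + i, log)
            i += 1
            if fit is None:
                continue
            results[sub] = (spec, fit)
            rows.append({"random_effect_on": " and ".join(sub), "waic": fit.waic})
    best = min(results, key=lambda s: (results[s][1].waic, len(s), s))
    table = pd.DataFrame(rows).sort_values("waic").reset_index(drop=True)
    return results[best][0], results[best][1], table


# ---------------------------------------------------------------------------
# Prediction


def linear_predict(row: Mapping[str, float], fixed: Mapping[str, float],
                   group_devs: Mapping[str, Mapping[str, float]] | None = None,
                   grouping: str | None = None) -> float:
    """Evaluate the (mixed) linear predictor for one patient row.

    ``fixed`` maps covariate → coefficient; ``group_devs`` maps covariate →
    {group level → deviation} and ``grouping`` names the column of ``row``
    holding the patient's level.  No intercept unless present in ``fixed``
    under the key ``"intercept"``.
    """
    total = 0.0
    for name, beta in fixed.items():
        x = 1.0 if name == "intercept" else float(row[name])
        coef = beta
        if group_devs and name in group_devs:
            level = str(row[grouping])
            coef = beta + group_devs[name].get(level, 0.0)
        total += coef * x
    return total


def predict_glmmpv(fit: FitResult, rows: pd.DataFrame) -> np.ndarray:
    """Predicted trough (GLMMPV, μg/mL) for each patient row, using the
    posterior-mean coefficients (fixed + group deviation) of the best model.
    """
    fixed = fit.fixed_coefficients()
    if fit.spec.intercept:
        fixed["intercept"] = fit.posterior_mean("beta[intercept]")
    devs = fit.group_deviations()
    grouping = fit.spec.random_effect.grouping if fit.spec.random_effect else None
    return np.array([linear_predict(row, fixed, devs or None, grouping)
                     for _, row in rows.iterrows()])


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SelectionReport:
    """Stage-by-stage artifacts of the selection pipeline plus the winner."""

    correlations: pd.DataFrame        # stage 2: Spearman screen
    single_additions: pd.DataFrame    # stage 3: one-at-a-time WAIC
    subsets: pd.DataFrame             # stage 4: fixed-effect subset search
    icc: pd.DataFrame                 # stage 5: ICC screen of discrete variables
    placements: pd.DataFrame          # stage 6: random-effect placement search
    best_spec: ModelSpec
    best_fit: FitResult
    basic_waic: float
    shapiro_p: float                  # normality gate on the response
    log: list[str] = field(default_factory=list)

    def best_model_table(self) -> pd.DataFrame:
        """Coefficient table of the best model (fixed effects and deviations)."""
        fit = self.best_fit
        rows = []
        for k in fit.spec.fixed_effects:
            name = f"beta[{k}]"
            rows.append({"explanatory_variable": f"{k} (fixed effect)",
                         "coefficient": fit.posterior_mean(name),
                         "l95": float(fit.summary.loc[name, "l95"]),
                         "u95": float(fit.summary.loc[name, "u95"])})
        for k, devs in fit.group_deviations().items():
            for level in fit.group_levels:
                name = f"u[{k},{level}]"
                rows.append({"explanatory_variable": f"{fit.spec.random_effect.grouping}: "
                                                     f"{level} (random effect on {k})",
                             "coefficient": devs[level],
                             "l95": float(fit.summary.loc[name, "l95"]),
                             "u95": float(fit.summary.loc[name, "u95"])})
        return pd.DataFrame(rows)


def run_selection(dataset: AnalysisDataset, mcmc: McmcSettings | None = None,
                  seed: int = 0, rho_threshold: float = 0.2,
                  duplicate_pairs: Sequence[tuple[str, str]] = (("bun_adjscr", "bun_scr"),),
                  auto_duplicate_rho: float = 0.9) -> SelectionReport:
    """Run the full staged construction of the best trough-correction model.

    Every fit feeding a selection decision satisfies R̂ ≤ 1.1 (non-converged
    fits are refit with doubled draws or excluded, logged).  A Shapiro-Wilk
    test on the response is reported as a gate: failure warns but never
    aborts, since the normal-family model is the procedure under study.
    """
    mcmc = mcmc or McmcSettings()
    log: list[str] = []
    y = dataset.table[dataset.response].to_numpy(float)
    shapiro_p = float(stats.shapiro(y).pvalue)
    if shapiro_p < 0.05:
        warnings.warn(f"response normality rejected by Shapiro-Wilk (p={shapiro_p:.3g}); "
                      "the normal-family model may be misspecified", stacklevel=2)
        log.append(f"Shapiro-Wilk gate: p={shapiro_p:.4f} < 0.05 (warning only)")

    pmmpdq = dataset.pmmpdq()
    corr = screen_fixed_candidate1(dataset, pmmpdq, threshold=rho_threshold)
    candidate1 = [str(r.covariate) for r in corr.itertuples() if r.kept]

    basic = fit_bayesian_lm(ModelSpec(fixed_effects=("pmmpv",)), dataset, mcmc, seed=seed)
    if not basic.converged:
        raise RuntimeError("basic model failed to converge")
    candidate2, singles = select_fixed_candidate2(
        dataset, candidate1, basic, mcmc, seed=seed,
        duplicate_pairs=duplicate_pairs, auto_duplicate_rho=auto_duplicate_rho, log=log)

    if candidate2:
        fixed_spec, fixed_fit, subsets = search_fixed_model(
            dataset, candidate2, mcmc, seed=seed, log=log)
    else:
        fixed_spec, fixed_fit = basic.spec, basic
        subsets = pd.DataFrame([{"covariates": "(basic model)", "n_covariates": 0,
                                 "waic": basic.waic}])
        log.append("no fixed-effect candidate lowered WAIC; basic model retained")

    grouping, icc_table = screen_random_candidate(dataset, pmmpdq)
    best_spec, best_fit, placements = search_random_placement(
        dataset, fixed_spec, grouping, fixed_fit, mcmc, seed=seed, log=log)

    report = SelectionReport(
        correlations=corr, single_additions=singles, subsets=subsets,
        icc=icc_table, placements=placements, best_spec=best_spec,
        best_fit=best_fit, basic_waic=basic.waic, shapiro_p=shapiro_p, log=log)
    # the winner must be the minimum over everything evaluated in the last stage
    assert best_fit.waic == placements["waic"].min()
    assert all(v <= RHAT_LIMIT for v in best_fit.rhat.values() if math.isfinite(v))
    return report
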