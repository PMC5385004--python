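"""Covariate screening, ICC, the staged WAIC search, and best-model prediction."""

import math

import numpy as np
import pandas as pd
import pingouin
import pytest

import vcmtdm as v
from vcmtdm.glmm import icc_oneway, linear_predict, spearman_rho


# ---------------------------------------------------------------------------
# Spearman correlation


def test_spearman_perfect_and_reversed_ranks():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    rho, _ = spearman_rho(x, x)
    assert rho == pytest.approx(1.0)
    rho, _ = spearman_rho(x, -x)
    assert rho == pytest.approx(-1.0)


def test_spearman_with_ties_matches_average_rank_formula():
    """Pearson correlation of mid-ranks, computed by hand, to 1e-12."""
    x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0])
    y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 8.0])

    def midranks(a):
        order = np.argsort(a, kind="mergesort")
        ranks = np.empty(len(a))
        i = 0
        while i < len(a):
            j = i
            while j + 1 < len(a) and a[order[j + 1]] == a[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    manual = np.corrcoef(rx, ry)[0, 1]
    rho, _ = spearman_rho(x, y)
    assert rho == pytest.approx(manual, abs=1e-12)


def test_spearman_zero_variance_is_undefined():
    rho, p = spearman_rho([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert math.isnan(rho) and math.isnan(p)


def test_spearman_rejects_short_input():
    with pytest.raises(ValueError):
        spearman_rho([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Stage 2: fixed-effect candidate screen


def _screen_dataset(n, seed, signal_strength=0.0):
    rng = np.random.default_rng(seed)
    pmmpv = rng.uniform(8, 20, n)
    bepv = pmmpv + rng.normal(0, 2, n)
    pmmpdq = bepv - pmmpv
    table = pd.DataFrame({
        "pmmpv": pmmpv, "bepv": bepv,
        "tracker": pmmpdq + rng.normal(0, signal_strength if signal_strength else 1e-3, n),
        "noise": rng.normal(0, 1, n),
    })
    return v.AnalysisDataset(table=table, continuous=("pmmpv", "tracker", "noise"),
                             discrete=())


def test_screen_keeps_tracking_covariate_with_high_rho():
    data = _screen_dataset(200, seed=0, signal_strength=0.1)
    out = v.screen_fixed_candidate1(data)
    row = out[out["covariate"] == "tracker"].iloc[0]
    assert row["kept"] and row["rho"] > 0.95


def test_screen_excludes_independent_covariate_usually():
    excluded = 0
    reps = 50
    for rep in range(reps):
        data = _screen_dataset(200, seed=1000 + rep)
        out = v.screen_fixed_candidate1(data)
        if not out[out["covariate"] == "noise"]["kept"].iloc[0]:
            excluded += 1
    assert excluded >= 0.9 * reps


def test_screen_impossible_threshold_keeps_nothing():
    data = _screen_dataset(100, seed=2, signal_strength=0.1)
    out = v.screen_fixed_candidate1(data, threshold=1.1)
    assert not out["kept"].any()


def test_screen_never_offers_pmmpv_itself():
    data = _screen_dataset(100, seed=3)
    assert "pmmpv" not in set(v.screen_fixed_candidate1(data)["covariate"])


# ---------------------------------------------------------------------------
# ICC


def test_icc_perfect_clustering():
    vals = [1.0, 1.0, 1.0, 5.0, 5.0, 5.0]
    groups = ["a", "a", "a", "b", "b", "b"]
    icc, lo, hi = icc_oneway(vals, groups)
    assert icc == pytest.approx(1.0)


def test_icc_matches_hand_anova_closed_form():
    vals = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    groups = ["a", "a", "a", "b", "b", "b"]
    # hand ANOVA: k=2, n=6, group means 2 and 8, grand mean 5
    ssb = 3 * (2 - 5) ** 2 + 3 * (8 - 5) ** 2          # 54
    ssw = sum((x - m) ** 2 for x, m in zip(vals, [2] * 3 + [8] * 3))  # 4
    msb, msw = ssb / 1, ssw / 4
    kbar = (6 - (9 + 9) / 6) / 1                        # 3 (balanced)
    expected = (msb - msw) / (msb + (kbar - 1) * msw)
    icc, _, _ = icc_oneway(vals, groups)
    assert icc == pytest.approx(expected, abs=1e-12)


def test_icc_agrees_with_pingouin_on_balanced_data():
    rng = np.random.default_rng(8)
    k, m = 6, 10
    effects = rng.normal(0, 2.0, k)
    vals, groups, raters = [], [], []
    for g in range(k):
        for j in range(m):
            vals.append(effects[g] + rng.normal(0, 1.0))
            groups.append(f"g{g}")
            raters.append(j)
    icc, _, _ = icc_oneway(vals, groups)
    df = pd.DataFrame({"targets": groups, "raters": raters, "ratings": vals})
    ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                   ratings="ratings")
    icc1 = float(ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0])
    assert icc == pytest.approx(icc1, abs=1e-9)


def test_icc_near_zero_under_label_permutation():
    rng = np.random.default_rng(9)
    vals = rng.normal(0, 1, 200)
    good = 0
    reps = 20
    for _ in range(reps):
        groups = rng.permutation(["a"] * 100 + ["b"] * 100)
        icc, _, _ = icc_oneway(vals, groups)
        if abs(icc) < 0.1:
            good += 1
    assert good >= 0.9 * reps


def test_icc_single_group_undefined():
    with pytest.raises(ValueError):
        icc_oneway([1.0, 2.0, 3.0], ["a", "a", "a"])


def test_icc_negative_values_possible():
    # anti-clustered: within-group spread exceeds between-group spread
    vals = [0.0, 10.0, 0.1, 9.9, 0.2, 10.2]
    groups = ["a", "a", "b", "b", "c", "c"]
    icc, _, _ = icc_oneway(vals, groups)
    assert icc < 0


# ---------------------------------------------------------------------------
# Stage 3: single additions + duplicate rule


def test_candidate2_keeps_true_and_drops_duplicate(toy_dataset, fast_mcmc):
    data = toy_dataset(n=300, seed=20, beta_bun=0.15, resid_sd=1.5, n_noise=1)
    # a near-duplicate of the true covariate, declared as a pair
    table = data.table.assign(bun_copy=data.table["bun_adjscr"]
                              + np.random.default_rng(0).normal(0, 0.05, 300))
    data = v.AnalysisDataset(table=table,
                             continuous=data.continuous + ("bun_copy",),
                             discrete=data.discrete)
    basic = v.fit_bayesian_lm(v.ModelSpec(fixed_effects=("pmmpv",)), data,
                              fast_mcmc, seed=20)
    kept, table3 = v.select_fixed_candidate2(
        data, ["bun_adjscr", "bun_copy"], basic, fast_mcmc, seed=20,
        duplicate_pairs=[("bun_adjscr", "bun_copy")])
    assert len(kept) == 1 and kept[0] in ("bun_adjscr", "bun_copy")
    assert set(table3["covariate"]) == {"(basic model)", "bun_adjscr", "bun_copy"}


def test_candidate2_excludes_noise_usually(toy_dataset, fast_mcmc):
    wins = 0
    reps = 20
    for rep in range(reps):
        data = toy_dataset(n=300, seed=300 + rep, beta1=1.0, resid_sd=2.0, n_noise=1)
        basic = v.fit_bayesian_lm(v.ModelSpec(fixed_effects=("pmmpv",)), data,
                                  fast_mcmc, seed=rep)
        kept, _ = v.select_fixed_candidate2(data, ["z1"], basic, fast_mcmc, seed=rep)
        if "z1" not in kept:
            wins += 1
    assert wins >= 0.7 * reps


def test_candidate2_retains_data_generating_covariate(toy_dataset, fast_mcmc):
    data = toy_dataset(n=300, seed=21, beta_bun=0.15, resid_sd=1.5)
    basic = v.fit_bayesian_lm(v.ModelSpec(fixed_effects=("pmmpv",)), data,
                              fast_mcmc, seed=21)
    kept, _ = v.select_fixed_candidate2(data, ["bun_adjscr"], basic, fast_mcmc, seed=21)
    assert kept == ["bun_adjscr"]


# ---------------------------------------------------------------------------
# Stage 4: subset search


def test_subset_search_with_empty_candidates_returns_basic(toy_dataset, fast_mcmc):
    data = toy_dataset(n=100, seed=30)
    spec, fit, table = v.search_fixed_model(data, [], fast_mcmc, seed=30)
    assert spec.fixed_effects == ("pmmpv",)
    assert len(table) == 1


def test_subset_search_cap():
    data_names = [f"c{i}" for i in range(11)]
    rng = np.random.default_rng(0)
    table = pd.DataFrame({**{n: rng.normal(size=30) for n in data_names},
                          "pmmpv": rng.uniform(8, 20, 30),
                          "bepv": rng.uniform(8, 20, 30)})
    data = v.AnalysisDataset(table=table, continuous=("pmmpv",) + tuple(data_names),
                             discrete=())
    with pytest.raises(ValueError, match="tighten"):
        v.search_fixed_model(data, data_names, max_subsets=1024)


def test_subset_search_finds_true_covariate_among_noise(toy_dataset, fast_mcmc):
    wins = 0
    reps = 10
    for rep in range(reps):
        data = toy_dataset(n=400, seed=400 + rep, beta_bun=0.15, resid_sd=1.5, n_noise=3)
        spec, _, _ = v.search_fixed_model(
            data, ["bun_adjscr", "z1", "z2", "z3"], fast_mcmc, seed=rep)
        if "bun_adjscr" in spec.fixed_effects:
            wins += 1
    assert wins >= 0.8 * reps


def test_subset_search_prefers_jointly_necessary_pair(fast_mcmc):
    """Two covariates that only work together beat either singleton."""
    rng = np.random.default_rng(55)
    n = 300
    pmmpv = rng.uniform(8, 20, n)
    x1 = rng.normal(0, 1, n)
    x2 = -x1 + rng.normal(0, 0.1, n)   # near-cancelling pair
    y = pmmpv + 5 * (x1 + x2) + rng.normal(0, 0.5, n)
    table = pd.DataFrame({"pmmpv": pmmpv, "x1": x1, "x2": x2, "bepv": y})
    data = v.AnalysisDataset(table=table, continuous=("pmmpv", "x1", "x2"), discrete=())
    spec, _, _ = v.search_fixed_model(data, ["x1", "x2"], fast_mcmc, seed=56)
    assert set(spec.fixed_effects) == {"pmmpv", "x1", "x2"}


# ---------------------------------------------------------------------------
# Stage 5/6: random effect


def test_random_screen_selects_shifted_group():
    rng = np.random.default_rng(60)
    n = 200
    pmmpv = rng.uniform(8, 20, n)
    grp = rng.choice(["x", "y"], n)
    bepv = pmmpv + np.where(grp == "x", 2.0, -2.0) + rng.normal(0, 1, n)
    table = pd.DataFrame({"pmmpv": pmmpv, "bepv": bepv, "shifted": grp,
                          "junk": rng.choice(["p", "q"], n)})
    data = v.AnalysisDataset(table=table, continuous=("pmmpv",),
                             discrete=("shifted", "junk"))
    best, table5 = v.screen_random_candidate(data)
    assert best == "shifted"
    assert list(table5.columns) == ["covariate", "icc", "l95", "u95"]


def test_random_screen_always_returns_argmax():
    rng = np.random.default_rng(61)
    n = 80
    table = pd.DataFrame({"pmmpv": rng.uniform(8, 20, n),
                          "bepv": rng.uniform(8, 20, n),
                          "g1": rng.choice(["a", "b"], n),
                          "g2": rng.choice(["c", "d"], n)})
    data = v.AnalysisDataset(table=table, continuous=("pmmpv",), discrete=("g1", "g2"))
    best, _ = v.screen_random_candidate(data)
    assert best in ("g1", "g2")  # max rule: something is always returned

    single = v.AnalysisDataset(table=table, continuous=("pmmpv",), discrete=("g1",))
    best, _ = v.screen_random_candidate(single)
    assert best == "g1"


def test_placement_enumeration_size_single_fixed_effect(toy_dataset, fast_mcmc):
    data = toy_dataset(n=150, seed=62)
    spec = v.ModelSpec(fixed_effects=("pmmpv",))
    fit = v.fit_bayesian_lm(spec, data, fast_mcmc, seed=62)
    best, best_fit, table6 = v.search_random_placement(
        data, spec, "sex", fit, fast_mcmc, seed=62)
    assert len(table6) == 2  # fixed model + deviations on the lone coefficient


def test_placement_detects_sex_specific_slope(toy_dataset, fast_mcmc):
    wins = 0
    reps = 10
    for rep in range(reps):
        data = toy_dataset(n=400, seed=600 + rep, sex_dev=(-0.08, 0.08), resid_sd=1.0)
        spec = v.ModelSpec(fixed_effects=("pmmpv",))
        fit = v.fit_bayesian_lm(spec, data, fast_mcmc, seed=rep)
        best, _, _ = v.search_random_placement(data, spec, "sex", fit, fast_mcmc, seed=rep)
        if best.random_effect is not None and "pmmpv" in best.random_effect.targets:
            wins += 1
    assert wins >= 0.7 * reps


def test_placement_keeps_fixed_model_competitive_without_group_effect(
        toy_dataset, fast_mcmc):
    good = 0
    reps = 10
    for rep in range(reps):
        data = toy_dataset(n=300, seed=700 + rep, sex_dev=(0.0, 0.0), resid_sd=2.0)
        spec = v.ModelSpec(fixed_effects=("pmmpv",))
        fit = v.fit_bayesian_lm(spec, data, fast_mcmc, seed=rep)
        best, best_fit, _ = v.search_random_placement(
            data, spec, "sex", fit, fast_mcmc, seed=rep)
        if best.random_effect is None or best_fit.waic >= fit.waic - 2.0:
            good += 1
    assert good >= 0.7 * reps


# ---------------------------------------------------------------------------
# Prediction with published-style coefficients


PUBLISHED_FIXED = {"pmmpv": 0.977, "bun_adjscr": 0.101, "scr_adj_amt": -12.899}
PUBLISHED_DEVS = {"pmmpv": {"male": 0.029, "female": -0.081}}


@pytest.mark.parametrize("row, expected", [
    ({"pmmpv": 10.0, "bun_adjscr": 20.0, "scr_adj_amt": 0.0, "sex": "male"}, 12.08),
    ({"pmmpv": 8.40, "bun_adjscr": 34.52, "scr_adj_amt": 0.0, "sex": "male"}, 11.93692),
    ({"pmmpv": 0.0, "bun_adjscr": 0.0, "scr_adj_amt": 0.0, "sex": "female"}, 0.0),
])
def test_linear_predict_hand_arithmetic(row, expected):
    out = linear_predict(row, PUBLISHED_FIXED, PUBLISHED_DEVS, grouping="sex")
    assert out == pytest.approx(expected, abs=5e-3)


def test_linear_predict_female_branch():
    row = {"pmmpv": 10.0, "bun_adjscr": 0.0, "scr_adj_amt": 0.0, "sex": "female"}
    out = linear_predict(row, PUBLISHED_FIXED, PUBLISHED_DEVS, grouping="sex")
    assert out == pytest.approx((0.977 - 0.081) * 10.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Orchestration


def test_run_selection_end_to_end_small(toy_dataset):
    """Full staged pipeline on a small dataset with a clear bun_adjscr signal."""
    data = toy_dataset(n=250, seed=77, beta_bun=0.15, sex_dev=(-0.05, 0.05),
                       resid_sd=1.5, n_noise=2)
    mcmc = v.McmcSettings(draws=400, warmup=300)
    report = v.run_selection(data, mcmc=mcmc, seed=77)
    assert "bun_adjscr" in report.best_spec.fixed_effects
    assert report.best_fit.waic == report.placements["waic"].min()
    # stage tables all populated and winner's rhat within the convergence rule
    assert len(report.correlations) and len(report.icc)
    assert all(r <= 1.1 for r in report.best_fit.rhat.values() if math.isfinite(r))
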