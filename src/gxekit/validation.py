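"""Simulation-based validation studies with known ground truth.

Every public function here runs one self-contained study: it generates
synthetic inputs from :mod:`gxekit.simulate`, pushes them through the
corresponding analysis arm, and returns the summary quantities (recovery
error, coverage, rejection rates, detection rates, oracle discrepancies).
The oracle helpers (grid maximizers, exhaustive enumeration, the
definitional BH step-up) are deliberately written as independent
re-derivations, not calls into the implementation paths they check.

Replicate counts and sample sizes are the package's standard desk-scale
study conditions; every function takes an explicit seed.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import burden, mr, simulate, survival

__all__ = [
    "ivw_recovery_study",
    "egger_calibration_study",
    "weighted_median_breakdown_study",
    "radial_detection_study",
    "harmonization_invariance_study",
    "cox_grid_oracle_check",
    "cox_recovery_study",
    "sliding_discrimination_study",
    "firth_separation_sweep",
    "firth_grid_oracle_check",
    "burden_power_study",
    "burden_null_study",
    "fisher_enumeration_check",
    "bh_stepup_check",
]


def _sumstat_config(seed: int, **kwargs) -> simulate.SumstatSimConfig:
    return simulate.SumstatSimConfig(seed=seed, **kwargs)


def _harmonized(config: simulate.SumstatSimConfig) -> pd.DataFrame:
    exposure, outcome = simulate.gen_sumstats(config)
    return mr.harmonize(exposure, outcome)


# ---------------------------------------------------------------------------
# MR arm
# ---------------------------------------------------------------------------

def ivw_recovery_study(
    seed: int, theta: float = 0.1, n_snps: int = 100, n_reps: int = 500
) -> dict:
    """IVW parameter recovery and 95% CI coverage under valid instruments."""
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, bool)
    for rep in range(n_reps):
        h = _harmonized(_sumstat_config(seed + rep, theta=theta, n_snps=n_snps))
        est = mr.ivw(h)
        estimates[rep] = est.beta
        lo, hi = est.beta - 1.959964 * est.se, est.beta + 1.959964 * est.se
        covered[rep] = lo <= theta <= hi
    return {
        "theta": theta,
        "mean_estimate": float(estimates.mean()),
        "mc_se": float(estimates.std(ddof=1) / math.sqrt(n_reps)),
        "coverage": float(covered.mean()),
        "n_reps": n_reps,
    }


def egger_calibration_study(
    seed: int,
    mode: str = "balanced",
    invalid_fraction: float = 0.3,
    n_snps: int = 200,
    n_reps: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the MR-Egger intercept test under balanced
    (type-I error) or directional (power) pleiotropy."""
    reject = np.empty(n_reps, bool)
    for rep in range(n_reps):
        cfg = _sumstat_config(
            seed + rep,
            theta=0.1,
            n_snps=n_snps,
            pleiotropy_mode=mode,
            invalid_fraction=invalid_fraction,
        )
        h = _harmonized(cfg)
        _, intercept = mr.egger(h)
        reject[rep] = intercept.pvalue < alpha
    return {"mode": mode, "rejection_rate": float(reject.mean()), "n_reps": n_reps}


def weighted_median_breakdown_study(
    seed: int,
    theta: float = 0.1,
    invalid_fraction: float = 0.4,
    n_snps: int = 100,
    n_reps: int = 200,
) -> dict:
    """Fraction of replicates where the weighted median is less biased than
    IVW under directional pleiotropy contaminating 40% of instruments."""
    wins = np.empty(n_reps, bool)
    for rep in range(n_reps):
        cfg = _sumstat_config(
            seed + rep,
            theta=theta,
            n_snps=n_snps,
            pleiotropy_mode="directional",
            invalid_fraction=invalid_fraction,
        )
        h = _harmonized(cfg)
        bias_ivw = abs(mr.ivw(h).beta - theta)
        # point estimate only; the bootstrap se is irrelevant to bias
        wm = mr._weighted_median_point(
            h["wald_ratio"].to_numpy(), h["weight"].to_numpy()
        )
        wins[rep] = abs(wm - theta) < bias_ivw
    return {"win_rate": float(wins.mean()), "n_reps": n_reps}


def _plant_outlier(h: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Append one gross outlier: Wald ratio 10x the causal effect, smallest se."""
    b_x = float(np.median(np.abs(h["b_x"])))
    se_y = 0.5 * float(h["se_y"].min())
    se_x = float(h["se_x"].min())
    row = {
        "variant_id": "planted_outlier",
        "b_x": b_x,
        "se_x": se_x,
        "p_x": 1e-12,
        "b_y": 10.0 * theta * b_x,
        "se_y": se_y,
        "p_y": 0.5,
        "eaf_x": 0.3,
        "eaf_y": 0.3,
    }
    row["wald_ratio"] = row["b_y"] / row["b_x"]
    row["wald_se"] = row["se_y"] / abs(row["b_x"])
    row["weight"] = 1.0 / row["wald_se"] ** 2
    row["f_stat"] = (row["b_x"] / row["se_x"]) ** 2
    return pd.concat([h, pd.DataFrame([row])], ignore_index=True)


def radial_detection_study(
    seed: int,
    theta: float = 0.1,
    n_clean: int = 50,
    n_reps: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Radial-MR outlier screen: detection of one planted gross outlier and
    the per-SNP false-flag rate on clean instruments."""
    detected = np.empty(n_reps, bool)
    false_flags = 0
    clean_snps = 0
    for rep in range(n_reps):
        h = _harmonized(_sumstat_config(seed + rep, theta=theta, n_snps=n_clean))
        ids, _ = mr.radial_outliers(h, alpha)
        false_flags += len(ids)
        clean_snps += len(h)
        contaminated = _plant_outlier(h, theta)
        ids, _ = mr.radial_outliers(contaminated, alpha)
        detected[rep] = "planted_outlier" in ids
    return {
        "detection_rate": float(detected.mean()),
        "false_flag_rate": false_flags / clean_snps,
        "n_reps": n_reps,
    }


def harmonization_invariance_study(seed: int, n_configs: int = 50) -> dict:
    """Allele-relabeling invariance: scrambling outcome allele labels (with
    consistent beta negation) must leave every battery statistic identical."""
    rng = np.random.default_rng(seed)
    n_identical = 0
    for _ in range(n_configs):
        base = simulate.SumstatSimConfig(
            n_snps=int(rng.integers(60, 150)),
            theta=float(rng.uniform(-0.2, 0.2)),
            pleiotropy_mode="balanced",
            invalid_fraction=float(rng.uniform(0.0, 0.3)),
            palindrome_fraction=float(rng.uniform(0.0, 0.3)),
            seed=int(rng.integers(0, 2**31 - 1)),
            allele_scramble=False,
        )
        cfg = mr.MrConfig(seed=int(rng.integers(0, 2**31 - 1)), n_boot=200)
        exp_a, out_a = simulate.gen_sumstats(base)
        exp_b, out_b = simulate.gen_sumstats(replace(base, allele_scramble=True))
        rep_a = mr.run_mr_battery(exp_a, out_a, cfg).to_dict()
        rep_b = mr.run_mr_battery(exp_b, out_b, cfg).to_dict()
        n_identical += int(rep_a == rep_b)
    return {"n_identical": n_identical, "n_configs": n_configs}


# ---------------------------------------------------------------------------
# survival arm
# ---------------------------------------------------------------------------

def _cox_partial_loglik_grid(
    times: np.ndarray, events: np.ndarray, x: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Written-out no-ties partial log likelihood on a coefficient grid
    (independent oracle; naive double loop over events and risk sets)."""
    pl = np.zeros_like(grid)
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        eta = np.outer(x[risk], grid)
        pl += x[i] * grid - np.log(np.exp(eta).sum(axis=0))
    return pl


def grid_cox_oracle(
    times: np.ndarray, events: np.ndarray, x: np.ndarray,
    lo: float = -8.0, hi: float = 8.0,
) -> float:
    """Two-stage grid maximization of the explicit partial likelihood."""
    coarse = np.linspace(lo, hi, 16001)
    best = coarse[np.argmax(_cox_partial_loglik_grid(times, events, x, coarse))]
    fine = np.linspace(best - 2e-3, best + 2e-3, 4001)
    return float(fine[np.argmax(_cox_partial_loglik_grid(times, events, x, fine))])


def _small_cox_fixtures(seed: int, n_fixtures: int = 20) -> list[pd.DataFrame]:
    """Deterministic no-ties datasets with <= 5 subjects and a finite MLE
    (grid argmax interior)."""
    rng = np.random.default_rng(seed)
    fixtures = []
    while len(fixtures) < n_fixtures:
        n = int(rng.integers(3, 6))
        df = pd.DataFrame(
            {
                "time": np.sort(rng.uniform(0.5, 10.0, n)),
                "event": (rng.random(n) < 0.7).astype(int),
                "dose": rng.normal(0.0, 1.0, n),
            }
        )
        if df["event"].sum() == 0 or df["dose"].nunique() < 2:
            continue
        t, e, x = (df[c].to_numpy() for c in ("time", "event", "dose"))
        coarse = np.linspace(-8.0, 8.0, 1601)
        pl = _cox_partial_loglik_grid(t, e, x, coarse)
        if np.ptp(pl) < 1e-3:
            continue  # uninformative (e.g. the only event closes the risk set)
        oracle = grid_cox_oracle(t, e, x)
        if abs(oracle) < 6.0:  # interior maximum: MLE exists and is finite
            fixtures.append(df)
    return fixtures


def cox_grid_oracle_check(seed: int, n_fixtures: int = 20) -> dict:
    """Newton Cox coefficient vs grid-maximized partial likelihood on every
    small no-ties fixture."""
    diffs = []
    for df in _small_cox_fixtures(seed, n_fixtures):
        fit = survival.cox_fit(df, "dose")
        oracle = grid_cox_oracle(
            df["time"].to_numpy(), df["event"].to_numpy(), df["dose"].to_numpy()
        )
        diffs.append(abs(fit.coefficients["dose"] - oracle))
    return {"max_abs_diff": float(max(diffs)), "n_fixtures": n_fixtures}


def cox_recovery_study(seed: int, n: int = 1000, n_reps: int = 200) -> dict:
    """Two-group exponential simulation with true hazard ratio 2: the Cox
    fit should recover log(2) within Monte-Carlo error."""
    truth = math.log(2.0)
    coefs = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = simulate.CohortSimConfig(
            n=n,
            zero_mass=0.5,
            dose_log_mean=0.0,
            dose_log_sd=1e-9,
            effect_model="linear",
            beta_dose=truth,
            baseline_hazard=0.1,
            censor_rate=0.05,
            seed=seed + rep,
        )
        cohort = simulate.gen_cohort(cfg)
        coefs[rep] = survival.cox_fit(cohort, "dose").coefficients["dose"]
    return {
        "truth": truth,
        "mean_coefficient": float(coefs.mean()),
        "sim_se": float(coefs.std(ddof=1) / math.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def sliding_discrimination_study(
    seed: int,
    n: int = 400,
    window: int = 20,
    n_reps: int = 100,
    beta_dose: float = 6e-4,
    baseline_hazard: float = 0.05,
) -> dict:
    """Sliding-removal sensitivity under a threshold dose effect (confined
    above the 90th dose percentile) versus a matched homogeneous linear
    effect with the same per-unit coefficient.

    A threshold effect should produce systematically negative correlations
    between removed-subset mean dose and the refit coefficient; the
    homogeneous model is correctly specified on every subset, so its
    correlation is centred on zero.
    """
    results: dict[str, np.ndarray] = {}
    for model in ("threshold", "linear"):
        rs = np.empty(n_reps)
        for rep in range(n_reps):
            cfg = simulate.CohortSimConfig(
                n=n,
                effect_model=model,
                beta_dose=beta_dose,
                baseline_hazard=baseline_hazard,
                threshold_quantile=0.9,
                seed=seed + rep,  # paired cohorts across the two models
            )
            cohort = simulate.gen_cohort(cfg)
            res = survival.sliding_removal_sensitivity(
                cohort, window=window, covariate_terms=("enrol_age",)
            )
            rs[rep] = res.pearson_r
        results[model] = rs
    return {
        "frac_negative_threshold": float((results["threshold"] < 0).mean()),
        "mean_abs_r_threshold": float(np.abs(results["threshold"]).mean()),
        "mean_abs_r_homogeneous": float(np.abs(results["linear"]).mean()),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# burden arm
# ---------------------------------------------------------------------------

def _grid_firth_oracle(y: np.ndarray, X: np.ndarray, lo=-8.0, hi=8.0) -> np.ndarray:
    """Coarse-to-fine 2-D grid maximization of the written-out Jeffreys-
    penalized log likelihood (independent oracle for intercept + slope)."""

    def pl(b0: np.ndarray, b1: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast_shapes(b0.shape, b1.shape))
        it = np.nditer([b0, b1, out], op_flags=[["readonly"], ["readonly"], ["writeonly"]])
        for a, b, o in it:
            eta = X[:, 0] * a + X[:, 1] * b
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            info = (X * w[:, None]).T @ X
            det = info[0, 0] * info[1, 1] - info[0, 1] * info[1, 0]
            ll = np.sum(y * eta - np.logaddexp(0.0, eta))
            o[...] = ll + 0.5 * math.log(det) if det > 0 else -np.inf
        return out

    g = np.linspace(lo, hi, 161)
    b0g, b1g = np.meshgrid(g, g, indexing="ij")
    vals = pl(b0g, b1g)
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    center = (g[i], g[j])
    for span, steps in ((0.2, 81), (0.01, 81), (5e-4, 81)):
        g0 = np.linspace(center[0] - span, center[0] + span, steps)
        g1 = np.linspace(center[1] - span, center[1] + span, steps)
        b0g, b1g = np.meshgrid(g0, g1, indexing="ij")
        vals = pl(b0g, b1g)
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        center = (g0[i], g1[j])
    return np.array(center)


def firth_grid_oracle_check() -> dict:
    """Firth Newton fit vs 2-D penalized-likelihood grid on the completely
    separated 4-case/4-control toy."""
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    X = np.column_stack([np.ones(8), x])
    fit = burden.firth_logistic(y, X, test_idx=[1])
    oracle = _grid_firth_oracle(y, X)
    return {
        "slope": float(fit.coefficients[1]),
        "oracle_slope": float(oracle[1]),
        "abs_diff": float(np.max(np.abs(fit.coefficients - oracle))),
    }


def firth_separation_sweep(max_n: int = 12) -> dict:
    """Exhaustive sweep of separated 2x2 carrier configurations with
    n <= max_n: Firth estimates must all be finite."""
    n_configs = 0
    n_finite = 0
    for n1 in range(1, max_n):
        for n0 in range(1, max_n - n1 + 1):
            for a in range(n1 + 1):
                for c in range(n0 + 1):
                    cells = (a, n1 - a, c, n0 - c)
                    if min(cells) != 0:
                        continue  # not separated
                    carriers = a + c
                    if carriers == 0 or carriers == n1 + n0:
                        continue  # carrier status constant
                    y = np.r_[np.ones(n1), np.zeros(n0)]
                    x = np.r_[np.ones(a), np.zeros(n1 - a), np.ones(c), np.zeros(n0 - c)]
                    X = np.column_stack([np.ones(n1 + n0), x])
                    n_configs += 1
                    fit = burden.firth_logistic(y, X, test_idx=[])
                    n_finite += int(np.all(np.isfinite(fit.coefficients)))
    return {"n_configs": n_configs, "finite_rate": n_finite / n_configs}


def burden_power_study(
    seed: int,
    n_reps: int = 50,
    n_cases: int = 2000,
    n_controls: int = 2000,
    n_genes: int = 200,
    odds_ratio: float = 10.0,
) -> dict:
    """One planted high-odds-ratio gene among nulls: how often does it attain
    the smallest burden p-value?"""
    rank_first = np.empty(n_reps, bool)
    for rep in range(n_reps):
        cfg = simulate.GenotypeSimConfig(
            n_cases=n_cases,
            n_controls=n_controls,
            n_genes=n_genes,
            signal_genes=[(0, odds_ratio)],
            seed=seed + rep,
        )
        carriers, pheno, variants = simulate.gen_genotypes(cfg)
        scan = burden.burden_scan(
            carriers,
            variants,
            pheno.set_index("sample_id")["phenotype"],
            pheno.set_index("sample_id")[["cov1", "cov2"]],
        )
        rank_first[rep] = scan["gene"].iloc[0] == "GENE0001"
    return {"rank_first_rate": float(rank_first.mean()), "n_reps": n_reps}


def burden_null_study(
    seed: int,
    n_reps: int = 50,
    n_cases: int = 1000,
    n_controls: int = 1000,
    n_genes: int = 200,
    fdr_threshold: float = 0.05,
) -> dict:
    """All-null burden scan: mean count of FDR-significant genes should be
    consistent with BH control (well below alpha times the null count)."""
    counts = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = simulate.GenotypeSimConfig(
            n_cases=n_cases, n_controls=n_controls, n_genes=n_genes, seed=seed + rep
        )
        carriers, pheno, variants = simulate.gen_genotypes(cfg)
        scan = burden.burden_scan(
            carriers,
            variants,
            pheno.set_index("sample_id")["phenotype"],
            pheno.set_index("sample_id")[["cov1", "cov2"]],
            fdr_threshold=fdr_threshold,
        )
        counts[rep] = scan["significant"].sum()
    return {
        "mean_significant": float(counts.mean()),
        "bound": fdr_threshold * n_genes,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# exact-test oracles
# ---------------------------------------------------------------------------

def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact integer
    hypergeometric weights (independent oracle)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        weight = math.comb(r1, x) * math.comb(r2, c1 - x)
        if weight <= obs:
            total += weight
    return total / denom


def fisher_enumeration_check(max_total: int = 30) -> dict:
    """Compare fisher_exact_2x2 against exact enumeration for every 2x2
    table with grand total <= max_total."""
    max_diff = 0.0
    n_tables = 0
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    _, p = burden.fisher_exact_2x2([[a, b], [c, d]])
                    p_oracle = fisher_enum_p(a, b, c, d)
                    max_diff = max(max_diff, abs(p - p_oracle))
                    n_tables += 1
    return {"max_abs_diff": max_diff, "n_tables": n_tables}


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Definitional BH step-up: adjusted_(i) = min_{j >= i} p_(j) m / j,
    capped at 1, mapped back to input order (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def bh_stepup_check(seed: int, n_vectors: int = 10_000, length: int = 20) -> dict:
    """Compare bh_fdr against the definitional step-up on random p-vectors."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_vectors):
        p = rng.random(length)
        max_diff = max(max_diff, float(np.max(np.abs(burden.bh_fdr(p) - bh_stepup_oracle(p)))))
    return {"max_abs_diff": max_diff, "n_vectors": n_vectors}
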