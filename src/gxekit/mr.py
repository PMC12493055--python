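"""Two-sample Mendelian-randomization battery.

Instrument selection, greedy LD clumping, allele harmonization with
palindrome exclusion, an outcome-vs-exposure p-value pleiotropy filter, five
estimators (IVW, MR-Egger slope and intercept, weighted median, weighted
mode) and the full sensitivity suite (Cochran's Q, I-squared, mean F,
radial-MR outlier removal, leave-one-out).

All estimators operate on a harmonized-instrument table: one row per SNP with
exposure association (b_x, se_x, p_x), outcome association aligned to the
exposure effect allele (b_y, se_y, p_y), the Wald ratio b_y/b_x, its
first-order delta-method standard error se_y/|b_x|, the inverse-variance
weight, and the instrument-strength F statistic (b_x/se_x)^2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "MrConfig",
    "MrEstimate",
    "MrReport",
    "select_instruments",
    "greedy_clump",
    "harmonize",
    "pleiotropy_filter",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "i_squared",
    "mean_f",
    "radial_outliers",
    "leave_one_out",
    "run_mr_battery",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class MrEstimate:
    """One estimator's result: method name, beta, se, p-value, SNP count."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int


@dataclass
class MrConfig:
    """Battery-level thresholds; defaults follow the standard stringent recipe."""

    p_threshold: float = 5e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    palindrome_maf: float = 0.42
    radial_alpha: float = 0.05
    radial_iterate: bool = False
    pleiotropy_filter: bool = True
    second_order_se: bool = False
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ParameterError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ParameterError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ParameterError("clump_window_kb must be > 0")
        if not (0.0 <= self.palindrome_maf <= 0.5):
            raise ParameterError("palindrome_maf must be in [0, 0.5]")
        if not (0.0 <= self.radial_alpha < 1.0):
            raise ParameterError("radial_alpha must be in [0, 1)")
        if self.n_boot < 1:
            raise ParameterError("n_boot must be >= 1")


@dataclass
class MrReport:
    """The full battery output for one exposure -> outcome test."""

    estimates: list[MrEstimate]
    cochran_q: float
    q_pvalue: float
    i_squared: float
    i_squared_gx: float
    mean_f: float
    weak_instruments: bool
    egger_intercept: float
    egger_intercept_p: float
    radial_outlier_ids: list[str]
    n_snps_initial: int
    n_snps_final: int
    n_removed_radial: int
    n_removed_pleiotropy: int
    loo_table: pd.DataFrame
    n_loo_above_05: int

    def estimate(self, method: str) -> MrEstimate:
        for e in self.estimates:
            if e.method == method:
                return e
        raise KeyError(method)

    def to_flat_frame(self) -> pd.DataFrame:
        """One row per statistic, mirroring the usual MR summary-table layout."""
        rows: list[tuple[str, float]] = []
        for e in self.estimates:
            rows.append((f"{e.method} beta", e.beta))
            rows.append((f"{e.method} se", e.se))
            rows.append((f"{e.method} P-value", e.pvalue))
        rows += [
            ("Mean F test", self.mean_f),
            ("IVW Cochran's Q", self.cochran_q),
            ("IVW Cochran's Q test P-value", self.q_pvalue),
            ("I2", self.i_squared),
            ("I2 (instrument strength, GX)", self.i_squared_gx),
            ("Egger intercept", self.egger_intercept),
            ("Egger intercept test", self.egger_intercept_p),
            ("Radial MR outlier SNPs", float(len(self.radial_outlier_ids))),
            ("Number of SNPs LOO > 0.05", float(self.n_loo_above_05)),
            ("Total number of SNPs", float(self.n_snps_final)),
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def to_dict(self) -> dict:
        d = {row.statistic: row.value for row in self.to_flat_frame().itertuples()}
        d["radial outlier ids"] = list(self.radial_outlier_ids)
        return d


# ---------------------------------------------------------------------------
# instrument selection, clumping, harmonization, filtering
# ---------------------------------------------------------------------------

def select_instruments(exposure: pd.DataFrame, p_threshold: float = 5e-5) -> pd.DataFrame:
    """Keep exposure rows with p strictly below the threshold, order preserved."""
    if len(exposure) == 0:
        raise ParameterError("exposure table is empty")
    if not (0.0 < p_threshold < 1.0):
        raise ParameterError("p_threshold must be in (0, 1)")
    kept = exposure[exposure["pvalue"] < p_threshold]
    if len(kept) == 0:
        logger.warning("no instruments pass p < %g; returning empty table", p_threshold)
    return kept.reset_index(drop=True)


def greedy_clump(
    instruments: pd.DataFrame,
    ld_r2: Mapping[tuple[str, str], float] | None,
    window_kb: float = 10_000.0,
    r2_threshold: float = 0.001,
) -> pd.DataFrame:
    """Greedy p-value-ranked clumping against a user-supplied pairwise r2 map.

    SNPs are visited by ascending p; a SNP is kept iff no already-kept SNP on
    the same chromosome within ``window_kb`` has r2 >= ``r2_threshold`` with
    it. Missing pairs are treated as r2 = 0 with a logged warning, so a
    ``None`` map means "already independent" (the post-clumping state).
    """
    if len(instruments) == 0:
        return instruments.copy()
    count_missing = ld_r2 is not None
    if ld_r2 is None:
        logger.info("no LD map supplied; treating all pairs as r2 = 0")
        ld_r2 = {}

    order = instruments.sort_values("pvalue", kind="stable").index
    kept: list[int] = []
    missing = 0
    window_bp = window_kb * 1000.0
    for i in order:
        row = instruments.loc[i]
        ok = True
        for j in kept:
            other = instruments.loc[j]
            if row["chrom"] != other["chrom"]:
                continue
            if abs(float(row["pos"]) - float(other["pos"])) > window_bp:
                continue
            key = (row["variant_id"], other["variant_id"])
            r2 = ld_r2.get(key, ld_r2.get((key[1], key[0])))
            if r2 is None:
                missing += count_missing
                r2 = 0.0
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    if missing:
        logger.warning("%d in-window SNP pairs missing from LD map; treated as r2 = 0", missing)
    return instruments.loc[sorted(kept)].reset_index(drop=True)


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf_limit: float = 0.42,
    second_order_se: bool = False,
) -> pd.DataFrame:
    """Align outcome betas to the exposure effect allele and build instruments.

    Swapped outcome alleles negate b_y (and reflect eaf); strand-complement
    labels are resolved for non-palindromic pairs; incompatible allele pairs
    are dropped with a logged count. Palindromic (A/T, G/C) variants with
    min(eaf, 1-eaf) above ``palindrome_maf_limit`` are excluded because their
    strand cannot be resolved safely near 50% frequency.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_x", "_y"), how="inner")
    n_unmatched = len(exposure) - len(merged)
    if n_unmatched:
        logger.info("%d exposure instruments absent from outcome GWAS; dropped", n_unmatched)
    if len(merged) == 0:
        raise InsufficientDataError("no shared variants between exposure and outcome")

    ea_x = merged["effect_allele_x"].to_numpy()
    oa_x = merged["other_allele_x"].to_numpy()
    ea_y = merged["effect_allele_y"].to_numpy()
    oa_y = merged["other_allele_y"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)

    direct = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    c_ea, c_oa = comp(ea_y), comp(oa_y)
    comp_direct = ~direct & ~swapped & (c_ea == ea_x) & (c_oa == oa_x)
    comp_swapped = ~direct & ~swapped & (c_ea == oa_x) & (c_oa == ea_x)
    flip = swapped | comp_swapped
    compatible = direct | swapped | comp_direct | comp_swapped

    n_incompatible = int((~compatible).sum())
    if n_incompatible:
        logger.warning("%d variants with incompatible alleles dropped", n_incompatible)

    b_y = np.where(flip, -merged["beta_y"], merged["beta_y"])
    eaf_y = np.where(flip, 1.0 - merged["eaf_y"], merged["eaf_y"])

    pal = np.array([_is_palindromic(a, b) for a, b in zip(ea_x, oa_x)])
    eaf_x = merged["eaf_x"].to_numpy()
    maf_x = np.minimum(eaf_x, 1.0 - eaf_x)
    pal_drop = pal & (maf_x > palindrome_maf_limit)
    if pal_drop.any():
        logger.info("%d palindromic variants with MAF > %g excluded",
                    int(pal_drop.sum()), palindrome_maf_limit)

    b_x = merged["beta_x"].to_numpy()
    zero_bx = b_x == 0.0
    if zero_bx.any():
        logger.warning("%d variants with zero exposure beta dropped", int(zero_bx.sum()))

    keep = compatible & ~pal_drop & ~zero_bx
    out = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "b_x": b_x,
            "se_x": merged["se_x"],
            "p_x": merged["pvalue_x"],
            "b_y": b_y,
            "se_y": merged["se_y"],
            "p_y": merged["pvalue_y"],
            "eaf_x": eaf_x,
            "eaf_y": eaf_y,
        }
    )[keep].reset_index(drop=True)
    if len(out) == 0:
        raise InsufficientDataError("no instruments survive harmonization")

    out["wald_ratio"] = out["b_y"] / out["b_x"]
    if second_order_se:
        # delta method including the exposure-side term
        out["wald_se"] = np.sqrt(
            out["se_y"] ** 2 / out["b_x"] ** 2
            + out["b_y"] ** 2 * out["se_x"] ** 2 / out["b_x"] ** 4
        )
    else:
        out["wald_se"] = out["se_y"] / out["b_x"].abs()
    out["weight"] = 1.0 / out["wald_se"] ** 2
    out["f_stat"] = (out["b_x"] / out["se_x"]) ** 2
    return out


def pleiotropy_filter(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Drop SNPs more strongly associated with the outcome than the exposure.

    Removal is strict: a SNP goes iff p_y < p_x.
    """
    if len(harmonized) == 0:
        raise InsufficientDataError("empty harmonized table")
    removed = harmonized[harmonized["p_y"] < harmonized["p_x"]]
    if len(removed):
        logger.info("pleiotropy filter removed %d SNPs: %s",
                    len(removed), list(removed["variant_id"]))
    kept = harmonized[harmonized["p_y"] >= harmonized["p_x"]].reset_index(drop=True)
    if len(kept) == 0:
        raise InsufficientDataError("pleiotropy filter removed every instrument")
    return kept


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _require_k(harmonized: pd.DataFrame, k_min: int, what: str) -> None:
    if len(harmonized) < k_min:
        raise InsufficientDataError(
            f"insufficient instruments for {what}: need >= {k_min}, have {len(harmonized)}"
        )


def ivw(harmonized: pd.DataFrame) -> MrEstimate:
    """Multiplicative random-effects inverse-variance weighted estimate.

    beta is the weight-averaged Wald ratio; the fixed-effect standard error
    sqrt(1/sum(w)) is inflated by max(1, sqrt(Q/(k-1))) so heterogeneity can
    widen but never narrow the interval.
    """
    _require_k(harmonized, 2, "IVW")
    w = harmonized["weight"].to_numpy()
    r = harmonized["wald_ratio"].to_numpy()
    k = len(r)
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (r - beta) ** 2))
    se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MrEstimate("IVW", beta, se, max(p, np.finfo(float).tiny), k)


def egger(harmonized: pd.DataFrame) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger weighted regression with intercept.

    Instruments are oriented so b_x >= 0 (negating b_y in tandem), which the
    intercept needs to be identifiable. Weights are 1/se_y^2; standard errors
    carry the same multiplicative max(1, sqrt(Q/df)) scaling as IVW with
    df = k - 2, and p-values use the t distribution on k - 2 df.
    """
    _require_k(harmonized, 3, "MR-Egger")
    sign = np.sign(harmonized["b_x"].to_numpy())
    sign[sign == 0] = 1.0
    bx = harmonized["b_x"].to_numpy() * sign
    by = harmonized["b_y"].to_numpy() * sign
    w = 1.0 / harmonized["se_y"].to_numpy() ** 2
    k = len(bx)

    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (k - 2)))
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov)) * scale
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=k - 2)
    intercept = MrEstimate("Egger-intercept", float(coef[0]), float(se[0]),
                           float(max(pvals[0], np.finfo(float).tiny)), k)
    slope = MrEstimate("Egger-slope", float(coef[1]), float(se[1]),
                       float(max(pvals[1], np.finfo(float).tiny)), k)
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    harmonized: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimator: consistent when valid instruments carry
    a majority of the weight.

    The point estimate interpolates the sorted Wald ratios at cumulative
    normalized weight 0.5; the standard error is a parametric bootstrap
    (ratios resampled from Normal(ratio_j, wald_se_j), weights fixed).
    """
    _require_k(harmonized, 3, "weighted median")
    r = harmonized["wald_ratio"].to_numpy()
    s = harmonized["wald_se"].to_numpy()
    w = harmonized["weight"].to_numpy()
    beta = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(r, s, size=(n_boot, len(r)))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MrEstimate("weighted-median", beta, max(se, np.finfo(float).tiny),
                      max(p, np.finfo(float).tiny), len(r))


def _weighted_mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float
) -> float:
    if np.ptp(ratios) == 0.0:
        return float(ratios[0])
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    scale = min(np.std(ratios, ddof=1), iqr / 1.349) if iqr > 0 else np.std(ratios, ddof=1)
    h = bandwidth_factor * 0.9 * scale * len(ratios) ** (-1 / 5)
    if h <= 0:
        raise ParameterError("degenerate kernel: bandwidth is zero")
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    harmonized: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Weighted-mode estimator: argmax of a weighted Gaussian kernel density
    over the Wald ratios, bandwidth on a modified-Silverman scale.

    Standard error by the same parametric bootstrap as the weighted median.
    """
    _require_k(harmonized, 3, "weighted mode")
    if bandwidth_factor <= 0:
        raise ParameterError("bandwidth_factor must be > 0")
    r = harmonized["wald_ratio"].to_numpy()
    s = harmonized["wald_se"].to_numpy()
    w = harmonized["weight"].to_numpy()
    beta = _weighted_mode_point(r, w, bandwidth_factor)

    rng = np.random.default_rng(seed)
    draws = rng.normal(r, s, size=(n_boot, len(r)))
    boots = np.array([_weighted_mode_point(d, w, bandwidth_factor) for d in draws])
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MrEstimate("weighted-mode", beta, max(se, np.finfo(float).tiny),
                      max(p, np.finfo(float).tiny), len(r))


# ---------------------------------------------------------------------------
# sensitivity statistics
# ---------------------------------------------------------------------------

def cochran_q(harmonized: pd.DataFrame, beta_ref: float) -> tuple[float, float]:
    """Heterogeneity of the per-SNP Wald ratios around a reference estimate."""
    _require_k(harmonized, 2, "Cochran's Q")
    w = harmonized["weight"].to_numpy()
    r = harmonized["wald_ratio"].to_numpy()
    q = float(np.sum(w * (r - beta_ref) ** 2))
    p = float(stats.chi2.sf(q, df=len(r) - 1))
    return q, p


def i_squared(q: float, k: int) -> float:
    """Proportional excess of Q over its degrees of freedom, floored at 0."""
    if k < 2:
        raise ParameterError("i_squared needs k >= 2")
    if q <= 0.0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def i_squared_gx(harmonized: pd.DataFrame) -> float:
    """Instrument-strength I2 from exposure-side dispersion.

    Measures how far the SNP-exposure effects stand out of their sampling
    noise (values near 1 mean regression-dilution bias toward the null is
    negligible); distinct from the heterogeneity I2 over causal estimates.
    """
    _require_k(harmonized, 2, "I2_GX")
    b = harmonized["b_x"].to_numpy()
    w = 1.0 / harmonized["se_x"].to_numpy() ** 2
    bbar = np.sum(w * b) / np.sum(w)
    q_gx = float(np.sum(w * (b - bbar) ** 2))
    return i_squared(q_gx, len(b))


def mean_f(harmonized: pd.DataFrame) -> tuple[float, bool]:
    """Arithmetic mean instrument F; flag weak instruments at mean F <= 10."""
    if len(harmonized) == 0:
        raise InsufficientDataError("empty harmonized table")
    f = float(harmonized["f_stat"].mean())
    return f, f <= 10.0


def radial_outliers(
    harmonized: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Radial-MR outlier screen, single pass.

    Fits the radial IVW (regression of ratio*sqrt(w) on sqrt(w) through the
    origin, identical to fixed-effect IVW), computes each SNP's contribution
    Q_j = w_j (ratio_j - beta)^2 and flags SNPs whose Q_j exceeds the
    chi-square(1) critical value at ``alpha``.
    """
    _require_k(harmonized, 3, "radial MR")
    w = harmonized["weight"].to_numpy()
    r = harmonized["wald_ratio"].to_numpy()
    beta = np.sum(w * r) / np.sum(w)
    q_j = w * (r - beta) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    flagged = p_j < alpha
    ids = list(harmonized["variant_id"][flagged])
    if len(ids) == len(harmonized):
        raise InsufficientDataError("radial MR flagged every instrument as an outlier")
    if ids:
        logger.info("radial MR removed %d outlier SNPs: %s", len(ids), ids)
    cleaned = harmonized[~flagged].reset_index(drop=True)
    return ids, cleaned


def leave_one_out(harmonized: pd.DataFrame) -> pd.DataFrame:
    """IVW re-estimated with each SNP left out in turn.

    Returns one row per left-out SNP (variant_id, beta, se, pvalue).
    """
    _require_k(harmonized, 3, "leave-one-out")
    rows = []
    for i in range(len(harmonized)):
        rest = harmonized.drop(harmonized.index[i])
        est = ivw(rest)
        rows.append((harmonized["variant_id"].iloc[i], est.beta, est.se, est.pvalue))
    return pd.DataFrame(rows, columns=["left_out", "beta", "se", "pvalue"])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_mr_battery(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    config: MrConfig | None = None,
    ld_r2: Mapping[tuple[str, str], float] | None = None,
) -> MrReport:
    """Run the full battery: select -> clump -> harmonize -> radial outlier
    removal -> pleiotropy filter -> estimators -> sensitivity statistics.

    Radial outliers are removed before any other statistical test; every
    removal is logged with its reason and accounted for in the report counts.
    """
    cfg = config or MrConfig()
    selected = select_instruments(exposure, cfg.p_threshold)
    if len(selected) == 0:
        raise InsufficientDataError("no instruments pass the selection threshold")
    clumped = greedy_clump(selected, ld_r2, cfg.clump_window_kb, cfg.clump_r2)
    harmonized = harmonize(clumped, outcome, cfg.palindrome_maf, cfg.second_order_se)
    n_initial = len(harmonized)

    outlier_ids, harmonized = radial_outliers(harmonized, cfg.radial_alpha)
    while cfg.radial_iterate and outlier_ids and len(harmonized) >= 3:
        more, harmonized = radial_outliers(harmonized, cfg.radial_alpha)
        if not more:
            break
        outlier_ids = outlier_ids + more
    n_removed_pleio = 0
    if cfg.pleiotropy_filter:
        before = len(harmonized)
        harmonized = pleiotropy_filter(harmonized)
        n_removed_pleio = before - len(harmonized)

    ivw_est = ivw(harmonized)
    slope, intercept = egger(harmonized)
    wm = weighted_median(harmonized, cfg.n_boot, cfg.seed)
    wmode = weighted_mode(harmonized, cfg.bandwidth_factor, cfg.n_boot, cfg.seed)

    q, q_p = cochran_q(harmonized, ivw_est.beta)
    i2 = i_squared(q, len(harmonized))
    i2_gx = i_squared_gx(harmonized)
    f_mean, weak = mean_f(harmonized)
    loo = leave_one_out(harmonized)
    n_loo = int((loo["pvalue"] > 0.05).sum())

    return MrReport(
        estimates=[ivw_est, slope, intercept, wm, wmode],
        cochran_q=q,
        q_pvalue=q_p,
        i_squared=i2,
        i_squared_gx=i2_gx,
        mean_f=f_mean,
        weak_instruments=weak,
        egger_intercept=intercept.beta,
        egger_intercept_p=intercept.pvalue,
        radial_outlier_ids=outlier_ids,
        n_snps_initial=n_initial,
        n_snps_final=len(harmonized),
        n_removed_radial=len(outlier_ids),
        n_removed_pleiotropy=n_removed_pleio,
        loo_table=loo,
        n_loo_above_05=n_loo,
    )
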