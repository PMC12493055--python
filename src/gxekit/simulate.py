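"""Synthetic-data generators for all three analysis arms.

Every generator draws from an explicit integer seed and is fully reproducible:
identical configs give byte-identical tables. The generators emulate the shape
of the real inputs (paired GWAS summary statistics, a prospective activity
cohort, a rare-variant carrier package) with controllable ground truth, so
every downstream stage has a parameter-recovery or calibration surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "SumstatSimConfig",
    "CohortSimConfig",
    "GenotypeSimConfig",
    "gen_sumstats",
    "gen_cohort",
    "gen_genotypes",
    "gen_gene_sets",
]

_NUCLEOTIDES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
# A/T and G/C pairs: strand cannot be resolved from allele labels alone.
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in _NUCLEOTIDES
    for b in _NUCLEOTIDES
    if a != b and _COMPLEMENT[a] != b
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SumstatSimConfig:
    """Paired exposure/outcome GWAS summary statistics with known causal effect.

    The true causal effect of the exposure on the outcome is ``theta``; per-SNP
    direct (pleiotropic) effects on the outcome are controlled by
    ``pleiotropy_mode`` / ``pleiotropy_mean`` / ``pleiotropy_sd`` applied to a
    random ``invalid_fraction`` of instruments. Standard errors follow the
    usual GWAS approximation 1/sqrt(2*p*(1-p)*n).
    """

    n_snps: int = 100
    theta: float = 0.0
    n_exposure: int = 175_000
    n_outcome: int = 65_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    instrument_effect_sd: float = 0.08
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.1
    pleiotropy_sd: float = 0.005
    invalid_fraction: float = 0.0
    outlier_fraction: float = 0.0
    palindrome_fraction: float = 0.0
    allele_scramble: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ParameterError(
                f"MAF range must satisfy 0 < maf_low <= maf_high <= 0.5, "
                f"got ({self.maf_low}, {self.maf_high})"
            )
        for name in ("invalid_fraction", "outlier_fraction", "palindrome_fraction"):
            _check_fraction(name, getattr(self, name))
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ParameterError(
                f"unknown pleiotropy_mode {self.pleiotropy_mode!r}"
            )
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ParameterError("GWAS sample sizes must be >= 2")
        if self.instrument_effect_sd <= 0:
            raise ParameterError("instrument_effect_sd must be > 0")
        if self.pleiotropy_sd < 0:
            raise ParameterError("pleiotropy_sd must be >= 0")


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(beta) / se)
    # keep p in (0, 1] so downstream validation accepts every row
    return np.clip(p, 1e-300, 1.0)


def gen_sumstats(config: SumstatSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an (exposure, outcome) pair of summary-statistic tables.

    True per-SNP exposure effects are drawn positive (allele coding is
    arbitrary, and one-signed effects make "directional" pleiotropy genuinely
    directional on the Wald-ratio scale). The outcome effect of SNP j is
    ``theta * gamma_j + alpha_j`` plus sampling noise, with ``alpha_j`` the
    direct effect (zero for valid instruments).
    """
    k = config.n_snps
    rng = np.random.default_rng(config.seed)

    maf = rng.uniform(config.maf_low, config.maf_high, k)
    gamma = np.abs(rng.normal(0.0, config.instrument_effect_sd, k))
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)

    b_x = gamma + rng.normal(0.0, se_x)

    alpha = np.zeros(k)
    if config.pleiotropy_mode != "none" and config.invalid_fraction > 0:
        n_invalid = int(round(k * config.invalid_fraction))
        invalid = rng.choice(k, size=n_invalid, replace=False)
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha[invalid] = rng.normal(mean, config.pleiotropy_sd, n_invalid)
    if config.outlier_fraction > 0:
        n_out = max(1, int(round(k * config.outlier_fraction)))
        out = rng.choice(k, size=n_out, replace=False)
        # gross outliers: direct effects inflated >= 10x the pleiotropy scale
        scale = 10.0 * max(config.pleiotropy_sd, 0.05)
        alpha[out] = rng.choice([-1.0, 1.0], n_out) * scale

    b_y = config.theta * gamma + alpha + rng.normal(0.0, se_y)

    # allele pairs; a configurable fraction is palindromic (A/T or G/C)
    is_pal = rng.random(k) < config.palindrome_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), k)
    non_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), k)
    effect_allele = np.where(
        is_pal,
        np.array([p[0] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[0] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )
    other_allele = np.where(
        is_pal,
        np.array([p[1] for p in _PALINDROMIC_PAIRS])[pal_idx],
        np.array([p[1] for p in _NONPALINDROMIC_PAIRS])[non_idx],
    )

    chrom = (np.arange(k) % 22 + 1).astype(str)
    pos = (np.arange(k) // 22 + 1) * 1_000_000 + rng.integers(0, 500_000, k)

    eaf_out = np.clip(maf + rng.normal(0.0, 0.005, k), 1e-4, 1.0 - 1e-4)

    def _table(beta, se, eaf, n):
        return pd.DataFrame(
            {
                "variant_id": [f"rs{i + 1}" for i in range(k)],
                "chrom": chrom,
                "pos": pos,
                "effect_allele": effect_allele,
                "other_allele": other_allele,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pvalue": _two_sided_p(beta, se),
                "n": n,
            }
        )

    exposure = _table(b_x, se_x, maf, config.n_exposure)
    outcome = _table(b_y, se_y, eaf_out, config.n_outcome)

    if config.allele_scramble:
        flip = rng.random(k) < 0.5
        ea = outcome["effect_allele"].to_numpy().copy()
        oa = outcome["other_allele"].to_numpy().copy()
        outcome.loc[flip, "effect_allele"] = oa[flip]
        outcome.loc[flip, "other_allele"] = ea[flip]
        outcome.loc[flip, "beta"] = -outcome.loc[flip, "beta"]
        outcome.loc[flip, "eaf"] = 1.0 - outcome.loc[flip, "eaf"]

    return exposure, outcome


@dataclass
class CohortSimConfig:
    """Prospective activity cohort with exponential event times.

    The activity dose is zero-inflated and right-skewed (a point mass at zero
    plus a log-normal), matching self-reported leisure-time activity where the
    bottom quartile is dominated by zero recorded activity. Event times are
    exponential with hazard ``baseline_hazard * exp(beta_dose * f(dose))``
    where ``f`` is the identity (linear model) or ``dose * 1[dose > q]`` with
    ``q`` the configured dose quantile (threshold model, concentrating the
    effect in the heaviest exercisers).
    """

    n: int = 1000
    zero_mass: float = 0.25
    dose_log_mean: float = float(np.log(1000.0))
    dose_log_sd: float = 1.0
    effect_model: str = "linear"  # linear | threshold
    beta_dose: float = 0.0
    threshold_quantile: float = 0.9
    baseline_hazard: float = 0.02  # events per person-year
    censor_rate: float = 0.1  # per person-year
    enrol_age_mean: float = 57.0
    enrol_age_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError("n must be >= 2")
        _check_fraction("zero_mass", self.zero_mass)
        if self.effect_model not in ("linear", "threshold"):
            raise ParameterError(f"unknown effect_model {self.effect_model!r}")
        if not (0.0 < self.threshold_quantile < 1.0):
            raise ParameterError("threshold_quantile must be in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        if self.censor_rate <= 0:
            raise ParameterError("censor_rate must be > 0")
        if self.enrol_age_sd < 0:
            raise ParameterError("enrol_age_sd must be >= 0")


def gen_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Generate one participant-level cohort table.

    Columns: id, dose, time (years from enrolment), event, enrol_age, sex.
    Continuous event/censoring times mean ties are absent almost surely.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n

    dose = np.where(
        rng.random(n) < config.zero_mass,
        0.0,
        rng.lognormal(config.dose_log_mean, config.dose_log_sd, n),
    )

    if config.effect_model == "linear":
        f = dose
    else:
        q = np.quantile(dose, config.threshold_quantile)
        f = dose * (dose > q)

    hazard = config.baseline_hazard * np.exp(config.beta_dose * f)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / config.censor_rate, n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    enrol_age = np.clip(
        rng.normal(config.enrol_age_mean, config.enrol_age_sd, n), 40.0, 70.0
    )
    sex = np.where(rng.random(n) < 0.5, "male", "female")

    return pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "dose": dose,
            "time": time,
            "event": event,
            "enrol_age": enrol_age,
            "sex": sex,
        }
    )


@dataclass
class GenotypeSimConfig:
    """Rare-variant carrier package for the gene-burden arm.

    Per gene, carrier status of a qualifying loss-of-function variant is
    Bernoulli(``carrier_freq``) in controls; for ``signal_genes`` the case
    carrier odds are multiplied by the configured odds ratio. Each gene also
    gets a common missense variant (MAF >= 1%) so the LOF filter is exercised.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_genes: int = 100
    carrier_freq: float = 0.02
    signal_genes: list[tuple[int, float]] = field(default_factory=list)
    n_covariates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("n_cases and n_controls must be >= 1")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if not (0.0 < self.carrier_freq < 1.0):
            raise ParameterError("carrier_freq must be in (0, 1)")
        for idx, odds_ratio in self.signal_genes:
            if not 0 <= idx < self.n_genes:
                raise ParameterError(f"signal gene index {idx} out of range")
            if odds_ratio <= 0:
                raise ParameterError("signal gene odds ratios must be > 0")
        if self.n_covariates < 0:
            raise ParameterError("n_covariates must be >= 0")


def gen_genotypes(
    config: GenotypeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (carrier matrix, phenotype table, variant annotation table).

    The carrier matrix is samples x variants with 0/1 entries. Each gene has
    two qualifying variants (nonsense + splice-site, each MAF < 1%) among
    which gene-level carriers are split at random, plus one common missense
    variant that the LOF filter must discard.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    phenotype = np.array([1] * config.n_cases + [0] * config.n_controls)

    signal = dict(config.signal_genes)
    base_odds = config.carrier_freq / (1.0 - config.carrier_freq)

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    variant_rows = []
    columns = {}
    for g_idx, gene in enumerate(genes):
        odds_ratio = signal.get(g_idx, 1.0)
        case_odds = base_odds * odds_ratio
        p_case = case_odds / (1.0 + case_odds)
        p = np.where(phenotype == 1, p_case, config.carrier_freq)
        carrier = (rng.random(n) < p).astype(np.int8)

        v_nonsense = f"{gene}_lof1"
        v_splice = f"{gene}_lof2"
        v_missense = f"{gene}_mis1"
        # split gene-level carriers between the two qualifying variants
        pick = rng.random(n) < 0.5
        columns[v_nonsense] = carrier * pick
        columns[v_splice] = carrier * ~pick
        mis_freq = rng.uniform(0.05, 0.3)
        columns[v_missense] = (rng.random(n) < mis_freq).astype(np.int8)

        variant_rows.append((v_nonsense, gene, "nonsense", config.carrier_freq / 4))
        variant_rows.append((v_splice, gene, "splice-site", config.carrier_freq / 4))
        variant_rows.append((v_missense, gene, "missense", min(mis_freq, 0.5)))

    carrier_matrix = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    carrier_matrix = carrier_matrix.astype(np.int8)

    pheno = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": phenotype,
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        }
    )
    for c in range(config.n_covariates):
        pheno[f"cov{c + 1}"] = rng.normal(0.0, 1.0, n)

    variants = pd.DataFrame(
        variant_rows, columns=["variant_id", "gene", "consequence", "maf"]
    )
    return carrier_matrix, pheno, variants


def gen_gene_sets(
    universe_size: int,
    size_a: int,
    size_b: int,
    overlap: int,
    seed: int = 0,
) -> tuple[set[str], set[str], set[str]]:
    """Generate two gene sets with an exactly specified overlap in a universe."""
    if overlap > min(size_a, size_b):
        raise ParameterError("overlap cannot exceed the smaller set size")
    if max(size_a, size_b) > universe_size:
        raise ParameterError("set sizes cannot exceed the universe size")
    if size_a + size_b - overlap > universe_size:
        raise ParameterError("requested sets do not fit in the universe")
    rng = np.random.default_rng(seed)
    universe = [f"G{i + 1:05d}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    shared = [universe[i] for i in perm[:overlap]]
    a_only = [universe[i] for i in perm[overlap : size_a]]
    b_only = [universe[i] for i in perm[size_a : size_a + size_b - overlap]]
    return set(shared + a_only), set(shared + b_only), set(universe)
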