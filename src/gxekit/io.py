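"""Readers/writers for the plain-text table dialects used by the pipeline.

All tables are TSV/CSV with mandatory headers. Output files carry a leading
comment block (``# key: value`` lines) recording the package version, the
parameters and the seed of the run; readers skip those lines. Malformed rows
are rejected with their line numbers in the log; a missing column is a hard
error naming it.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_cohort",
    "write_cohort",
    "read_variants",
    "read_carrier_matrix",
    "read_gene_set",
    "write_gene_set",
    "write_table",
    "stage_seed",
]

SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]
COHORT_COLUMNS = ["id", "dose", "time", "event", "enrol_age", "sex"]
VARIANT_COLUMNS = ["variant_id", "gene", "consequence", "maf"]
CONSEQUENCES = {"nonsense", "splice-site", "missense", "synonymous", "other"}
_VALID_ALLELES = {"A", "C", "G", "T"}


def stage_seed(global_seed: int, stage: int) -> int:
    """Expand one global seed into per-stage sub-seeds by a fixed counter
    scheme: sub-seed k of seed s is SeedSequence(s).spawn-equivalent
    (s * 1000003 + k) mod 2^31, so stages can be re-run alone."""
    return (int(global_seed) * 1_000_003 + int(stage)) % (2**31)


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"{path}: missing required column(s) {missing}")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    params: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    """Write a table with a ``#``-comment header block (version, params)."""
    from . import __version__

    lines = [f"# gxekit_version: {__version__}"]
    for key, value in (params or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        # %.17g guarantees bit-exact float round-trips (and >= 6 significant
        # digits on p-values, which FDR ordering depends on)
        df.to_csv(fh, sep=sep, index=index, float_format="%.17g")


def _read_commented(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype={"chrom": str})


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV, validating every row.

    Rows with nonpositive se, p outside (0, 1], invalid or identical
    alleles, or eaf outside (0, 1) are rejected and logged with their line
    numbers; allele case is normalized to upper.
    """
    df = _read_commented(path, "\t")
    _require_columns(df, SUMSTAT_COLUMNS, path)
    df = df[SUMSTAT_COLUMNS].copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    ok = (
        (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & (df["eaf"] > 0)
        & (df["eaf"] < 1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
    )
    if (~ok).any():
        for i in df.index[~ok]:
            logger.warning("%s: rejected malformed row at data line %d", path, i + 1)
    return df[ok].reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path: str | Path, **params) -> None:
    write_table(df[SUMSTAT_COLUMNS], path, sep="\t", params=params)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the cohort CSV (id, dose, time, event, enrol_age, sex, covariates...)."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, COHORT_COLUMNS, path)
    bad_event = ~df["event"].isin((0, 1))
    bad_sex = ~df["sex"].isin(("male", "female"))
    bad = bad_event | bad_sex | (df["time"] <= 0) | (df["dose"] < 0)
    if bad.any():
        for i in df.index[bad]:
            logger.warning("%s: rejected malformed cohort row at data line %d", path, i + 1)
    return df[~bad].reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path: str | Path, **params) -> None:
    write_table(df, path, sep=",", params=params)


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read the variant annotation TSV (variant_id, gene, consequence, maf)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, VARIANT_COLUMNS, path)
    unknown = ~df["consequence"].isin(CONSEQUENCES)
    if unknown.any():
        first = df.index[unknown][0]
        raise ParameterError(
            f"{path}: unknown consequence {df['consequence'][first]!r} at data line {first + 1}"
        )
    if ((df["maf"] <= 0) | (df["maf"] > 0.5)).any():
        raise ParameterError(f"{path}: maf must be in (0, 0.5]")
    return df[VARIANT_COLUMNS].copy()


def read_carrier_matrix(path: str | Path) -> pd.DataFrame:
    """Read a dense samples x variants 0/1 TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ParameterError(f"{path}: carrier matrix entries must be 0/1")
    return df.astype(np.int8)


def read_gene_set(path: str | Path) -> set[str]:
    """Read a newline-delimited gene symbol list; duplicates are dropped
    with a warning."""
    symbols = [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    if len(symbols) != len(set(symbols)):
        logger.warning("%s: %d duplicate symbols de-duplicated",
                       path, len(symbols) - len(set(symbols)))
    return set(symbols)


def write_gene_set(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(set(symbols))) + "\n")
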