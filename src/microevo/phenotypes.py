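"""Phenotype records and the study's inclusion rules.

A phenotype table has one row per capture: id, weight (kg), capture_age
(months), capture_year, capture_month, sex.  Repeated measures per
individual are retained throughout; the inclusion rules keep only August
captures of animals at least 28 months old, which removes most growth
effects from the adult-weight analysis.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "weight", "capture_age", "capture_year", "capture_month", "sex")
AUGUST = 8


class PhenotypeError(ValueError):
    pass


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"phenotype table missing columns: {missing}")
    df = df.copy()
    df["id"] = df["id"].astype(str)
    df["weight"] = df["weight"].astype(float)
    df["capture_age"] = df["capture_age"].astype(float)
    df["capture_year"] = df["capture_year"].astype(int)
    df["capture_month"] = df["capture_month"].astype(int)
    df["sex"] = df["sex"].astype(str).str.upper().str[:1]
    if (df["weight"] <= 0).any():
        raise PhenotypeError("weights must be positive")
    if (df["capture_age"] < 0).any():
        raise PhenotypeError("capture ages must be non-negative")
    return df


def read_phenotypes(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, sep=None, engine="python"))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def filter_phenotypes(
    records: pd.DataFrame, min_age_months: float = 28, month: int = AUGUST
) -> pd.DataFrame:
    """Keep August captures of animals at least ``min_age_months`` old.

    The age boundary is inclusive; repeated measures per individual are kept.
    """
    records = validate_phenotypes(records)
    keep = (records["capture_month"] == month) & (records["capture_age"] >= min_age_months)
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("phenotype filter removed every record")
    else:
        logger.info("phenotype filter kept %d of %d records", len(out), len(records))
    return out
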