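"""Reading and writing the tabular formats used throughout the pipeline.

Two kinds of table circulate:

* **household surveys** — one row per household, a ``district`` label column
  plus binary (0/1) asset-ownership indicator columns;
* **district tables** — one row per district with its population, its
  normalized asset index, its under-five severe-stunting rate, and the
  population-weighting/share columns derived from them.

Both are plain UTF-8 CSV with a mandatory header.  Thousands separators
("1,897,167"-style) are stripped on read; files are written without them.

The module also ships, as package data, the published scoring-weight table
(per-variable mean, standard deviation and first-principal-component factor
score from the Malawi MICS 2006 analysis) and the published district table
(2008 populations, normalized asset indices, weighted populations and
shares for the 26 districts with survey coverage).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISTRICT_COLUMN = "district"

#: Canonical district-table column names.
DISTRICT_TABLE_COLUMNS = (
    DISTRICT_COLUMN,
    "population_2008",
    "normalized_asset_index",
    "weighted_population_asset",
    "weighted_population_stunting",
    "share_asset_pct",
    "share_stunting_pct",
    "stunting_rate",
)

_FIXTURES = {"table2": "table2.csv", "table3": "table3.csv"}


class SurveyFormatError(ValueError):
    """A household-survey file violates the binary-indicator contract."""


def _strip_thousands(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            cleaned = df[col].astype(str).str.replace(",", "", regex=False)
            converted = pd.to_numeric(cleaned, errors="coerce")
            if converted.notna().all():
                df[col] = converted
    return df


def read_household_survey(
    path: str | Path, schema: Iterable[str] | str = "infer"
) -> pd.DataFrame:
    """Read a household asset survey CSV.

    Parameters
    ----------
    path:
        CSV file with a ``district`` column and one 0/1 column per asset
        indicator.
    schema:
        Either ``"infer"`` (all non-district columns are indicators, in file
        order) or an explicit ordered list of indicator names that must all
        be present; columns are returned in that order.

    Returns
    -------
    pandas.DataFrame
        ``district`` label column first, then integer 0/1 indicator columns,
        rows in file order.

    Raises
    ------
    SurveyFormatError
        If the district column is missing or any indicator cell is not
        exactly 0 or 1 (the error names the offending row and column).
    """
    df = pd.read_csv(path)
    if DISTRICT_COLUMN not in df.columns:
        raise SurveyFormatError(
            f"{path}: missing required column '{DISTRICT_COLUMN}'"
        )
    if schema == "infer":
        indicators = [c for c in df.columns if c != DISTRICT_COLUMN]
    else:
        indicators = list(schema)
        missing = [c for c in indicators if c not in df.columns]
        if missing:
            raise SurveyFormatError(f"{path}: missing indicator columns {missing}")
    for col in indicators:
        values = df[col]
        bad = ~values.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SurveyFormatError(
                f"{path}: non-binary value {values.iloc[row]!r} in column "
                f"'{col}', data row {row}"
            )
        df[col] = values.astype(np.int64)
    out = df[[DISTRICT_COLUMN] + indicators].copy()
    out[DISTRICT_COLUMN] = out[DISTRICT_COLUMN].astype(str)
    logger.info(
        "read %d household records (%d indicators) from %s",
        len(out), len(indicators), path,
    )
    return out


def write_household_survey(survey: pd.DataFrame, path: str | Path) -> None:
    """Write a household survey to CSV (inverse of :func:`read_household_survey`)."""
    survey.to_csv(path, index=False)


def read_district_table(path: str | Path) -> pd.DataFrame:
    """Read a district table CSV, stripping thousands separators.

    Only ``district`` is mandatory; any subset of the canonical numeric
    columns may be present.  District names are stripped of surrounding
    whitespace.
    """
    df = pd.read_csv(path)
    if DISTRICT_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column '{DISTRICT_COLUMN}'")
    df = _strip_thousands(df)
    df[DISTRICT_COLUMN] = df[DISTRICT_COLUMN].astype(str).str.strip()
    return df


def write_district_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a district table to CSV at full float precision."""
    table.to_csv(path, index=False)


def load_published_table(name: str) -> pd.DataFrame:
    """Load a packaged published table.

    ``"table2"`` is the scoring-weight table: per retained survey variable
    its sample mean, standard deviation and first-principal-component factor
    score (26 rows).  ``"table3"`` is the district table: 2008 population,
    normalized asset index, the two weighted-population columns and the two
    share columns for the 26 districts (two newer districts had no separate
    survey coverage).
    """
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(_FIXTURES)}"
        )
    ref = resources.files("needsalloc.data").joinpath(_FIXTURES[name])
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    if name == "table3":
        df[DISTRICT_COLUMN] = df[DISTRICT_COLUMN].astype(str).str.strip()
    return df


def match_district(table: pd.DataFrame, name: str) -> pd.Series:
    """Return the row for ``name``, matched case-insensitively after trimming."""
    key = name.strip().lower()
    names = table[DISTRICT_COLUMN].str.strip().str.lower()
    hits = table[names == key]
    if len(hits) != 1:
        raise KeyError(f"district {name!r}: {len(hits)} matches")
    return hits.iloc[0]


def derive_implied_stunting(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``stunting_rate`` by inverting the population weighting.

    The stunting weighting multiplies population by ``1 + stunting_rate``,
    so the rate implied by a district table is
    ``weighted_population_stunting / population_2008 - 1``.  Values outside
    [0, 1] are reported via a warning but not clipped.
    """
    for col in ("population_2008", "weighted_population_stunting"):
        if col not in table.columns:
            raise ValueError(f"derive_implied_stunting: missing column '{col}'")
    if (table["population_2008"] <= 0).any():
        raise ValueError("derive_implied_stunting: nonpositive population")
    out = table.copy()
    rate = out["weighted_population_stunting"] / out["population_2008"] - 1.0
    outside = (rate < 0) | (rate > 1)
    if outside.any():
        logger.warning(
            "implied stunting rate outside [0, 1] for districts: %s",
            out.loc[outside, DISTRICT_COLUMN].tolist(),
        )
    out["stunting_rate"] = rate
    return out
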