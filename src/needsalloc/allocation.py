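"""Needs-based capitation: weighted populations, shares, and budget splits.

District need is proxied by population weighted by a socioeconomic
indicator.  Two weightings are supported:

* **asset** (composite): ``population * normalized_asset_index``;
* **stunting** (simple): ``population * (1 + stunting_rate)``, the form
  that reproduces the published weighted-population column (every published
  ratio of stunting-weighted population to population lies in [1.1, 1.3],
  i.e. 1 plus a severe-stunting proportion).

A district's capitation share is its fraction of the national weighted
population.  The full allocation formula splits a recurrent budget ``B``
over districts through weighted variable shares,

    x_i = B * sum_n a_n * V_ni / sum_j V_nj

with nonnegative policy weights ``a_n`` summing to one — the additive form
that conserves the budget exactly.  Monetary results can be rounded to a
currency unit by largest-remainder apportionment, which preserves the total
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: indicator name -> (required column, multiplier function)
_INDICATORS = {
    "asset": "normalized_asset_index",
    "stunting": "stunting_rate",
}


@dataclass(frozen=True)
class AllocationConfig:
    """Budget and per-variable policy weights ``a_n``.

    Weights must be nonnegative; with ``normalize_weights`` (default) they
    are rescaled to sum to one, otherwise they must already do so.
    """

    total_budget: float
    variables: tuple[tuple[str, float], ...] = (("weighted_population", 1.0),)
    normalize_weights: bool = True

    def weights(self) -> pd.Series:
        names = [n for n, _ in self.variables]
        w = np.array([float(a) for _, a in self.variables])
        if (w < 0).any():
            raise ValueError("policy weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("policy weights sum to zero")
        if self.normalize_weights:
            w = w / total
        elif abs(total - 1.0) > 1e-9:
            raise ValueError(f"policy weights sum to {total}, not 1")
        return pd.Series(w, index=names, name="a_n")


@dataclass(frozen=True)
class AllocationResult:
    """Per-district allocation ``x_i`` with the shares it derives from."""

    allocations: pd.Series  # currency
    shares: pd.Series  # percent, sums to 100
    total_budget: float
    weighted_population: pd.Series | None = field(default=None)


def weight_population(table: pd.DataFrame, indicator: str) -> pd.Series:
    """Weighted population under the chosen indicator.

    ``asset``: population times the normalized asset index.
    ``stunting``: population times ``1 + stunting_rate``.
    """
    if indicator not in _INDICATORS:
        raise ValueError(
            f"unknown indicator {indicator!r}; choose from {sorted(_INDICATORS)}"
        )
    col = _INDICATORS[indicator]
    if col not in table.columns:
        raise ValueError(f"indicator {indicator!r} requires column '{col}'")
    if "population_2008" not in table.columns:
        raise ValueError("missing column 'population_2008'")
    pop = table["population_2008"].astype(float)
    if indicator == "asset":
        weighted = pop * table[col]
    else:
        weighted = pop * (1.0 + table[col])
    weighted.name = f"weighted_population_{indicator}"
    if "district" in table.columns:
        weighted.index = pd.Index(table["district"], name="district")
    return weighted


def compute_shares(weighted: pd.Series) -> pd.Series:
    """Percent share of the national weighted population per district."""
    total = float(weighted.sum())
    if total <= 0:
        raise ValueError("total weighted population must be positive")
    shares = 100.0 * weighted / total
    shares.name = "share_pct"
    return shares


def allocate(config: AllocationConfig, variables: pd.DataFrame) -> AllocationResult:
    """Split the budget over districts via weighted variable shares.

    ``variables`` is a district-by-variable matrix of nonnegative values
    ``V_ni`` (rows indexed by district).  Each variable is converted to a
    within-variable share and the shares are combined with the policy
    weights: ``x_i = B * sum_n a_n * V_ni / sum_j V_nj``.  The budget is
    conserved exactly up to float precision.
    """
    w = config.weights()
    missing = [n for n in w.index if n not in variables.columns]
    if missing:
        raise ValueError(f"variable matrix missing columns: {missing}")
    V = variables[list(w.index)].astype(float)
    if (V < 0).to_numpy().any():
        raise ValueError("variable values must be nonnegative")
    col_sums = V.sum(axis=0)
    dead = col_sums[col_sums <= 0].index.tolist()
    if dead:
        raise ValueError(f"variable columns sum to zero: {dead}")
    shares_frac = (V / col_sums) @ w  # sum_n a_n V_ni / sum_j V_nj
    allocations = config.total_budget * shares_frac
    allocations.name = "allocation"
    shares = 100.0 * shares_frac
    shares.name = "share_pct"
    return AllocationResult(
        allocations=allocations, shares=shares, total_budget=config.total_budget
    )


def round_to_currency(result: AllocationResult, unit: float = 1.0) -> AllocationResult:
    """Round allocations to a currency unit by largest-remainder apportionment.

    The rounded amounts sum to the budget exactly in currency units
    (the budget itself is rounded to the nearest unit if needed).
    """
    if unit <= 0:
        raise ValueError("currency unit must be positive")
    x = result.allocations / unit
    budget_units = int(round(result.total_budget / unit))
    floors = np.floor(x.to_numpy())
    remainder = int(budget_units - floors.sum())
    rounded = floors.copy()
    if remainder > 0:
        top = np.argsort(-(x.to_numpy() - floors), kind="stable")[:remainder]
        rounded[top] += 1
    elif remainder < 0:  # only possible when the budget is not a whole number of units
        bottom = np.argsort(x.to_numpy() - floors, kind="stable")[: -remainder]
        rounded[bottom] -= 1
    allocations = pd.Series(
        rounded * unit, index=result.allocations.index, name="allocation"
    )
    return AllocationResult(
        allocations=allocations,
        shares=result.shares,
        total_budget=budget_units * unit,
        weighted_population=result.weighted_population,
    )


def allocate_by_indicator(
    table: pd.DataFrame, indicator: str, total_budget: float
) -> AllocationResult:
    """Single-variable capitation on a weighted population column."""
    weighted = weight_population(table, indicator)
    shares = compute_shares(weighted)
    allocations = total_budget * shares / 100.0
    allocations.name = "allocation"
    return AllocationResult(
        allocations=allocations,
        shares=shares,
        total_budget=total_budget,
        weighted_population=weighted,
    )
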