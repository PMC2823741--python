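"""Comparing the simple and composite weighting schemes.

The two schemes are compared on the district capitation shares they
produce: tie-aware Spearman rank correlation with a t-based significance
call, per-district percentage-point (pp) differences, classification of
districts by which indicator favours them, subgroup means of the absolute
differences, and (for monetary allocations) relative differences against a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import AllocationResult
from .io import DISTRICT_COLUMN


class SpearmanResult(NamedTuple):
    rho: float
    t_stat: float
    p_value: float
    significant: bool
    alpha: float


def spearman_rho(x, y, alpha: float = 0.01) -> SpearmanResult:
    """Spearman rank correlation with midrank ties and a t-test.

    ``rho`` is the Pearson correlation of the average-rank (midrank)
    vectors.  Significance uses the large-sample statistic
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` against Student-t with
    ``n - 2`` degrees of freedom, two-sided.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 observations, or a constant
        vector (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        t = np.inf if rho > 0 else -np.inf
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    p = float(p)
    return SpearmanResult(rho, float(t), p, p < alpha, alpha)


@dataclass(frozen=True)
class ComparisonSummary:
    """Paired-indicator share comparison.

    ``pp_difference`` is simple minus composite (stunting share minus asset
    share) in percentage points; a positive value means the simple
    indicator favours the district.
    """

    table: pd.DataFrame  # district, share_asset_pct, share_stunting_pct, pp_difference
    rho: float
    significant_at_1pct: bool
    p_value: float
    n_higher_simple: int
    n_higher_composite: int
    n_ties: int
    mean_pp_higher_simple: float
    mean_pp_higher_composite: float
    named_gains: dict[str, float]  # composite-favoured district -> pp gain
    degenerate: str | None = None


def compare_shares(table: pd.DataFrame, alpha: float = 0.01) -> ComparisonSummary:
    """Compare the two share columns of a district table.

    Classification and subgroup means use full-precision shares; rounding
    to 2 dp happens only at presentation time.
    """
    for col in ("share_asset_pct", "share_stunting_pct"):
        if col not in table.columns:
            raise ValueError(f"compare_shares: missing column '{col}'")
    out = table[[DISTRICT_COLUMN, "share_asset_pct", "share_stunting_pct"]].copy()
    diff = out["share_stunting_pct"] - out["share_asset_pct"]
    out["pp_difference"] = diff

    degenerate = None
    try:
        sp = spearman_rho(out["share_asset_pct"], out["share_stunting_pct"], alpha)
        rho, p, sig = sp.rho, sp.p_value, sp.significant
    except ValueError:
        identical = np.allclose(out["share_asset_pct"], out["share_stunting_pct"])
        degenerate = "degenerate: identical" if identical else "degenerate: constant"
        rho, p, sig = float("nan"), float("nan"), False

    higher_simple = diff > 0
    higher_composite = diff < 0
    gains = {
        str(d): float(-g)
        for d, g in zip(out[DISTRICT_COLUMN][higher_composite], diff[higher_composite])
    }
    return ComparisonSummary(
        table=out,
        rho=rho,
        significant_at_1pct=sig,
        p_value=p,
        n_higher_simple=int(higher_simple.sum()),
        n_higher_composite=int(higher_composite.sum()),
        n_ties=int((diff == 0).sum()),
        mean_pp_higher_simple=float(diff[higher_simple].abs().mean()),
        mean_pp_higher_composite=float(diff[higher_composite].abs().mean()),
        named_gains=gains,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class AllocationComparison:
    table: pd.DataFrame  # district, allocation_a, allocation_b, relative_diff_pct
    threshold_pct: float
    n_above_threshold: int
    mean_below_threshold: float
    rho: float
    degenerate: str | None = None


def compare_allocations(
    a: AllocationResult,
    b: AllocationResult,
    threshold: float = 10.0,
    denominator: str = "max",
) -> AllocationComparison:
    """Relative differences between two monetary allocations.

    The relative difference for district i is
    ``100 * |x_i^a - x_i^b| / D_i`` with ``D_i`` set by ``denominator``:
    ``"max"`` (default; symmetric and bounded by 100%), ``"a"`` or ``"b"``.
    """
    xa, xb = a.allocations, b.allocations
    if not xa.index.equals(xb.index):
        raise ValueError("allocation district sets differ")
    if abs(a.total_budget - b.total_budget) > 1e-6 * max(a.total_budget, 1.0):
        raise ValueError("allocations drawn from different budgets")
    denom = {
        "max": np.maximum(xa, xb),
        "a": xa,
        "b": xb,
    }.get(denominator)
    if denom is None:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    rel = 100.0 * (xa - xb).abs() / denom
    above = rel > threshold
    degenerate = None
    try:
        rho = spearman_rho(xa, xb).rho
    except ValueError:
        degenerate = (
            "degenerate: identical" if np.allclose(xa, xb) else "degenerate: constant"
        )
        rho = float("nan")
    table = pd.DataFrame(
        {
            DISTRICT_COLUMN: xa.index,
            "allocation_a": xa.to_numpy(),
            "allocation_b": xb.to_numpy(),
            "relative_diff_pct": rel.to_numpy(),
        }
    )
    below = rel[~above]
    return AllocationComparison(
        table=table,
        threshold_pct=threshold,
        n_above_threshold=int(above.sum()),
        mean_below_threshold=float(below.mean()) if len(below) else float("nan"),
        rho=rho,
        degenerate=degenerate,
    )


def population_summaries(
    table: pd.DataFrame,
    big_set: list[str],
    national_total: int,
    n_total_districts: int,
) -> tuple[float, float]:
    """Mean population of a named district set and of all remaining districts.

    The remainder mean is computed against the *national* total and
    district count, so districts absent from the table (here the two
    districts without survey coverage) are included in the remainder.
    """
    names = set(n.strip().lower() for n in big_set)
    mask = table[DISTRICT_COLUMN].str.strip().str.lower().isin(names)
    if mask.sum() != len(big_set):
        missing = names - set(
            table[DISTRICT_COLUMN].str.strip().str.lower()[mask]
        )
        raise ValueError(f"districts not found in table: {sorted(missing)}")
    if len(big_set) >= n_total_districts:
        raise ValueError("big_set must be a proper subset of all districts")
    big_pop = table.loc[mask, "population_2008"]
    big_mean = float(big_pop.mean())
    remainder_mean = (national_total - float(big_pop.sum())) / (
        n_total_districts - len(big_set)
    )
    return big_mean, remainder_mean


def render_report(summary: ComparisonSummary, out: str | Path) -> dict[str, Path]:
    """Write the per-district comparison CSV and a paired-share bar chart.

    ``out`` is a directory; returns the paths written
    (``comparison.csv``, ``shares.png``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "comparison.csv"
    summary.table.to_csv(csv_path, index=False)

    t = summary.table
    pos = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(11, 5))
    ax.bar(pos - 0.2, t["share_asset_pct"], width=0.4, label="composite (asset index)")
    ax.bar(pos + 0.2, t["share_stunting_pct"], width=0.4, label="simple (stunting)")
    ax.set_xticks(pos)
    ax.set_xticklabels(t[DISTRICT_COLUMN], rotation=90)
    ax.set_ylabel("share of national weighted population (%)")
    ax.legend()
    fig.tight_layout()
    png_path = out / "shares.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "plot": png_path}
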