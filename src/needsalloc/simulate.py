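"""Synthetic household-survey generator.

Emulates the data-generating structure the downstream analysis assumes: each
district has a latent socioeconomic status (SES), each household deviates
from its district's level, binary asset indicators load on household SES
through a logistic link, and the district's under-five severe-stunting rate
decreases (for a negative slope) in district SES, again on the log-odds
scale.

Mutually exclusive dwelling-characteristic blocks (water source, toilet
type, floor, roof, cooking fuel) are generated as a single categorical
draw per block — category probabilities are proportional to
``baseline_prevalence * exp(loading * ses)`` — so exactly one dummy per
block is 1, as in the real survey.

The default design mirrors the survey the analysis was built for: 26
districts, 1,200 households per district, and the published variable list
with baseline prevalences equal to the published sample means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import DISTRICT_COLUMN, load_published_table

#: Scale factor turning the published factor scores (unit-norm eigenvector
#: entries, magnitude ~0.1) into default logistic loadings of magnitude ~1,
#: a strong single-factor signal.
_DEFAULT_LOADING_SCALE = 10.0


@dataclass(frozen=True)
class VariableSpec:
    """One asset indicator: baseline prevalence and signed SES loading.

    ``group`` marks membership of a mutually exclusive category block
    (``None`` for a free-standing 0/1 asset).
    """

    name: str
    prevalence: float
    loading: float
    group: str | None = None


@dataclass(frozen=True)
class SurveyDesign:
    """Parameters of a synthetic household survey.

    Defaults are the study conditions: 26 districts of 1,200 households,
    the published variable list with strong loadings, district SES spread
    0.5 (half the within-district household SD), severe-stunting baseline
    0.20 with slope -0.5 on the log-odds scale.
    """

    n_districts: int = 26
    households_per_district: int = 1_200
    variables: tuple[VariableSpec, ...] = field(default_factory=lambda: default_variables())
    ses_spread: float = 0.5
    stunting_base: float = 0.20
    stunting_slope: float = -0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_districts < 2:
            raise ValueError("need at least 2 districts (comparison undefined)")
        if self.households_per_district < 1:
            raise ValueError("households_per_district must be positive")
        for v in self.variables:
            if not 0.0 < v.prevalence < 1.0:
                raise ValueError(f"prevalence of {v.name!r} not in (0, 1)")
        if sum(v.loading != 0 for v in self.variables) < 4:
            raise ValueError("need at least 4 variables with nonzero loading")
        if not 0.0 < self.stunting_base < 1.0:
            raise ValueError("stunting_base not in (0, 1)")
        if self.ses_spread < 0:
            raise ValueError("ses_spread must be nonnegative")


def default_variables(loading_scale: float = _DEFAULT_LOADING_SCALE) -> tuple[VariableSpec, ...]:
    """Variable list patterned on the published scoring table.

    Baseline prevalences are the published sample means; loadings are the
    published factor scores scaled by ``loading_scale`` so wealth markers
    (car, refrigerator, flush toilet, finished floor, ...) load positively
    and poverty markers (sand floor, thatch roof, wood fuel, ...) load
    negatively.
    """
    t2 = load_published_table("table2")
    specs = []
    for row in t2.itertuples(index=False):
        group = None if pd.isna(row.group) else str(row.group)
        specs.append(
            VariableSpec(
                name=str(row.variable),
                prevalence=float(row.mean),
                loading=float(row.factor_score) * loading_scale,
                group=group,
            )
        )
    return tuple(specs)


def district_names(n: int) -> list[str]:
    """Synthetic district labels; the published 26 names when ``n`` matches."""
    if n == 26:
        return load_published_table("table3")[DISTRICT_COLUMN].tolist()
    return [f"D{i + 1:02d}" for i in range(n)]


def default_populations(n: int) -> pd.Series:
    """Default district populations (published 2008 counts when ``n`` = 26)."""
    names = district_names(n)
    if n == 26:
        t3 = load_published_table("table3")
        return pd.Series(
            t3["population_2008"].to_numpy(), index=names, name="population_2008"
        )
    return pd.Series(np.full(n, 400_000), index=names, name="population_2008")


def generate_survey(design: SurveyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic survey and its ground truth.

    Returns
    -------
    survey : pandas.DataFrame
        One row per household: ``district`` plus 0/1 indicator columns in
        the design's variable order.
    truth : pandas.DataFrame
        One row per district: ``district``, ``latent_ses``,
        ``true_stunting_rate``.

    Notes
    -----
    District latent SES is Normal(0, ses_spread**2); household SES adds a
    standard-normal deviation.  A free-standing indicator is Bernoulli with
    log-odds ``logit(prevalence) + loading * household_ses``; a category
    block is one categorical draw with probabilities proportional to
    ``prevalence_c * exp(loading_c * household_ses)``.  Fully reproducible
    from ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    names = district_names(design.n_districts)
    n_hh = design.households_per_district

    z_district = rng.normal(0.0, design.ses_spread, size=design.n_districts)
    true_stunting = expit(
        logit(design.stunting_base) + design.stunting_slope * z_district
    )
    truth = pd.DataFrame(
        {
            DISTRICT_COLUMN: names,
            "latent_ses": z_district,
            "true_stunting_rate": true_stunting,
        }
    )

    ses = np.repeat(z_district, n_hh) + rng.normal(
        0.0, 1.0, size=design.n_districts * n_hh
    )
    n_total = ses.size
    data: dict[str, np.ndarray] = {
        DISTRICT_COLUMN: np.repeat(np.asarray(names, dtype=object), n_hh)
    }

    free = [v for v in design.variables if v.group is None]
    groups: dict[str, list[VariableSpec]] = {}
    for v in design.variables:
        if v.group is not None:
            groups.setdefault(v.group, []).append(v)

    for v in free:
        p = expit(logit(v.prevalence) + v.loading * ses)
        data[v.name] = (rng.random(n_total) < p).astype(np.int64)

    for members in groups.values():
        # category utilities: log baseline prevalence + loading * ses
        logp = np.stack(
            [np.log(v.prevalence) + v.loading * ses for v in members], axis=1
        )
        logp -= logp.max(axis=1, keepdims=True)
        probs = np.exp(logp)
        probs /= probs.sum(axis=1, keepdims=True)
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_total)
        choice = (u[:, None] > cum).sum(axis=1)
        for j, v in enumerate(members):
            data[v.name] = (choice == j).astype(np.int64)

    # restore design variable order
    survey = pd.DataFrame(data)[
        [DISTRICT_COLUMN] + [v.name for v in design.variables]
    ]
    return survey, truth


def true_district_table(
    truth: pd.DataFrame, populations: pd.Series | Sequence[int]
) -> pd.DataFrame:
    """Build a district table from ground truth and populations.

    The asset-index columns are left unset; the pipeline fills them after
    fitting the index to the survey.
    """
    pops = pd.Series(populations)
    if not pops.index.equals(pd.RangeIndex(len(pops))):
        # name-indexed: align explicitly
        missing = set(truth[DISTRICT_COLUMN]) - set(pops.index)
        extra = set(pops.index) - set(truth[DISTRICT_COLUMN])
        if missing or extra:
            raise ValueError(
                f"district mismatch between truth and populations: "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        pops = pops.reindex(truth[DISTRICT_COLUMN]).reset_index(drop=True)
    elif len(pops) != len(truth):
        raise ValueError(
            f"{len(pops)} populations for {len(truth)} districts"
        )
    if (pops <= 0).any():
        raise ValueError("populations must be positive")
    return pd.DataFrame(
        {
            DISTRICT_COLUMN: truth[DISTRICT_COLUMN].to_numpy(),
            "population_2008": pops.to_numpy(),
            "stunting_rate": truth["true_stunting_rate"].to_numpy(),
        }
    )


def with_seed(design: SurveyDesign, seed: int) -> SurveyDesign:
    """Copy of ``design`` with a different seed."""
    return replace(design, seed=seed)
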