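"""Reading and validating country indicator tables, and reconstructing
ordinal exposure levels from published weighted component scores.

The interchange format is UTF-8 CSV with a header row.  Expected columns
(renameable through ``column_map``)::

    country, che_per_capita_usd, external_share_pct, budget_space,
    debt_risk [, poverty_rate_pct]

Categorical fields are normalised to lower snake case through a synonym
table so that prose labels such as ``"In Debt Distress"`` or ``"N/A"``
ingest cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InconsistencyError, ValidationError

BUDGET_SPACE_CATEGORIES = ("expansion", "stagnation", "contraction")
DEBT_RISK_CATEGORIES = ("in_distress_or_very_high", "high", "moderate", "low_or_na")

#: Prose labels seen in source tables, mapped onto canonical categories.
BUDGET_SPACE_SYNONYMS: dict[str, str] = {
    "expansion": "expansion",
    "expand": "expansion",
    "expansionary": "expansion",
    "stagnation": "stagnation",
    "stagnant": "stagnation",
    "stagnate": "stagnation",
    "contraction": "contraction",
    "contract": "contraction",
    "contractionary": "contraction",
}

DEBT_RISK_SYNONYMS: dict[str, str] = {
    "in_distress_or_very_high": "in_distress_or_very_high",
    "in_debt_distress": "in_distress_or_very_high",
    "in_distress": "in_distress_or_very_high",
    "debt_distress": "in_distress_or_very_high",
    "very_high": "in_distress_or_very_high",
    "high": "high",
    "moderate": "moderate",
    "low": "low_or_na",
    "low_or_na": "low_or_na",
    "n_a": "low_or_na",
    "na": "low_or_na",
    "none": "low_or_na",
    "not_assessed": "low_or_na",
    "not_classified": "low_or_na",
}

REQUIRED_COLUMNS = (
    "country",
    "che_per_capita_usd",
    "external_share_pct",
    "budget_space",
    "debt_risk",
)
OPTIONAL_COLUMNS = ("poverty_rate_pct",)


def _snake(label: str) -> str:
    out = "".join(c if c.isalnum() else "_" for c in str(label).strip().lower())
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def normalize_category(value: str, synonyms: Mapping[str, str], field_name: str) -> str:
    key = _snake(value)
    if key not in synonyms:
        raise ValidationError(f"unknown {field_name} category: {value!r}")
    return synonyms[key]


@dataclass(frozen=True)
class CountryIndicatorRecord:
    """Raw health-financing and macro-fiscal indicators for one country.

    Attributes
    ----------
    country_name : str
    che_per_capita : float
        Current health expenditure per person per year, US$ (>= 0).
    external_share : float
        Share of current health expenditure financed from external
        sources, in percent (0-100).
    budget_space : str
        One of ``expansion`` / ``stagnation`` / ``contraction``.
    debt_risk : str
        One of ``in_distress_or_very_high`` / ``high`` / ``moderate`` /
        ``low_or_na``.
    poverty_rate : float or None
        Optional multidimensional poverty prevalence, percent.
    """

    country_name: str
    che_per_capita: float
    external_share: float
    budget_space: str
    debt_risk: str
    poverty_rate: float | None = None

    def __post_init__(self) -> None:
        if not str(self.country_name).strip():
            raise ValidationError("country_name must be non-empty")
        if not np.isfinite(self.che_per_capita) or self.che_per_capita < 0:
            raise ValidationError(
                f"{self.country_name}: che_per_capita must be >= 0, "
                f"got {self.che_per_capita!r}"
            )
        if not (0.0 <= self.external_share <= 100.0):
            raise ValidationError(
                f"{self.country_name}: external_share must be in [0, 100], "
                f"got {self.external_share!r}"
            )
        object.__setattr__(
            self,
            "budget_space",
            normalize_category(self.budget_space, BUDGET_SPACE_SYNONYMS, "budget_space"),
        )
        object.__setattr__(
            self,
            "debt_risk",
            normalize_category(self.debt_risk, DEBT_RISK_SYNONYMS, "debt_risk"),
        )
        if self.poverty_rate is not None and not (0.0 <= self.poverty_rate <= 100.0):
            raise ValidationError(
                f"{self.country_name}: poverty_rate must be in [0, 100], "
                f"got {self.poverty_rate!r}"
            )


@dataclass
class OrdinalDataset:
    """A countries x factors matrix of integer exposure levels.

    ``max_levels`` gives the highest attainable level per factor;
    ``norm_denominators`` the divisor used when scores are normalised
    (these may differ: the published capacity-to-borrow component is
    normalised by 5 although its scale tops out at level 4).
    """

    countries: list[str]
    levels: np.ndarray
    factor_names: list[str]
    max_levels: list[int]
    norm_denominators: list[int]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=int)
        n, k = self.levels.shape
        if len(self.countries) != n:
            raise ConfigurationError("countries length does not match level rows")
        if not (len(self.factor_names) == len(self.max_levels) == len(self.norm_denominators) == k):
            raise ConfigurationError("factor metadata lengths do not match level columns")
        for j, (name, mx) in enumerate(zip(self.factor_names, self.max_levels)):
            col = self.levels[:, j]
            if col.min() < 1 or col.max() > mx:
                raise ValidationError(
                    f"factor {name!r}: levels must lie in [1, {mx}], "
                    f"observed [{col.min()}, {col.max()}]"
                )

    @property
    def n_countries(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.countries, columns=self.factor_names)


def read_country_indicators(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[CountryIndicatorRecord]:
    """Read a per-country indicator CSV into validated records.

    ``column_map`` maps *actual* column names in the file onto the
    canonical names.  Rows failing validation are collected and reported
    together with their (1-based, header-excluded) row numbers.
    """
    df = pd.read_csv(path, encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValidationError(f"no records in {path}")

    records: list[CountryIndicatorRecord] = []
    failures: list[str] = []
    has_poverty = "poverty_rate_pct" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            pov = row.get("poverty_rate_pct") if has_poverty else None
            if pov is not None and pd.isna(pov):
                pov = None
            records.append(
                CountryIndicatorRecord(
                    country_name=str(row["country"]),
                    che_per_capita=float(row["che_per_capita_usd"]),
                    external_share=float(row["external_share_pct"]),
                    budget_space=str(row["budget_space"]),
                    debt_risk=str(row["debt_risk"]),
                    poverty_rate=None if pov is None else float(pov),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            failures.append(f"row {i}: {exc}")
    if failures:
        raise ValidationError(
            "invalid indicator rows:\n  " + "\n  ".join(failures)
        )
    return records


def write_country_indicators(records: Sequence[CountryIndicatorRecord], path: str | Path) -> None:
    rows = [
        {
            "country": r.country_name,
            "che_per_capita_usd": r.che_per_capita,
            "external_share_pct": r.external_share,
            "budget_space": r.budget_space,
            "debt_risk": r.debt_risk,
            "poverty_rate_pct": r.poverty_rate,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if all(r.poverty_rate is None for r in records):
        df = df.drop(columns=["poverty_rate_pct"])
    df.to_csv(path, index=False, encoding="utf-8")


def backout_levels(
    weighted_components: np.ndarray | pd.DataFrame,
    weights: Sequence[float],
    norm_denominators: Sequence[int],
    countries: Sequence[str] | None = None,
    factor_names: Sequence[str] | None = None,
    max_levels: Sequence[int] | None = None,
    rounding: float = 0.005,
) -> OrdinalDataset:
    """Invert published weighted component scores back to integer levels.

    A component printed at two decimals satisfies
    ``printed = level / denominator * weight`` up to +/- ``rounding``;
    the implied level is ``printed / weight * denominator`` and must fall
    within the propagated rounding band of an integer, otherwise the cell
    is inconsistent with the claimed weights and an
    :class:`~healthvuln.errors.InconsistencyError` is raised naming the
    country and factor.
    """
    if isinstance(weighted_components, pd.DataFrame):
        if countries is None:
            countries = list(weighted_components.index.astype(str))
        if factor_names is None:
            factor_names = list(weighted_components.columns)
        weighted_components = weighted_components.to_numpy(dtype=float)
    X = np.asarray(weighted_components, dtype=float)
    w = np.asarray(weights, dtype=float)
    den = np.asarray(norm_denominators, dtype=int)
    if np.any(w <= 0):
        raise ConfigurationError("all weights must be > 0 to invert component scores")
    n, k = X.shape
    if countries is None:
        countries = [f"row{i + 1}" for i in range(n)]
    if factor_names is None:
        factor_names = [f"factor{j + 1}" for j in range(k)]

    implied = X / w * den
    levels = np.rint(implied).astype(int)
    tol = rounding * den / w + 1e-6  # propagate the 2-dp print tolerance
    bad = np.abs(implied - levels) > tol
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InconsistencyError(
            f"{countries[i]} / {factor_names[j]}: component {X[i, j]} implies "
            f"level {implied[i, j]:.4f}, not an integer within +/-{tol[j]:.4g}"
        )
    if max_levels is None:
        # the scale maximum is unknowable from scores alone; default to the
        # observed maximum per factor
        max_levels = [int(levels[:, j].max()) for j in range(k)]
    return OrdinalDataset(
        countries=list(countries),
        levels=levels,
        factor_names=list(factor_names),
        max_levels=[int(m) for m in max_levels],
        norm_denominators=[int(d) for d in den],
    )
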