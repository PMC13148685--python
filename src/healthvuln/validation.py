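"""Validity-stage statistics: correlation / simple linear regression of
V-scores against an outcome series, and agreement between scoring
variants."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError


@dataclass
class ValidationResult:
    n: int
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "n_dropped": self.n_dropped,
        }


def correlate(scores: Sequence[float], outcome: Sequence[float]) -> ValidationResult:
    """Pearson r, OLS slope/intercept, R^2 and two-sided p-value for a
    paired score/outcome series; pairs with a missing value are dropped
    and counted in ``n_dropped``."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("scores and outcome must be equal-length 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(f"need at least 3 complete pairs, have {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined: zero variance in an input")
    fit = stats.linregress(x, y)
    return ValidationResult(
        n=int(x.size),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n_dropped=dropped,
    )


def method_agreement(
    score_table: pd.DataFrame, base: str = "polychoric_pca"
) -> pd.DataFrame:
    """Pearson r and r^2 of every scoring variant against the base method.

    ``score_table`` is countries x methods; constant columns are
    reported as undefined (NaN) rather than raising.
    """
    if base not in score_table.columns:
        raise ConfigurationError(f"base method {base!r} not in table columns")
    if score_table.shape[1] < 2 or score_table.shape[0] < 3:
        raise ValidationError("need >= 2 methods and >= 3 countries")
    rows = []
    b = score_table[base].to_numpy(dtype=float)
    for col in score_table.columns:
        if col == base:
            continue
        y = score_table[col].to_numpy(dtype=float)
        if np.ptp(b) == 0 or np.ptp(y) == 0:
            rows.append({"method": col, "r": np.nan, "r_squared": np.nan, "degenerate": True})
            continue
        r = float(stats.pearsonr(b, y).statistic)
        rows.append({"method": col, "r": r, "r_squared": r * r, "degenerate": False})
    return pd.DataFrame(rows).set_index("method")


def _norm_name(name: str) -> str:
    return " ".join(str(name).strip().lower().replace("’", "'").split())


#: Common alternative spellings for regional country names.
COUNTRY_ALIASES: dict[str, str] = {
    "cote d'ivoire": "côte d'ivoire",
    "ivory coast": "côte d'ivoire",
    "drc": "democratic republic of the congo",
    "dr congo": "democratic republic of the congo",
    "congo, dem. rep.": "democratic republic of the congo",
    "congo, rep.": "congo",
    "republic of the congo": "congo",
    "tanzania": "united republic of tanzania",
    "cape verde": "cabo verde",
    "swaziland": "eswatini",
    "the gambia": "gambia",
    "gambia, the": "gambia",
    "sao tome & principe": "sao tome and principe",
    "são tomé and príncipe": "sao tome and principe",
}


def join_outcome(
    scores: pd.DataFrame,
    outcome: pd.DataFrame,
    score_col: str = "v_score",
    outcome_col: str | None = None,
    country_col: str = "country",
) -> pd.DataFrame:
    """Join a results table with a user-supplied outcome series on a
    normalised country name (trim, case-fold, alias table).  Countries
    without an outcome survive the join with NaN so that
    :func:`correlate` can report them as dropped."""
    if outcome_col is None:
        candidates = [c for c in outcome.columns if c != country_col]
        if len(candidates) != 1:
            raise ConfigurationError(
                f"cannot infer outcome column from {list(outcome.columns)}; pass outcome_col"
            )
        outcome_col = candidates[0]

    def keyed(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["_key"] = (
            df[country_col].map(_norm_name).map(lambda k: COUNTRY_ALIASES.get(k, k))
        )
        return df

    left = keyed(scores)
    right = keyed(outcome)[["_key", outcome_col]]
    merged = left.merge(right, on="_key", how="left").drop(columns=["_key"])
    return merged
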