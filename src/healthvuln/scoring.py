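"""Composite vulnerability scores, archetype categorisation and summary
statistics.

The V-score for a country is the weighted sum of its normalised exposure
levels::

    v = sum_j  level_j / denominator_j * weight_j        (0-100 scale)

Two normalisation modes are provided.  ``"reproduction"`` (the default)
uses each factor's ``norm_denominator`` — (4, 5, 3, 5) for the standard
four factors, i.e. capacity to borrow divided by 5, which is what every
published component score and unweighted score encodes.  ``"eq1_literal"``
normalises by the scale maximum (4, 5, 3, 4), matching the printed form
of the scoring equation; under it a country at the worst level on every
factor scores exactly 100.

Archetype boundaries are half-open from below: scores below 40 are Low,
[40, 59.5) Moderate, [59.5, 73] High, above 73 Very High — the reading
consistent with all 47 published labels.

Reported values are rounded half-up to 2 decimals; internal arithmetic
is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .exposure import ExposureProfile
from .ingest import OrdinalDataset
from .weighting import WeightVector

ARCHETYPES = ("Low", "Moderate", "High", "Very High")
DEFAULT_CATEGORY_BOUNDS = (40.0, 59.5, 73.0)

MODES = ("reproduction", "eq1_literal")


def round2(x: float) -> float:
    """Round half-up to 2 decimals (published tables round 0.005 up, which
    bankers' rounding on binary floats does not reproduce)."""
    return math.floor(x * 100.0 + 0.5 + 1e-6) / 100.0


@dataclass
class VulnerabilityResult:
    """Component scores (unrounded), total and archetype for one country."""

    country_name: str
    factor_names: list[str]
    component_scores: np.ndarray
    v_score: float
    archetype: str
    mode: str

    def components_2dp(self) -> list[float]:
        return [round2(c) for c in self.component_scores]

    @property
    def v_score_2dp(self) -> float:
        return round2(self.v_score)


def component_score(level: int, denominator: int, weight: float) -> float:
    """One factor's contribution: ``level / denominator * weight``."""
    if level < 1 or level > denominator:
        # the scale maximum is itself <= the normalising denominator, so a
        # valid level can never exceed it
        raise ValidationError(
            f"level {level} outside [1, {denominator}] for this factor"
        )
    return level / denominator * weight


def _denominators(
    max_levels: Sequence[int], norm_denominators: Sequence[int], mode: str
) -> np.ndarray:
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "reproduction":
        return np.asarray(norm_denominators, dtype=float)
    return np.asarray(max_levels, dtype=float)


def vulnerability_score(
    profile: ExposureProfile | Sequence[int],
    weights: WeightVector,
    mode: str = "reproduction",
    max_levels: Sequence[int] | None = None,
    norm_denominators: Sequence[int] | None = None,
    country_name: str | None = None,
) -> VulnerabilityResult:
    """Score one country from its exposure levels.

    ``profile`` may be an :class:`~healthvuln.exposure.ExposureProfile`
    or a plain level sequence.  For the standard four factors the scale
    maxima (4, 5, 3, 4) and normalising denominators (4, 5, 3, 5) are
    implied; other factor sets must pass both explicitly.
    """
    if isinstance(profile, ExposureProfile):
        levels = np.asarray(profile.as_tuple(), dtype=int)
        name = country_name or profile.country_name
    else:
        levels = np.asarray(profile, dtype=int)
        name = country_name or "?"
    k = levels.size
    if len(weights.factor_names) != k:
        raise ConfigurationError(
            f"profile has {k} factors but weights cover {len(weights.factor_names)}"
        )
    if max_levels is None or norm_denominators is None:
        if k == 4:
            max_levels = (4, 5, 3, 4)
            norm_denominators = (4, 5, 3, 5)
        elif k == 5:
            max_levels = (4, 5, 3, 4, 5)
            norm_denominators = (4, 5, 3, 5, 5)
        else:
            raise ConfigurationError(
                "max_levels and norm_denominators are required for "
                f"non-standard factor sets (k={k})"
            )
    for lev, mx in zip(levels, max_levels):
        if not (1 <= lev <= mx):
            raise ValidationError(f"{name}: level {lev} outside [1, {mx}]")
    den = _denominators(max_levels, norm_denominators, mode)
    comps = levels / den * weights.weights
    v = float(comps.sum())
    return VulnerabilityResult(
        country_name=name,
        factor_names=list(weights.factor_names),
        component_scores=comps,
        v_score=v,
        archetype=categorize(v),
        mode=mode,
    )


def categorize(v_score: float, bounds: Sequence[float] = DEFAULT_CATEGORY_BOUNDS) -> str:
    """Map a 0-100 V-score onto its vulnerability archetype."""
    if not (0.0 <= v_score <= 100.0):
        raise ValidationError(f"v_score must be in [0, 100], got {v_score!r}")
    low, moderate, high = bounds
    if v_score < low:
        return "Low"
    if v_score < moderate:
        return "Moderate"
    if v_score <= high:
        return "High"
    return "Very High"


def score_dataset(
    data: OrdinalDataset, weights: WeightVector, mode: str = "reproduction"
) -> list[VulnerabilityResult]:
    """Score every country in an ordinal dataset."""
    if list(weights.factor_names) != list(data.factor_names):
        raise ConfigurationError(
            f"weights cover {weights.factor_names} but dataset has {data.factor_names}"
        )
    return [
        vulnerability_score(
            data.levels[i],
            weights,
            mode=mode,
            max_levels=data.max_levels,
            norm_denominators=data.norm_denominators,
            country_name=data.countries[i],
        )
        for i in range(data.n_countries)
    ]


def results_frame(results: Sequence[VulnerabilityResult]) -> pd.DataFrame:
    """Per-country results table with 2-dp component columns, total and
    archetype (input order preserved)."""
    if not results:
        raise ValidationError("no results")
    names = results[0].factor_names
    rows = []
    for r in results:
        row = {"country": r.country_name}
        row.update({f"{f}_component": c for f, c in zip(names, r.components_2dp())})
        row["v_score"] = r.v_score_2dp
        row["archetype"] = r.archetype
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    results: Sequence[VulnerabilityResult], data: OrdinalDataset | None = None
) -> dict:
    """Footer statistics and count tables.

    Returns per-component and total mean/min/max (2 dp, computed on the
    unrounded scores), archetype counts, and — when the level dataset is
    supplied — per-factor level frequency tables.
    """
    if not results:
        raise ValidationError("no results")
    names = results[0].factor_names
    comp = np.array([r.component_scores for r in results])
    tot = np.array([r.v_score for r in results])
    stats = {}
    for j, f in enumerate(names):
        stats[f] = {
            "mean": round2(comp[:, j].mean()),
            "min": round2(comp[:, j].min()),
            "max": round2(comp[:, j].max()),
        }
    stats["v_score"] = {
        "mean": round2(tot.mean()),
        "min": round2(tot.min()),
        "max": round2(tot.max()),
    }
    counts = {a: 0 for a in ARCHETYPES}
    for r in results:
        counts[r.archetype] += 1
    out = {"stats": stats, "archetype_counts": counts}
    if data is not None:
        freq = {}
        for j, f in enumerate(data.factor_names):
            levels, c = np.unique(data.levels[:, j], return_counts=True)
            freq[f] = {int(l): int(n) for l, n in zip(levels, c)}
        out["level_frequencies"] = freq
    return out
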