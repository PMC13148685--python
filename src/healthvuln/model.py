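"""Model / Results objects tying the pipeline together.

:class:`VulnerabilityIndex` is constructed from data (raw indicators,
integer exposure levels, or published weighted components) and holds the
modelling choices — weighting method, normalisation mode, category
bounds.  Its :meth:`~VulnerabilityIndex.fit` estimates the weights (or
adopts supplied ones), scores every country and returns a
:class:`VulnerabilityIndexResults` carrying the per-country scores,
archetypes, the weight vector with its diagnostics, the polychoric
matrix when one was estimated, and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .exposure import (
    DEFAULT_FACTORS,
    BandConfig,
    FactorSpec,
    build_profiles,
    profiles_to_dataset,
)
from .ingest import CountryIndicatorRecord, OrdinalDataset, backout_levels
from .polychoric import PolychoricResult, polychoric_matrix
from .scoring import (
    DEFAULT_CATEGORY_BOUNDS,
    VulnerabilityResult,
    results_frame,
    score_dataset,
    summarize,
)
from .validation import ValidationResult, correlate, join_outcome
from .weighting import WeightVector, derive_weights, user_weights


class VulnerabilityIndex:
    """Health-financing vulnerability index model.

    Parameters
    ----------
    data : OrdinalDataset
        Countries x factors matrix of integer exposure levels.
    method : str
        Weighting method for :meth:`fit` when no explicit weights are
        given: ``polychoric_pca`` (default), ``efa``, ``entropy`` or
        ``equal``.
    mode : str
        Score normalisation: ``reproduction`` (per-factor norm
        denominators; default) or ``eq1_literal`` (scale maxima).
    category_bounds : (float, float, float)
        Archetype boundaries (Low|Moderate|High|Very High).
    """

    def __init__(
        self,
        data: OrdinalDataset,
        method: str = "polychoric_pca",
        mode: str = "reproduction",
        category_bounds: Sequence[float] = DEFAULT_CATEGORY_BOUNDS,
    ):
        self.data = data
        self.method = method
        self.mode = mode
        self.category_bounds = tuple(category_bounds)

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def from_indicators(
        cls,
        records: Sequence[CountryIndicatorRecord] | pd.DataFrame,
        band_config: BandConfig | None = None,
        **kwargs,
    ) -> "VulnerabilityIndex":
        """Build from raw indicator records (or a DataFrame with the
        canonical indicator columns), banding them into levels."""
        if isinstance(records, pd.DataFrame):
            from .ingest import REQUIRED_COLUMNS

            missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
            if missing:
                raise ConfigurationError(f"missing column(s): {', '.join(missing)}")
            records = [
                CountryIndicatorRecord(
                    country_name=str(r["country"]),
                    che_per_capita=float(r["che_per_capita_usd"]),
                    external_share=float(r["external_share_pct"]),
                    budget_space=str(r["budget_space"]),
                    debt_risk=str(r["debt_risk"]),
                    poverty_rate=(
                        float(r["poverty_rate_pct"])
                        if "poverty_rate_pct" in r and pd.notna(r["poverty_rate_pct"])
                        else None
                    ),
                )
                for _, r in records.iterrows()
            ]
        profiles = build_profiles(list(records), band_config)
        return cls(profiles_to_dataset(profiles), **kwargs)

    @classmethod
    def from_levels(
        cls,
        levels: pd.DataFrame,
        factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
        **kwargs,
    ) -> "VulnerabilityIndex":
        """Build from a countries x factors table of integer levels
        (index = country names, columns matching the factor spec)."""
        factors = list(factors)
        cols = [f.name for f in factors]
        missing = [c for c in cols if c not in levels.columns]
        if missing:
            raise ConfigurationError(f"missing level column(s): {', '.join(missing)}")
        data = OrdinalDataset(
            countries=list(levels.index.astype(str)),
            levels=levels[cols].to_numpy(dtype=int),
            factor_names=cols,
            max_levels=[f.max_level for f in factors],
            norm_denominators=[f.norm_denominator for f in factors],
        )
        return cls(data, **kwargs)

    @classmethod
    def from_components(
        cls,
        components: pd.DataFrame,
        weights: Sequence[float] | WeightVector,
        factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
        **kwargs,
    ) -> "VulnerabilityIndex":
        """Build by inverting published weighted component scores back to
        integer levels (see :func:`healthvuln.ingest.backout_levels`)."""
        w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
        factors = list(factors)
        data = backout_levels(
            components.to_numpy(dtype=float),
            w,
            [f.norm_denominator for f in factors],
            countries=list(components.index.astype(str)),
            factor_names=[f.name for f in factors],
            max_levels=[f.max_level for f in factors],
        )
        return cls(data, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        weights: WeightVector | Sequence[float] | None = None,
        method: str | None = None,
        mode: str | None = None,
    ) -> "VulnerabilityIndexResults":
        """Estimate (or adopt) weights and score every country."""
        mode = mode or self.mode
        method = method or self.method
        poly: PolychoricResult | None = None
        if weights is not None:
            if not isinstance(weights, WeightVector):
                weights = user_weights(self.data.factor_names, weights)
        else:
            if method in ("polychoric_pca", "efa"):
                poly = polychoric_matrix(self.data)
            weights = derive_weights(self.data, method=method, poly=poly)
        results = score_dataset(self.data, weights, mode=mode)
        return VulnerabilityIndexResults(self, weights, results, poly, mode)


class VulnerabilityIndexResults:
    """Fit results: per-country scores plus estimation diagnostics."""

    def __init__(
        self,
        model: VulnerabilityIndex,
        weights: WeightVector,
        results: list[VulnerabilityResult],
        poly: PolychoricResult | None,
        mode: str,
    ):
        self.model = model
        self.weights = weights
        self.results = results
        self.polychoric = poly
        self.mode = mode

    @property
    def frame(self) -> pd.DataFrame:
        """Per-country table: levels, 2-dp components, total, archetype."""
        f = results_frame(self.results)
        lv = self.model.data.to_frame().reset_index(drop=True)
        lv.columns = [f"{c}_level" for c in lv.columns]
        return pd.concat([f[["country"]], lv, f.drop(columns=["country"])], axis=1)

    @property
    def scores(self) -> pd.Series:
        return pd.Series(
            [r.v_score_2dp for r in self.results],
            index=[r.country_name for r in self.results],
            name="v_score",
        )

    @property
    def archetypes(self) -> pd.Series:
        return pd.Series(
            [r.archetype for r in self.results],
            index=[r.country_name for r in self.results],
            name="archetype",
        )

    def summary_stats(self) -> dict:
        return summarize(self.results, self.model.data)

    def ranked_frame(self) -> pd.DataFrame:
        """Report presentation: countries sorted by descending V-score."""
        return self.frame.sort_values("v_score", ascending=False, kind="mergesort").reset_index(
            drop=True
        )

    def validate(
        self, outcome: pd.DataFrame | pd.Series, outcome_col: str | None = None
    ) -> ValidationResult:
        """Correlate the fitted V-scores against an external outcome
        series (joined on normalised country names when a DataFrame with
        a ``country`` column is given)."""
        if isinstance(outcome, pd.Series):
            aligned = outcome.reindex(self.scores.index)
            return correlate(self.scores.to_numpy(), aligned.to_numpy())
        merged = join_outcome(
            self.frame[["country", "v_score"]], outcome, outcome_col=outcome_col
        )
        ocol = [c for c in merged.columns if c not in ("country", "v_score")][-1]
        return correlate(merged["v_score"].to_numpy(), merged[ocol].to_numpy())

    def summary(self) -> str:
        """Readable fit summary: weights, score statistics, archetype
        counts."""
        s = self.summary_stats()
        lines = [
            "Health Financing Vulnerability Index",
            "=" * 54,
            f"Countries: {self.model.data.n_countries}    "
            f"Factors: {self.model.data.n_factors}    Mode: {self.mode}",
            f"Weighting: {self.weights.method}",
            "",
            "Weights (% contribution)",
            "-" * 32,
        ]
        for name, w in zip(self.weights.factor_names, self.weights.weights):
            lines.append(f"  {name:<12s} {w:8.2f}")
        if self.polychoric is not None:
            ev = self.weights.diagnostics.get("explained_variance")
            if ev is not None:
                lines.append(f"  PC1 explained variance: {100 * ev[0]:.1f}%")
            if self.polychoric.smoothed:
                lines.append("  note: polychoric matrix smoothed to nearest PSD")
        lines += [
            "",
            "V-score  mean {mean:6.2f}   min {min:6.2f}   max {max:6.2f}".format(
                **s["stats"]["v_score"]
            ),
            "",
            "Archetypes",
            "-" * 32,
        ]
        for a, c in s["archetype_counts"].items():
            lines.append(f"  {a:<12s} {c:4d}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<VulnerabilityIndexResults n={self.model.data.n_countries} "
            f"method={self.weights.method!r} mode={self.mode!r}>"
        )
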