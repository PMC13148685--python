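"""Ordinal exposure-level assignment for the four health-financing and
macro-fiscal factors of exposure.

Each factor maps a raw indicator onto an integer "level of exposure";
higher levels always mean a higher propensity to vulnerability.  Bands
are half-open and lower-inclusive on the risk-increasing side, closing
the gaps and overlaps that prose band descriptions leave open.

Default bands (per-capita spending in US$, aid share in %):

====================  =========================================  ======
factor                bands                                      levels
====================  =========================================  ======
che (CHE per capita)  <55 / [55,85) / [85,180) / >=180           4..1
fad (aid dependency)  [0,10) / [10,15) / [15,25) / [25,45) / >=45  1..5
bsp (budget space)    expansion / stagnation / contraction       1..3
ctb (borrow capacity) low_or_na / moderate / high / distress     1..4
====================  =========================================  ======
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError
from .ingest import CountryIndicatorRecord, OrdinalDataset

#: Dollar cut-points separating CHE per-capita levels 4|3|2|1 (20/40/60/80th
#: percentile of the 2022 regional distribution, kept fixed for
#: reproducibility; see :func:`che_cutpoints_from_percentiles`).
DEFAULT_CHE_CUTPOINTS: tuple[float, ...] = (55.0, 85.0, 180.0)

#: Percent cut-points separating aid-dependency levels 1|2|3|4|5.
DEFAULT_FAD_CUTPOINTS: tuple[float, ...] = (10.0, 15.0, 25.0, 45.0)

BSP_LEVELS = {"expansion": 1, "stagnation": 2, "contraction": 3}
CTB_LEVELS = {"low_or_na": 1, "moderate": 2, "high": 3, "in_distress_or_very_high": 4}


@dataclass(frozen=True)
class FactorSpec:
    """Name, scale maximum and normalisation denominator for one factor."""

    name: str
    max_level: int
    norm_denominator: int


#: The four-factor specification used throughout: note the
#: capacity-to-borrow factor is normalised by 5 although its scale tops
#: out at 4 — this is what the published component scores encode.
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("che", 4, 4),
    FactorSpec("fad", 5, 5),
    FactorSpec("bsp", 3, 3),
    FactorSpec("ctb", 4, 5),
)

POVERTY_FACTOR = FactorSpec("poverty", 5, 5)


@dataclass(frozen=True)
class ExposureProfile:
    """The ordinal exposure levels for one country."""

    country_name: str
    che_level: int
    fad_level: int
    bsp_level: int
    ctb_level: int
    poverty_level: int | None = None

    def as_tuple(self) -> tuple[int, ...]:
        base = (self.che_level, self.fad_level, self.bsp_level, self.ctb_level)
        return base if self.poverty_level is None else base + (self.poverty_level,)


def level_from_che(
    che_per_capita: float, cutpoints: Sequence[float] = DEFAULT_CHE_CUTPOINTS
) -> int:
    """Level 4 (most exposed) below the first cut-point down to level 1 at
    or above the last; non-increasing in spending."""
    if not np.isfinite(che_per_capita) or che_per_capita < 0:
        raise ValidationError(f"che_per_capita must be >= 0, got {che_per_capita!r}")
    n_bands = len(cutpoints) + 1
    return n_bands - int(np.searchsorted(cutpoints, che_per_capita, side="right"))


def level_from_fad(
    external_share: float, cutpoints: Sequence[float] = DEFAULT_FAD_CUTPOINTS
) -> int:
    """Level 1 for near self-financed systems up to level 5 at >=45% aid
    share; non-decreasing in dependency."""
    if not (0.0 <= external_share <= 100.0):
        raise ValidationError(f"external_share must be in [0, 100], got {external_share!r}")
    return 1 + int(np.searchsorted(cutpoints, external_share, side="right"))


def level_from_bsp(budget_space: str) -> int:
    try:
        return BSP_LEVELS[budget_space]
    except KeyError:
        raise ValidationError(f"unknown budget_space category: {budget_space!r}") from None


def level_from_ctb(debt_risk: str) -> int:
    try:
        return CTB_LEVELS[debt_risk]
    except KeyError:
        raise ValidationError(f"unknown debt_risk category: {debt_risk!r}") from None


def level_from_poverty(poverty_rate: float, quintile_cuts: Sequence[float]) -> int:
    """Quintile-based banding of poverty prevalence, level 1 (lowest
    poverty) to 5.  The banding rule for this sensitivity factor is a
    package choice; it has no published counterpart."""
    if not (0.0 <= poverty_rate <= 100.0):
        raise ValidationError(f"poverty_rate must be in [0, 100], got {poverty_rate!r}")
    return 1 + int(np.searchsorted(quintile_cuts, poverty_rate, side="right"))


def poverty_quintile_cuts(rates: Sequence[float]) -> np.ndarray:
    """20/40/60/80th percentile cut-points from a supplied poverty column."""
    return np.percentile(np.asarray(rates, dtype=float), [20, 40, 60, 80])


def che_cutpoints_from_percentiles(values: Sequence[float]) -> np.ndarray:
    """Re-estimate the CHE cut-points as the 20/40/60th percentiles of a
    new expenditure distribution (opt-in; the fixed dollar defaults are
    used otherwise)."""
    return np.percentile(np.asarray(values, dtype=float), [20, 40, 60])


@dataclass
class BandConfig:
    """Banding configuration; defaults reproduce the published rules."""

    che_cutpoints: tuple[float, ...] = DEFAULT_CHE_CUTPOINTS
    fad_cutpoints: tuple[float, ...] = DEFAULT_FAD_CUTPOINTS
    poverty_cuts: tuple[float, ...] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "BandConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "che_cutpoints" in raw:
            cfg.che_cutpoints = tuple(float(x) for x in raw["che_cutpoints"])
        if "fad_cutpoints" in raw:
            cfg.fad_cutpoints = tuple(float(x) for x in raw["fad_cutpoints"])
        if "poverty_cuts" in raw:
            cfg.poverty_cuts = tuple(float(x) for x in raw["poverty_cuts"])
        for cuts in (cfg.che_cutpoints, cfg.fad_cutpoints, cfg.poverty_cuts or ()):
            if list(cuts) != sorted(cuts):
                raise ConfigurationError(f"cut-points must be increasing: {cuts}")
        return cfg


def build_profile(
    record: CountryIndicatorRecord, config: BandConfig | None = None
) -> ExposureProfile:
    """Assemble the exposure profile for one country record.

    The poverty level is populated only when the record carries a poverty
    rate *and* the config supplies quintile cut-points (they depend on
    the whole sample, so they cannot default per record).
    """
    cfg = config or BandConfig()
    pov = None
    if record.poverty_rate is not None and cfg.poverty_cuts is not None:
        pov = level_from_poverty(record.poverty_rate, cfg.poverty_cuts)
    return ExposureProfile(
        country_name=record.country_name,
        che_level=level_from_che(record.che_per_capita, cfg.che_cutpoints),
        fad_level=level_from_fad(record.external_share, cfg.fad_cutpoints),
        bsp_level=level_from_bsp(record.budget_space),
        ctb_level=level_from_ctb(record.debt_risk),
        poverty_level=pov,
    )


def build_profiles(
    records: Sequence[CountryIndicatorRecord], config: BandConfig | None = None
) -> list[ExposureProfile]:
    cfg = config or BandConfig()
    if (
        cfg.poverty_cuts is None
        and all(r.poverty_rate is not None for r in records)
        and len(records) >= 5
    ):
        cfg = BandConfig(
            che_cutpoints=cfg.che_cutpoints,
            fad_cutpoints=cfg.fad_cutpoints,
            poverty_cuts=tuple(poverty_quintile_cuts([r.poverty_rate for r in records])),
        )
    return [build_profile(r, cfg) for r in records]


def profiles_to_dataset(
    profiles: Sequence[ExposureProfile],
    factors: Sequence[FactorSpec] | None = None,
) -> OrdinalDataset:
    """Stack profiles into an :class:`~healthvuln.ingest.OrdinalDataset`.

    The poverty column is included only when every profile carries it.
    """
    if not profiles:
        raise ValidationError("no profiles")
    with_poverty = all(p.poverty_level is not None for p in profiles)
    factors = list(factors) if factors is not None else list(DEFAULT_FACTORS) + (
        [POVERTY_FACTOR] if with_poverty else []
    )
    levels = np.array(
        [p.as_tuple()[: len(factors)] for p in profiles], dtype=int
    )
    return OrdinalDataset(
        countries=[p.country_name for p in profiles],
        levels=levels,
        factor_names=[f.name for f in factors],
        max_levels=[f.max_level for f in factors],
        norm_denominators=[f.norm_denominator for f in factors],
    )
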