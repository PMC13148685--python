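"""Bundled reference data for the 47-country WHO African Region
health-financing vulnerability assessment.

``afro47_weighted_components.csv`` carries the published weighted
exposure-component scores (2 dp), overall V-scores and archetype labels;
``afro47_method_scores.csv`` the published overall scores under the
alternative weighting methods.  The integer exposure levels are not
shipped — they are recovered exactly by inverting the component scores
through the published weights (:func:`load_reference_levels`).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..exposure import DEFAULT_FACTORS
from ..ingest import OrdinalDataset, backout_levels
from ..weighting import WeightVector, user_weights

#: Published per-factor weights (% contribution): CHE per capita,
#: foreign-aid dependency, budget-space potential, capacity to borrow.
REFERENCE_WEIGHTS: tuple[float, ...] = (32.10, 30.70, 7.60, 29.60)

FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in DEFAULT_FACTORS)


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_weighted_components() -> pd.DataFrame:
    """Published weighted component scores, overall V-score and archetype
    per country (presentation order: descending V-score)."""
    return _read("afro47_weighted_components.csv")


def load_method_scores() -> pd.DataFrame:
    """Published overall V-scores per country under each weighting
    variant (alphabetical order)."""
    return _read("afro47_method_scores.csv")


def reference_weights() -> WeightVector:
    """The published weight vector as a verbatim user WeightVector."""
    return user_weights(list(FACTOR_NAMES), REFERENCE_WEIGHTS)


def load_reference_levels() -> OrdinalDataset:
    """Recover the 47 x 4 integer exposure levels by inverting the
    published component scores through the published weights."""
    df = load_weighted_components()
    comp = df[[f"{n}_component" for n in FACTOR_NAMES]].to_numpy(dtype=float)
    return backout_levels(
        comp,
        np.asarray(REFERENCE_WEIGHTS),
        [f.norm_denominator for f in DEFAULT_FACTORS],
        countries=list(df["country"]),
        factor_names=list(FACTOR_NAMES),
        max_levels=[f.max_level for f in DEFAULT_FACTORS],
    )
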