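"""Per-factor weight derivation for the composite vulnerability score.

The primary method takes the first principal component of the polychoric
correlation matrix and converts its loadings to percentage weights by
squaring and normalising to 100 — the standard variance-contribution
reading of a component.  Sensitivity alternatives: single-factor
principal-axis factoring (EFA), the classical entropy weight method on
the raw level matrix, equal weights, and verbatim user weights.

All methods return a :class:`WeightVector` whose weights are
non-negative and sum to 100 (within 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .ingest import OrdinalDataset
from .polychoric import PolychoricResult

_TIE_TOL = 1e-9


@dataclass
class WeightVector:
    factor_names: list[str]
    weights: np.ndarray  # percent, sums to 100
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.factor_names) != self.weights.size:
            raise ConfigurationError("factor_names and weights lengths differ")
        if np.any(self.weights < -1e-12):
            raise ValidationError("weights must be non-negative")
        if abs(self.weights.sum() - 100.0) > 1e-6:
            raise ValidationError(
                f"weights must sum to 100, got {self.weights.sum():.8f}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.factor_names, self.weights.tolist()))


def _corr_and_names(
    poly: PolychoricResult | np.ndarray, factor_names: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(poly, PolychoricResult):
        return np.asarray(poly.corr, dtype=float), list(poly.factor_names)
    corr = np.asarray(poly, dtype=float)
    names = list(factor_names) if factor_names else [f"factor{i+1}" for i in range(corr.shape[0])]
    return corr, names


def pca_weights(
    poly: PolychoricResult | np.ndarray, factor_names: Sequence[str] | None = None
) -> WeightVector:
    """Squared first-principal-component loadings, normalised to 100.

    The component is oriented so its loading on the first factor is
    non-negative.  With the loading vector of unit norm, squared loadings
    already sum to one, so the weights are simply ``100 * v1**2``.  A tie
    between the two leading eigenvalues (no dominant direction of shared
    variance) is broken by falling back to equal weights, flagged in the
    diagnostics.
    """
    corr, names = _corr_and_names(poly, factor_names)
    k = corr.shape[0]
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValidationError("correlation matrix must be positive semi-definite")
    vals, vecs = np.linalg.eigh(corr)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    explained = vals / vals.sum()
    if k > 1 and vals[0] - vals[1] < _TIE_TOL:
        return WeightVector(
            names,
            np.full(k, 100.0 / k),
            "polychoric_pca",
            {"tie": True, "explained_variance": explained},
        )
    v1 = vecs[:, 0]
    if v1[0] < 0:
        v1 = -v1
    return WeightVector(
        names,
        100.0 * v1**2,
        "polychoric_pca",
        {"tie": False, "explained_variance": explained, "loadings": v1 * np.sqrt(vals[0])},
    )


def efa_weights(
    poly: PolychoricResult | np.ndarray,
    factor_names: Sequence[str] | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> WeightVector:
    """Single-factor principal-axis factoring; weights are squared factor
    loadings normalised to 100.

    Communalities start at the squared multiple correlations and are
    iterated to ``tol`` (or ``max_iter``).  Heywood cases (communality
    reaching 1) are clipped to 0.999 and flagged.
    """
    corr, names = _corr_and_names(poly, factor_names)
    k = corr.shape[0]
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValidationError("correlation matrix must be positive semi-definite")
    # SMC initial communalities; ridge if the matrix is singular
    try:
        inv = np.linalg.inv(corr)
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        inv = np.linalg.inv(corr + 1e-6 * np.eye(k))
        h2 = 1.0 - 1.0 / np.diag(inv)
    h2 = np.clip(h2, 0.0, 0.999)
    heywood = False
    loadings = np.zeros(k)
    for _ in range(max_iter):
        R = corr.copy()
        np.fill_diagonal(R, h2)
        vals, vecs = np.linalg.eigh(R)
        lead = max(vals[-1], 0.0)
        loadings = np.sqrt(lead) * vecs[:, -1]
        if loadings[np.argmax(np.abs(loadings))] < 0:
            loadings = -loadings
        h2_new = loadings**2
        if np.any(h2_new > 1.0):
            heywood = True
            h2_new = np.clip(h2_new, None, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    total = loadings @ loadings
    if total < 1e-8:
        # no common factor at all (e.g. identity matrix): tie rule
        return WeightVector(
            names, np.full(k, 100.0 / k), "efa", {"tie": True, "heywood": heywood}
        )
    return WeightVector(
        names,
        100.0 * loadings**2 / total,
        "efa",
        {"tie": False, "heywood": heywood, "loadings": loadings, "communalities": h2},
    )


def entropy_weights(data: OrdinalDataset | np.ndarray, factor_names: Sequence[str] | None = None) -> WeightVector:
    """Classical entropy weight method on the raw level matrix.

    Column shares ``p_ij = x_ij / sum_i x_ij``; normalised Shannon
    entropy ``e_j = -(1/ln n) sum p ln p`` (0 ln 0 := 0); diversification
    ``d_j = 1 - e_j``; weights proportional to ``d_j``.  A constant
    column carries no information and gets weight 0 (flagged); if every
    column is constant there is nothing to weight.
    """
    if isinstance(data, OrdinalDataset):
        X = data.levels.astype(float)
        names = list(data.factor_names)
    else:
        X = np.asarray(data, dtype=float)
        names = list(factor_names) if factor_names else [f"factor{j+1}" for j in range(X.shape[1])]
    n, k = X.shape
    if n < 2:
        raise ValidationError("entropy weighting needs at least 2 rows")
    p = X / X.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = np.clip(1.0 - e, 0.0, None)
    zero_info = [names[j] for j in range(k) if d[j] <= 1e-12]
    if d.sum() <= 1e-12:
        raise ValidationError("no information: every column is constant")
    return WeightVector(
        names,
        100.0 * d / d.sum(),
        "entropy",
        {"entropy": e, "diversification": d, "zero_information": zero_info},
    )


def equal_weights(factor_names: Sequence[str]) -> WeightVector:
    names = list(factor_names)
    if not names:
        raise ValidationError("need at least one factor")
    return WeightVector(names, np.full(len(names), 100.0 / len(names)), "equal")


def user_weights(factor_names: Sequence[str], values: Sequence[float]) -> WeightVector:
    """Wrap user-supplied weights (e.g. published ones) verbatim; inputs
    not summing to 100 are rescaled, with the original kept in the
    diagnostics."""
    w = np.asarray(values, dtype=float)
    if np.any(w < 0):
        raise ValidationError("user weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValidationError("user weights must not all be zero")
    diag = {}
    if abs(total - 100.0) > 1e-6:
        diag["original"] = w.copy()
        w = 100.0 * w / total
    return WeightVector(list(factor_names), w, "user", diag)


_METHODS = {
    "polychoric_pca": pca_weights,
    "efa": efa_weights,
    "entropy": entropy_weights,
    "equal": equal_weights,
}


def derive_weights(
    data: OrdinalDataset,
    method: str = "polychoric_pca",
    poly: PolychoricResult | None = None,
) -> WeightVector:
    """Dispatch to a weighting method by name, computing the polychoric
    matrix on demand for the correlation-based methods."""
    if method not in _METHODS:
        raise ConfigurationError(
            f"unknown weighting method {method!r}; choose from {sorted(_METHODS)}"
        )
    if method in ("polychoric_pca", "efa"):
        if poly is None:
            from .polychoric import polychoric_matrix

            poly = polychoric_matrix(data)
        return _METHODS[method](poly)
    if method == "entropy":
        return entropy_weights(data)
    return equal_weights(data.factor_names)
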