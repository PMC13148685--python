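"""Polychoric correlation estimation for ordinal indicators.

Each pair of ordinal variables is modelled as a discretisation of a
latent bivariate standard-normal vector: variable ``X`` takes category
``i`` when the latent value falls between thresholds ``t[i-1]`` and
``t[i]``.  Estimation is the classic two-step (Olsson) procedure:

1. thresholds per variable from the marginal category proportions,
   ``t_k = Phi^{-1}(cumulative proportion up to category k)``;
2. the latent correlation ``rho`` by maximising the multinomial
   log-likelihood of the observed contingency table under
   bivariate-normal rectangle probabilities, with the thresholds held
   fixed.

The optimisation is a deterministic bounded scalar maximisation on
``(-0.999, 0.999)`` with absolute tolerance 1e-6; no random starts.
Rectangle probabilities are floored at 1e-12 so sparse tables (the
regional dataset has only 47 rows) cannot produce ``-inf``
log-likelihoods.

Pairwise estimates need not assemble into a positive semi-definite
matrix; :func:`polychoric_matrix` smooths any indefinite result by
clipping negative eigenvalues at 1e-6 and rescaling to unit diagonal,
reporting that it did so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import DegenerateVariableError, ValidationError
from .ingest import OrdinalDataset

RHO_BOUND = 0.999
_CELL_FLOOR = 1e-12

# Gauss-Legendre nodes for the single-integral form of the bivariate
# normal CDF (Drezner & Wesolowsky); 24 nodes give ~1e-12 absolute
# accuracy for |rho| <= 0.999 on an analytic integrand.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(24)


def bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal (X, Y) with
    correlation ``rho``; vectorised over ``h`` and ``k``.

    Uses the identity
    ``Phi2(h, k, rho) = Phi(h) Phi(k) + (1/2pi) \\int_0^{asin rho}
    exp(-(h^2 + k^2 - 2 h k sin t) / (2 cos^2 t)) dt``
    evaluated by fixed Gauss-Legendre quadrature.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if abs(rho) >= 1.0:
        raise ValidationError(f"|rho| must be < 1, got {rho}")
    a = 0.5 * float(np.arcsin(rho))
    t = a * (_GL_X[:, None] + 1.0)  # nodes mapped onto [0, asin(rho)]
    sin_t = np.sin(t)
    cos2_t = 1.0 - sin_t**2
    hh, kk = h.ravel()[None, :], k.ravel()[None, :]
    f = np.exp(-(hh**2 + kk**2 - 2.0 * hh * kk * sin_t) / (2.0 * cos2_t))
    integral = a * (_GL_W[:, None] * f).sum(axis=0) / (2.0 * np.pi)
    out = norm.cdf(h.ravel()) * norm.cdf(k.ravel()) + integral
    return np.clip(out, 0.0, 1.0).reshape(h.shape)


def estimate_thresholds(levels: np.ndarray, max_level: int | None = None) -> np.ndarray:
    """Latent-scale thresholds from marginal proportions.

    Returns one cut-point per *observed* category boundary,
    ``Phi^{-1}`` of the cumulative proportions; strictly increasing.
    Unobserved categories contribute no threshold.
    """
    x = np.asarray(levels, dtype=int)
    if max_level is not None and (x.min() < 1 or x.max() > max_level):
        raise ValidationError(f"levels outside [1, {max_level}]")
    _, counts = np.unique(x, return_counts=True)
    if counts.size < 2:
        raise DegenerateVariableError(
            "variable has a single observed category; thresholds undefined"
        )
    cum = np.cumsum(counts[:-1]) / x.size
    return norm.ppf(cum)


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xv.size, yv.size))
    np.add.at(table, (xi, yi), 1.0)
    return table


def _cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the latent bivariate normal over the
    grid defined by thresholds ``tx`` x ``ty`` (without +/-inf edges)."""
    ax = np.concatenate(([-np.inf], tx, [np.inf]))
    ay = np.concatenate(([-np.inf], ty, [np.inf]))
    nx, ny = ax.size, ay.size
    C = np.zeros((nx, ny))
    C[-1, :] = norm.cdf(ay)
    C[:, -1] = norm.cdf(ax)
    C[-1, -1] = 1.0
    if nx > 2 and ny > 2:
        gx, gy = np.meshgrid(ax[1:-1], ay[1:-1], indexing="ij")
        C[1:-1, 1:-1] = bvn_cdf(gx, gy, rho)
    C[1:-1, 0] = 0.0
    C[0, :] = 0.0
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, _CELL_FLOOR, None)


def pair_loglik(table: np.ndarray, tx: np.ndarray, ty: np.ndarray, rho: float) -> float:
    """Multinomial log-likelihood of a contingency table at latent
    correlation ``rho`` with thresholds held fixed."""
    return float((table * np.log(_cell_probs(tx, ty, rho))).sum())


@dataclass
class PairEstimate:
    rho: float
    loglik: float
    converged: bool


def estimate_polychoric_rho(x: np.ndarray, y: np.ndarray) -> PairEstimate:
    """Two-step polychoric correlation for one pair of ordinal vectors.

    Falls back to a coarse grid search (step 0.01) if the bounded
    optimiser reports failure, flagging ``converged=False``.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 10:
        raise ValidationError(f"need at least 10 paired observations, got {x.size}")
    tx = estimate_thresholds(x)
    ty = estimate_thresholds(y)
    table = _contingency(x, y)

    def nll(rho: float) -> float:
        return -pair_loglik(table, tx, ty, rho)

    res = optimize.minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded", options={"xatol": 1e-6}
    )
    if res.success:
        return PairEstimate(rho=float(res.x), loglik=float(-res.fun), converged=True)
    grid = np.arange(-0.99, 0.995, 0.01)
    lls = np.array([-nll(r) for r in grid])
    best = int(np.argmax(lls))
    return PairEstimate(rho=float(grid[best]), loglik=float(lls[best]), converged=False)


def nearest_psd_correlation(corr: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues at ``eig_floor`` and rescale to unit
    diagonal, yielding the nearest PSD correlation in the eigenvalue
    metric."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, eig_floor, None)
    S = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


@dataclass
class PolychoricResult:
    """Pairwise polychoric correlation matrix with diagnostics.

    ``thresholds`` maps factor name to its latent cut-points;
    ``converged`` maps (name_i, name_j) pairs to the optimiser status;
    ``excluded`` lists factors dropped as degenerate (single observed
    category).
    """

    corr: np.ndarray
    thresholds: dict[str, np.ndarray]
    n_obs: int
    factor_names: list[str]
    converged: dict[tuple[str, str], bool] = field(default_factory=dict)
    smoothed: bool = False
    excluded: list[str] = field(default_factory=list)


def polychoric_matrix(data: OrdinalDataset) -> PolychoricResult:
    """Assemble the pairwise polychoric correlation matrix of a dataset.

    Degenerate factors (single observed category) are excluded and
    reported rather than poisoning every pair.  If pairwise assembly is
    indefinite, the matrix is smoothed to the nearest PSD correlation
    and flagged.
    """
    names, cols, thresholds, excluded = [], [], {}, []
    for j, name in enumerate(data.factor_names):
        col = data.levels[:, j]
        try:
            thresholds[name] = estimate_thresholds(col, data.max_levels[j])
            names.append(name)
            cols.append(col)
        except DegenerateVariableError:
            excluded.append(name)
    k = len(names)
    if k < 2:
        raise DegenerateVariableError(
            f"need at least 2 non-degenerate factors, have {k} "
            f"(excluded: {excluded or 'none'})"
        )
    corr = np.eye(k)
    converged: dict[tuple[str, str], bool] = {}
    for i in range(k):
        for j in range(i + 1, k):
            est = estimate_polychoric_rho(cols[i], cols[j])
            corr[i, j] = corr[j, i] = est.rho
            converged[(names[i], names[j])] = est.converged
    smoothed = False
    if np.linalg.eigvalsh(corr).min() < 0:
        corr = nearest_psd_correlation(corr)
        smoothed = True
    return PolychoricResult(
        corr=corr,
        thresholds=thresholds,
        n_obs=data.n_countries,
        factor_names=names,
        converged=converged,
        smoothed=smoothed,
        excluded=excluded,
    )
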