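"""Item correlation matrices for ordinal questionnaire data.

Likert items are ordinal, so the default input to network estimation is the
polychoric correlation: each pair of items is modeled as a discretized
bivariate normal, thresholds are fixed at the inverse-normal transforms of the
cumulative marginal proportions, and the latent correlation maximizes the
bivariate-normal likelihood of the observed contingency table (the classical
two-step estimator).  Pearson correlations are available as a config option,
and are used automatically for pairs involving continuous columns (e.g.
factor-score composites created by redundancy merging).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .data import ResponseMatrix

__all__ = [
    "CorrelationMatrix",
    "pearson_corr",
    "polychoric_corr",
    "corr_matrix",
    "nearest_psd",
    "bivariate_normal_cdf",
]

_PSD_EPS = 1e-8


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Symmetric item correlation matrix with estimation metadata."""

    values: np.ndarray
    method: str
    n: int
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise CorrelationError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise CorrelationError("correlation matrix must have unit diagonal")
        if np.any(np.abs(v) > 1 + 1e-8):
            raise CorrelationError("correlations must lie in [-1, 1]")


def pearson_corr(data: ResponseMatrix) -> CorrelationMatrix:
    """Product-moment correlations of the raw item scores."""
    x = data.values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = data.item_ids[int(np.argmin(sd))]
        raise CorrelationError(f"item {bad!r} is constant")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, "pearson", data.n_respondents, tuple(data.item_ids))


def bivariate_normal_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's-T formulation; vectorized over (h, k) and exact at rho = +/-1 and
    at infinite arguments.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(np.minimum(h, k))
    if rho <= -1.0 + 1e-12:
        return np.clip(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0, None)
    denom = np.sqrt(1.0 - rho * rho)
    # replace exact zeros so the Owen's-T slope arguments stay well defined
    hs = np.where(h == 0.0, 1e-300, h)
    ks = np.where(k == 0.0, 1e-300, k)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ah = (ks / hs - rho) / denom
        ak = (hs / ks - rho) / denom
    # T(+/-inf, a) = 0; make infinite arguments safe
    ah = np.where(np.isfinite(h), ah, 0.0)
    ak = np.where(np.isfinite(k), ak, 0.0)
    ah = np.nan_to_num(ah, nan=0.0, posinf=1e300, neginf=-1e300)
    ak = np.nan_to_num(ak, nan=0.0, posinf=1e300, neginf=-1e300)
    hf = np.where(np.isfinite(h), h, 0.0)
    kf = np.where(np.isfinite(k), k, 0.0)
    t1 = np.where(np.isfinite(h), special.owens_t(hf, ah), 0.0)
    t2 = np.where(np.isfinite(k), special.owens_t(kf, ak), 0.0)
    with np.errstate(invalid="ignore"):
        hk = h * k
        beta = np.where((hk > 0) | ((hk == 0) & (hf + kf >= 0)), 0.0, 0.5)
    out = 0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k)) - t1 - t2 - beta
    # exact-origin case: Phi2(0,0,rho) = 1/4 + asin(rho)/(2*pi)
    both_zero = (h == 0.0) & (k == 0.0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    # infinite shortcuts
    out = np.where(h == -np.inf, 0.0, out)
    out = np.where(k == -np.inf, 0.0, out)
    out = np.where(h == np.inf, stats.norm.cdf(k), out)
    out = np.where((k == np.inf) & np.isfinite(h), stats.norm.cdf(h), out)
    out = np.where((h == np.inf) & (k == np.inf), 1.0, out)
    return np.clip(out, 0.0, 1.0)


def _cell_probabilities(
    tau_x: np.ndarray, tau_y: np.ndarray, rho: float
) -> np.ndarray:
    """Rectangle probabilities of the discretized bivariate normal."""
    gx = np.concatenate(([-np.inf], tau_x, [np.inf]))
    gy = np.concatenate(([-np.inf], tau_y, [np.inf]))
    cdf = bivariate_normal_cdf(gx[:, None], gy[None, :], rho)
    return np.maximum(cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1], 0.0)


def polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step polychoric correlation of two ordinal vectors."""
    cats_x, xi = np.unique(x, return_inverse=True)
    cats_y, yi = np.unique(y, return_inverse=True)
    if len(cats_x) < 2 or len(cats_y) < 2:
        raise CorrelationError("polychoric needs >= 2 observed categories per item")
    n = len(x)
    table = np.zeros((len(cats_x), len(cats_y)))
    np.add.at(table, (xi, yi), 1.0)
    # a margin can only be empty after external subsetting; regularize then
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        table = table + 0.5
    tau_x = stats.norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / table.sum())
    tau_y = stats.norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / table.sum())

    def nll(rho: float) -> float:
        pi = _cell_probabilities(tau_x, tau_y, rho)
        return -float(np.sum(table * np.log(np.maximum(pi, 1e-300))))

    res = optimize.minimize_scalar(
        nll, bounds=(-0.9999, 0.9999), method="bounded",
        options={"xatol": 1e-6, "maxiter": 200},
    )
    if not res.success:
        raise CorrelationError("polychoric likelihood search did not converge")
    return float(res.x)


def polychoric_corr(data: ResponseMatrix) -> CorrelationMatrix:
    """Pairwise two-step polychoric matrix, smoothed to the nearest PSD.

    Pairs in which either column is continuous (merged composites) use the
    Pearson correlation instead.
    """
    ids = data.item_ids
    p = len(ids)
    x = data.values.to_numpy(dtype=float)
    r = np.eye(p)
    ordinal = [data.is_ordinal(i) for i in ids]
    for i in range(p):
        for j in range(i + 1, p):
            if ordinal[i] and ordinal[j]:
                try:
                    rij = polychoric_pair(x[:, i], x[:, j])
                except CorrelationError as exc:
                    raise CorrelationError(
                        f"polychoric failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                    ) from exc
            else:
                sx, sy = x[:, i].std(), x[:, j].std()
                if sx == 0 or sy == 0:
                    raise CorrelationError(
                        f"constant item in pair ({ids[i]!r}, {ids[j]!r})"
                    )
                rij = float(np.corrcoef(x[:, i], x[:, j])[0, 1])
            r[i, j] = r[j, i] = rij
    smoothed = nearest_psd_values(r)
    return CorrelationMatrix(smoothed, "polychoric", data.n_respondents, tuple(ids))


def corr_matrix(data: ResponseMatrix, method: str = "polychoric") -> CorrelationMatrix:
    """Dispatch on the configured correlation type."""
    if method == "polychoric":
        return polychoric_corr(data)
    if method == "pearson":
        return pearson_corr(data)
    raise ValueError(f"unknown correlation method {method!r}")


def nearest_psd_values(m: np.ndarray, eps: float = _PSD_EPS) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T, atol=1e-10):
        raise CorrelationError("matrix must be symmetric")
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    if w.min() >= eps:
        return m
    w = np.maximum(w, eps)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def nearest_psd(m: np.ndarray, n: int = 0, eps: float = _PSD_EPS) -> CorrelationMatrix:
    """Eigenvalue-clipping PSD repair, rescaled back to unit diagonal."""
    repaired = nearest_psd_values(m, eps=eps)
    ids = tuple(str(i) for i in range(repaired.shape[0]))
    return CorrelationMatrix(repaired, "smoothed", n, ids)
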