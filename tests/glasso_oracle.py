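"""Independent brute-force optimizer of the lasso-penalized Gaussian
log-likelihood, used only to verify the coordinate-descent solver.

The precision matrix is parameterized as ``diag(d)`` plus an off-diagonal
split ``a - b`` with ``a, b >= 0``, which makes the penalty
``lam * sum(a + b)`` smooth, and the whole objective is minimized with
L-BFGS-B and the analytic gradient ``S - inv(Theta)``.  A light eigenvalue
barrier keeps iterates positive definite.
"""

import numpy as np
from scipy import optimize


def brute_force_glasso(S: np.ndarray, lam: float) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])

    def build(x):
        d, a, b = x[:p], x[p:p + m], x[p + m:]
        theta = np.zeros((p, p))
        theta[iu] = a - b
        theta = theta + theta.T
        theta[np.diag_indices(p)] = d
        return theta

    def objective(x):
        theta = build(x)
        w = np.linalg.eigvalsh(theta)
        if w.min() <= 1e-10:
            # push back towards the PD cone with a linear barrier
            return 1e6 - float(w.min()), np.zeros_like(x)
        sign, logdet = np.linalg.slogdet(theta)
        # the penalty sums over ordered pairs, so each a/b pair counts twice
        val = -logdet + float(np.sum(S * theta)) + 2.0 * lam * float(np.sum(x[p:]))
        inv = np.linalg.inv(theta)
        g_theta = S - inv
        g_d = np.diag(g_theta)
        g_off = 2.0 * g_theta[iu]  # each off pair appears twice in theta
        grad = np.concatenate([g_d, g_off + 2.0 * lam, -g_off + 2.0 * lam])
        return val, grad

    theta0 = np.linalg.inv(S + lam * np.eye(p))
    off0 = theta0[iu]
    x0 = np.concatenate(
        [np.diag(theta0), np.maximum(off0, 0.0), np.maximum(-off0, 0.0)]
    )
    bounds = [(1e-8, None)] * p + [(0.0, None)] * (2 * m)
    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "maxfun": 100000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return build(res.x)


def kkt_gap(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Largest violation of the stationarity conditions of the objective."""
    W = np.linalg.inv(theta)
    p = S.shape[0]
    gap = float(np.abs(np.diag(W - S)).max())
    for i in range(p):
        for j in range(i + 1, p):
            t = theta[i, j]
            if abs(t) > 1e-8:
                gap = max(gap, abs(W[i, j] - S[i, j] - lam * np.sign(t)))
            else:
                gap = max(gap, max(0.0, abs(S[i, j] - W[i, j]) - lam))
    return gap
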