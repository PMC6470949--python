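"""Independent reference computations used by multiple test modules.

These deliberately avoid the code paths they check: brute-force loops,
closed-form GLS, and numerical quadrature.
"""

import math

import numpy as np
from scipy.optimize import minimize


def gls_random_intercept_ml(X: np.ndarray, Y: np.ndarray):
    """Closed-form-GLS maximum-likelihood fit of a balanced
    random-intercept linear mixed model y_i ~ N(X beta, tau^2 J + sigma^2 I).

    beta is profiled out in closed form (GLS) for each variance pair;
    the two variance parameters are optimized numerically on the log
    scale.  Returns (beta, sigma, tau).
    """
    n, T = Y.shape

    def profile_nll(theta):
        tau2, sig2 = np.exp(theta)
        V = tau2 * np.ones((T, T)) + sig2 * np.eye(T)
        Vinv = np.linalg.inv(V)
        A = X.T @ Vinv @ X * n
        rhs = X.T @ Vinv @ Y.sum(axis=0)
        beta = np.linalg.solve(A, rhs)
        R = Y - (X @ beta)[None, :]
        sign, logdet = np.linalg.slogdet(V)
        quad = np.einsum("it,ts,is->", R, Vinv, R)
        return 0.5 * (n * logdet + quad + n * T * math.log(2 * math.pi))

    best = None
    for start in ([0.0, 0.0], [2.0, 1.0], [-2.0, 1.0]):
        res = minimize(profile_nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    tau2, sig2 = np.exp(best.x)
    V = tau2 * np.ones((T, T)) + sig2 * np.eye(T)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X * n, X.T @ Vinv @ Y.sum(axis=0))
    return beta, math.sqrt(sig2), math.sqrt(tau2), -best.fun
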