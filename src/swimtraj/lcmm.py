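"""Latent-class linear mixed models for TTL trajectories.

A latent-class (growth-mixture) linear mixed model assumes each subject
i belongs to one of K unobserved classes; given class g the outcome
vector satisfies

    y_i | (class = g)  ~  N( X_i beta_g ,  Z_i B_g Z_i' + sigma^2 I ),

where X_i is a natural cubic spline basis in weeks-before-best-
performance (class-specific mean curves), Z_i the random-effects design
(random intercept by default, optionally intercept + linear slope), B_g
the random-effect covariance and sigma the residual SD.  Class
membership follows an intercept-only multinomial logit with
probabilities pi_g.  Under the "common" class structure B_g = B for all
g; under the "proportional" structure B_g = w_g^2 * B with w_K = 1 for
identifiability.

Estimation is maximum likelihood: EM with both the class labels and the
random effects as missing data (all M-step updates in closed form, so
the marginal log-likelihood is non-decreasing across iterations),
followed by quasi-Newton polishing of the marginal likelihood, with
multiple seeded starts around a K-means initialization of per-subject
least-squares curves.  Model choice follows a two-stage protocol: AIC
picks the best configuration (knots, covariance structure) within each
K, BIC compares across K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from sklearn.cluster import KMeans

__all__ = [
    "LCMMSpec",
    "LCMMParams",
    "LCMMFit",
    "TrajectoryData",
    "spline_basis",
    "NaturalSplineBasis",
    "marginal_loglik",
    "posterior_probs",
    "fit",
    "assign_and_summarize",
    "weighted_class_means",
    "model_search",
]

_SIGMA_FLOOR = 1e-4


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Natural cubic spline basis


class NaturalSplineBasis:
    """Natural cubic spline basis with intercept.

    Truncated-power construction with natural (linear) boundary
    behaviour: with knots k_1 < ... < k_K the basis is {1, t, N_1..N_{K-2}}
    where N_j(t) = d_j(t) - d_{K-1}(t) and
    d_j(t) = [(t - k_j)_+^3 - (t - k_K)_+^3] / (k_K - k_j).
    The fit is linear beyond the boundary knots, so evaluation outside
    the observed range extrapolates linearly.  Interior knots are placed
    at equally spaced quantiles of the observation times; boundary knots
    at the extremes.  Column count is n_interior_knots + 2.
    """

    def __init__(self, times: np.ndarray, n_interior_knots: int):
        t = np.asarray(times, dtype=float)
        uniq = np.unique(t)
        if len(uniq) < n_interior_knots + 2:
            raise ValueError(
                f"need >= {n_interior_knots + 2} distinct times, got {len(uniq)}"
            )
        if n_interior_knots > 0:
            qs = np.arange(1, n_interior_knots + 1) / (n_interior_knots + 1)
            interior = np.quantile(t, qs)
        else:
            interior = np.array([])
        knots = np.unique(np.concatenate([[uniq[0]], interior, [uniq[-1]]]))
        if len(knots) != n_interior_knots + 2:
            raise ValueError("degenerate knot placement (duplicate quantiles)")
        self.knots = knots

    @property
    def n_columns(self) -> int:
        return len(self.knots)

    def __call__(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        k = self.knots
        cols = [np.ones_like(t), t]

        def d(j: int) -> np.ndarray:
            return (
                np.maximum(t - k[j], 0.0) ** 3 - np.maximum(t - k[-1], 0.0) ** 3
            ) / (k[-1] - k[j])

        d_last = d(len(k) - 2)
        for j in range(len(k) - 2):
            cols.append(d(j) - d_last)
        return np.column_stack(cols)


def spline_basis(times: np.ndarray, n_interior_knots: int) -> np.ndarray:
    """Design matrix of the natural cubic spline basis at ``times``."""
    return NaturalSplineBasis(times, n_interior_knots)(times)


# ---------------------------------------------------------------------------
# Model specification, parameters, data


@dataclass(frozen=True)
class LCMMSpec:
    """Configuration of one latent-class mixed model."""

    n_classes: int = 3
    n_interior_knots: int = 3
    random_effects: str = "intercept"  # or "intercept_slope"
    re_covariance: str = "diagonal"  # or "unstructured"
    re_class_structure: str = "common"  # or "proportional"

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 5:
            raise ValueError("n_classes must be in 1..5")
        if not 0 <= self.n_interior_knots <= 15:
            raise ValueError("n_interior_knots must be in 0..15")
        if self.random_effects not in ("intercept", "intercept_slope"):
            raise ValueError(f"bad random_effects {self.random_effects!r}")
        if self.re_covariance not in ("diagonal", "unstructured"):
            raise ValueError(f"bad re_covariance {self.re_covariance!r}")
        if self.re_class_structure not in ("common", "proportional"):
            raise ValueError(f"bad re_class_structure {self.re_class_structure!r}")

    @property
    def q(self) -> int:
        return 1 if self.random_effects == "intercept" else 2

    def n_parameters(self, p: int) -> int:
        """Free-parameter count: (K-1) membership logits, K*p spline
        coefficients, covariance entries, (K-1) proportional scales, and
        the residual SD."""
        k = self.n_classes
        cov = self.q if self.re_covariance == "diagonal" else self.q * (self.q + 1) // 2
        prop = k - 1 if self.re_class_structure == "proportional" else 0
        return (k - 1) + k * p + cov + prop + 1


@dataclass
class LCMMParams:
    """Parameter set: membership logits (last class pinned at 0),
    per-class spline coefficients, random-effect covariance B, per-class
    proportional scales w (all 1 under the common structure, w_K = 1
    always), residual SD sigma."""

    logits: np.ndarray  # (K-1,)
    beta: np.ndarray  # (K, p)
    B: np.ndarray  # (q, q)
    w: np.ndarray  # (K,)
    sigma: float

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]

    @property
    def pi(self) -> np.ndarray:
        full = np.concatenate([self.logits, [0.0]])
        return softmax(full)

    def class_cov(self, g: int) -> np.ndarray:
        return self.w[g] ** 2 * self.B

    def copy(self) -> "LCMMParams":
        return LCMMParams(
            self.logits.copy(), self.beta.copy(), self.B.copy(), self.w.copy(), self.sigma
        )


@dataclass
class _Block:
    """Subjects sharing one observation-time pattern (vectorized unit)."""

    times: np.ndarray  # (T,)
    X: np.ndarray  # (T, p)
    Z: np.ndarray  # (T, q)
    Y: np.ndarray  # (n_b, T)
    idx: np.ndarray  # subject indices into the full cohort


class TrajectoryData:
    """Outcome trajectories plus design matrices, grouped into blocks of
    subjects that share the same observation times so the likelihood and
    EM steps vectorize."""

    def __init__(
        self,
        series: list[tuple[np.ndarray, np.ndarray]],
        n_interior_knots: int,
        random_effects: str = "intercept",
    ):
        if not series:
            raise ValueError("no subjects")
        for t, y in series:
            if len(t) < 2:
                raise ValueError("every subject needs >= 2 observations")
        all_times = np.concatenate([t for t, _ in series])
        self.basis = NaturalSplineBasis(all_times, n_interior_knots)
        self.p = self.basis.n_columns
        self.q = 1 if random_effects == "intercept" else 2
        self.random_effects = random_effects
        self.n_subjects = len(series)
        self.n_obs = sum(len(y) for _, y in series)
        self.time_range = (float(all_times.min()), float(all_times.max()))
        self._t_center = float(all_times.mean())

        groups: dict[tuple, list[int]] = {}
        for i, (t, _) in enumerate(series):
            groups.setdefault(tuple(np.asarray(t, dtype=float)), []).append(i)
        self.blocks: list[_Block] = []
        for key, members in groups.items():
            t = np.asarray(key)
            X = self.basis(t)
            Z = self._z_design(t)
            Y = np.vstack([np.asarray(series[i][1], dtype=float) for i in members])
            self.blocks.append(_Block(t, X, Z, Y, np.asarray(members)))

    def _z_design(self, t: np.ndarray) -> np.ndarray:
        if self.q == 1:
            return np.ones((len(t), 1))
        return np.column_stack([np.ones_like(t), t - self._t_center])

    @classmethod
    def from_ttl(cls, ttl_series, spec: LCMMSpec) -> "TrajectoryData":
        """Build from a list of :class:`swimtraj.loads.TTLSeries`."""
        series = [
            (np.asarray(s.week_index, dtype=float), np.asarray(s.values, dtype=float))
            for s in ttl_series
        ]
        return cls(series, spec.n_interior_knots, spec.random_effects)


# ---------------------------------------------------------------------------
# Likelihood


def _class_loglik_matrix(params: LCMMParams, data: TrajectoryData) -> np.ndarray:
    """(n_subjects, K) matrix of log pi_g + log N(y_i; X beta_g, V_g)."""
    k = params.n_classes
    out = np.empty((data.n_subjects, k))
    logpi = np.log(params.pi)
    for g in range(k):
        Bg = params.class_cov(g)
        for blk in data.blocks:
            T = len(blk.times)
            V = blk.Z @ Bg @ blk.Z.T + params.sigma**2 * np.eye(T)
            try:
                cf = cho_factor(V, lower=True)
            except LinAlgError as e:
                raise FitError(f"non-PSD marginal covariance: {e}") from e
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            R = blk.Y - (blk.X @ params.beta[g])[None, :]
            W = cho_solve(cf, R.T)  # (T, n_b)
            quad = np.einsum("ti,ti->i", R.T, W)
            out[blk.idx, g] = (
                logpi[g] - 0.5 * (T * math.log(2 * math.pi) + logdet + quad)
            )
    return out


def marginal_loglik(params: LCMMParams, data: TrajectoryData) -> float:
    """Marginal log-likelihood: sum_i log sum_g pi_g N(y_i; X beta_g, V_g),
    stabilized with log-sum-exp."""
    return float(logsumexp(_class_loglik_matrix(params, data), axis=1).sum())


def posterior_probs(params: LCMMParams, data: TrajectoryData) -> np.ndarray:
    """Posterior class-membership probabilities (rows sum to 1)."""
    m = _class_loglik_matrix(params, data)
    return softmax(m, axis=1)


# ---------------------------------------------------------------------------
# EM


def _e_step(params: LCMMParams, data: TrajectoryData):
    """Posterior class weights and random-effect moments per (block, class)."""
    m = _class_loglik_matrix(params, data)
    ll = float(logsumexp(m, axis=1).sum())
    tau = softmax(m, axis=1)
    moments = []  # per block: list over g of (bhat (q, n_b), Var (q, q))
    for blk in data.blocks:
        T = len(blk.times)
        per_class = []
        for g in range(params.n_classes):
            Bg = params.class_cov(g)
            V = blk.Z @ Bg @ blk.Z.T + params.sigma**2 * np.eye(T)
            cf = cho_factor(V, lower=True)
            R = blk.Y - (blk.X @ params.beta[g])[None, :]
            W = cho_solve(cf, R.T)  # V^{-1} r_i columns
            bhat = Bg @ blk.Z.T @ W  # (q, n_b)
            Var = Bg - Bg @ blk.Z.T @ cho_solve(cf, blk.Z @ Bg)
            per_class.append((bhat, Var))
        moments.append(per_class)
    return ll, tau, moments


def _m_step(params: LCMMParams, data: TrajectoryData, tau, moments, spec: LCMMSpec):
    k = params.n_classes
    q = data.q
    # membership
    pi = tau.mean(axis=0)
    pi = np.clip(pi, 1e-12, None)
    pi /= pi.sum()
    logits = np.log(pi[:-1]) - math.log(pi[-1])
    # spline coefficients: weighted OLS on partial residuals y - Z bhat
    beta = np.empty_like(params.beta)
    for g in range(k):
        A = np.zeros((data.p, data.p))
        rhs = np.zeros(data.p)
        for bi, blk in enumerate(data.blocks):
            w_i = tau[blk.idx, g]
            bhat, _ = moments[bi][g]
            resid = blk.Y - (blk.Z @ bhat).T  # (n_b, T)
            A += blk.X.T @ blk.X * w_i.sum()
            rhs += blk.X.T @ (resid * w_i[:, None]).sum(axis=0)
        beta[g] = np.linalg.solve(A, rhs)
    # random-effect covariance
    S = np.zeros((k, q, q))  # per class: sum_i tau E[b b']
    n_g = tau.sum(axis=0)
    for bi, blk in enumerate(data.blocks):
        for g in range(k):
            bhat, Var = moments[bi][g]
            w_i = tau[blk.idx, g]
            S[g] += (bhat * w_i[None, :]) @ bhat.T + w_i.sum() * Var
    if spec.re_class_structure == "common":
        B = S.sum(axis=0) / data.n_subjects
        w = np.ones(k)
    else:
        # ECM inner loop: B given w, then w given B (exact conditional maxima)
        w2 = params.w**2
        B = params.B.copy()
        for _ in range(3):
            B = sum(S[g] / w2[g] for g in range(k)) / data.n_subjects
            B = _cov_floor(B, spec)
            Binv = np.linalg.pinv(B)
            for g in range(k - 1):
                w2[g] = max(np.trace(Binv @ S[g]) / (q * max(n_g[g], 1e-12)), 1e-10)
            w2[k - 1] = 1.0  # anchor class
            # fold the anchor's implied scale into B for identifiability
            scale = np.trace(Binv @ S[k - 1]) / (q * max(n_g[k - 1], 1e-12))
            if scale > 1e-10:
                B = B * scale
                w2 = w2 / scale
                w2[k - 1] = 1.0
        w = np.sqrt(w2)
    B = _cov_floor(B, spec)
    # residual variance
    sse = 0.0
    for bi, blk in enumerate(data.blocks):
        T = len(blk.times)
        for g in range(k):
            bhat, Var = moments[bi][g]
            w_i = tau[blk.idx, g]
            resid = blk.Y - (blk.X @ beta[g])[None, :] - (blk.Z @ bhat).T
            sse += float((w_i * np.einsum("it,it->i", resid, resid)).sum())
            sse += float(w_i.sum() * np.trace(blk.Z @ Var @ blk.Z.T))
    sigma = max(math.sqrt(sse / data.n_obs), _SIGMA_FLOOR)
    return LCMMParams(logits, beta, B, w, sigma)


def _cov_floor(B: np.ndarray, spec: LCMMSpec) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if spec.re_covariance == "diagonal":
        B = np.diag(np.clip(np.diag(B), 0.0, None))
    else:
        # symmetrize and clip tiny negative eigenvalues
        B = (B + B.T) / 2
        vals, vecs = np.linalg.eigh(B)
        B = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return B


def _em(
    params: LCMMParams,
    data: TrajectoryData,
    spec: LCMMSpec,
    max_iter: int,
    tol: float,
    param_tol: float = 1e-5,
):
    history = []
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        ll, tau, moments = _e_step(params, data)
        history.append(ll)
        new = _m_step(params, data, tau, moments, spec)
        delta = _param_change(params, new)
        params = new
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * abs(ll_prev) and delta < param_tol:
            converged = True
            break
        ll_prev = ll
    ll_final = marginal_loglik(params, data)
    history.append(ll_final)
    return params, ll_final, converged, history


def _param_change(a: LCMMParams, b: LCMMParams) -> float:
    return max(
        float(np.max(np.abs(a.beta - b.beta), initial=0.0)),
        float(np.max(np.abs(a.B - b.B), initial=0.0)),
        float(np.max(np.abs(a.w - b.w), initial=0.0)),
        abs(a.sigma - b.sigma),
        float(np.max(np.abs(a.logits - b.logits), initial=0.0)) if a.logits.size else 0.0,
    )


# ---------------------------------------------------------------------------
# Quasi-Newton polish on the marginal likelihood


def _pack(params: LCMMParams, spec: LCMMSpec) -> np.ndarray:
    q = params.B.shape[0]
    parts = [params.logits, params.beta.ravel()]
    if spec.re_covariance == "diagonal":
        parts.append(np.log(np.sqrt(np.clip(np.diag(params.B), 1e-12, None))))
    else:
        L = cholesky(params.B + 1e-10 * np.eye(q), lower=True)
        tril = []
        for i in range(q):
            for j in range(i + 1):
                tril.append(math.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
        parts.append(np.array(tril))
    if spec.re_class_structure == "proportional":
        parts.append(np.log(np.clip(params.w[:-1], 1e-8, None)))
    parts.append(np.array([math.log(max(params.sigma, _SIGMA_FLOOR))]))
    return np.concatenate(parts)


def _unpack(theta: np.ndarray, spec: LCMMSpec, p: int) -> LCMMParams:
    k, q = spec.n_classes, spec.q
    pos = 0
    logits = theta[pos : pos + k - 1]
    pos += k - 1
    beta = theta[pos : pos + k * p].reshape(k, p)
    pos += k * p
    if spec.re_covariance == "diagonal":
        B = np.diag(np.exp(2 * theta[pos : pos + q]))
        pos += q
    else:
        L = np.zeros((q, q))
        for i in range(q):
            for j in range(i + 1):
                v = theta[pos]
                L[i, j] = math.exp(v) if i == j else v
                pos += 1
        B = L @ L.T
    if spec.re_class_structure == "proportional":
        w = np.concatenate([np.exp(theta[pos : pos + k - 1]), [1.0]])
        pos += k - 1
    else:
        w = np.ones(k)
    sigma = math.exp(theta[pos])
    return LCMMParams(np.asarray(logits, dtype=float), beta, B, w, sigma)


def _polish(params, data, spec, max_iter):
    theta0 = _pack(params, spec)

    def nll(theta):
        try:
            return -marginal_loglik(_unpack(theta, spec, data.p), data)
        except (FitError, LinAlgError, FloatingPointError):
            return 1e12

    res = minimize(nll, theta0, method="L-BFGS-B", options={"maxiter": max_iter})
    cand = _unpack(res.x, spec, data.p)
    cand.sigma = max(cand.sigma, _SIGMA_FLOOR)
    ll_new = marginal_loglik(cand, data)
    ll_old = marginal_loglik(params, data)
    return (cand, ll_new) if ll_new > ll_old else (params, ll_old)


# ---------------------------------------------------------------------------
# Initialization, fitting, multi-start


def _subject_curves(data: TrajectoryData) -> np.ndarray:
    """Per-subject ridge-regularized least-squares spline coefficients."""
    coefs = np.empty((data.n_subjects, data.p))
    lam = 1e-6
    for blk in data.blocks:
        A = blk.X.T @ blk.X + lam * np.eye(data.p)
        sol = np.linalg.solve(A, blk.X.T @ blk.Y.T)  # (p, n_b)
        coefs[blk.idx] = sol.T
    return coefs


def _initial_params(
    data: TrajectoryData, spec: LCMMSpec, rng: np.random.Generator, jitter: bool
) -> LCMMParams:
    k, q = spec.n_classes, data.q
    coefs = _subject_curves(data)
    if k == 1:
        labels = np.zeros(data.n_subjects, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(coefs)
    beta = np.empty((k, data.p))
    for g in range(k):
        members = labels == g
        beta[g] = coefs[members].mean(axis=0) if members.any() else coefs.mean(axis=0)
    if jitter:
        beta *= 1.0 + 0.2 * rng.standard_normal(beta.shape)
    counts = np.bincount(labels, minlength=k).astype(float)
    pi = np.clip(counts / counts.sum(), 0.05, None)
    pi /= pi.sum()
    logits = np.log(pi[:-1]) - math.log(pi[-1])
    # residual and intercept-spread moments from the per-subject fits
    sse, nres = 0.0, 0
    intercept_dev = []
    for blk in data.blocks:
        fitted = (blk.X @ coefs[blk.idx].T).T
        sse += float(((blk.Y - fitted) ** 2).sum())
        nres += blk.Y.size
        intercept_dev.extend((blk.Y - (blk.X @ beta[labels[blk.idx]].T).T).mean(axis=1))
    sigma = max(math.sqrt(sse / max(nres, 1)), 0.5)
    var_int = max(float(np.var(intercept_dev)), 0.25)
    B = np.zeros((q, q))
    B[0, 0] = var_int
    if q == 2:
        B[1, 1] = var_int / 100.0
    return LCMMParams(logits, beta, B, np.ones(k), sigma)


def _canonicalize(params: LCMMParams, data: TrajectoryData) -> LCMMParams:
    """Order classes by descending mean fitted trajectory level; the
    likelihood is invariant under this relabeling."""
    X_all = np.vstack([blk.X for blk in data.blocks])
    level = (X_all @ params.beta.T).mean(axis=0)
    order = np.argsort(-level, kind="stable")
    pi = params.pi[order]
    logits = np.log(pi[:-1]) - math.log(pi[-1])
    w = params.w[order]
    # renormalize proportional scales so the last class is the anchor
    B = params.B * w[-1] ** 2
    w = w / w[-1]
    return LCMMParams(logits, params.beta[order], B, w, params.sigma)


@dataclass
class LCMMFit:
    """A fitted latent-class mixed model."""

    spec: LCMMSpec
    params: LCMMParams
    loglik: float
    n_params: int
    aic: float
    bic: float
    posterior: np.ndarray
    modal_class: np.ndarray  # 1-based
    mean_posterior_by_class: np.ndarray
    class_shares: np.ndarray
    converged: bool
    n_starts_used: int
    loglik_history: list = field(default_factory=list, repr=False)

    def class_curve(self, g: int, times: np.ndarray, data: TrajectoryData) -> np.ndarray:
        """Fitted mean TTL curve of class g (1-based) at ``times``."""
        return data.basis(np.asarray(times, dtype=float)) @ self.params.beta[g - 1]


def fit(
    data: TrajectoryData,
    spec: LCMMSpec,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_em_iter: int = 500,
    max_polish_iter: int = 100,
) -> LCMMFit:
    """Maximum-likelihood fit of a latent-class mixed model.

    Runs ``n_starts`` EM runs (K-means-based initialization, seeded
    multiplicative jitter on later starts), polishes the best run with
    L-BFGS on the marginal likelihood, and returns the highest-likelihood
    solution with classes ordered by descending mean trajectory level.
    """
    if spec.n_classes > data.n_subjects:
        raise ValueError("more classes than subjects")
    if data.q != spec.q:
        raise ValueError("data random-effects design does not match spec")
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        try:
            init = _initial_params(data, spec, rng, jitter=s > 0)
            params, ll, conv, hist = _em(init, data, spec, max_em_iter, tol)
        except (FitError, LinAlgError):
            continue
        if best is None or ll > best[1]:
            best = (params, ll, conv, hist)
    if best is None:
        raise FitError("all starts failed")
    params, ll, conv, hist = best
    if max_polish_iter > 0:
        params, ll = _polish(params, data, spec, max_polish_iter)
    if not conv:
        # EM decays geometrically when a random-effect variance heads to
        # its boundary; try collapsing near-zero components to exactly 0
        # (B = 0 is an EM fixed point) and adopt only on improvement,
        # then refine briefly to re-assess convergence
        ll0 = marginal_loglik(params, data)
        diag = np.diag(params.B).copy()
        small = diag < 1e-2 * params.sigma**2
        if small.any():
            cand = params.copy()
            scale = np.where(small, 0.0, 1.0)
            cand.B = cand.B * np.outer(scale, scale)
            if marginal_loglik(cand, data) >= ll0:
                params = cand
        params, ll, conv, hist2 = _em(params, data, spec, 100, tol)
        hist.extend(hist2)
    params = _canonicalize(params, data)
    ll = marginal_loglik(params, data)
    post = posterior_probs(params, data)
    modal, mean_post, shares = assign_and_summarize(post)
    n_par = spec.n_parameters(data.p)
    return LCMMFit(
        spec=spec,
        params=params,
        loglik=ll,
        n_params=n_par,
        aic=-2 * ll + 2 * n_par,
        bic=-2 * ll + n_par * math.log(data.n_subjects),
        posterior=post,
        modal_class=modal,
        mean_posterior_by_class=mean_post,
        class_shares=shares,
        converged=conv,
        n_starts_used=max(n_starts, 1),
        loglik_history=hist,
    )


def assign_and_summarize(posterior: np.ndarray):
    """Modal class per subject (1-based; ties break to the lowest class
    index), mean posterior probability among subjects assigned to each
    class (NaN for empty classes), and assigned class shares."""
    post = np.asarray(posterior, dtype=float)
    modal0 = post.argmax(axis=1)  # argmax takes the first maximum: lowest index
    k = post.shape[1]
    mean_post = np.full(k, np.nan)
    shares = np.zeros(k)
    for g in range(k):
        members = modal0 == g
        shares[g] = members.mean()
        if members.any():
            mean_post[g] = post[members, g].mean()
    return modal0 + 1, mean_post, shares


def weighted_class_means(data: TrajectoryData, posterior: np.ndarray) -> pd.DataFrame:
    """Observed class-specific mean outcome per week, weighted by the
    class-membership probabilities:
    mean_g(t) = sum_i tau_ig y_it / sum_i tau_ig over subjects observed
    at week t.  Returns a tidy frame (class, week, mean, n_effective)."""
    post = np.asarray(posterior, dtype=float)
    k = post.shape[1]
    num: dict[tuple[int, float], float] = {}
    den: dict[tuple[int, float], float] = {}
    for blk in data.blocks:
        tau = post[blk.idx]  # (n_b, K)
        for g in range(k):
            wsum = tau[:, g].sum()
            wy = tau[:, g] @ blk.Y  # (T,)
            for j, t in enumerate(blk.times):
                key = (g, float(t))
                num[key] = num.get(key, 0.0) + wy[j]
                den[key] = den.get(key, 0.0) + wsum
    rows = []
    for key in sorted(num, key=lambda x: (x[0], -x[1])):
        g, t = key
        d = den[key]
        rows.append(
            {
                "class": g + 1,
                "week_before_bp": t,
                "mean": num[key] / d if d > 0 else np.nan,
                "n_effective": d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model search


def model_search(
    data_builder,
    k_range=range(1, 6),
    knot_range=range(1, 16),
    re_covariances=("diagonal", "unstructured"),
    re_class_structures=("common", "proportional"),
    random_effects: str = "intercept",
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_em_iter: int = 500,
    max_polish_iter: int = 100,
):
    """Two-stage model search over K, knot count and covariance options.

    ``data_builder`` maps an :class:`LCMMSpec` to a
    :class:`TrajectoryData` (the basis depends on the knot count); pass
    a list of TTLSeries and it is wrapped automatically.  For each K the
    AIC-minimal converged configuration is kept; across K the BIC-minimal
    K-best model is selected.  Returns (best_fit, table) where the table
    lists every cell (K, knots, structures, loglik, n_params, AIC, BIC,
    converged); redundant cells (covariance structures that coincide for
    a 1-dim random effect, proportional scaling with K=1) are fitted
    once only.
    """
    if not callable(data_builder):
        series = data_builder

        def data_builder(spec):  # noqa: F811
            return TrajectoryData.from_ttl(series, spec)

    rows = []
    fits = {}
    rng = np.random.default_rng(seed)
    q = 1 if random_effects == "intercept" else 2
    for k in k_range:
        for knots in knot_range:
            seen = set()
            for cov in re_covariances:
                for struct in re_class_structures:
                    cov_eff = "diagonal" if q == 1 else cov
                    struct_eff = "common" if k == 1 else struct
                    key = (k, knots, cov_eff, struct_eff)
                    if key in seen:
                        continue
                    seen.add(key)
                    spec = LCMMSpec(
                        n_classes=k,
                        n_interior_knots=knots,
                        random_effects=random_effects,
                        re_covariance=cov_eff,
                        re_class_structure=struct_eff,
                    )
                    cell_seed = int(rng.integers(2**31))
                    try:
                        f = fit(
                            data_builder(spec),
                            spec,
                            n_starts=n_starts,
                            seed=cell_seed,
                            tol=tol,
                            max_em_iter=max_em_iter,
                            max_polish_iter=max_polish_iter,
                        )
                        fits[key] = f
                        rows.append(
                            {
                                "K": k,
                                "n_interior_knots": knots,
                                "re_covariance": cov_eff,
                                "re_class_structure": struct_eff,
                                "loglik": f.loglik,
                                "n_params": f.n_params,
                                "AIC": f.aic,
                                "BIC": f.bic,
                                "converged": f.converged,
                            }
                        )
                    except (FitError, ValueError):
                        rows.append(
                            {
                                "K": k,
                                "n_interior_knots": knots,
                                "re_covariance": cov_eff,
                                "re_class_structure": struct_eff,
                                "loglik": np.nan,
                                "n_params": np.nan,
                                "AIC": np.nan,
                                "BIC": np.nan,
                                "converged": False,
                            }
                        )
    table = pd.DataFrame(rows)
    ok = table[table["converged"] & table["AIC"].notna()]
    if ok.empty:
        raise FitError("no converged model in the search grid")
    best_per_k = ok.loc[ok.groupby("K")["AIC"].idxmin()]
    sel = best_per_k.loc[best_per_k["BIC"].idxmin()]
    best_key = (
        int(sel["K"]),
        int(sel["n_interior_knots"]),
        sel["re_covariance"],
        sel["re_class_structure"],
    )
    return fits[best_key], table
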