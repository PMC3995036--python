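"""Pooled equal-variance Gaussian mixture fitting by EM, with AIC order selection.

The model: every standardized measurement z_ij (subject i, voxel j) is an
independent draw from

    f(z) = sum_k tau(k) * phi((z - mu_k) / sigma) / sigma,    k = 1..m,

a convex combination of m Gaussian densities sharing one standard deviation
sigma, so components differ only by their means.  Means are reported in
strictly ascending order, which fixes the labelling.  The mixture is fit
*once* to the pooled data of all subjects; subject- and group-level structure
is recovered afterwards from posterior membership probabilities (see
:mod:`mixshape.density`).

Model dimension for AIC is d = 2m: m means + (m - 1) free mixing
probabilities + 1 shared variance.

EM updates
----------
E-step:  tau_ij(k) = tau(k) phi_k(z_ij) / sum_l tau(l) phi_l(z_ij),
         computed in log space with log-sum-exp stabilization.
M-step:  mu_k    = sum_ij z_ij tau_ij(k) / sum_ij tau_ij(k)
         sigma^2 = sum_ijk (z_ij - mu_k)^2 tau_ij(k) / (nN)   (pooled MLE form)
         tau(k)  = (1/nN) sum_ij tau_ij(k)

After convergence the mixing probabilities are refined to the fixed point
tau = grand mean of memberships evaluated at the reported parameters, so the
reported global tau is exactly self-consistent with posterior memberships
recomputed from the reported fit (each refinement step is a coordinate
M-step and cannot decrease the likelihood).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .data_io import SubjectVoxelMatrix

__all__ = [
    "GMMParams",
    "FitResult",
    "ComponentCollapseError",
    "mixture_density",
    "e_step",
    "m_step",
    "fit_em",
    "aic",
    "select_m",
]

_LOG_2PI = math.log(2.0 * math.pi)


class ComponentCollapseError(RuntimeError):
    """A mixture component lost essentially all membership mass."""


@dataclass
class GMMParams:
    """Equal-variance mixture parameters, components in ascending-mean order."""

    mu: np.ndarray
    sigma: float
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if self.mu.shape != self.tau.shape or self.mu.ndim != 1:
            raise ValueError("mu and tau must be 1-D of equal length")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mu.size > 1 and not np.all(np.diff(self.mu) > 0):
            raise ValueError("component means must be strictly ascending")
        if np.any(self.tau < 0) or np.any(self.tau > 1):
            raise ValueError("mixing probabilities must lie in [0, 1]")
        if abs(float(self.tau.sum()) - 1.0) > 1e-12:
            raise ValueError("mixing probabilities must sum to 1")

    @property
    def m(self) -> int:
        return self.mu.size


@dataclass
class FitResult:
    """An EM fit: parameters plus likelihood trace and convergence metadata."""

    params: GMMParams
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    aic: float
    n_params: int

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        return pd.DataFrame(
            {
                "component": np.arange(1, p.m + 1),
                "mu": p.mu,
                "sigma": np.full(p.m, p.sigma),
                "tau": p.tau,
            }
        )


def _as_flat(Z) -> np.ndarray:
    if isinstance(Z, SubjectVoxelMatrix):
        return Z.values.ravel()
    return np.asarray(Z, dtype=float).ravel()


def _log_weighted_density(z: np.ndarray, params: GMMParams) -> np.ndarray:
    """log[tau(k) phi_k(z)] as an (M, m) array; -inf where tau(k) == 0."""
    d = (z[:, None] - params.mu[None, :]) / params.sigma
    logphi = -0.5 * d * d - math.log(params.sigma) - 0.5 * _LOG_2PI
    with np.errstate(divide="ignore"):
        return logphi + np.log(params.tau)[None, :]


def mixture_density(z, params: GMMParams) -> np.ndarray | float:
    """Evaluate the mixture density f(z) = sum_k tau(k) phi_k(z) / sigma."""
    zf = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.exp(logsumexp(_log_weighted_density(zf, params), axis=1))
    return float(out[0]) if np.isscalar(z) or np.ndim(z) == 0 else out


def log_likelihood(Z, params: GMMParams) -> float:
    """Pooled log-likelihood of the data under `params`."""
    z = _as_flat(Z)
    return float(logsumexp(_log_weighted_density(z, params), axis=1).sum())


def _e_step_flat(z: np.ndarray, params: GMMParams) -> tuple[np.ndarray, float]:
    """Membership matrix (M, m) and the log-likelihood, log-sum-exp stabilized.

    Fused in-place version of ``exp(logw - logsumexp(logw))``; a single (M, m)
    buffer is reused for log-densities, exponentials and memberships.
    """
    d = z[:, None] - params.mu[None, :]
    d /= params.sigma
    np.multiply(d, d, out=d)
    d *= -0.5
    with np.errstate(divide="ignore"):
        d += np.log(params.tau)[None, :] - math.log(params.sigma) - 0.5 * _LOG_2PI
    amax = d.max(axis=1)
    d -= amax[:, None]
    np.exp(d, out=d)
    s = d.sum(axis=1)
    ll = float(np.log(s).sum() + amax.sum())
    d /= s[:, None]
    return d, ll


def e_step(Z, params: GMMParams) -> np.ndarray:
    """Posterior memberships tau_ij(k), shaped (n, N, m) for matrix input."""
    if isinstance(Z, SubjectVoxelMatrix):
        shape = Z.values.shape + (params.m,)
    else:
        shape = np.asarray(Z).shape + (params.m,)
    resp, _ = _e_step_flat(_as_flat(Z), params)
    return resp.reshape(shape)


def _check_collapse(nk: np.ndarray) -> None:
    for k, w in enumerate(nk):
        if w < 1e-10:
            raise ComponentCollapseError(
                f"component collapse: component {k + 1} has total weight {w:.3e}"
            )


def _m_step_flat(z: np.ndarray, resp: np.ndarray) -> GMMParams:
    M = z.size
    nk = resp.sum(axis=0)
    _check_collapse(nk)
    mu = (resp * z[:, None]).sum(axis=0) / nk
    sigma2 = float((resp * (z[:, None] - mu[None, :]) ** 2).sum()) / M
    tau = nk / M
    order = np.argsort(mu, kind="stable")
    return GMMParams(mu=mu[order], sigma=math.sqrt(sigma2), tau=tau[order])


def _m_step_fast(z: np.ndarray, resp: np.ndarray, zsum: float, zsq: float) -> GMMParams:
    """M-step using sufficient statistics; valid when membership rows sum to 1.

    The pooled variance reduces to (sum z^2 - sum_k n_k mu_k^2) / M because
    the cross term collapses under sum_k tau_ij(k) = 1.
    """
    M = z.size
    nk = resp.sum(axis=0)
    _check_collapse(nk)
    mu = resp.T @ z / nk
    sigma2 = max((zsq - float(nk @ (mu * mu))) / M, 1e-300)
    tau = nk / M
    order = np.argsort(mu, kind="stable")
    return GMMParams(mu=mu[order], sigma=math.sqrt(sigma2), tau=tau[order])


def m_step(Z, memberships: np.ndarray) -> GMMParams:
    """Maximization step: weighted means, pooled shared variance, grand-mean tau.

    Raises :class:`ComponentCollapseError` if a component's total membership
    weight falls below 1e-10.
    """
    z = _as_flat(Z)
    resp = np.asarray(memberships, dtype=float).reshape(z.size, -1)
    return _m_step_flat(z, resp)


def _init_params(z: np.ndarray, m: int, init: str, rng: np.random.Generator | None) -> GMMParams:
    sd = float(z.std())
    if sd == 0:
        sd = 1.0
    if init == "quantile":
        mu = np.quantile(z, (np.arange(1, m + 1)) / (m + 1))
    elif init == "random":
        if rng is None:
            raise ValueError("random init requires a seed")
        mu = np.sort(rng.choice(z, size=m, replace=False))
    else:
        raise ValueError(f"unknown init strategy {init!r}")
    # jitter exact ties apart so means are strictly ascending
    for k in range(1, m):
        if mu[k] <= mu[k - 1]:
            mu[k] = mu[k - 1] + 1e-6 * max(sd, 1.0)
    return GMMParams(mu=mu, sigma=sd, tau=np.full(m, 1.0 / m))


def _refine_tau(
    z: np.ndarray,
    params: GMMParams,
    shape: tuple[int, int] | None,
    max_rounds: int = 50,
) -> GMMParams:
    """Iterate tau <- grand mean of memberships to its (bitwise) fixed point.

    When the data's (n, N) shape is known, the grand mean is taken as the
    voxel mean per subject followed by the subject mean — the same reduction
    order the a-posteriori subject/group mixing estimators use — so the
    reported global tau is bit-identical to the all-subjects group estimate.

    The map is a coordinate ascent on a likelihood that is concave in tau, so
    it has a unique fixed point; plain iteration is linearly convergent and an
    Aitken extrapolation is used to reach the bitwise fixed point quickly.
    """

    def reduce(resp: np.ndarray) -> np.ndarray:
        if shape is not None:
            n, N = shape
            return resp.reshape(n, N, -1).mean(axis=1).mean(axis=0)
        return resp.mean(axis=0)

    def real_step(tau: np.ndarray) -> np.ndarray:
        resp, _ = _e_step_flat(
            z, GMMParams(mu=params.mu, sigma=params.sigma, tau=tau)
        )
        return reduce(resp)

    # row-stabilized component densities, computed once for the cheap map
    q = (z[:, None] - params.mu[None, :]) / params.sigma
    np.multiply(q, q, out=q)
    q *= -0.5
    q -= q.max(axis=1, keepdims=True)
    np.exp(q, out=q)

    def cheap_step(tau: np.ndarray) -> np.ndarray:
        w = q * tau
        return reduce(w / w.sum(axis=1, keepdims=True))

    m = params.m

    # Newton iteration on the stationarity condition F(tau) = g(tau) - tau = 0
    # with g(tau) = mean_i resp_i(tau); quadratically convergent regardless of
    # component overlap.  dg_k/dtau_l = delta_kl g_k/tau_k - C_kl/tau_l with
    # C = resp' resp / M, reduced to the m-1 free coordinates of the simplex.
    tau = params.tau
    for _ in range(30):
        w = q * tau
        resp = w / w.sum(axis=1, keepdims=True)
        g = reduce(resp)
        F = g - tau
        if np.max(np.abs(F)) < 1e-15 or m == 1 or np.any(tau <= 0):
            break
        C = (resp.T @ resp) / resp.shape[0]
        J = np.diag(g / tau) - C / tau[None, :]
        H = (J[:-1, :-1] - J[:-1, -1][:, None]) - np.eye(m - 1)
        try:
            delta = np.linalg.solve(H, -F[:-1])
        except np.linalg.LinAlgError:
            tau = g
            continue
        cand = tau[:-1] + delta
        cand = np.append(cand, 1.0 - cand.sum())
        if np.all(cand > 0) and np.all(cand < 1):
            tau = cand
        else:
            tau = g  # fall back to a plain (monotone) coordinate M-step

    # polish with the exact E-step map so the returned tau is a bitwise fixed
    # point of the downstream code path
    older: np.ndarray | None = None
    for _ in range(max_rounds):
        t1 = real_step(tau)
        if np.array_equal(t1, tau):
            break
        if older is not None and np.array_equal(t1, older):
            # two-cycle at float resolution: no exact fixed point exists
            break
        older, tau = tau, t1
    return GMMParams(mu=params.mu, sigma=params.sigma, tau=tau)


def _pack(p: GMMParams) -> np.ndarray:
    """Unconstrained coordinates (mu, log sigma, log tau) for extrapolation."""
    with np.errstate(divide="ignore"):
        return np.concatenate([p.mu, [math.log(p.sigma)], np.log(p.tau)])


def _unpack(vec: np.ndarray, m: int) -> GMMParams | None:
    """Inverse of :func:`_pack`; None when the point is not a valid parameter."""
    if not np.all(np.isfinite(vec[: m + 1])):
        return None
    mu = vec[:m].copy()
    sigma = math.exp(float(vec[m]))
    w = np.exp(vec[m + 1 :] - vec[m + 1 :].max())
    tau = w / w.sum()
    order = np.argsort(mu, kind="stable")
    mu, tau = mu[order], tau[order]
    if sigma <= 0 or not np.isfinite(sigma) or np.any(tau <= 0):
        return None
    if m > 1 and not np.all(np.diff(mu) > 0):
        return None
    return GMMParams(mu=mu, sigma=sigma, tau=tau)


def _em_accel(
    params: GMMParams, step, loglik_fn, tol: float, max_iter: int
) -> tuple[GMMParams, list[float], int, bool]:
    """Monotone EM with SQUAREM-style extrapolation.

    Plain EM converges linearly at a rate set by the fraction of missing
    component information, which is painfully slow for overlapping
    components.  Every two EM steps, a squared-extrapolation candidate is
    formed in unconstrained coordinates and accepted only if it does not
    decrease the log-likelihood, so the recorded trace stays non-decreasing
    and every accept is at least as good as the plain double step.
    `max_iter` caps the number of elementary EM steps.
    """
    trace: list[float] = []
    prev = -np.inf
    n_steps = 0
    converged = False
    theta = params
    while n_steps < max_iter:
        th1, ll0 = step(theta, n_steps + 1)
        n_steps += 1
        trace.append(ll0)
        if ll0 - prev < tol:
            converged = True
            break
        prev = ll0
        if n_steps >= max_iter:
            theta = th1
            break
        th2, ll1 = step(th1, n_steps + 1)
        n_steps += 1
        trace.append(ll1)
        if ll1 - ll0 < tol:
            converged = True
            theta = th1
            break
        prev = ll1
        p0, p1, p2 = _pack(theta), _pack(th1), _pack(th2)
        r = p1 - p0
        v = (p2 - p1) - r
        vn = float(np.linalg.norm(v))
        if not np.isfinite(vn) or vn < 1e-300:
            theta = th2
            continue
        alpha = -max(float(np.linalg.norm(r)) / vn, 1.0)
        cand = _unpack(p0 - 2.0 * alpha * r + alpha * alpha * v, theta.m)
        if cand is None:
            theta = th2
            continue
        llc = loglik_fn(cand)
        theta = cand if (np.isfinite(llc) and llc >= ll1) else th2
    return theta, trace, n_steps, converged


try:
    from numba import njit as _njit

    @_njit(cache=False)
    def _fused_em_kernel(z, mu, inv_sigma, logtau, nk, sk):  # pragma: no cover
        """One fused E+M pass: Kahan-summed log-likelihood plus the
        sufficient statistics sum_i resp_ik and sum_i resp_ik z_i."""
        M = z.size
        m = mu.size
        c = np.log(inv_sigma) - 0.5 * np.log(2.0 * np.pi)
        for k in range(m):
            nk[k] = 0.0
            sk[k] = 0.0
        w = np.empty(m)
        ll = 0.0
        comp = 0.0
        for i in range(M):
            amax = -np.inf
            for k in range(m):
                d = (z[i] - mu[k]) * inv_sigma
                w[k] = logtau[k] + c - 0.5 * d * d
                if w[k] > amax:
                    amax = w[k]
            s = 0.0
            for k in range(m):
                w[k] = np.exp(w[k] - amax)
                s += w[k]
            y = (np.log(s) + amax) - comp
            t = ll + y
            comp = (t - ll) - y
            ll = t
            inv = 1.0 / s
            for k in range(m):
                r = w[k] * inv
                nk[k] += r
                sk[k] += r * z[i]
        return ll

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _make_generic_step(z: np.ndarray):
    zsq = float(z @ z)
    M = z.size

    if _HAVE_NUMBA:
        nk = np.empty(1)
        sk = np.empty(1)

        def e_stats(p: GMMParams) -> tuple[float, np.ndarray, np.ndarray]:
            nonlocal nk, sk
            if nk.size != p.m:
                nk = np.empty(p.m)
                sk = np.empty(p.m)
            with np.errstate(divide="ignore"):
                logtau = np.log(p.tau)
            ll = _fused_em_kernel(z, p.mu, 1.0 / p.sigma, logtau, nk, sk)
            return ll, nk, sk

    else:

        def e_stats(p: GMMParams) -> tuple[float, np.ndarray, np.ndarray]:
            resp, ll = _e_step_flat(z, p)
            return ll, resp.sum(axis=0), resp.T @ z

    def step(p: GMMParams, it: int) -> tuple[GMMParams, float]:
        ll, nk_, sk_ = e_stats(p)
        try:
            _check_collapse(nk_)
        except ComponentCollapseError as exc:
            raise ComponentCollapseError(f"{exc} (iteration {it})") from exc
        mu = sk_ / nk_
        sigma2 = max((zsq - float(nk_ @ (mu * mu))) / M, 1e-300)
        tau = nk_ / M
        order = np.argsort(mu, kind="stable")
        new = GMMParams(mu=mu[order], sigma=math.sqrt(sigma2), tau=tau[order])
        return new, ll

    def ll_fn(p: GMMParams) -> float:
        return e_stats(p)[0]

    return step, ll_fn


def _make_m2_step(z: np.ndarray):
    """Two-component EM exploiting that the log posterior odds are linear in z.

    For m = 2 with shared sigma, log[tau(2)phi_2 / tau(1)phi_1] = c0 + c1 z,
    so the E-step needs one logistic transform of a linear function and the
    M-step only the sufficient statistics sum(r2) and sum(r2 z).  Identical
    mathematics to the generic path, at a fraction of the memory traffic.
    """
    from scipy.special import expit

    M = z.size
    zsum = float(z.sum())
    zsq = float(z @ z)

    def _odds_and_ll(p: GMMParams) -> tuple[np.ndarray, float]:
        mu1, mu2 = (float(x) for x in p.mu)
        t1 = float(p.tau[0])
        sigma = float(p.sigma)
        s2 = sigma * sigma
        c1 = (mu2 - mu1) / s2
        with np.errstate(divide="ignore"):
            c0 = math.log(float(p.tau[1]) / t1) - c1 * (mu1 + mu2) / 2.0
        t = c1 * z
        t += c0
        # loglik = sum log[tau(1)phi_1] + sum softplus(log odds)
        a1 = M * (math.log(t1) - math.log(sigma) - 0.5 * _LOG_2PI) - (
            zsq - 2.0 * mu1 * zsum + M * mu1 * mu1
        ) / (2.0 * s2)
        sp = float(np.maximum(t, 0.0).sum() + np.log1p(np.exp(-np.abs(t))).sum())
        return t, a1 + sp

    def step(p: GMMParams, it: int) -> tuple[GMMParams, float]:
        t, ll = _odds_and_ll(p)
        r2 = expit(t)
        n2 = float(r2.sum())
        n1 = M - n2
        try:
            _check_collapse(np.array([n1, n2]))
        except ComponentCollapseError as exc:
            raise ComponentCollapseError(f"{exc} (iteration {it})") from exc
        s2sum = float(r2 @ z)
        mu2n = s2sum / n2
        mu1n = (zsum - s2sum) / n1
        sigma2 = max((zsq - n1 * mu1n * mu1n - n2 * mu2n * mu2n) / M, 1e-300)
        if mu1n > mu2n:
            mu1n, mu2n, n1, n2 = mu2n, mu1n, n2, n1
        elif mu1n == mu2n:  # degenerate: nudge apart so ordering stays strict
            mu2n = np.nextafter(mu2n, np.inf)
        new = GMMParams(
            mu=np.array([mu1n, mu2n]),
            sigma=math.sqrt(sigma2),
            tau=np.array([n1 / M, n2 / M]),
        )
        return new, ll

    def ll_fn(p: GMMParams) -> float:
        return _odds_and_ll(p)[1]

    return step, ll_fn


def fit_em(
    Z,
    m: int,
    *,
    init: str = "quantile",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> FitResult:
    """Fit the m-component equal-variance mixture to the pooled data by EM.

    Parameters
    ----------
    Z
        Standardized :class:`SubjectVoxelMatrix` or any array of observations
        (pooled over subjects and voxels).
    m
        Number of Gaussian components (>= 1).
    init
        ``"quantile"`` (deterministic: means at the k/(m+1) data quantiles)
        or ``"random"`` (means drawn from the data; requires `seed`).
    tol
        Stop when the log-likelihood improves by less than this.
    max_iter
        Iteration cap; `converged` is False if it is reached first.
    seed
        Seed for random initialization.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if isinstance(Z, SubjectVoxelMatrix) and not Z.standardized:
        raise ValueError("matrix must be standardized before fitting")
    z = _as_flat(Z)
    if np.unique(z).size < m:
        raise ValueError(
            f"m={m} exceeds the number of distinct data values ({np.unique(z).size})"
        )
    rng = np.random.default_rng(seed) if seed is not None else None
    params = _init_params(z, m, init, rng)

    step, ll_fn = (_make_m2_step if m == 2 else _make_generic_step)(z)
    params, trace, n_iter, converged = _em_accel(params, step, ll_fn, tol, max_iter)

    shape = Z.values.shape if isinstance(Z, SubjectVoxelMatrix) else (
        np.asarray(Z).shape if np.asarray(Z).ndim == 2 else None
    )
    params = _refine_tau(z, params, shape)
    _, ll = _e_step_flat(z, params)
    trace.append(ll)
    d = 2 * m
    return FitResult(
        params=params,
        loglik=ll,
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        aic=2.0 * d - 2.0 * ll,
        n_params=d,
    )


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2d - 2 loglik with d = 2m."""
    return 2.0 * fit.n_params - 2.0 * fit.loglik


def select_m(
    Z,
    m_candidates,
    *,
    restarts: int = 5,
    seed: int = 0,
    init: str = "quantile",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[FitResult, pd.DataFrame]:
    """Fit each candidate order and pick the one minimizing AIC.

    Each m is fit once from the deterministic quantile initialization plus
    `restarts` seeded random initializations; the best log-likelihood fit is
    kept per m.  AIC ties break toward smaller m (parsimony).

    Returns the selected fit and the full m -> AIC table.
    """
    m_candidates = list(m_candidates)
    if not m_candidates:
        raise ValueError("m_candidates must be non-empty")
    rows = []
    best_fit: FitResult | None = None
    errors: list[str] = []
    rng = np.random.default_rng(seed)
    for m in sorted(m_candidates):
        fit_m: FitResult | None = None
        seeds = [None] + [int(rng.integers(2**31 - 1)) for _ in range(restarts)]
        for s in seeds:
            try:
                f = fit_em(
                    Z, m,
                    init=init if s is None else "random",
                    tol=tol, max_iter=max_iter, seed=s,
                )
            except (ComponentCollapseError, ValueError) as exc:
                errors.append(f"m={m}: {exc}")
                continue
            if fit_m is None or f.loglik > fit_m.loglik:
                fit_m = f
        if fit_m is None:
            continue
        rows.append(
            {"m": m, "loglik": fit_m.loglik, "d": fit_m.n_params, "aic": fit_m.aic}
        )
        if best_fit is None or fit_m.aic < best_fit.aic:
            best_fit = fit_m
    if best_fit is None:
        raise RuntimeError("all candidate fits failed: " + "; ".join(errors))
    table = pd.DataFrame(rows)
    table["selected"] = table["m"] == best_fit.params.m
    return best_fit, table
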