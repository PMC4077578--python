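"""EM fitting of a single sample's t / skew-t mixture, with BIC order selection.

The t family uses the classical ECM updates (closed-form weighted moments,
digamma score equation for the degrees of freedom).  The unrestricted
skew-t family uses closed-form proposal updates built from
coordinate-wise truncated-normal moments of the latent skewing vector,
accepted through a backtracking line search on the observed-data
log-likelihood.  The safeguard makes every recorded log-likelihood trace
non-decreasing by construction, for both families, which is the
correctness contract the fitting procedure is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq
from sklearn.cluster import KMeans

from .distributions import (ComponentParams, LatentAugmentation, MixtureModel,
                            _chol, component_logpdf_matrix)

__all__ = [
    "FitOptions",
    "SampleFit",
    "FittingError",
    "initialize_mixture",
    "posterior_responsibilities",
    "update_parameters",
    "fit_mixture",
    "bic_score",
    "parameter_count",
    "select_components",
]

NU_MIN, NU_MAX = 0.5, 400.0


class FittingError(RuntimeError):
    """Raised when no EM start produces a usable fit."""


class _Collapse(RuntimeError):
    """Internal signal: a component lost essentially all of its cells."""


@dataclass
class FitOptions:
    family: str = "t"
    g: int = 1
    max_iter: int = 500
    tol: float = 1e-6
    n_starts: int = 3
    seed: int = 0
    nu_mode: str = "estimate"       # "estimate" or "fixed:<value>"
    min_cluster_fraction: float = 1e-3

    def validate(self) -> None:
        if self.family not in ("t", "skew-t"):
            raise ValueError(f"family must be 't' or 'skew-t', got {self.family!r}")
        if self.tol <= 0 or self.max_iter < 1 or self.n_starts < 1:
            raise ValueError("tol > 0, max_iter >= 1 and n_starts >= 1 required")

    @property
    def fixed_nu(self) -> float | None:
        if self.nu_mode == "estimate":
            return None
        if self.nu_mode.startswith("fixed:"):
            return float(self.nu_mode.split(":", 1)[1])
        raise ValueError(f"nu_mode must be 'estimate' or 'fixed:<value>', got {self.nu_mode!r}")


@dataclass
class SampleFit:
    model: MixtureModel
    loglik_trace: list[float]
    responsibilities: np.ndarray
    labels: np.ndarray
    bic: float
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


# ---------------------------------------------------------------------------
# initialization


def initialize_mixture(Y: np.ndarray, g: int, family: str, seed: int,
                       subsample: int = 20_000) -> MixtureModel:
    """k-means initialization: centers, within-cluster covariances, fractions."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n < g * (p + 1):
        raise ValueError(
            f"n={n} too small to initialize g={g} components in {p} dimensions; "
            "use a smaller g")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=min(n, subsample), replace=False) if n > subsample else np.arange(n)
    Ys = Y[idx]
    if g == 1:
        centers = Ys.mean(axis=0)[None, :]
        assign = np.zeros(len(Ys), dtype=int)
    else:
        km = KMeans(n_clusters=g, n_init=3, random_state=int(seed) % (2**31))
        assign = km.fit_predict(Ys)
        centers = km.cluster_centers_
    total_cov = np.atleast_2d(np.cov(Ys.T))
    reg = 1e-6 * max(np.trace(total_cov) / p, 1e-12) * np.eye(p)
    comps = []
    for h in range(g):
        mask = assign == h
        frac = max(mask.mean(), 1.0 / len(Ys))
        if mask.sum() > p + 1:
            cov = np.atleast_2d(np.cov(Ys[mask].T)) + reg
        else:
            cov = total_cov + reg
        delta = np.zeros(p)
        if family == "skew-t" and mask.sum() > p + 1:
            # seed the skew from the coordinate-wise sample skewness: delta = 0
            # is nearly a fixed point of the moment updates, so an informative
            # start matters more than its exact calibration
            X = Ys[mask]
            sd = X.std(axis=0)
            gam = np.mean((X - X.mean(axis=0)) ** 3, axis=0) / np.clip(sd, 1e-12, None) ** 3
            delta = np.sign(gam) * sd * np.cbrt(np.clip(np.abs(gam), 0.0, 4.0))
        comps.append(ComponentParams(pi=frac, mu=centers[h].copy(), Sigma=cov,
                                     delta=delta, nu=30.0))
    tot = sum(c.pi for c in comps)
    for c in comps:
        c.pi /= tot
    return MixtureModel(family=family, components=comps, marker_names=[])


# ---------------------------------------------------------------------------
# E-step


def _truncnorm_moments(m: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of N(m, s^2) truncated to (0, inf), elementwise.

    Uses the scaled complementary error function for a stable hazard ratio
    phi(a)/Phi(a) far into the left tail.
    """
    a = m / s
    H = np.sqrt(2.0 / np.pi) / special.erfcx(-a / np.sqrt(2.0))
    mean = m + s * H
    var = s * s * np.clip(1.0 - H * (H - a), 1e-12, None)
    return mean, var


def _skew_latent_moments(Y: np.ndarray, comp: ComponentParams):
    """Approximate conditional moments of (w, z=|u0|) given y for one component.

    w is approximated by its t-family form under the convolved scale
    Omega = Sigma + Delta^2; z by coordinate-wise truncated-normal moments
    of its exact conditional Gaussian (diagonal covariance approximation,
    exact at p = 1).  These feed proposal M-steps that are safeguarded
    against the observed likelihood, so the approximation affects only the
    step quality, never correctness.
    """
    p = comp.p
    delta = comp.delta
    R = Y - comp.mu
    Omega = comp.Sigma + np.diag(delta ** 2)
    Lo = _chol(Omega, "Omega")
    zo = np.linalg.solve(Lo, R.T)
    d = np.einsum("ij,ij->j", zo, zo)
    w = (comp.nu + p) / (comp.nu + d)
    Si = np.linalg.inv(comp.Sigma + 1e-12 * np.trace(comp.Sigma) / p * np.eye(p))
    Sz = np.linalg.inv(np.eye(p) + (delta[:, None] * Si) * delta[None, :])
    m_z = R @ (Si * delta) @ Sz          # rows: S_z Delta Sigma^-1 (y - mu)
    s_z = np.sqrt(np.clip(np.diag(Sz), 1e-12, None)[None, :] / w[:, None])
    Ez, Vz = _truncnorm_moments(m_z, s_z)
    return w, d, Ez, Vz


def posterior_responsibilities(Y: np.ndarray, model: MixtureModel) -> LatentAugmentation:
    """E-step quantities: responsibilities, gamma weights, latent skew moments."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    logL = component_logpdf_matrix(Y, model)
    with np.errstate(divide="ignore"):
        A = logL + np.log(np.clip(model.pi, 1e-300, None))
    norm = special.logsumexp(A, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        raise FloatingPointError(
            f"all component densities vanished at cell index {int(np.flatnonzero(bad)[0])}")
    tau = np.exp(A - norm[:, None])
    w = np.empty((n, model.g))
    u_mean = u_var = None
    if model.family == "skew-t":
        u_mean = np.empty((n, model.g, p))
        u_var = np.empty((n, model.g, p))
    for h, comp in enumerate(model.components):
        if model.family == "skew-t":
            w[:, h], _, u_mean[:, h], u_var[:, h] = _skew_latent_moments(Y, comp)
        elif model.family == "t":
            z = np.linalg.solve(_chol(comp.Sigma), (Y - comp.mu).T)
            d = np.einsum("ij,ij->j", z, z)
            w[:, h] = (comp.nu + p) / (comp.nu + d)
        else:
            w[:, h] = 1.0
    return LatentAugmentation(tau=tau, w=w, u_mean=u_mean, u_var=u_var)


# ---------------------------------------------------------------------------
# M-step


def _update_nu(nu_old: float, p: int, tau_h: np.ndarray, w_h: np.ndarray) -> float:
    """Solve the degrees-of-freedom score equation on [NU_MIN, NU_MAX].

    Standard one-step ECM update: E[log w] is evaluated at the current nu,
    giving the digamma-based score whose root is the new nu.
    """
    n_h = tau_h.sum()
    c = (np.sum(tau_h * (np.log(w_h) - w_h)) / n_h + 1.0
         + special.digamma((nu_old + p) / 2.0) - np.log((nu_old + p) / 2.0))

    def score(nu):
        return -special.digamma(nu / 2.0) + np.log(nu / 2.0) + c

    lo, hi = score(NU_MIN), score(NU_MAX)
    if lo <= 0:
        return NU_MIN
    if hi >= 0:
        return NU_MAX          # effectively Gaussian
    return float(brentq(score, NU_MIN, NU_MAX, xtol=1e-6))


def update_parameters(Y: np.ndarray, latents: LatentAugmentation,
                      model: MixtureModel, options: FitOptions) -> MixtureModel:
    """One conditional-maximization pass; returns the proposed new model.

    For the t family these are the exact ECM updates.  For the skew-t
    family they are proposal updates (the caller safeguards them against
    the observed log-likelihood).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    tau, w = latents.tau, latents.w
    n_h = tau.sum(axis=0)
    floor = options.min_cluster_fraction * n
    if np.any(n_h < max(floor, p + 1.0)):
        raise _Collapse(f"component occupancy {n_h.min():.2f} below floor")
    fixed_nu = options.fixed_nu
    new_comps = []
    for h, comp in enumerate(model.components):
        th, wh = tau[:, h], w[:, h]
        twh = th * wh
        if model.family == "skew-t":
            Ez, Vz = latents.u_mean[:, h], latents.u_var[:, h]
            mu = (twh[:, None] * (Y - Ez * comp.delta)).sum(axis=0) / twh.sum()
            num = (twh[:, None] * (Y - mu) * Ez).sum(axis=0)
            den = (twh[:, None] * (Ez * Ez + Vz)).sum(axis=0)
            delta = num / np.clip(den, 1e-12, None)
            R = Y - mu - Ez * delta
            scatter = (twh[:, None] * R).T @ R
            zvar = ((th * wh)[:, None] * Vz).sum(axis=0)
            Sigma = (scatter + np.diag(delta * zvar * delta)) / n_h[h]
        else:
            mu = (twh[:, None] * Y).sum(axis=0) / twh.sum()
            R = Y - mu
            Sigma = (twh[:, None] * R).T @ R / n_h[h]
            delta = np.zeros(p)
        Sigma = 0.5 * (Sigma + Sigma.T)
        Sigma += 1e-10 * max(np.trace(Sigma) / p, 1e-12) * np.eye(p)
        nu = fixed_nu if fixed_nu is not None else _update_nu(comp.nu, p, th, wh)
        new_comps.append(ComponentParams(pi=n_h[h] / n, mu=mu, Sigma=Sigma,
                                         delta=delta, nu=float(nu)))
    return MixtureModel(model.family, new_comps, list(model.marker_names))


# ---------------------------------------------------------------------------
# driver


def _observed_loglik(Y: np.ndarray, model: MixtureModel) -> tuple[float, np.ndarray]:
    logL = component_logpdf_matrix(Y, model)
    with np.errstate(divide="ignore"):
        A = logL + np.log(np.clip(model.pi, 1e-300, None))
    norm = special.logsumexp(A, axis=1)
    return float(norm.sum()), np.exp(A - norm[:, None])


def _interp_model(old: MixtureModel, new: MixtureModel, t: float) -> MixtureModel:
    comps = []
    for co, cn in zip(old.components, new.components):
        comps.append(ComponentParams(
            pi=(1 - t) * co.pi + t * cn.pi,
            mu=(1 - t) * co.mu + t * cn.mu,
            Sigma=(1 - t) * co.Sigma + t * cn.Sigma,
            delta=(1 - t) * co.delta + t * cn.delta,
            nu=float(np.exp((1 - t) * np.log(co.nu) + t * np.log(cn.nu))),
        ))
    return MixtureModel(old.family, comps, list(old.marker_names))


def _polish_skew(Y: np.ndarray, model: MixtureModel, ll: float,
                 options: FitOptions) -> tuple[MixtureModel, float]:
    """Coordinate-wise conditional maximization of each skew entry and dof.

    The moment-based proposals can under-move delta near symmetric
    configurations; a golden-section line search on the observed
    log-likelihood, one coordinate at a time, escapes them.  Only
    improvements are accepted, so monotonicity is preserved.
    """
    from scipy.optimize import minimize_scalar

    for h, comp in enumerate(model.components):
        sd = np.sqrt(np.diag(comp.Sigma))
        # E|t_nu| factor: moving delta by dv shifts the component mean by
        # c_nu * dv, so the search compensates mu to stay on the
        # mean-preserving ridge where the likelihood actually discriminates
        nu = comp.nu
        c_nu = (np.sqrt(nu / np.pi) * np.exp(special.gammaln((nu - 1) / 2.0)
                                             - special.gammaln(nu / 2.0))
                if nu > 1.1 else np.sqrt(2.0 / np.pi))
        for i in range(comp.p):
            cur = comp.delta[i]
            span = 2.0 * sd[i] + abs(cur)

            def neg(v, h=h, i=i, cur=cur):
                trial = model.copy()
                trial.components[h].delta[i] = v
                trial.components[h].mu[i] += (cur - v) * c_nu
                val, _ = _observed_loglik(Y, trial)
                return -val

            res = minimize_scalar(neg, bounds=(cur - span, cur + span),
                                  method="bounded",
                                  options={"xatol": 5e-3 * sd[i], "maxiter": 25})
            if np.isfinite(res.fun) and -res.fun > ll:
                comp.mu[i] += (cur - float(res.x)) * c_nu
                comp.delta[i] = float(res.x)
                ll = -res.fun
        if options.fixed_nu is None:

            def neg_nu(lognu, h=h):
                trial = model.copy()
                trial.components[h].nu = float(np.exp(lognu))
                val, _ = _observed_loglik(Y, trial)
                return -val

            res = minimize_scalar(neg_nu, bounds=(np.log(NU_MIN), np.log(NU_MAX)),
                                  method="bounded", options={"xatol": 1e-2})
            if np.isfinite(res.fun) and -res.fun > ll:
                model.components[h].nu = float(np.exp(res.x))
                ll = -res.fun
    return model, ll


def _em_run(Y: np.ndarray, model: MixtureModel, options: FitOptions):
    ll, _ = _observed_loglik(Y, model)
    trace = [ll]
    converged = False
    polish = model.family == "skew-t"
    for _ in range(options.max_iter):
        latents = posterior_responsibilities(Y, model)
        proposal = update_parameters(Y, latents, model, options)
        ll_new, _ = _observed_loglik(Y, proposal)
        t = 1.0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-10) and t > 1e-3:
            t *= 0.5
            proposal = _interp_model(model, proposal, t)
            ll_new, _ = _observed_loglik(Y, proposal)
        if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
            model = proposal
        else:
            ll_new = ll                # keep the current model; no decrease recorded
        stalled = abs(ll_new - ll) <= options.tol * abs(ll)
        if stalled and polish:
            # the moment proposals have flat directions in (mu, delta); a
            # conditional line-search pass either escapes the stall or
            # certifies convergence
            model, ll_polished = _polish_skew(Y, model, ll_new, options)
            stalled = abs(ll_polished - ll_new) <= options.tol * abs(ll_new)
            ll_new = ll_polished
        trace.append(ll_new)
        ll = ll_new
        if stalled:
            converged = True
            break
    return model, trace, converged


def fit_mixture(Y: np.ndarray, options: FitOptions) -> SampleFit:
    """Best-of-n_starts EM fit of a g-component mixture to one sample."""
    options.validate()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = Y.shape
    best = None
    errors = []
    for start in range(options.n_starts):
        fit = None
        for attempt in range(2):       # one restart on component collapse
            seed = options.seed + 1000 * start + 500 * attempt
            try:
                init = initialize_mixture(Y, options.g, options.family, seed)
                if options.fixed_nu is not None:
                    for c in init.components:
                        c.nu = options.fixed_nu
                model, trace, converged = _em_run(Y, init, options)
                fit = (model, trace, converged)
                break
            except _Collapse as exc:
                errors.append(str(exc))
            except ValueError as exc:
                raise
        if fit is None:
            continue
        if best is None or fit[1][-1] > best[1][-1]:
            best = fit
    if best is None:
        raise FittingError(
            f"all {options.n_starts} EM starts collapsed for g={options.g}; "
            f"try a smaller g ({'; '.join(errors[:2])})")
    model, trace, converged = best
    ll, tau = _observed_loglik(Y, model)
    labels = np.argmax(tau, axis=1)
    d = parameter_count(options.family, options.g, p)
    return SampleFit(model=model, loglik_trace=trace, responsibilities=tau,
                     labels=labels, bic=bic_score(ll, d, n),
                     converged=converged, n_iter=len(trace) - 1)


def parameter_count(family: str, g: int, p: int) -> int:
    """Free parameters: proportions + means + scales + dof (+ skews)."""
    d = (g - 1) + g * p + g * p * (p + 1) // 2 + g
    if family == "skew-t":
        d += g * p
    return d


def bic_score(loglik: float, d: int, n: int) -> float:
    """Bayesian Information Criterion: -2 loglik + d log n (smaller is better)."""
    if n < 1 or d < 1:
        raise ValueError("need n >= 1 and d >= 1")
    return -2.0 * loglik + d * np.log(n)


def select_components(Y: np.ndarray, g_range: tuple[int, int],
                      options: FitOptions) -> SampleFit:
    """Fit every g in the inclusive range and return the BIC-minimizing fit.

    Ties break toward the smaller g.
    """
    lo, hi = g_range
    if not (1 <= lo <= hi <= 30):
        raise ValueError(f"g_range must lie within [1, 30], got {g_range}")
    best = None
    errors = []
    for g in range(lo, hi + 1):
        try:
            fit = fit_mixture(Y, replace(options, g=g))
        except (FittingError, ValueError) as exc:
            errors.append(f"g={g}: {exc}")
            continue
        if best is None or fit.bic < best.bic:
            best = fit
    if best is None:
        raise FittingError("no mixture order could be fitted: " + "; ".join(errors))
    return best
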