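"""Multivariate t and unrestricted skew-t components and their mixtures.

Each cell population is modeled by one mixture component.  The symmetric
family is the multivariate t with location ``mu``, SPD scale ``Sigma`` and
degrees of freedom ``nu``; the asymmetric family is the unrestricted
(Sahu-form) skew t, built from the latent representation

    y = mu + Delta |u0| + u1,        w ~ Gamma(nu/2, nu/2),
    (u0, u1) | w  ~  N(0, blockdiag(I_p, Sigma) / w),

with ``Delta = diag(delta)``.  Its density has the closed form

    f(y) = 2^p t_p(y; mu, Omega, nu) T_p(q(y) s(y); 0, Lambda, nu + p),

where ``Omega = Sigma + Delta^2``, ``q(y) = Delta Omega^{-1} (y - mu)``,
``s(y) = sqrt((nu + p) / (nu + d_Omega(y)))``, ``Lambda = I - Delta
Omega^{-1} Delta`` and ``d_Omega`` is the squared Mahalanobis distance
under ``Omega``.  Small nu gives heavy tails (robustness to debris and
outlier events); delta captures the asymmetric tail subpopulations common
in fluorescence data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special, stats
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import gammaln

__all__ = [
    "ComponentParams",
    "MixtureModel",
    "LatentAugmentation",
    "mahalanobis_sq",
    "log_mvt_pdf",
    "mvt_cdf",
    "log_mvskewt_pdf",
    "log_mixture_pdf",
    "sample_mixture",
]

FAMILIES = ("normal", "t", "skew-t")

#: diagonal regularization factor applied when a Cholesky factorization fails
_REG_EPS = 1e-8


@dataclass
class ComponentParams:
    """Parameters of one mixture component (one cell population)."""

    pi: float
    mu: np.ndarray
    Sigma: np.ndarray
    delta: np.ndarray
    nu: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def validate(self) -> None:
        p = self.p
        if self.Sigma.shape != (p, p):
            raise ValueError(f"Sigma shape {self.Sigma.shape} != ({p}, {p})")
        if self.delta.shape != (p,):
            raise ValueError(f"delta shape {self.delta.shape} != ({p},)")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma is not symmetric")
        if np.linalg.eigvalsh(self.Sigma)[0] <= 0:
            raise ValueError("Sigma is not positive definite")
        if not self.nu > 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError(f"pi must lie in [0, 1], got {self.pi}")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.Sigma))
                and np.all(np.isfinite(self.delta))):
            raise ValueError("non-finite component parameter")


@dataclass
class MixtureModel:
    """A g-component mixture of normal / t / skew-t populations."""

    family: str
    components: list[ComponentParams]
    marker_names: list[str] = field(default_factory=list)

    @property
    def g(self) -> int:
        return len(self.components)

    @property
    def p(self) -> int:
        return self.components[0].p

    @property
    def pi(self) -> np.ndarray:
        return np.array([c.pi for c in self.components])

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.g < 1:
            raise ValueError("mixture needs at least one component")
        for c in self.components:
            c.validate()
        if abs(sum(c.pi for c in self.components) - 1.0) > 1e-10:
            raise ValueError("mixing proportions do not sum to 1")
        if self.family in ("normal", "t"):
            for c in self.components:
                if np.any(c.delta != 0):
                    raise ValueError(f"family {self.family!r} requires zero skew")
        if self.marker_names and len(self.marker_names) != self.p:
            raise ValueError("marker_names length does not match dimension")

    def copy(self) -> "MixtureModel":
        comps = [replace(c, mu=c.mu.copy(), Sigma=c.Sigma.copy(), delta=c.delta.copy())
                 for c in self.components]
        return MixtureModel(self.family, comps, list(self.marker_names))


@dataclass
class LatentAugmentation:
    """Conditional expectations of the latent variables given the data.

    ``tau`` are the posterior component responsibilities, ``w`` the
    conditional gamma weights; for the skew family ``u_mean``/``u_var``
    hold first/second central moments of the truncated latent vector
    (n, g, p), computed coordinate-wise (see mixture_em docs).
    """

    tau: np.ndarray
    w: np.ndarray
    u_mean: np.ndarray | None = None
    u_var: np.ndarray | None = None


# ---------------------------------------------------------------------------
# linear algebra helpers


def _chol(Sigma: np.ndarray, name: str = "Sigma"):
    """Cholesky factor with a single regularization retry.

    Near-degenerate clusters can produce numerically indefinite scale
    matrices mid-EM; one additive jitter of eps*trace/p on the diagonal is
    attempted before giving up.
    """
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        p = Sigma.shape[0]
        jitter = _REG_EPS * np.trace(Sigma) / p
        try:
            return np.linalg.cholesky(Sigma + jitter * np.eye(p))
        except np.linalg.LinAlgError as exc:
            raise LinAlgError(f"matrix {name} is not positive definite") from exc


def mahalanobis_sq(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray | float:
    """Squared Mahalanobis distance (y-mu)' Sigma^-1 (y-mu).

    Computed through a triangular solve of the Cholesky factor; accepts a
    single p-vector or an (n, p) matrix of points.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    mu = np.asarray(mu, dtype=float)
    if Y.shape[1] != mu.shape[0]:
        raise ValueError(f"dimension mismatch: y has {Y.shape[1]} columns, mu has {mu.shape[0]}")
    L = _chol(np.asarray(Sigma, dtype=float))
    z = np.linalg.solve(L, (Y - mu).T)
    d = np.einsum("ij,ij->j", z, z)
    return float(d[0]) if single else d


def _log_mvt(Y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray, nu: float) -> np.ndarray:
    """Log density of the p-variate t at the rows of Y (vectorized)."""
    p = mu.shape[0]
    L = _chol(Sigma)
    z = np.linalg.solve(L, (np.atleast_2d(Y) - mu).T)
    d = np.einsum("ij,ij->j", z, z)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return (gammaln((nu + p) / 2.0) - gammaln(nu / 2.0)
            - 0.5 * p * np.log(np.pi * nu) - 0.5 * logdet
            - 0.5 * (nu + p) * np.log1p(d / nu))


def log_mvt_pdf(y: np.ndarray, comp: ComponentParams) -> np.ndarray | float:
    """Log of the multivariate t density of ``comp`` at ``y``."""
    if not comp.nu > 0:
        raise ValueError(f"degrees of freedom must be positive, got {comp.nu}")
    y = np.asarray(y, dtype=float)
    out = _log_mvt(y, comp.mu, comp.Sigma, comp.nu)
    return float(out[0]) if y.ndim == 1 else out


# ---------------------------------------------------------------------------
# multivariate t distribution function


def _bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF via Owen's T function (exact, vectorized)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    denom = np.sqrt(1.0 - rho * rho)
    # Owen's formula is singular at h=0 or k=0; nudge off the axis
    hs = np.where(h == 0, 1e-14, h)
    ks = np.where(k == 0, 1e-14, k)
    ah = (ks - rho * hs) / (hs * denom)
    ak = (hs - rho * ks) / (ks * denom)
    beta = np.where((hs * ks > 0) | ((hs * ks == 0) & (hs + ks >= 0)), 0.0, 0.5)
    return (0.5 * (special.ndtr(hs) + special.ndtr(ks))
            - special.owens_t(hs, ah) - special.owens_t(ks, ak) - beta)


_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(n: int):
    if n not in _GL_CACHE:
        x, w = leggauss(n)
        _GL_CACHE[n] = ((x + 1.0) / 2.0, w / 2.0)
    return _GL_CACHE[n]


def _bvt_cdf(x1, x2, rho: float, nu: float, nodes: int = 48) -> np.ndarray:
    """Centered bivariate t CDF with unit scales and correlation rho.

    Deterministic Gauss-Legendre quadrature of the normal CDF over the
    gamma mixing variable; vectorized over evaluation points.
    """
    u, wgt = _gl_nodes(nodes)
    w = stats.gamma.ppf(u, a=nu / 2.0, scale=2.0 / nu)
    s = np.sqrt(w)
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))[:, None]
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))[:, None]
    return _bvn_cdf(x1 * s, x2 * s, rho) @ wgt


def mvt_cdf(x: np.ndarray, Sigma: np.ndarray, nu: float, tol: float = 1e-4,
            seed: int = 0) -> float:
    """P(T <= x) for a centered p-variate t with scale Sigma and df nu.

    p = 1 and p = 2 use exact deterministic evaluations; 3 <= p <= 20 uses
    randomized quasi-Monte-Carlo integration with the internal seed derived
    from ``seed`` (estimated standard error kept at or below ``tol``).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    p = x.shape[0]
    if p > 20:
        raise ValueError(f"dimension {p} unsupported (max 20)")
    sd = np.sqrt(np.diag(Sigma))
    z = x / sd
    if p == 1:
        return float(stats.t.cdf(z[0], nu))
    if p == 2:
        rho = Sigma[0, 1] / (sd[0] * sd[1])
        return float(_bvt_cdf(z[:1], z[1:], rho, nu)[0])
    corr = Sigma / np.outer(sd, sd)
    dist = stats.multivariate_t(loc=np.zeros(p), shape=corr, df=nu)
    # a few independent QMC randomizations give a standard-error estimate
    reps = [dist.cdf(z, random_state=np.random.default_rng((seed * 7919 + r) % (2**31)))
            for r in range(3)]
    val = float(np.mean(reps))
    se = float(np.std(reps, ddof=1) / np.sqrt(len(reps)))
    if se > tol:
        reps += [dist.cdf(z, random_state=np.random.default_rng((seed * 104729 + r) % (2**31)),
                          maxpts=2_000_000 * p) for r in range(3, 8)]
        val = float(np.mean(reps))
    return min(max(val, 0.0), 1.0)


# ---------------------------------------------------------------------------
# skew-t density


def _orthant_t_cdf(X: np.ndarray, Lam: np.ndarray, nu: float, seed: int = 0) -> np.ndarray:
    """T_p(x; 0, Lam, nu) at the rows of X (vectorized for p <= 2)."""
    p = Lam.shape[0]
    sd = np.sqrt(np.diag(Lam))
    Z = np.atleast_2d(X) / sd
    if p == 1:
        return stats.t.cdf(Z[:, 0], nu)
    if p == 2:
        rho = Lam[0, 1] / (sd[0] * sd[1])
        return _bvt_cdf(Z[:, 0], Z[:, 1], rho, nu)
    corr = Lam / np.outer(sd, sd)
    dist = stats.multivariate_t(loc=np.zeros(p), shape=corr, df=nu)
    rng = np.random.default_rng(seed % (2**31))
    return np.array([dist.cdf(z, random_state=rng) for z in Z])


def log_mvskewt_pdf(y: np.ndarray, comp: ComponentParams) -> np.ndarray | float:
    """Log density of the unrestricted (Sahu-form) multivariate skew t."""
    if not comp.nu > 0:
        raise ValueError(f"degrees of freedom must be positive, got {comp.nu}")
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    p = comp.p
    nu = comp.nu
    delta = comp.delta
    if np.all(delta == 0):
        out = _log_mvt(Y, comp.mu, comp.Sigma, nu)
        return float(out[0]) if single else out
    Omega = comp.Sigma + np.diag(delta ** 2)
    L = _chol(Omega, "Omega")
    R = Y - comp.mu
    z = np.linalg.solve(L, R.T)
    d = np.einsum("ij,ij->j", z, z)
    Oi = cho_solve((L, True), np.eye(p))
    q = R @ (Oi * delta)                      # rows: Delta Omega^-1 (y - mu)
    s = np.sqrt((nu + p) / (nu + d))
    Lam = np.eye(p) - (delta[:, None] * Oi) * delta[None, :]
    T = _orthant_t_cdf(q * s[:, None], Lam, nu + p)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    log_t = (gammaln((nu + p) / 2.0) - gammaln(nu / 2.0)
             - 0.5 * p * np.log(np.pi * nu) - 0.5 * logdet
             - 0.5 * (nu + p) * np.log1p(d / nu))
    out = p * np.log(2.0) + log_t + np.log(np.clip(T, 1e-300, None))
    return float(out[0]) if single else out


def _log_component_pdf(Y: np.ndarray, comp: ComponentParams, family: str) -> np.ndarray:
    if family == "normal":
        # evaluated as a t with very large nu would also do; use the exact form
        L = _chol(comp.Sigma)
        z = np.linalg.solve(L, (np.atleast_2d(Y) - comp.mu).T)
        d = np.einsum("ij,ij->j", z, z)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        p = comp.p
        return -0.5 * (p * np.log(2 * np.pi) + logdet + d)
    if family == "t":
        return _log_mvt(np.atleast_2d(Y), comp.mu, comp.Sigma, comp.nu)
    if family == "skew-t":
        return np.atleast_1d(log_mvskewt_pdf(np.atleast_2d(Y), comp))
    raise ValueError(f"unknown family {family!r}")


def component_logpdf_matrix(Y: np.ndarray, model: MixtureModel) -> np.ndarray:
    """(n, g) matrix of per-component log densities (without proportions)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return np.column_stack([_log_component_pdf(Y, c, model.family) for c in model.components])


def log_mixture_pdf(y: np.ndarray, model: MixtureModel) -> np.ndarray | float:
    """Log mixture density log sum_h pi_h f_h(y), via log-sum-exp."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Lmat = component_logpdf_matrix(y, model)
    with np.errstate(divide="ignore"):
        out = special.logsumexp(Lmat + np.log(np.clip(model.pi, 1e-300, None)), axis=1)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# sampling


def sample_mixture(model: MixtureModel, n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw n cells from the mixture via the latent construction.

    Returns the (n, p) matrix and the component-origin labels (0-based).
    Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    p = model.p
    labels = rng.choice(model.g, size=n, p=model.pi / model.pi.sum())
    Y = np.empty((n, p))
    for h, comp in enumerate(model.components):
        idx = np.flatnonzero(labels == h)
        if idx.size == 0:
            continue
        m = idx.size
        if model.family == "normal":
            w = np.ones(m)
        else:
            w = rng.gamma(comp.nu / 2.0, 2.0 / comp.nu, size=m)
        Lc = _chol(comp.Sigma)
        u1 = (rng.standard_normal((m, p)) @ Lc.T) / np.sqrt(w)[:, None]
        y = comp.mu + u1
        if model.family == "skew-t" and np.any(comp.delta != 0):
            u0 = rng.standard_normal((m, p)) / np.sqrt(w)[:, None]
            y = y + np.abs(u0) * comp.delta
        Y[idx] = y
    return Y, labels
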