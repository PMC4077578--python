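"""The two-level batch model: template mixture + per-sample random effects.

Every sample k in a batch instantiates the batch template through an
affine map of the component means,

    y_ijk = a_hik mu_hi + b_hik + e_hijk,
    a_hik ~ N(1, sigma_a^2),   b_hik ~ N(0, sigma_b^2),

so component h means the same population in every sample (registration by
shared template index).  Scale matrices, skewness and degrees of freedom
are template-level; only means and mixing proportions vary per sample.
Fitting is an Expectation-Conditional-Maximization scheme: the template
parameters are updated from all samples' weighted sufficient statistics,
the per-sample effects (a, b) by their closed-form MAP (ridge) solution
under the random-effects priors, and the prior variances from the fitted
effects.  A backtracking safeguard keeps the recorded total observed-data
log-likelihood non-decreasing.

Registered per-cell labels use the file convention 1..g (0 = outlier).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .distributions import ComponentParams, MixtureModel, _chol
from .em import (FitOptions, FittingError, SampleFit, _Collapse, _interp_model,
                 _observed_loglik, _update_nu, bic_score, fit_mixture,
                 parameter_count, posterior_responsibilities)
from .io import MarkerSample, SampleBatch

__all__ = [
    "SampleTransform",
    "REMVariances",
    "JCMOptions",
    "JCMFit",
    "sample_model_from_template",
    "fit_jcm",
    "estimate_transform",
    "export_feature_matrix",
]


@dataclass
class SampleTransform:
    """One sample's realization of the random effects: y ~ a*mu + b per (h, i)."""

    a: np.ndarray          # (g, p) scaling effects, > 0 in simulation
    b: np.ndarray          # (g, p) translation effects
    pi: np.ndarray         # (g,) sample-specific proportions

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)

    @classmethod
    def identity(cls, g: int, p: int, pi: np.ndarray) -> "SampleTransform":
        return cls(a=np.ones((g, p)), b=np.zeros((g, p)), pi=np.asarray(pi, float).copy())

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite transform entries")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("sample proportions do not sum to 1")


@dataclass
class REMVariances:
    """Variances of the scaling/translation random effects (scalars, shared
    over components and markers)."""

    sigma_a2: float
    sigma_b2: float

    def validate(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_b2 < 0:
            raise ValueError("random-effect variances must be non-negative")


@dataclass
class JCMOptions(FitOptions):
    """Fitting options for the two-level model.

    ``sigma_a2``/``sigma_b2`` = None estimates the variance from the
    fitted effects; a number fixes it (0 freezes the effect at identity).
    """

    sigma_a2: float | None = None
    sigma_b2: float | None = None
    translation_only: bool = False
    outlier_floor: bool = False
    init_subsample: int = 5000


@dataclass
class PerSampleFit:
    sample_id: str
    responsibilities: np.ndarray | None
    labels: np.ndarray          # registered, 1..g (0 = outlier)
    loglik: float


@dataclass
class JCMFit:
    template: MixtureModel
    transforms: list[SampleTransform]
    rem: REMVariances
    per_sample: list[PerSampleFit]
    total_loglik_trace: list[float]
    bic: float
    options: JCMOptions | None = None
    converged: bool = False

    @property
    def total_loglik(self) -> float:
        return self.total_loglik_trace[-1]

    def sample_model(self, k: int) -> MixtureModel:
        return sample_model_from_template(self.template, self.transforms[k])

    def to_dict(self) -> dict:
        from .io import _mixture_to_dict
        return {
            **_mixture_to_dict(self.template),
            "rem": {"sigma_a2": self.rem.sigma_a2, "sigma_b2": self.rem.sigma_b2},
            "transforms": [
                {"sample_id": ps.sample_id, "a": tr.a.tolist(), "b": tr.b.tolist(),
                 "pi": tr.pi.tolist(), "loglik": ps.loglik}
                for tr, ps in zip(self.transforms, self.per_sample)
            ],
            "total_loglik": self.total_loglik,
            "bic": self.bic,
        }

    @classmethod
    def from_dict(cls, doc: dict, mixture_from_dict) -> "JCMFit":
        template = mixture_from_dict(doc)
        transforms, per_sample = [], []
        for t in doc["transforms"]:
            transforms.append(SampleTransform(np.array(t["a"]), np.array(t["b"]),
                                              np.array(t["pi"])))
            per_sample.append(PerSampleFit(sample_id=t["sample_id"], responsibilities=None,
                                           labels=np.empty(0, dtype=int),
                                           loglik=float(t.get("loglik", np.nan))))
        rem = REMVariances(doc["rem"]["sigma_a2"], doc["rem"]["sigma_b2"])
        return cls(template=template, transforms=transforms, rem=rem,
                   per_sample=per_sample, total_loglik_trace=[doc["total_loglik"]],
                   bic=doc["bic"])


def sample_model_from_template(template: MixtureModel, tr: SampleTransform) -> MixtureModel:
    """Instantiate a sample's mixture: means a*mu + b, proportions pi_k;
    scale, skew and dof inherited from the template."""
    g, p = template.g, template.p
    if tr.a.shape != (g, p) or tr.pi.shape != (g,):
        raise ValueError(f"transform shape mismatch for template with g={g}, p={p}")
    comps = []
    for h, c in enumerate(template.components):
        comps.append(ComponentParams(pi=float(tr.pi[h]), mu=tr.a[h] * c.mu + tr.b[h],
                                     Sigma=c.Sigma.copy(), delta=c.delta.copy(), nu=c.nu))
    return MixtureModel(template.family, comps, list(template.marker_names))


# ---------------------------------------------------------------------------
# internal state and conditional maximization steps


@dataclass
class _State:
    template: MixtureModel
    transforms: list[SampleTransform]
    sigma_a2: float
    sigma_b2: float

    def copy(self) -> "_State":
        return _State(self.template.copy(),
                      [SampleTransform(t.a.copy(), t.b.copy(), t.pi.copy())
                       for t in self.transforms],
                      self.sigma_a2, self.sigma_b2)


def _interp_state(old: _State, new: _State, t: float) -> _State:
    trs = [SampleTransform((1 - t) * to.a + t * tn.a, (1 - t) * to.b + t * tn.b,
                           (1 - t) * to.pi + t * tn.pi)
           for to, tn in zip(old.transforms, new.transforms)]
    return _State(_interp_model(old.template, new.template, t), trs,
                  (1 - t) * old.sigma_a2 + t * new.sigma_a2,
                  (1 - t) * old.sigma_b2 + t * new.sigma_b2)


def _total_loglik(Ys: list[np.ndarray], state: _State) -> float:
    total = 0.0
    for Y, tr in zip(Ys, state.transforms):
        ll, _ = _observed_loglik(Y, sample_model_from_template(state.template, tr))
        total += ll
    return total


def _estep_all(Ys: list[np.ndarray], state: _State):
    out = []
    for Y, tr in zip(Ys, state.transforms):
        model_k = sample_model_from_template(state.template, tr)
        out.append(posterior_responsibilities(Y, model_k))
    return out


def _update_ab(Y, latents, template, tr, sigma_a2, sigma_b2, translation_only):
    """MAP (ridge) update of the per-sample effects, closed-form per (h, i).

    Weighted regression y ~ a*mu + b with weights tau*w / Sigma_hii and
    priors a ~ N(1, sigma_a2), b ~ N(0, sigma_b2).  A zero prior variance
    freezes the corresponding effect.
    """
    g, p = template.g, template.p
    a_new = np.ones((g, p))
    b_new = np.zeros((g, p))
    for h, comp in enumerate(template.components):
        tw = latents.tau[:, h] * latents.w[:, h]
        target = Y
        if template.family == "skew-t":
            target = Y - latents.u_mean[:, h] * comp.delta
        sii = np.clip(np.diag(comp.Sigma), 1e-12, None)
        Sw = tw.sum() / sii                       # (p,)
        Sy = (tw[:, None] * target).sum(axis=0) / sii
        mu = comp.mu
        est_a = sigma_a2 > 0 and not translation_only
        est_b = sigma_b2 > 0
        if est_a and est_b:
            A11 = mu * mu * Sw + 1.0 / sigma_a2
            A12 = mu * Sw
            A22 = Sw + 1.0 / sigma_b2
            r1 = mu * Sy + 1.0 / sigma_a2
            r2 = Sy
            det = A11 * A22 - A12 * A12
            a_new[h] = (r1 * A22 - r2 * A12) / det
            b_new[h] = (A11 * r2 - A12 * r1) / det
        elif est_b:
            b_new[h] = (Sy - mu * Sw) / (Sw + 1.0 / sigma_b2)
        elif est_a:
            a_new[h] = (mu * Sy + 1.0 / sigma_a2) / (mu * mu * Sw + 1.0 / sigma_a2)
    return a_new, b_new


def _update_template(Ys, latents_all, state: _State, options: JCMOptions) -> MixtureModel:
    """CM-1: template parameters from all samples' weighted statistics,
    each cell mapped through its sample's mean transform."""
    template = state.template
    g, p = template.g, template.p
    fixed_nu = options.fixed_nu
    new_comps = []
    for h, comp in enumerate(template.components):
        # location: solve [sum_k S_k A_k Sigma^-1 A_k] mu = sum_k A_k Sigma^-1 s_k
        Si = np.linalg.inv(comp.Sigma + 1e-12 * np.trace(comp.Sigma) / p * np.eye(p))
        M = np.zeros((p, p))
        v = np.zeros(p)
        pooled_tau, pooled_w = [], []
        n_h = 0.0
        for Y, lat, tr in zip(Ys, latents_all, state.transforms):
            tw = lat.tau[:, h] * lat.w[:, h]
            target = Y - tr.b[h]
            if template.family == "skew-t":
                target = target - lat.u_mean[:, h] * comp.delta
            s_k = (tw[:, None] * target).sum(axis=0)
            Ak = np.diag(tr.a[h])
            M += tw.sum() * Ak @ Si @ Ak
            v += Ak @ Si @ s_k
            pooled_tau.append(lat.tau[:, h])
            pooled_w.append(lat.w[:, h])
            n_h += lat.tau[:, h].sum()
        if n_h < max(options.min_cluster_fraction * sum(len(Y) for Y in Ys), p + 1.0):
            raise _Collapse(f"template component {h} occupancy {n_h:.2f} below floor")
        mu = np.linalg.solve(M, v)
        # skewness (pooled over samples, in sample coordinates)
        if template.family == "skew-t":
            num = np.zeros(p)
            den = np.zeros(p)
            for Y, lat, tr in zip(Ys, latents_all, state.transforms):
                tw = lat.tau[:, h] * lat.w[:, h]
                mu_k = tr.a[h] * mu + tr.b[h]
                num += (tw[:, None] * (Y - mu_k) * lat.u_mean[:, h]).sum(axis=0)
                den += (tw[:, None] * (lat.u_mean[:, h] ** 2 + lat.u_var[:, h])).sum(axis=0)
            delta = num / np.clip(den, 1e-12, None)
        else:
            delta = np.zeros(p)
        # scale: pooled weighted scatter of residuals
        scatter = np.zeros((p, p))
        zvar = np.zeros(p)
        for Y, lat, tr in zip(Ys, latents_all, state.transforms):
            tw = lat.tau[:, h] * lat.w[:, h]
            R = Y - (tr.a[h] * mu + tr.b[h])
            if template.family == "skew-t":
                R = R - lat.u_mean[:, h] * delta
                zvar += (tw[:, None] * lat.u_var[:, h]).sum(axis=0)
            scatter += (tw[:, None] * R).T @ R
        Sigma = (scatter + np.diag(delta * zvar * delta)) / n_h
        Sigma = 0.5 * (Sigma + Sigma.T)
        Sigma += 1e-10 * max(np.trace(Sigma) / p, 1e-12) * np.eye(p)
        tau_h = np.concatenate(pooled_tau)
        w_h = np.concatenate(pooled_w)
        nu = fixed_nu if fixed_nu is not None else _update_nu(comp.nu, p, tau_h, w_h)
        new_comps.append(ComponentParams(pi=comp.pi, mu=mu, Sigma=Sigma,
                                         delta=delta, nu=float(nu)))
    model = MixtureModel(template.family, new_comps, list(template.marker_names))
    return model


def _registered_labels(tau: np.ndarray, g: int, outlier_floor: bool) -> np.ndarray:
    labels = np.argmax(tau, axis=1) + 1
    if outlier_floor:
        labels[np.max(tau, axis=1) < 1.0 / (2.0 * g)] = 0
    return labels


# ---------------------------------------------------------------------------
# drivers


def fit_jcm(batch: SampleBatch, options: JCMOptions) -> JCMFit:
    """Fit the batch template and per-sample transforms jointly by ECM."""
    options.validate()
    batch.validate()
    Ys = [s.data for s in batch.samples]
    m = batch.m
    g, p = options.g, len(batch.marker_names)
    for s in batch.samples:
        if s.n_cells < g * (p + 1):
            raise ValueError(f"sample {s.sample_id!r} has too few cells for g={g}")

    fixed_zero = (options.sigma_a2 == 0.0 and options.sigma_b2 == 0.0)
    if m == 1 and fixed_zero:
        # with a single sample and degenerate random effects the two-level
        # model reduces exactly to the single-sample mixture fit
        fit = fit_mixture(Ys[0], FitOptions(
            family=options.family, g=g, max_iter=options.max_iter, tol=options.tol,
            n_starts=options.n_starts, seed=options.seed, nu_mode=options.nu_mode,
            min_cluster_fraction=options.min_cluster_fraction))
        fit.model.marker_names = list(batch.marker_names)
        tr = SampleTransform.identity(g, p, fit.model.pi)
        ps = PerSampleFit(batch.samples[0].sample_id, fit.responsibilities,
                          fit.labels + 1, fit.loglik)
        return JCMFit(template=fit.model, transforms=[tr],
                      rem=REMVariances(0.0, 0.0), per_sample=[ps],
                      total_loglik_trace=list(fit.loglik_trace),
                      bic=fit.bic, options=options, converged=fit.converged)

    # (i) template initialization on a balanced pooled subsample
    rng = np.random.default_rng(options.seed)
    pooled = []
    for Y in Ys:
        take = min(len(Y), options.init_subsample)
        idx = rng.choice(len(Y), size=take, replace=False)
        pooled.append(Y[idx])
    pooled = np.vstack(pooled)
    init_fit = fit_mixture(pooled, FitOptions(
        family=options.family, g=g, max_iter=options.max_iter, tol=options.tol,
        n_starts=options.n_starts, seed=options.seed, nu_mode=options.nu_mode,
        min_cluster_fraction=options.min_cluster_fraction))
    template = init_fit.model
    template.marker_names = list(batch.marker_names)

    state = _State(
        template=template,
        transforms=[SampleTransform.identity(g, p, template.pi) for _ in range(m)],
        sigma_a2=options.sigma_a2 if options.sigma_a2 is not None else 0.01,
        sigma_b2=options.sigma_b2 if options.sigma_b2 is not None else 0.01,
    )
    ll = _total_loglik(Ys, state)
    trace = [ll]
    converged = False
    n_total = sum(len(Y) for Y in Ys)
    for _ in range(options.max_iter):
        latents_all = _estep_all(Ys, state)                      # (ii)
        new = state.copy()
        new.template = _update_template(Ys, latents_all, state, options)   # (iii)
        for k, (Y, lat) in enumerate(zip(Ys, latents_all)):      # (iv)
            if not fixed_zero:
                a_k, b_k = _update_ab(Y, lat, new.template, state.transforms[k],
                                      state.sigma_a2, state.sigma_b2,
                                      options.translation_only)
                new.transforms[k].a = a_k
                new.transforms[k].b = b_k
            new.transforms[k].pi = lat.tau.mean(axis=0)
        if options.sigma_a2 is None:                             # (v)
            A = np.stack([t.a for t in new.transforms])
            new.sigma_a2 = max(float(np.mean((A - 1.0) ** 2)), 1e-8)
        if options.sigma_b2 is None:
            B = np.stack([t.b for t in new.transforms])
            new.sigma_b2 = max(float(np.mean(B ** 2)), 1e-8)
        # template proportions: cell-count-weighted mean of the sample proportions
        weights = np.array([len(Y) for Y in Ys], dtype=float)
        pi_bar = (weights[:, None] * np.stack([t.pi for t in new.transforms])).sum(axis=0)
        pi_bar /= weights.sum()
        for h, c in enumerate(new.template.components):
            c.pi = float(pi_bar[h])
        ll_new = _total_loglik(Ys, new)
        t = 1.0
        while (not np.isfinite(ll_new) or ll_new < ll - 1e-10) and t > 1e-3:
            t *= 0.5
            new = _interp_state(state, new, t)
            ll_new = _total_loglik(Ys, new)
        if not np.isfinite(ll_new) or ll_new < ll - 1e-10:
            converged = True
            break
        state = new
        trace.append(ll_new)
        if abs(ll_new - ll) <= options.tol * abs(ll):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    per_sample = []
    final_ll = 0.0
    for k, (Y, s) in enumerate(zip(Ys, batch.samples)):
        model_k = sample_model_from_template(state.template, state.transforms[k])
        ll_k, tau_k = _observed_loglik(Y, model_k)
        final_ll += ll_k
        per_sample.append(PerSampleFit(
            sample_id=s.sample_id, responsibilities=tau_k,
            labels=_registered_labels(tau_k, g, options.outlier_floor), loglik=ll_k))
    d = parameter_count(options.family, g, p) + m * (g - 1) + 2
    return JCMFit(template=state.template, transforms=state.transforms,
                  rem=REMVariances(state.sigma_a2, state.sigma_b2),
                  per_sample=per_sample, total_loglik_trace=trace,
                  bic=bic_score(final_ll, d, n_total), options=options,
                  converged=converged)


def estimate_transform(sample: MarkerSample, template: MixtureModel,
                       rem: REMVariances, options: JCMOptions | None = None,
                       max_iter: int = 100, tol: float = 1e-7):
    """Fit one sample's transform against a frozen template.

    Returns ``(transform, labels, loglik)`` with registered 1..g labels.
    """
    options = options or JCMOptions(family=template.family, g=template.g)
    rem.validate()
    if template.marker_names and sample.marker_names != template.marker_names:
        diff = set(sample.marker_names) ^ set(template.marker_names)
        raise ValueError(f"marker mismatch between sample and template: {sorted(diff)}")
    Y = sample.data
    g, p = template.g, template.p
    tr = SampleTransform.identity(g, p, template.pi)
    ll_prev = -np.inf
    for _ in range(max_iter):
        model_k = sample_model_from_template(template, tr)
        lat = posterior_responsibilities(Y, model_k)
        if rem.sigma_a2 > 0 or rem.sigma_b2 > 0:
            a_k, b_k = _update_ab(Y, lat, template, tr, rem.sigma_a2, rem.sigma_b2,
                                  options.translation_only)
            tr.a, tr.b = a_k, b_k
        tr.pi = lat.tau.mean(axis=0)
        ll, _ = _observed_loglik(Y, sample_model_from_template(template, tr))
        if abs(ll - ll_prev) <= tol * abs(ll):
            ll_prev = ll
            break
        ll_prev = ll
    model_k = sample_model_from_template(template, tr)
    ll, tau = _observed_loglik(Y, model_k)
    labels = _registered_labels(tau, g, options.outlier_floor)
    return tr, labels, ll


def export_feature_matrix(fits: list[JCMFit]) -> pd.DataFrame:
    """Feature-by-sample matrix over all samples of the given fits.

    Rows are named "{param}.{component}.{marker}" (component index 1..g;
    the marker part is omitted for the scalar parameters pi and nu);
    columns are sample ids.  Values come from each sample's transformed
    model together with its fitted effects.
    """
    if not fits:
        raise ValueError("no fits given")
    g, p = fits[0].template.g, fits[0].template.p
    markers = fits[0].template.marker_names or [f"V{i+1}" for i in range(p)]
    for f in fits:
        if f.template.g != g or f.template.p != p:
            raise ValueError("all fits must share the same g and p")
    rows = []
    for h in range(1, g + 1):
        rows.append(f"pi.{h}")
        rows += [f"mu.{h}.{mk}" for mk in markers]
        rows += [f"sigma_diag.{h}.{mk}" for mk in markers]
        rows += [f"delta.{h}.{mk}" for mk in markers]
        rows.append(f"nu.{h}")
        rows += [f"a.{h}.{mk}" for mk in markers]
        rows += [f"b.{h}.{mk}" for mk in markers]
    cols = {}
    for fit in fits:
        for k, ps in enumerate(fit.per_sample):
            model_k = fit.sample_model(k)
            tr = fit.transforms[k]
            vals = []
            for h in range(g):
                c = model_k.components[h]
                vals.append(c.pi)
                vals += list(c.mu)
                vals += list(np.diag(c.Sigma))
                vals += list(c.delta)
                vals.append(c.nu)
                vals += list(tr.a[h])
                vals += list(tr.b[h])
            cols[ps.sample_id] = vals
    return pd.DataFrame(cols, index=rows)
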