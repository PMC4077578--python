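"""Synthetic batches with the exact generative structure the model assumes.

A known template mixture plus per-sample random effects: every sample's
component means are ``a * mu + b`` with a ~ N(1, sigma_a^2) truncated to
(0, inf) and b ~ N(0, sigma_b^2); per-sample proportions are drawn from a
Dirichlet centered on the template's (a concentration of infinity fixes
them exactly).  Ground truth (transforms and per-cell component labels,
1-based to match the registered-label convention) is always emitted, so
every fitting and evaluation path is testable without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .distributions import ComponentParams, MixtureModel, sample_mixture
from .io import MarkerSample, SampleBatch
from .jcm import SampleTransform, sample_model_from_template

__all__ = ["BatchSpec", "BatchTruth", "default_template", "simulate_batch"]


@dataclass
class BatchSpec:
    template: MixtureModel
    m: int
    n_per_sample: int | list[int] = 2000
    sigma_a: float = 0.0
    sigma_b: float = 0.0
    proportion_jitter: float = np.inf   # Dirichlet concentration; inf = fixed
    seed: int = 0

    def validate(self) -> None:
        self.template.validate()
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.sigma_a < 0 or self.sigma_b < 0:
            raise ValueError("effect SDs must be non-negative")

    def n_for(self, k: int) -> int:
        if isinstance(self.n_per_sample, int):
            return self.n_per_sample
        return int(self.n_per_sample[k])


@dataclass
class BatchTruth:
    transforms: list[SampleTransform]
    labels: list[np.ndarray]            # per-cell template component index, 1..g


def default_template(p: int, g: int, family: str = "t", separation: float = 4.0,
                     seed: int = 0) -> MixtureModel:
    """A well-conditioned g-component template with controlled separation.

    Component means sit on a jittered lattice with pairwise distance at
    least separation*sqrt(p); scales are identity with a random SPD
    perturbation; nu is drawn in [4, 15] (moderately heavy tails); skews
    are zero for the t family and uniform in [-2, 2] for skew-t.
    """
    if p < 1 or g < 1:
        raise ValueError("need p >= 1 and g >= 1")
    rng = np.random.default_rng(seed)
    spacing = 1.1 * separation * np.sqrt(p)
    side = int(np.ceil(g ** (1.0 / p)))
    lattice = np.array(list(itertools.product(range(side + 1), repeat=p))[:g], dtype=float)
    means = lattice * spacing + rng.uniform(-0.05, 0.05, size=(g, p)) * spacing
    comps = []
    for h in range(g):
        A = rng.standard_normal((p, p)) / np.sqrt(p)
        Sigma = np.eye(p) + 0.2 * (A @ A.T)
        nu = rng.uniform(4.0, 15.0)
        delta = rng.uniform(-2.0, 2.0, size=p) if family == "skew-t" else np.zeros(p)
        comps.append(ComponentParams(pi=1.0 / g, mu=means[h], Sigma=Sigma,
                                     delta=delta, nu=float(nu)))
    model = MixtureModel(family=family, components=comps,
                         marker_names=[f"M{i+1}" for i in range(p)])
    model.validate()
    return model


def _truncated_normal_pos(rng: np.random.Generator, mean: float, sd: float,
                          shape) -> np.ndarray:
    """N(mean, sd^2) truncated to (0, inf) by rejection (negligible for sd <= 0.3)."""
    out = rng.normal(mean, sd, size=shape)
    for _ in range(100):
        bad = out <= 0
        if not np.any(bad):
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    out[out <= 0] = 1e-3
    return out


def simulate_batch(spec: BatchSpec) -> tuple[SampleBatch, BatchTruth]:
    """Draw a batch and its complete ground truth from the template + REM."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    g, p = template.g, template.p
    pi0 = template.pi
    samples, transforms, labels_all = [], [], []
    for k in range(spec.m):
        a = (_truncated_normal_pos(rng, 1.0, spec.sigma_a, (g, p))
             if spec.sigma_a > 0 else np.ones((g, p)))
        b = rng.normal(0.0, spec.sigma_b, size=(g, p)) if spec.sigma_b > 0 else np.zeros((g, p))
        if np.isinf(spec.proportion_jitter):
            pi_k = pi0.copy()
        else:
            pi_k = rng.dirichlet(spec.proportion_jitter * pi0)
            pi_k = np.clip(pi_k, 1e-6, None)
            pi_k /= pi_k.sum()
        tr = SampleTransform(a=a, b=b, pi=pi_k)
        model_k = sample_model_from_template(template, tr)
        Y, lab = sample_mixture(model_k, spec.n_for(k),
                                seed=int(rng.integers(2**31)))
        samples.append(MarkerSample(sample_id=f"sample{k+1:02d}",
                                    marker_names=list(template.marker_names),
                                    data=Y))
        transforms.append(tr)
        labels_all.append(lab + 1)
    batch = SampleBatch(class_id="simulated", samples=samples)
    batch.validate()
    return batch, BatchTruth(transforms=transforms, labels=labels_all)
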