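"""Scoring clusterings against reference labels and comparing fitted models.

The misclassification rate (MCR) is the fraction of cells whose predicted
cluster, after the best one-to-one matching of predicted clusters to
reference classes, disagrees with the reference; it is the minimum over
all label permutations.  The F-measure is the flowCAP convention: the
size-weighted average over true classes of the best harmonic mean of
precision and recall against any predicted cluster.  Model similarity is
measured by Monte-Carlo Kullback-Leibler divergence, and new samples are
classified against class templates by transform-adjusted log-likelihood
(or symmetric KL).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .distributions import MixtureModel, log_mixture_pdf, sample_mixture
from .em import FitOptions, fit_mixture
from .io import MarkerSample
from .jcm import JCMOptions, REMVariances, estimate_transform

__all__ = [
    "EvaluationResult",
    "misclassification_rate",
    "f_measure",
    "kl_divergence_mc",
    "classify_sample",
    "summarize_mcr_table",
    "evaluate_batch",
]


@dataclass
class EvaluationResult:
    per_sample: dict[str, dict[str, float]]
    amcr: float
    median_mcr: float


def _check_lengths(pred, truth):
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError(f"pred and truth must be equal-length vectors "
                         f"({pred.shape} vs {truth.shape})")
    return pred, truth


def misclassification_rate(pred, truth) -> float:
    """Minimum error fraction over all one-to-one matchings of cluster labels.

    Computed by optimal assignment on the contingency table, which attains
    the same optimum as exhaustive permutation search; predicted clusters
    left unmatched (when there are more clusters than reference classes)
    count entirely as errors, and cells predicted 0 (outlier/unassigned)
    always count as errors.
    """
    pred, truth = _check_lengths(pred, truth)
    n = len(truth)
    pred_ids = np.unique(pred[pred != 0])
    truth_ids = np.unique(truth)
    C = np.zeros((len(pred_ids), len(truth_ids)))
    for r, pid in enumerate(pred_ids):
        mask = pred == pid
        for c, tid in enumerate(truth_ids):
            C[r, c] = np.sum(mask & (truth == tid))
    if C.size == 0:
        return 1.0
    rows, cols = linear_sum_assignment(-C)
    matched = C[rows, cols].sum()
    return float(1.0 - matched / n)


def f_measure(pred, truth) -> float:
    """flowCAP F-measure: size-weighted best harmonic mean per true class."""
    pred, truth = _check_lengths(pred, truth)
    n = len(truth)
    total = 0.0
    pred_ids = np.unique(pred)
    for tid in np.unique(truth):
        cmask = truth == tid
        csize = cmask.sum()
        best = 0.0
        for pid in pred_ids:
            qmask = pred == pid
            inter = np.sum(cmask & qmask)
            if inter:
                best = max(best, 2.0 * inter / (csize + qmask.sum()))
        total += (csize / n) * best
    return float(total)


def kl_divergence_mc(model_p: MixtureModel, model_q: MixtureModel,
                     n_mc: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo estimate of KL(p || q) = E_p[log p - log q], with its SE.

    The estimate is clipped at 0 from below.  Raises if q vanishes at a
    drawn point (advice: regularize q's scale matrices).
    """
    if model_p.p != model_q.p:
        raise ValueError("models have different dimensions")
    Y, _ = sample_mixture(model_p, n_mc, seed)
    lp = log_mixture_pdf(Y, model_p)
    lq = log_mixture_pdf(Y, model_q)
    if not np.all(np.isfinite(lq)):
        raise FloatingPointError(
            "q has zero density at a sampled point; regularize its scale matrices")
    diff = lp - lq
    kl = float(diff.mean())
    se = float(diff.std(ddof=1) / np.sqrt(n_mc))
    return max(kl, 0.0), se


def classify_sample(sample: MarkerSample,
                    class_templates: dict[str, tuple[MixtureModel, REMVariances]],
                    method: str = "loglik", seed: int = 0,
                    n_mc: int = 50_000) -> tuple[str, dict[str, float]]:
    """Assign a sample to the class whose template fits it best.

    ``method='loglik'`` (default, deterministic) scores each class by the
    per-cell log-likelihood after fitting the sample's transform against
    the class template; ``method='kl'`` by the negated symmetric
    Monte-Carlo KL between the sample's own fitted mixture and the
    template.  Higher score wins; ties break to the lexicographically
    smallest class id.
    """
    if not class_templates:
        raise ValueError("need at least one class template")
    scores: dict[str, float] = {}
    own_fit = None
    for cid in sorted(class_templates):
        template, rem = class_templates[cid]
        if template.marker_names and sample.marker_names != template.marker_names:
            diff = set(sample.marker_names) ^ set(template.marker_names)
            raise ValueError(f"marker mismatch for class {cid!r}: {sorted(diff)}")
        if method == "loglik":
            _, _, ll = estimate_transform(sample, template, rem)
            scores[cid] = ll / sample.n_cells
        elif method == "kl":
            if own_fit is None:
                own_fit = fit_mixture(sample.data, FitOptions(
                    family=template.family, g=template.g, seed=seed, n_starts=2))
                own_fit.model.marker_names = list(sample.marker_names)
            kl_pq, _ = kl_divergence_mc(own_fit.model, template, n_mc, seed)
            kl_qp, _ = kl_divergence_mc(template, own_fit.model, n_mc, seed + 1)
            scores[cid] = -(kl_pq + kl_qp)
        else:
            raise ValueError(f"unknown method {method!r}")
    best = max(sorted(scores), key=lambda c: scores[c])
    return best, scores


def _round4(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def summarize_mcr_table(table: dict[str, list[float]]) -> dict[str, dict[str, float]]:
    """Per-method average (AMCR) and median MCR, rounded half-up to 4 decimals."""
    lengths = {len(v) for v in table.values()}
    if not table or 0 in lengths:
        raise ValueError("every method needs a non-empty MCR sequence")
    if len(lengths) > 1:
        raise ValueError(f"unequal sequence lengths across methods: {sorted(lengths)}")
    out = {}
    for method, vals in table.items():
        vals = np.asarray(vals, dtype=float)
        out[method] = {"amcr": _round4(vals.mean()), "median": _round4(np.median(vals))}
    return out


def evaluate_batch(pred_labels: list[np.ndarray], truth_labels: list[np.ndarray],
                   sample_ids: list[str] | None = None) -> EvaluationResult:
    """Per-sample and aggregate MCR / F-measure for a batch."""
    if len(pred_labels) != len(truth_labels) or not pred_labels:
        raise ValueError("need equally many non-empty pred and truth label sets")
    ids = sample_ids or [f"sample{k+1}" for k in range(len(pred_labels))]
    per = {}
    mcrs = []
    for sid, pred, truth in zip(ids, pred_labels, truth_labels):
        mcr = misclassification_rate(pred, truth)
        per[sid] = {"mcr": mcr, "f_measure": f_measure(pred, truth)}
        mcrs.append(mcr)
    return EvaluationResult(per_sample=per, amcr=float(np.mean(mcrs)),
                            median_mcr=float(np.median(mcrs)))
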