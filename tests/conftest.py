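import itertools

import numpy as np
import pytest

from jcmflow import ComponentParams, MixtureModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def t_mixture_1d():
    """Two well-separated univariate t components."""
    comps = [
        ComponentParams(pi=0.3, mu=np.array([-3.0]), Sigma=np.array([[1.0]]),
                        delta=np.zeros(1), nu=5.0),
        ComponentParams(pi=0.7, mu=np.array([3.0]), Sigma=np.array([[1.0]]),
                        delta=np.zeros(1), nu=5.0),
    ]
    return MixtureModel("t", comps, ["M1"])


@pytest.fixture
def t_mixture_2d():
    comps = [
        ComponentParams(pi=0.4, mu=np.array([0.0, 0.0]),
                        Sigma=np.array([[1.0, 0.3], [0.3, 1.5]]),
                        delta=np.zeros(2), nu=8.0),
        ComponentParams(pi=0.6, mu=np.array([6.0, 5.0]),
                        Sigma=np.array([[1.2, -0.2], [-0.2, 0.8]]),
                        delta=np.zeros(2), nu=12.0),
    ]
    return MixtureModel("t", comps, ["CD4", "CD45RA"])


def brute_force_mcr(pred, truth):
    """Exhaustive permutation minimum of the misclassification rate.

    Independent oracle: tries every injective assignment of predicted
    cluster labels to reference classes; predicted 0 is always an error.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    n = len(truth)
    pred_ids = sorted(set(pred[pred != 0]))
    truth_ids = sorted(set(truth))
    best = 0
    if len(pred_ids) <= len(truth_ids):
        pairings = ((list(zip(pred_ids, chosen)))
                    for chosen in itertools.permutations(truth_ids, len(pred_ids)))
    else:
        pairings = ((list(zip(chosen, truth_ids)))
                    for chosen in itertools.permutations(pred_ids, len(truth_ids)))
    for pairing in pairings:
        correct = 0
        for pid, tid in pairing:
            correct += int(np.sum((pred == pid) & (truth == tid)))
        best = max(best, correct)
    return 1.0 - best / n
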