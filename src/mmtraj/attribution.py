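"""Model-agnostic Shapley-value feature attribution.

Implements the permutation-sampling estimator of interventional Shapley
values: for a random permutation of the features, features are revealed one
by one (replacing background values with the explained sample's values) and
each feature is credited with the change in the mean model output at its
reveal step. Within one permutation the credits telescope to
``f(x) - E_background[f]`` exactly, so the local-accuracy identity

    base_value + sum_j phi_j(x) = f(x)

holds to floating-point precision for any number of sampled permutations;
sampling only affects how the total is split among correlated features.
Antithetic pairs (each permutation together with its reverse) reduce the
estimator variance at no extra model-call cost.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

DEFAULT_N_PERMUTATIONS = 8
DEFAULT_BACKGROUND_SIZE = 25


def shapley_values(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature Shapley attributions of ``predict``.

    Parameters
    ----------
    predict
        Vectorized model output, mapping an (n, p) array to n reals.
    X
        Samples to explain, shape (n, p).
    background
        Reference samples defining the "feature absent" distribution,
        shape (m, p). Subsample large training sets before passing.
    n_permutations
        Number of sampled feature orderings (rounded up to an even count;
        half are reverses of the other half).
    seed
        Seed of the permutation sampler.

    Returns
    -------
    (attributions, base_value)
        ``attributions`` has shape (n, p); ``base_value`` is the mean model
        output over the background.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, p = X.shape
    m = background.shape[0]
    if background.shape[1] != p:
        raise ValueError("background feature count does not match X")
    rng = np.random.default_rng(seed)
    n_perm = max(2, n_permutations + (n_permutations % 2))
    perms = []
    for _ in range(n_perm // 2):
        perm = rng.permutation(p)
        perms.append(perm)
        perms.append(perm[::-1])

    base_value = float(np.mean(predict(background)))
    phi = np.zeros((n, p))
    n_batches = len(perms) * p
    for i in range(n):
        x = X[i]
        # one predict call per sample: all reveal steps of all permutations
        hybrids = np.empty((n_batches, m, p))
        b = 0
        for perm in perms:
            current = background.copy()
            for j in perm:
                current[:, j] = x[j]
                hybrids[b] = current
                b += 1
        means = predict(hybrids.reshape(n_batches * m, p)).reshape(n_batches, m).mean(axis=1)
        b = 0
        for perm in perms:
            prev = base_value
            for j in perm:
                phi[i, j] += means[b] - prev
                prev = means[b]
                b += 1
    phi /= len(perms)
    return phi, base_value


def mean_abs_attribution(phi: np.ndarray) -> np.ndarray:
    """Mean absolute attribution per feature across samples."""
    return np.mean(np.abs(phi), axis=0)
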