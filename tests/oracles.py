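"""Independent brute-force oracles for the HMM and the enrichment test.

These share no inference code with the package: posteriors and best paths
are computed by explicitly materializing *every* state path and summing or
maximizing over them (numpy-vectorized so thousands of instances stay
cheap), and the hypergeometric tail by exact rational summation.  Only
feasible for tiny instances, which is the point.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def _log_gauss(x: np.ndarray, means: np.ndarray, var: float) -> np.ndarray:
    """(T, K) table of Gaussian log-densities."""
    return (
        -0.5 * (x[:, None] - means[None, :]) ** 2 / var
        - 0.5 * math.log(2 * math.pi * var)
    )


def _all_path_logprobs(
    initial: np.ndarray,
    transition: np.ndarray,
    means: np.ndarray,
    var: float,
    x: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Every state path (k^T, T) with its log joint probability (k^T,)."""
    k, t_len = len(initial), len(x)
    paths = np.stack(np.unravel_index(np.arange(k**t_len), (k,) * t_len), axis=1)
    logdens = _log_gauss(np.asarray(x, float), np.asarray(means, float), var)
    lp = np.log(initial)[paths[:, 0]]
    lp += logdens[np.arange(t_len)[None, :], paths].sum(axis=1)
    if t_len > 1:
        lp += np.log(transition)[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    return paths, lp


def enumerate_posteriors(initial, transition, means, var, x):
    """Posteriors and log-likelihood by summing over every state path."""
    k, t_len = len(initial), len(x)
    paths, lp = _all_path_logprobs(initial, transition, means, var, x)
    m = lp.max()
    w = np.exp(lp - m)
    total = w.sum()
    gamma = np.empty((t_len, k))
    for t in range(t_len):
        for s in range(k):
            gamma[t, s] = w[paths[:, t] == s].sum() / total
    return gamma, float(m + math.log(total))


def best_path_logprob(initial, transition, means, var, x) -> float:
    """Log joint probability of the single best state path, by enumeration."""
    _, lp = _all_path_logprobs(initial, transition, means, var, x)
    return float(lp.max())


def path_logprob(initial, transition, means, var, x, states) -> float:
    """Log joint probability of one given state path."""
    logdens = _log_gauss(np.asarray(x, float), np.asarray(means, float), var)
    lp = math.log(initial[states[0]]) + logdens[0, states[0]]
    for t in range(1, len(x)):
        lp += math.log(transition[states[t - 1], states[t]]) + logdens[t, states[t]]
    return float(lp)


def hypergeom_tail(k: int, n_bg: int, big_k: int, n_fg: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), by rational summation."""
    total = Fraction(0)
    denom = math.comb(n_bg, n_fg)
    for i in range(k, min(n_fg, big_k) + 1):
        total += Fraction(math.comb(big_k, i) * math.comb(n_bg - big_k, n_fg - i), denom)
    return float(total)
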