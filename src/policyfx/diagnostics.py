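"""Split-R-hat and effective sample size for pooled MCMC chains.

Classic (non-rank-normalized) forms: split-R-hat per Gelman et al. (BDA3) and
ESS via per-chain FFT autocovariances combined with Geyer's initial monotone
positive sequence.
"""

from __future__ import annotations

import numpy as np


def split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half: (m, n) -> (2m, n//2)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)


def split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction factor on split chains.

    ``x`` has shape (chains, draws).  Returns NaN for degenerate input
    (fewer than 4 draws total or zero variance).
    """
    z = split_chains(x)
    m, n = z.shape
    if n < 2:
        return float("nan")
    chain_means = z.mean(axis=1)
    chain_vars = z.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocovariance(y: np.ndarray) -> np.ndarray:
    """Biased autocovariance estimates (divide by n) via FFT."""
    n = y.shape[0]
    y = y - y.mean()
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[:n].real
    return acov / n


def ess_mean(x: np.ndarray) -> float:
    """Effective sample size for the posterior mean, over split chains."""
    z = split_chains(x)
    m, n = z.shape
    if n < 4:
        return float("nan")
    chain_means = z.mean(axis=1)
    chain_vars = z.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + (b / n if m > 1 else 0.0)
    if var_plus == 0:
        return float("nan")

    acov = np.stack([_autocovariance(z[j]) for j in range(m)])
    # Stan's combined rho_t over chains
    rho = 1.0 - (w - acov.mean(axis=0) * n / (n - 1)) / var_plus
    rho[0] = 1.0

    # Geyer initial monotone positive sequence on paired sums
    max_pairs = (n - 1) // 2
    tau = 0.0
    prev_pair = np.inf
    total = 0.0
    for k in range(max_pairs):
        pair = rho[2 * k] + rho[2 * k + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        total += pair
    tau = max(2.0 * total - 1.0, 1.0 / np.log10(m * n + 10))
    return float(m * n / tau)


def diagnostics_table(draws_by_param: dict[str, np.ndarray]):
    """Per-parameter split-R-hat and ESS.

    ``draws_by_param`` maps parameter name -> array (chains, draws).
    Returns a list of dicts (name, rhat, ess).
    """
    return [
        {"parameter": name, "rhat": split_rhat(a), "ess": ess_mean(a)}
        for name, a in draws_by_param.items()
    ]
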