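"""Pólya-Gamma draws for logistic data augmentation.

A PG(1, z) random variable has the infinite-convolution representation

    omega = (1 / (2 pi^2)) * sum_{k>=1} g_k / ((k - 1/2)^2 + z^2 / (4 pi^2)),

with g_k iid standard exponential, and mean tanh(z/2) / (2 z).  Draws here
truncate the sum after ``n_terms`` terms and add the expectation of the
omitted tail, which keeps the mean essentially exact; the missing tail
variance is O(n_terms^-3).
"""

from __future__ import annotations

import numpy as np

_TWO_PI_SQ = 2.0 * np.pi**2


def pg_mean(z: np.ndarray) -> np.ndarray:
    """Exact mean of PG(1, z): tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out[nz] = np.tanh(z[nz] / 2.0) / (2.0 * z[nz])
    return out


def _tail_mean(a: np.ndarray, n_terms: int) -> np.ndarray:
    # E of the omitted tail: (1/2pi^2) * sum_{k>n} 1/((k-1/2)^2 + a^2),
    # midpoint-rule identity: sum ~ int_n^inf dx/(x^2+a^2).
    small = a < 1e-10
    a_safe = np.where(small, 1.0, a)
    tail = (np.pi / 2.0 - np.arctan(n_terms / a_safe)) / a_safe
    tail = np.where(small, 1.0 / n_terms, tail)
    return tail / _TWO_PI_SQ


def sample_pg(z: np.ndarray, rng: np.random.Generator, n_terms: int = 100) -> np.ndarray:
    """Draw omega_i ~ PG(1, z_i) elementwise.

    Parameters
    ----------
    z : array of tilting parameters (the linear predictor values).
    rng : numpy Generator; the only source of randomness.
    n_terms : number of gamma terms kept in the convolution.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    a = np.abs(z) / (2.0 * np.pi)  # z^2/(4 pi^2) = a^2
    k = np.arange(1, n_terms + 1, dtype=float) - 0.5
    denom = k[:, None] ** 2 + a[None, :] ** 2
    g = rng.standard_exponential((n_terms, z.size))
    omega = (g / denom).sum(axis=0) / _TWO_PI_SQ
    return omega + _tail_mean(a, n_terms)
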