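"""Closed-form inverse square root of the compound-symmetry block covariance.

Plots in the same incomplete block share a random block effect, so the
within-block covariance (in units of the residual variance sigma^2) is
I + delta * J, with J the all-ones matrix and delta the block-to-error
variance ratio.  Its inverse square root is the rank-one update

    (I + delta J)^(-1/2) = I + [(1 + k delta)^(-1/2) - 1] / k * J,

which lets whitening be applied to any block-sorted vector in O(n) as
v + a * sum(v) per block.
"""

from __future__ import annotations

import numpy as np


def inv_sqrt_coeff(k: int, delta: float) -> float:
    """Coefficient ``a`` such that (I + delta J)^(-1/2) = I + a J (k x k)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if k < 1:
        raise ValueError("block size must be >= 1")
    return ((1.0 + k * delta) ** -0.5 - 1.0) / k


def sigma_inv_sqrt_block(k: int, delta: float) -> np.ndarray:
    """The k x k symmetric matrix (I + delta J)^(-1/2)."""
    return np.eye(k) + inv_sqrt_coeff(k, delta) * np.ones((k, k))


def block_whiten(values: np.ndarray, n_blocks: int, k: int, delta: float) -> np.ndarray:
    """Apply the block-diagonal Sigma^(-1/2) to block-sorted rows.

    ``values`` has ``n_blocks * k`` rows grouped contiguously by block;
    columns are whitened independently.
    """
    a = inv_sqrt_coeff(k, delta)
    arr = np.asarray(values, dtype=float)
    flat = arr.ndim == 1
    if flat:
        arr = arr[:, None]
    if arr.shape[0] != n_blocks * k:
        raise ValueError("row count does not match block structure")
    resh = arr.reshape(n_blocks, k, arr.shape[1])
    out = resh + a * resh.sum(axis=1, keepdims=True)
    out = out.reshape(arr.shape[0], arr.shape[1])
    return out[:, 0] if flat else out
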