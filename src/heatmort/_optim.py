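"""Numerically stable scalar transforms shared by the trainable models."""

from __future__ import annotations

import numpy as np


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    return np.logaddexp(0.0, x)


def softplus_inv(y: np.ndarray | float) -> np.ndarray | float:
    """Inverse of softplus; y must be > 0."""
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))
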