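"""Softmax and cross-entropy loss with gradient."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    b = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    idx = np.arange(b)
    loss = float(-np.log(np.maximum(p[idx, labels], 1e-300)).mean())
    dlogits = p
    dlogits[idx, labels] -= 1.0
    return loss, (dlogits / b).astype(np.float32)
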