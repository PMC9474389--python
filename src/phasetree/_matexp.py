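"""Vectorized matrix exponential for stacks of small matrices.

Likelihood evaluation touches one small sub-generator exponential per branch;
a tree set can easily hold thousands of branches, so the per-branch cost of a
library call dominates the fit.  This module applies the standard
scaling-and-squaring method with a Pade [13/13] approximant simultaneously to
a whole ``(m, n, n)`` stack, using batched matmuls.  The scaling power is
chosen from the largest 1-norm in the stack, so every slice is at least as
heavily scaled as scipy would scale it on its own.
"""

from __future__ import annotations

import numpy as np

# Pade [13/13] coefficients (same approximant scipy uses at its top order).
_B13 = (
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0, 670442572800.0,
    33522128640.0, 1323241920.0, 40840800.0, 960960.0, 16380.0, 182.0, 1.0,
)
_THETA13 = 4.25  # 1-norm bound below which the [13/13] approximant is accurate


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of every slice of a ``(..., n, n)`` stack."""
    A = np.asarray(A, dtype=float)
    if A.ndim == 2:
        return expm_batch(A[None])[0]
    norm = np.abs(A).sum(axis=-2).max(axis=-1).max()
    s = 0
    if norm > _THETA13:
        s = int(np.ceil(np.log2(norm / _THETA13)))
    A = A / (2.0**s)

    n = A.shape[-1]
    ident = np.broadcast_to(np.eye(n), A.shape)
    A2 = A @ A
    A4 = A2 @ A2
    A6 = A4 @ A2
    b = _B13
    U = A @ (
        A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
        + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * ident
    )
    V = (
        A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
        + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * ident
    )
    E = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        E = E @ E
    return E
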