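"""Closed-form 2x2 matrix exponentials and log-scaled matrix products.

Every matrix in the detection likelihood is 2x2 (the switching chain has two
states), so the matrix exponential has a closed form.  For a matrix
A = [[a, b], [c, d]] with b*c >= 0 the eigenvalues are m +/- q with
m = (a+d)/2 and q = sqrt(((a-d)/2)^2 + b*c) >= 0, and

    exp(A*t) = e^{m t} [ cosh(q t) I + sinh(q t)/q (A - m I) ].

Products of many such matrices underflow for long deployments, so matrices
are carried in scaled form: a pair ``(M, log_s)`` representing
``exp(log_s) * M`` with the entries of ``M`` of order one.
"""

from __future__ import annotations

import numpy as np

__all__ = ["expm2_scaled"]


def expm2_scaled(a, b, c, d, dt):
    """exp(dt * [[a, b], [c, d]]) for batched entries with b*c >= 0.

    All arguments broadcast against each other.  Returns ``(M, log_s)`` with
    ``exp(dt*A) = exp(log_s) * M``; the log scale is ``(m + q) * dt`` (the
    leading eigenvalue times dt) so the entries of ``M`` never overflow.
    """
    a, b, c, d, dt = np.broadcast_arrays(a, b, c, d, dt)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    dt = np.asarray(dt, dtype=float)

    m = 0.5 * (a + d)
    q = np.sqrt(np.maximum(0.25 * (a - d) ** 2 + b * c, 0.0))
    x = q * dt
    em2x = np.exp(-2.0 * x)
    # e^{-x} cosh(x) and e^{-x} sinh(x)/q, with a series fallback at q -> 0
    ch = 0.5 * (1.0 + em2x)
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = np.where(q > 0, (1.0 - em2x) / np.where(q > 0, 2.0 * q, 1.0), 0.0)
    small = x < 1e-6
    if np.any(small):
        sc = np.where(small, dt * (1.0 - x), sc)

    M = np.empty(a.shape + (2, 2), dtype=float)
    M[..., 0, 0] = ch + sc * (a - m)
    M[..., 0, 1] = sc * b
    M[..., 1, 0] = sc * c
    M[..., 1, 1] = ch + sc * (d - m)
    return M, (m + q) * dt


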