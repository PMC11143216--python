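"""Numerical primitives shared across the package.

Everything here is *dtype-agnostic*: it accepts real or complex arrays and
never branches on imaginary parts. That property is what makes complex-step
differentiation of the training objective exact — a parameter perturbed by
``1j*h`` flows through these helpers untouched, and the imaginary part of the
result is ``h`` times the derivative.  Stability branches (overflow guards)
therefore inspect only the real part of their argument.
"""

from __future__ import annotations

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))

# sigmoid(x) ~ Phi(sqrt(pi/8) x): the scaled-probit matching constant.
PROBIT_COEF = np.pi / 8.0


def sigmoid(z):
    """Logistic sigmoid, overflow-safe, real or complex input."""
    z = np.asarray(z)
    re = np.real(z)
    # exp argument kept non-positive in real part on both branches
    z_neg = np.where(re >= 0, -z, z)
    e = np.exp(z_neg)
    return np.where(re >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def softplus(z):
    """log(1 + exp(z)) with linear tail for large real part."""
    z = np.asarray(z)
    re = np.real(z)
    big = re > 30.0
    z_safe = np.where(big, 0.0 * z, z)
    return np.where(big, z, np.log1p(np.exp(z_safe)))


def log_sigmoid(z):
    return -softplus(-np.asarray(z))


def gauss_logpdf(x, mean, var):
    """Elementwise univariate Gaussian log-density (var may broadcast)."""
    d = x - mean
    return -0.5 * (LOG2PI + np.log(var) + d * d / var)


def logsumexp(a, axis=-1):
    """Complex-safe log-sum-exp along ``axis`` (shift by max real part)."""
    a = np.asarray(a)
    m = np.max(np.real(a), axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def inv_spd(mat, jitter=1e-9):
    """Inverse of a small symmetric positive-definite matrix.

    Works on complex-symmetric matrices too (complex-step path), which rules
    out Cholesky; the matrices here are at most d_f+k sized so an explicit
    inverse is cheap.  Adds ``jitter`` on the diagonal if the plain inverse
    fails or is non-finite.
    """
    mat = np.asarray(mat)
    try:
        out = np.linalg.inv(mat)
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    eye = np.eye(mat.shape[-1], dtype=mat.dtype)
    return np.linalg.inv(mat + jitter * eye)


def slogdet_sym(mat):
    """log|det| of a (complex-)symmetric PD matrix; returns the log-det only."""
    mat = np.asarray(mat)
    sign, logdet = np.linalg.slogdet(mat)
    if np.iscomplexobj(mat):
        # slogdet returns complex sign*exp(logdet); fold the phase back in
        return logdet + np.log(sign)
    return logdet


def bit_combinations(k: int) -> np.ndarray:
    """All 2**k binary assignments as a (2**k, k) {0,1} float array."""
    if k == 0:
        return np.zeros((1, 0))
    bits = (np.arange(2**k)[:, None] >> np.arange(k)[None, :]) & 1
    return bits.astype(float)
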