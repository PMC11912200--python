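"""Monotone rational-quadratic splines on [-1, 1].

Each spline has ``n_bins`` trainable segments whose widths, heights and knot
derivatives are produced by a conditioner network. Raw (unconstrained)
parameters map through softmax / softplus such that an all-zero raw vector
yields exactly the identity map — the initialization contract of the coupling
layers. Points outside the working interval are passed through the identity
with zero log-volume, keeping the map bijective on the whole real line.

Periodic dimensions (circular splines) share the derivative of the two
boundary knots so the density is continuous across the seam.
"""

from __future__ import annotations

import numpy as np

from . import _ad
from ._ad import Tensor

N_BINS_DEFAULT = 5
_MIN_BIN_FRAC = 1e-3
_MIN_DERIV = 1e-4
# softplus(_DERIV_SHIFT) + _MIN_DERIV == 1, so zero raw parameters give unit slope
_DERIV_SHIFT = float(np.log(np.expm1(1.0 - _MIN_DERIV)))

LEFT, RIGHT = -1.0, 1.0


def n_raw_params(n_bins: int = N_BINS_DEFAULT) -> int:
    """Raw parameters per transformed dimension (widths, heights, derivatives)."""
    return 3 * n_bins


# ---------------------------------------------------------------------------
# knot construction (numpy mirror used by the inverse / sampling path)
# ---------------------------------------------------------------------------

def _knots_np(raw: np.ndarray, n_bins: int, periodic: np.ndarray):
    K = n_bins
    raw_w, raw_h, raw_d = raw[..., :K], raw[..., K:2 * K], raw[..., 2 * K:3 * K]

    def _softmax(z):
        e = np.exp(z - z.max(axis=-1, keepdims=True))
        return e / e.sum(axis=-1, keepdims=True)

    rng = RIGHT - LEFT
    w = rng * (_MIN_BIN_FRAC + (1.0 - _MIN_BIN_FRAC * K) * _softmax(raw_w))
    h = rng * (_MIN_BIN_FRAC + (1.0 - _MIN_BIN_FRAC * K) * _softmax(raw_h))
    xk = LEFT + np.concatenate([np.zeros(w.shape[:-1] + (1,)), np.cumsum(w, axis=-1)], axis=-1)
    yk = LEFT + np.concatenate([np.zeros(h.shape[:-1] + (1,)), np.cumsum(h, axis=-1)], axis=-1)
    inner = _MIN_DERIV + np.logaddexp(0.0, raw_d + _DERIV_SHIFT)
    ones = np.ones(inner.shape[:-1] + (1,))
    d_np = np.concatenate([ones, inner[..., : K - 1], ones], axis=-1)
    d_p = np.concatenate([inner, inner[..., :1]], axis=-1)
    mask = np.broadcast_to(periodic[None, :, None], d_np.shape)
    d = np.where(mask, d_p, d_np)
    return w, h, xk, yk, d


def _bin_index(x: np.ndarray, xk: np.ndarray, n_bins: int) -> np.ndarray:
    b = (x[..., None] >= xk[..., 1:-1]).sum(axis=-1)
    return np.clip(b, 0, n_bins - 1)


# ---------------------------------------------------------------------------
# differentiable forward (training / density evaluation)
# ---------------------------------------------------------------------------

def forward(x: Tensor, raw: Tensor, n_bins: int, periodic: np.ndarray):
    """Apply the spline elementwise; returns ``(y, logdet)`` Tensors of x's shape.

    ``x`` is (B, D), ``raw`` is (B, D, 3 n_bins); ``periodic`` is a (D,) bool
    mask selecting circular dimensions.
    """
    K = n_bins
    raw_w = raw[..., :K]
    raw_h = raw[..., K:2 * K]
    raw_d = raw[..., 2 * K:3 * K]

    rng = RIGHT - LEFT
    w = (_MIN_BIN_FRAC * rng) + (rng * (1.0 - _MIN_BIN_FRAC * K)) * _ad.softmax(raw_w)
    h = (_MIN_BIN_FRAC * rng) + (rng * (1.0 - _MIN_BIN_FRAC * K)) * _ad.softmax(raw_h)
    zeros = Tensor(np.zeros(w.data.shape[:-1] + (1,)))
    xk = _ad.concat([zeros, _ad.cumsum_last(w)], axis=-1) + LEFT
    yk = _ad.concat([zeros, _ad.cumsum_last(h)], axis=-1) + LEFT
    inner = _ad.softplus(raw_d + _DERIV_SHIFT) + _MIN_DERIV
    ones = Tensor(np.ones(inner.data.shape[:-1] + (1,)))
    d_nonper = _ad.concat([ones, inner[..., : K - 1], ones], axis=-1)
    d_per = _ad.concat([inner, inner[..., :1]], axis=-1)
    pmask = np.broadcast_to(periodic[None, :, None], d_nonper.data.shape)
    d = _ad.where(pmask, d_per, d_nonper)

    inside = (x.data >= LEFT) & (x.data <= RIGHT)
    x_in = _ad.where(inside, x, Tensor(np.clip(x.data, LEFT, RIGHT)))

    b = _bin_index(x_in.data, xk.data, K)
    wb = _ad.gather_last(w, b)
    hb = _ad.gather_last(h, b)
    x0 = _ad.gather_last(xk, b)
    y0 = _ad.gather_last(yk, b)
    d0 = _ad.gather_last(d, b)
    d1 = _ad.gather_last(d, b + 1)

    s = hb / wb
    xi = (x_in - x0) / wb
    xi1 = 1.0 - xi
    xixi1 = xi * xi1
    denom = s + (d1 + d0 - 2.0 * s) * xixi1
    y = y0 + hb * (s * xi * xi + d0 * xixi1) / denom
    num2 = d1 * xi * xi + 2.0 * s * xixi1 + d0 * xi1 * xi1
    logdet = 2.0 * _ad.log(s) + _ad.log(num2) - 2.0 * _ad.log(denom)

    y = _ad.where(inside, y, x)
    logdet = _ad.where(inside, logdet, Tensor(np.zeros_like(x.data)))
    return y, logdet


def forward_np(x: np.ndarray, raw: np.ndarray, n_bins: int, periodic: np.ndarray):
    """Tape-free forward pass (density evaluation); mirrors :func:`forward`."""
    K = n_bins
    w, h, xk, yk, d = _knots_np(raw, K, periodic)
    inside = (x >= LEFT) & (x <= RIGHT)
    x_in = np.clip(x, LEFT, RIGHT)

    b = _bin_index(x_in, xk, K)
    take = lambda arr, idx: np.take_along_axis(arr, idx[..., None], axis=-1)[..., 0]
    wb, hb = take(w, b), take(h, b)
    x0, y0 = take(xk, b), take(yk, b)
    d0, d1 = take(d, b), take(d, b + 1)

    s = hb / wb
    xi = (x_in - x0) / wb
    xi1 = 1.0 - xi
    xixi1 = xi * xi1
    denom = s + (d1 + d0 - 2.0 * s) * xixi1
    y = y0 + hb * (s * xi * xi + d0 * xixi1) / denom
    num2 = d1 * xi * xi + 2.0 * s * xixi1 + d0 * xi1 * xi1
    logdet = 2.0 * np.log(s) + np.log(num2) - 2.0 * np.log(denom)

    y = np.where(inside, y, x)
    logdet = np.where(inside, logdet, 0.0)
    return y, logdet


# ---------------------------------------------------------------------------
# numpy inverse (sampling path)
# ---------------------------------------------------------------------------

def inverse(y: np.ndarray, raw: np.ndarray, n_bins: int, periodic: np.ndarray):
    """Exact inverse of :func:`forward`; returns ``(x, logdet_x_to_y)``."""
    K = n_bins
    w, h, xk, yk, d = _knots_np(raw, K, periodic)
    inside = (y >= LEFT) & (y <= RIGHT)
    y_in = np.clip(y, LEFT, RIGHT)

    b = _bin_index(y_in, yk, K)
    take = lambda arr, idx: np.take_along_axis(arr, idx[..., None], axis=-1)[..., 0]
    wb, hb = take(w, b), take(h, b)
    x0, y0 = take(xk, b), take(yk, b)
    d0, d1 = take(d, b), take(d, b + 1)

    s = hb / wb
    dy = y_in - y0
    t = d1 + d0 - 2.0 * s
    a = hb * (s - d0) + dy * t
    bb = hb * d0 - dy * t
    c = -s * dy
    disc = np.maximum(bb * bb - 4.0 * a * c, 0.0)
    xi = 2.0 * c / (-bb - np.sqrt(disc))
    xi = np.clip(xi, 0.0, 1.0)
    x = x0 + xi * wb

    xi1 = 1.0 - xi
    xixi1 = xi * xi1
    denom = s + t * xixi1
    num2 = d1 * xi * xi + 2.0 * s * xixi1 + d0 * xi1 * xi1
    logdet = 2.0 * np.log(s) + np.log(num2) - 2.0 * np.log(denom)

    x = np.where(inside, x, y)
    logdet = np.where(inside, logdet, 0.0)
    return x, logdet
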