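"""Interatomic-distance embedding: Bessel basis, cutoff envelope, radial MLP.

All learnable filter content of the network lives here: a filter is
``R(r) * Y(r_hat)`` where the radial function ``R`` is a small MLP acting on
a trainable Bessel expansion of the distance, smoothly truncated by a
polynomial envelope so that messages vanish (with two continuous
derivatives) at the cutoff radius.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["envelope", "bessel_basis", "BesselBasis", "RadialMLP"]


def envelope(u, p: int = 6):
    """Smooth cutoff polynomial on the scaled distance ``u = r / r_c``.

    ``1 - (p+1)(p+2)/2 u^p + p(p+2) u^(p+1) - p(p+1)/2 u^(p+2)`` for u < 1,
    identically zero beyond; value, first and second derivative vanish at
    u = 1.  Negative input is rejected.
    """
    if p < 2:
        raise ValueError("envelope order p must be >= 2")
    a = (p + 1.0) * (p + 2.0) / 2.0
    b = p * (p + 2.0)
    c = p * (p + 1.0) / 2.0
    if isinstance(u, Tensor):
        if np.any(u.data < 0):
            raise ValueError("scaled distance must be non-negative")
        up = u**float(p)
        val = 1.0 - a * up + b * (up * u) - c * (up * (u * u))
        return ad.where(u.data < 1.0, val, Tensor(np.zeros(u.shape)))
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("scaled distance must be non-negative")
    val = 1.0 - a * u**p + b * u ** (p + 1) - c * u ** (p + 2)
    return np.where(u < 1.0, val, 0.0)


class BesselBasis:
    """Sine-cardinal radial basis of size ``n_basis`` with trainable frequencies.

    Frequencies initialize to ``b * pi`` for ``b = 1..n_basis`` and are
    optimized alongside the network weights.
    """

    def __init__(self, n_basis: int = 8, r_c: float = 4.0, envelope_p: int = 6):
        if n_basis < 1:
            raise ValueError("n_basis must be >= 1")
        if r_c <= 0:
            raise ValueError("cutoff radius must be positive")
        self.n_basis = int(n_basis)
        self.r_c = float(r_c)
        self.envelope_p = int(envelope_p)

    def init_params(self):
        return {"frequencies": np.pi * np.arange(1, self.n_basis + 1, dtype=float)}

    def __call__(self, r, frequencies):
        """Basis values; works on numpy arrays or autodiff Tensors.

        ``B_b(r) = (2/r_c) sin(f_b r / r_c) / r * envelope(r / r_c)``,
        evaluated through the series-safe form ``(2 f_b / r_c^2) sinc(f_b r/r_c)``
        so the r -> 0 limit ``(2/r_c)(f_b/r_c)`` is exact.
        """
        is_t = isinstance(r, Tensor) or isinstance(frequencies, Tensor)
        if is_t:
            r = r if isinstance(r, Tensor) else Tensor(np.asarray(r, dtype=float))
            f = frequencies if isinstance(frequencies, Tensor) else Tensor(frequencies)
            u = r * (1.0 / self.r_c)
            n_e = u.shape[0]
            x = u.reshape((n_e, 1)) * f.reshape((1, f.shape[0]))
            small = np.abs(x.data) < 1e-8
            xs = ad.where(small, Tensor(np.ones(x.shape)), x)
            sinc = ad.where(small, 1.0 - (x * x) * (1.0 / 6.0), ad.sin(xs) / xs)
            env = envelope(u, self.envelope_p)
            pref = (f * (2.0 / self.r_c**2)).reshape((1, f.shape[0])) \
                * env.reshape((n_e, 1))
            return pref * sinc
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("distance must be non-negative")
        f = np.asarray(frequencies, dtype=float)
        u = r[..., None] / self.r_c
        x = u * f
        sinc = np.sinc(x / np.pi)  # sin(x)/x, safe at 0
        env = envelope(r / self.r_c, self.envelope_p)[..., None]
        return (2.0 / self.r_c**2) * f * sinc * env


class RadialMLP:
    """MLP mapping the Bessel embedding to all per-(path, channel) weights.

    SiLU between hidden layers, biases on hidden layers only; weight matrices
    are stored standard-normal and rescaled by 1/sqrt(fan_in) at application
    so activations stay O(1) at initialization.
    """

    def __init__(self, n_in: int, hidden=(64, 64, 64), n_out: int = 1):
        if n_out < 1:
            raise ValueError("radial MLP output width must be >= 1")
        self.widths = [int(n_in)] + [int(h) for h in hidden] + [int(n_out)]

    def init_params(self, rng):
        params = {}
        for k in range(len(self.widths) - 1):
            params[f"W{k}"] = rng.standard_normal((self.widths[k], self.widths[k + 1]))
            if k < len(self.widths) - 2:
                params[f"b{k}"] = np.zeros(self.widths[k + 1])
        return params

    def __call__(self, basis: Tensor, params) -> Tensor:
        h = basis
        n_layers = len(self.widths) - 1
        for k in range(n_layers):
            W = params[f"W{k}"]
            W = W if isinstance(W, Tensor) else Tensor(W)
            h = ad.matmul(h, W) * (1.0 / np.sqrt(self.widths[k]))
            if k < n_layers - 1:
                b = params[f"b{k}"]
                h = h + (b if isinstance(b, Tensor) else Tensor(b))
                h = ad.silu(h)
        return h
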