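"""One-dimensional Parzen (kernel) density estimation for coefficients.

The decision rule multiplies class-conditional densities of individual
canonical coefficients.  Because the decomposition removes the dependence
structure, only one-dimensional nonparametric estimates are needed — the
whole point of the construction is to avoid multivariate density
estimation.  The estimate is the usual Parzen mixture

    f_hat(x) = (1/(L h)) sum_l K((x - p_l) / h)

with a Gaussian kernel by default and Silverman's robust bandwidth rule
``h = 0.9 * min(sd, IQR / 1.34) * L ** (-1/5)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["KernelDensity", "fit_parzen", "silverman_bandwidth", "KERNELS"]

#: fallback bandwidth when the sample has zero spread (density becomes a
#: narrow bump at the common point)
DEGENERATE_BANDWIDTH = 1e-3

_SQRT_2PI = math.sqrt(2.0 * math.pi)


def _gaussian(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / _SQRT_2PI


def _epanechnikov(u: np.ndarray) -> np.ndarray:
    return np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u * u), 0.0)


KERNELS = {"gaussian": _gaussian, "epanechnikov": _epanechnikov}


def silverman_bandwidth(samples: np.ndarray) -> float:
    """``0.9 * min(sd, IQR/1.34) * L**(-1/5)``; 0 if the spread is zero."""
    s = np.asarray(samples, dtype=float)
    L = s.size
    if L < 2:
        return 0.0
    sd = float(s.std(ddof=1))
    q75, q25 = np.percentile(s, [75.0, 25.0])
    iqr = float(q75 - q25)
    spreads = [v for v in (sd, iqr / 1.34) if v > 0.0]
    if not spreads:
        return 0.0
    return 0.9 * min(spreads) * L ** (-0.2)


@dataclass
class KernelDensity:
    """A fitted Parzen estimate: stored sample points plus a bandwidth.

    Evaluation is bit-reproducible from ``(samples, h, kernel)``, which is
    what model files persist.
    """

    samples: np.ndarray
    h: float
    kernel: str = "gaussian"
    floor: float = 1e-300

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float).ravel()
        if s.size == 0:
            raise InvalidInputError("kernel density needs at least one sample")
        if not np.all(np.isfinite(s)):
            raise InvalidInputError("kernel density samples must be finite")
        if not (self.h > 0.0 and np.isfinite(self.h)):
            raise InvalidInputError(f"bandwidth must be positive, got {self.h}")
        if self.kernel not in KERNELS:
            raise InvalidInputError(
                f"unknown kernel {self.kernel!r}; choose from {sorted(KERNELS)}"
            )
        self.samples = s

    def pdf(self, x) -> np.ndarray | float:
        x_arr = np.asarray(x, dtype=float)
        single = x_arr.ndim == 0
        xv = np.atleast_1d(x_arr)
        if not np.all(np.isfinite(xv)):
            raise InvalidInputError("density evaluation point must be finite")
        kern = KERNELS[self.kernel]
        # chunk over evaluation points to bound the (n_x, L) intermediate
        out = np.empty(xv.size)
        step = max(1, int(4_000_000 // max(self.samples.size, 1)))
        for start in range(0, xv.size, step):
            block = xv[start : start + step]
            u = (block[:, None] - self.samples[None, :]) / self.h
            out[start : start + step] = kern(u).mean(axis=1) / self.h
        return float(out[0]) if single else out

    def logpdf(self, x) -> np.ndarray | float:
        """``log(max(f_hat, floor))`` — never ``-inf``.

        The floor keeps one out-of-support coefficient from wiping out all
        other factors of the likelihood product.
        """
        p = np.maximum(self.pdf(x), self.floor)
        return float(np.log(p)) if np.ndim(p) == 0 else np.log(p)


def fit_parzen(
    samples,
    bandwidth="silverman",
    kernel: str = "gaussian",
    floor: float = 1e-300,
) -> KernelDensity:
    """Fit a Parzen estimate to a coefficient sample.

    ``bandwidth`` may be the string ``"silverman"`` (default), a positive
    float, or a callable ``samples -> h``.  A zero-spread sample falls back
    to the fixed small constant :data:`DEGENERATE_BANDWIDTH`.
    """
    s = np.asarray(samples, dtype=float).ravel()
    if s.size == 0:
        raise InvalidInputError("fit_parzen: empty sample list")
    if not np.all(np.isfinite(s)):
        raise InvalidInputError("fit_parzen: samples must be finite")
    if callable(bandwidth):
        h = float(bandwidth(s))
    elif bandwidth == "silverman":
        h = silverman_bandwidth(s)
    else:
        h = float(bandwidth)
    if h <= 0.0 or not np.isfinite(h):
        h = DEGENERATE_BANDWIDTH
    return KernelDensity(samples=s, h=h, kernel=kernel, floor=floor)
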