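"""Stationary time-correlation machinery and hydrogen-bond rate fitting.

For a binary bond population h on a fixed pair universe, the survival-style
autocorrelation is

    c(t) = <h(0) h(t)> / <h>,

averaged over all pairs and all valid time origins on a uniform grid.  The
companion function

    n(t) = <h(0) [1 - h(t)] h^d(t)> / <h>

is the probability that an initially bonded pair is unbonded at t yet still
in oxygen contact, and the reactive flux is k(t) = -dc/dt.  The breaking and
reforming rate constants (k, k') follow from a least-squares fit of the
kinetic relation k(t) = k c(t) - k' n(t) over a lag window that excludes the
sub-transient region.  The same machinery serves the plain Luzar-Chandler
populations and the interface-gated ones; only the input arrays differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

__all__ = [
    "CorrelationResult",
    "RateConstants",
    "population_autocorrelation",
    "unbonded_contact_correlation",
    "reactive_flux",
    "fit_rate_constants",
    "block_correlations",
]


class EmptyPopulationError(ValueError):
    """No pair is ever bonded: the correlation is undefined."""


@dataclass
class CorrelationResult:
    """c, n, k on a uniform lag grid for one method and depth."""

    lags: np.ndarray  # ps, starting at 0
    c: np.ndarray
    n: np.ndarray | None = None
    k: np.ndarray | None = None
    method: str = "LC"  # LC | IHB
    d: float | None = None  # layer thickness, A
    origins: np.ndarray | None = None  # origin count per lag

    def value_at(self, t: float) -> float:
        """c at reference time t (linear interpolation on the lag grid)."""
        return float(np.interp(t, self.lags, self.c))

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_ps\tc\tn\tk\tn_origins\n")
            for i, t in enumerate(self.lags):
                n = self.n[i] if self.n is not None else float("nan")
                k = self.k[i] if self.k is not None else float("nan")
                o = int(self.origins[i]) if self.origins is not None else -1
                fh.write(f"{t:.6f}\t{self.c[i]:.8f}\t{n:.8f}\t{k:.8f}\t{o}\n")


@dataclass
class RateConstants:
    """Breaking (k) and reforming (k') rate constants from the kinetic fit."""

    k: float  # ps^-1
    k_prime: float | None  # ps^-1; None when the design is singular (n == 0)
    window: tuple[float, float] = (0.2, 10.0)
    residual: float = 0.0

    @property
    def lifetime(self) -> float:
        """HB lifetime 1/k (ps)."""
        if self.k <= 0:
            return float("inf")
        return 1.0 / self.k


def _xcorr_sum(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """sum over pairs and origins of x[t0] * y[t0 + t], t = 0..max_lag.

    x, y: (T, P) arrays.  FFT-based, linear (zero-padded) correlation.
    """
    T = x.shape[0]
    nfft = 1
    while nfft < T + max_lag + 1:
        nfft *= 2
    X = np.fft.rfft(x, nfft, axis=0)
    Y = np.fft.rfft(y, nfft, axis=0)
    full = np.fft.irfft(np.conj(X) * Y, nfft, axis=0)
    return full[: max_lag + 1].sum(axis=1)


def _origin_counts(T: int, max_lag: int, stride: int) -> np.ndarray:
    lags = np.arange(max_lag + 1)
    return np.ceil(np.maximum(T - lags, 0) / stride).astype(int)


def _corr(
    x: np.ndarray, y: np.ndarray, max_lag: int, origin_stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Numerator and denominator of <x(0) y(t)> / <x> per lag."""
    T = x.shape[0]
    if origin_stride == 1:
        numer = _xcorr_sum(x, y, max_lag)
        row = x.sum(axis=1)
        # denom(t) = sum of x over valid origins t0 <= T-1-t
        cum = np.cumsum(row)
        denom = cum[T - 1 - np.arange(max_lag + 1)]
    else:
        origins = np.arange(0, T, origin_stride)
        numer = np.empty(max_lag + 1)
        denom = np.empty(max_lag + 1)
        for t in range(max_lag + 1):
            valid = origins[origins + t < T]
            numer[t] = np.einsum("op,op->", x[valid], y[valid + t])
            denom[t] = x[valid].sum()
    return numer, denom


def population_autocorrelation(
    h: np.ndarray,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> CorrelationResult:
    """c(t) = <h(0)h(t)> / <h> over multiple time origins.

    h is a (T, P) binary array: frames by pairs.  ``origin_stride`` sets the
    origin grid in frames (default every frame).
    """
    h = np.asarray(h)
    if h.ndim != 2:
        raise ValueError("h must be (n_frames, n_pairs)")
    if not h.any():
        raise EmptyPopulationError("empty population: no pair is ever bonded")
    T = h.shape[0]
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    x = h.astype(np.float64)
    numer, denom = _corr(x, x, max_lag, origin_stride)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, numer / denom, 0.0)
    lags = np.arange(max_lag + 1) * dt
    return CorrelationResult(
        lags=lags, c=c, origins=_origin_counts(T, max_lag, origin_stride)
    )


def unbonded_contact_correlation(
    h: np.ndarray,
    hd: np.ndarray,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> np.ndarray:
    """n(t) = <h(0) [1 - h(t)] h^d(t)> / <h>.

    Same grid and normalization as :func:`population_autocorrelation`;
    returns the n values only.
    """
    h = np.asarray(h)
    hd = np.asarray(hd)
    if h.shape != hd.shape:
        raise ValueError("h and hd must have the same shape")
    if not h.any():
        raise EmptyPopulationError("empty population: no pair is ever bonded")
    T = h.shape[0]
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    x = h.astype(np.float64)
    g = ((~h.astype(bool)) & hd.astype(bool)).astype(np.float64)
    numer, denom = _corr(x, g, max_lag, origin_stride)
    numer = np.maximum(numer, 0.0)  # FFT roundoff can leave ~1e-17 negatives
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, numer / denom, 0.0)


def reactive_flux(c: np.ndarray, dt: float) -> np.ndarray:
    """k(t) = -dc/dt: central differences interior, one-sided at the ends."""
    c = np.asarray(c, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 lag points for the reactive flux")
    return -np.gradient(c, dt, edge_order=2)


def fit_rate_constants(
    lags: np.ndarray,
    c: np.ndarray,
    n: np.ndarray,
    k_flux: np.ndarray,
    window: tuple[float, float] = (0.2, 10.0),
) -> RateConstants:
    """Least squares for (k, k') in k(t) = k c(t) - k' n(t), both clamped >= 0.

    When n vanishes identically inside the window the design is singular:
    only k is fitted and k' is reported as undefined (None).
    """
    lags = np.asarray(lags)
    sel = (lags >= window[0]) & (lags <= window[1])
    if not np.any(sel):
        raise ValueError(f"fit window {window} contains no lag points")
    cs, ns, ks = c[sel], n[sel], k_flux[sel]
    if np.max(np.abs(ns)) < 1e-12:
        kk = float(np.dot(ks, cs) / np.dot(cs, cs))
        kk = max(kk, 0.0)
        resid = float(np.linalg.norm(ks - kk * cs))
        return RateConstants(k=kk, k_prime=None, window=window, residual=resid)
    A = np.column_stack([cs, -ns])
    res = lsq_linear(A, ks, bounds=(0.0, np.inf))
    k, kp = res.x
    return RateConstants(
        k=float(k), k_prime=float(kp), window=window, residual=float(np.linalg.norm(res.fun))
    )


def block_correlations(
    h: np.ndarray,
    dt: float,
    n_blocks: int,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> list[CorrelationResult]:
    """c(t) per contiguous sub-trajectory block, for simple error estimates."""
    T = h.shape[0]
    size = T // n_blocks
    out = []
    for b in range(n_blocks):
        hb = h[b * size : (b + 1) * size]
        if hb.any():
            out.append(
                population_autocorrelation(hb, dt, max_lag=max_lag, origin_stride=origin_stride)
            )
    return out
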