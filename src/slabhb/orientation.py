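"""Orientational anisotropy decay and free-OH persistence at the interface.

C2(t) = <P2(u(0).u(t))> is the second-Legendre autocorrelation of OH bond
unit vectors, averaged over the OH groups whose molecule lies inside the
depth-d layer at the time origin (origin-only gating: the tagged
subpopulation is then followed, so reorientation is not conflated with
layer exchange).  C2 is fitted with a biexponential decay
A1 exp(-t/tau1) + A2 exp(-t/tau2), tau1 <= tau2.

A free OH donates no hydrogen bond (a dangling hydroxyl; the acceptor
status of its oxygen is ignored).  Its interfacial persistence
c_f(t) = <f(0) f(t)> / <f> with f = (free AND molecule inside the layer,
evaluated instantaneously) supplies an independent depth scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .tcf import EmptyPopulationError, population_autocorrelation
from .trajio import Trajectory, minimum_image_displacement

__all__ = [
    "OrientationResult",
    "BiexponentialFit",
    "FreeOHResult",
    "oh_unit_vectors",
    "c2_correlation",
    "biexponential_fit",
    "free_oh_correlation",
]


@dataclass
class OrientationResult:
    lags: np.ndarray
    c2: np.ndarray
    d: float | None = None
    fit: "BiexponentialFit | None" = None

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.lags, self.c2))

    def export_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_ps\tC2\n")
            for t, v in zip(self.lags, self.c2):
                fh.write(f"{t:.6f}\t{v:.8f}\n")


@dataclass
class BiexponentialFit:
    """C2(t) ~ A1 exp(-t/tau1) + A2 exp(-t/tau2) with tau1 <= tau2."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    residual: float
    degenerate: bool = False  # single-exponential-like solution

    @property
    def slow_time(self) -> float:
        """The slow relaxation time, reported when one number is needed."""
        return self.tau2


@dataclass
class FreeOHResult:
    lags: np.ndarray
    c_f: np.ndarray
    d: float | None = None

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.lags, self.c_f))


def oh_unit_vectors(traj: Trajectory, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image O->H unit vectors for every frame.

    Returns (u, oh_mol): u has shape (T, 2*n_waters, 3); oh_mol maps each OH
    group to its molecule index.
    """
    waters = traj.frames[0].waters
    o_idx = np.array([w[0] for w in waters])
    h_idx = np.array([[w[1], w[2]] for w in waters]).reshape(-1)
    oh_mol = np.repeat(np.arange(len(waters)), 2)
    T = traj.n_frames
    u = np.empty((T, len(h_idx), 3), dtype=dtype)
    for t, f in enumerate(traj.frames):
        d = minimum_image_displacement(
            f.positions[o_idx][oh_mol], f.positions[h_idx], traj.cell
        )
        u[t] = (d / np.linalg.norm(d, axis=-1, keepdims=True)).astype(dtype)
    return u, oh_mol


def _sym_products(u: np.ndarray) -> np.ndarray:
    """6-component symmetric products so that dot(Q, Q') = (u.u')^2."""
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    s = np.sqrt(np.float32(2.0))
    return np.stack([x * x, y * y, z * z, s * x * y, s * x * z, s * y * z], axis=-1)


def c2_correlation(
    u: np.ndarray,
    oh_mol: np.ndarray,
    member: np.ndarray | None,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 5,
    d: float | None = None,
) -> OrientationResult:
    """C2(t) over OH groups interfacial at the time origin.

    ``u`` is the (T, n_OH, 3) unit-vector array; ``member`` the per-frame
    molecule membership (None means no gating — every OH contributes).
    """
    T = u.shape[0]
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    if member is not None:
        mask = member[:, oh_mol]
        if not mask.any():
            raise EmptyPopulationError(f"no interfacial OH at any origin for d = {d}")
    else:
        mask = np.ones((T, u.shape[1]), dtype=bool)
    Q = _sym_products(u)  # (T, nOH, 6)
    origins = np.arange(0, T, origin_stride)
    c2 = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        valid = origins[origins + lag < T]
        m = mask[valid]
        w = m.sum()
        if w == 0:
            c2[lag] = np.nan
            continue
        dots = np.einsum(
            "ons,ons->on", Q[valid], Q[valid + lag], optimize=True
        )
        c2[lag] = (1.5 * (dots * m).sum() / w) - 0.5
    lags = np.arange(max_lag + 1) * dt
    return OrientationResult(lags=lags, c2=c2, d=d)


def c2_depth_scan(
    u: np.ndarray,
    oh_mol: np.ndarray,
    depths: np.ndarray,
    d_grid: np.ndarray,
    t_star,
    dt: float,
    origin_stride: int = 5,
) -> np.ndarray:
    """C2(t*) over a depth grid, sharing the orientation products across d.

    Only the reference-time lags are evaluated, so the expensive P2 inner
    products are computed once per lag and reused for every layer
    thickness.  Returns a (len(d_grid), len(t_star)) matrix.
    """
    T = u.shape[0]
    lags = [int(round(t / dt)) for t in t_star]
    if max(lags) > T - 1:
        raise ValueError("reference time beyond trajectory length")
    Q = _sym_products(u)
    origins = np.arange(0, T, origin_stride)
    out = np.empty((len(d_grid), len(lags)))
    for li, lag in enumerate(lags):
        valid = origins[origins + lag < T]
        dots = np.einsum("ons,ons->on", Q[valid], Q[valid + lag], optimize=True)
        p2 = 1.5 * dots - 0.5
        for di, d in enumerate(d_grid):
            m = ((depths[valid] >= 0.0) & (depths[valid] <= d))[:, oh_mol]
            w = m.sum()
            out[di, li] = (p2 * m).sum() / w if w > 0 else np.nan
    return out


def biexponential_fit(
    lags: np.ndarray, c2: np.ndarray, n_starts: int = 8, seed: int = 0
) -> BiexponentialFit:
    """Bounded nonlinear least squares of a two-exponential decay.

    Multistart initialization over log-spaced time-constant guesses; the
    components are relabeled so tau1 <= tau2.  A vanishing amplitude or a
    time-constant ratio within 5% flags the solution as degenerate
    (effectively single-exponential).
    """
    lags = np.asarray(lags, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if lags.size < 8:
        raise ValueError("need at least 8 lag points for a biexponential fit")
    if np.any(lags < 0):
        raise ValueError("negative lag grid")
    if np.any(~np.isfinite(c2)):
        raise ValueError("non-finite C2 values")

    span = max(lags[-1], lags[1] if lags[0] == 0 else lags[0])
    rng = np.random.default_rng(seed)

    def model(p, t):
        a1, t1, a2, t2 = p
        return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2)

    best = None
    tgrid = np.geomspace(max(span * 1e-3, 1e-4), span * 3, max(n_starts, 2))
    for i in range(n_starts):
        t1g = tgrid[i % len(tgrid)]
        t2g = tgrid[(i * 3 + 1) % len(tgrid)]
        if t2g < t1g:
            t1g, t2g = t2g, t1g
        a0 = max(c2[0], 0.1)
        p0 = [0.5 * a0 * (1 + 0.1 * rng.standard_normal()), t1g, 0.5 * a0, t2g * 1.5]
        p0 = np.clip(p0, 1e-8, None)
        try:
            res = least_squares(
                lambda p: model(p, lags) - c2,
                p0,
                bounds=([0, 1e-8, 0, 1e-8], [np.inf] * 4),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError(
            "biexponential fit did not converge after multistart; "
            f"last status: {None if best is None else best.message}"
        )
    a1, t1, a2, t2 = best.x
    if t1 > t2:
        a1, t1, a2, t2 = a2, t2, a1, t1
    amp = max(a1 + a2, 1e-12)
    degenerate = (min(a1, a2) / amp < 1e-3) or (t2 / max(t1, 1e-12) < 1.05)
    return BiexponentialFit(
        a1=float(a1),
        tau1=float(t1),
        a2=float(a2),
        tau2=float(t2),
        residual=float(np.sqrt(2 * best.cost)),
        degenerate=bool(degenerate),
    )


def free_oh_correlation(
    donor_oh: np.ndarray,
    oh_mol: np.ndarray,
    member: np.ndarray | None,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 1,
    d: float | None = None,
) -> FreeOHResult:
    """Persistence correlation of interfacial free (dangling) OH groups.

    ``donor_oh`` is the (T, n_OH) flag that the OH donates a bond; the free
    flag is its negation, gated instantaneously by layer membership of the
    molecule.  c_f(t) = <f(0) f(t)> / <f> over all OH groups and origins.
    """
    free = ~np.asarray(donor_oh, dtype=bool)
    if member is not None:
        free = free & member[:, oh_mol]
    if not free.any():
        raise EmptyPopulationError(f"no free interfacial OH at any origin for d = {d}")
    res = population_autocorrelation(
        free, dt, max_lag=max_lag, origin_stride=origin_stride
    )
    return FreeOHResult(lags=res.lags, c_f=res.c, d=d)
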