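"""The two bracketing scenarios for interfacial hydrogen-bond dynamics.

Scenario 1 (LC): split the trajectory into consecutive sub-trajectories of
length t_traj, collect the union of interfacial molecules at evenly spaced
sampling moments in each window, and compute the plain Luzar-Chandler
correlations over pairs drawn from that union — no interface gating inside
the window.  Molecules that slip into the bulk keep contributing, so this
route *underestimates* interfacial HB breaking.

Scenario 2 (IHB): gate the populations at every frame with the interface
HB population h^(s) (bonded AND both molecules inside the layer).  A pair
leaving the layer counts as a loss even if the bond survives, so this route
*overestimates* interfacial HB breaking.  The genuine interfacial kinetics
lie between the two, and both converge as the layer thickness d grows —
which is what the thickness scan exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hbond import PairPopulations
from .tcf import (
    CorrelationResult,
    EmptyPopulationError,
    _corr,
    reactive_flux,
)

__all__ = [
    "Scenario1Config",
    "sample_scenario1_molecules",
    "scenario1_correlations",
    "scenario2_correlations",
]


@dataclass(frozen=True)
class Scenario1Config:
    """Sub-trajectory sampling for the LC scenario.

    t_traj is the sub-trajectory length in ps (long enough to observe HB
    decay, short enough that molecules do not all cross the interface);
    n_sampling moments are spread evenly across each window.
    """

    d: float
    t_traj: float = 40.0
    n_sampling: int = 10

    def __post_init__(self):
        if self.t_traj <= 0:
            raise ValueError("t_traj must be positive")
        if self.n_sampling < 2:
            raise ValueError("need at least 2 sampling moments")
        if self.d < 0:
            raise ValueError("layer thickness d must be >= 0")


def sample_scenario1_molecules(
    member: np.ndarray, dt: float, cfg: Scenario1Config
) -> list[tuple[slice, np.ndarray]]:
    """Window slices and per-window unions of interfacial molecules.

    ``member`` is the (T, n_waters) membership matrix at the config's depth.
    The trajectory is partitioned into consecutive non-overlapping windows
    of t_traj; a partial trailing window is discarded.  Within each window
    the union over the evenly spaced sampling moments is taken.
    """
    T = member.shape[0]
    w = int(round(cfg.t_traj / dt))
    if w < 2 or w > T:
        raise ValueError(
            f"t_traj = {cfg.t_traj} ps needs {w} frames but trajectory has {T}"
        )
    out = []
    for start in range(0, T - w + 1, w):
        sl = slice(start, start + w)
        moments = start + np.round(np.linspace(0, w - 1, cfg.n_sampling)).astype(int)
        union = member[moments].any(axis=0)
        out.append((sl, np.flatnonzero(union)))
    return out


def scenario1_correlations(
    pops: PairPopulations,
    member: np.ndarray,
    cfg: Scenario1Config,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> CorrelationResult:
    """Window-averaged LC correlations on the sampled molecule unions.

    Within each window the plain h/h^d populations are restricted to pairs
    whose both members belong to that window's union; c, n are accumulated
    across windows with origin-count weighting (shared numerator and
    denominator sums).
    """
    windows = sample_scenario1_molecules(member, dt, cfg)
    w = windows[0][0].stop - windows[0][0].start
    if max_lag is None:
        max_lag = w - 1
    max_lag = min(max_lag, w - 1)
    num_c = np.zeros(max_lag + 1)
    num_n = np.zeros(max_lag + 1)
    den = np.zeros(max_lag + 1)
    origins = np.zeros(max_lag + 1, dtype=int)
    any_union = False
    for sl, mols in windows:
        if mols.size == 0:
            continue
        any_union = True
        inset = np.zeros(member.shape[1], dtype=bool)
        inset[mols] = True
        cols = np.flatnonzero(inset[pops.pairs[:, 0]] & inset[pops.pairs[:, 1]])
        if cols.size == 0:
            continue
        h = pops.h[sl][:, cols].astype(np.float64)
        hd = pops.hd[sl][:, cols]
        g = ((~pops.h[sl][:, cols]) & hd).astype(np.float64)
        nc, dc = _corr(h, h, max_lag, origin_stride)
        nn, _ = _corr(h, g, max_lag, origin_stride)
        num_c += nc
        num_n += nn
        den += dc
        lagf = np.arange(max_lag + 1)
        origins += np.ceil(np.maximum(w - lagf, 0) / origin_stride).astype(int)
    if not any_union:
        raise EmptyPopulationError(
            f"no interfacial molecule in any window at d = {cfg.d}"
        )
    if not np.any(den > 0):
        raise EmptyPopulationError(
            f"no bonded pair among sampled molecules at d = {cfg.d}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num_c / den, 0.0)
        n = np.where(den > 0, num_n / den, 0.0)
    lags = np.arange(max_lag + 1) * dt
    return CorrelationResult(
        lags=lags,
        c=c,
        n=n,
        k=reactive_flux(c, dt),
        method="LC",
        d=cfg.d,
        origins=origins,
    )


def scenario2_correlations(
    pops: PairPopulations,
    member: np.ndarray,
    d: float,
    dt: float,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> CorrelationResult:
    """Interface-gated (IHB) correlations c^(s), n^(s), k^(s) at depth d.

    The gate h^(s) = h AND both-member is evaluated at every frame, not just
    at origins, so leaving the layer interrupts the population.
    """
    hs, hds = pops.gated(member)
    if not hs.any():
        raise EmptyPopulationError(
            f"no interfacial bonded pair at any origin for d = {d}"
        )
    T = hs.shape[0]
    if max_lag is None:
        max_lag = T - 1
    max_lag = min(max_lag, T - 1)
    x = hs.astype(np.float64)
    g = ((~hs) & hds).astype(np.float64)
    num_c, den = _corr(x, x, max_lag, origin_stride)
    num_n, _ = _corr(x, g, max_lag, origin_stride)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num_c / den, 0.0)
        n = np.where(den > 0, num_n / den, 0.0)
    lags = np.arange(max_lag + 1) * dt
    lagf = np.arange(max_lag + 1)
    return CorrelationResult(
        lags=lags,
        c=c,
        n=n,
        k=reactive_flux(c, dt),
        method="IHB",
        d=d,
        origins=np.ceil(np.maximum(T - lagf, 0) / origin_stride).astype(int),
    )
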