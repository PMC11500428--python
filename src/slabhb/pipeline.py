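"""End-to-end orchestration: trajectory -> depths -> scans -> thickness.

`SlabAnalysis` bundles the expensive intermediates (H-bond populations,
per-frame molecular depths, OH unit vectors) so the four depth scans — HB
correlations, HB rates, C2(t*) and free-OH persistence — share them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import orientation as ori
from .hbond import HBCriteria, PairPopulations, population_series
from .scenarios import Scenario1Config, scenario1_correlations, scenario2_correlations
from .tcf import fit_rate_constants
from .thickness import (
    DEFAULT_D_GRID,
    DEFAULT_T_STAR,
    DEFAULT_TOL,
    ThicknessScan,
    combined_convergence,
    d_scan,
)
from .trajio import Trajectory
from .wcsurface import DEFAULT_GRID_SPACING, DEFAULT_XI, surface_for_trajectory

__all__ = ["AnalysisConfig", "SlabAnalysis"]


@dataclass
class AnalysisConfig:
    """Resolved configuration of one analysis run (embedded in reports)."""

    criteria: HBCriteria = field(default_factory=HBCriteria)
    xi: float = DEFAULT_XI
    grid_spacing: float = DEFAULT_GRID_SPACING
    surface_average_stride: int | None = 10
    surface_mode: str = "heightfield"
    d_grid: tuple = tuple(DEFAULT_D_GRID)
    t_star: tuple = DEFAULT_T_STAR
    t_traj: float = 40.0
    n_sampling: int = 10
    fit_window: tuple = (0.2, 10.0)
    max_lag_ps: float = 10.0
    origin_stride: int = 1
    c2_origin_stride: int = 5
    tol: float = DEFAULT_TOL
    convergence_mode: str = "knee"

    def to_dict(self) -> dict:
        return {
            "r_oo_cutoff_A": self.criteria.r_oo,
            "angle_cutoff_deg": self.criteria.theta_deg,
            "angle_convention": self.criteria.angle_convention,
            "xi_A": self.xi,
            "grid_spacing_A": self.grid_spacing,
            "surface_average_stride": self.surface_average_stride,
            "surface_mode": self.surface_mode,
            "d_grid_A": list(self.d_grid),
            "t_star_ps": list(self.t_star),
            "t_traj_ps": self.t_traj,
            "n_sampling": self.n_sampling,
            "fit_window_ps": list(self.fit_window),
            "max_lag_ps": self.max_lag_ps,
            "origin_stride": self.origin_stride,
            "c2_origin_stride": self.c2_origin_stride,
            "tolerance": self.tol,
            "convergence_mode": self.convergence_mode,
        }


class SlabAnalysis:
    """Shared intermediates and the four depth scans for one trajectory."""

    def __init__(self, traj: Trajectory, config: AnalysisConfig | None = None):
        self.traj = traj
        self.config = config or AnalysisConfig()
        self.dt = traj.timestep
        self._pops: PairPopulations | None = None
        self._depths: np.ndarray | None = None
        self._u = None
        self._oh_mol = None

    # --- lazily computed intermediates -----------------------------------
    @property
    def populations(self) -> PairPopulations:
        if self._pops is None:
            self._pops = population_series(
                self.traj, self.config.criteria, with_donors=True
            )
        return self._pops

    @property
    def depths(self) -> np.ndarray:
        if self._depths is None:
            _, self._depths = surface_for_trajectory(
                self.traj,
                xi=self.config.xi,
                grid_spacing=self.config.grid_spacing,
                average_stride=self.config.surface_average_stride,
                mode=self.config.surface_mode,
            )
        return self._depths

    @property
    def max_lag(self) -> int:
        return int(round(self.config.max_lag_ps / self.dt))

    def _oh_vectors(self):
        if self._u is None:
            self._u, self._oh_mol = ori.oh_unit_vectors(self.traj)
        return self._u, self._oh_mol

    # --- per-depth correlation providers ---------------------------------
    def lc_correlation(self, member: np.ndarray, d: float):
        cfg = Scenario1Config(
            d=d, t_traj=self.config.t_traj, n_sampling=self.config.n_sampling
        )
        return scenario1_correlations(
            self.populations,
            member,
            cfg,
            self.dt,
            max_lag=self.max_lag,
            origin_stride=self.config.origin_stride,
        )

    def ihb_correlation(self, member: np.ndarray, d: float):
        return scenario2_correlations(
            self.populations,
            member,
            d,
            self.dt,
            max_lag=self.max_lag,
            origin_stride=self.config.origin_stride,
        )

    def _corr_provider(self, method: str, rate: bool):
        fn = self.lc_correlation if method == "LC" else self.ihb_correlation

        def provider(member, d):
            res = fn(member, d)
            if rate:
                rc = fit_rate_constants(
                    res.lags, res.c, res.n, res.k, window=self.config.fit_window
                )
                return [rc.k]
            return [res.value_at(t) for t in self.config.t_star]

        return provider

    # --- scans ------------------------------------------------------------
    def hb_correlation_scan(self, methods=("LC", "IHB")) -> ThicknessScan:
        """c(t*) and c^(s)(t*) over the depth grid."""
        scan = ThicknessScan(
            d_grid=np.asarray(self.config.d_grid),
            t_star=self.config.t_star,
            property_name="hb_correlation",
            tol=self.config.tol,
            mode=self.config.convergence_mode,
        )
        for m in methods:
            scan.matrices[m] = d_scan(
                self._corr_provider(m, rate=False), self.depths, scan.d_grid
            )
        scan.converge()
        return scan

    def hb_rate_scan(self, methods=("LC", "IHB")) -> ThicknessScan:
        """Fitted breaking rates k_LC(d) and k_IHB(d)."""
        scan = ThicknessScan(
            d_grid=np.asarray(self.config.d_grid),
            t_star=None,
            property_name="hb_breaking_rate",
            tol=self.config.tol,
            mode=self.config.convergence_mode,
        )
        for m in methods:
            scan.matrices[m] = d_scan(
                self._corr_provider(m, rate=True), self.depths, scan.d_grid
            )
        scan.converge()
        return scan

    def c2_scan(self) -> tuple[np.ndarray, object]:
        """C2(t*) matrix over the depth grid and its convergence result."""
        u, oh_mol = self._oh_vectors()
        mat = ori.c2_depth_scan(
            u,
            oh_mol,
            self.depths,
            np.asarray(self.config.d_grid),
            self.config.t_star,
            self.dt,
            origin_stride=self.config.c2_origin_stride,
        )
        res = combined_convergence(
            np.asarray(self.config.d_grid),
            mat,
            tol=self.config.tol,
            mode=self.config.convergence_mode,
        )
        return mat, res

    def free_oh_scan(self) -> tuple[np.ndarray, object]:
        """c_f(t*) matrix over the depth grid and its convergence result."""
        pops = self.populations
        if pops.donor_oh is None:
            raise RuntimeError("populations were computed without donor flags")
        _, oh_mol = self._oh_vectors()
        d_grid = np.asarray(self.config.d_grid)

        def provider(member, d):
            res = ori.free_oh_correlation(
                pops.donor_oh,
                oh_mol,
                member,
                self.dt,
                max_lag=self.max_lag,
                origin_stride=self.config.origin_stride,
                d=d,
            )
            return [res.value_at(t) for t in self.config.t_star]

        mat = d_scan(provider, self.depths, d_grid)
        res = combined_convergence(
            d_grid, mat, tol=self.config.tol, mode=self.config.convergence_mode
        )
        return mat, res

    def c2_curve(self, d: float, max_lag: int | None = None):
        """Full C2(t) at one depth (for the biexponential fit)."""
        u, oh_mol = self._oh_vectors()
        member = (self.depths >= 0.0) & (self.depths <= d)
        return ori.c2_correlation(
            u,
            oh_mol,
            member,
            self.dt,
            max_lag=max_lag if max_lag is not None else self.max_lag,
            origin_stride=self.config.c2_origin_stride,
            d=d,
        )

    # --- reports -----------------------------------------------------------
    def thickness_report(self, include=("correlation", "rate")) -> dict:
        report: dict = {"config": self.config.to_dict(), "scans": {}}
        if "correlation" in include:
            scan = self.hb_correlation_scan()
            report["scans"]["hb_correlation"] = scan.to_dict()
        if "rate" in include:
            scan = self.hb_rate_scan()
            report["scans"]["hb_breaking_rate"] = scan.to_dict()
        if "c2" in include:
            mat, res = self.c2_scan()
            report["scans"]["c2"] = {
                "matrix": mat.tolist(),
                "converged": res.converged,
                "d_f": res.d_f,
            }
        if "free_oh" in include:
            mat, res = self.free_oh_scan()
            report["scans"]["free_oh"] = {
                "matrix": mat.tolist(),
                "converged": res.converged,
                "d_f": res.d_f,
            }
        return report

    def write_report(self, report: dict, path) -> None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
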