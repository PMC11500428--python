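"""Geometric hydrogen-bond detection and interface-gated populations.

A pair of waters is H-bonded (h = 1) when the inter-oxygen distance is at
most r_OO^c and some donor O-H makes an H-O(donor)-O(acceptor) angle of at
most theta_c, both under the minimum-image convention.  h^d = 1 records
mere oxygen contact (R_OO < r_OO^c).  The interface populations gate these
on layer membership of *both* molecules: h^(s) = h AND both members,
h^(d,s) = h^d AND both members.

Populations are kept on undirected molecule pairs: a pair counts as bonded
if either molecule donates to the other through either of its hydrogens,
so a proton swap within a persistent bond does not register as breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajio import Frame, SimulationCell, minimum_image_displacement

__all__ = [
    "HBCriteria",
    "PairPopulations",
    "detect_hbonds",
    "interface_hb_population",
    "population_series",
]


@dataclass(frozen=True)
class HBCriteria:
    """Geometric criterion: O-O cutoff (A) and donor-angle cutoff (degrees).

    Defaults are the canonical values for liquid water, r_OO^c = 3.5 A and
    theta_c = 30 deg with the angle measured as H-O(donor)-O(acceptor).
    """

    r_oo: float = 3.5
    theta_deg: float = 30.0
    angle_convention: str = "H-Od-Oa"

    def __post_init__(self):
        if self.r_oo <= 0:
            raise ValueError("r_oo must be positive")
        if not (0.0 < self.theta_deg < 90.0):
            raise ValueError("theta_deg must lie in (0, 90)")


def detect_hbonds(
    frame: Frame,
    cell: SimulationCell,
    criteria: HBCriteria = HBCriteria(),
    return_donors: bool = False,
):
    """All contact pairs of one frame with their h and h^d flags.

    Returns (pairs, h, hd) where pairs is an (m, 2) array of undirected
    water-index pairs (i < j) with R_OO <= r_OO^c, hd is all ones on that
    list by construction, and h marks pairs where either molecule donates.
    With ``return_donors`` a fourth (n_waters, 2) boolean array flags each
    OH group that donates at least one bond (used for free-OH analysis).
    Neighbor search uses a periodic k-d tree on the oxygen positions.
    """
    if not frame.waters:
        raise ValueError("frame has no water topology; run assign_water_topology")
    n_waters = len(frame.waters)
    opos = frame.positions[frame.oxygen_indices()]
    # wrap into the box so the periodic tree accepts the coordinates; the
    # vacuum gap means no pair can straddle the z boundary
    wrapped = np.mod(opos, cell.lengths)
    tree = cKDTree(wrapped, boxsize=cell.lengths)
    raw = tree.query_pairs(r=criteria.r_oo, output_type="ndarray")
    if raw.size == 0:
        empty = (np.empty((0, 2), dtype=int), np.zeros(0, bool), np.zeros(0, bool))
        return empty + (np.zeros((n_waters, 2), bool),) if return_donors else empty
    pairs = np.sort(raw, axis=1)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    cos_c = np.cos(np.deg2rad(criteria.theta_deg))
    h_idx = np.array([[w[1], w[2]] for w in frame.waters])
    # minimum-image O->H bond vectors, (n_waters, 2, 3)
    oh = minimum_image_displacement(
        opos[:, None, :], frame.positions[h_idx], cell
    )
    oh_unit = oh / np.linalg.norm(oh, axis=-1, keepdims=True)
    i, j = pairs[:, 0], pairs[:, 1]
    oo = minimum_image_displacement(opos[i], opos[j], cell)
    oo_unit = oo / np.linalg.norm(oo, axis=-1, keepdims=True)
    # donor angle for both hydrogens of both directions
    cos_i = np.einsum("phx,px->ph", oh_unit[i], oo_unit)
    cos_j = np.einsum("phx,px->ph", oh_unit[j], -oo_unit)
    don_i = cos_i >= cos_c  # (m, 2): i's hydrogens donating to j
    don_j = cos_j >= cos_c
    h = don_i.any(axis=1) | don_j.any(axis=1)
    if not return_donors:
        return pairs, h, np.ones(len(pairs), dtype=bool)
    donor_oh = np.zeros((n_waters, 2), dtype=bool)
    np.logical_or.at(donor_oh, i, don_i)
    np.logical_or.at(donor_oh, j, don_j)
    return pairs, h, np.ones(len(pairs), dtype=bool), donor_oh


def interface_hb_population(
    h: np.ndarray, hd: np.ndarray, pairs: np.ndarray, member: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gate pair populations on joint layer membership.

    ``member`` holds per-water membership flags; broadcasting over a leading
    time axis is supported (member shape (..., n_waters), h/hd shape
    (..., n_pairs)).  Returns (h_s, h_ds).
    """
    both = member[..., pairs[:, 0]] & member[..., pairs[:, 1]]
    return h & both, hd & both


@dataclass
class PairPopulations:
    """Trajectory-wide binary populations on a fixed undirected pair universe.

    The universe is every molecule pair that is ever in oxygen contact at
    any frame; pairs contribute zeros at frames where they are absent.
    """

    pairs: np.ndarray  # (P, 2) water indices
    h: np.ndarray  # (T, P) bool
    hd: np.ndarray  # (T, P) bool
    times: np.ndarray  # (T,)
    donor_oh: np.ndarray | None = None  # (T, 2 * n_waters) bool, OH donates

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def gated(self, member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """h^(s), h^(d,s) for per-frame membership flags (T, n_waters)."""
        return interface_hb_population(self.h, self.hd, self.pairs, member)

    def export_tsv(self, path, frame_slice=slice(None)) -> None:
        with open(path, "w") as fh:
            fh.write("time\tdonor\tacceptor\th\thd\n")
            idx = range(*frame_slice.indices(len(self.times)))
            for t in idx:
                for p in range(self.n_pairs):
                    if self.hd[t, p]:
                        fh.write(
                            f"{self.times[t]:.4f}\t{self.pairs[p, 0]}\t{self.pairs[p, 1]}"
                            f"\t{int(self.h[t, p])}\t1\n"
                        )


def population_series(
    traj, criteria: HBCriteria = HBCriteria(), with_donors: bool = False
) -> PairPopulations:
    """Detect H-bonds on every frame and assemble (T, P) population arrays."""
    per_frame = []
    universe: dict[tuple[int, int], int] = {}
    T = traj.n_frames
    n_waters = len(traj.frames[0].waters)
    donors = np.zeros((T, 2 * n_waters), dtype=bool) if with_donors else None
    for t, f in enumerate(traj.frames):
        out = detect_hbonds(f, traj.cell, criteria, return_donors=with_donors)
        if with_donors:
            pairs, h, hd, don = out
            donors[t] = don.reshape(-1)
        else:
            pairs, h, hd = out
        for i, j in pairs:
            universe.setdefault((int(i), int(j)), len(universe))
        per_frame.append((pairs, h, hd))
    P = len(universe)
    H = np.zeros((T, P), dtype=bool)
    HD = np.zeros((T, P), dtype=bool)
    for t, (pairs, h, hd) in enumerate(per_frame):
        if len(pairs) == 0:
            continue
        cols = np.array([universe[(int(i), int(j))] for i, j in pairs])
        H[t, cols] = h
        HD[t, cols] = hd
    pair_arr = np.empty((P, 2), dtype=int)
    for (i, j), c in universe.items():
        pair_arr[c] = (i, j)
    return PairPopulations(
        pairs=pair_arr, h=H, hd=HD, times=traj.times, donor_oh=donors
    )
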