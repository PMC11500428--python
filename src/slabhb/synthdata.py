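"""Synthetic slab trajectories with known depth-dependent HB kinetics.

The generator emulates the statistical structure the interface-thickness
analysis measures, not water physics.  Disjoint donor-acceptor water pairs
sit on a lateral lattice whose pitch guarantees that no two molecules of
different pairs ever come within the O-O contact cutoff, so the geometric
detector sees exactly the generator's bookkeeping.  Each pair carries an
independent two-state telegraph H-bond process whose breaking/reforming
rates switch between interfacial values (within depth d0 of the nearer
surface) and bulk values (deeper): d0 is the constructed interface depth
the full pipeline must recover.  Pair geometries are snapped to canonical
configurations — bonded (R_OO = 2.8 A, donor H on the O-O axis),
unbonded-in-contact (R_OO = 3.2 A, donor H rotated past the angle cutoff)
or separated (R_OO = 4.5 A) — rather than integrated from forces.

Depths are stratified: the pair z coordinates form an exactly uniform grid
over the occupied slab, and the z-exchange process swaps the z values of
random pair couples, so molecules migrate between layers while the density
profile (hence the instantaneous surface) stays statistically static.

All randomness flows from the single seed in the spec; a fixed seed gives
byte-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import Frame, SimulationCell, Trajectory

__all__ = [
    "SyntheticSlabSpec",
    "SyntheticSlab",
    "generate_markov_slab",
    "telegraph_correlation_closed_form",
    "generate_flat_slab_frame",
    "generate_rotational_diffusion",
    "generate_three_state_pairs",
]

# canonical pair geometries (A, degrees)
R_BONDED = 2.8
R_CONTACT = 3.2
R_SEPARATED = 4.5
OH_LENGTH = 0.96
HOH_ANGLE = 104.5
UNBONDED_TILT = 60.0  # donor-H tilt off the O-O axis when unbonded

# lattice pitches guaranteeing cross-pair O-O > 3.5 A for any pair states
PITCH_X = 8.75
PITCH_Y = 4.25
MAX_LATERAL_JITTER = 0.3


@dataclass(frozen=True)
class SyntheticSlabSpec:
    """Study conditions for one synthetic slab.

    Rates are in ps^-1, lengths in A, times in ps.  The defaults define the
    reference conditions used throughout the test suite: a 576-water slab
    (288 pairs), interfacial HB breaking three times faster than bulk, a
    4 A interfacial band, and slow layer exchange (mean residence 50 ps,
    somewhat longer than the 40 ps LC sub-trajectory — molecules may leave
    the layer within a sub-trajectory but most do not, which is the premise
    of the sub-trajectory sampling scenario).
    """

    n_pairs: int = 288
    z0: float = 12.0  # occupied half-thickness; surfaces sit at +-z0
    d0: float = 4.0  # constructed interface depth
    kappa_i: float = 1.2  # interfacial breaking rate
    kappa_i_prime: float = 0.7  # interfacial reforming rate
    kappa_b: float = 0.4  # bulk breaking rate
    kappa_b_prime: float = 0.7  # bulk reforming rate
    exchange_rate: float = 0.02  # per-pair z-swap participation rate, ps^-1
    lateral_step: float = 0.05  # lateral random-walk step per frame
    p_contact: float = 0.8  # unbonded sojourn is in-contact with this prob.
    timestep: float = 0.1
    n_frames: int = 8000
    vacuum: float = 16.0  # z gap above + below the slab
    seed: int = 0

    def __post_init__(self):
        for name in (
            "kappa_i",
            "kappa_i_prime",
            "kappa_b",
            "kappa_b_prime",
            "exchange_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.d0 < self.z0):
            raise ValueError("need 0 < d0 < z0")
        if self.n_pairs < 4:
            raise ValueError("need at least 4 pairs")
        if self.timestep <= 0 or self.n_frames < 2:
            raise ValueError("invalid time grid")

    @property
    def lattice(self) -> tuple[int, int]:
        """(n_x, n_y) divisor pair of n_pairs closest to a square box."""
        best = None
        for nx in range(1, self.n_pairs + 1):
            if self.n_pairs % nx:
                continue
            ny = self.n_pairs // nx
            cost = abs(nx * PITCH_X - ny * PITCH_Y)
            if best is None or cost < best[0]:
                best = (cost, nx, ny)
        return best[1], best[2]

    @property
    def cell(self) -> SimulationCell:
        nx, ny = self.lattice
        return SimulationCell(
            lengths=np.array([nx * PITCH_X, ny * PITCH_Y, 2 * self.z0 + self.vacuum])
        )

    def to_toml(self, path) -> None:
        with open(path, "w") as fh:
            for key in self.__dataclass_fields__:
                val = getattr(self, key)
                fh.write(f"{key} = {val}\n")


@dataclass
class SyntheticSlab:
    """Generated trajectory plus the ground truth behind it."""

    trajectory: Trajectory
    spec: SyntheticSlabSpec
    h_true: np.ndarray  # (T, P) bonded state
    hd_true: np.ndarray  # (T, P) in-contact state (bonded or contact substate)
    depth_true: np.ndarray  # (T, P) pair depth below nearer surface
    pair_waters: np.ndarray  # (P, 2) water indices of each pair


def telegraph_correlation_closed_form(kappa: float, kappa_prime: float, t) -> np.ndarray:
    """c(t) = pi1 + (1 - pi1) exp(-(k + k') t), pi1 = k'/(k + k').

    The survival-style autocorrelation <h(0)h(t)>/<h> of a stationary
    two-state telegraph process with breaking rate kappa and reforming rate
    kappa_prime.
    """
    total = kappa + kappa_prime
    if total <= 0:
        raise ValueError("kappa + kappa_prime must be positive")
    pi1 = kappa_prime / total
    t = np.asarray(t, dtype=float)
    return pi1 + (1.0 - pi1) * np.exp(-total * t)


def _pair_axes_geometry():
    """Static H-direction unit vectors (in the xz plane) per pair state."""

    def dirvec(theta_deg):
        th = np.deg2rad(theta_deg)
        return np.array([np.cos(th), 0.0, np.sin(th)])

    donor_h = {
        # bonded: H1 on the O-O axis (angle 0), H2 at the HOH angle
        True: (dirvec(0.0), dirvec(HOH_ANGLE)),
        # unbonded: H1 tilted past the 30 deg cutoff
        False: (dirvec(UNBONDED_TILT), dirvec(UNBONDED_TILT + HOH_ANGLE)),
    }
    # acceptor hydrogens point away from the donor (angles to the O_a->O_d
    # direction, i.e. to -x, both exceed the angle cutoff)
    acceptor_h = (dirvec(20.0), dirvec(20.0 + HOH_ANGLE))
    return donor_h, acceptor_h


def generate_markov_slab(spec: SyntheticSlabSpec) -> SyntheticSlab:
    """Simulate the slab and synthesize its atomic trajectory."""
    rng = np.random.default_rng(spec.seed)
    P = spec.n_pairs
    T = spec.n_frames
    dt = spec.timestep
    cell = spec.cell
    nx, ny = spec.lattice
    Lz = cell.lengths[2]
    zmid = Lz / 2.0

    # lateral lattice sites
    ix, iy = np.divmod(np.arange(P), ny)
    site_xy = np.column_stack([(ix + 0.5) * PITCH_X, (iy + 0.5) * PITCH_Y])

    # stratified z: an exactly uniform grid over the occupied slab, shuffled
    z_slots = -spec.z0 + (np.arange(P) + 0.5) * (2 * spec.z0 / P)
    z = z_slots[rng.permutation(P)]

    def depth_of(zv):
        return spec.z0 - np.abs(zv)

    def rates_for(depth):
        interfacial = depth < spec.d0
        k = np.where(interfacial, spec.kappa_i, spec.kappa_b)
        kp = np.where(interfacial, spec.kappa_i_prime, spec.kappa_b_prime)
        return k, kp

    # initial HB states from the local equilibrium occupation
    k, kp = rates_for(depth_of(z))
    pi1 = kp / (k + kp)
    bonded = rng.random(P) < pi1
    contact_sub = rng.random(P) < spec.p_contact  # substate of unbonded sojourns

    jitter = np.zeros((P, 2))
    donor_h, acceptor_h = _pair_axes_geometry()

    n_swaps_per_frame = rng.poisson(0.5 * spec.exchange_rate * P * dt, size=T)

    h_true = np.empty((T, P), dtype=bool)
    hd_true = np.empty((T, P), dtype=bool)
    depth_true = np.empty((T, P))
    frames: list[Frame] = []

    symbols = (["O", "H", "H", "O", "H", "H"]) * P
    waters = []
    for p in range(P):
        base = 6 * p
        waters.append((base, base + 1, base + 2))
        waters.append((base + 3, base + 4, base + 5))
    pair_waters = np.arange(2 * P).reshape(P, 2)

    r_by_state = np.empty(P)
    for t_index in range(T):
        # record state, then build geometry for this frame
        h_true[t_index] = bonded
        hd_true[t_index] = bonded | contact_sub
        depth = depth_of(z)
        depth_true[t_index] = depth

        r_by_state[:] = np.where(
            bonded, R_BONDED, np.where(contact_sub, R_CONTACT, R_SEPARATED)
        )
        centers = np.column_stack(
            [site_xy[:, 0] + jitter[:, 0], site_xy[:, 1] + jitter[:, 1], zmid + z]
        )
        pos = np.empty((P, 6, 3))
        half = 0.5 * r_by_state
        pos[:, 0] = centers
        pos[:, 0, 0] -= half  # donor O
        pos[:, 3] = centers
        pos[:, 3, 0] += half  # acceptor O
        db = donor_h[True]
        du = donor_h[False]
        for hh in range(2):
            dirs = np.where(bonded[:, None], db[hh][None, :], du[hh][None, :])
            pos[:, 1 + hh] = pos[:, 0] + OH_LENGTH * dirs
            pos[:, 4 + hh] = pos[:, 3] + OH_LENGTH * acceptor_h[hh][None, :]
        frames.append(
            Frame(
                time=t_index * dt,
                symbols=symbols,
                positions=pos.reshape(-1, 3),
                waters=waters,
            )
        )

        if t_index == T - 1:
            break

        # --- advance the Markov state to the next frame ---
        k, kp = rates_for(depth)
        total = k + kp
        decay = np.exp(-total * dt)
        pi1 = kp / total
        p_bb = pi1 + (1 - pi1) * decay  # bonded -> bonded over dt
        p_ub = pi1 * (1 - decay)  # unbonded -> bonded
        u = rng.random(P)
        new_bonded = np.where(bonded, u < p_bb, u < p_ub)
        breaking = bonded & ~new_bonded
        # a fresh unbonded sojourn picks its geometry substate once
        new_sub = rng.random(P) < spec.p_contact
        contact_sub = np.where(breaking, new_sub, contact_sub)
        bonded = new_bonded

        # z exchange: swap the z values of random pair couples
        for _ in range(n_swaps_per_frame[t_index]):
            a, b = rng.choice(P, size=2, replace=False)
            z[a], z[b] = z[b], z[a]

        # bounded lateral random walk of the pair centers
        jitter += rng.normal(0.0, spec.lateral_step, size=(P, 2))
        np.clip(jitter, -MAX_LATERAL_JITTER, MAX_LATERAL_JITTER, out=jitter)

    traj = Trajectory(frames=frames, timestep=dt, cell=cell)
    return SyntheticSlab(
        trajectory=traj,
        spec=spec,
        h_true=h_true,
        hd_true=hd_true,
        depth_true=depth_true,
        pair_waters=pair_waters,
    )


def generate_flat_slab_frame(
    n_waters: int, cell: SimulationCell, z0: float, seed: int = 0
) -> Frame:
    """Uniform random waters in |z - Lz/2| < z0 with ideal rigid geometry.

    A fixture for surface construction: positions are independent uniforms
    (no excluded volume), orientations random.  Topology is attached
    directly, so overlapping oxygens cannot confuse H assignment.
    """
    rng = np.random.default_rng(seed)
    zmid = cell.lengths[2] / 2.0
    opos = np.column_stack(
        [
            rng.uniform(0, cell.lengths[0], n_waters),
            rng.uniform(0, cell.lengths[1], n_waters),
            rng.uniform(zmid - z0, zmid + z0, n_waters),
        ]
    )
    # random molecular orientations
    axis = rng.normal(size=(n_waters, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    helper = rng.normal(size=(n_waters, 3))
    perp = np.cross(axis, helper)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    half = np.deg2rad(HOH_ANGLE / 2.0)
    h1 = opos + OH_LENGTH * (np.cos(half) * axis + np.sin(half) * perp)
    h2 = opos + OH_LENGTH * (np.cos(half) * axis - np.sin(half) * perp)

    symbols = []
    positions = np.empty((3 * n_waters, 3))
    waters = []
    for i in range(n_waters):
        positions[3 * i] = opos[i]
        positions[3 * i + 1] = h1[i]
        positions[3 * i + 2] = h2[i]
        symbols += ["O", "H", "H"]
        waters.append((3 * i, 3 * i + 1, 3 * i + 2))
    return Frame(time=0.0, symbols=symbols, positions=positions, waters=waters)


def generate_rotational_diffusion(
    n_rotors: int, d_r: float, dt: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Unit vectors undergoing isotropic rotational diffusion.

    Small-step tangent-space Euler scheme; for d_r * dt << 1 the P2
    autocorrelation decays as exp(-6 d_r t).  Returns (n_frames, n, 3).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_rotors, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    out = np.empty((n_frames, n_rotors, 3))
    sigma = np.sqrt(2.0 * d_r * dt)
    for t in range(n_frames):
        out[t] = u
        xi = rng.normal(0.0, sigma, size=(n_rotors, 3))
        xi -= np.sum(xi * u, axis=1, keepdims=True) * u  # tangent projection
        u = u + xi
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return out


def generate_three_state_pairs(
    k12: float,
    k21: float,
    k23: float,
    k32: float,
    n_pairs: int,
    dt: float,
    n_frames: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bonded <-> contact <-> separated chains; returns (h, hd) arrays.

    State 0 is bonded (h = hd = 1), state 1 unbonded-in-contact (hd = 1),
    state 2 separated.  Transitions use the exact matrix-exponential
    single-step probabilities, so the sampled chain is the continuous-time
    process observed on the frame grid.
    """
    from scipy.linalg import expm

    Q = np.array(
        [
            [-k12, k12, 0.0],
            [k21, -(k21 + k23), k23],
            [0.0, k32, -k32],
        ]
    )
    P1 = expm(Q * dt)
    rng = np.random.default_rng(seed)
    if k23 == 0.0 and k32 == 0.0:
        # separated state decoupled: stationary support is {bonded, contact}
        pi = np.array([k21, k12, 0.0]) / (k12 + k21)
    else:
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
    state = rng.choice(3, size=n_pairs, p=pi)
    cum = np.cumsum(P1, axis=1)
    h = np.empty((n_frames, n_pairs), dtype=bool)
    hd = np.empty((n_frames, n_pairs), dtype=bool)
    for t in range(n_frames):
        h[t] = state == 0
        hd[t] = state <= 1
        u = rng.random(n_pairs)
        state = (u[:, None] > cum[state]).sum(axis=1)
    return h, hd
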