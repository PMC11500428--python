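"""Slab-trajectory I/O and water topology.

Trajectories are plain XYZ or extended-XYZ files of a water slab in an
orthorhombic box.  The slab normal is the z axis: x and y are periodic,
z carries the vacuum gap and is treated as non-periodic for all depth
logic even when the file declares a fully periodic cell.

Units throughout the package: Angstrom and picosecond.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SimulationCell",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "read_trajectory",
    "write_trajectory",
    "assign_water_topology",
    "minimum_image_displacement",
]

#: Covalent O-H assignment cutoff (A).  Well above the 0.96 A equilibrium
#: bond length and below any H...O hydrogen-bond distance, so assignment is
#: robust for DFT-quality geometries.
DEFAULT_OH_CUTOFF = 1.2


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory input."""


@dataclass(frozen=True)
class SimulationCell:
    """Orthorhombic cell with the slab normal fixed to z."""

    lengths: np.ndarray  # (3,) A
    periodic: tuple[bool, bool, bool] = (True, True, False)
    normal_axis: int = 2

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        if lengths.shape != (3,) or not np.all(lengths > 0):
            raise TrajectoryError(f"cell lengths must be 3 positive values, got {lengths}")
        if not (self.periodic[0] and self.periodic[1]):
            raise TrajectoryError("x and y must be periodic for a slab geometry")
        if self.normal_axis != 2:
            raise TrajectoryError("slab normal must be the z axis")


@dataclass
class Frame:
    """One snapshot: element labels, positions, and water topology."""

    time: float  # ps
    symbols: list[str]
    positions: np.ndarray  # (n_atoms, 3) A
    waters: list[tuple[int, int, int]] = field(default_factory=list)  # (O, H, H)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def oxygen_indices(self) -> np.ndarray:
        return np.array([w[0] for w in self.waters], dtype=int)

    def validate(self) -> None:
        if self.positions.shape != (self.n_atoms, 3):
            raise TrajectoryError(
                f"positions shape {self.positions.shape} does not match {self.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("non-finite positions")
        seen_h: set[int] = set()
        for o, h1, h2 in self.waters:
            if self.symbols[o] != "O" or self.symbols[h1] != "H" or self.symbols[h2] != "H":
                raise TrajectoryError(f"water ({o},{h1},{h2}) has wrong element labels")
            if h1 in seen_h or h2 in seen_h or h1 == h2:
                raise TrajectoryError("a hydrogen belongs to more than one water")
            seen_h.update((h1, h2))


@dataclass
class Trajectory:
    """Ordered frames with a uniform timestep on a fixed cell."""

    frames: list[Frame]
    timestep: float  # ps
    cell: SimulationCell

    def __post_init__(self):
        if not self.frames:
            raise TrajectoryError("empty trajectory")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                bad = int(np.argmax(dts <= 0))
                raise TrajectoryError(f"times not strictly increasing at frame {bad + 1}")
            if not np.allclose(dts, self.timestep, rtol=1e-6, atol=1e-9):
                bad = int(np.argmax(~np.isclose(dts, self.timestep, rtol=1e-6, atol=1e-9)))
                raise TrajectoryError(f"non-uniform timestep at frame {bad + 1}")
        n0 = self.frames[0].n_atoms
        s0 = self.frames[0].symbols
        for i, f in enumerate(self.frames):
            if f.n_atoms != n0 or f.symbols != s0:
                raise TrajectoryError(f"frame {i} changes atom count or ordering")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def minimum_image_displacement(a, b, cell: SimulationCell) -> np.ndarray:
    """Displacement b - a under the minimum-image convention.

    Periodic components are wrapped into [-L/2, L/2); non-periodic axes are
    returned untouched.  Broadcasts over leading dimensions.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    out = np.array(d, copy=True)
    for ax in range(3):
        if cell.periodic[ax]:
            L = cell.lengths[ax]
            out[..., ax] -= L * np.floor(out[..., ax] / L + 0.5)
    return out


def assign_water_topology(
    frame: Frame, cell: SimulationCell, oh_cutoff: float = DEFAULT_OH_CUTOFF
) -> list[tuple[int, int, int]]:
    """Assign each H to its nearest O under minimum image.

    Returns the water list as (O index, H index, H index) tuples, sorted by
    O index, so the result is independent of atom ordering in the file.
    Raises if any O does not end up with exactly two hydrogens within
    ``oh_cutoff``.
    """
    symbols = np.asarray(frame.symbols)
    o_idx = np.flatnonzero(symbols == "O")
    h_idx = np.flatnonzero(symbols == "H")
    if len(o_idx) + len(h_idx) != frame.n_atoms:
        bad = sorted(set(frame.symbols) - {"O", "H"})
        raise TrajectoryError(f"only O and H are supported, found {bad}")
    if len(h_idx) != 2 * len(o_idx):
        raise TrajectoryError(
            f"need 2 H per O, got {len(o_idx)} O and {len(h_idx)} H"
        )
    opos = frame.positions[o_idx]  # (nO, 3)
    hpos = frame.positions[h_idx]  # (nH, 3)
    # (nH, nO) minimum-image distances
    disp = minimum_image_displacement(opos[None, :, :], hpos[:, None, :], cell)
    dist = np.linalg.norm(disp, axis=-1)
    owner = np.argmin(dist, axis=1)
    owner_dist = dist[np.arange(len(h_idx)), owner]

    buckets: dict[int, list[int]] = {int(o): [] for o in o_idx}
    for hi, (oo, dd) in enumerate(zip(owner, owner_dist)):
        if dd <= oh_cutoff:
            buckets[int(o_idx[oo])].append(int(h_idx[hi]))
    offenders = [o for o, hs in buckets.items() if len(hs) != 2]
    if offenders:
        raise TrajectoryError(
            f"oxygens without exactly two H within {oh_cutoff} A: {offenders}"
        )
    return [(o, hs[0], hs[1]) for o, hs in sorted(buckets.items())]


# ---------------------------------------------------------------------------
# extended-XYZ parsing

_KEYVAL_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> dict:
    out = {}
    for m in _KEYVAL_RE.finditer(comment):
        key = m.group(1)
        out[key.lower()] = m.group(2) if m.group(2) is not None else m.group(3)
    return out


def _cell_from_lattice(lattice: str) -> SimulationCell:
    vals = np.array([float(x) for x in lattice.split()])
    if vals.size != 9:
        raise TrajectoryError(f"Lattice must have 9 numbers, got {vals.size}")
    mat = vals.reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if not np.allclose(off, 0.0, atol=1e-8):
        raise TrajectoryError("only orthorhombic (diagonal Lattice) cells are supported")
    return SimulationCell(lengths=np.diag(mat).copy())


def read_trajectory(
    path,
    format: str = "extxyz",
    cell: SimulationCell | None = None,
    timestep: float | None = None,
    oh_cutoff: float = DEFAULT_OH_CUTOFF,
    assign_topology: bool = True,
) -> Trajectory:
    """Read an (ext)XYZ trajectory and validate slab invariants.

    For plain ``xyz`` files the cell and timestep must be supplied by the
    caller (the CLI reads them from a TOML sidecar).  For ``extxyz`` they are
    taken from the ``Lattice=`` and ``Time=`` comment keys; an explicit
    ``cell``/``timestep`` argument overrides the header.
    """
    if format not in ("xyz", "extxyz"):
        raise TrajectoryError(f"unknown format {format!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    nframe = 0
    file_cell = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryError(
                f"frame {nframe}: expected atom count, got {lines[i]!r}"
            ) from None
        if i + 2 + natoms > len(lines):
            raise TrajectoryError(
                f"frame {nframe} declares {natoms} atoms but the file ends early"
            )
        comment = lines[i + 1]
        meta = _parse_comment(comment) if format == "extxyz" else {}
        symbols: list[str] = []
        pos = np.empty((natoms, 3))
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise TrajectoryError(
                    f"frame {nframe}: atom line {j} malformed: {lines[i + 2 + j]!r}"
                )
            symbols.append(parts[0])
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        t = float(meta["time"]) if "time" in meta else float(nframe)
        if "lattice" in meta and file_cell is None:
            file_cell = _cell_from_lattice(meta["lattice"])
        frames.append(Frame(time=t, symbols=symbols, positions=pos))
        i += 2 + natoms
        nframe += 1

    use_cell = cell if cell is not None else file_cell
    if use_cell is None:
        raise TrajectoryError(
            "no cell: supply one explicitly or use extxyz with a Lattice= key"
        )
    if timestep is None:
        if len(frames) < 2:
            timestep = 1.0
        else:
            timestep = frames[1].time - frames[0].time
    if assign_topology:
        waters0 = assign_water_topology(frames[0], use_cell, oh_cutoff)
        for f in frames:
            f.waters = waters0  # constant ordering across frames is validated
            f.validate()
    traj = Trajectory(frames=frames, timestep=float(timestep), cell=use_cell)
    return traj


def write_trajectory(traj: Trajectory, path) -> None:
    """Write extended-XYZ with Lattice=, Properties= and Time= keys."""
    L = traj.cell.lengths
    lattice = f"{L[0]:.8f} 0.0 0.0 0.0 {L[1]:.8f} 0.0 0.0 0.0 {L[2]:.8f}"
    pbc = " ".join("T" if p else "F" for p in traj.cell.periodic)
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{f.n_atoms}\n")
            fh.write(
                f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
                f'Time={f.time:.6f} pbc="{pbc}"\n'
            )
            for s, p in zip(f.symbols, f.positions):
                fh.write(f"{s} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
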