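"""Coarse-grained density, surface extraction and depth assignment."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator
from scipy.special import ndtr

from slabhb.synthdata import generate_flat_slab_frame
from slabhb.trajio import Frame, SimulationCell
from slabhb.wcsurface import (
    KERNEL_CUTOFF_SIGMAS,
    DensityField,
    InstantaneousSurface,
    SurfaceError,
    bulk_density,
    coarse_grained_density,
    deposited_density,
    extract_flat_surface,
    extract_instantaneous_surface,
    interface_members,
    molecule_depths,
)


def one_oxygen_frame(pos):
    pos = np.asarray(pos, float)
    positions = np.vstack([pos, pos + [0.96, 0, 0], pos + [-0.24, 0, 0.93]])
    return Frame(
        time=0.0, symbols=["O", "H", "H"], positions=positions, waters=[(0, 1, 2)]
    )


class TestDensity:
    def test_kernel_normalization_at_node(self):
        cell = SimulationCell(lengths=np.array([20.0, 20.0, 40.0]))
        xi = 2.4
        f = one_oxygen_frame([10.0, 10.0, 20.0])  # a grid node for spacing 1.0
        field = coarse_grained_density(f, cell, xi=xi, grid_spacing=1.0)
        expected = (2 * np.pi * xi * xi) ** -1.5
        assert field.values[10, 10, 20] == pytest.approx(expected, rel=1e-12)

    def test_grid_integral_counts_atoms(self):
        cell = SimulationCell(lengths=np.array([16.0, 16.0, 36.0]))
        frame = generate_flat_slab_frame(40, cell, z0=8.0, seed=1)
        field = coarse_grained_density(frame, cell, xi=2.4, grid_spacing=0.8)
        total = field.values.sum() * np.prod(field.spacing)
        assert total == pytest.approx(40.0, rel=1e-3)

    def test_matches_brute_force_kernel_sum(self):
        rng = np.random.default_rng(7)
        cell = SimulationCell(lengths=np.array([12.0, 12.0, 24.0]))
        xi = 2.0
        opos = np.column_stack(
            [rng.uniform(0, 12, 10), rng.uniform(0, 12, 10), rng.uniform(6, 18, 10)]
        )
        frame = Frame(time=0.0, symbols=["O"] * 10, positions=opos,
                      waters=[(i, i, i) for i in range(10)])
        field = coarse_grained_density(frame, cell, xi=xi, grid_spacing=1.0,
                                       positions=opos)
        norm = (2 * np.pi * xi * xi) ** -1.5
        cut = KERNEL_CUTOFF_SIGMAS * xi
        nodes = np.column_stack(
            [rng.integers(0, s, 20) for s in field.values.shape]
        )
        for ix, iy, iz in nodes:
            node = np.array([ix, iy, iz]) * field.spacing
            total = 0.0
            for p in opos:
                for sx in range(-1, 2):
                    for sy in range(-1, 2):
                        img = p + np.array([12.0 * sx, 12.0 * sy, 0.0])
                        r2 = np.sum((node - img) ** 2)
                        if r2 <= cut * cut:
                            total += norm * np.exp(-r2 / (2 * xi * xi))
            assert field.values[ix, iy, iz] == pytest.approx(total, abs=1e-12)

    def test_empty_frame_is_error(self):
        cell = SimulationCell(lengths=np.array([10.0, 10.0, 10.0]))
        f = Frame(time=0.0, symbols=[], positions=np.empty((0, 3)), waters=[])
        with pytest.raises(SurfaceError):
            coarse_grained_density(f, cell)

    def test_deposited_matches_exact_within_grid_error(self):
        """The CIC + convolution estimator agrees with the exact kernel sum
        to the expected O((h/xi)^2) level."""
        cell = SimulationCell(lengths=np.array([16.0, 16.0, 32.0]))
        frame = generate_flat_slab_frame(60, cell, z0=8.0, seed=3)
        opos = frame.positions[frame.oxygen_indices()]
        exact = coarse_grained_density(frame, cell, xi=3.0, grid_spacing=1.0)
        fast = deposited_density(opos, cell, xi=3.0, grid_spacing=1.0)
        scale = exact.values.max()
        assert np.max(np.abs(fast.values - exact.values)) / scale < 0.05


def analytic_smoothed_step_field(cell, z0, xi, grid_spacing, rho0=0.03):
    """Gaussian-smoothed slab density rho0 * 1{|z - zmid| < z0}."""
    shape = np.maximum(2, np.round(cell.lengths / grid_spacing).astype(int))
    spacing = cell.lengths / shape
    z = np.arange(shape[2]) * spacing[2]
    zmid = cell.lengths[2] / 2
    prof = rho0 * (ndtr((z0 - (z - zmid)) / xi) - ndtr((-z0 - (z - zmid)) / xi))
    vals = np.broadcast_to(prof, tuple(shape)).copy()
    return DensityField(values=vals, spacing=spacing, xi=xi, cell=cell)


class TestSurface:
    cell = SimulationCell(lengths=np.array([10.0, 10.0, 40.0]))

    def test_smoothed_step_sheets_at_plus_minus_z0(self):
        z0 = 8.0
        field = analytic_smoothed_step_field(self.cell, z0, xi=2.4, grid_spacing=0.5)
        surf = extract_instantaneous_surface(field, isovalue=0.015)
        zmid = 20.0
        assert np.all(np.abs(surf.z_upper - (zmid + z0)) < 0.25)
        assert np.all(np.abs(surf.z_lower - (zmid - z0)) < 0.25)

    def test_isovalue_above_max_is_error(self):
        field = analytic_smoothed_step_field(self.cell, 8.0, 2.4, 1.0)
        with pytest.raises(SurfaceError):
            extract_instantaneous_surface(field, isovalue=1.0)

    def test_refinement_convergence(self):
        z0 = 7.3  # off-grid so interpolation matters
        h1 = extract_instantaneous_surface(
            analytic_smoothed_step_field(self.cell, z0, 2.4, 1.0), 0.015
        ).z_upper[0, 0]
        h2 = extract_instantaneous_surface(
            analytic_smoothed_step_field(self.cell, z0, 2.4, 0.5), 0.015
        ).z_upper[0, 0]
        assert abs(h2 - (20 + z0)) < abs(h1 - (20 + z0)) + 1e-9
        assert abs(h2 - (20 + z0)) < 1.0

    def test_torn_column_is_reported(self):
        field = analytic_smoothed_step_field(self.cell, 8.0, 2.4, 1.0)
        field.values[3, 4, :] = 0.0
        with pytest.raises(SurfaceError, match=r"\(3,4\)"):
            extract_instantaneous_surface(field, 0.015)

    def test_flat_slab_recovers_construction_plane(self):
        cell = SimulationCell(lengths=np.array([30.0, 30.0, 40.0]))
        frame = generate_flat_slab_frame(2000, cell, z0=10.0, seed=4)
        field = coarse_grained_density(frame, cell, xi=2.4, grid_spacing=1.0)
        iso = 0.5 * bulk_density(field)
        surf = extract_instantaneous_surface(field, iso)
        assert abs(surf.z_upper.mean() - 30.0) < 0.5
        assert abs(surf.z_lower.mean() - 10.0) < 0.5

    def test_mirror_symmetric_field_gives_mirror_sheets(self):
        field = analytic_smoothed_step_field(self.cell, 6.0, 2.4, 1.0)
        # field is exactly symmetric about zmid by construction
        surf = extract_instantaneous_surface(field, 0.015)
        np.testing.assert_allclose(
            surf.z_upper - 20.0, 20.0 - surf.z_lower, atol=1e-9
        )

    def test_flat_surface_mode_matches_heightfield_mean(self):
        cell = SimulationCell(lengths=np.array([30.0, 30.0, 40.0]))
        frame = generate_flat_slab_frame(2000, cell, z0=10.0, seed=4)
        field = coarse_grained_density(frame, cell, xi=2.4, grid_spacing=1.0)
        iso = 0.5 * bulk_density(field)
        hf = extract_instantaneous_surface(field, iso)
        fl = extract_flat_surface(field, iso)
        assert abs(fl.z_upper[0, 0] - hf.z_upper.mean()) < 0.5
        assert abs(fl.z_lower[0, 0] - hf.z_lower.mean()) < 0.5


class TestDepths:
    def _flat_surface(self, up, lo, cell):
        nx, ny = 4, 4
        return InstantaneousSurface(
            time=0.0,
            x=np.arange(nx) * cell.lengths[0] / nx,
            y=np.arange(ny) * cell.lengths[1] / ny,
            z_upper=np.full((nx, ny), up),
            z_lower=np.full((nx, ny), lo),
            isovalue=0.015,
            cell=cell,
        )

    def test_depth_from_nearer_sheet(self, cube_cell):
        surf = self._flat_surface(25.0, 5.0, cube_cell)
        f = one_oxygen_frame([3.0, 3.0, 22.0])
        m = molecule_depths(f, surf)
        assert m.depths[0] == pytest.approx(3.0)

    def test_negative_depth_above_surface(self, cube_cell):
        surf = self._flat_surface(25.0, 5.0, cube_cell)
        f = one_oxygen_frame([3.0, 3.0, 26.0])
        assert molecule_depths(f, surf).depths[0] == pytest.approx(-1.0)

    def test_sinusoidal_heightfield_oracle(self):
        cell = SimulationCell(lengths=np.array([20.0, 20.0, 60.0]))
        nx = ny = 20
        x = np.arange(nx) * 1.0
        y = np.arange(ny) * 1.0
        up = 45.0 + 1.5 * np.sin(2 * np.pi * x[:, None] / 20) * np.cos(
            2 * np.pi * y[None, :] / 20
        )
        lo = np.broadcast_to(
            15.0 + 1.0 * np.cos(2 * np.pi * x[:, None] / 20), (nx, ny)
        ).copy()
        surf = InstantaneousSurface(
            time=0.0, x=x, y=y, z_upper=up, z_lower=lo, isovalue=0.015, cell=cell
        )
        rng = np.random.default_rng(9)
        pts = np.column_stack(
            [rng.uniform(0, 20, 50), rng.uniform(0, 20, 50), rng.uniform(20, 40, 50)]
        )
        frame = Frame(
            time=0.0,
            symbols=["O"] * 50,
            positions=pts,
            waters=[(i, i, i) for i in range(50)],
        )
        got = molecule_depths(frame, surf).depths
        # independent bilinear interpolation with periodic padding
        xg = np.append(x, 20.0)
        yg = np.append(y, 20.0)
        up_p = np.pad(up, ((0, 1), (0, 1)), mode="wrap")
        lo_p = np.pad(lo, ((0, 1), (0, 1)), mode="wrap")
        iup = RegularGridInterpolator((xg, yg), up_p)
        ilo = RegularGridInterpolator((xg, yg), lo_p)
        exp = np.minimum(
            iup(pts[:, :2]) - pts[:, 2], pts[:, 2] - ilo(pts[:, :2])
        )
        np.testing.assert_allclose(got, exp, atol=1e-9)


class TestMembership:
    def test_zero_thickness_is_empty(self):
        depths = np.array([0.5, 3.0, -1.0, 7.0])
        assert not interface_members(depths, 0.0).any()

    def test_nesting_monotone_in_d(self, small_slab):
        rng = np.random.default_rng(2)
        depths = rng.uniform(-2, 12, size=200)
        prev = np.zeros(200, dtype=bool)
        for d in np.arange(0.0, 12.0, 0.5):
            cur = interface_members(depths, d)
            assert np.all(prev <= cur)
            prev = cur

    def test_full_depth_covers_slab(self):
        depths = np.array([0.0, 1.0, 5.0, 11.9])
        assert interface_members(depths, 12.0).all()
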