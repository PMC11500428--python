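"""Shared fixtures: synthetic slabs at the reference study conditions.

The heavy end-to-end fixtures are session-scoped so the bracketing,
monotonicity and thickness-recovery tests share one analysis per
constructed interface depth.
"""

import numpy as np
import pytest

from slabhb.pipeline import AnalysisConfig, SlabAnalysis
from slabhb.synthdata import SyntheticSlabSpec, generate_markov_slab
from slabhb.trajio import SimulationCell


def study_config() -> AnalysisConfig:
    """Analysis configuration matched to the synthetic slab.

    The synthetic slab is ~15x sparser than liquid water (isolated pair
    lattice), so the coarse-graining width is widened to 4 A with a 2 A
    grid; its interface is flat by construction (stratified z, no capillary
    waves), so the laterally averaged surface mode is appropriate.
    """
    return AnalysisConfig(xi=4.0, grid_spacing=2.0, surface_mode="flat")


@pytest.fixture(scope="session")
def slab_d4():
    """Reference slab: d0 = 4 A, default study conditions."""
    return generate_markov_slab(SyntheticSlabSpec(d0=4.0, seed=11))


@pytest.fixture(scope="session")
def analysis_d4(slab_d4):
    return SlabAnalysis(slab_d4.trajectory, study_config())


@pytest.fixture(scope="session")
def analyses_by_d0(slab_d4, analysis_d4):
    """SlabAnalysis per constructed depth d0 in {3, 4, 5} A."""
    out = {4.0: analysis_d4}
    for d0, seed in [(3.0, 21), (5.0, 22)]:
        slab = generate_markov_slab(SyntheticSlabSpec(d0=d0, seed=seed))
        out[d0] = SlabAnalysis(slab.trajectory, study_config())
    return out


@pytest.fixture
def small_slab():
    """A light slab for invariant checks (not statistics)."""
    return generate_markov_slab(
        SyntheticSlabSpec(n_pairs=24, n_frames=200, seed=5)
    )


@pytest.fixture
def cube_cell():
    return SimulationCell(lengths=np.array([12.0, 12.0, 30.0]))
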