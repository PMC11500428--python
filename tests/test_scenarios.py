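"""Scenario 1 (LC sub-trajectory sampling) and Scenario 2 (IHB gating)."""

import numpy as np
import pytest

from slabhb.hbond import PairPopulations
from slabhb.scenarios import (
    Scenario1Config,
    sample_scenario1_molecules,
    scenario1_correlations,
    scenario2_correlations,
)
from slabhb.tcf import EmptyPopulationError, population_autocorrelation


def make_pops(h, hd, pairs, dt=0.1):
    T = h.shape[0]
    return PairPopulations(
        pairs=np.asarray(pairs),
        h=np.asarray(h, bool),
        hd=np.asarray(hd, bool),
        times=np.arange(T) * dt,
    )


class TestSampling:
    def test_single_moment_membership_enters_union(self):
        member = np.zeros((10, 3), dtype=bool)
        member[5, 1] = True  # interfacial at one sampling moment only
        cfg = Scenario1Config(d=2.0, t_traj=1.0, n_sampling=10)
        windows = sample_scenario1_molecules(member, dt=0.1, cfg=cfg)
        assert len(windows) == 1
        assert 1 in windows[0][1]

    def test_never_member_excluded(self):
        rng = np.random.default_rng(0)
        member = rng.random((20, 5)) < 0.5
        member[:, 3] = False
        cfg = Scenario1Config(d=2.0, t_traj=2.0, n_sampling=5)
        for _, mols in sample_scenario1_molecules(member, 0.1, cfg):
            assert 3 not in mols

    def test_union_matches_brute_force(self):
        rng = np.random.default_rng(3)
        member = rng.random((40, 8)) < 0.3
        cfg = Scenario1Config(d=1.0, t_traj=2.0, n_sampling=4)
        windows = sample_scenario1_molecules(member, 0.1, cfg)
        w = 20
        for widx, (sl, mols) in enumerate(windows):
            start = widx * w
            moments = start + np.round(np.linspace(0, w - 1, 4)).astype(int)
            expected = set()
            for m in moments:
                expected |= set(np.flatnonzero(member[m]))
            assert set(mols.tolist()) == expected

    def test_trajectory_shorter_than_window_is_error(self):
        member = np.zeros((5, 2), dtype=bool)
        cfg = Scenario1Config(d=1.0, t_traj=10.0)
        with pytest.raises(ValueError, match="t_traj"):
            sample_scenario1_molecules(member, 0.1, cfg)

    def test_partial_trailing_window_discarded(self):
        member = np.ones((25, 2), dtype=bool)
        cfg = Scenario1Config(d=1.0, t_traj=1.0, n_sampling=2)
        windows = sample_scenario1_molecules(member, 0.1, cfg)
        assert len(windows) == 2  # 25 frames, 10-frame windows, 5 discarded


class TestScenario1:
    def test_full_membership_equals_ungated_lc(self):
        rng = np.random.default_rng(5)
        h = rng.random((40, 6)) < 0.6
        hd = h | (rng.random((40, 6)) < 0.2)
        pairs = np.array([[0, 1], [1, 2], [2, 3], [3, 4], [4, 5], [0, 5]])
        pops = make_pops(h, hd, pairs)
        member = np.ones((40, 6), dtype=bool)
        cfg = Scenario1Config(d=99.0, t_traj=4.0, n_sampling=4)
        res = scenario1_correlations(pops, member, cfg, dt=0.1, max_lag=39)
        # single 40-frame window covering everything == plain correlation
        ref = population_autocorrelation(h, 0.1, max_lag=39)
        np.testing.assert_allclose(res.c, ref.c, atol=1e-12)

    def test_window_average_matches_brute_force_two_window_toy(self):
        """Origin-count-weighted window averaging equals a direct
        enumeration with the same pair-restriction rule."""
        rng = np.random.default_rng(8)
        T, N = 20, 4
        h = rng.random((T, 6)) < 0.5
        hd = np.ones_like(h)
        pairs = np.array([[0, 1], [0, 2], [1, 2], [2, 3], [1, 3], [0, 3]])
        member = rng.random((T, N)) < 0.5
        cfg = Scenario1Config(d=1.0, t_traj=1.0, n_sampling=3)
        pops = make_pops(h, hd, pairs)
        res = scenario1_correlations(pops, member, cfg, dt=0.1, max_lag=9)

        w = 10
        num = np.zeros(10)
        den = np.zeros(10)
        for start in (0, 10):
            moments = start + np.round(np.linspace(0, 9, 3)).astype(int)
            union = set()
            for m in moments:
                union |= set(np.flatnonzero(member[m]))
            cols = [
                k for k, (a, b) in enumerate(pairs) if a in union and b in union
            ]
            for lag in range(10):
                for t0 in range(start, start + w - lag):
                    for k in cols:
                        num[lag] += h[t0, k] * h[t0 + lag, k]
                        den[lag] += h[t0, k]
        np.testing.assert_allclose(res.c, num / den, atol=1e-12)

    def test_no_interfacial_molecule_anywhere_is_error(self):
        h = np.ones((20, 1), dtype=bool)
        pops = make_pops(h, h, [[0, 1]])
        member = np.zeros((20, 2), dtype=bool)
        cfg = Scenario1Config(d=0.5, t_traj=1.0, n_sampling=2)
        with pytest.raises(EmptyPopulationError):
            scenario1_correlations(pops, member, cfg, dt=0.1)


class TestScenario2:
    def test_partner_exit_interrupts_population(self):
        """A pair bonded throughout whose partner leaves the layer at t1
        loses h^(s) from t1 on, lowering c^(s)."""
        T = 10
        h = np.ones((T, 1), dtype=bool)
        pops = make_pops(h, h, [[0, 1]])
        member = np.ones((T, 2), dtype=bool)
        member[6:, 1] = False
        res = scenario2_correlations(pops, member, d=2.0, dt=0.1, max_lag=9)
        full = scenario2_correlations(
            pops, np.ones((T, 2), bool), d=2.0, dt=0.1, max_lag=9
        )
        assert res.c[0] == 1.0
        assert np.all(res.c[1:] < full.c[1:])

    def test_full_depth_equals_ungated_lc(self, small_slab):
        from slabhb.hbond import population_series

        pops = population_series(small_slab.trajectory)
        T = small_slab.trajectory.n_frames
        member = np.ones((T, 2 * small_slab.spec.n_pairs), dtype=bool)
        res = scenario2_correlations(pops, member, d=99.0, dt=0.1, max_lag=50)
        ref = population_autocorrelation(pops.h, 0.1, max_lag=50)
        np.testing.assert_allclose(res.c, ref.c, atol=1e-12)

    def test_eight_molecule_enumeration_oracle(self):
        """c^(s), n^(s) on a handcrafted 8-molecule population equal an
        exhaustive loop over origins and pairs."""
        rng = np.random.default_rng(11)
        T, N = 30, 8
        pairs = np.array([[i, j] for i in range(N) for j in range(i + 1, N)])
        h = rng.random((T, len(pairs))) < 0.3
        hd = h | (rng.random((T, len(pairs))) < 0.2)
        member = rng.random((T, N)) < 0.7
        pops = make_pops(h, hd, pairs)
        res = scenario2_correlations(pops, member, d=3.0, dt=0.1, max_lag=12)

        both = member[:, pairs[:, 0]] & member[:, pairs[:, 1]]
        hs = h & both
        hds = hd & both
        c_exp = np.zeros(13)
        n_exp = np.zeros(13)
        for lag in range(13):
            num_c = num_n = den = 0.0
            for t0 in range(T - lag):
                num_c += float(np.sum(hs[t0] & hs[t0 + lag]))
                num_n += float(np.sum(hs[t0] & ~hs[t0 + lag] & hds[t0 + lag]))
                den += float(np.sum(hs[t0]))
            c_exp[lag] = num_c / den
            n_exp[lag] = num_n / den
        np.testing.assert_allclose(res.c, c_exp, atol=1e-12)
        np.testing.assert_allclose(res.n, n_exp, atol=1e-12)

    def test_no_interfacial_bonded_pair_is_error(self):
        h = np.ones((10, 1), dtype=bool)
        pops = make_pops(h, h, [[0, 1]])
        member = np.zeros((10, 2), dtype=bool)
        with pytest.raises(EmptyPopulationError):
            scenario2_correlations(pops, member, d=1.0, dt=0.1)


def test_scenario1_decays_slower_than_scenario2(analysis_d4):
    """With slower bulk kinetics beneath the layer, the LC route's c(t)
    sits above the IHB route's c^(s)(t) at the same depth."""
    d = 2.0
    member = (analysis_d4.depths >= 0) & (analysis_d4.depths <= d)
    lc = analysis_d4.lc_correlation(member, d)
    ihb = analysis_d4.ihb_correlation(member, d)
    sel = lc.lags >= 0.5
    assert np.all(lc.c[sel] > ihb.c[sel])
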