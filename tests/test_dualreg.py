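"""Dual regression: both stages against a normal-equations oracle, rank
checks, normalization contracts, and planted-amplitude linearity."""

import numpy as np
import pytest

from rsnpipe.dualreg import (
    RankDeficiencyError,
    stage1_timecourses,
    stage2_maps,
    run_dual_regression,
)
from rsnpipe.groupica import SpatialMapSet
from rsnpipe.simdata import SimConfig, SimTruth, synthesize_subject
from conftest import make_run, full_mask, ols_oracle


def mapset_from(maps):
    maps = np.atleast_2d(np.asarray(maps, float))
    return SpatialMapSet(maps=maps, mask_ref=full_mask((maps.shape[1], 1, 1)),
                         k=maps.shape[0], seed=0)


def run_from_matrix(x):
    """(T, V) matrix as a BoldRun on a (V, 1, 1) grid."""
    t, v = x.shape
    return make_run(x.T.reshape(v, 1, 1, t))


class TestStage1:
    def test_exact_single_source_model(self, rng):
        m = rng.standard_normal(40)
        s = rng.standard_normal(12)
        run = run_from_matrix(np.outer(s, m))
        tc = stage1_timecourses(run, mapset_from(m), full_mask((40, 1, 1)))
        assert abs(np.corrcoef(tc[:, 0], s)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_toy_matches_normal_equations_oracle(self, rng):
        maps = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]]).T  # (2,4)
        y = rng.standard_normal((3, 4))  # 3 timepoints, 4 voxels
        run = run_from_matrix(y)
        tc = stage1_timecourses(run, mapset_from(maps), full_mask((4, 1, 1)))
        gc = maps.T - maps.T.mean(axis=0)
        yc = (y - y.mean(axis=1, keepdims=True)).T  # voxels x timepoints
        expected = ols_oracle(gc, yc).T  # oracle adds its own intercept
        np.testing.assert_allclose(tc, expected, atol=1e-10)

    def test_duplicate_maps_rejected(self, rng):
        m = rng.standard_normal(20)
        with pytest.raises(RankDeficiencyError):
            stage1_timecourses(
                run_from_matrix(rng.standard_normal((6, 20))),
                mapset_from([m, m]), full_mask((20, 1, 1)),
            )

    def test_empty_retained_set_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            stage1_timecourses(
                run_from_matrix(rng.standard_normal((6, 20))),
                mapset_from(np.empty((0, 20))), full_mask((20, 1, 1)),
            )


class TestStage2:
    def test_noiseless_pe_proportional_to_map(self, rng):
        m = rng.standard_normal(30)
        s = rng.standard_normal(15)
        run = run_from_matrix(np.outer(s, m))
        pe, z = stage2_maps(run, s[:, None], full_mask((30, 1, 1)))
        assert abs(np.corrcoef(pe[0], m)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_toy_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal((9, 4))
        tc = rng.standard_normal((9, 2))
        pe, _ = stage2_maps(run_from_matrix(y), tc, full_mask((4, 1, 1)),
                            normalize=False)
        expected = ols_oracle(tc, y)
        np.testing.assert_allclose(pe, expected, atol=1e-10)

    def test_scaling_a_column_is_absorbed_by_normalization(self, rng):
        y = rng.standard_normal((12, 6))
        tc = rng.standard_normal((12, 2))
        tc2 = tc.copy()
        tc2[:, 0] *= 2.0
        pe_a, _ = stage2_maps(run_from_matrix(y), tc, full_mask((6, 1, 1)),
                              normalize=True)
        pe_b, _ = stage2_maps(run_from_matrix(y), tc2, full_mask((6, 1, 1)),
                              normalize=True)
        np.testing.assert_allclose(pe_a, pe_b, atol=1e-10)

    def test_constant_column_rejected(self, rng):
        y = rng.standard_normal((10, 4))
        tc = np.column_stack([np.ones(10), rng.standard_normal(10)])
        with pytest.raises(ValueError, match="constant"):
            stage2_maps(run_from_matrix(y), tc, full_mask((4, 1, 1)))

    def test_too_short_run_rejected(self, rng):
        y = rng.standard_normal((3, 4))
        tc = rng.standard_normal((3, 2))
        with pytest.raises(ValueError, match="T >= K"):
            stage2_maps(run_from_matrix(y), tc, full_mask((4, 1, 1)))

    def test_z_maps_have_t_statistic_scale(self, rng):
        y = rng.standard_normal((50, 8))
        tc = rng.standard_normal((50, 2))
        run = run_from_matrix(y)
        pe, z = stage2_maps(run, tc, full_mask((8, 1, 1)), normalize=False)
        # independent per-voxel OLS t statistic for one voxel
        import statsmodels.api as sm

        fit = sm.OLS(y[:, 3], sm.add_constant(tc)).fit()
        np.testing.assert_allclose(z[:, 3], fit.tvalues[1:], atol=1e-8)


class TestCohort:
    def test_identical_runs_identical_outputs(self, rng):
        m = rng.standard_normal((2, 25))
        y = rng.standard_normal((10, 25))
        runs = [run_from_matrix(y) for _ in range(4)]
        sms = run_dual_regression(runs, mapset_from(m), full_mask((25, 1, 1)))
        for sm_ in sms[1:]:
            np.testing.assert_array_equal(sm_.pe_maps, sms[0].pe_maps)
            np.testing.assert_array_equal(sm_.timecourses, sms[0].timecourses)

    def test_data_scaling_scales_pe_maps(self, rng):
        m = rng.standard_normal((2, 25))
        y = rng.standard_normal((10, 25))
        base = run_dual_regression([run_from_matrix(y)], mapset_from(m),
                                   full_mask((25, 1, 1)))[0]
        scaled = run_dual_regression([run_from_matrix(3.0 * y)], mapset_from(m),
                                     full_mask((25, 1, 1)))[0]
        np.testing.assert_allclose(scaled.pe_maps, 3.0 * base.pe_maps,
                                   atol=1e-10)

    def test_stage1_on_reconstruction_returns_mixing(self, rng):
        # self-consistency: regressing the (mixing @ maps) reconstruction on
        # the maps gives back the mixing rows, up to the spatial demeaning
        maps = rng.standard_normal((3, 40))
        maps -= maps.mean(axis=1, keepdims=True)
        mixing = rng.standard_normal((15, 3))
        recon = mixing @ maps
        tc = stage1_timecourses(run_from_matrix(recon), mapset_from(maps),
                                full_mask((40, 1, 1)))
        np.testing.assert_allclose(tc, mixing, atol=1e-8)

    def test_planted_half_amplitude_halves_pe_maps(self):
        # two subjects share identical node time courses; the patient's
        # network amplitude is 0.5, noise 0 -> PE maps exactly halved
        cfg = SimConfig(grid_dims=(10, 10, 5), n_timepoints=40, n_networks=2,
                        n_controls=2, n_patients=2, noise_sigma=0.0,
                        patient_factor=0.5, attenuated_networks=(0, 1), seed=3)
        from rsnpipe.simdata import make_network_maps, make_timecourses

        maps = make_network_maps(cfg)
        shared_tc = make_timecourses(cfg, 0)
        truth = SimTruth(true_maps=maps,
                         true_timecourses=[shared_tc] * cfg.n_subjects,
                         amplitude_factor=cfg.amplitude_factor,
                         labels=cfg.group_labels, seed=cfg.seed)
        run_c = synthesize_subject(truth, cfg, 0)   # control
        run_p = synthesize_subject(truth, cfg, 2)   # patient
        ms = mapset_from(maps)
        mask = full_mask(cfg.grid_dims)
        sm_c, sm_p = run_dual_regression([run_c, run_p], ms, mask)
        np.testing.assert_allclose(sm_p.pe_maps, 0.5 * sm_c.pe_maps,
                                   atol=1e-8)
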