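import numpy as np
import pytest
from scipy.integrate import quad

from sipspect import (
    DosimetryConfig,
    KineticsModel,
    absorbed_dose,
    fit_biexponential,
    scale_marrow_concentration,
    sphere_voi,
    time_integrated_concentration,
    voi_concentration,
)
from sipspect.dosimetry import run_dosimetry
from sipspect.recon import ReconVolume

from oracles import sphere_count_loops


class TestSphereVOI:
    def test_four_ml_sphere_voxel_count_matches_bruteforce(self):
        shape = (32, 32, 32)
        center = (15.5, 15.5, 15.5)
        mask = sphere_voi(center, 4.0, 4.42, shape)
        r_mm = (3.0 * 4.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        expected = sphere_count_loops(center, r_mm, 4.42, shape)
        assert mask.sum() == expected

    def test_fine_voxel_volume_converges_to_requested(self):
        # at coarse SPECT voxels a 4-ml sphere quantises to 33-56 voxels
        # depending on centre alignment; at 1 mm pitch the voxelised volume
        # tracks the request closely
        mask = sphere_voi((31.5, 31.5, 31.5), 4.0, 1.0, (64, 64, 64))
        assert abs(mask.sum() * (0.1**3) - 4.0) / 4.0 < 0.02

    def test_subvoxel_volume_gives_single_voxel(self):
        mask = sphere_voi((8, 8, 8), 0.01, 4.42, (16, 16, 16))
        assert mask.sum() == 1
        assert mask[8, 8, 8]

    def test_doubling_voxel_size_shrinks_voxel_radius(self):
        m1 = sphere_voi((15.5, 15.5, 15.5), 4.0, 4.42, (32, 32, 32))
        m2 = sphere_voi((15.5, 15.5, 15.5), 4.0, 8.84, (32, 32, 32))
        assert 5 * m2.sum() < m1.sum()

    def test_sphere_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            sphere_voi((1, 1, 1), 4.0, 4.42, (16, 16, 16))


class TestBiexponentialFit:
    def test_parameter_recovery_noiseless(self):
        t = np.array([3.0, 24.0, 48.0, 168.0])
        c = 100 * np.exp(-0.05 * t) + 20 * np.exp(-0.005 * t)
        A1, l1, A2, l2 = fit_biexponential(t, c)
        assert A1 == pytest.approx(100.0, rel=1e-3)
        assert l1 == pytest.approx(0.05, rel=1e-3)
        assert A2 == pytest.approx(20.0, rel=1e-3)
        assert l2 == pytest.approx(0.005, rel=1e-3)

    def test_monoexponential_degenerates_gracefully(self):
        t = np.array([3.0, 24.0, 48.0, 168.0])
        c = 50 * np.exp(-0.02 * t)
        params = fit_biexponential(t, c)
        tia = time_integrated_concentration(params)
        assert tia == pytest.approx(50.0 / 0.02, rel=1e-3)

    def test_lambda_ordering_enforced(self):
        t = np.array([1.0, 10.0, 50.0, 100.0, 200.0])
        c = 30 * np.exp(-0.3 * t) + 5 * np.exp(-0.01 * t)
        _, l1, _, l2 = fit_biexponential(t, c)
        assert l1 > l2 > 0

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_biexponential([3.0, 2.0, 48.0, 168.0], [1, 2, 3, 4])

    def test_deterministic(self):
        t = np.array([3.0, 24.0, 48.0, 168.0])
        rng = np.random.default_rng(0)
        c = (100 * np.exp(-0.05 * t) + 20 * np.exp(-0.005 * t)) * rng.uniform(0.95, 1.05, 4)
        assert fit_biexponential(t, c) == fit_biexponential(t, c)


class TestTimeIntegration:
    def test_closed_form(self):
        assert time_integrated_concentration((10, 0.1, 5, 0.01)) == pytest.approx(600.0)

    def test_matches_numeric_quadrature(self):
        A1, l1, A2, l2 = 80.0, 0.07, 12.0, 0.004
        num, _ = quad(lambda t: A1 * np.exp(-l1 * t) + A2 * np.exp(-l2 * t), 0, 10 / l2,
                      limit=200)
        tail = A1 / l1 * np.exp(-l1 * 10 / l2) + A2 / l2 * np.exp(-10.0)
        assert time_integrated_concentration((A1, l1, A2, l2)) == pytest.approx(
            num + tail, rel=1e-6
        )

    def test_linearity_in_amplitudes(self):
        base = time_integrated_concentration((10, 0.1, 5, 0.01))
        assert time_integrated_concentration((20, 0.1, 10, 0.01)) == pytest.approx(2 * base)

    def test_nonpositive_integral_rejected(self):
        with pytest.raises(ValueError):
            time_integrated_concentration((-10, 0.1, 0.0001, 0.01))


class TestAbsorbedDose:
    def test_kidney_dimensional_analysis(self):
        # independent re-derivation: 1 MBq.h/ml = 3.6e9 decays/ml;
        # 147.9 keV/decay = 147.9 * 1.602176634e-16 J; density 1.05e-3 kg/ml
        cfg = DosimetryConfig()
        expected = 3.6e9 * 147.9 * 1.602176634e-16 / 1.05e-3
        assert absorbed_dose(1.0e6, "kidney", cfg) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0812, rel=2e-3)

    def test_marrow_is_kidney_times_stated_factors(self):
        cfg = DosimetryConfig(marrow_density_g_per_ml=1.05)
        k = absorbed_dose(2.5e5, "kidney", cfg)
        m = absorbed_dose(2.5e5, "marrow", cfg)
        assert m == pytest.approx(k * 0.65 / 0.57, rel=1e-12)

    def test_linear_in_tia(self):
        cfg = DosimetryConfig()
        assert absorbed_dose(2e6, "kidney", cfg) == pytest.approx(
            2 * absorbed_dose(1e6, "kidney", cfg)
        )

    def test_unknown_organ_rejected(self):
        with pytest.raises(ValueError, match="organ"):
            absorbed_dose(1.0, "liver", DosimetryConfig())


class TestConcentrationHelpers:
    def test_scale_marrow_definitional(self):
        cfg = DosimetryConfig()
        assert scale_marrow_concentration(0.57, cfg) == pytest.approx(1.0)
        assert scale_marrow_concentration(0.0, cfg) == 0.0
        assert scale_marrow_concentration(3.0, cfg) >= 3.0

    def test_voi_concentration_rc_correction(self):
        rec = ReconVolume(values=np.full((8, 8, 8), 10.0), method_label="x",
                          iterations=1, subsets=1, calibration_factor=2.0)
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        assert voi_concentration(rec, mask, 1.0) == pytest.approx(20.0)
        assert voi_concentration(rec, mask, 0.87) == pytest.approx(20.0 / 0.87)

    def test_empty_mask_rejected(self):
        rec = ReconVolume(values=np.ones((4, 4, 4)), method_label="x", iterations=1, subsets=1)
        with pytest.raises(ValueError, match="empty"):
            voi_concentration(rec, np.zeros((4, 4, 4), bool))


class TestRunDosimetry:
    def _recons(self, scale=1.0):
        times = (2.0, 24.0, 48.0, 168.0)
        kin = KineticsModel(1.0e5, 0.06, 2.0e4, 0.008)
        out = {}
        for t in times:
            conc = scale * (kin.A1 * np.exp(-kin.lambda1 * t) + kin.A2 * np.exp(-kin.lambda2 * t))
            out[t] = ReconVolume(values=np.full((16, 16, 16), conc), method_label="m",
                                 iterations=10, subsets=6)
        return out, kin

    def _masks(self):
        m = np.zeros((16, 16, 16), bool)
        m[4:8, 4:8, 4:8] = True
        s = np.zeros((16, 16, 16), bool)
        s[10:12, 10:12, 10:12] = True
        return {"kidney_L": m, "kidney_R": m.copy(), "marrow_spheres": s}

    def test_identical_recons_give_identical_doses(self):
        recs, _ = self._recons()
        res = run_dosimetry({"a": recs, "b": {t: r for t, r in recs.items()}},
                            self._masks(), {"a": 0.9, "b": 0.9}, DosimetryConfig())
        by = {(r.method_label, r.organ): r.absorbed_dose_Gy for r in res}
        for organ in ("kidney_L", "kidney_R", "marrow"):
            assert by[("a", organ)] == pytest.approx(by[("b", organ)], rel=1e-12)

    def test_row_count_is_organs_times_methods(self):
        recs, _ = self._recons()
        res = run_dosimetry({"a": recs, "b": recs}, self._masks(),
                            {"a": 1.0, "b": 1.0}, DosimetryConfig())
        assert len(res) == 6

    def test_uniform_pipeline_recovers_analytic_dose(self):
        recs, kin = self._recons()
        res = run_dosimetry({"a": recs}, self._masks(), {"a": 1.0}, DosimetryConfig())
        kd = next(r for r in res if r.organ == "kidney_L")
        expected = absorbed_dose(kin.A1 / kin.lambda1 + kin.A2 / kin.lambda2,
                                 "kidney", DosimetryConfig())
        assert kd.absorbed_dose_Gy == pytest.approx(expected, rel=1e-4)

    def test_missing_time_point_names_method(self):
        recs, _ = self._recons()
        del recs[48.0]
        with pytest.raises(ValueError, match="a"):
            run_dosimetry({"a": recs}, self._masks(), {"a": 1.0}, DosimetryConfig(),
                          times_h=(2.0, 24.0, 48.0, 168.0))

    def test_tia_consistency_invariant(self):
        recs, _ = self._recons()
        res = run_dosimetry({"a": recs}, self._masks(), {"a": 1.0}, DosimetryConfig())
        for r in res:
            A1, l1, A2, l2 = r.fit_params
            assert r.tia_conc_Bqh_per_ml == pytest.approx(A1 / l1 + A2 / l2, rel=1e-9)
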