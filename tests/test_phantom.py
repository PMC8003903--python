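import numpy as np
import pytest
from scipy import stats as sps

from chondroquant.meshmodel import compute_thickness
from chondroquant.phantom import (
    PhantomSpec,
    ProgressionModel,
    cartilage_mask,
    icosphere,
    make_condyle_models,
    render_multiecho,
    simulate_cohort,
    simulate_measure_table,
)
from chondroquant.relaxometry import fit_t2_map, median_t2


class TestSpecValidation:
    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError, match="thickness"):
            PhantomSpec(thickness_base=0.3, thickness_ap_amplitude=0.4)

    def test_overlapping_condyles_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            PhantomSpec(condyle_separation=20.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(noise_sigma=-1.0)

    def test_kl1_multiplier_must_be_identity(self):
        with pytest.raises(ValueError, match="KL1"):
            ProgressionModel(t2_multipliers={"KL1": {"M": 1.1}})

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ProgressionModel(t2_multipliers={"KL2": {"M": -0.5}})


class TestIcosphere:
    def test_pole_alignment(self):
        m = icosphere(2)
        y = m.vertices[:, 1]
        assert np.isclose(y.max(), 1.0)
        assert np.isclose(y.min(), -1.0)

    def test_unit_radius(self):
        m = icosphere(3)
        assert np.allclose(np.linalg.norm(m.vertices, axis=1), 1.0)


class TestMakeCondyleModels:
    def test_constant_thickness(self):
        spec = PhantomSpec(thickness_ap_amplitude=0.0, thickness_base=2.0,
                           mesh_resolution=3.0, noise_sigma=0.0)
        _, _, truth, _ = make_condyle_models(spec)
        assert np.all(truth == 2.0)

    def test_determinism_bitwise(self, coarse_spec):
        b1, c1, t1, _ = make_condyle_models(coarse_spec)
        b2, c2, t2, _ = make_condyle_models(coarse_spec)
        assert np.array_equal(b1.vertices, b2.vertices)
        assert np.array_equal(c1.vertices, c2.vertices)
        assert np.array_equal(t1, t2)

    def test_thickness_cross_check(self, coarse_spec, coarse_models):
        bone, cart, truth, _ = coarse_models
        tmap = compute_thickness(bone, cart)
        assert tmap.covered.all()
        assert np.max(np.abs(tmap.thickness - truth)) <= 2 * coarse_spec.mesh_resolution

    def test_cartilage_offset_along_normals(self, coarse_spec, coarse_models):
        bone, cart, truth, _ = coarse_models
        offsets = np.linalg.norm(cart.vertices - bone.vertices, axis=1)
        assert np.allclose(offsets, truth)


class TestRenderMultiecho:
    def test_closed_form_signal(self):
        spec = PhantomSpec(noise_sigma=0.0, t2_deep=40.0, t2_superficial=40.0,
                           mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0))
        _, _, _, fld = make_condyle_models(spec)
        vol = render_multiecho(spec, fld)
        mask = cartilage_mask(fld, vol.geometry)
        te40 = list(vol.echo_times).index(40.0)
        inside = vol.signals[te40][mask]
        assert np.allclose(inside, spec.s0 * np.exp(-1.0))
        assert np.all(vol.signals[:, ~mask] == 0)

    def test_seed_determinism(self):
        spec = PhantomSpec(mesh_resolution=3.0, spacing=(2.0, 2.0, 3.0), seed=11)
        _, _, _, fld = make_condyle_models(spec)
        v1 = render_multiecho(spec, fld)
        v2 = render_multiecho(spec, fld)
        assert np.array_equal(v1.signals, v2.signals)

    def test_background_is_rayleigh(self):
        spec = PhantomSpec(noise_sigma=10.0, mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0))
        _, _, _, fld = make_condyle_models(spec)
        vol = render_multiecho(spec, fld)
        mask = cartilage_mask(fld, vol.geometry)
        bg = vol.signals[0][~mask].ravel()
        # KS against the Rayleigh law at the nominal sigma
        stat, p = sps.kstest(bg, sps.rayleigh(scale=10.0).cdf)
        assert p > 0.01

    def test_noiseless_fit_recovers_truth(self):
        spec = PhantomSpec(noise_sigma=0.0, mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0))
        _, _, _, fld = make_condyle_models(spec)
        vol = render_multiecho(spec, fld)
        mask = cartilage_mask(fld, vol.geometry)
        t2map = fit_t2_map(vol, mask)
        pts = vol.geometry.grid_world_coords().reshape(-1, 3)[mask.ravel()]
        truth = fld.t2_at(pts)
        assert np.nanmax(np.abs(t2map.t2[mask] - truth)) < 1e-6

    def test_noiseless_chain_recovers_voi_medians(self):
        spec = PhantomSpec(noise_sigma=0.0, mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0))
        _, _, _, fld = make_condyle_models(spec)
        vol = render_multiecho(spec, fld)
        mask = cartilage_mask(fld, vol.geometry)
        t2map = fit_t2_map(vol, mask)
        pts = vol.geometry.grid_world_coords().reshape(-1, 3)[mask.ravel()]
        voi, _ = fld.voi_at(pts)
        truth = fld.t2_at(pts)
        fitted = t2map.t2[mask]
        for label in np.unique(voi):
            sel = voi == label
            assert abs(median_t2(fitted[sel]).median - median_t2(truth[sel]).median) < 1e-3

    def test_background_only_mask_voxels_invalid_or_excluded(self):
        spec = PhantomSpec(noise_sigma=0.0, mesh_resolution=3.0, spacing=(1.5, 1.5, 3.0))
        _, _, _, fld = make_condyle_models(spec)
        vol = render_multiecho(spec, fld)
        mask = cartilage_mask(fld, vol.geometry)
        t2map = fit_t2_map(vol, np.ones(vol.geometry.dims, dtype=bool))
        # zero-signal background voxels must be invalid
        assert not t2map.valid[~mask].any()
        assert t2map.valid[mask].all()


class TestSimulateCohort:
    def _fast_spec(self):
        return PhantomSpec(noise_sigma=0.0, mesh_resolution=3.5, spacing=(2.0, 2.0, 3.0))

    def test_zero_variability_identity_model(self):
        model = ProgressionModel(knee_t2_sd=0, knee_thickness_sd=0, knee_radius_sd=0,
                                 timepoint_thickness_sd=0, timepoint_t2_sd=0)
        cohort = simulate_cohort(3, self._fast_spec(), model, seed=5)
        for tps in cohort.knees:
            ref = tps["KL1"]
            for tp in ("KL2", "KL3"):
                assert np.array_equal(tps[tp].volume.signals, ref.volume.signals)
                assert np.array_equal(tps[tp].bone.vertices, ref.bone.vertices)
                assert np.array_equal(tps[tp].truth_thickness, ref.truth_thickness)

    def test_truth_table_bookkeeping_exact(self):
        model = ProgressionModel(t2_multipliers={"KL2": {"M": 1.10}},
                                 timepoint_t2_sd=0, timepoint_thickness_sd=0)
        cohort = simulate_cohort(2, self._fast_spec(), model, seed=5, render=False)
        t = cohort.truth_table
        for knee in (0, 1):
            for region in ("Ma", "Mc", "Mp", "Mae"):
                kl1 = t[(t.knee == knee) & (t.timepoint == "KL1") & (t.region == region)]
                kl2 = t[(t.knee == knee) & (t.timepoint == "KL2") & (t.region == region)]
                assert np.isclose(kl2.true_t2.iloc[0] / kl1.true_t2.iloc[0], 1.10)
            la1 = t[(t.knee == knee) & (t.timepoint == "KL1") & (t.region == "La")]
            la2 = t[(t.knee == knee) & (t.timepoint == "KL2") & (t.region == "La")]
            assert np.isclose(la2.true_t2.iloc[0] / la1.true_t2.iloc[0], 1.0)

    def test_seed_reproducibility(self):
        model = ProgressionModel()
        c1 = simulate_cohort(2, self._fast_spec(), model, seed=9)
        c2 = simulate_cohort(2, self._fast_spec(), model, seed=9)
        assert np.array_equal(c1.knees[0]["KL2"].volume.signals,
                              c2.knees[0]["KL2"].volume.signals)

    def test_knee_substreams_stable_under_cohort_size(self):
        # knee k's data does not depend on how many knees follow it
        model = ProgressionModel()
        c2 = simulate_cohort(2, self._fast_spec(), model, seed=9)
        c4 = simulate_cohort(4, self._fast_spec(), model, seed=9)
        assert np.array_equal(c2.knees[1]["KL1"].volume.signals,
                              c4.knees[1]["KL1"].volume.signals)

    def test_minimum_knees(self):
        with pytest.raises(ValueError, match="2 knees"):
            simulate_cohort(1, self._fast_spec(), ProgressionModel(), seed=0)

    def test_months_column(self):
        model = ProgressionModel(months_between=(12.0, 24.0))
        cohort = simulate_cohort(2, self._fast_spec(), model, seed=0, render=False)
        months = cohort.truth_table.groupby("timepoint")["months"].first()
        assert months["KL1"] == 0.0 and months["KL2"] == 12.0 and months["KL3"] == 36.0


class TestSimulateMeasureTable:
    def test_shape_and_determinism(self):
        model = ProgressionModel()
        t1 = simulate_measure_table(5, model, seed=3)
        t2 = simulate_measure_table(5, model, seed=3)
        assert t1.equals(t2)
        assert set(t1.columns) == {"knee", "timepoint", "months", "measure", "value"}
        # 5 knees x 3 timepoints x 12 regions x 2 families
        assert len(t1) == 5 * 3 * 12 * 2

    def test_injected_effect_visible(self):
        model = ProgressionModel(t2_multipliers={"KL2": {"M": 1.5}}, measurement_sd=0.001,
                                 knee_t2_sd=0.0)
        t = simulate_measure_table(4, model, seed=3)
        ma = t[t.measure == "Ma_T2"].pivot(index="knee", columns="timepoint", values="value")
        ratio = (ma["KL2"] / ma["KL1"]).mean()
        assert abs(ratio - 1.5) < 0.01
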