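import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretmix.image_io import LabelMask
from fretmix.sensor_model import SensorSpec
from fretmix.synthetic import SimulationConfig, generate_tissue, render_acquisition
from fretmix.unmixing import (
    SpectralSignature,
    build_mixing_matrix,
    compute_fret_map,
    constant_background_subtract,
    estimate_af_signature,
    estimate_sensor_signatures,
    unmix_image,
)

from conftest import constant_acquisition, make_acquisition


def sig(species, coeffs):
    return SpectralSignature(species=species, coefficients=np.asarray(coeffs, dtype=float))


class TestSpectralSignature:
    def test_sum_must_be_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sig("donor_fluor", [0.5, 0.4, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sig("donor_fluor", [1.2, -0.2, 0.0])

    def test_from_counts_normalizes(self):
        s = SpectralSignature.from_counts("autofluorescence", [30, 20, 50])
        np.testing.assert_allclose(s.coefficients, [0.3, 0.2, 0.5])


class TestEstimateAfSignature:
    def test_constant_channels(self, full_mask):
        acq = constant_acquisition((30, 20, 50))
        s = estimate_af_signature(acq, full_mask(), min_pixels=10)
        np.testing.assert_allclose(s.coefficients, [0.3, 0.2, 0.5])

    def test_scale_invariance(self, full_mask):
        a = estimate_af_signature(constant_acquisition((30, 20, 50)), full_mask(), min_pixels=10)
        b = estimate_af_signature(constant_acquisition((210, 140, 350)), full_mask(), min_pixels=10)
        np.testing.assert_allclose(a.coefficients, b.coefficients)

    def test_too_few_pixels(self, full_mask):
        acq = constant_acquisition((30, 20, 50))
        with pytest.raises(ValueError, match="need >="):
            estimate_af_signature(acq, full_mask(), min_pixels=100)

    def test_poisson_recovery_within_tolerance(self):
        # sensor-free scene, heterogeneous AF with true signature (0.25, 0.25, 0.5)
        sigs = (
            sig("donor_fluor", [0.8, 0.2, 0.0]),
            sig("acceptor_fluor", [0.05, 0.9, 0.05]),
            sig("autofluorescence", [0.25, 0.25, 0.5]),
        )
        cfg = SimulationConfig(
            height=100, width=100, n_cells=10, signatures=sigs, specimen="none",
            af_mean=500.0, af_heterogeneity=0.3, af_granule_density=0.0, seed=21,
        )
        acq = render_acquisition(generate_tissue(cfg), cfg)
        est = estimate_af_signature(acq, LabelMask(np.ones((100, 100), np.int32)))
        np.testing.assert_allclose(est.coefficients, [0.25, 0.25, 0.5], atol=0.01)


class TestEstimateSensorSignatures:
    def test_no_af_case(self, full_mask):
        donor_only = constant_acquisition((80, 20, 0))
        acceptor_only = constant_acquisition((5, 90, 5))
        af = sig("autofluorescence", [0.3, 0.2, 0.5])
        d, a = estimate_sensor_signatures(donor_only, acceptor_only, af, full_mask())
        np.testing.assert_allclose(d.coefficients, [0.8, 0.2, 0.0], atol=1e-12)

    def test_scale_invariance(self, full_mask):
        af = sig("autofluorescence", [0.3, 0.2, 0.5])
        d1, _ = estimate_sensor_signatures(
            constant_acquisition((80, 20, 0)), constant_acquisition((5, 90, 5)), af, full_mask()
        )
        d2, _ = estimate_sensor_signatures(
            constant_acquisition((160, 40, 0)), constant_acquisition((10, 180, 10)), af, full_mask()
        )
        np.testing.assert_allclose(d1.coefficients, d2.coefficients)

    def test_synthetic_acceptor_recovery(self):
        # acceptor-only specimen (no AF-window bleed) rendered by the
        # forward model on top of heterogeneous AF
        sigs = (
            sig("donor_fluor", [0.8, 0.2, 0.0]),
            sig("acceptor_fluor", [0.06, 0.94, 0.0]),
            sig("autofluorescence", [0.3, 0.2, 0.5]),
        )
        cfg = SimulationConfig(
            height=100, width=100, n_cells=10, signatures=sigs,
            specimen="acceptor_only", direct_excitation_coeff=1.0,  # acceptor directly excited here
            photon_budget=2000.0, af_mean=100.0, af_heterogeneity=0.3,
            af_granule_density=0.0, seed=22,
        )
        acq = render_acquisition(generate_tissue(cfg), cfg)
        donor_only = constant_acquisition((80, 20, 0), shape=(100, 100))
        mask = LabelMask(np.ones((100, 100), np.int32))
        _, a = estimate_sensor_signatures(donor_only, acq, sigs[2], mask)
        np.testing.assert_allclose(a.coefficients, [0.06, 0.94, 0.0], atol=0.02)

    def test_af_window_bleed_gives_orthogonalized_signature(self):
        # with nonzero bleed into the AF window the two-species split is not
        # identifiable; the estimator must return the AF-orthogonalized
        # member of the solution family (closed-form oracle)
        true_sig = np.array([0.05, 0.9, 0.05])
        af = np.array([0.3, 0.2, 0.5])
        rng = np.random.default_rng(3)
        s = rng.uniform(500, 3000, size=(40, 40))
        a = rng.uniform(50, 300, size=(40, 40))
        channels = s[..., None] * true_sig + a[..., None] * af
        acq = make_acquisition(channels[..., 0], channels[..., 1], channels[..., 2])
        mask = LabelMask(np.ones((40, 40), np.int32))
        _, est = estimate_sensor_signatures(
            constant_acquisition((80, 20, 0), shape=(40, 40)),
            acq,
            sig("autofluorescence", af),
            mask,
        )
        expected = true_sig - (true_sig[2] / af[2]) * af
        expected /= expected.sum()
        np.testing.assert_allclose(est.coefficients, expected, atol=1e-9)

    def test_unusable_reference(self, full_mask):
        af = sig("autofluorescence", [0.3, 0.2, 0.5])
        pure_af = constant_acquisition((30, 20, 50))  # no sensor signal at all
        with pytest.raises(ValueError, match="principal channel"):
            estimate_sensor_signatures(pure_af, pure_af, af, full_mask())


class TestBuildMixingMatrix:
    def test_identity(self):
        M = build_mixing_matrix(
            sig("donor_fluor", [1, 0, 0]),
            sig("acceptor_fluor", [0, 1, 0]),
            sig("autofluorescence", [0, 0, 1]),
        )
        np.testing.assert_array_equal(M.matrix, np.eye(3))
        assert M.condition_number == pytest.approx(1.0)

    def test_singular_rejected(self):
        same = [0.5, 0.5, 0.0]
        with pytest.raises(ValueError, match="ill-conditioned"):
            build_mixing_matrix(
                sig("donor_fluor", same), sig("acceptor_fluor", same), sig("autofluorescence", [0.3, 0.2, 0.5])
            )

    def test_condition_number_matches_svd_oracle(self, signatures):
        M = build_mixing_matrix(*signatures)
        # independent oracle: ratio of extreme singular values
        svals = np.linalg.svd(np.vstack([s.coefficients for s in signatures]), compute_uv=False)
        assert M.condition_number == pytest.approx(svals[0] / svals[-1], rel=1e-12)

    def test_cond_cap_enforced(self, signatures):
        with pytest.raises(ValueError, match="cond"):
            build_mixing_matrix(*signatures, cond_cap=1.5)


class TestUnmixImage:
    def test_identity_matrix_passthrough(self):
        M = build_mixing_matrix(
            sig("donor_fluor", [1, 0, 0]),
            sig("acceptor_fluor", [0, 1, 0]),
            sig("autofluorescence", [0, 0, 1]),
        )
        acq = constant_acquisition((10, 20, 5))
        um = unmix_image(acq, M)
        assert np.all(um.donor_abundance == 10)
        assert np.all(um.acceptor_abundance == 20)
        assert np.all(um.autofluo_abundance == 5)
        assert np.all(um.residual_norm == 0)

    @pytest.mark.parametrize("policy", ["clamp", "nnls"])
    def test_forward_model_inversion(self, mixing_matrix, policy):
        rng = np.random.default_rng(7)
        truth = rng.uniform(0, 100, size=(32, 32, 3))
        intensities = truth @ mixing_matrix.matrix  # pixels x channels
        acq = make_acquisition(intensities[..., 0], intensities[..., 1], intensities[..., 2])
        um = unmix_image(acq, mixing_matrix, nonneg=policy)
        np.testing.assert_allclose(um.donor_abundance, truth[..., 0], atol=1e-9)
        np.testing.assert_allclose(um.acceptor_abundance, truth[..., 1], atol=1e-9)
        np.testing.assert_allclose(um.autofluo_abundance, truth[..., 2], atol=1e-9)
        assert um.residual_norm.max() < 1e-9

    def test_pure_autofluorescence_pixel(self, signatures, mixing_matrix):
        af = signatures[2].coefficients * 50.0
        acq = constant_acquisition(tuple(af))
        um = unmix_image(acq, mixing_matrix, nonneg="nnls")
        np.testing.assert_allclose(um.donor_abundance, 0, atol=1e-9)
        np.testing.assert_allclose(um.acceptor_abundance, 0, atol=1e-9)
        np.testing.assert_allclose(um.autofluo_abundance, 50.0, atol=1e-9)

    def test_all_zero_pixels(self, mixing_matrix):
        um = unmix_image(constant_acquisition((0, 0, 0)), mixing_matrix)
        assert np.all(um.donor_abundance == 0)
        assert np.all(um.residual_norm == 0)

    def test_lstsq_oracle_equivalence(self, mixing_matrix):
        # unconstrained branch vs an independently coded least-squares solve
        rng = np.random.default_rng(11)
        truth = rng.uniform(0, 50, size=(40, 40, 3))
        intensities = truth @ mixing_matrix.matrix
        acq = make_acquisition(intensities[..., 0], intensities[..., 1], intensities[..., 2])
        um = unmix_image(acq, mixing_matrix, nonneg="clamp")
        flat = intensities.reshape(-1, 3)
        oracle = np.array([np.linalg.lstsq(mixing_matrix.matrix.T, px, rcond=None)[0] for px in flat])
        got = np.stack(
            [um.donor_abundance, um.acceptor_abundance, um.autofluo_abundance], axis=-1
        ).reshape(-1, 3)
        np.testing.assert_allclose(got, oracle, atol=1e-9)

    def test_residual_positive_under_poisson_noise(self, small_config, mixing_matrix):
        acq = render_acquisition(generate_tissue(small_config), small_config)
        um = unmix_image(acq, mixing_matrix, nonneg="nnls")
        assert um.residual_norm.mean() > 0


class TestConstantBackgroundSubtract:
    def test_exact_cancellation(self):
        out = constant_background_subtract(constant_acquisition((10, 10, 10)), (10, 10, 10))
        assert np.all(out.donor.pixels == 0)
        assert out.background_corrected

    def test_zero_background_identity(self):
        acq = constant_acquisition((10, 20, 5))
        out = constant_background_subtract(acq, (0, 0, 0))
        np.testing.assert_array_equal(out.donor.pixels, acq.donor.pixels)

    def test_clamps_at_zero(self):
        out = constant_background_subtract(constant_acquisition((5, 5, 5)), (10, 0, 0))
        assert np.all(out.donor.pixels == 0)

    def test_cb_retains_af_structure_lu_removes_it(self, signatures, mixing_matrix):
        # heterogeneous AF + uniform sensor: the CB residual keeps the AF
        # spatial pattern in the donor channel; LU assigns it to the AF species
        cfg = SimulationConfig(
            height=64, width=64, n_cells=1,
            expression_lognormal_mu_sigma=(0.0, 0.0),
            conc_distribution={"name": "constant", "value": 0.0},
            sensor=SensorSpec(fret_eff_unbound=0.3, fret_eff_bound=0.05),
            af_mean=300.0, af_heterogeneity=0.6, af_granule_density=0.0,
            photon_budget=500.0, read_noise_sd=0.0, seed=31,
        )
        truth = generate_tissue(cfg)
        acq = render_acquisition(truth, cfg)
        af_pattern = truth.af_field - truth.af_field.mean()

        cb = constant_background_subtract(acq, truth.af_field.mean() * signatures[2].coefficients)
        cb_resid = cb.donor.pixels - cb.donor.pixels.mean()
        cb_corr = np.corrcoef(cb_resid.ravel(), af_pattern.ravel())[0, 1]

        um = unmix_image(acq, mixing_matrix, nonneg="nnls")
        lu_resid = um.donor_abundance - um.donor_abundance.mean()
        lu_corr = np.corrcoef(lu_resid.ravel(), af_pattern.ravel())[0, 1]

        assert cb_corr > 0.5
        assert abs(lu_corr) < 0.1


class TestComputeFretMap:
    def test_uniform_ratio(self, mixing_matrix):
        um = unmix_image(constant_acquisition((0, 0, 0)), mixing_matrix)
        um.donor_abundance[:] = 10.0
        um.acceptor_abundance[:] = 5.0
        fmap = compute_fret_map(um, min_intensity=1.0)
        assert fmap.valid.all()
        np.testing.assert_allclose(fmap.ratio, 0.5)

    def test_zero_donor_invalid(self, mixing_matrix):
        um = unmix_image(constant_acquisition((0, 0, 0)), mixing_matrix)
        um.acceptor_abundance[:] = 10.0
        fmap = compute_fret_map(um, min_intensity=1.0)
        assert not fmap.valid.any()

    def test_min_intensity_threshold(self, mixing_matrix):
        um = unmix_image(constant_acquisition((0, 0, 0)), mixing_matrix)
        um.donor_abundance[:] = 2.0
        um.acceptor_abundance[:] = 1.0
        assert not compute_fret_map(um, min_intensity=5.0).valid.any()
        assert compute_fret_map(um, min_intensity=3.0).valid.all()

    def test_raw_acquisition_rejected(self):
        with pytest.raises(ValueError, match="background-corrected"):
            compute_fret_map(constant_acquisition((10, 20, 5)), min_intensity=1.0)

    def test_orientation_flip(self, mixing_matrix):
        um = unmix_image(constant_acquisition((0, 0, 0)), mixing_matrix)
        um.donor_abundance[:] = 10.0
        um.acceptor_abundance[:] = 5.0
        flipped = compute_fret_map(um, 1.0, orientation="donor_over_acceptor")
        np.testing.assert_allclose(flipped.ratio, 2.0)

    def test_binding_lowers_ratio_between_populations(self, signatures, mixing_matrix):
        # two cell populations at bound fractions 0.2 and 0.8: more binding
        # means less FRET, so the high-f population shows the lower ratio
        spec = SensorSpec(kd=1.0, fret_eff_unbound=0.45, fret_eff_bound=0.05)
        cfg = SimulationConfig(
            height=64, width=64, n_cells=40,
            conc_distribution={"name": "choice", "values": [0.25, 4.0]},  # f = 0.2 or 0.8
            sensor=spec, af_mean=80.0, af_heterogeneity=0.4, photon_budget=500.0, seed=41,
        )
        truth = generate_tissue(cfg)
        acq = render_acquisition(truth, cfg)
        fmap = compute_fret_map(unmix_image(acq, mixing_matrix), min_intensity=10.0)
        f_px = truth.bound_fraction[truth.cell_labels.labels - 1]
        low = fmap.mean_ratio(np.isclose(f_px, 0.2))
        high = fmap.mean_ratio(np.isclose(f_px, 0.8))
        assert high < low


@settings(max_examples=30, deadline=None)
@given(
    d=st.floats(1.0, 500.0),
    a=st.floats(1.0, 500.0),
    af=st.floats(0.0, 500.0),
    k=st.floats(0.01, 100.0),
)
def test_scale_invariance_of_ratio(d, a, af, k):
    """Multiplying all three channels of a pixel by k > 0 leaves the ratio unchanged."""
    sigs = tuple(
        SpectralSignature(species=sp, coefficients=np.array(c))
        for sp, c in (
            ("donor_fluor", (0.8, 0.2, 0.0)),
            ("acceptor_fluor", (0.05, 0.9, 0.05)),
            ("autofluorescence", (0.3, 0.2, 0.5)),
        )
    )
    M = build_mixing_matrix(*sigs)
    base = np.array([d, a, af]) @ M.matrix
    for scale in (1.0, k):
        px = base * scale
        acq = constant_acquisition(tuple(px), shape=(1, 1))
        um = unmix_image(acq, M, nonneg="nnls")
        fmap = compute_fret_map(um, min_intensity=1e-12)
        if scale == 1.0:
            ref = fmap.ratio[0, 0]
        else:
            np.testing.assert_allclose(fmap.ratio[0, 0], ref, rtol=1e-9)
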