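"""Pretreatment operators: SNV, MSC, SG derivative, min-max, chains."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirbran import (
    PretreatmentSpec,
    apply_chain,
    first_derivative,
    minmax,
    msc,
    snv,
)

spectra_arrays = st.lists(
    st.floats(-10, 10, allow_nan=False), min_size=5, max_size=40
).map(np.array).filter(lambda a: a.std(ddof=1) > 1e-6)


class TestSnv:
    def test_simple_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    @given(spectra_arrays)
    @settings(max_examples=50, deadline=None)
    def test_output_mean_zero_sd_one(self, x):
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    @given(spectra_arrays, st.floats(0.1, 5), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, x, a, b):
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(10, 2.0))


class TestMsc:
    def test_reference_itself_unchanged(self):
        ref = np.array([0.1, 0.4, 0.2, 0.6, 0.3])
        out, used = msc(ref, reference=ref)
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_exact_affine_scatter_removed(self):
        ref = np.array([0.1, 0.4, 0.2, 0.6, 0.3])
        out, _ = msc(2.0 * ref + 5.0, reference=ref)
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_slopes_match_hand_computed_ols(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(3, 5))
        corrected, ref = msc(X)
        np.testing.assert_allclose(ref, X.mean(axis=0))
        for i in range(3):
            slope, intercept = np.polyfit(ref, X[i], 1)
            np.testing.assert_allclose(corrected[i], (X[i] - intercept) / slope,
                                       atol=1e-10)

    def test_deterministic_under_row_order_with_explicit_reference(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(4, 6))
        ref = X.mean(axis=0)
        a, _ = msc(X, reference=ref)
        b, _ = msc(X[::-1], reference=ref)
        np.testing.assert_allclose(a, b[::-1], atol=1e-12)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            msc(np.array([[1.0, 2.0, 3.0]]), reference=np.full(3, 1.0))


class TestFirstDerivative:
    def test_constant_maps_to_zero(self):
        out = first_derivative(np.full(30, 2.5))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_linear_ramp_gives_slope(self):
        x = 0.3 * np.arange(40.0) + 1.0
        out = first_derivative(x)
        np.testing.assert_allclose(out, 0.3, atol=1e-10)

    def test_sine_matches_analytic_derivative(self):
        # slowly varying sine: interior SG derivative ~ cosine
        t = np.arange(500.0)
        freq = 2 * np.pi / 200.0
        x = np.sin(freq * t)
        out = first_derivative(x)
        expected = freq * np.cos(freq * t)
        interior = slice(20, -20)
        err = np.abs(out[interior] - expected[interior]).max()
        assert err < 0.01 * np.abs(expected).max()

    def test_output_length_preserved(self):
        assert first_derivative(np.arange(25.0)).size == 25

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            first_derivative(np.arange(30.0), window=16)
        with pytest.raises(ValueError, match="exceeds"):
            first_derivative(np.arange(10.0), window=17)


class TestMinmax:
    def test_simple_example(self):
        np.testing.assert_allclose(minmax(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0])

    @given(spectra_arrays)
    @settings(max_examples=50, deadline=None)
    def test_attains_both_endpoints(self, x):
        out = minmax(x)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_idempotent(self):
        x = np.array([0.3, 0.9, 0.1, 0.5])
        np.testing.assert_allclose(minmax(minmax(x)), minmax(x), atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax(np.full(5, 1.0))


class TestChains:
    def test_none_is_identity(self, small_pair):
        dr, _ = small_pair
        out, state = apply_chain(dr, PretreatmentSpec.from_name("none"))
        np.testing.assert_array_equal(out.absorbance, dr.absorbance)
        assert state == []

    def test_chain_error_names_step(self):
        # MSC cannot fit a reference from a single spectrum: fails at step 2
        one = np.sin(np.linspace(0, 3, 30))[None, :]
        with pytest.raises(ValueError, match=r"step 2 \(msc\)"):
            apply_chain(one, PretreatmentSpec.from_name("1st der + MSC"))

    def test_minmax_not_combinable(self):
        with pytest.raises(ValueError, match="block-level"):
            PretreatmentSpec(("minmax", "snv"))

    def test_stateless_chain_matches_pooled_application(self, small_pair):
        dr, _ = small_pair
        spec = PretreatmentSpec.from_name("SNV")
        cal, state = apply_chain(dr.absorbance[:20], spec)
        val, _ = apply_chain(dr.absorbance[20:], spec, state=state)
        pooled, _ = apply_chain(dr.absorbance, spec)
        np.testing.assert_allclose(val, pooled[20:], atol=1e-12)

    def test_msc_state_reused_for_new_samples(self, small_pair):
        dr, _ = small_pair
        spec = PretreatmentSpec.from_name("MSC")
        _, state = apply_chain(dr.absorbance[:20], spec)
        np.testing.assert_allclose(state[0], dr.absorbance[:20].mean(axis=0))
        one, _ = apply_chain(dr.absorbance[20:21], spec, state=state)
        again, _ = apply_chain(dr.absorbance[20:21], spec, state=state)
        np.testing.assert_array_equal(one, again)

    @pytest.mark.parametrize(
        "name", ["none", "1st der", "MSC", "SNV", "1st der + MSC", "1st der + SNV"]
    )
    def test_all_conditions_preserve_shape(self, small_pair, name):
        dr, _ = small_pair
        out, _ = apply_chain(dr, PretreatmentSpec.from_name(name))
        assert out.absorbance.shape == dr.absorbance.shape
        np.testing.assert_array_equal(out.wavenumbers, dr.wavenumbers)
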