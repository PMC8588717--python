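import numpy as np
import pytest

from ferrospec.harmonics import (
    PARAMETER_NAMES,
    component_target_correlation,
    decompositions_to_table,
    harmonic_decompose,
    harmonic_reconstruct,
    select_harmonic_parameters,
)


def decompose_oracle(v, order):
    """Naive double loop over k and h: the defining sums, written first."""
    n = len(v)
    remainder = sum(v) / n
    cos_amp, sin_amp = [], []
    for h in range(1, order + 1):
        a = 0.0
        b = 0.0
        for k in range(1, n + 1):
            a += v[k - 1] * np.cos(2 * np.pi * h * k / n)
            b += v[k - 1] * np.sin(2 * np.pi * h * k / n)
        cos_amp.append(2 * a / n)
        sin_amp.append(2 * b / n)
    return remainder, np.array(cos_amp), np.array(sin_amp)


class TestDecompose:
    def test_matches_double_loop_oracle(self, rng):
        v = rng.normal(size=15)
        dec = harmonic_decompose(v, 7)
        rem, a, b = decompose_oracle(v, 7)
        assert dec.remainder == pytest.approx(rem, rel=1e-12)
        np.testing.assert_allclose(dec.cos_amp, a, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(dec.sin_amp, b, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(dec.amplitude, np.hypot(a, b), rtol=1e-10)

    def test_constant_input_all_components_zero(self):
        dec = harmonic_decompose(np.full(12, 4.2), 5)
        assert dec.remainder == pytest.approx(4.2)
        np.testing.assert_allclose(dec.cos_amp, 0.0, atol=1e-12)
        np.testing.assert_allclose(dec.sin_amp, 0.0, atol=1e-12)
        np.testing.assert_allclose(dec.phase, 0.0)  # zero-amplitude convention

    def test_pure_fundamental_sine(self):
        n = 16
        k = np.arange(1, n + 1)
        dec = harmonic_decompose(np.sin(2 * np.pi * k / n), 3)
        assert dec.sin_amp[0] == pytest.approx(1.0, abs=1e-12)
        assert dec.cos_amp[0] == pytest.approx(0.0, abs=1e-12)
        assert dec.amplitude[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(dec.amplitude[1:], 0.0, atol=1e-12)

    def test_phase_quadrant_consistency(self, rng):
        """C_h sin(2*pi*h*k/N + phi_h) must reproduce the (A_h, B_h) term."""
        v = rng.normal(size=20)
        dec = harmonic_decompose(v, 9)
        n = dec.n_bands
        k = np.arange(1, n + 1)
        for idx in range(9):
            h = idx + 1
            angle = 2 * np.pi * h * k / n
            via_ab = dec.cos_amp[idx] * np.cos(angle) + dec.sin_amp[idx] * np.sin(angle)
            via_cphi = dec.amplitude[idx] * np.sin(angle + dec.phase[idx])
            np.testing.assert_allclose(via_cphi, via_ab, atol=1e-10)

    def test_phase_in_half_open_interval(self, rng):
        dec = harmonic_decompose(rng.normal(size=40), 19)
        assert np.all(dec.phase > -np.pi) and np.all(dec.phase <= np.pi)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            harmonic_decompose(np.zeros(1), 1)
        with pytest.raises(ValueError):
            harmonic_decompose(np.zeros(8), 0)


class TestReconstruct:
    def test_constant_reconstructs_for_any_order(self):
        dec = harmonic_decompose(np.full(10, 2.5), 4)
        for used in (1, 2, 4):
            np.testing.assert_allclose(harmonic_reconstruct(dec, used), 2.5, rtol=1e-12)

    def test_full_order_identity_odd_n(self, rng):
        v = rng.normal(size=15)
        dec = harmonic_decompose(v, 7)
        np.testing.assert_allclose(harmonic_reconstruct(dec, 7), v, rtol=1e-9, atol=1e-12)

    def test_rms_error_monotone_in_order(self, rng):
        v = rng.normal(size=64)
        dec = harmonic_decompose(v, 31)
        errors = [
            np.sqrt(np.mean((harmonic_reconstruct(dec, h) - v) ** 2))
            for h in range(1, 32)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))

    def test_order_beyond_decomposition_rejected(self, rng):
        dec = harmonic_decompose(rng.normal(size=10), 3)
        with pytest.raises(ValueError, match="exceeds"):
            harmonic_reconstruct(dec, 4)


class TestInvariants:
    def test_parseval_odd_n_full_order(self, rng):
        v = rng.normal(size=15)
        dec = harmonic_decompose(v, 7)
        lhs = dec.remainder**2 + 0.5 * np.sum(dec.amplitude**2)
        assert lhs == pytest.approx(np.mean(v**2), rel=1e-9)

    def test_aliasing_mirror(self, rng):
        """Orders h and N-h mirror: A_{N-h} = A_h, B_{N-h} = -B_h."""
        n = 30
        v = rng.normal(size=n)
        dec = harmonic_decompose(v, n - 1)
        for h in range(1, n // 2):
            assert dec.cos_amp[n - h - 1] == pytest.approx(dec.cos_amp[h - 1], abs=1e-10)
            assert dec.sin_amp[n - h - 1] == pytest.approx(-dec.sin_amp[h - 1], abs=1e-10)


class TestParameterSelection:
    def test_constant_input_parameter_vector(self):
        params = select_harmonic_parameters(harmonic_decompose(np.full(150, 1.3), 150))
        np.testing.assert_allclose(params[0], 1.3)
        np.testing.assert_allclose(params[1:], 0.0, atol=1e-12)

    def test_pure_fundamental_parameters(self):
        n = 150
        k = np.arange(1, n + 1)
        params = select_harmonic_parameters(harmonic_decompose(np.sin(2 * np.pi * k / n), n))
        names = dict(zip(PARAMETER_NAMES, params))
        assert names["B_1"] == pytest.approx(1.0, abs=1e-10)
        assert names["C_1"] == pytest.approx(1.0, abs=1e-10)
        for key in ("A_1", "A_2", "A_3", "B_2", "B_3", "C_2", "C_3"):
            assert names[key] == pytest.approx(0.0, abs=1e-10)

    def test_entries_match_decomposition_fields(self, rng):
        dec = harmonic_decompose(rng.normal(size=50), 10)
        params = select_harmonic_parameters(dec)
        expected = [dec.remainder,
                    *dec.cos_amp[:3], *dec.sin_amp[:3], *dec.amplitude[:3],
                    dec.phase[0], dec.phase[1]]
        np.testing.assert_allclose(params, expected, rtol=1e-12)

    def test_low_order_rejected(self, rng):
        with pytest.raises(ValueError, match="order"):
            select_harmonic_parameters(harmonic_decompose(rng.normal(size=10), 2))


class TestComponentCorrelation:
    def test_component_identical_to_target_r_one(self, rng):
        tics = np.array([18.0, 20.0, 22.0, 24.0, 26.0])
        decs = [harmonic_decompose(np.full(10, t), 3) for t in tics]
        table = component_target_correlation(decs, tics)
        row = table[table["component"] == "A0_2"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert not row["zero_variance"]

    def test_anticorrelated_component(self):
        tics = np.array([18.0, 20.0, 22.0, 24.0, 26.0])
        decs = [harmonic_decompose(np.full(10, -t), 3) for t in tics]
        table = component_target_correlation(decs, tics)
        assert table[table["component"] == "A0_2"].iloc[0]["r"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_nan(self):
        tics = np.array([18.0, 20.0, 22.0])
        decs = [harmonic_decompose(np.zeros(10), 3) for _ in tics]
        table = component_target_correlation(decs, tics)
        assert table["zero_variance"].all()
        assert np.isfinite(table["r"]).all()

    def test_matches_textbook_pearson(self, rng):
        tics = rng.uniform(10, 30, size=10)
        decs = [harmonic_decompose(rng.normal(size=20), 5) for _ in range(10)]
        table = component_target_correlation(decs, tics).set_index("component")
        cols = decompositions_to_table(decs)
        for name in cols.columns:
            x = cols[name].to_numpy()
            num = np.sum((x - x.mean()) * (tics - tics.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((tics - tics.mean()) ** 2))
            assert table.loc[name, "r"] == pytest.approx(num / den, rel=1e-10)
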