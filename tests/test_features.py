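import numpy as np
import pytest

from ergdwt import features as feat
from ergdwt.features import (
    BAND_LEVELS_2048,
    DEFAULT_WINDOWS_MS,
    CoefficientPyramid,
    DWTDescriptors,
    build_scalogram,
    extract_descriptors,
    haar_dwt,
    inverse_haar_dwt,
    percent_ops,
    time_domain_features,
)
from ergdwt.simulate import EpochSpec, ERGModelParams, synth_erg


def brute_force_haar(x):
    """Independent oracle: explicit inner products with the orthonormal
    discrete Haar basis (+1 on the first half of the support, -1 on the
    second, normalized), plus the constant scaling function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    depth = int(np.log2(n))
    levels = {}
    for j in range(1, depth + 1):
        width = 2**j
        coeffs = []
        for k in range(n // width):
            basis = np.zeros(n)
            basis[k * width : k * width + width // 2] = 1.0
            basis[k * width + width // 2 : (k + 1) * width] = -1.0
            basis /= np.sqrt(width)
            coeffs.append(basis @ x)
        levels[j] = np.array(coeffs)
    approx = np.array([x.sum() / np.sqrt(n)])
    return levels, approx


class TestHaarDWT:
    def test_known_small_signal(self):
        pyr = haar_dwt(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(pyr.levels[1], [-1 / np.sqrt(2), -1 / np.sqrt(2)])
        np.testing.assert_allclose(pyr.levels[2], [-2.0])
        np.testing.assert_allclose(pyr.approximation, [5.0])
        assert pyr.energy() == pytest.approx(30.0)

    def test_constant_signal_has_zero_details(self):
        pyr = haar_dwt(np.full(8, 5.0))
        for d in pyr.levels.values():
            np.testing.assert_array_equal(d, 0.0)

    @pytest.mark.parametrize("n", [8, 16, 32])
    def test_matches_brute_force_inner_products(self, n, rng):
        for _ in range(50):
            x = rng.normal(size=n)
            pyr = haar_dwt(x)
            levels, approx = brute_force_haar(x)
            for j, d in levels.items():
                np.testing.assert_allclose(pyr.levels[j], d, atol=1e-12)
            np.testing.assert_allclose(pyr.approximation, approx, atol=1e-12)

    def test_parseval_and_reconstruction(self, rng):
        for _ in range(25):
            x = rng.normal(size=256)
            pyr = haar_dwt(x)
            assert pyr.energy() == pytest.approx(np.sum(x**2), rel=1e-9)
            np.testing.assert_allclose(inverse_haar_dwt(pyr), x, rtol=1e-9, atol=1e-12)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            haar_dwt(np.zeros(250))


class TestScalogram:
    def test_band_segment_counts_and_widths(self):
        sc = build_scalogram(haar_dwt(np.zeros(256)))
        assert len(sc.bands[20]) == 4
        assert len(sc.bands[40]) == 8
        assert len(sc.bands[80]) == 16
        assert len(sc.bands[160]) == 32
        t0, t1, _ = sc.bands[20][0]
        assert t1 - t0 == pytest.approx(31.25)
        t0, t1, _ = sc.bands[160][0]
        assert t1 - t0 == pytest.approx(3.90625)

    def test_zero_signal_zero_magnitudes(self):
        sc = build_scalogram(haar_dwt(np.zeros(256)))
        assert all(m == 0.0 for segs in sc.bands.values() for _, _, m in segs)

    def test_segments_tile_epoch_without_overlap(self):
        sc = build_scalogram(haar_dwt(np.zeros(256)))
        for segs in sc.bands.values():
            starts = [s for s, _, _ in segs]
            ends = [e for _, e, _ in segs]
            assert starts[0] == pytest.approx(-20.0)
            assert ends[-1] == pytest.approx(105.0)
            np.testing.assert_allclose(ends[:-1], starts[1:])

    def test_unmapped_sampling_rate_needs_explicit_map(self):
        pyr = haar_dwt(np.zeros(256))
        pyr.sampling_rate_hz = 1000.0
        with pytest.raises(ValueError, match="band map"):
            build_scalogram(pyr)


def synthesize_single_coefficient(level, index, fs=2048.0, n=256):
    """Inverse-transform a pyramid holding a single unit coefficient."""
    depth = int(np.log2(n))
    levels = {j: np.zeros(n // 2**j) for j in range(1, depth + 1)}
    levels[level][index] = 1.0
    pyr = CoefficientPyramid(
        levels=levels,
        approximation=np.zeros(1),
        sampling_rate_hz=fs,
        epoch_start_ms=-20.0,
    )
    return inverse_haar_dwt(pyr)


class TestExtractDescriptors:
    def test_zero_signal_all_zero_and_pct_undefined(self):
        d = extract_descriptors(build_scalogram(haar_dwt(np.zeros(256))))
        assert all(
            getattr(d, k) == 0.0 for k in ("a20", "a40", "b20", "b40", "op80", "op160")
        )
        assert d.pct_ops is None

    @pytest.mark.parametrize("name", list(DEFAULT_WINDOWS_MS))
    @pytest.mark.parametrize("mode", ["max_abs", "rss", "sum_abs"])
    def test_single_coefficient_synthesis(self, name, mode):
        """A unit coefficient whose segment midpoint falls in window w of
        band b yields descriptor b=1 in w and 0 in every other descriptor."""
        center, (w0, w1) = DEFAULT_WINDOWS_MS[name]
        level = BAND_LEVELS_2048[center]
        width_ms = 2**level / 2048.0 * 1000.0
        mids = -20.0 + width_ms * (np.arange(256 // 2**level) + 0.5)
        inside = np.flatnonzero((mids >= w0) & (mids <= w1))
        k = int(inside[len(inside) // 2])
        x = synthesize_single_coefficient(level, k)
        d = extract_descriptors(build_scalogram(haar_dwt(x)), mode=mode)
        for other in DEFAULT_WINDOWS_MS:
            o_center, (o0, o1) = DEFAULT_WINDOWS_MS[other]
            expected = 1.0 if (o_center == center and o0 <= mids[k] <= o1) else 0.0
            assert getattr(d, other) == pytest.approx(expected, abs=1e-9), other

    @pytest.mark.parametrize("mode", ["max_abs", "rss", "sum_abs"])
    def test_positive_homogeneity(self, mode, rng):
        x = rng.normal(size=256)
        d1 = extract_descriptors(build_scalogram(haar_dwt(x)), mode=mode)
        d2 = extract_descriptors(build_scalogram(haar_dwt(2 * x)), mode=mode)
        for k in ("a20", "a40", "b20", "b40", "op80", "op160"):
            assert getattr(d2, k) == pytest.approx(2 * getattr(d1, k), rel=1e-9)

    def test_coefficients_outside_all_windows_ignored(self, rng):
        x = rng.normal(size=256)
        d1 = extract_descriptors(build_scalogram(haar_dwt(x)))
        # add a late-epoch (>55 ms) unit coefficient in each band level
        x2 = x.copy()
        for level in BAND_LEVELS_2048.values():
            x2 = x2 + synthesize_single_coefficient(level, 256 // 2**level - 1)
        d2 = extract_descriptors(build_scalogram(haar_dwt(x2)))
        for k in ("a20", "a40", "b20", "b40", "op80", "op160"):
            assert getattr(d2, k) == pytest.approx(getattr(d1, k), rel=1e-9)


class TestPercentOps:
    def test_equal_contributions_give_half(self):
        d = DWTDescriptors(a20=0, a40=0, b20=1, b40=1, op80=1, op160=1)
        assert percent_ops(d) == pytest.approx(50.0)

    def test_no_op_energy_gives_zero(self):
        d = DWTDescriptors(a20=0, a40=0, b20=2, b40=1, op80=0, op160=0)
        assert percent_ops(d) == pytest.approx(0.0)

    def test_arbitrary_values_direct_arithmetic(self):
        d = DWTDescriptors(a20=0, a40=0, b20=65.2, b40=55.5, op80=20.2, op160=10.8)
        expected = 100 * (20.2 + 10.8) / (65.2 + 55.5 + 20.2 + 10.8)
        assert percent_ops(d) == pytest.approx(expected)
        assert percent_ops(d) == pytest.approx(20.435, abs=0.001)

    def test_zero_denominator_undefined_not_raised(self):
        d = DWTDescriptors(a20=1, a40=1, b20=0, b40=0, op80=0, op160=0)
        assert percent_ops(d) is None

    def test_invariant_under_waveform_scaling(self, rng):
        x = np.abs(rng.normal(size=256)) + 0.1
        d1 = extract_descriptors(build_scalogram(haar_dwt(x)))
        d2 = extract_descriptors(build_scalogram(haar_dwt(5 * x)))
        assert percent_ops(d1) == pytest.approx(percent_ops(d2), rel=1e-9)


class TestTimeDomainFeatures:
    def test_designed_trough_and_peak(self):
        p = ERGModelParams(
            a_amp=10, a_time=15, a_width=3, b_amp=30, b_time=40, b_width=6,
            op_amp=0, noise_sd=0,
        )
        td = time_domain_features(synth_erg(p))
        assert td.a_amp == pytest.approx(10.0, rel=0.02)
        assert td.b_amp == pytest.approx(40.0, rel=0.02)  # trough-to-peak
        assert td.a_time_ms == pytest.approx(15.0, abs=1.0)
        assert td.b_time_ms == pytest.approx(40.0, abs=1.0)

    def test_zero_trace(self):
        rec = synth_erg(ERGModelParams(a_amp=0, b_amp=0, op_amp=0, noise_sd=0))
        td = time_domain_features(rec)
        assert td.a_amp == 0.0 and td.b_amp == 0.0

    def test_dc_shift_invariance(self):
        rec = synth_erg(ERGModelParams(noise_sd=0))
        shifted = synth_erg(ERGModelParams(noise_sd=0))
        shifted.amplitude_uv = shifted.amplitude_uv + 5.0
        td1, td2 = time_domain_features(rec), time_domain_features(shifted)
        assert td1.a_amp == pytest.approx(td2.a_amp)
        assert td1.b_amp == pytest.approx(td2.b_amp)

    def test_window_outside_epoch_rejected(self):
        rec = synth_erg(ERGModelParams(noise_sd=0))
        short = rec.time_ms <= 40.0
        from ergdwt.waveform_io import ERGRecording

        clipped = ERGRecording(
            "p", "control", "right", 1.0,
            rec.time_ms[short], rec.amplitude_uv[short], rec.sampling_rate_hz,
        )
        with pytest.raises(ValueError, match="windows"):
            time_domain_features(clipped)
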