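"""Diameter tracking, moving-average baseline and both pulsatility indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_trace, random_smooth_trace
from pvq.errors import ComputationError, ValidationError
from pvq.pulsatility import (
    Kymograph,
    batch_pulsatility,
    epoch_slices,
    extract_diameter_trace,
    moving_average_baseline,
    pulsatility_index,
    relative_pulsatility_index,
)
from pvq.synthetic import KymographSpec, make_kymograph

SINE_EPOCH_INTEGRAL = 3 * (2 / np.pi) * 1000.0  # integral of |sin(2 pi t / 1000)| over 3000 ms


def trapezoid_index_oracle(trace, epoch_ms=3000.0):
    """Independent brute-force check: trapezoidal integration of |D - d|
    over the same documented epoch layout."""
    dt = trace.line_period_ms
    n_epoch = int(round(epoch_ms / dt))
    half = int(round(trace.window_ms / dt)) // 2 if trace.window_ms else 0
    start = half if trace.n - 2 * half >= n_epoch else 0
    m = (trace.n - 2 * half) // n_epoch if start else trace.n // n_epoch
    dev = np.abs(trace.D_um - trace.d_um)
    sums = [
        np.trapezoid(dev[start + i * n_epoch : start + (i + 1) * n_epoch], dx=dt)
        for i in range(m)
    ]
    return float(np.mean(sums))


class TestDiameterExtraction:
    def test_constant_rectangular_lumen(self):
        """A 10-px-wide rectangular lumen at 0.5 um/px reads 5.0 um on every line."""
        img = np.full((41, 100), 100.0)
        img[15:25, :] = 1000.0
        kymo = Kymograph(img, pixel_size_um=0.5, line_period_ms=1.0)
        trace = extract_diameter_trace(kymo, temporal_cutoff_hz=None)
        assert trace.valid.all()
        assert trace.D_um == pytest.approx(5.0, abs=0.01)

    def test_sinusoid_subpixel_tracking(self):
        """Noiseless sinusoidal kymograph: every line within half a pixel of truth."""
        spec = KymographSpec(
            baseline_diameter_um=10.0, pulse_amplitude_um=1.0,
            pulse_frequency_hz=6.0, duration_ms=4000.0,
        )
        kymo, truth = make_kymograph(spec)
        trace = extract_diameter_trace(kymo)
        err_px = np.abs(trace.D_um - truth.D_um) / spec.pixel_size_um
        assert np.nanmax(err_px) <= 0.5

    def test_all_zero_image_rejected(self):
        kymo = Kymograph(np.zeros((31, 50)), pixel_size_um=0.5, line_period_ms=1.0)
        with pytest.raises(ComputationError, match="no detectable lumen"):
            extract_diameter_trace(kymo)

    def test_threshold_method_requires_level(self):
        kymo = Kymograph(np.ones((5, 5)), pixel_size_um=1.0, line_period_ms=1.0)
        with pytest.raises(ValidationError):
            extract_diameter_trace(kymo, method="threshold")


class TestMovingAverageBaseline:
    def test_constant_trace_baseline_is_constant(self):
        trace = moving_average_baseline(make_trace(np.full(2000, 7.5)), 300.0)
        assert trace.d_um == pytest.approx(7.5)

    def test_matches_direct_windowed_mean(self):
        """Interior samples equal the brute-force centered windowed mean."""
        rng = np.random.default_rng(0)
        trace = random_smooth_trace(rng, n=2000)
        window_ms = 250.0
        out = moving_average_baseline(trace, window_ms)
        half = int(round(window_ms / trace.line_period_ms)) // 2
        expected = np.array(
            [trace.D_um[i - half : i + half + 1].mean() for i in range(half, 2000 - half)]
        )
        np.testing.assert_allclose(out.d_um[half : 2000 - half], expected, atol=1e-6)

    def test_full_record_window_gives_global_mean_at_center(self):
        D = np.random.default_rng(1).uniform(5, 15, 1001)
        out = moving_average_baseline(make_trace(D), 1001.0)
        assert out.d_um[500] == pytest.approx(D.mean())

    def test_window_longer_than_record_rejected(self):
        with pytest.raises(ValidationError, match="longer than the record"):
            moving_average_baseline(make_trace(np.full(100, 5.0)), 500.0)


class TestPulsatilityIndex:
    def test_constant_vessel_gives_zero(self):
        trace = moving_average_baseline(make_trace(np.full(4000, 9.0)), 500.0)
        res = pulsatility_index(trace)
        assert res.pulsatility_index == pytest.approx(0.0, abs=1e-9)
        assert res.relative_pulsatility_index == pytest.approx(0.0, abs=1e-9)

    def test_sine_with_fixed_baseline_matches_rectified_integral(self):
        """D = 10 + sin(2 pi t / 1000), d fixed at 10: per-epoch index equals the
        numerically integrated |sin| over 3000 ms (analytically 3*(2/pi)*1000)."""
        t = np.arange(3000)
        D = 10.0 + np.sin(2 * np.pi * t / 1000.0)
        trace = make_trace(D, d=np.full(3000, 10.0))
        res = pulsatility_index(trace)
        oracle = trapezoid_index_oracle(trace)
        assert res.pulsatility_index == pytest.approx(oracle, rel=1e-3)
        assert res.pulsatility_index == pytest.approx(SINE_EPOCH_INTEGRAL, rel=3e-3)
        assert res.relative_pulsatility_index == pytest.approx(
            res.pulsatility_index / 10.0, rel=1e-9
        )

    def test_no_complete_epoch_raises(self):
        with pytest.raises(ComputationError, match="no complete"):
            pulsatility_index(make_trace(np.full(1000, 5.0), d=np.full(1000, 5.0)))

    def test_missing_baseline_raises(self):
        with pytest.raises(ValidationError, match="baseline"):
            pulsatility_index(make_trace(np.full(4000, 5.0)))

    def test_invalid_samples_renormalized_then_epoch_rejected(self):
        """A few flagged samples renormalize the sum; too many reject the epoch."""
        D = np.full(3000, 10.0) + 1.0
        trace = make_trace(D, d=np.full(3000, 10.0))
        trace.valid[:100] = False  # 3.3% < 5%: renormalized
        res = pulsatility_index(trace)
        assert res.pulsatility_index == pytest.approx(3000.0, rel=1e-9)
        trace.valid[:300] = False  # 10% > 5%: rejected
        with pytest.raises(ComputationError, match="rejected"):
            pulsatility_index(trace)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.1, 10.0))
    def test_homogeneity_and_relative_scale_invariance(self, seed, c):
        """Scaling D(t) by c scales the absolute index by c exactly and leaves
        the relative index unchanged."""
        rng = np.random.default_rng(seed)
        trace = moving_average_baseline(random_smooth_trace(rng), 500.0)
        scaled = moving_average_baseline(
            make_trace(trace.D_um * c, trace.line_period_ms), 500.0
        )
        res, res_c = pulsatility_index(trace), pulsatility_index(scaled)
        assert res_c.pulsatility_index == pytest.approx(c * res.pulsatility_index, rel=1e-9)
        assert res_c.relative_pulsatility_index == pytest.approx(
            res.relative_pulsatility_index, rel=1e-9
        )

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_time_reversal_invariance(self, seed):
        """Reversing the time axis leaves both indices unchanged (record sized so
        the epoch tiling is itself mirror-symmetric)."""
        rng = np.random.default_rng(seed)
        window_ms = 500.0
        n = 3000 + 2 * (int(round(window_ms)) // 2)
        trace = random_smooth_trace(rng, n=n)
        fwd = pulsatility_index(moving_average_baseline(trace, window_ms))
        rev = pulsatility_index(
            moving_average_baseline(make_trace(trace.D_um[::-1]), window_ms)
        )
        assert rev.pulsatility_index == pytest.approx(fwd.pulsatility_index, rel=1e-9)
        assert rev.relative_pulsatility_index == pytest.approx(
            fwd.relative_pulsatility_index, rel=1e-9
        )

    def test_epoch_layout_avoids_baseline_edges_when_possible(self):
        trace = moving_average_baseline(make_trace(np.full(4000, 5.0)), 500.0)
        slices, edges = epoch_slices(trace)
        assert not edges
        assert slices[0].start == int(round(500.0)) // 2
        short = moving_average_baseline(make_trace(np.full(3000, 5.0)), 500.0)
        _, edges_short = epoch_slices(short)
        assert edges_short  # record too short to avoid the shrunken-window edges


class TestRelativeIndex:
    def test_relative_index_is_absolute_over_static_mean(self):
        rng = np.random.default_rng(3)
        trace = moving_average_baseline(random_smooth_trace(rng), 500.0)
        res = relative_pulsatility_index(trace)
        assert res.relative_pulsatility_index == pytest.approx(
            res.pulsatility_index / trace.mean_D_um, rel=1e-12
        )


class TestBatch:
    def test_amplitude_ordering_and_single_vessel_consistency(self):
        kymos = []
        for i, amp in enumerate((0.0, 1.0)):
            spec = KymographSpec(pulse_amplitude_um=amp, duration_ms=4000.0, seed=i)
            kymo, _ = make_kymograph(spec)
            kymo.vessel_id = f"v{i}"
            kymos.append(kymo)
        table = batch_pulsatility(kymos)
        assert table.qc_pass.all()
        assert (
            table.loc[0, "pulsatility_index_um_ms"] < table.loc[1, "pulsatility_index_um_ms"]
        )
        single = batch_pulsatility([kymos[1]])
        trace = moving_average_baseline(extract_diameter_trace(kymos[1]), 500.0)
        expected = pulsatility_index(trace)
        assert single.loc[0, "pulsatility_index_um_ms"] == pytest.approx(
            expected.pulsatility_index
        )

    def test_empty_input_keeps_schema(self):
        table = batch_pulsatility([])
        assert table.empty
        assert "pulsatility_index_um_ms" in table.columns

    def test_failed_vessel_flagged_not_dropped(self):
        bad = Kymograph(np.zeros((31, 4000)), pixel_size_um=0.5, line_period_ms=1.0,
                        vessel_id="dead")
        table = batch_pulsatility([bad])
        assert len(table) == 1
        assert not table.loc[0, "qc_pass"]
        assert "lumen" in table.loc[0, "qc_note"]
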