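import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circabiolum import (PeakSet, PhaseShift, amplitude_response, build_prc,
                         entrainment_filter, expected_peak,
                         make_protocol, onset_ct, phase_shift,
                         phase_relationship_table, pick_peaks,
                         to_circadian_entrained, to_circadian_free_run)
from circabiolum.cosinor import CosinorResults

from .conftest import make_cosine_trace


def _fit(a=30.0, tau=24.0, theta=0.0, offset=100.0):
    return CosinorResults(a, tau, theta, offset, rss=0.0, nobs=100,
                          converged=True)


class TestPickPeaks:
    def test_exact_quadratic_vertex(self):
        t = np.arange(35.0, 65.0001, 0.5)
        v = -((t - 50.0) ** 2) + 100.0
        peaks = pick_peaks((t, v))
        assert len(peaks) == 1
        assert peaks.peak_times_h[0] == pytest.approx(50.0, abs=1e-9)

    def test_noiseless_cosine_peaks(self):
        tr = make_cosine_trace(a=30, tau=24, theta=0.0, offset=100,
                               duration_h=96)
        peaks = pick_peaks(tr)
        # interior true maxima at t = 24, 48, 72
        expected = np.array([24.0, 48.0, 72.0])
        assert len(peaks) >= 3
        for e in expected:
            assert np.min(np.abs(peaks.peak_times_h - e)) < 0.05

    def test_constant_trace_yields_empty_set(self):
        t = np.arange(0, 96.0001, 0.5)
        assert len(pick_peaks((t, np.full_like(t, 7.0)))) == 0

    def test_minimum_separation_enforced(self):
        tr = make_cosine_trace(a=30, tau=24, theta=0.0, offset=100,
                               duration_h=96, noise_sd=4.0, seed=9)
        peaks = pick_peaks(tr)
        assert np.all(np.diff(peaks.peak_times_h) >= 12.0 - 1e-9)


class TestCircadianTime:
    def test_reference_peak_maps_to_ct18(self):
        assert to_circadian_free_run(100.0, 24.0, 100.0) == pytest.approx(18.0)

    def test_six_hours_later_wraps_to_ct0(self):
        assert to_circadian_free_run(106.0, 24.0, 100.0) == pytest.approx(0.0)

    def test_short_period_rescaling(self):
        assert to_circadian_free_run(106.0, 20.0, 100.0) == pytest.approx(1.2)

    def test_non_circadian_tau_rejected(self):
        with pytest.raises(ValueError):
            to_circadian_free_run(106.0, 17.0, 100.0)

    def test_entrained_cold_end_is_ct12(self, t20_protocol):
        assert to_circadian_entrained(82.0, t20_protocol) == pytest.approx(12.0)
        # T-periodic: any later cold end too
        assert to_circadian_entrained(142.0, t20_protocol) == pytest.approx(12.0)

    def test_entrained_rescaling(self, t20_protocol, t24_protocol):
        assert to_circadian_entrained(87.0, t20_protocol) == pytest.approx(18.0)
        assert to_circadian_entrained(96.0, t24_protocol) == pytest.approx(0.0)

    def test_peak_outside_during_rejected(self, t20_protocol):
        with pytest.raises(ValueError):
            to_circadian_entrained(10.0, t20_protocol)

    @given(st.floats(72.0, 191.0))
    @settings(max_examples=50, deadline=None)
    def test_entrained_ct_is_cycle_periodic(self, t):
        prot = make_protocol(20, 10, 4, 6, 72)
        if t + 20.0 < prot.end_h:
            a = to_circadian_entrained(t, prot)
            b = to_circadian_entrained(t + 20.0, prot)
            assert a == pytest.approx(b, abs=1e-9)


class TestExpectedPeakAndShift:
    def test_expected_peak_examples(self):
        assert expected_peak(_fit(tau=24.0), 71.0) == pytest.approx(72.0)
        assert expected_peak(_fit(tau=20.0), 71.0) == pytest.approx(80.0)

    def test_rejected_fit_raises(self):
        bad = CosinorResults(30.0, 35.0, 0.0, 100.0, rss=0.0, nobs=10,
                             converged=True)
        with pytest.raises(ValueError):
            expected_peak(bad, 71.0)

    def test_shift_sign_convention(self):
        assert phase_shift(48.0, 52.0, 24.0) == pytest.approx(-4.0)  # delay
        assert phase_shift(48.0, 48.0, 24.0) == 0.0
        assert phase_shift(50.0, 48.0, 20.0) == pytest.approx(2.4)   # advance

    def test_shift_identity_on_grid(self):
        for tau in (18.0, 20.0, 24.0, 27.0, 30.0):
            for delta in np.linspace(-tau / 2 + 0.01, tau / 2 - 0.01, 21):
                got = phase_shift(100.0, 100.0 + delta, tau)
                assert got == pytest.approx(-delta * 24.0 / tau, abs=1e-12)

    def test_ambiguous_pairing_rejected(self):
        with pytest.raises(ValueError):
            phase_shift(48.0, 48.0 + 13.0, 24.0)

    def test_multiplication_mode_available(self):
        assert phase_shift(48.0, 52.0, 20.0, ct_mode="multiplication") \
            == pytest.approx(-4.0 * 20.0 / 24.0)


class TestOnsetCT:
    def test_examples(self):
        peaks = np.array([30.0, 54.0])
        assert onset_ct(54.0, peaks, 24.0) == pytest.approx(18.0)
        assert onset_ct(60.0, peaks, 24.0) == pytest.approx(0.0)
        assert onset_ct(74.0, peaks, 24.0) == pytest.approx(14.0)

    def test_no_preceding_peak_raises(self):
        with pytest.raises(ValueError):
            onset_ct(10.0, np.array([30.0]), 24.0)


class TestEntrainmentFilter:
    @pytest.mark.parametrize("tau, accept", [(20.4, True), (21.5, False),
                                             (21.0, True), (19.0, True)])
    def test_tolerance_band(self, t20_protocol, tau, accept):
        assert entrainment_filter(_fit(tau=tau), t20_protocol) is accept


class TestPrcAssembly:
    def test_group_means_arithmetic(self):
        shifts = [PhaseShift("a", 0, 0, 24, -3.0, 8.0),
                  PhaseShift("b", 0, 0, 24, -5.0, 12.0),
                  PhaseShift("c", 0, 0, 24, 2.0, 20.0)]
        prc = build_prc(shifts)
        assert prc["groups"]["delay"]["mean"] == pytest.approx(-4.0)
        assert prc["groups"]["advance"]["mean"] == pytest.approx(2.0)

    def test_all_zero_shifts_not_significant(self):
        shifts = [PhaseShift(str(i), 0, 0, 24, 0.0, ct)
                  for i, ct in enumerate([2.0, 8.0, 10.0, 14.0, 20.0, 23.0])]
        prc = build_prc(shifts)
        assert prc["groups"]["delay"]["mean"] == 0.0
        assert prc["groups"]["advance"]["mean"] == 0.0
        assert not (prc["p_value"] < 0.05)  # nan or 1: not significant

    def test_empty_group_flagged(self):
        shifts = [PhaseShift(str(i), 0, 0, 24, -3.0, 8.0 + i) for i in range(4)]
        prc = build_prc(shifts)
        assert not prc["groups"]["advance"]["defined"]


class TestAmplitudeResponse:
    def test_identical_fits_give_unity(self):
        raw = np.full(8, 100.0)
        assert amplitude_response(_fit(a=10), _fit(a=10), raw, raw) \
            == pytest.approx(1.0)

    def test_doubled_amplitude(self):
        raw = np.full(8, 100.0)
        assert amplitude_response(_fit(a=10), _fit(a=20), raw, raw) \
            == pytest.approx(2.0)


class TestPhaseRelationship:
    def _peaks_at(self, cell, times):
        return PeakSet(cell, np.asarray(times), np.ones(len(times)))

    def test_peaks_on_cold_onsets_give_zero_slope(self, t20_protocol):
        peaks = {f"c{i}": self._peaks_at(f"c{i}", [152.0, 172.0])
                 for i in range(4)}
        taus = {f"c{i}": 22.0 + i for i in range(4)}
        out = phase_relationship_table(peaks, t20_protocol, taus)
        assert np.allclose(out["table"]["lag_h"], 0.0)
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_linear_lag_recovered_exactly(self, t20_protocol):
        peaks, taus = {}, {}
        for i, tau in enumerate([22.0, 23.0, 25.0, 26.0]):
            lag = 2.0 * (tau - 24.0)
            peaks[f"c{i}"] = self._peaks_at(f"c{i}", [152.0 + lag, 172.0 + lag])
            taus[f"c{i}"] = tau
        out = phase_relationship_table(peaks, t20_protocol, taus)
        assert out["slope"] == pytest.approx(2.0, abs=1e-9)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_cells_with_missing_peaks_dropped(self, t20_protocol):
        peaks = {"good": self._peaks_at("good", [152.0, 172.0]),
                 "bad": self._peaks_at("bad", [100.0])}
        taus = {"good": 24.0, "bad": 24.0}
        out = phase_relationship_table(peaks, t20_protocol, taus)
        assert list(out["table"]["cell_id"]) == ["good"]
        assert out["dropped"][0]["cell_id"] == "bad"
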