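"""Parameter computations against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from semiogram import features
from semiogram.exceptions import GaitError, InsufficientDataError
from semiogram.features import ParameterSet
from semiogram.segmentation import FEET, GaitEvents, UTurnInterval


def _toy_seg(uturn=(5.7, 6.3), span=12.0, T=1.0, t0=1.0, n=10, swing=0.4):
    ic = {
        FEET[0]: t0 + T * np.arange(n),
        FEET[1]: t0 + T / 2 + T * np.arange(n),
    }
    fc = {f: ic[f] - swing for f in FEET}
    ev = GaitEvents(ic=ic, fc=fc)
    ut = UTurnInterval(start=uturn[0], end=uturn[1],
                       time=np.arange(0, span, 0.01),
                       angle_trace=np.zeros(int(span * 100)))
    from semiogram.segmentation import segment_trial
    return segment_trial(ev, ut, (0.0, span))


class TestSpatioTemporal:
    def test_velocity_arithmetic(self):
        # events spanning 25 s with a 5 s U-turn over 20 m -> 1 m/s
        seg = _toy_seg()
        # craft explicit spans: first event at 0.6, last at 25.6
        ev = seg.events
        ev.fc[FEET[0]][0] = 0.6
        ev.ic[FEET[1]][-1] = 25.6
        seg.uturn.start, seg.uturn.end = 10.0, 15.0
        assert features.velocity(seg, 20.0) == pytest.approx(1.0)

    def test_velocity_rejects_impossible_turn(self):
        seg = _toy_seg()
        seg.uturn.start, seg.uturn.end = 0.0, 50.0
        with pytest.raises(GaitError, match="invalid segmentation"):
            features.velocity(seg, 20.0)

    def test_stride_time_on_exact_grid(self):
        seg = _toy_seg(T=1.1)
        assert features.stride_time(seg) == pytest.approx(1.1, abs=1e-12)

    def test_uturn_time(self):
        ut = UTurnInterval(start=12.0, end=14.6, time=np.zeros(1),
                           angle_trace=np.zeros(1))
        assert features.uturn_time(ut) == pytest.approx(2.6)

    def test_step_length_hand_value(self):
        seg = _toy_seg()
        seg.steps = np.arange(29, dtype=float)
        assert features.step_length(seg, 20.0) == pytest.approx(0.6897, abs=1e-4)
        seg.steps = np.arange(58, dtype=float)
        assert features.step_length(seg, 20.0) == pytest.approx(20.0 / 58)


class TestVariationCoefficient:
    def test_constant_series_is_zero(self):
        assert features.variation_coefficient([2.0, 2.0, 2.0]) == 0.0

    def test_hand_value(self):
        got = features.variation_coefficient([1.0, 1.1, 1.2])
        assert got == pytest.approx(100 * 0.1 / 1.1, abs=1e-10)

    def test_scale_invariance(self, rng):
        x = rng.uniform(0.5, 1.5, size=20)
        a = features.variation_coefficient(x)
        b = features.variation_coefficient(3.7 * x)
        assert a == pytest.approx(b, rel=1e-12)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            features.variation_coefficient([1.0, 1.1])


class TestSparc:
    @staticmethod
    def _sinusoid_oracle(f0, fs, n, padlevel, oversample=10):
        """Closed-form DTFT magnitude of a finite sinusoid, evaluated on a
        grid ``oversample`` x finer than the implementation's, and its arc
        length under the same cutoff rule."""
        h = 1.0 / fs
        nfft = int(2 ** np.ceil(np.log2(n) + padlevel))
        df = fs / nfft / oversample
        f = np.arange(0, 20.0 + df, df)

        def G(nu):
            den = np.sin(np.pi * nu * h)
            safe = np.where(np.abs(den) < 1e-12, 1.0, den)
            D = np.where(np.abs(den) < 1e-12, float(n),
                         np.sin(np.pi * nu * n * h) / safe)
            return np.exp(1j * np.pi * nu * (n - 1) * h) * D

        m = np.abs((G(f0 - f) - G(-f0 - f)) / 2j)
        m /= m.max()
        above = np.nonzero(m >= 0.05)[0]
        f, m = f[: above[-1] + 1], m[: above[-1] + 1]
        frange = f[-1] - f[0]
        return -float(np.sum(np.hypot(np.diff(f) / frange, np.diff(m))))

    def test_matches_oversampled_closed_form_on_sinusoid(self):
        fs, n = 100.0, 1000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        got = features.sparc(x, fs, padlevel=12)
        assert got == pytest.approx(
            self._sinusoid_oracle(1.0, fs, n, padlevel=12), abs=1e-3
        )

    def test_added_high_frequency_is_less_smooth(self):
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        pure = features.sparc(np.sin(2 * np.pi * t), fs)
        mixed = features.sparc(
            np.sin(2 * np.pi * t) + 0.5 * np.sin(2 * np.pi * 8 * t), fs
        )
        assert mixed < pure

    def test_zero_signal_rejected(self):
        with pytest.raises(GaitError, match="degenerate"):
            features.sparc(np.zeros(1000), 100.0)

    def test_healthy_trial_in_reference_band(self, healthy_results):
        assert -5.37 - 3 * 0.84 <= healthy_results.params.SPARC_G <= -5.37 + 3 * 0.84


class TestLdlj:
    def test_exact_discrete_closed_form(self):
        """Unfiltered sinusoid matches the hand-derived discrete value."""
        fs, T = 100.0, 10.0
        h = 1 / fs
        n = int(T * fs)
        t = np.arange(n) * h
        a = np.sin(2 * np.pi * t)
        # centred differences: j_n = cos(2*pi*t_n) * sin(2*pi*h)/h (interior)
        C = math.sin(2 * math.pi * h) / h
        # sum of cos^2 over the full lattice is exactly n/2
        interior = C * C * (n / 2 - math.cos(0.0) ** 2
                            - math.cos(2 * math.pi * t[-1]) ** 2)
        j0 = math.sin(2 * math.pi * h) / h  # one-sided at the start
        jl = (math.sin(2 * math.pi * t[-1])
              - math.sin(2 * math.pi * t[-2])) / h
        integral = h * (0.5 * j0 ** 2 + interior + 0.5 * jl ** 2)
        expected = -math.log(T * integral / 1.0 ** 2)
        got = features.ldlj(a, fs, lowpass=None)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_white_jerk_noise_is_less_smooth(self, rng):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        a = np.sin(2 * np.pi * t)
        noisy = a + 0.2 * rng.standard_normal(t.size)
        assert features.ldlj(noisy, fs) < features.ldlj(a, fs)

    def test_zero_signal_rejected(self):
        with pytest.raises(GaitError, match="degenerate"):
            features.ldlj(np.zeros(1000), 100.0)

    def test_healthy_trial_in_reference_band(self, healthy_results):
        assert -8.07 - 3 * 0.35 <= healthy_results.params.LDLJ_A <= -8.07 + 3 * 0.35


class TestAutocorrelation:
    def _oracle(self, x, max_lag):
        x = np.asarray(x, float) - np.mean(x)
        n = x.size
        denom = sum(v * v for v in x) / n
        out = []
        for k in range(max_lag + 1):
            acc = 0.0
            for i in range(n - k):
                acc += x[i] * x[i + k]
            out.append(acc / (n - k) / denom)
        return np.array(out)

    def test_matches_dot_product_oracle(self, rng):
        x = rng.standard_normal(400)
        got = features.unbiased_autocorrelation(x, 120)
        np.testing.assert_allclose(got, self._oracle(x, 120), atol=1e-9)

    def test_periodic_signal_has_unit_peaks(self):
        fs = 100.0
        t = np.arange(0, 22, 1 / fs)
        x = np.cos(2 * np.pi * 4 * t)  # identical steps: period = step time
        p1, p2 = features.autocorr_peaks(x, fs, step_lag=0.25, stride_lag=0.5)
        assert p1 == pytest.approx(1.0, abs=1e-6)
        assert p2 == pytest.approx(1.0, abs=1e-6)

    def test_alternating_step_amplitudes_rank_p2_above_p1(self):
        fs = 100.0
        t = np.arange(0, 30, 1 / fs)
        # step-frequency content plus stride-locked amplitude alternation
        x = np.cos(2 * np.pi * 2 * t) * (1 + 0.4 * np.cos(2 * np.pi * 1 * t))
        p1, p2 = features.autocorr_peaks(x, fs, step_lag=0.5, stride_lag=1.0)
        assert p2 > p1


class TestRms:
    def test_zero_signal(self):
        assert features.rms_ml(np.zeros(500), [(0, 500)]) == 0.0

    def test_sinusoid_whole_periods(self):
        t = np.arange(0, 10, 0.01)
        x = 2.5 * np.sin(2 * np.pi * t)
        assert features.rms_ml(x, [(0, 1000)]) == pytest.approx(
            2.5 / math.sqrt(2), abs=1e-6
        )

    def test_constant_offset_is_not_removed(self):
        x = np.full(500, -0.7)
        assert features.rms_ml(x, [(0, 500)]) == pytest.approx(0.7)


def _harmonic_signal(fs, stride_t, n_strides, harmonics):
    n = int(round(stride_t * fs))
    t = np.arange(n * n_strides) / fs
    x = np.zeros_like(t)
    for k, a in harmonics.items():
        x += a * np.cos(2 * np.pi * k * t / stride_t)
    strides = [("left_foot", i * stride_t, (i + 1) * stride_t)
               for i in range(n_strides)]
    return x, strides


class TestIhr:
    def test_pure_intrinsic_is_100(self):
        x, strides = _harmonic_signal(100.0, 1.1, 4, {2: 1.0, 4: 0.5})
        assert features.ihr(x, 100.0, strides, "AP") == pytest.approx(100.0)

    def test_pure_extrinsic_is_0(self):
        x, strides = _harmonic_signal(100.0, 1.1, 4, {1: 1.0})
        assert features.ihr(x, 100.0, strides, "AP") == pytest.approx(0.0, abs=1e-8)

    def test_equal_power_mix_is_50(self):
        x, strides = _harmonic_signal(100.0, 1.1, 4, {1: 0.8, 2: 0.8})
        assert features.ihr(x, 100.0, strides, "AP") == pytest.approx(50.0, abs=1e-6)

    def test_ml_axis_uses_odd_harmonics(self):
        x, strides = _harmonic_signal(100.0, 1.1, 4, {1: 1.0, 3: 0.5})
        assert features.ihr(x, 100.0, strides, "ML") == pytest.approx(100.0)

    def test_matches_brute_force_fourier_series(self, rng):
        fs, stride_t = 100.0, 1.2
        n = int(stride_t * fs)
        x = rng.standard_normal(4 * n)
        strides = [("left_foot", i * stride_t, (i + 1) * stride_t)
                   for i in range(4)]
        got = features.ihr(x, fs, strides, "CC")

        vals = []
        for _, a, b in strides:
            seg = x[int(round(a * fs)):int(round(b * fs))]
            seg = seg - seg.mean()
            m = seg.size
            even = odd = 0.0
            for k in range(1, 21):
                c = sum(seg[j] * math.cos(2 * math.pi * k * j / m)
                        for j in range(m))
                s = sum(seg[j] * math.sin(2 * math.pi * k * j / m)
                        for j in range(m))
                p = c * c + s * s
                if k % 2 == 0:
                    even += p
                else:
                    odd += p
            vals.append(100.0 * even / (even + odd))
        assert got == pytest.approx(np.mean(vals), abs=1e-6)


class TestBilateralTiming:
    def test_equal_swings_give_unit_ratio(self):
        seg = _toy_seg()
        swtr, p1p2 = features.symmetry_ratios(seg.events, seg, 0.9, 0.9)
        assert swtr == pytest.approx(1.0)
        assert p1p2 == pytest.approx(1.0)

    def test_hand_swing_ratio(self):
        seg = _toy_seg()
        # left swings 0.50, right swings 0.40
        seg.events.fc[FEET[0]] = seg.events.ic[FEET[0]] - 0.5
        seg.events.fc[FEET[1]] = seg.events.ic[FEET[1]] - 0.4
        swtr, _ = features.symmetry_ratios(seg.events, seg, 0.8, 0.9)
        assert swtr == pytest.approx(0.8, abs=1e-9)

    def test_p1p2_hand_value(self):
        seg = _toy_seg()
        _, p1p2 = features.symmetry_ratios(seg.events, seg, 0.8, 0.9)
        assert p1p2 == pytest.approx(0.8 / 0.9)

    def test_zero_p2_rejected(self):
        seg = _toy_seg()
        with pytest.raises(GaitError, match="undefined"):
            features.symmetry_ratios(seg.events, seg, 0.8, 0.0)

    def test_double_stance_hand_value(self):
        # cycle 1.0 s; contralateral FC 0.12 after each IC -> ds1 = ds2 = 0.12
        seg = _toy_seg(swing=0.38)  # FC = IC - 0.38 -> contra FC at IC + 0.12
        dst, series = features.double_stance(seg.events, seg)
        assert dst == pytest.approx(24.0, abs=1e-9)
        assert np.allclose(series, 24.0)

    def test_double_stance_ground_truth(self, healthy_trial):
        trial, truth = healthy_trial
        assert np.mean(truth.double_stance_pct) == pytest.approx(
            truth.commanded["dstT"], abs=1.5
        )


class TestComputeAll:
    def test_determinism(self, healthy_trial):
        trial, _ = healthy_trial
        p1, _ = features.compute_all(trial)
        p2, _ = features.compute_all(trial)
        assert p1.to_dict() == p2.to_dict()

    def test_invariants_hold(self, healthy_results):
        p = healthy_results.params
        for name in ("iHR_aAP", "iHR_aML", "iHR_aCC"):
            assert 0.0 <= getattr(p, name) <= 100.0
        assert 0.0 < p.swTr <= 1.0
        assert 0.0 < p.dstT < 100.0
        assert p.CV_StrT >= 0 and p.CV_dstT >= 0
        for name in ("V", "StrT", "UtrT", "SteL", "RMS_aML"):
            assert getattr(p, name) > 0

    def test_mirror_symmetry(self, healthy_trial):
        from semiogram import imu
        trial, _ = healthy_trial
        swapped = imu.ImuTrial(
            sample_rate=trial.sample_rate,
            sensors={
                "left_foot": trial.sensor("right_foot"),
                "right_foot": trial.sensor("left_foot"),
                "lower_back": trial.sensor("lower_back"),
            },
        )
        a, _ = features.compute_all(trial)
        b, _ = features.compute_all(swapped)
        for k, v in a.to_dict().items():
            assert b.to_dict()[k] == pytest.approx(v, rel=1e-9), k

    def test_table_reference_band(self, healthy_results):
        from semiogram import ReferenceStats
        ref = ReferenceStats.default()
        for k, v in healthy_results.params.to_dict().items():
            z = abs(v - ref.mean[k]) / ref.sd[k]
            assert z <= 3.0, f"{k}: {v} vs {ref.mean[k]} +- {ref.sd[k]}"

    def test_path_length_scaling(self, healthy_trial):
        trial, _ = healthy_trial
        p20, _ = features.compute_all(trial, 20.0)
        p40, _ = features.compute_all(trial, 40.0)
        assert p40.V == pytest.approx(2 * p20.V)
        assert p40.SteL == pytest.approx(2 * p20.SteL)

    def test_parameter_set_serialisation_round_trip(self, healthy_results):
        p = healthy_results.params
        row = p.to_csv_row()
        assert list(row.columns) == list(features.PARAMETER_NAMES)
        back = ParameterSet.from_dict(row.iloc[0].to_dict())
        assert back.to_dict() == p.to_dict()

    def test_incomplete_dict_rejected(self):
        with pytest.raises(GaitError, match="incomplete"):
            ParameterSet.from_dict({"V": 1.0})
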