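import numpy as np
import pytest
from scipy import signal as sps

import fasd_eeg as fe
from fasd_eeg.core import ParameterError


class TestBackground:
    def test_white_case_unit_variance(self):
        rec = fe.generate_background(60, 250, 3, spectral_exponent=0.0, seed=2)
        assert rec.samples.var(axis=1) == pytest.approx(1.0, rel=0.05)

    def test_determinism(self):
        a = fe.generate_background(5, 250, 2, 1.0, seed=9)
        b = fe.generate_background(5, 250, 2, 1.0, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_pink_loglog_slope(self):
        rec = fe.generate_background(60, 250, 8, spectral_exponent=1.0, seed=3)
        f, p = sps.welch(rec.samples, fs=250, nperseg=2048)
        m = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log(f[m]), np.log(p[:, m].mean(axis=0)), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            fe.generate_background(0, 250, 2)
        with pytest.raises(ParameterError):
            fe.generate_background(10, -1, 2)


class TestBandOscillation:
    def test_zero_variance_is_noop(self):
        rec = fe.generate_background(5, 250, 2, 0.0, seed=1)
        out = fe.add_band_oscillation(rec, 7, 12, 0.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_power_lands_in_band(self):
        zero = fe.Recording("z", np.zeros((1, 15000)), 250.0, ("a",))
        out = fe.add_band_oscillation(zero, 7, 12, 4.0, seed=4)
        f, p = sps.periodogram(out.samples[0], fs=250)
        frac = p[(f >= 6) & (f <= 13)].sum() / p.sum()
        assert frac >= 0.95
        assert out.samples[0].var() == pytest.approx(4.0, rel=1e-9)

    def test_independent_components_add(self):
        zero = fe.Recording("z", np.zeros((2, 15000)), 250.0, ("a", "b"))
        out = fe.add_band_oscillation(zero, 7, 12, 3.0, seed=5)
        out = fe.add_band_oscillation(out, 12, 30, 2.0, seed=6)
        assert out.samples.var(axis=1) == pytest.approx(5.0, rel=0.10)

    def test_band_outside_nyquist_rejected(self):
        zero = fe.Recording("z", np.zeros((1, 1000)), 250.0, ("a",))
        with pytest.raises(ParameterError):
            fe.add_band_oscillation(zero, 100, 130, 1.0)


class TestBlinks:
    def test_rate_zero_is_noop(self):
        rec = fe.Recording("s", np.zeros((2, 2500)), 250.0, ("Fp1-F3", "F3-C3"))
        out, times = fe.inject_blinks(rec, 0.0, 100.0)
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert times.size == 0

    def test_event_count_in_poisson_range(self):
        rec = fe.Recording("s", np.zeros((1, 15000)), 250.0, ("Fp2-F8",))
        # Poisson(12): central 99.8% well inside [4, 24]
        counts = [
            fe.inject_blinks(rec, 12.0, 100.0, seed=s)[1].size for s in range(50)
        ]
        assert all(4 <= c <= 24 for c in counts)

    def test_only_frontopolar_channels_touched(self):
        rec = fe.Recording(
            "s", np.zeros((3, 5000)), 250.0, ("Fp2-F8", "F8-T4", "Cz-Pz")
        )
        out, times = fe.inject_blinks(rec, 20.0, 50.0, seed=1)
        assert times.size > 0
        np.testing.assert_array_equal(out.samples[1], 0.0)
        np.testing.assert_array_equal(out.samples[2], 0.0)
        assert out.samples[0].max() >= 50.0 * 0.9
        assert out.samples[0].min() >= 0.0  # positive-going transient


class TestCohort:
    def test_sizes_and_labels(self, tiny_cohort, tiny_config):
        assert len(tiny_cohort) == tiny_config.n_control + tiny_config.n_fasd
        labels = [r.label for r in tiny_cohort]
        assert labels.count("control") == tiny_config.n_control
        assert labels.count("fasd") == tiny_config.n_fasd
        assert all(r.channel_labels == fe.DOUBLE_BANANA_18 for r in tiny_cohort)

    def test_bit_reproducible(self, tiny_config, tiny_cohort):
        again = fe.generate_cohort(tiny_config)
        for a, b in zip(tiny_cohort, again):
            np.testing.assert_array_equal(a.samples, b.samples)
            assert a.subject_id == b.subject_id and a.label == b.label

    def test_alpha_reduction_scales_alpha_power(self):
        # isolate the alpha scaling: no background, no subject variability
        cfg = fe.SimConfig(
            n_control=12,
            n_fasd=12,
            duration_s=20.0,
            background_rms=0.0,
            alpha_reduction=0.5,
            blink_rate={"control": 0.0, "fasd": 0.0},
            subject_sigma=0.0,
            channel_sigma=0.0,
            seed=21,
        )
        cohort = fe.generate_cohort(cfg)

        def alpha_power(rec):
            band = np.vstack(
                [fe.bandpass(ch, 7, 12, rec.fs) for ch in rec.samples]
            )
            return band.var(axis=1).mean()

        ctl = np.mean([alpha_power(r) for r in cohort if r.label == "control"])
        fasd = np.mean([alpha_power(r) for r in cohort if r.label == "fasd"])
        assert fasd / ctl == pytest.approx(0.5, rel=0.10)

    def test_power_accounting(self):
        cfg = fe.SimConfig(
            n_control=1,
            n_fasd=1,
            duration_s=60.0,
            blink_rate={"control": 0.0, "fasd": 0.0},
            subject_sigma=0.0,
            channel_sigma=0.0,
            seed=5,
        )
        rec = fe.generate_cohort(cfg)[0]
        expected = cfg.background_rms**2 + sum(cfg.band_powers.values())
        assert rec.samples.var(axis=1).mean() == pytest.approx(expected, rel=0.10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            fe.SimConfig(n_control=0)
        with pytest.raises(ParameterError):
            fe.SimConfig(alpha_reduction=1.0)
        with pytest.raises(ParameterError):
            fe.SimConfig(band_powers={"alpha": -1.0})
        with pytest.raises(ParameterError):
            fe.SimConfig(fs=80.0)  # below twice the top gamma edge

    def test_yaml_round_trip(self, tmp_path, tiny_config):
        path = tmp_path / "sim.yaml"
        tiny_config.to_yaml(path)
        back = fe.SimConfig.from_yaml(path)
        assert back == tiny_config

    def test_null_variant_removes_class_effect(self, tiny_config):
        null = tiny_config.null_variant()
        assert null.alpha_reduction == 0.0
        assert null.blink_rate["control"] == null.blink_rate["fasd"]
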