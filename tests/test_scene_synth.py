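import numpy as np
import pytest
from scipy.signal import welch

from bicisim import (
    BinauralScene,
    Interferer,
    SourceSpec,
    make_noise,
    make_speech_like,
    make_tone,
    render_scene,
)
from bicisim.scene_synth import SceneError

RATE = 16000.0


class TestMakeTone:
    def test_3s_at_16khz_has_48000_samples(self):
        assert make_tone(440.0, 3.0).n_samples == 48000

    def test_spectral_peak_at_requested_frequency(self):
        sig = make_tone(1250.0, 1.0)
        spectrum = np.abs(np.fft.rfft(sig.samples))
        freqs = np.fft.rfftfreq(sig.n_samples, 1.0 / RATE)
        assert freqs[np.argmax(spectrum)] == pytest.approx(1250.0, abs=1.0)

    def test_zero_crossing_count(self):
        sig = make_tone(440.0, 3.0)
        crossings = np.sum(np.diff(np.signbit(sig.samples)) != 0)
        assert crossings == pytest.approx(2 * 440 * 3, rel=0.01)

    def test_above_nyquist_rejected(self):
        with pytest.raises(SceneError):
            make_tone(8000.0, 1.0)

    def test_ramps_attenuate_endpoints(self):
        sig = make_tone(440.0, 1.0)
        assert np.max(np.abs(sig.samples[:20])) < 0.1
        assert np.max(np.abs(sig.samples[-20:])) < 0.1
        assert np.max(np.abs(sig.samples)) == pytest.approx(1.0, abs=1e-3)


class TestMakeNoise:
    def test_deterministic_given_seed(self):
        a = make_noise("SSN", 0.5, RATE, seed=9)
        b = make_noise("SSN", 0.5, RATE, seed=9)
        assert np.array_equal(a.samples, b.samples)
        c = make_noise("babble", 0.5, RATE, seed=9)
        d = make_noise("babble", 0.5, RATE, seed=9)
        assert np.array_equal(c.samples, d.samples)

    def test_unit_rms(self):
        for kind in ("SSN", "babble"):
            sig = make_noise(kind, 1.0, RATE, seed=1)
            assert np.sqrt(np.mean(sig.samples**2)) == pytest.approx(1.0)

    def test_ssn_spectrum_falls_above_500_hz(self):
        sig = make_noise("SSN", 4.0, RATE, seed=5)
        f, p = welch(sig.samples, RATE, nperseg=2048)
        p_db = 10 * np.log10(p)
        i500 = np.argmin(np.abs(f - 500.0))
        i2k = np.argmin(np.abs(f - 2000.0))
        i4k = np.argmin(np.abs(f - 4000.0))
        assert p_db[i2k] < p_db[i500] - 5.0
        assert p_db[i4k] < p_db[i2k] - 5.0

    def test_unknown_type_rejected(self):
        with pytest.raises(SceneError):
            make_noise("pink", 1.0, RATE, seed=0)

    def test_speech_like_is_modulated(self):
        sig = make_speech_like(2.0, RATE, seed=3)
        env = np.abs(sig.samples)
        frame = int(0.05 * RATE)
        frames = env[: len(env) // frame * frame].reshape(-1, frame).mean(axis=1)
        assert frames.std() / frames.mean() > 0.2


class TestRenderScene:
    def test_zero_azimuth_gives_identical_ears(self):
        scene = BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=0.0)
        sig = render_scene(scene, duration=0.5, seed=0)
        assert np.allclose(sig.samples[:, 0], sig.samples[:, 1])

    @staticmethod
    def _raw_lag(sig, window):
        """Cross-correlation lag of the raw ears, restricted to |lag|<=window.

        The restriction resolves the periodic ambiguity of a sustained tone
        (correlation peaks recur every carrier period).
        """
        l, r = sig.samples[:, 0], sig.samples[:, 1]
        corr = np.correlate(r - r.mean(), l - l.mean(), "full")
        lags = np.arange(-(len(l) - 1), len(l))
        mask = np.abs(lags) <= window
        return lags[mask][np.argmax(corr[mask])]

    def test_neg90_left_leads_by_itd_at_90(self):
        scene = BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=-90.0)
        sig = render_scene(scene, duration=1.0, seed=0)
        lag = self._raw_lag(sig, window=14)
        expected = scene.itd_at_90 * RATE  # 11.84 samples
        assert abs(lag - expected) <= 1.0

    def test_scene_itd_follows_sine_law(self):
        for az in (-45.0, 30.0):
            scene = BinauralScene(
                source=SourceSpec(kind="tone", freq=440.0), azimuth=az
            )
            sig = render_scene(scene, duration=1.0, seed=0)
            lag = self._raw_lag(sig, window=14)
            expected = -scene.itd_at_90 * np.sin(np.deg2rad(az)) * RATE
            assert abs(lag - expected) <= 1.0

    def test_single_source_ild_within_tolerance(self):
        scene = BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=-90.0)
        sig = render_scene(scene, duration=1.0, seed=0)
        l, r = sig.samples[:, 0], sig.samples[:, 1]
        ild = 20 * np.log10(np.sqrt(np.mean(l**2)) / np.sqrt(np.mean(r**2)))
        assert ild == pytest.approx(scene.ild_at_90, abs=0.2)

    def test_mirror_symmetry(self):
        left_scene = BinauralScene(
            source=SourceSpec(kind="tone", freq=440.0), azimuth=-45.0
        )
        right_scene = BinauralScene(
            source=SourceSpec(kind="tone", freq=440.0), azimuth=45.0
        )
        a = render_scene(left_scene, duration=0.5, seed=0)
        b = render_scene(right_scene, duration=0.5, seed=0)
        assert np.allclose(a.samples[:, 0], b.samples[:, 1])
        assert np.allclose(a.samples[:, 1], b.samples[:, 0])

    def test_snr_mixing_at_5_db(self):
        scene = BinauralScene(
            source=SourceSpec(kind="tone", freq=440.0),
            azimuth=0.0,
            interferers=(Interferer(kind="SSN", azimuth=0.0, snr_db=5.0),),
        )
        sig = render_scene(scene, duration=3.0, seed=4)
        mix = sig.samples[:, 0]
        tone = render_scene(
            BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=0.0),
            duration=3.0,
            seed=4,
        ).samples[:, 0]
        # project the mix onto the known source to separate source and noise
        gain = np.dot(mix, tone) / np.dot(tone, tone)
        source_part = gain * tone
        noise_part = mix - source_part
        snr = 10 * np.log10(
            np.sum(source_part**2) / np.sum(noise_part**2)
        )
        assert snr == pytest.approx(5.0, abs=0.1)

    def test_off_grid_azimuth_rejected(self):
        with pytest.raises(SceneError):
            BinauralScene(source=SourceSpec(kind="tone"), azimuth=-92.0)

    def test_unknown_interferer_rejected(self):
        with pytest.raises(SceneError):
            Interferer(kind="hum", azimuth=0.0, snr_db=5.0)

    def test_deterministic_given_seed(self):
        scene = BinauralScene(
            source=SourceSpec(kind="speech"),
            azimuth=15.0,
            interferers=(Interferer(kind="babble", azimuth=-30.0, snr_db=5.0),),
        )
        a = render_scene(scene, duration=0.5, seed=8)
        b = render_scene(scene, duration=0.5, seed=8)
        assert np.array_equal(a.samples, b.samples)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scene.yaml"
        path.write_text(
            "source: {kind: tone, freq: 440.0}\n"
            "azimuth: -90.0\n"
            "interferers:\n"
            "  - {kind: SSN, azimuth: 0.0, snr_db: 5.0}\n"
        )
        scene = BinauralScene.from_yaml(path)
        assert scene.azimuth == -90.0
        assert scene.interferers[0].kind == "SSN"
        assert scene.itd_at_90 == pytest.approx(740e-6)
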