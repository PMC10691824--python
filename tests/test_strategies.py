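import numpy as np
import pytest
from scipy.signal import lfilter

from bicisim import (
    FormantState,
    StrategyConfig,
    ace_select,
    cis_select,
    compress,
    continuity_filter,
    estimate_formants,
    face_select,
)
from bicisim.filterbank import hann_window, power_spectrum, channel_envelopes
from bicisim.strategies import StrategyError, normalize_envelope

RATE = 16000.0


class TestCompress:
    def test_fixes_zero_and_one(self):
        assert compress(0.0) == 0.0
        assert compress(1.0) == pytest.approx(1.0)

    def test_midpoint_closed_form(self):
        # log(1 + 415.995/2) / log(1 + 415.995)
        assert compress(0.5) == pytest.approx(0.8855, abs=1e-4)

    def test_monotone_on_grid(self):
        x = np.linspace(0.0, 1.0, 1000)
        y = compress(x)
        assert np.all(np.diff(y) > 0)
        assert np.all((y >= 0) & (y <= 1))

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert compress(1.5) == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert compress(-0.1) == 0.0

    def test_invalid_b_rejected(self):
        with pytest.raises(StrategyError):
            compress(0.5, b=-1.0)


class TestConfigValidation:
    def test_unknown_strategy_rejected(self):
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="SPEAK")

    def test_n_maxima_bounds(self):
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="ACE", n_maxima=23)
        with pytest.raises(StrategyError):
            StrategyConfig(strategy="ACE", n_maxima=0)


class TestCisSelect:
    def test_all_22_channels_selected(self):
        cfg = StrategyConfig(strategy="CIS")
        sel = cis_select(np.ones(22) * 500.0, cfg)
        assert len(sel.channels) == 22
        assert set(sel.channels.tolist()) == set(range(1, 23))

    def test_zero_envelope_zero_magnitudes(self):
        cfg = StrategyConfig(strategy="CIS")
        sel = cis_select(np.zeros(22), cfg)
        assert np.all(sel.magnitudes == 0.0)

    def test_base_to_apex_order(self):
        cfg = StrategyConfig(strategy="CIS")
        sel = cis_select(np.linspace(1, 22, 22), cfg)
        assert list(sel.channels) == sorted(sel.channels, reverse=True)

    def test_inactive_channels_excluded(self):
        cfg = StrategyConfig(strategy="CIS", active_channels=range(1, 9), n_maxima=8)
        sel = cis_select(np.ones(22), cfg)
        assert set(sel.channels.tolist()) == set(range(1, 9))


class TestAceSelect:
    def test_single_hot_channel_always_selected(self):
        cfg = StrategyConfig(strategy="ACE", n_maxima=8)
        z = np.zeros(22)
        z[14] = 900.0
        sel = ace_select(z, cfg)
        assert 15 in sel.channels
        assert len(sel.channels) == 8

    def test_decreasing_envelope_selects_first_eight(self):
        cfg = StrategyConfig(strategy="ACE", n_maxima=8)
        z = np.linspace(22.0, 1.0, 22)
        sel = ace_select(z, cfg)
        assert set(sel.channels.tolist()) == set(range(1, 9))

    def test_ties_break_toward_lower_channel(self):
        cfg = StrategyConfig(strategy="ACE", n_maxima=4)
        sel = ace_select(np.full(22, 7.0), cfg)
        assert set(sel.channels.tolist()) == {1, 2, 3, 4}

    def test_n_equals_m_matches_cis_selection(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0, 1200, 22)
        ace_cfg = StrategyConfig(strategy="ACE", n_maxima=22)
        cis_cfg = StrategyConfig(strategy="CIS")
        ace_set = dict(zip(ace_select(z, ace_cfg).channels,
                           ace_select(z, ace_cfg).magnitudes))
        cis_set = dict(zip(cis_select(z, cis_cfg).channels,
                           cis_select(z, cis_cfg).magnitudes))
        assert ace_set.keys() == cis_set.keys()
        for ch in ace_set:
            assert ace_set[ch] == pytest.approx(cis_set[ch])

    def test_matches_brute_force_oracle(self):
        cfg = StrategyConfig(strategy="ACE", n_maxima=8)
        rng = np.random.default_rng(17)
        for _ in range(500):
            z = rng.uniform(0, 1500, 22)
            sel = ace_select(z, cfg)
            oracle = sorted(range(22), key=lambda i: (-z[i], i))[:8]
            assert set(sel.channels.tolist()) == {i + 1 for i in oracle}


class TestNormalization:
    def test_below_floor_is_silence(self):
        cfg = StrategyConfig()
        z = np.array([0.0, cfg.env_saturation * 1e-6, cfg.env_saturation])
        x = normalize_envelope(z, cfg)
        assert x[0] == 0.0 and x[1] == 0.0
        assert x[2] == 1.0

    def test_saturation_clips_to_one(self):
        cfg = StrategyConfig()
        x = normalize_envelope(np.array([cfg.env_saturation * 10]), cfg)
        assert x[0] == 1.0


class TestFormants:
    def test_resonator_pole_recovered(self):
        r, f = 0.98, 1000.0
        imp = np.zeros(1024)
        imp[0] = 1.0
        x = lfilter([1.0], [1.0, -2 * r * np.cos(2 * np.pi * f / RATE), r * r], imp)
        cands = estimate_formants(x[:128] * hann_window(128), RATE)
        assert cands, "no candidates from a clean resonator"
        best = min(cands, key=lambda c: c[1])
        assert best[0] == pytest.approx(1000.0, abs=250.0)  # within 2 bins

    def test_zero_frame_empty(self):
        assert estimate_formants(np.zeros(128), RATE) == []

    def test_order_28_default(self):
        assert StrategyConfig().lpc_order == 28

    def test_order_must_be_below_frame_length(self):
        with pytest.raises(StrategyError):
            estimate_formants(np.ones(20), RATE, order=28)

    def test_noise_frame_contract_only(self):
        rng = np.random.default_rng(23)
        cands = estimate_formants(rng.standard_normal(128), RATE)
        assert len(cands) >= 0  # values are unstable; only the contract holds


class TestContinuityFilter:
    def test_candidate_within_window_accepted(self):
        prev = FormantState(formants=(500.0, 1500.0, 2500.0))
        state = continuity_filter([(1510.0, 90.0)], prev, bw_ceiling=200.0)
        assert state.formants[1] == pytest.approx(1510.0)

    def test_jump_outside_window_carries_previous(self):
        prev = FormantState(formants=(500.0, 1500.0, 2500.0))
        state = continuity_filter([(2100.0, 90.0)], prev, bw_ceiling=200.0)
        assert state.formants[1] == 1500.0

    def test_empty_candidates_identity(self):
        prev = FormantState(formants=(500.0, 1500.0, 2500.0))
        assert continuity_filter([], prev).formants == prev.formants

    def test_cold_start_accepts_without_filtering(self):
        state = continuity_filter(
            [(400.0, 80.0), (1200.0, 90.0), (2300.0, 70.0)], FormantState()
        )
        assert state.formants == (400.0, 1200.0, 2300.0)

    def test_wide_bandwidth_rejected(self):
        state = continuity_filter([(1000.0, 500.0)], FormantState())
        assert state.formants == (None, None, None)


class TestFaceSelect:
    def _run(self, signal, cfg, weights, n_frames=40):
        window = hann_window(128)
        state = FormantState()
        sels = []
        for i in range(n_frames):
            frame = signal[i * 32 : i * 32 + 128] * window
            z = channel_envelopes(power_spectrum(frame, RATE), weights)
            sel, state = face_select(frame, z, state, cfg, weights)
            sels.append(sel)
        return sels, state

    def test_vowel_formant_channels_selected(self, weights, vowel_500_1500_2500):
        cfg = StrategyConfig(strategy="FACE")
        sels, state = self._run(vowel_500_1500_2500, cfg, weights)
        expected = {weights.channel_for_frequency(f) for f in (500, 1500, 2500)}
        assert set(sels[-1].formant_channels) == expected
        assert expected <= set(sels[-1].channels.tolist())

    def test_formant_channels_stable_after_cold_start(
        self, weights, vowel_500_1500_2500
    ):
        cfg = StrategyConfig(strategy="FACE")
        sels, _ = self._run(vowel_500_1500_2500, cfg, weights)
        sets = {s.formant_channels for s in sels[5:]}
        assert len(sets) == 1

    def test_cardinality_equals_n_maxima(self, weights, vowel_500_1500_2500):
        cfg = StrategyConfig(strategy="FACE", n_maxima=8)
        sels, _ = self._run(vowel_500_1500_2500, cfg, weights)
        assert all(len(s.channels) == 8 for s in sels)

    def test_tone_falls_back_to_maxima(self, weights):
        # a pure tone exposes at most one formant; the rest are maxima picks
        t = np.arange(4000) / RATE
        tone = np.sin(2 * np.pi * 440.0 * t)
        cfg = StrategyConfig(strategy="FACE")
        sels, _ = self._run(tone, cfg, weights, n_frames=20)
        assert all(len(s.channels) == cfg.n_maxima for s in sels)
        assert all(len(s.formant_channels) <= 3 for s in sels)

    def test_never_selects_inactive_channels(self, weights, vowel_500_1500_2500):
        cfg = StrategyConfig(
            strategy="FACE", active_channels=range(1, 13), n_maxima=6
        )
        sels, _ = self._run(vowel_500_1500_2500, cfg, weights)
        for s in sels:
            assert set(s.channels.tolist()) <= set(range(1, 13))
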