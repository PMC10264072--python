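"""Synthetic-session generator: protocol structure, determinism, physiology."""

import numpy as np
import pytest
from scipy import stats

from pico_coord import (
    GeneratorConfig,
    LARYNGEAL,
    NO_RESPONSE,
    SWALLOW,
    generate_recording,
    render_burst,
    rectify_smooth,
    schedule_stimuli,
)
from pico_coord.synthgen import CapacityError, ConfigError

FS = 5000.0


class TestConfigValidation:
    def test_rate_below_band_limit(self):
        with pytest.raises(ConfigError, match="1400"):
            GeneratorConfig(sampling_rate=1000.0).validate()

    @pytest.mark.parametrize("field,value", [
        ("session_duration", -1.0),
        ("breath_period_mean", 0.0),
        ("swallow_duration_mean", -5.0),
    ])
    def test_nonpositive_durations(self, field, value):
        with pytest.raises(ConfigError):
            GeneratorConfig(**{field: value}).validate()

    def test_policy_must_sum_to_one(self):
        bad = [(0.0, 1.01, {SWALLOW: 0.5, LARYNGEAL: 0.2, NO_RESPONSE: 0.2})]
        with pytest.raises(ConfigError, match="sum to 1"):
            GeneratorConfig(behavior_policy=bad).validate()

    def test_policy_must_tile_unit_interval(self):
        bad = [(0.0, 0.5, {SWALLOW: 1.0})]
        with pytest.raises(ConfigError, match="cover"):
            GeneratorConfig(behavior_policy=bad).validate()

    def test_json_round_trip(self, tmp_path, quick_config):
        p = tmp_path / "cfg.json"
        quick_config.to_json(p)
        back = GeneratorConfig.from_json(p)
        assert back == quick_config


class TestProtocolStructure:
    def test_full_protocol_counts(self, session1):
        _, rec, gt, _ = session1
        laser = [e for e in gt.events if e.trigger == "laser"]
        assert len(laser) == 125  # 25 pulses x 5 durations
        assert len(rec.stimuli) == 125
        durs = [s.duration for s in rec.stimuli]
        for d in (40.0, 80.0, 120.0, 160.0, 200.0):
            assert durs.count(d) == 25

    def test_stimuli_sorted_nonoverlapping(self, session1):
        _, rec, _, _ = session1
        for a, b in zip(rec.stimuli, rec.stimuli[1:]):
            assert b.onset >= a.offset

    def test_capacity_error(self):
        cfg = GeneratorConfig(seed=0, session_duration=30.0)
        with pytest.raises(CapacityError):
            generate_recording(cfg)

    def test_determinism(self, quick_config):
        rec1, gt1 = generate_recording(quick_config)
        rec2, gt2 = generate_recording(quick_config)
        for name in rec1.channels:
            assert np.array_equal(rec1.channels[name], rec2.channels[name])
        assert rec1.stimuli == rec2.stimuli
        assert gt1.to_frame().equals(gt2.to_frame())

    def test_null_policy_leaves_channels_silent(self):
        cfg = GeneratorConfig(
            seed=3, session_duration=80.0, pulses_per_duration=3,
            n_water_boluses=0,
            behavior_policy=[(0.0, 1.01, {NO_RESPONSE: 1.0})])
        rec, gt = generate_recording(cfg)
        assert all(e.behavior_class == NO_RESPONSE for e in gt.events)
        # submental/laryngeal contain nothing but noise + cardiac artifact:
        # their envelope stays far below any burst scale
        for chan in ("submental", "laryngeal"):
            env = rectify_smooth(rec.channels[chan], cfg.sampling_rate)
            assert env.samples.max() < 0.3 * cfg.amplitude[chan]


class TestScheduleStimuli:
    def make_onsets(self, n, rng, period=0.7, cv=0.1):
        return np.concatenate([[0.0], np.cumsum(
            rng.normal(period, cv * period, n - 1).clip(0.3))])

    def test_count_conservation(self, rng):
        onsets = self.make_onsets(300, rng)
        cfg = GeneratorConfig(seed=0)
        evs = schedule_stimuli(onsets, cfg, np.random.default_rng(1))
        assert len(evs) == 125
        for a, b in zip(evs, evs[1:]):
            assert b.onset >= a.offset

    def test_one_pulse_per_duration(self, rng):
        onsets = self.make_onsets(30, rng)
        cfg = GeneratorConfig(seed=0, pulses_per_duration=1)
        evs = schedule_stimuli(onsets, cfg, np.random.default_rng(2))
        assert sorted(e.duration for e in evs) == [40.0, 80.0, 120.0, 160.0, 200.0]

    def test_phase_uniformity(self, rng):
        """Scheduled phases are KS-indistinguishable from U(0,1) at n=1000,
        and each onset realizes its phase on the expected-cycle scale."""
        onsets = self.make_onsets(2500, rng)
        cfg = GeneratorConfig(seed=0, pulses_per_duration=200)
        evs, phases = schedule_stimuli(onsets, cfg, np.random.default_rng(3),
                                       with_phases=True)
        assert len(evs) == 1000
        assert stats.kstest(phases, "uniform").pvalue > 0.01
        # every onset is (cycle onset + u * preceding cycle duration) for
        # some host cycle in the train
        for e, u in zip(evs, phases):
            cand = onsets[1:-1] + u * np.diff(onsets[:-1])
            assert np.min(np.abs(cand - e.onset)) < 1e-9

    def test_too_few_breaths(self):
        with pytest.raises(ValueError):
            schedule_stimuli(np.array([0.0]), GeneratorConfig(),
                             np.random.default_rng(0))


class TestRenderBurst:
    def test_zero_amplitude_flat(self, rng):
        assert np.all(render_burst(100.0, 0.0, FS, rng) == 0)

    def test_energy_confined(self, rng):
        """Envelope above half-max only within [onset-10ms, offset+25ms]."""
        seg = render_burst(100.0, 1.0, FS, rng)
        x = np.zeros(int(FS))
        i0 = 2000
        x[i0 : i0 + len(seg)] = seg
        env = rectify_smooth(x, FS).samples
        above = np.flatnonzero(env > 0.5 * env.max())
        assert above[0] >= i0 - 0.010 * FS
        assert above[-1] <= i0 + len(seg) + 0.025 * FS

    def test_nonpositive_duration(self, rng):
        with pytest.raises(ValueError):
            render_burst(0.0, 1.0, FS, rng)

    def test_disjoint_bursts_additive(self):
        rng1 = np.random.default_rng(5)
        a = render_burst(50.0, 1.0, FS, rng1)
        rng2 = np.random.default_rng(6)
        b = render_burst(50.0, 1.0, FS, rng2)
        x = np.zeros(2000)
        x[100 : 100 + len(a)] += a
        x[1200 : 1200 + len(b)] += b
        assert np.allclose(x[100 : 100 + len(a)], a)
        assert np.allclose(x[1200 : 1200 + len(b)], b)


class TestGroundTruthPhysiology:
    def _pooled_events(self, default_sessions, klass):
        return [e for _, _, gt, _ in default_sessions
                for e in gt.events if e.trigger == "laser" and e.behavior_class == klass]

    def test_all_or_none_swallow(self, default_sessions):
        """True swallow duration is uncorrelated with laser pulse duration."""
        sw = self._pooled_events(default_sessions, SWALLOW)
        assert len(sw) >= 100
        r = stats.pearsonr([e.pulse_duration_ms for e in sw],
                           [e.swallow_duration_ms for e in sw])[0]
        assert abs(r) < 0.2

    def test_graded_laryngeal(self, default_sessions):
        """True laryngeal-activation duration tracks pulse duration."""
        la = self._pooled_events(default_sessions, LARYNGEAL)
        rho = stats.spearmanr([e.pulse_duration_ms for e in la],
                              [e.laryngeal_duration_ms for e in la])[0]
        assert rho > 0.9

    def test_swallow_motor_sequence(self, default_sessions):
        """Submental peak precedes laryngeal peak in every true swallow."""
        for _, _, gt, _ in default_sessions:
            for e in gt.events:
                if e.behavior_class == SWALLOW:
                    assert e.sub_peak_time < e.lar_peak_time

    def test_swallow_outlasts_stimulus(self, default_sessions):
        for e in self._pooled_events(default_sessions, SWALLOW):
            assert e.lar_offset > e.onset + e.pulse_duration_ms * 1e-3

    def test_reset_delays_next_breath(self, session1):
        """With reset on, the next inspiration follows the swallow offset."""
        cfg, _, gt, _ = session1
        onsets = gt.breath_onsets
        for e in gt.events:
            if e.behavior_class == SWALLOW:
                nxt = onsets[np.searchsorted(onsets, e.onset)]
                assert nxt == pytest.approx(e.lar_offset + cfg.post_swallow_ibi, abs=1e-9)
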