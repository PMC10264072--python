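"""Phase computation, binned curves, probabilities, reset regression."""

import math

import numpy as np
import pytest

from pico_coord import (
    BehaviorEvent,
    Breath,
    PhaseSample,
    bin_curve,
    phase_shift,
    probability_curves,
    reset_correlation,
    respiratory_phase,
    swallow_timing,
)
from pico_coord.phase_stats import make_phase_samples
from pico_coord.synthgen import LARYNGEAL, NO_RESPONSE, SWALLOW


def uniform_breaths(n=10, period=0.7):
    return [Breath(i * period, i * period + 0.1, 1.0, i * period + 0.2,
                   (i + 1) * period) for i in range(n)]


class TestRespiratoryPhase:
    def test_stim_at_inspiration_onset_is_zero(self):
        breaths = uniform_breaths()
        ph, idx = respiratory_phase(2.1, breaths, [True] * 10)
        assert ph == pytest.approx(0.0)
        assert idx == 3

    def test_half_cycle(self):
        """0.35 s into a cycle with a 0.70 s preceding cycle: phase 0.5."""
        breaths = uniform_breaths()
        ph, _ = respiratory_phase(2.1 + 0.35, breaths, [True] * 10)
        assert ph == pytest.approx(0.5)

    def test_phase_above_one_retained(self):
        """A lengthened containing cycle yields phase > 1 (kept as overflow)."""
        breaths = [Breath(0.0, 0.1, 1, 0.2, 0.5), Breath(0.5, 0.6, 1, 0.7, 1.5)]
        ph, _ = respiratory_phase(1.2, breaths, [True, True])
        assert ph == pytest.approx(1.4)
        curve = bin_curve([PhaseSample(0, ph, 1.0, SWALLOW)], 10)
        assert curve.overflow == 1
        assert curve.n.sum() == 0

    def test_no_preceding_control_excluded(self):
        breaths = uniform_breaths(3)
        assert respiratory_phase(0.3, breaths, [False, False, False]) is None
        assert respiratory_phase(99.0, breaths, [True] * 3) is None

    def test_perturbed_predecessor_uses_earlier_control(self):
        breaths = [Breath(0.0, 0.1, 1, 0.2, 0.8),   # control, 0.8 s
                   Breath(0.8, 0.9, 1, 1.0, 1.4),   # perturbed
                   Breath(1.4, 1.5, 1, 1.6, 2.1)]
        ph, _ = respiratory_phase(1.8, breaths, [True, False, True])
        assert ph == pytest.approx(0.4 / 0.8)


class TestPhaseShift:
    def test_ratio(self):
        """Containing cycle 1.05 s after a 0.70 s control: shift 1.5."""
        breaths = [Breath(0.0, 0.1, 1, 0.2, 0.7), Breath(0.7, 0.8, 1, 0.9, 1.75)]
        assert phase_shift(0.9, breaths, [True, True]) == pytest.approx(1.5)

    def test_unperturbed_is_unity(self):
        breaths = uniform_breaths()
        assert phase_shift(2.2, breaths, [True] * 10) == pytest.approx(1.0)


class TestBinCurve:
    def test_bin_edges(self):
        s = [PhaseSample(0, 0.05, 1.0, SWALLOW)]
        curve = bin_curve(s, 10)
        assert curve.n[0] == 1 and curve.n[1:].sum() == 0

    def test_phase_one_goes_to_last_bin(self):
        curve = bin_curve([PhaseSample(0, 1.0, 1.0, SWALLOW)], 10)
        assert curve.n[-1] == 1 and curve.overflow == 0

    def test_constant_value(self):
        s = [PhaseSample(i, p, 2.5, SWALLOW) for i, p in enumerate(np.linspace(0, 0.99, 40))]
        curve = bin_curve(s, 10)
        assert np.allclose(curve.mean[curve.n > 0], 2.5)
        assert np.allclose(curve.sd[curve.n > 0], 0.0)

    def test_uniform_counts(self, rng):
        s = [PhaseSample(i, float(p), 1.0, SWALLOW)
             for i, p in enumerate(rng.uniform(0, 1, 1000))]
        curve = bin_curve(s, 10)
        assert curve.n.sum() == 1000
        assert np.all(np.abs(curve.n - 100) <= 30)  # binomial 3-sigma

    def test_empty_error(self):
        with pytest.raises(ValueError):
            bin_curve([], 10)


def _event(i, phase, klass, shift=1.0):
    return BehaviorEvent(stimulus_id=i, trigger="laser", behavior_class=klass,
                         atypical=False, stim_onset=0.0, pulse_duration_ms=40.0,
                         respiratory_phase=phase, phase_shift=shift)


class TestProbabilityCurves:
    def test_pure_swallow_bin(self):
        evs = [_event(i, 0.05, SWALLOW) for i in range(5)]
        curves = probability_curves(evs)
        assert curves[SWALLOW].mean[0] == 1.0
        assert curves[LARYNGEAL].mean[0] == 0.0
        assert curves[NO_RESPONSE].mean[0] == 0.0

    def test_probabilities_sum_to_one(self, rng):
        klasses = [SWALLOW, LARYNGEAL, NO_RESPONSE]
        evs = [_event(i, float(rng.uniform()), klasses[int(rng.integers(3))])
               for i in range(300)]
        curves = probability_curves(evs)
        total = sum(c.mean for c in curves.values())
        filled = curves[SWALLOW].n > 0
        assert np.allclose(total[filled], 1.0)

    def test_empty_bin_undefined(self):
        evs = [_event(0, 0.05, SWALLOW)]
        curves = probability_curves(evs)
        assert math.isnan(curves[SWALLOW].mean[5])

    def test_policy_recovery(self, default_sessions):
        """Recovered P(swallow) in the early-phase bins matches the policy."""
        probs, ns = [], []
        for cfg, _, _, res in default_sessions:
            target = cfg.behavior_policy[0][2][SWALLOW]
            curves = probability_curves(res.events, 10)
            # interior bins of the first policy interval [0, 0.4)
            for b in (1, 2):
                probs.append(curves[SWALLOW].mean[b] * curves[SWALLOW].n[b])
                ns.append(curves[SWALLOW].n[b])
        n = sum(ns)
        p_hat = sum(probs) / n
        se = math.sqrt(target * (1 - target) / n)
        assert abs(p_hat - target) < 3 * se + 0.02


class TestSwallowTiming:
    def test_onset_at_inspiratory_peak(self):
        breaths = uniform_breaths()
        ev = _event(0, 0.1, SWALLOW)
        ev.submental_onset = breaths[2].insp_peak_time
        rows, hist = swallow_timing([ev], breaths)
        assert rows[0].onset_rel_insp_peak_ms == pytest.approx(0.0)
        assert hist.sum() == 1

    def test_onset_phase_fraction_of_cycle(self):
        breaths = [Breath(0.0, 0.1, 1, 0.2, 0.5), Breath(0.5, 0.6, 1, 0.7, 1.0)]
        ev = _event(0, 0.1, SWALLOW)
        ev.submental_onset = 0.1
        rows, hist = swallow_timing([ev], breaths)
        assert rows[0].onset_phase == pytest.approx(0.2)
        assert hist[2] == 1

    def test_postinspiratory_mode(self, session1):
        """Swallows triggered in inspiration/early expiration cluster
        just after the inspiratory phase."""
        _, _, _, res = session1
        hist = res.timing_hist
        assert hist.sum() >= 50
        assert 1 <= int(np.argmax(hist)) <= 5


class TestResetCorrelation:
    def test_collinear(self):
        s = [PhaseSample(i, x, 0.5 + 0.9 * x, SWALLOW)
             for i, x in enumerate(np.linspace(0, 1, 20))]
        fit = reset_correlation(s, "swallow")
        assert fit.r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.9)
        assert fit.intercept == pytest.approx(0.5)

    def test_null_reset_slope_zero(self, rng):
        s = [PhaseSample(i, float(x), 1.0 + float(e), LARYNGEAL)
             for i, (x, e) in enumerate(zip(rng.uniform(0, 1, 500),
                                            rng.normal(0, 0.01, 500)))]
        fit = reset_correlation(s, "non_swallow")
        assert abs(fit.slope) < 0.01

    def test_zero_variance_error(self):
        s = [PhaseSample(i, 0.5, float(i), SWALLOW) for i in range(5)]
        with pytest.raises(ValueError):
            reset_correlation(s, "swallow")

    def test_group_membership(self):
        assert PhaseSample(0, 0.5, 1.0, LARYNGEAL).group == "non_swallow"
        assert PhaseSample(0, 0.5, 1.0, NO_RESPONSE).group == "non_swallow"
        assert PhaseSample(0, 0.5, 1.0, SWALLOW).group == "swallow"

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            reset_correlation([PhaseSample(0, 0.1, 1.0, SWALLOW)], "swallow")

    def test_brute_force_equivalence(self, rng):
        """Matches direct covariance/normal-equation formulas to 1e-12."""
        xs = rng.uniform(0, 1, 200)
        ys = 0.8 * xs + rng.normal(1.0, 0.1, 200)
        s = [PhaseSample(i, float(x), float(y), SWALLOW)
             for i, (x, y) in enumerate(zip(xs, ys))]
        fit = reset_correlation(s, "swallow")
        mx, my = xs.mean(), ys.mean()
        sxy = np.sum((xs - mx) * (ys - my))
        sxx = np.sum((xs - mx) ** 2)
        syy = np.sum((ys - my) ** 2)
        assert fit.r == pytest.approx(sxy / math.sqrt(sxx * syy), abs=1e-12)
        assert fit.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert fit.intercept == pytest.approx(my - (sxy / sxx) * mx, abs=1e-12)


class TestMakePhaseSamples:
    def test_excludes_water_and_unphased(self):
        evs = [_event(0, 0.2, SWALLOW), _event(1, float("nan"), SWALLOW)]
        evs[0].trigger = "laser"
        water = _event(2, 0.3, SWALLOW)
        water.trigger = "water"
        samples = make_phase_samples(evs + [water])
        assert [s.stimulus_id for s in samples] == [0]
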