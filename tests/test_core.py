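"""Unit and property tests for the lock-in controller primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lifopt import (
    DataError,
    DimensionConfig,
    DimensionState,
    LockInController,
    SequencingError,
    WarmupError,
    lockin_sum,
    propose_stimulus,
    record_response,
    spectral_diagnostics,
    suggest_window,
    update_center,
)
from lifopt.core import LockinResult

from conftest import quadratic_window


def make_state(config, center=None):
    st_ = DimensionState.fresh(config)
    if center is not None:
        st_.center = center
    return st_


class TestDimensionConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"omega": 0.0},
            {"omega": -1.0},
            {"delta": -1.0},
            {"gamma": -0.1},
            {"n_window": 1},
            {"x_init": 5.0},   # no room for the dither at the low bound
            {"x_init": 97.0},  # ... nor at the high bound
            {"direction": "sideways"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(omega=2.63, delta=8.0, gamma=0.0006, n_window=150,
                    x_init=20.0, lo=1.0, hi=100.0)
        with pytest.raises(ValueError):
            DimensionConfig(**{**base, **kwargs})

    def test_degenerate_dither_and_learning_are_legal(self):
        DimensionConfig(omega=2.63, delta=0.0, gamma=0.0, n_window=10, x_init=20.0)


class TestProposeAndRecord:
    def test_dithered_proposal_values(self):
        cfg = DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=150,
                              x_init=20.0)
        st_ = make_state(cfg)
        x = propose_stimulus(st_, cfg, 1)
        assert x == pytest.approx(20.0 + 8.0 * math.cos(2.63), abs=1e-12)
        assert x == pytest.approx(13.0242727691847, abs=1e-9)

    def test_zero_dither_returns_center(self):
        cfg = DimensionConfig(omega=2.63, delta=0.0, gamma=0.0006, n_window=10,
                              x_init=20.0)
        st_ = make_state(cfg)
        assert propose_stimulus(st_, cfg, 1) == 20.0

    def test_phase_zero_adds_full_amplitude(self):
        # omega*trial = 2*pi exactly -> cos = 1
        cfg = DimensionConfig(omega=2 * math.pi / 10, delta=8.0, gamma=0.0,
                              n_window=10, x_init=20.0)
        st_ = make_state(cfg)
        st_.trial = 9
        assert propose_stimulus(st_, cfg, 10) == pytest.approx(28.0, abs=1e-12)

    def test_nonconsecutive_trial_rejected(self):
        cfg = DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=10,
                              x_init=20.0)
        st_ = make_state(cfg)
        propose_stimulus(st_, cfg, 1)
        record_response(st_, 1, 50.0)
        with pytest.raises(SequencingError):
            propose_stimulus(st_, cfg, 3)

    def test_response_without_matching_proposal_rejected(self):
        cfg = DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=10,
                              x_init=20.0)
        st_ = make_state(cfg)
        propose_stimulus(st_, cfg, 1)
        with pytest.raises(SequencingError):
            record_response(st_, 7, 50.0)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_nonfinite_response_rejected(self, bad):
        cfg = DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=10,
                              x_init=20.0)
        st_ = make_state(cfg)
        propose_stimulus(st_, cfg, 1)
        with pytest.raises(DataError):
            record_response(st_, 1, bad)

    def test_ring_buffer_evicts_oldest(self):
        cfg = DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=150,
                              x_init=20.0)
        st_ = make_state(cfg)
        for t in range(1, 152):
            propose_stimulus(st_, cfg, t)
            record_response(st_, t, 50.0)
        assert len(st_.buffer) == 150
        assert st_.buffer[0][0] == 2  # trial 1 evicted

    def test_proposals_clipped_to_bounds(self):
        cfg = DimensionConfig(omega=2 * math.pi / 10, delta=8.0, gamma=0.0,
                              n_window=10, x_init=9.0, lo=1.0, hi=100.0)
        st_ = make_state(cfg)
        st_.center = 5.0  # force a center illegally close to the bound
        xs = []
        for t in range(1, 11):
            xs.append(propose_stimulus(st_, cfg, t))
            record_response(st_, t, 1.0)
        assert min(xs) == 1.0  # clipped, not 5 - 8 = -3
        assert all(1.0 <= x <= 100.0 for x in xs)


class TestLockinSum:
    def test_constant_window_demodulates_to_zero(self):
        om = 2 * math.pi / 10
        buf = [(i, 7.5) for i in range(1, 51)]
        res = lockin_sum(buf, om)
        assert res.y_lock == pytest.approx(0.0, abs=1e-10)
        assert (res.window_start, res.window_end) == (1, 50)

    def test_inphase_cosine_gives_half_window_length(self):
        om = 2 * math.pi / 10
        buf = [(i, math.cos(om * i)) for i in range(1, 51)]
        assert lockin_sum(buf, om).y_lock == pytest.approx(25.0, abs=1e-10)

    def test_quadratic_window_matches_gradient_closed_form(self):
        # over whole periods the demodulated quadratic reduces to a1*delta*n*d
        buf = quadratic_window(a1=-0.01, delta=8.0, d=-10.0, omega=2 * math.pi / 10, n=50)
        assert lockin_sum(buf, 2 * math.pi / 10).y_lock == pytest.approx(40.0, rel=1e-9)

    def test_uses_absolute_trial_indices(self):
        # same values at shifted indices demodulate differently
        om = 2.63
        vals = np.linspace(10, 90, 150)
        a = lockin_sum(list(zip(range(1, 151), vals)), om).y_lock
        b = lockin_sum(list(zip(range(51, 201), vals)), om).y_lock
        assert a != pytest.approx(b, abs=1e-6)
        expected = float(np.dot(vals, np.cos(om * np.arange(51, 201))))
        assert b == pytest.approx(expected, abs=1e-9)

    def test_short_buffer_is_warmup_error(self):
        buf = [(i, 1.0) for i in range(1, 50)]
        with pytest.raises(WarmupError):
            lockin_sum(buf, 2.63, n_window=150)

    def test_gap_in_buffer_rejected(self):
        buf = [(1, 1.0), (2, 1.0), (4, 1.0)]
        with pytest.raises(SequencingError):
            lockin_sum(buf, 2.63)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.sampled_from([20, 30, 40, 50, 60, 80, 100, 150]),
        m=st.integers(min_value=1, max_value=40),
        a1=st.floats(min_value=-0.1, max_value=-0.001),
        delta=st.floats(min_value=0.5, max_value=20.0),
        d=st.floats(min_value=-25.0, max_value=25.0),
    )
    def test_whole_period_oracle_equivalence(self, n, m, a1, delta, d):
        """On whole-period windows the lock-in sum equals a1*delta*n*(x - xm)."""
        if m % n == 0 or (2 * m) % n == 0 or (3 * m) % n == 0:
            return  # harmonic aliasing: leakage terms survive by construction
        if abs(d) < 0.5:
            d = 0.5
        omega = 2 * math.pi * m / n
        buf = quadratic_window(a1=a1, delta=delta, d=d, omega=omega, n=n)
        got = lockin_sum(buf, omega).y_lock
        assert got == pytest.approx(a1 * delta * n * d, rel=1e-9, abs=1e-9)


class TestUpdateCenter:
    def _cfg(self, direction="maximize"):
        return DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=150,
                               x_init=45.0, direction=direction)

    def _state(self, cfg, centers):
        st_ = make_state(cfg, center=centers[-1])
        st_.center_history = list(centers)
        return st_

    def test_zero_locksum_is_fixed_point(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [45.0] * 150)
        lock = LockinResult(y_lock=0.0, window_start=1, window_end=150)
        for baseline in ("current", "window_mean"):
            assert update_center(st_, cfg, lock, baseline=baseline) == 45.0

    def test_ascent_arithmetic(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [45.0] * 150)
        lock = LockinResult(y_lock=40.0, window_start=1, window_end=150)
        assert update_center(st_, cfg, lock) == pytest.approx(45.024, abs=1e-12)

    def test_minimize_flips_sign(self):
        cfg = self._cfg(direction="minimize")
        st_ = self._state(cfg, [45.0] * 150)
        lock = LockinResult(y_lock=40.0, window_start=1, window_end=150)
        assert update_center(st_, cfg, lock) == pytest.approx(44.976, abs=1e-12)

    def test_raw_sign_reproduces_printed_minus(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [45.0] * 150)
        lock = LockinResult(y_lock=40.0, window_start=1, window_end=150)
        assert update_center(st_, cfg, lock, raw_sign=True) == pytest.approx(44.976)

    def test_window_mean_baseline_uses_history(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [40.0] * 75 + [50.0] * 75)  # mean 45, current 50
        lock = LockinResult(y_lock=40.0, window_start=1, window_end=150)
        assert update_center(st_, cfg, lock, baseline="window_mean") == pytest.approx(45.024)
        assert update_center(st_, cfg, lock, baseline="current") == pytest.approx(50.024)

    def test_update_before_warmup_rejected(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [45.0] * 10)
        lock = LockinResult(y_lock=40.0, window_start=1, window_end=150)
        with pytest.raises(WarmupError):
            update_center(st_, cfg, lock)

    def test_center_clipped_so_dither_fits(self):
        cfg = self._cfg()
        st_ = self._state(cfg, [45.0] * 150)
        lock = LockinResult(y_lock=1e6, window_start=1, window_end=150)
        assert update_center(st_, cfg, lock) == 92.0  # hi - delta


class TestSpectralDiagnostics:
    def test_pure_first_harmonic(self):
        om = 2 * math.pi / 10
        buf = [(i, 3.0 * math.cos(om * i)) for i in range(1, 51)]
        diag = spectral_diagnostics(buf, om)
        assert diag.amp_omega == pytest.approx(3.0, abs=1e-10)
        assert diag.amp_2omega == pytest.approx(0.0, abs=1e-10)

    def test_at_optimum_signal_moves_to_second_harmonic(self):
        # center on the optimum of a parabola: amp at omega vanishes and the
        # dither folds onto 2*omega with amplitude |a1|*delta^2/2
        buf = quadratic_window(a1=-0.01, delta=8.0, d=0.0, omega=2 * math.pi / 10, n=50)
        diag = spectral_diagnostics(buf, 2 * math.pi / 10)
        assert abs(diag.amp_omega) < 1e-9
        assert abs(diag.amp_2omega) == pytest.approx(0.32, rel=1e-9)
        assert diag.amp_2omega < 0  # concave response

    def test_phase_sign_tells_side_of_optimum(self):
        om = 2 * math.pi / 10
        below = quadratic_window(a1=-0.01, delta=8.0, d=-10.0, omega=om, n=50)
        above = quadratic_window(a1=-0.01, delta=8.0, d=+10.0, omega=om, n=50)
        assert spectral_diagnostics(below, om).amp_omega > 0
        assert spectral_diagnostics(above, om).amp_omega < 0

    def test_constant_window(self):
        buf = [(i, 42.0) for i in range(1, 51)]
        diag = spectral_diagnostics(buf, 2 * math.pi / 10)
        assert diag.amp_omega == pytest.approx(0.0, abs=1e-10)
        assert diag.amp_2omega == pytest.approx(0.0, abs=1e-10)
        assert diag.mean_level == 42.0

    def test_zero_window_all_zero(self):
        buf = [(i, 0.0) for i in range(1, 51)]
        diag = spectral_diagnostics(buf, 2.63)
        assert diag.amp_omega == 0.0 and diag.amp_2omega == 0.0 and diag.mean_level == 0.0


class TestSuggestWindow:
    @pytest.mark.parametrize("omega,expected", [
        (2 * math.pi / 10, 10),
        (2 * math.pi / 7, 7),
        (math.pi / 5, 10),
    ])
    def test_exact_periods(self, omega, expected):
        assert suggest_window(omega) == expected

    def test_irrational_frequency_minimizes_leakage(self):
        n = suggest_window(2.63, max_n=500)
        cycles = 2.63 * n / (2 * math.pi)
        assert abs(cycles - round(cycles)) < 0.02


class TestController:
    def test_warmup_keeps_centers_at_init(self, table1_configs):
        ctl = LockInController(table1_configs)
        for t in range(1, 151):
            ctl.propose(t)
            ctl.observe(t, 100.0 * ((t % 7) / 7.0))
        # observing trial 150 completes warm-up and triggers the first update
        history = ctl.states[0].center_history
        assert all(c == 20.0 for c in history[:150])

    def test_first_update_at_window_boundary(self, table1_configs):
        ctl = LockInController(table1_configs)
        for t in range(1, 150):
            ctl.propose(t)
            ctl.observe(t, 50.0)
        assert ctl.centers == [20.0, 20.0]
        ctl.propose(150)
        ctl.observe(150, 50.0)
        assert ctl.last_locks[0] is not None  # update ran exactly at trial n

    def test_descent_direction_toward_optimum(self, wholeperiod_config):
        """sign(new center - baseline) matches sign(x_max - center)."""
        for d0 in (-10.0, +10.0):
            ctl = LockInController([wholeperiod_config])
            xm = ctl.centers[0] - d0
            for t in range(1, 52):
                (x,) = ctl.propose(t)
                ctl.observe(t, -0.01 * (x - xm) ** 2 + 70.0)
            moved = ctl.centers[0] - wholeperiod_config.x_init
            assert math.copysign(1.0, moved) == math.copysign(1.0, xm - wholeperiod_config.x_init)

    def test_no_dither_no_noise_center_constant(self):
        cfg = DimensionConfig(omega=2 * math.pi / 10, delta=0.0, gamma=0.0006,
                              n_window=50, x_init=20.0)
        ctl = LockInController([cfg])
        for t in range(1, 201):
            (x,) = ctl.propose(t)
            assert x == 20.0
            ctl.observe(t, -0.01 * (x - 55.0) ** 2 + 70.0)
        assert ctl.centers[0] == pytest.approx(20.0, abs=1e-9)

    def test_step_returns_next_proposals(self, table1_configs):
        ctl = LockInController(table1_configs)
        ctl.propose(1)
        xs = ctl.step(1, 50.0)
        assert len(xs) == 2
        assert xs[0] == pytest.approx(20.0 + 8.0 * math.cos(2.63 * 2))

    def test_quantized_proposals_are_integers(self, table1_configs):
        ctl = LockInController(table1_configs, quantize=True)
        xs = ctl.propose(1)
        assert all(x == round(x) for x in xs)

    def test_state_snapshot_resume_matches_uninterrupted_run(self, table1_configs):
        def responses(t):
            return 50.0 + 30.0 * math.sin(0.01 * t)

        full = LockInController(table1_configs)
        for t in range(1, 401):
            full.propose(t)
            full.observe(t, responses(t))

        half = LockInController(table1_configs)
        for t in range(1, 201):
            half.propose(t)
            half.observe(t, responses(t))
        resumed = LockInController.from_json(half.to_json(), table1_configs)
        for t in range(201, 401):
            resumed.propose(t)
            resumed.observe(t, responses(t))
        assert resumed.centers == full.centers
        assert [lk.y_lock for lk in resumed.last_locks] == [lk.y_lock for lk in full.last_locks]


class TestNoiseRejection:
    def test_pure_noise_locksum_mean_zero_variance_scaled(self):
        """E[y_lock] = 0 and Var[y_lock] = sigma^2 * sum cos^2(omega i)."""
        omega, n, sigma, reps = 2.63, 150, 25.0, 10_000
        idx = np.arange(1, n + 1)
        cosv = np.cos(omega * idx)
        rng = np.random.default_rng(20260930)
        eps = rng.normal(0.0, sigma, size=(reps, n))
        ylocks = eps @ cosv
        # spot-check the vectorization against the controller primitive
        for r in range(3):
            ref = lockin_sum(list(zip(idx.tolist(), eps[r].tolist())), omega).y_lock
            assert ylocks[r] == pytest.approx(ref, rel=1e-12)
        true_var = sigma**2 * float(np.sum(cosv**2))
        assert abs(ylocks.mean()) < 3.0 * math.sqrt(true_var / reps)
        se_var = true_var * math.sqrt(2.0 / (reps - 1))
        assert abs(ylocks.var(ddof=1) - true_var) < 3.0 * se_var
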