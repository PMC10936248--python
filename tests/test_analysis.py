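"""Cycle segmentation, normalization, outcomes and paired statistics."""

import numpy as np
import pytest
from scipy import stats as spstats

from neckbrace.analysis import (
    PCT_GRID,
    MovementCycle,
    compute_outcomes,
    extract_cycles,
    paired_stats,
    segment_cycles,
    time_normalize_and_average,
)
from neckbrace.errors import InvalidInputError, SegmentationError
from neckbrace.synthetic import SyntheticSpec, angle_profile

FS = 100.0


def protocol_trial(n_cycles=5, period=3.6, a1=40.0, a2=40.0, lead=1.0, tail=1.0):
    duration = lead + n_cycles * period + tail
    t = np.arange(int(duration * FS)) / FS
    x, truth = angle_profile(t, a1, a2, period, n_cycles, lead)
    return t, x, truth


class TestSegmentation:
    def test_protocol_trial_five_cycles(self):
        _, x, _ = protocol_trial()
        spans = segment_cycles(x)
        assert len(spans) == 5

    def test_flat_zero_empty(self):
        assert segment_cycles(np.zeros(500)) == []

    def test_boundaries_match_generator(self):
        t, x, truth = protocol_trial()
        spans = segment_cycles(x)
        expected = [int(round(b * FS)) for b in truth["boundaries_s"]]
        detected = [spans[0].start] + [s.end for s in spans]
        for d, e in zip(detected, expected):
            assert abs(d - e) <= 2
        # extrema located at the sub-block boundaries
        for k, s in enumerate(spans):
            assert abs(s.extremum1 - int(round(truth["extremum1_s"][k] * FS))) <= 2
            assert abs(s.extremum2 - int(round(truth["extremum2_s"][k] * FS))) <= 2

    def test_start_outside_band_raises(self):
        _, x, _ = protocol_trial()
        with pytest.raises(SegmentationError):
            segment_cycles(x + 30.0)

    def test_partial_trailing_excursion_discarded(self):
        t, x, _ = protocol_trial(n_cycles=3)
        cut = int((1.0 + 2 * 3.6 + 0.4 * 3.6) * FS)  # mid third cycle
        spans = segment_cycles(x[:cut])
        assert len(spans) == 2

    def test_count_invariant_to_small_noise(self):
        _, x, _ = protocol_trial()
        rng = np.random.default_rng(77)
        peak = np.max(np.abs(x))
        # noise below half the hysteresis band (exit - enter = 10% peak)
        noise = 0.04 * peak * rng.uniform(-1, 1, x.size)
        spans = segment_cycles(x + noise)
        assert len(spans) == 5

    def test_opposite_first_direction(self):
        _, x, _ = protocol_trial()
        assert len(segment_cycles(-x)) == 5


class TestNormalizeAverage:
    def make_cycle(self, scale=1.0, phase=+1.0):
        t = np.linspace(0, 1, 145)
        x, _ = angle_profile(t, phase * 30.0, phase * 30.0, 1.0, 1, 0.0)
        grid = np.linspace(0, len(t) - 1, 101)
        angle = np.interp(grid, np.arange(len(t)), x)
        return MovementCycle(
            motion_type="lateral_bending",
            angle=angle,
            envelopes={"SCM_L": np.abs(angle) / 30.0},
            duration_s=1.45 * scale,
        )

    def test_identical_cycles_mean_equals_one(self):
        cycles = [self.make_cycle() for _ in range(5)]
        mean = time_normalize_and_average(cycles)
        np.testing.assert_allclose(mean.angle, cycles[0].angle, atol=1e-12)
        np.testing.assert_allclose(
            mean.envelopes["SCM_L"], cycles[0].envelopes["SCM_L"], atol=1e-12
        )

    def test_endpoints_preserved_exactly(self):
        x = np.sin(np.linspace(0, 3, 137)) + 2.0
        t = np.arange(137, dtype=float)
        grid = np.linspace(0, 136, 101)
        res = np.interp(grid, t, x)
        assert res[0] == x[0]
        assert res[-1] == x[-1]

    def test_time_dilation_invariance(self):
        """Two cycles that are pure time dilations of one waveform.

        The waveform is piecewise linear on the percent grid so linear
        resampling is exact and the mean must reproduce it.
        """
        base_t = np.linspace(0, 1, 101)
        wave, _ = angle_profile(base_t, 20.0, 25.0, 1.0, 1, 0.0)

        def dilated(n):
            tt = np.linspace(0, 1, n)
            x = np.interp(tt, base_t, wave)  # same waveform, new sampling
            grid = np.linspace(0, n - 1, 101)
            return MovementCycle(
                motion_type="axial_rotation",
                angle=np.interp(grid, np.arange(n), x),
                duration_s=n / FS,
            )

        c1, c2 = dilated(401), dilated(201)  # grids nest the 101 points
        mean = time_normalize_and_average([c1, c2])
        np.testing.assert_allclose(mean.angle, wave, atol=1e-6)

    def test_opposite_phase_cycles_do_not_cancel(self):
        a = self.make_cycle(phase=+1.0)
        b = self.make_cycle(phase=-1.0)
        mean = time_normalize_and_average([a, b])
        assert np.max(np.abs(mean.angle)) > 25.0

    def test_mixed_motion_types_rejected(self):
        a = self.make_cycle()
        b = MovementCycle(
            motion_type="axial_rotation", angle=a.angle, duration_s=1.0
        )
        with pytest.raises(InvalidInputError):
            time_normalize_and_average([a, b])

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            time_normalize_and_average([])


class TestOutcomes:
    def test_extrema_and_rom(self):
        t = np.linspace(0, 1, 101)
        angle = 40.0 * np.sin(2 * np.pi * t)
        cyc = MovementCycle(
            motion_type="lateral_bending", angle=angle, duration_s=2.0
        )
        out = compute_outcomes(cyc)
        assert out.max_angle_deg == pytest.approx(40.0, abs=1e-2)
        assert out.min_angle_deg == pytest.approx(-40.0, abs=1e-2)
        assert out.rom_deg == pytest.approx(80.0, abs=2e-2)
        assert out.completion_time_s == 2.0

    def test_rom_invariant_to_sign_flip(self):
        t = np.linspace(0, 1, 101)
        angle = 35.0 * np.sin(2 * np.pi * t) + 3.0
        a = MovementCycle("axial_rotation", angle, duration_s=1.0)
        b = MovementCycle("axial_rotation", -angle, duration_s=1.0)
        oa, ob = compute_outcomes(a), compute_outcomes(b)
        assert oa.rom_deg == pytest.approx(ob.rom_deg, abs=1e-12)
        assert oa.max_angle_deg == pytest.approx(-ob.min_angle_deg, abs=1e-12)

    def test_raised_cosine_peak_at_25pct(self):
        pct = PCT_GRID
        env = np.zeros(101)
        mask = np.abs(pct - 25.0) <= 15.0
        env[mask] = 0.5 * (1 + np.cos(np.pi * (pct[mask] - 25.0) / 15.0))
        cyc = MovementCycle(
            "flexion_extension",
            np.sin(np.linspace(0, 2 * np.pi, 101)),
            envelopes={"SC_L": env},
            duration_s=1.0,
        )
        out = compute_outcomes(cyc)
        assert out.emg_peak_timing_pct["SC_L"] == pytest.approx(25.0)

    def test_constant_envelope_tie_is_earliest(self):
        cyc = MovementCycle(
            "flexion_extension",
            np.sin(np.linspace(0, 2 * np.pi, 101)),
            envelopes={"TR_R": np.ones(101)},
            duration_s=1.0,
        )
        assert compute_outcomes(cyc).emg_peak_timing_pct["TR_R"] == 0.0


class TestPairedStats:
    def test_hand_computed_example(self):
        """d = (1,2,3,4,5): frozen values from the closed-form t formulas."""
        pre = np.zeros(5)
        post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        st = paired_stats(pre, post)
        assert st.mean_diff == pytest.approx(3.0)
        assert st.t_stat == pytest.approx(4.2426, abs=1e-4)
        assert st.df == 4
        assert st.ci_low == pytest.approx(1.0368, abs=1e-4)
        assert st.ci_high == pytest.approx(4.9632, abs=1e-4)
        assert st.p_value == pytest.approx(0.0132, abs=2e-4)
        assert st.significant

    def test_small_differences_not_significant(self):
        pre = np.zeros(5)
        post = np.array([0.1, -0.1, 0.05, -0.05, 0.0])
        st = paired_stats(pre, post)
        assert abs(st.t_stat) < 1.0
        assert st.p_value > 0.5
        assert not st.significant

    def test_identical_groups_degenerate(self, rng):
        x = rng.uniform(-5, 5, 8)
        st = paired_stats(x, x)
        assert st.mean_diff == 0.0
        assert st.degenerate
        assert not st.significant
        assert st.p_value == 1.0

    def test_constant_nonzero_difference(self, rng):
        x = rng.uniform(-5, 5, 6)
        st = paired_stats(x, x + 2.0)
        assert st.degenerate
        assert st.significant
        assert st.p_value == 0.0
        assert st.t_stat == np.inf

    def test_against_scipy_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 20))
            pre = rng.normal(0, 3, n)
            post = pre + rng.normal(0.5, 2, n)
            st = paired_stats(pre, post)
            ref = spstats.ttest_rel(post, pre)
            assert st.t_stat == pytest.approx(ref.statistic, abs=1e-10)
            assert st.p_value == pytest.approx(ref.pvalue, abs=1e-8)
            lo, hi = ref.confidence_interval(0.95)
            assert st.ci_low == pytest.approx(lo, abs=1e-8)
            assert st.ci_high == pytest.approx(hi, abs=1e-8)

    def test_n_too_small(self):
        with pytest.raises(InvalidInputError):
            paired_stats([1.0], [2.0])

    def test_unequal_lengths(self):
        with pytest.raises(InvalidInputError):
            paired_stats([1.0, 2.0], [1.0, 2.0, 3.0])


class TestExtractCycles:
    def test_envelopes_resampled_alongside(self):
        t, x, _ = protocol_trial(n_cycles=3)
        env = {"SCM_L": np.abs(x) / 40.0}
        cycles = extract_cycles(x, FS, "lateral_bending", envelopes=env)
        assert len(cycles) == 3
        for c in cycles:
            assert c.angle.size == 101
            assert c.envelopes["SCM_L"].size == 101
            assert c.duration_s == pytest.approx(3.6, abs=0.1)
            b1, b2 = c.subblocks_pct
            assert 0 < b1 < b2 < 100
            assert b1 == pytest.approx(25.0, abs=2.0)
            assert b2 == pytest.approx(75.0, abs=2.0)
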