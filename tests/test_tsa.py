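"""Melt-curve Tm extraction, robust plate statistics and hit calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clickscreen.simulate import ScenarioSpec, gen_melt_plate
from clickscreen.tsa import (
    MeltCurve,
    ShiftTable,
    TmResult,
    analyze_plate,
    call_hits,
    compute_shifts,
    curves_from_frame,
    extract_tm,
    robust_stats,
)
from conftest import TEMPS, make_melt_curve


class TestExtractTm:
    @pytest.mark.parametrize("method", ["derivative", "boltzmann"])
    def test_noiseless_sigmoid_recovered_exactly(self, method):
        res = extract_tm(make_melt_curve(tm=55.0), method)
        assert res.usable
        assert res.tm == pytest.approx(55.0, abs=0.1)

    def test_noisy_sigmoid_within_tolerance(self):
        # 2% of amplitude Gaussian noise, default (sigmoid-fit) method
        errs = [
            abs(extract_tm(make_melt_curve(55.0, noise_sd=0.02, seed=s)).tm - 55.0)
            for s in range(20)
        ]
        assert max(errs) <= 0.3

    @pytest.mark.parametrize("method", ["derivative", "boltzmann"])
    def test_flat_curve_unusable(self, method):
        rng = np.random.default_rng(0)
        flat = MeltCurve(
            "P1", "W01", "c1", "sample", TEMPS,
            0.5 + 0.002 * rng.standard_normal(TEMPS.size),
        )
        assert not extract_tm(flat, method).usable

    def test_boundary_transition_unusable(self):
        res = extract_tm(make_melt_curve(tm=94.0), "derivative")
        # transition truncated by the ramp end: either boundary-flagged or
        # resolved within the grid; a mid-ramp curve must stay usable
        assert extract_tm(make_melt_curve(tm=55.0), "derivative").usable

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            MeltCurve("P", "W", "c", "sample", TEMPS[:10], np.ones(10))

    def test_non_monotone_grid_rejected(self):
        t = TEMPS.copy()
        t[5] = t[4]
        with pytest.raises(ValueError, match="increasing"):
            MeltCurve("P", "W", "c", "sample", t, np.ones(t.size))


class TestShifts:
    def make_results(self, tms):
        return {f"c{i}": TmResult(tm, "boltzmann", 10.0, True) for i, tm in enumerate(tms)}

    def test_delta_against_control_median(self):
        controls = [TmResult(55.0, "boltzmann", 10.0, True)] * 3
        table = compute_shifts("P1", self.make_results([57.0, 53.5]), controls)
        assert table.delta_tm["c0"] == pytest.approx(2.0)
        assert table.delta_tm["c1"] == pytest.approx(-1.5)

    def test_unusable_sample_excluded_with_reason(self):
        controls = [TmResult(55.0, "boltzmann", 10.0, True)]
        samples = {
            "good": TmResult(56.0, "boltzmann", 10.0, True),
            "bad": TmResult(0.0, "boltzmann", 0.0, False, reason="no transition"),
        }
        table = compute_shifts("P1", samples, controls)
        assert "bad" not in table.delta_tm
        assert table.excluded["bad"] == "no transition"

    def test_no_usable_controls_errors(self):
        with pytest.raises(ValueError, match="control"):
            compute_shifts("P1", {}, [TmResult(55.0, "x", 0.0, False)])


class TestRobustStats:
    def test_hand_checked_outlier_example(self):
        med, rsd = robust_stats([1, 2, 3, 4, 100])
        assert med == 3.0
        assert rsd == pytest.approx(1.4826)

    def test_all_equal_gives_zero_spread(self):
        assert robust_stats([2.0] * 6) == (2.0, 0.0)

    def test_symmetric_set_median_zero(self):
        med, _ = robust_stats([-1.5, 0.0, 1.5, 0.0])
        assert med == 0.0

    def test_sparse_plate_rejected(self):
        with pytest.raises(ValueError, match="sparse"):
            robust_stats([1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(-50, 50, allow_nan=False, allow_infinity=False),
            min_size=4,
            max_size=60,
        )
    )
    def test_matches_brute_force_median_mad_oracle(self, xs):
        def brute_median(v):
            v = sorted(v)
            n = len(v)
            return v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2

        med, rsd = robust_stats(xs)
        bmed = brute_median(xs)
        assert med == pytest.approx(bmed, abs=1e-9)
        assert rsd == pytest.approx(
            1.4826 * brute_median([abs(x - bmed) for x in xs]), abs=1e-9
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=30),
        st.floats(0.1, 20),
    )
    def test_scale_equivariance(self, xs, c):
        med, rsd = robust_stats(xs)
        med_c, rsd_c = robust_stats([c * x for x in xs])
        assert med_c == pytest.approx(c * med, rel=1e-9, abs=1e-9)
        assert rsd_c == pytest.approx(c * rsd, rel=1e-9, abs=1e-9)

    def test_bounded_breakdown_against_classical_sd(self):
        base = [0.1, -0.1, 0.05, 0.0, -0.05, 0.02]
        _, rsd0 = robust_stats(base)
        _, rsd1 = robust_stats(base + [1e6])
        assert rsd1 < 10 * (rsd0 + 0.1)  # scaled MAD barely moves
        assert np.std(base + [1e6]) > 1e5  # classical SD explodes


class TestCallHits:
    def make_table(self, shifts):
        return ShiftTable("P1", {f"c{i}": s for i, s in enumerate(shifts)})

    def test_quiet_plate_floor_rule_single_hit(self):
        table = call_hits(self.make_table([0.0] * 9 + [2.0]))
        assert table.med == 0.0 and table.rsd == 0.0
        assert table.threshold == 0.5  # floored
        assert table.hit_ids() == ["c9"]
        assert table.direction["c9"] == "positive"

    def test_subthreshold_shifts_never_hit(self):
        table = call_hits(self.make_table([0.4, -0.3, 0.2, 0.45, -0.45, 0.1]))
        assert table.hit_ids() == []

    def test_hit_set_invariant_when_floor_scales_with_shifts(self):
        shifts = [0.0, 0.1, -0.2, 0.05, 2.0, -1.5, 0.02, -0.07]
        t1 = call_hits(self.make_table(shifts), floor=0.5)
        t2 = call_hits(self.make_table([3 * s for s in shifts]), floor=1.5)
        assert t1.hit_ids() == t2.hit_ids()

    def test_planted_shifter_plate_recovers_structure(self):
        plate, truth = gen_melt_plate(ScenarioSpec(seed=42))
        table = analyze_plate(curves_from_frame(plate))
        assert len(table.hit_ids("positive")) == 5
        assert len(table.hit_ids("negative")) == 10
        planted = {cid for cid, s in truth.items() if s != 0.0}
        assert set(table.hit_ids()) == planted

    def test_extreme_control_leaves_reference_and_threshold_unchanged(self):
        samples = {
            f"c{i}": TmResult(tm, "boltzmann", 10.0, True)
            for i, tm in enumerate([55.0, 55.1, 54.9, 55.2, 58.0])
        }
        clean = [TmResult(t, "boltzmann", 10.0, True) for t in (55.0, 55.0, 55.0)]
        spiked = clean + [TmResult(200.0, "boltzmann", 10.0, True)]
        t_clean = call_hits(compute_shifts("P1", samples, clean))
        t_spiked = call_hits(compute_shifts("P1", samples, spiked))
        # the median control reference absorbs the outlier; med/rsd are
        # sample-only, so the threshold and hit set are identical
        assert t_spiked.med == pytest.approx(t_clean.med)
        assert t_spiked.rsd == pytest.approx(t_clean.rsd)
        assert t_spiked.hit_ids() == t_clean.hit_ids()

    def test_on_absolute_option_changes_basis(self):
        shifts = [1.0, -1.0, 1.0, -1.0, 3.0]
        signed = call_hits(self.make_table(shifts))
        absolute = call_hits(self.make_table(shifts), on_absolute=True)
        assert signed.med == pytest.approx(1.0)
        assert absolute.med == pytest.approx(1.0)
        assert absolute.rsd == pytest.approx(0.0)
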