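from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetamove.segmentation import (detect_calving, detect_migration_phases,
                                   lavielle_segment, optimal_breakpoints)


def exhaustive_contrast(x, K, Lmin):
    """Brute-force optimum over all K-segmentations (oracle for small n)."""
    n = len(x)

    def sse(a, b):
        seg = x[a:b]
        return float(np.sum((seg - seg.mean()) ** 2))

    if K == 1:
        return sse(0, n), []
    best = (np.inf, None)
    for bps in combinations(range(1, n), K - 1):
        bounds = [0, *bps, n]
        if any(b - a < Lmin for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        tot = sum(sse(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if tot < best[0]:
            best = (tot, list(bps))
    return best


class TestOptimalBreakpoints:
    @pytest.mark.parametrize("K", [1, 2, 3])
    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_enumeration(self, K, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 30))
        x = rng.normal(0, 1, n) + np.repeat(
            rng.normal(0, 2, 3), [n // 3, n // 3, n - 2 * (n // 3)])
        J, bps = optimal_breakpoints(x, K, Lmin=2)
        J_ref, bps_ref = exhaustive_contrast(x, K, 2)
        assert J == pytest.approx(J_ref, abs=1e-9)
        if K > 1:
            assert bps == bps_ref

    def test_contrast_nonincreasing_in_K(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 60)
        Js = [optimal_breakpoints(x, K, 2)[0] for K in range(1, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(Js, Js[1:]))

    def test_infeasible_K_raises(self):
        with pytest.raises(ValueError):
            optimal_breakpoints(np.zeros(10), K=4, Lmin=3)


class TestLavielleSelection:
    def test_constant_series_yields_one_segment(self):
        res = lavielle_segment(np.full(50, 2.5), Kmax=8, Lmin=4)
        assert res.K == 1
        assert res.breakpoints == []

    def test_clean_step_found_at_true_position(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.1, 0.02, 20), rng.normal(0.9, 0.02, 20)])
        res = lavielle_segment(x, Kmax=5, Lmin=2)
        assert res.K == 2
        assert abs(res.breakpoints[0] - 20) <= 1

    def test_segment_means_match_arithmetic_means(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(3, 0.1, 30)])
        res = lavielle_segment(x, Kmax=4, Lmin=4)
        for (a, b), m in zip(res.segment_bounds, res.segment_means):
            assert m == pytest.approx(np.mean(x[a:b]))

    def test_breakpoint_recovery_rate_on_step_changes(self):
        """>= 95% of high-SNR step changes located within +/-2 positions."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            b_true = int(rng.integers(30, 70))
            x = np.concatenate([rng.normal(0, 0.1, b_true),
                                rng.normal(1.0, 0.1, 100 - b_true)])  # SNR 10
            _, bps = optimal_breakpoints(x, 2, Lmin=8)
            hits += abs(bps[0] - b_true) <= 2
        assert hits / n_rep >= 0.95

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_random_series_dp_is_optimal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 18)
        J, _ = optimal_breakpoints(x, 3, Lmin=2)
        J_ref, _ = exhaustive_contrast(x, 3, 2)
        assert J == pytest.approx(J_ref, abs=1e-9)


def _gamma_track(levels, seg_len, noise, rng):
    gam = np.concatenate([np.full(seg_len, lv) for lv in levels])
    gam = np.clip(gam + rng.normal(0, noise, len(gam)), 0, 1)
    ts = pd.date_range("2019-01-08", periods=len(gam), freq="6h", tz="UTC")
    return pd.DataFrame({"timestamp": ts, "gamma": gam})


class TestMigrationPhases:
    def test_seven_phase_structure_recovered(self):
        rng = np.random.default_rng(21)
        levels = [0.2, 0.9, 0.25, 0.92, 0.2, 0.9, 0.3]
        tr = _gamma_track(levels, 60, 0.05, rng)
        res, phases = detect_migration_phases(tr, Kmax=10)
        assert res.K == 7
        truth = [60 * i for i in range(1, 7)]
        assert all(abs(b - t) <= 2 for b, t in zip(res.breakpoints, truth))
        assert [p.label for p in phases] == ["residence", "transit"] * 3 + ["residence"]

    def test_all_transit_track_is_single_transit_segment(self):
        rng = np.random.default_rng(2)
        tr = _gamma_track([0.9], 80, 0.03, rng)
        res, phases = detect_migration_phases(tr, Kmax=6)
        assert res.K == 1
        assert phases[0].label == "transit"

    def test_phase_times_cover_track(self):
        rng = np.random.default_rng(3)
        tr = _gamma_track([0.2, 0.8], 40, 0.05, rng)
        _, phases = detect_migration_phases(tr)
        assert phases[0].start == 0
        assert phases[-1].end == len(tr)


class TestCalvingDetection:
    def _speed_track(self, speeds):
        ts = pd.date_range("2019-03-01", periods=len(speeds), freq="6h", tz="UTC")
        return pd.DataFrame({"timestamp": ts, "speed_through_water": speeds})

    def test_speed_shift_found_within_one_day(self):
        rng = np.random.default_rng(31)
        b_true = 96  # 24 days in
        speeds = np.concatenate([
            np.clip(rng.normal(1.7, 0.35, b_true), 0, None),
            np.clip(rng.normal(1.3, 0.35, 244 - b_true), 0, None),
        ])
        res = detect_calving(self._speed_track(speeds))
        assert res.detected
        assert abs(res.breakpoint_index - b_true) <= 4   # 4 steps = 1 day
        assert res.median_speed_before > res.median_speed_after

    def test_constant_speed_leg_reports_no_change(self):
        rng = np.random.default_rng(5)
        speeds = np.clip(rng.normal(1.5, 0.01, 120), 0, None)
        res = detect_calving(self._speed_track(speeds))
        assert not res.detected

    @pytest.mark.parametrize("seed", range(10))
    def test_k2_optimum_matches_exhaustive_single_split(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(40, 120))
        b = int(rng.integers(10, n - 10))
        x = np.concatenate([rng.normal(1.6, 0.3, b), rng.normal(1.2, 0.3, n - b)])
        _, bps = optimal_breakpoints(x, 2, Lmin=8)
        best = min(
            range(8, n - 7),
            key=lambda s: np.sum((x[:s] - x[:s].mean()) ** 2)
            + np.sum((x[s:] - x[s:].mean()) ** 2),
        )
        assert bps[0] == best
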