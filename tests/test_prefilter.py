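import datetime as dt

import numpy as np
import pytest

from cetamove.geodesy import geodesic_inverse
from cetamove.io_formats import QUALITY_ORDER
from cetamove.prefilter import (FilterSettings, InsufficientDataError,
                                project_azimuthal_equidistant, sda_filter)
from tests.conftest import UTC, make_obs


def brute_force_speed_filter(obs, vmax):
    """Independent restatement of the iterative speed criterion.

    Repeatedly drop the single worst fix whose adjacent transit speeds all
    exceed vmax (worse class first, then later time), until none remain.
    """
    kept = list(range(len(obs)))

    def leg_speed(i, j):
        d, _ = geodesic_inverse(obs[i].lon, obs[i].lat, obs[j].lon, obs[j].lat)
        sec = (obs[j].timestamp - obs[i].timestamp).total_seconds()
        return d / sec if sec > 0 else float("inf")

    while True:
        flagged = []
        for pos, i in enumerate(kept):
            fast_in = pos > 0 and leg_speed(kept[pos - 1], i) > vmax
            fast_out = pos < len(kept) - 1 and leg_speed(i, kept[pos + 1]) > vmax
            if pos == 0:
                neigh_interior = (len(kept) > 2
                                  and leg_speed(kept[1], kept[2]) > vmax
                                  and leg_speed(kept[0], kept[1]) > vmax)
                if fast_out and not neigh_interior:
                    flagged.append(i)
            elif pos == len(kept) - 1:
                neigh_interior = (len(kept) > 2
                                  and leg_speed(kept[-3], kept[-2]) > vmax
                                  and leg_speed(kept[-2], kept[-1]) > vmax)
                if fast_in and not neigh_interior:
                    flagged.append(i)
            elif fast_in and fast_out:
                flagged.append(i)
        if not flagged:
            return kept
        worst = max(flagged, key=lambda i: (
            QUALITY_ORDER.index(obs[i].quality_class), obs[i].timestamp))
        kept.remove(worst)


def random_track(rng, n=20, outlier_prob=0.25):
    t0 = dt.datetime(2019, 1, 8, tzinfo=UTC)
    obs = []
    lon, lat = -20.0, 45.0
    for i in range(n):
        lon += rng.normal(0, 0.02)
        lat += rng.normal(0.02, 0.01)
        olon, olat = lon, lat
        if rng.random() < outlier_prob:
            olon = lon + rng.choice([-1, 1]) * rng.uniform(0.5, 2.0)
            olat = lat + rng.choice([-1, 1]) * rng.uniform(0.5, 2.0)
        qc = rng.choice(["3", "2", "1", "0", "A", "B"])
        obs.append(make_obs(t0 + dt.timedelta(hours=float(i)), olon, olat, qc))
    return obs


class TestProjection:
    def test_observations_project_and_center_is_origin(self, straight_track):
        xs, ys = project_azimuthal_equidistant(straight_track, (-20.0, 45.0))
        assert xs[0] == pytest.approx(0.0, abs=1e-9)
        assert ys[0] == pytest.approx(0.0, abs=1e-9)
        assert ys[-1] > ys[0]


class TestSdaFilter:
    def test_clean_slow_track_untouched(self, straight_track):
        kept, report = sda_filter(straight_track)
        assert len(kept) == len(straight_track)
        assert report.removals == []

    def test_fast_spike_middle_point_removed(self, t0):
        # middle point ~43 km off course one hour later: ~12 m/s in and out
        obs = [
            make_obs(t0, -20.0, 45.0),
            make_obs(t0 + dt.timedelta(hours=1), -20.0, 45.39),
            make_obs(t0 + dt.timedelta(hours=2), -20.0, 45.02),
            make_obs(t0 + dt.timedelta(hours=3), -20.0, 45.03),
        ]
        kept, report = sda_filter(obs)
        assert len(kept) == 3
        assert report.removals[0].reason == "speed > vmax"
        assert kept[0].timestamp == obs[0].timestamp
        assert kept[1].timestamp == obs[2].timestamp

    def test_class_z_always_removed(self, t0, straight_track):
        obs = list(straight_track)
        obs[4] = make_obs(obs[4].timestamp, obs[4].lon, obs[4].lat, "Z")
        kept, report = sda_filter(obs)
        assert all(o.quality_class != "Z" for o in kept)
        assert any("Z" in r.reason for r in report.removals)

    def test_too_few_usable_fixes_is_error(self, t0):
        obs = [make_obs(t0 + dt.timedelta(hours=i), -20.0, 45.0 + 0.001 * i, "Z")
               for i in range(3)]
        obs.append(make_obs(t0 + dt.timedelta(hours=3), -20.0, 45.01, "1"))
        with pytest.raises(InsufficientDataError):
            sda_filter(obs)

    def test_output_is_subsequence_of_input(self):
        rng = np.random.default_rng(11)
        obs = random_track(rng)
        kept, _ = sda_filter(obs)
        it = iter(obs)
        assert all(any(o is k for o in it) for k in kept)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        obs = random_track(rng)
        kept1, _ = sda_filter(obs)
        kept2, rep2 = sda_filter(kept1)
        assert len(kept2) == len(kept1)
        assert rep2.removals == []

    def test_report_accounts_for_every_row(self):
        rng = np.random.default_rng(17)
        obs = random_track(rng)
        kept, report = sda_filter(obs)
        assert report.n_input == len(obs)
        assert len(kept) + len(report.removals) == len(obs)

    @pytest.mark.parametrize("seed", range(20))
    def test_speed_criterion_matches_brute_force(self, seed):
        """Spike-free settings isolate the speed criterion against the oracle."""
        rng = np.random.default_rng(100 + seed)
        obs = random_track(rng)
        settings = FilterSettings(spike_angles=(), spike_distances=())
        kept, _ = sda_filter(obs, settings)
        expected = brute_force_speed_filter(obs, settings.vmax)
        assert [obs.index(k) for k in kept] == expected
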