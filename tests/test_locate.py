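import numpy as np
import pandas as pd
import pytest

from whaletrack import geo, locate, simulate
from whaletrack.exceptions import InputError
from whaletrack.locate import LocalizationConfig

from conftest import noiseless_detections


@pytest.fixture(scope="module")
def cfg():
    return LocalizationConfig(search_spacing_deg=(0.02, 0.03),
                              fine_halfwidth_km=15.0)


@pytest.fixture(scope="module")
def grid(network_4x4, curve, cfg):
    return locate.build_search_grid(network_4x4, curve, cfg)


def test_sigma_step_function():
    assert locate.sigma_for_probability(0.95) == 2.0
    assert locate.sigma_for_probability(0.9) == 2.0
    assert locate.sigma_for_probability(0.8) == 2.5
    assert locate.sigma_for_probability(0.5) == 3.0
    assert locate.sigma_for_probability(0.2) == 3.5
    assert locate.sigma_for_probability(0.05) == 3.5


def test_q_small_value(cfg):
    assert round(cfg.q_small, 3) == 0.011


class TestGatherCandidates:
    def base(self, network_4x4):
        st = network_4x4
        rows = [
            {"station": st["id"][5], "time": 1000.0, "rs": 6.5, "duration": 10.0,
             "p_true": 0.99},                                   # master
            {"station": st["id"][6], "time": 1050.0, "rs": 4.0, "duration": 8.0,
             "p_true": 0.5},
            {"station": st["id"][9], "time": 1101.0, "rs": 4.0, "duration": 8.0,
             "p_true": 0.5},                                    # 101 s late
            {"station": st["id"][10], "time": 1060.0, "rs": 3.0, "duration": 5.0,
             "p_true": 0.2},                                    # p exactly 0.2
            {"station": st["id"][0], "time": 1080.0, "rs": 3.0, "duration": 5.0,
             "p_true": 0.15},                                   # below p_detect_min
            {"station": st["id"][5], "time": 1040.0, "rs": 5.0, "duration": 8.0,
             "p_true": 0.9},                                    # master's own station
        ]
        return pd.DataFrame(rows)

    def test_window_and_thresholds(self, network_4x4, cfg):
        det = self.base(network_4x4)
        cs = locate.gather_candidates(0, det, network_4x4, cfg)
        gathered = {i for idx in cs.det_idx for i in idx}
        assert 0 in gathered         # the master itself
        assert 1 in gathered
        assert 2 not in gathered     # 101 s after the master
        assert 3 in gathered         # p = 0.2 inclusive
        assert 4 not in gathered     # p below 0.2
        assert 5 not in gathered     # later detection on the master's station

    def test_distant_station_excluded(self, network_4x4, cfg):
        det = self.base(network_4x4)
        # station 15 is ~3 cells away from station 5 -> > 150 km
        d = geo.great_circle_km(network_4x4["lon"][15], network_4x4["lat"][15],
                                network_4x4["lon"][5], network_4x4["lat"][5])
        assert d > cfg.max_station_dist_km
        det.loc[len(det)] = {"station": network_4x4["id"][15], "time": 1090.0,
                             "rs": 5.0, "duration": 8.0, "p_true": 0.9}
        cs = locate.gather_candidates(0, det, network_4x4, cfg)
        assert network_4x4["id"][15] not in cs.station_ids

    def test_low_probability_master_rejected(self, network_4x4, cfg):
        det = self.base(network_4x4)
        with pytest.raises(InputError):
            locate.gather_candidates(1, det, network_4x4, cfg)


class TestOriginTime:
    def test_identity_at_station(self, curve):
        assert locate.origin_time(1000.0, curve.predict(0.0)) == 1000.0

    def test_range_offset(self, curve):
        assert locate.origin_time(1000.0, curve.predict(74.0)) \
            == pytest.approx(950.0)

    def test_definition_everywhere(self, curve, rng):
        tt = curve.predict(rng.uniform(0, 300, 100))
        O = locate.origin_time(1000.0, tt)
        assert O + tt == pytest.approx(1000.0)


def _simple_cs(times_by_station, sigmas=None, probs=None, master_sigma=2.0):
    """CandidateSet over abstract stations (travel-time tables given directly)."""
    S = len(times_by_station)
    sigmas = sigmas or [[2.0] * len(t) for t in times_by_station]
    probs = probs or [[0.95] * len(t) for t in times_by_station]
    return locate.CandidateSet(
        0, "S0", float(times_by_station[0][0]), master_sigma,
        [f"S{i}" for i in range(S)], np.zeros(S), np.zeros(S),
        [np.asarray(t, dtype=float) for t in times_by_station],
        [np.asarray(s, dtype=float) for s in sigmas],
        [np.asarray(p, dtype=float) for p in probs],
        [np.arange(len(t)) for t in times_by_station])


class TestMethod1Surface:
    def test_floor_only_surface(self, cfg):
        # candidates that cannot fit anywhere: L = q_small^N * integration span
        cs = _simple_cs([[0.0], [5000.0], [6000.0]])
        tt = np.zeros((3, 10))
        L, tp = locate.method1_surface(cs, tt, cfg)
        # the master term itself is above the floor near t' = 0
        master = np.maximum(np.exp(-0.5 * (tp / 2.0) ** 2), cfg.q_small)
        expect = np.trapezoid(master * cfg.q_small ** 2, tp)
        assert L == pytest.approx(expect, rel=1e-12)

    def test_poorly_fitting_station_contributes_q_small(self, cfg):
        # a station whose only candidate is 10 sigma off sits at the floor
        cs = _simple_cs([[0.0], [20.0]])
        tt = np.zeros((2, 1))
        L, tp = locate.method1_surface(cs, tt, cfg)
        master = np.maximum(np.exp(-0.5 * (tp / 2.0) ** 2), cfg.q_small)
        with_floor = np.trapezoid(master * cfg.q_small, tp)
        assert L[0] == pytest.approx(with_floor, rel=1e-6)

    def test_argmax_at_true_node_noiseless(self, network_4x4, curve, cfg, grid):
        lon0, lat0 = geo.from_local_km(-20.0, -30.0, -127.0, 46.5)
        det = noiseless_detections(network_4x4, curve, float(lon0), float(lat0))
        cs = locate.gather_candidates(det["time"].idxmin(), det, network_4x4, cfg)
        mi = grid.station_index(cs.master_station)
        mask = (grid.ranges[mi] <= 150.0).reshape(-1)
        tt = grid.times[[grid.station_index(s) for s in cs.station_ids]]
        tt = tt.reshape(len(cs.station_ids), -1)[:, mask]
        L, _ = locate.method1_surface(cs, tt, cfg)
        glon, glat = np.meshgrid(grid.lon_axis, grid.lat_axis)
        j = int(np.argmax(L))
        err = geo.great_circle_km(glon.reshape(-1)[mask][j],
                                  glat.reshape(-1)[mask][j],
                                  float(lon0), float(lat0))
        assert err < 3.0  # within one search-grid cell of the truth

    def test_oracle_equivalence_small(self, cfg, rng):
        """Vectorized L equals a brute-force station x candidate x t' loop."""
        cs = _simple_cs(
            [[0.0]] + [list(np.sort(rng.uniform(0, 80, rng.integers(1, 5))))
                       for _ in range(4)],
            sigmas=None, probs=None)
        for i in range(1, 5):
            k = len(cs.times[i])
            cs.sigmas[i] = rng.choice([2.0, 2.5, 3.0, 3.5], k)
        tt = rng.uniform(0, 70, (5, 400))
        L, tp = locate.method1_surface(cs, tt, cfg)
        acc = np.ones((400, tp.size))
        for i in range(5):
            best = np.full((400, tp.size), -np.inf)
            O = cs.master_time - tt[0]
            for k in range(len(cs.times[i])):
                for a in range(tp.size):
                    r = cs.times[i][k] - tt[i] - O - tp[a]
                    g = np.exp(-0.5 * (r / cs.sigmas[i][k]) ** 2)
                    best[:, a] = np.maximum(best[:, a], g)
            acc *= np.maximum(best, cfg.q_small)
        L_oracle = np.trapezoid(acc, tp, axis=1)
        assert np.max(np.abs(L - L_oracle) / np.abs(L_oracle)) < 1e-10


class TestMethod2Surface:
    def test_single_station_distance_floor(self):
        # one fitting station 30 km away with p=1 and the station-count gate
        # disabled scores 1/R = 0.02
        cfg = LocalizationConfig(m_min=1)
        cs = _simple_cs([[0.0]], probs=[[1.0]])
        tt = np.zeros((1, 1))
        E, tp = locate.method2_surface(cs, tt, np.array([[30.0]]), cfg)
        assert E.max() == pytest.approx(1.0 / 50.0)

    def test_fit_boundary(self):
        cfg = LocalizationConfig(m_min=1)
        # master plus one station whose candidate sits exactly at m' sigma
        for offset, fits in ((3.0 * 2.0, True), (3.03 * 2.0, False)):
            cs = _simple_cs([[0.0], [offset]], probs=[[1.0], [1.0]])
            tt = np.zeros((2, 1))
            E, tp = locate.method2_surface(cs, tt, np.array([[0.0], [40.0]]), cfg)
            j = np.argmin(np.abs(tp))  # t' = 0 column
            expect_station = 1.0 / 50.0
            got = E[0, j]
            if fits:
                assert got == pytest.approx(1.0 / 50.0 + expect_station)
            else:
                assert got == pytest.approx(1.0 / 50.0)

    def test_six_stations_at_fifty_km(self, cfg):
        # six perfect detections at 50 km: E = 6/50 = 0.12
        cs = _simple_cs([[0.0]] + [[0.0]] * 5,
                        probs=[[1.0]] * 6)
        tt = np.zeros((6, 1))
        E, _ = locate.method2_surface(cs, tt, np.full((6, 1), 50.0), cfg)
        assert E.max() == pytest.approx(6.0 / 50.0)

    def test_gate_zeroes_sparse_nodes(self, cfg):
        # three fitting stations < M_min = 4 -> E = 0 everywhere
        cs = _simple_cs([[0.0], [0.0], [0.0]], probs=[[1.0]] * 3)
        tt = np.zeros((3, 1))
        E, _ = locate.method2_surface(cs, tt, np.full((3, 1), 60.0), cfg)
        assert np.all(E == 0.0)


class TestFittingSubset:
    def test_best_candidate_per_station(self, cfg):
        cs = _simple_cs([[0.0], [2.0, 4.0]])
        fitted = locate.fitting_subset(cs, np.zeros(2), 0.0, cfg)
        by_station = {f.station: f for f in fitted}
        assert by_station["S1"].time == 2.0      # 1-sigma beats 2-sigma

    def test_station_dropped_beyond_m_prime(self, cfg):
        cs = _simple_cs([[0.0], [20.0]])
        fitted = locate.fitting_subset(cs, np.zeros(2), 0.0, cfg)
        assert [f.station for f in fitted] == ["S0"]

    def test_noiseless_recovers_generating_set(self, network_4x4, curve, cfg, grid):
        lon0, lat0 = geo.from_local_km(10.0, 25.0, -127.0, 46.5)
        det = noiseless_detections(network_4x4, curve, float(lon0), float(lat0))
        m = det["time"].idxmin()
        loc = locate.localize_master(m, det, network_4x4, curve, cfg, grid)
        # every gathered in-window detection is recovered, one per station
        cs = locate.gather_candidates(m, det, network_4x4, cfg)
        assert loc.fitted_ids == frozenset(int(i) for idx in cs.det_idx
                                           for i in idx)


class TestPosteriorAndSummary:
    def test_normalization(self, network_4x4, curve, cfg, grid):
        lon0, lat0 = geo.from_local_km(-20.0, -30.0, -127.0, 46.5)
        det = noiseless_detections(network_4x4, curve, float(lon0), float(lat0))
        m = det["time"].idxmin()
        loc = locate.localize_master(m, det, network_4x4, curve, cfg, grid)
        assert loc.accepted
        # the posterior itself integrates to one: rebuild it directly
        lat_axis, lon_axis = locate._fine_axes(loc.x_star[0], loc.x_star[1], cfg)
        f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
        st = network_4x4.set_index("id")
        tt = [curve.predict_masked(geo.great_circle_km(
            f_lon, f_lat, st.loc[f.station, "lon"], st.loc[f.station, "lat"]))
            for f in loc.fitted]
        m_tt = curve.predict_masked(geo.great_circle_km(
            f_lon, f_lat, st.loc[loc.master_station, "lon"],
            st.loc[loc.master_station, "lat"]))
        dlat = float(np.mean(np.diff(lat_axis)))
        dlon = float(np.mean(np.diff(lon_axis)))
        areas = (dlat * geo.KM_PER_DEG) \
            * (dlon * geo.KM_PER_DEG * np.cos(np.radians(lat_axis)))[:, None] \
            * np.ones((1, len(lon_axis)))
        P = locate.posterior_surface([f.time for f in loc.fitted],
                                     [f.sigma for f in loc.fitted],
                                     np.array(tt), m_tt, loc.master_time, cfg,
                                     sigma11=2.0, areas=areas)
        assert float(np.sum(P * areas)) == pytest.approx(1.0, abs=1e-6)

    def test_single_station_ring(self, curve, cfg):
        # one travel-time constraint with a known origin time produces a
        # ring-shaped density peaking at the range circle
        lat_axis = np.arange(46.0, 47.0, 0.01)
        lon_axis = np.arange(-127.7, -126.3, 0.015)
        f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
        r = geo.great_circle_km(f_lon, f_lat, -127.0, 46.5)
        tt = curve.predict_masked(r)
        # fixed origin: the "master table" is identically zero so O(x) is the
        # known origin time everywhere
        P = locate.posterior_surface([1000.0 + curve.predict(60.0)], [2.0],
                                     tt[None, :, :], np.zeros_like(tt),
                                     1000.0, cfg, sigma11=2.0)
        top = np.argsort(P.reshape(-1))[::-1][:200]
        ranges = r.reshape(-1)[top]
        assert np.abs(np.median(ranges) - 60.0) < 3.0
        assert np.std(ranges) < 5.0  # top density nodes share one range

    def test_mean_close_to_mode_noiseless(self, network_4x4, curve, cfg, grid):
        lon0, lat0 = geo.from_local_km(-20.0, -30.0, -127.0, 46.5)
        det = noiseless_detections(network_4x4, curve, float(lon0), float(lat0))
        loc = locate.localize_master(det["time"].idxmin(), det, network_4x4,
                                     curve, cfg, grid)
        d = geo.great_circle_km(loc.x_star[0], loc.x_star[1],
                                loc.mean[0], loc.mean[1])
        sigma = np.sqrt(np.linalg.eigvalsh(loc.cov_km2).max())
        assert d < sigma

    def test_multimodal_rejected(self, cfg):
        lat_axis = np.arange(46.0, 47.5, 0.01)
        lon_axis = np.arange(-128.0, -126.0, 0.015)
        f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
        P = np.exp(-0.5 * (geo.great_circle_km(f_lon, f_lat, -127.6, 46.4) / 4) ** 2) \
            + np.exp(-0.5 * (geo.great_circle_km(f_lon, f_lat, -126.4, 47.1) / 4) ** 2)
        summ = locate.summarize_location(P, lat_axis, lon_axis, cfg)
        assert not summ.accepted
        assert "multimodal" in summ.reasons

    def test_wide_posterior_rejected(self, cfg):
        lat_axis = np.arange(44.0, 49.0, 0.02)
        lon_axis = np.arange(-130.0, -124.0, 0.03)
        f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
        P = np.exp(-0.5 * (geo.great_circle_km(f_lon, f_lat, -127.0, 46.5) / 25) ** 2)
        summ = locate.summarize_location(P, lat_axis, lon_axis, cfg)
        assert not summ.accepted
        assert "uncertainty>20km" in summ.reasons

    def test_boundary_touch_rejected(self, cfg):
        lat_axis = np.arange(46.0, 46.5, 0.01)
        lon_axis = np.arange(-127.3, -126.7, 0.015)
        f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
        P = np.exp(-0.5 * (geo.great_circle_km(f_lon, f_lat, -127.3, 46.0) / 8) ** 2)
        summ = locate.summarize_location(P, lat_axis, lon_axis, cfg)
        assert not summ.accepted
        assert "grid_boundary" in summ.reasons


class TestLocalizeMaster:
    def test_too_few_stations_skipped(self, network_4x4, curve, cfg, grid):
        det = pd.DataFrame([
            {"station": network_4x4["id"][5], "time": 1000.0, "rs": 6.5,
             "duration": 10.0, "p_true": 0.99},
            {"station": network_4x4["id"][6], "time": 1040.0, "rs": 4.0,
             "duration": 8.0, "p_true": 0.5},
        ])
        loc = locate.localize_master(0, det, network_4x4, curve, cfg, grid)
        assert not loc.accepted
        assert "too_few_stations" in loc.reasons

    def test_methods_agree_on_clean_call(self, network_4x4, curve, cfg, grid):
        lon0, lat0 = geo.from_local_km(15.0, -10.0, -127.0, 46.5)
        det = noiseless_detections(network_4x4, curve, float(lon0), float(lat0))
        m = det["time"].idxmin()
        l1 = locate.localize_master(m, det, network_4x4, curve, cfg, grid, method=1)
        l2 = locate.localize_master(m, det, network_4x4, curve, cfg, grid, method=2)
        assert l1.accepted and l2.accepted
        assert geo.great_circle_km(l1.x_star[0], l1.x_star[1],
                                   l2.x_star[0], l2.x_star[1]) < 2.0
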