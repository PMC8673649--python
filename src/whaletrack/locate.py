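"""Master-detection localization of B calls on a sparse network.

Each detection whose true-positive probability exceeds a high threshold is
tried in turn as a "master detection": the assumed earliest arrival of a
call.  Candidate detections that follow the master within a feasible time
window on stations at a feasible distance are gathered, and a call location
is sought on a latitude-longitude grid.

Two search surfaces are supported.  Method 1 maximizes a likelihood built
from the best-matching candidate per station, floored at a small value
q_small so stations with no fitting detection cannot dominate, and
marginalized over the master's origin-time misfit t'.  Method 2 instead
maximizes the probability-weighted count of fitting detections divided by
their (floored) distance to the trial point, which favours solutions with
many high-probability detections on nearby stations.

Either way the surface yields a fitting subset (best candidate per station
within m' standard deviations); a spatial posterior density is then built
from just those detections, and the location is summarized by its most
probable point (spline-refined to 100 m), mean, and 2x2 covariance.
Solutions whose 95% highest-density region is multimodal or reaches the grid
edge, or whose 1-sigma uncertainty exceeds 20 km, are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from . import geo
from .exceptions import InputError
from .geo import KM_PER_DEG, TravelTimeCurve, TravelTimeGrid, precompute_travel_time_grid


def sigma_for_probability(p):
    """Detection-time uncertainty (s) versus true-positive probability.

    Step function on the tabulated anchors: 2.0 s for p >= 0.9, 2.5 s for
    0.8 <= p < 0.9, 3.0 s for 0.5 <= p < 0.8, 3.5 s below.
    """
    p = np.asarray(p, dtype=float)
    s = np.select([p >= 0.9, p >= 0.8, p >= 0.5], [2.0, 2.5, 3.0], default=3.5)
    return s if s.shape else float(s)


@dataclass
class LocalizationConfig:
    """Localization parameters (defaults follow the reference configuration)."""

    p_master_min: float = 0.9        # min probability for a master detection
    p_detect_min: float = 0.2        # min probability for a detection in the solution
    max_station_dist_km: float = 150.0  # station distance from the master's station
    max_dt_s: float = 100.0          # detection time window after the master
    m: float = 3.0                   # master misfit multiplier (t' integration bound)
    q_small: float = float(np.exp(-4.5))  # likelihood floor for a poorly fitting station
    m_prime: float = 3.0             # max |residual|/sigma for a fitting detection
    r_floor_km: float = 50.0         # distance floor R in the method-2 weighting
    m_min: int = 4                   # minimum number of fitting stations
    t_step_s: float = 0.25           # t' quadrature step
    max_sigma_km: float = 20.0       # 1-sigma acceptance cap
    hdr_level: float = 0.95          # highest-density-region level for acceptance
    sigma_of_p: Callable = sigma_for_probability
    search_spacing_deg: Sequence[float] = (0.005, 0.01)   # (dlat, dlon) search grid
    fine_spacing_deg: Sequence[float] = (0.005, 0.01)     # posterior grid
    fine_halfwidth_km: float = 25.0  # posterior window half-width about the argmax
    fine_halfwidth_max_km: float = 80.0  # cap when the window auto-expands
    max_solution_range_km: float = 150.0  # search radius about the master's station
    grid_pad_deg: float = 0.6        # grid padding beyond the station bounding box


@dataclass
class CandidateSet:
    """Master detection plus per-station candidate arrivals.

    Station 0 is always the master's station and contributes only the master
    itself (the master is by construction the earliest arrival in the
    solution, so later same-station detections are excluded).
    """

    master_idx: int
    master_station: str
    master_time: float
    master_sigma: float
    station_ids: list
    station_lons: np.ndarray
    station_lats: np.ndarray
    times: list      # per station, ndarray of candidate arrival times
    sigmas: list
    probs: list
    det_idx: list

    @property
    def n_stations(self) -> int:
        return len(self.station_ids)


@dataclass
class FittedDetection:
    det_idx: int
    station: str
    time: float
    sigma: float
    p: float
    residual: float  # T - t_hat - O - t' at the reported solution, s


@dataclass
class Localization:
    master_idx: int
    master_station: str
    master_time: float
    method: int
    fitted: list = field(default_factory=list)
    x_star: Optional[tuple] = None   # (lon, lat) most probable point
    mean: Optional[tuple] = None     # (lon, lat) posterior mean
    cov_km2: Optional[np.ndarray] = None  # 2x2, (east, north) km^2
    accepted: bool = False
    reasons: list = field(default_factory=list)
    n_stations: int = 0
    t_prime: float = 0.0
    origin_time: Optional[float] = None
    surface_max: float = 0.0

    @property
    def fitted_ids(self) -> frozenset:
        return frozenset(f.det_idx for f in self.fitted)


def t_prime_grid(cfg: LocalizationConfig, sigma11: float) -> np.ndarray:
    """Origin-time misfit quadrature nodes, +-m*sigma11 at the configured step."""
    b = cfg.m * sigma11
    return np.arange(-b, b + cfg.t_step_s / 2.0, cfg.t_step_s)


def gather_candidates(master_idx: int, detections: pd.DataFrame,
                      stations: pd.DataFrame, cfg: LocalizationConfig,
                      excluded=None) -> CandidateSet:
    """Gather per-station candidate detections for one master.

    Candidates have p_true >= p_detect_min (inclusive), arrive in
    (T_master, T_master + max_dt_s], and sit on stations within
    max_station_dist_km of the master's station.  ``excluded`` is an optional
    set of detection indices locked to other tracks.
    """
    row = detections.loc[master_idx]
    if row["p_true"] < cfg.p_master_min:
        raise InputError("master detection below the master probability threshold")
    st = stations.set_index("id")
    m_station = row["station"]
    m_lon, m_lat = float(st.loc[m_station, "lon"]), float(st.loc[m_station, "lat"])
    dist = geo.great_circle_km(stations["lon"].to_numpy(), stations["lat"].to_numpy(),
                               m_lon, m_lat)
    near = stations.loc[dist <= cfg.max_station_dist_km]
    t0 = float(row["time"])
    t = detections["time"].to_numpy(dtype=float)
    p = detections["p_true"].to_numpy(dtype=float)
    in_window = (t > t0) & (t <= t0 + cfg.max_dt_s) & (p >= cfg.p_detect_min)
    if excluded:
        in_window &= ~detections.index.isin(list(excluded))
    cand = detections.loc[in_window]
    m_sigma = float(cfg.sigma_of_p(row["p_true"]))
    ids = [m_station]
    lons, lats = [m_lon], [m_lat]
    times, sigmas, probs, det_idx = [np.array([t0])], [np.array([m_sigma])], \
        [np.array([float(row["p_true"])])], [np.array([master_idx])]
    other = near.loc[near["id"] != m_station]
    # deterministic station order: by distance from the master's station
    d_other = geo.great_circle_km(other["lon"].to_numpy(), other["lat"].to_numpy(),
                                  m_lon, m_lat)
    for _, srow in other.iloc[np.argsort(d_other, kind="stable")].iterrows():
        sub = cand.loc[cand["station"] == srow["id"]]
        if len(sub) == 0:
            continue
        ids.append(srow["id"])
        lons.append(float(srow["lon"]))
        lats.append(float(srow["lat"]))
        times.append(sub["time"].to_numpy(dtype=float))
        sigmas.append(np.asarray(cfg.sigma_of_p(sub["p_true"].to_numpy()), dtype=float))
        probs.append(sub["p_true"].to_numpy(dtype=float))
        det_idx.append(sub.index.to_numpy())
    return CandidateSet(master_idx, m_station, t0, m_sigma, ids,
                        np.array(lons), np.array(lats), times, sigmas, probs, det_idx)


def origin_time(master_time, master_tt):
    """Origin time at a trial point: master arrival minus predicted travel time."""
    return np.asarray(master_time, dtype=float) - np.asarray(master_tt, dtype=float)


def _station_terms(times, sigmas, tt_i, O, tp):
    """Best-candidate Gaussian term per (node, t') for one station."""
    nan_mask = np.isnan(tt_i)
    tt_safe = np.where(nan_mask, 0.0, tt_i)
    res = times[:, None] - tt_safe[None, :] - O[None, :]          # (k, node)
    arg = (res[:, :, None] - tp[None, None, :]) / sigmas[:, None, None]
    term = np.exp(-0.5 * arg**2).max(axis=0)                       # (node, t')
    return term, nan_mask


def method1_surface(cs: CandidateSet, tt: np.ndarray, cfg: LocalizationConfig):
    """Likelihood L at every node: product over stations of the floored
    best-candidate term, integrated (trapezoid) over the origin-time misfit.

    ``tt`` is (n_station, n_node) of predicted travel times aligned with
    cs.station_ids (NaN marks nodes beyond a station's usable range; the
    master's row must be finite everywhere).  Returns (L, tp).
    """
    if np.any(np.isnan(tt[0])):
        raise InputError("search nodes must lie within the master station's range")
    tp = t_prime_grid(cfg, cs.master_sigma)
    O = origin_time(cs.master_time, tt[0])
    acc = np.ones((tt.shape[1], tp.size))
    for i in range(cs.n_stations):
        term, nan_mask = _station_terms(cs.times[i], cs.sigmas[i], tt[i], O, tp)
        term = np.maximum(term, cfg.q_small)
        if nan_mask.any():
            term[nan_mask, :] = cfg.q_small
        acc *= term
    return np.trapezoid(acc, tp, axis=1), tp


def method1_floor_value(cs: CandidateSet, cfg: LocalizationConfig) -> float:
    """Value of L where every station sits at the q_small floor."""
    tp = t_prime_grid(cfg, cs.master_sigma)
    return float(cfg.q_small ** cs.n_stations * (tp[-1] - tp[0]))


def method2_surface(cs: CandidateSet, tt: np.ndarray, dist: np.ndarray,
                    cfg: LocalizationConfig):
    """Detection-count surface E(x, t').

    A station fits when its best candidate's |residual|/sigma <= m'; each
    fitting station contributes the probability of that best candidate
    divided by its distance to the trial point floored at R; nodes with fewer
    than M_min fitting stations score zero.  Returns (E, tp) with E of shape
    (n_node, n_tp).
    """
    if np.any(np.isnan(tt[0])):
        raise InputError("search nodes must lie within the master station's range")
    tp = t_prime_grid(cfg, cs.master_sigma)
    O = origin_time(cs.master_time, tt[0])
    n_node = tt.shape[1]
    num = np.zeros((n_node, tp.size))
    nfit = np.zeros((n_node, tp.size), dtype=int)
    for i in range(cs.n_stations):
        nan_mask = np.isnan(tt[i])
        tt_safe = np.where(nan_mask, 0.0, tt[i])
        res = cs.times[i][:, None] - tt_safe[None, :] - O[None, :]
        norm = np.abs(res[:, :, None] - tp[None, None, :]) / cs.sigmas[i][:, None, None]
        best = np.argmin(norm, axis=0)                      # (node, t')
        best_norm = np.take_along_axis(norm, best[None, :, :], axis=0)[0]
        fit = (best_norm <= cfg.m_prime) & ~nan_mask[:, None]
        p_best = cs.probs[i][best]
        w = 1.0 / np.maximum(dist[i], cfg.r_floor_km)       # (node,)
        num += np.where(fit, p_best * w[:, None], 0.0)
        nfit += fit
    E = np.where(nfit >= cfg.m_min, num, 0.0)
    return E, tp


def fitting_subset(cs: CandidateSet, tt_at_x: np.ndarray, t_prime: float,
                   cfg: LocalizationConfig) -> list:
    """Best candidate per station at a solution point, retained if within m' sigma."""
    O = float(cs.master_time - tt_at_x[0])
    out = []
    for i in range(cs.n_stations):
        if np.isnan(tt_at_x[i]):
            continue
        res = cs.times[i] - tt_at_x[i] - O - t_prime
        norm = np.abs(res) / cs.sigmas[i]
        j = int(np.argmin(norm))
        if norm[j] <= cfg.m_prime:
            out.append(FittedDetection(int(cs.det_idx[i][j]), cs.station_ids[i],
                                       float(cs.times[i][j]), float(cs.sigmas[i][j]),
                                       float(cs.probs[i][j]), float(res[j])))
    return out


def posterior_surface(times, sigmas, tt, master_tt, master_time, cfg,
                      sigma11: Optional[float] = None, areas=None):
    """Normalized spatial probability density from the fitting detections.

    times/sigmas are per fitted detection (one per station); tt is
    (n_fit, ...) predicted travel times on the evaluation grid; master_tt the
    master station's times on the same grid.  The density is marginalized
    over the origin-time misfit and normalized so the spatial integral is
    one (``areas`` supplies node areas in km^2; defaults to uniform cells).
    """
    times = np.asarray(times, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    tt = np.asarray(tt, dtype=float)
    shape = tt.shape[1:]
    tt_flat = tt.reshape(len(times), -1)
    m_flat = np.asarray(master_tt, dtype=float).reshape(-1)
    tp = t_prime_grid(cfg, cfg.sigma_of_p(1.0) if sigma11 is None else sigma11)
    O = master_time - m_flat
    chi2 = np.zeros((tt_flat.shape[1], tp.size))
    for i in range(len(times)):
        res = times[i] - tt_flat[i] - O                      # (node,)
        chi2 += ((res[:, None] - tp[None, :]) / sigmas[i]) ** 2
    bad = np.isnan(chi2)
    integrand = np.exp(-0.5 * np.where(bad, np.inf, chi2))
    unnorm = np.trapezoid(integrand, tp, axis=1)
    if areas is None:
        areas = np.ones(unnorm.shape)
    a_flat = np.asarray(areas, dtype=float).reshape(-1)
    total = float(np.sum(unnorm * a_flat))
    if total <= 0:
        return None
    return (unnorm / total).reshape(shape)


@dataclass
class LocationSummary:
    x_star: tuple
    mean: tuple
    cov_km2: np.ndarray
    accepted: bool
    reasons: list


def summarize_location(P: np.ndarray, lat_axis: np.ndarray, lon_axis: np.ndarray,
                       cfg: LocalizationConfig) -> LocationSummary:
    """Most probable point, mean, covariance and acceptance of a density grid.

    The most probable point is refined by bicubic spline interpolation of the
    5x5 node neighbourhood of the argmax, evaluated on a 100-m lattice.  The
    solution is rejected when the 95% highest-density region has more than
    one 8-connected component or touches the grid boundary, or when the
    largest covariance eigenvalue exceeds the 1-sigma cap.
    """
    P = np.asarray(P, dtype=float)
    dlat = float(np.mean(np.diff(lat_axis)))
    dlon = float(np.mean(np.diff(lon_axis)))
    area = (dlat * KM_PER_DEG) * (dlon * KM_PER_DEG
                                  * np.cos(np.radians(lat_axis)))[:, None]
    mass = P * area
    mass = mass / mass.sum()
    # mean and covariance by quadrature in a local km frame
    glon, glat = np.meshgrid(lon_axis, lat_axis)
    mean_lon = float(np.sum(mass * glon))
    mean_lat = float(np.sum(mass * glat))
    dx, dy = geo.local_km_frame(glon, glat, mean_lon, mean_lat)
    cov = np.array([
        [np.sum(mass * dx * dx), np.sum(mass * dx * dy)],
        [np.sum(mass * dx * dy), np.sum(mass * dy * dy)],
    ])
    reasons = []
    # 95% highest-density region: accumulate node masses density-first
    order = np.argsort(P, axis=None)[::-1]
    cum = np.cumsum(mass.reshape(-1)[order])
    n_in = int(np.searchsorted(cum, cfg.hdr_level)) + 1
    hdr = np.zeros(P.size, dtype=bool)
    hdr[order[:n_in]] = True
    hdr = hdr.reshape(P.shape)
    n_comp = ndimage.label(hdr, structure=np.ones((3, 3), dtype=int))[1]
    if n_comp > 1:
        reasons.append("multimodal")
    if hdr[0, :].any() or hdr[-1, :].any() or hdr[:, 0].any() or hdr[:, -1].any():
        reasons.append("grid_boundary")
    if np.max(np.linalg.eigvalsh(cov)) > cfg.max_sigma_km ** 2:
        reasons.append("uncertainty>20km")
    # spline refinement of the most probable point to 100 m
    i0, j0 = np.unravel_index(int(np.argmax(P)), P.shape)
    i_lo, i_hi = max(0, i0 - 2), min(P.shape[0], i0 + 3)
    j_lo, j_hi = max(0, j0 - 2), min(P.shape[1], j0 + 3)
    x_star = (float(lon_axis[j0]), float(lat_axis[i0]))
    if i_hi - i_lo >= 4 and j_hi - j_lo >= 4:
        spl = RectBivariateSpline(lat_axis[i_lo:i_hi], lon_axis[j_lo:j_hi],
                                  P[i_lo:i_hi, j_lo:j_hi], kx=3, ky=3)
        lat_f = np.arange(lat_axis[i_lo], lat_axis[i_hi - 1] + 1e-12,
                          0.1 / KM_PER_DEG)
        lon_f = np.arange(lon_axis[j_lo], lon_axis[j_hi - 1] + 1e-12,
                          0.1 / (KM_PER_DEG * np.cos(np.radians(lat_axis[i0]))))
        fine = spl(lat_f, lon_f)
        fi, fj = np.unravel_index(int(np.argmax(fine)), fine.shape)
        x_star = (float(lon_f[fj]), float(lat_f[fi]))
    return LocationSummary(x_star, (mean_lon, mean_lat), cov,
                           accepted=len(reasons) == 0, reasons=reasons)


def _fine_axes(center_lon: float, center_lat: float, cfg: LocalizationConfig,
               halfwidth_km: Optional[float] = None):
    hw = cfg.fine_halfwidth_km if halfwidth_km is None else halfwidth_km
    hw_lat = hw / KM_PER_DEG
    hw_lon = hw / (KM_PER_DEG * np.cos(np.radians(center_lat)))
    dlat, dlon = cfg.fine_spacing_deg
    lat_axis = np.arange(center_lat - hw_lat, center_lat + hw_lat + dlat / 2, dlat)
    lon_axis = np.arange(center_lon - hw_lon, center_lon + hw_lon + dlon / 2, dlon)
    return lat_axis, lon_axis


def localize_master(master_idx: int, detections: pd.DataFrame,
                    stations: pd.DataFrame, curve: TravelTimeCurve,
                    cfg: LocalizationConfig, tt_grid: TravelTimeGrid,
                    method: int = 1, excluded=None) -> Localization:
    """Run the full localization chain for one master detection."""
    cs = gather_candidates(master_idx, detections, stations, cfg, excluded)
    loc = Localization(master_idx, cs.master_station, cs.master_time, method,
                       n_stations=cs.n_stations)
    if cs.n_stations < cfg.m_min:
        loc.reasons.append("too_few_stations")
        return loc
    # usable search nodes: within the feasibility radius of the master's station
    mi = tt_grid.station_index(cs.master_station)
    r_cap = min(cfg.max_solution_range_km, curve.max_range_km)
    mask = (tt_grid.ranges[mi] <= r_cap) & np.isfinite(tt_grid.times[mi])
    flat = mask.reshape(-1)
    glon, glat = np.meshgrid(tt_grid.lon_axis, tt_grid.lat_axis)
    node_lon, node_lat = glon.reshape(-1)[flat], glat.reshape(-1)[flat]
    s_rows = [tt_grid.station_index(s) for s in cs.station_ids]
    tt = tt_grid.times[s_rows].reshape(len(s_rows), -1)[:, flat]
    if method == 1:
        L, tp = method1_surface(cs, tt, cfg)
        loc.surface_max = float(L.max())
        if loc.surface_max <= method1_floor_value(cs, cfg) * (1 + 1e-9):
            loc.reasons.append("no_fit")
            return loc
        j = int(np.argmax(L))
        # best origin-time misfit at the argmax node
        acc = np.ones(tp.size)
        O_j = cs.master_time - tt[0, j]
        for i in range(cs.n_stations):
            if np.isnan(tt[i, j]):
                acc *= cfg.q_small
                continue
            res = cs.times[i] - tt[i, j] - O_j
            term = np.exp(-0.5 * ((res[:, None] - tp[None, :])
                                  / cs.sigmas[i][:, None]) ** 2).max(axis=0)
            acc *= np.maximum(term, cfg.q_small)
        t_pr = float(tp[int(np.argmax(acc))])
    elif method == 2:
        dist = np.stack([geo.great_circle_km(node_lon, node_lat,
                                             cs.station_lons[i], cs.station_lats[i])
                         for i in range(cs.n_stations)])
        E, tp = method2_surface(cs, tt, dist, cfg)
        loc.surface_max = float(E.max())
        if loc.surface_max <= 0.0:
            loc.reasons.append("no_solution")
            return loc
        j, jt = np.unravel_index(int(np.argmax(E)), E.shape)
        j, t_pr = int(j), float(tp[jt])
    else:
        raise InputError(f"unknown localization method {method}")
    loc.t_prime = t_pr
    st = stations.set_index("id")
    s_lon = np.array([float(st.loc[s, "lon"]) for s in cs.station_ids])
    s_lat = np.array([float(st.loc[s, "lat"]) for s in cs.station_ids])
    # The fitting subset is re-selected at the refined most-probable point
    # and the posterior recomputed until the subset is stable: selecting it
    # at a coarse search node shifts residuals and wrongly drops detections
    # near the m' boundary.
    x_eval = (float(node_lon[j]), float(node_lat[j]))
    summ = None
    fitted = []
    prev_ids = None
    for _ in range(3):
        r_eval = geo.great_circle_km(x_eval[0], x_eval[1], s_lon, s_lat)
        tt_eval = np.asarray(curve.predict_masked(r_eval), dtype=float)
        if np.isnan(tt_eval[0]):
            break
        tp = t_prime_grid(cfg, cs.master_sigma)
        acc = np.ones(tp.size)
        O_e = cs.master_time - tt_eval[0]
        for i in range(cs.n_stations):
            if np.isnan(tt_eval[i]):
                acc *= cfg.q_small
                continue
            res = cs.times[i] - tt_eval[i] - O_e
            term = np.exp(-0.5 * ((res[:, None] - tp[None, :])
                                  / cs.sigmas[i][:, None]) ** 2).max(axis=0)
            acc *= np.maximum(term, cfg.q_small)
        t_pr = float(tp[int(np.argmax(acc))])
        fitted = fitting_subset(cs, tt_eval, t_pr, cfg)
        if len(fitted) < cfg.m_min:
            break
        ids = frozenset(f.det_idx for f in fitted)
        if ids == prev_ids:
            break
        prev_ids = ids
        # posterior on a fine local grid about the evaluation point; the
        # window expands when the 95% region reaches its edge, so a
        # "grid_boundary" rejection reflects a genuinely unbounded region
        # rather than an undersized evaluation window
        hw = cfg.fine_halfwidth_km
        while True:
            lat_axis, lon_axis = _fine_axes(x_eval[0], x_eval[1], cfg, hw)
            f_lon, f_lat = np.meshgrid(lon_axis, lat_axis)
            tt_fine = []
            for f in fitted:
                r = geo.great_circle_km(f_lon, f_lat, st.loc[f.station, "lon"],
                                        st.loc[f.station, "lat"])
                tt_fine.append(curve.predict_masked(r))
            r_m = geo.great_circle_km(f_lon, f_lat, st.loc[cs.master_station, "lon"],
                                      st.loc[cs.master_station, "lat"])
            master_tt = curve.predict_masked(r_m)
            dlat = float(np.mean(np.diff(lat_axis)))
            dlon = float(np.mean(np.diff(lon_axis)))
            areas = (dlat * KM_PER_DEG) * (dlon * KM_PER_DEG
                                           * np.cos(np.radians(lat_axis)))[:, None] \
                * np.ones((1, len(lon_axis)))
            P = posterior_surface([f.time for f in fitted],
                                  [f.sigma for f in fitted],
                                  np.array(tt_fine), master_tt, cs.master_time,
                                  cfg, sigma11=cs.master_sigma, areas=areas)
            if P is None:
                loc.fitted = fitted
                loc.reasons.append("degenerate_posterior")
                return loc
            summ = summarize_location(P, lat_axis, lon_axis, cfg)
            if "grid_boundary" in summ.reasons and hw < cfg.fine_halfwidth_max_km:
                hw = min(2.0 * hw, cfg.fine_halfwidth_max_km)
                continue
            break
        x_eval = summ.x_star
    loc.fitted = fitted
    if len(fitted) < cfg.m_min:
        loc.reasons.append("too_few_fitting")
        return loc
    if summ is None:
        loc.reasons.append("degenerate_posterior")
        return loc
    loc.x_star, loc.mean, loc.cov_km2 = summ.x_star, summ.mean, summ.cov_km2
    loc.accepted, loc.reasons = summ.accepted, loc.reasons + summ.reasons
    # residuals and origin time at the reported most probable point
    xs_lon, xs_lat = loc.x_star
    tt_star = np.array([float(curve.predict_masked(
        geo.great_circle_km(xs_lon, xs_lat, st.loc[f.station, "lon"],
                            st.loc[f.station, "lat"]))) for f in fitted])
    m_tt_star = float(curve.predict_masked(geo.great_circle_km(
        xs_lon, xs_lat, st.loc[cs.master_station, "lon"],
        st.loc[cs.master_station, "lat"])))
    if np.all(np.isfinite(tt_star)) and np.isfinite(m_tt_star):
        O_star = cs.master_time - m_tt_star
        tp = t_prime_grid(cfg, cs.master_sigma)
        res0 = np.array([f.time for f in fitted]) - tt_star - O_star
        chi2 = np.sum(((res0[:, None] - tp[None, :])
                       / np.array([f.sigma for f in fitted])[:, None]) ** 2, axis=0)
        t_star = float(tp[int(np.argmin(chi2))])
        for f, r in zip(fitted, res0 - t_star):
            f.residual = float(r)
        loc.t_prime = t_star
        loc.origin_time = float(O_star + t_star)
    return loc


def build_search_grid(stations: pd.DataFrame, curve: TravelTimeCurve,
                      cfg: LocalizationConfig) -> TravelTimeGrid:
    """Travel-time grid over the padded station bounding box at search spacing."""
    pad = cfg.grid_pad_deg
    bbox = (stations["lon"].min() - pad, stations["lon"].max() + pad,
            stations["lat"].min() - pad, stations["lat"].max() + pad)
    return precompute_travel_time_grid(curve, stations, bbox, cfg.search_spacing_deg)


def localize_all(detections: pd.DataFrame, stations: pd.DataFrame,
                 curve: TravelTimeCurve, cfg: LocalizationConfig,
                 method: int = 1, assignment: Optional[dict] = None,
                 tt_grid: Optional[TravelTimeGrid] = None,
                 masters: Optional[Sequence[int]] = None) -> list:
    """Localize every qualifying master detection.

    Every detection with p_true >= p_master_min is tried as a master (a
    detection may appear in multiple localizations; deduplication is the
    tracks module's job).  ``assignment`` maps detection index -> the master
    index of the tracked location the detection belongs to; an assigned
    detection is excluded from the candidate sets of every other master, and
    a master assigned to a different location is not retried.
    """
    if tt_grid is None:
        tt_grid = build_search_grid(stations, curve, cfg)
    if masters is None:
        sel = detections.loc[detections["p_true"] >= cfg.p_master_min]
        masters = sel.sort_values("time", kind="stable").index.to_list()
    out = []
    for m_idx in masters:
        excluded = None
        if assignment:
            if assignment.get(m_idx, m_idx) != m_idx:
                continue
            excluded = {i for i, anchor in assignment.items() if anchor != m_idx}
        out.append(localize_master(m_idx, detections, stations, curve, cfg,
                                   tt_grid, method=method, excluded=excluded))
    return out
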