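"""Smooth-path fitting, misfit statistics, and double-difference relocation.

A whale track is a time-ordered sequence of call locations with 2x2 spatial
covariances.  Two refinements are provided.

The smooth-track inversion penalizes changes in speed and direction: for each
interior call the constraint (1-w) x_{i-1} - x_i + w x_{i+1} = 0 with
w = (O_i - O_{i-1})/(O_{i+1} - O_{i-1}), weighted by 1/(O_{i+1} - O_{i-1})
(uniform penalty on acceleration) and 1/min(w, 1-w) (sensitivity of the
central call).  The constraints are stacked against the covariance-whitened
location misfits with a smoothing weight alpha and solved by iterated least
squares; alpha is decreased until the locations are fit to their expected
uncertainty (mean squared normalized spatial misfit ~ 2 for two degrees of
freedom), discarding calls inconsistent with a smooth path at the 99%
chi-squared level.

Double-difference relocation instead fits the differences between arrival
-time residuals of nearby calls on common stations, which cancels travel-time
modeling errors shared by the two paths, solving jointly for position and
origin-time shifts with the same smoothing constraint.  Poorly fitting
difference times are discarded after a few iterations; spurious detections
reveal themselves through difference times far beyond their uncertainty.

All algebra runs in a local tangent-plane km frame centred on the track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import geo
from .exceptions import InputError

CHI2_2DOF_99 = float(stats.chi2.ppf(0.99, 2))  # 9.21


@dataclass
class SmoothPath:
    """A smoothed track: per-call positions plus fit diagnostics."""

    times: np.ndarray                 # origin times, s
    lonlats_raw: np.ndarray           # (n, 2) input locations
    lonlats: np.ndarray               # (n, 2) smoothed (NaN for removed calls)
    alpha: float = np.nan             # smoothing weight actually used
    mean_norm_var: float = np.nan     # mean squared normalized spatial misfit
    outliers: list = field(default_factory=list)  # removed call indices

    @property
    def speeds_kmh(self) -> np.ndarray:
        keep = ~np.isnan(self.lonlats[:, 0])
        return path_speed(self.times[keep], self.lonlats[keep])


def smoothing_system(origin_times: np.ndarray) -> np.ndarray:
    """Weighted constraint matrix S for one coordinate.

    One row per interior call with coefficients (1-w, -1, w) scaled by
    1/(O_{i+1}-O_{i-1}) and 1/min(w, 1-w).  Shape (n-2, n).
    """
    O = np.asarray(origin_times, dtype=float)
    n = O.size
    if n < 3:
        raise InputError("need at least 3 calls to build smoothing constraints")
    if np.any(np.diff(O) == 0):
        raise InputError("duplicate origin times in track")
    S = np.zeros((n - 2, n))
    for i in range(1, n - 1):
        span = O[i + 1] - O[i - 1]
        w = (O[i] - O[i - 1]) / span
        u = (1.0 / span) * (1.0 / min(w, 1.0 - w))
        S[i - 1, i - 1] = u * (1.0 - w)
        S[i - 1, i] = -u
        S[i - 1, i + 1] = u * w
    return S


def _whitener(cov: np.ndarray) -> Optional[np.ndarray]:
    """Inverse square root of a 2x2 covariance; None if not positive definite."""
    vals, vecs = np.linalg.eigh(np.asarray(cov, dtype=float))
    if np.any(vals <= 0):
        return None
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T


def _solve_smooth(times, xy_star, whiteners, alpha, tol_km=0.01, max_iter=50):
    """Iterated stacked least squares for one alpha; returns (xy, misfits)."""
    n = len(times)
    S1 = smoothing_system(times)
    S = np.block([[S1, np.zeros_like(S1)], [np.zeros_like(S1), S1]])
    xy = xy_star.copy()
    for _ in range(max_iter):
        top = np.zeros((2 * n, 2 * n))
        rhs_top = np.zeros(2 * n)
        for i, W in enumerate(whiteners):
            top[2 * i:2 * i + 2, i] = W[:, 0]
            top[2 * i:2 * i + 2, n + i] = W[:, 1]
            rhs_top[2 * i:2 * i + 2] = W @ (xy_star[i] - xy[i])
        xvec = np.concatenate([xy[:, 0], xy[:, 1]])
        A = np.vstack([top, alpha * S])
        b = np.concatenate([rhs_top, -alpha * (S @ xvec)])
        delta, *_ = np.linalg.lstsq(A, b, rcond=None)
        xy = xy + np.column_stack([delta[:n], delta[n:]])
        if np.max(np.abs(delta)) < tol_km:
            break
    misfits = np.array([float(np.sum((W @ (xy[i] - xy_star[i])) ** 2))
                        for i, W in enumerate(whiteners)])
    return xy, misfits


def fit_smooth_track(origin_times, lonlats, covs_km2,
                     alpha_schedule: Optional[Sequence[float]] = None,
                     chi2_conf: float = 0.99, target_misfit: float = 2.0,
                     tol_km: float = 0.01) -> SmoothPath:
    """Fit a smooth path to a track, decreasing alpha until locations are fit
    to their uncertainty.

    For each alpha (descending) the stacked system is solved to convergence,
    calls whose normalized squared spatial misfit exceeds the chi-squared
    (2 dof) quantile at ``chi2_conf`` are removed and the fit repeated; the
    schedule stops at the first alpha whose mean squared normalized misfit
    reaches the two-degree-of-freedom expectation (~2).
    """
    times = np.asarray(origin_times, dtype=float)
    lonlats = np.asarray(lonlats, dtype=float)
    covs = np.asarray(covs_km2, dtype=float)
    n = times.size
    if n < 3:
        raise InputError("need at least 3 calls to fit a smooth track")
    order = np.argsort(times, kind="stable")
    times, lonlats, covs = times[order], lonlats[order], covs[order]
    lon0, lat0 = float(np.mean(lonlats[:, 0])), float(np.mean(lonlats[:, 1]))
    x, y = geo.local_km_frame(lonlats[:, 0], lonlats[:, 1], lon0, lat0)
    xy_star = np.column_stack([x, y])
    chi2_cut = float(stats.chi2.ppf(chi2_conf, 2))
    removed: set = set()
    whit_all = []
    for i in range(n):
        W = _whitener(covs[i])
        if W is None:
            warnings.warn(f"call {i}: non-invertible covariance, excluded",
                          stacklevel=2)
            removed.add(i)
            whit_all.append(None)
        else:
            whit_all.append(W)
    if alpha_schedule is None:
        alpha_schedule = np.logspace(8, 3, 21)
    result_xy, result_alpha, result_misfit = None, np.nan, np.nan
    active_idx: list = []
    for alpha in alpha_schedule:
        while True:
            active_idx = [i for i in range(n) if i not in removed]
            if len(active_idx) < 3:
                raise InputError("too few calls remain after outlier removal")
            xy, misfits = _solve_smooth(times[active_idx], xy_star[active_idx],
                                        [whit_all[i] for i in active_idx],
                                        float(alpha), tol_km)
            bad = np.nonzero(misfits > chi2_cut)[0]
            if bad.size == 0:
                break
            for b in bad:
                removed.add(active_idx[int(b)])
        result_xy, result_alpha = xy, float(alpha)
        result_misfit = float(np.mean(misfits))
        if result_misfit <= target_misfit:
            break
    out = np.full((n, 2), np.nan)
    lon_s, lat_s = geo.from_local_km(result_xy[:, 0], result_xy[:, 1], lon0, lat0)
    out[active_idx, 0] = lon_s
    out[active_idx, 1] = lat_s
    return SmoothPath(times, lonlats, out, result_alpha, result_misfit,
                      sorted(removed))


def misfit_stats(localizations) -> dict:
    """Pooled travel-time misfit statistic s and its expectation for tracked calls.

    s^2 is the mean of squared residuals normalized to their uncertainties;
    its expectation Sum(M_j - 3)/Sum(M_j) accounts for the three parameters
    (two coordinates and origin time) absorbed by each call's solution.
    ``localizations`` may be Localization objects or (residuals, sigmas)
    pairs.
    """
    res_list, sig_list = [], []
    for loc in localizations:
        if hasattr(loc, "fitted"):
            res_list.append(np.array([f.residual for f in loc.fitted], dtype=float))
            sig_list.append(np.array([f.sigma for f in loc.fitted], dtype=float))
        else:
            r, s = loc
            res_list.append(np.asarray(r, dtype=float))
            sig_list.append(np.asarray(s, dtype=float))
    M = np.array([r.size for r in res_list])
    total = int(M.sum())
    if total <= 3 * len(res_list):
        raise InputError("fewer residuals than free parameters; s undefined")
    s2 = float(sum(np.sum((r / s) ** 2) for r, s in zip(res_list, sig_list)) / total)
    e_s2 = float(np.sum(M - 3) / total)
    return {"s": float(np.sqrt(s2)), "s2": s2,
            "expected_s": float(np.sqrt(e_s2)), "expected_s2": e_s2,
            "n_calls": len(res_list), "n_residuals": total}


@dataclass
class DDResult:
    """Double-difference relocation output for one smoothing weight."""

    beta: float
    path: SmoothPath
    origin_shifts: np.ndarray
    n_differences: int
    n_retained: int
    norm_var: float  # mean of (d/sigma_d)^2 over retained differences

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_differences if self.n_differences else np.nan


def _build_pairs(origin_times, station_sets, max_links: int, window_s: float,
                 min_common: int):
    pairs = []
    n = len(origin_times)
    for j in range(n):
        links = 0
        for l in range(j + 1, n):
            if origin_times[l] - origin_times[j] > window_s:
                break
            common = sorted(station_sets[j] & station_sets[l])
            if len(common) < min_common:
                continue
            pairs.append((j, l, common))
            links += 1
            if links >= max_links:
                break
    return pairs


def dd_relocate(origin_times, lonlats, fitted_per_call, stations, curve,
                beta_schedule: Sequence[float] = (10.0, 2.0, 0.5),
                n_iter: int = 5, reject_after: int = 3, reject_mult: float = 3.0,
                max_links: int = 8, link_window_s: float = 3600.0,
                min_common: int = 4, rcond: float = 0.05) -> list:
    """Double-difference relocation of a track.

    ``fitted_per_call`` holds, per call, the fitted detections as objects
    with station/time/sigma attributes (or (station, time, sigma) tuples).
    Each call is linked to up to ``max_links`` later calls within an hour
    sharing at least ``min_common`` stations.  Rows are weighted by the
    reciprocal of sigma_d with sigma_d^2 the sum of the two detection-time
    variances; after ``reject_after`` iterations differences with absolute
    misfit beyond ``reject_mult`` sigma_d are dropped.  Returns one DDResult
    per smoothing weight (each solved from the raw locations).

    Difference times constrain only relative geometry: uniform translations
    of the whole track (and a uniform origin-time shift) are near-null modes
    of the stacked system, and unregularized least squares amplifies noise
    along them into multi-kilometre drifts.  Singular values below ``rcond``
    times the largest are therefore truncated, which pins the absolute
    position to the starting locations; the genuinely constrained modes sit
    two orders of magnitude above the translation modes.
    """
    times = np.asarray(origin_times, dtype=float)
    lonlats = np.asarray(lonlats, dtype=float)
    n = times.size
    if n < 3:
        raise InputError("need at least 3 calls for double-difference relocation")
    norm_calls = []
    for calls in fitted_per_call:
        out = {}
        for f in calls:
            if hasattr(f, "station"):
                out[f.station] = (float(f.time), float(f.sigma))
            else:
                out[f[0]] = (float(f[1]), float(f[2]))
        norm_calls.append(out)
    st = stations.set_index("id")
    lon0, lat0 = float(np.mean(lonlats[:, 0])), float(np.mean(lonlats[:, 1]))
    x0, y0 = geo.local_km_frame(lonlats[:, 0], lonlats[:, 1], lon0, lat0)
    sx, sy = geo.local_km_frame(st["lon"].to_numpy(), st["lat"].to_numpy(),
                                lon0, lat0)
    st_xy = dict(zip(st.index, zip(sx, sy)))
    pairs = _build_pairs(times, [set(c) for c in norm_calls], max_links,
                         link_window_s, min_common)
    rows = [(j, l, s) for j, l, common in pairs for s in common]
    if not rows:
        raise InputError("no linkable call pairs (need >=4 common stations "
                         "within the linking window)")
    results = []
    for beta in beta_schedule:
        xy = np.column_stack([x0, y0]).astype(float)
        O = times.astype(float).copy()
        rejected = np.zeros(len(rows), dtype=bool)
        for it in range(n_iter):
            d, sig_d, G = _dd_system(rows, xy, O, norm_calls, st_xy, curve, n)
            keep = ~rejected
            S1 = smoothing_system(O)
            S = np.block([[S1, np.zeros_like(S1)], [np.zeros_like(S1), S1]])
            Sfull = np.hstack([S, np.zeros((S.shape[0], n))])
            xvec = np.concatenate([xy[:, 0], xy[:, 1]])
            wG = G[keep] / sig_d[keep, None]
            wd = d[keep] / sig_d[keep]
            A = np.vstack([wG, beta * Sfull])
            b = np.concatenate([wd, -beta * (S @ xvec)])
            if not (np.all(np.isfinite(A)) and np.all(np.isfinite(b))):
                raise InputError("non-finite double-difference system "
                                 "(a call drifted beyond the travel-time range?)")
            delta, _, rank, _ = np.linalg.lstsq(A, b, rcond=rcond)
            if rank < 2 * n:
                raise InputError(
                    f"double-difference system is rank deficient (rank {rank} "
                    f"for {n} calls); calls may share identical geometry")
            xy = xy + np.column_stack([delta[:n], delta[n:2 * n]])
            O = O + delta[2 * n:]
            if it + 1 >= reject_after:
                d, sig_d, _ = _dd_system(rows, xy, O, norm_calls, st_xy, curve,
                                         n, need_G=False)
                rejected |= np.abs(d) > reject_mult * sig_d
        d, sig_d, _ = _dd_system(rows, xy, O, norm_calls, st_xy, curve, n,
                                 need_G=False)
        keep = ~rejected
        lon_s, lat_s = geo.from_local_km(xy[:, 0], xy[:, 1], lon0, lat0)
        path = SmoothPath(times, lonlats, np.column_stack([lon_s, lat_s]),
                          alpha=float(beta),
                          mean_norm_var=float(np.mean((d[keep] / sig_d[keep]) ** 2)))
        results.append(DDResult(float(beta), path, O - times, len(rows),
                                int(keep.sum()), path.mean_norm_var))
    return results


def _dd_system(rows, xy, O, norm_calls, st_xy, curve, n, need_G: bool = True):
    """Double-difference times, uncertainties and (optionally) the G matrix."""
    d = np.zeros(len(rows))
    sig_d = np.zeros(len(rows))
    G = np.zeros((len(rows), 3 * n)) if need_G else None
    for r, (j, l, s_id) in enumerate(rows):
        sx_i, sy_i = st_xy[s_id]
        out = []
        for c in (j, l):
            dx, dy = xy[c, 0] - sx_i, xy[c, 1] - sy_i
            rng = max(np.hypot(dx, dy), 1e-6)
            t_pred = O[c] + float(curve.predict(rng, check=False))
            T, sig = norm_calls[c][s_id]
            out.append((T - t_pred, sig, dx / rng, dy / rng, rng))
        (res_j, sig_j, ux_j, uy_j, r_j), (res_l, sig_l, ux_l, uy_l, r_l) = out
        d[r] = res_j - res_l
        sig_d[r] = np.sqrt(sig_j**2 + sig_l**2)
        if need_G:
            sl_j, sl_l = curve.slope(r_j), curve.slope(r_l)
            G[r, j] = sl_j * ux_j
            G[r, n + j] = sl_j * uy_j
            G[r, 2 * n + j] = 1.0
            G[r, l] = -sl_l * ux_l
            G[r, n + l] = -sl_l * uy_l
            G[r, 2 * n + l] = -1.0
    return d, sig_d, G


def path_speed(times, lonlats) -> np.ndarray:
    """Great-circle segment speeds in km/hr between successive positions."""
    t = np.asarray(times, dtype=float)
    p = np.asarray(lonlats, dtype=float)
    if t.size < 2:
        raise InputError("need at least 2 positions for a speed")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise InputError("zero time gap between successive positions")
    d = geo.great_circle_km(p[:-1, 0], p[:-1, 1], p[1:, 0], p[1:, 1])
    return np.asarray(d) / (dt / 3600.0)
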