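"""Grouping localizations into whale tracks and scoring their reliability.

Localizations are first deduplicated (a solution whose fitted detections are
a subset of an earlier master's solution is a repeat), then clustered by a
space-time filter: a location within 10 km and 15 minutes of at least four
other locations seeds a group that is expanded iteratively; groups separated
by no more than an hour are merged when at least four locations of one lie
within 20 km of four locations of the other.

Spurious tracks built by systematically mixing detections from successive
calls (the ~50-s ABB call spacing is close to the inter-station travel time
on a 70-km network) are eliminated iteratively: detections in sufficiently
large tracks are assigned to their track, the localization pass is repeated
with assigned detections locked to their track, and the minimum track size is
lowered between rounds.  Assigning with one localization method and
finalizing with the other recovers the most calls; the preferred pairing
assigns with method 2 and finalizes with method 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import geo, locate


@dataclass
class Track:
    """Time-ordered localizations attributed to one whale."""

    id: int
    localizations: list = field(default_factory=list)

    @property
    def n_locations(self) -> int:
        return len(self.localizations)

    @property
    def detection_ids(self) -> frozenset:
        out = set()
        for loc in self.localizations:
            out |= loc.fitted_ids
        return frozenset(out)

    @property
    def origin_times(self) -> np.ndarray:
        return np.array([loc.origin_time for loc in self.localizations])

    @property
    def first_time(self) -> float:
        return float(min(loc.origin_time for loc in self.localizations))


def drop_repeat_locations(locs: Sequence) -> list:
    """Remove repeat localizations.

    Scanning in master-time order, a localization whose fitted detection set
    is a subset of any earlier-kept localization's set is dropped.
    """
    ordered = sorted(locs, key=lambda l: (l.master_time, l.master_idx))
    kept = []
    for loc in ordered:
        ids = loc.fitted_ids
        if any(ids <= k.fitted_ids for k in kept):
            continue
        kept.append(loc)
    return kept


def _neighbor_matrix(locs, radius_km: float, window_s: float) -> np.ndarray:
    lons = np.array([l.x_star[0] for l in locs])
    lats = np.array([l.x_star[1] for l in locs])
    times = np.array([l.origin_time for l in locs])
    n = len(locs)
    near = np.zeros((n, n), dtype=bool)
    for i in range(n):
        d = geo.great_circle_km(lons, lats, lons[i], lats[i])
        near[i] = (d <= radius_km) & (np.abs(times - times[i]) <= window_s)
        near[i, i] = False
    return near


def group_into_tracks(locs: Sequence, radius_km: float = 10.0,
                      window_s: float = 900.0, min_neighbors: int = 4,
                      merge_gap_s: float = 3600.0, merge_radius_km: float = 20.0,
                      merge_count: int = 4) -> list:
    """Seed-and-expand clustering of accepted localizations, then merging.

    A location with >= min_neighbors others within radius_km and window_s
    seeds a group; all its neighbours join, and the expansion repeats from
    every added location that itself qualifies.  The merge pass (time gap
    <= 1 hr and merge_count cross-close locations) is applied to a fixed
    point.  Input is sorted by origin time (ties by master index) so the
    result is deterministic.
    """
    usable = [l for l in locs if l.accepted and l.x_star is not None
              and l.origin_time is not None]
    usable.sort(key=lambda l: (l.origin_time, l.master_idx))
    if not usable:
        return []
    near = _neighbor_matrix(usable, radius_km, window_s)
    degree = near.sum(axis=1)
    unassigned = set(range(len(usable)))
    groups = []
    for seed in range(len(usable)):
        if seed not in unassigned or degree[seed] < min_neighbors:
            continue
        group = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            if degree[i] < min_neighbors:
                continue  # non-core members join but do not expand
            for j in np.nonzero(near[i])[0]:
                if j in unassigned and j not in group:
                    group.add(int(j))
                    frontier.append(int(j))
        unassigned -= group
        groups.append(sorted(group))
    # merge pass, iterated to a fixed point
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if _groups_mergeable(usable, groups[a], groups[b], merge_gap_s,
                                     merge_radius_km, merge_count):
                    groups[a] = sorted(groups[a] + groups[b])
                    del groups[b]
                    merged = True
                    break
            if merged:
                break
    tracks = []
    for k, g in enumerate(groups):
        members = sorted((usable[i] for i in g),
                         key=lambda l: (l.origin_time, l.master_idx))
        tracks.append(Track(k, members))
    return tracks


def _groups_mergeable(locs, g1, g2, gap_s, radius_km, count) -> bool:
    t1 = [locs[i].origin_time for i in g1]
    t2 = [locs[i].origin_time for i in g2]
    gap = max(min(t2) - max(t1), min(t1) - max(t2))
    if gap > gap_s:
        return False
    for ga, gb in ((g1, g2), (g2, g1)):
        lons_b = np.array([locs[i].x_star[0] for i in gb])
        lats_b = np.array([locs[i].x_star[1] for i in gb])
        n_ok = 0
        for i in ga:
            d = geo.great_circle_km(lons_b, lats_b, locs[i].x_star[0],
                                    locs[i].x_star[1])
            if np.sum(d <= radius_km) >= count:
                n_ok += 1
                if n_ok >= count:
                    return True
    return False


def _assign_detections(tracks: Sequence, min_locations: int) -> dict:
    """Map detections in big-enough tracks to the location they belong to.

    A detection appearing in locations of more than one track goes to the
    track with most locations (ties: earlier first call); within that track
    it is pinned to the location with the earliest master.  The returned
    dict maps detection index -> master index of its assigned location.
    """
    big = [t for t in tracks if t.n_locations >= min_locations]
    assignment: dict = {}
    best: dict = {}
    for t in big:
        for loc in t.localizations:
            for det in loc.fitted_ids:
                key = (-t.n_locations, t.first_time, loc.master_time,
                       loc.master_idx)
                if det not in best or key < best[det]:
                    best[det] = key
                    assignment[det] = loc.master_idx
    return assignment


def iterate_track_assignment(detections: pd.DataFrame, stations: pd.DataFrame,
                             curve: geo.TravelTimeCurve,
                             cfg: locate.LocalizationConfig,
                             assign_method: int = 2, final_method: int = 1,
                             thresholds: Sequence[int] = (25, 15),
                             tt_grid=None, group_kwargs: Optional[dict] = None,
                             log: Optional[dict] = None) -> list:
    """Iteratively localize, group, and lock detections to tracks.

    Each round localizes all masters with ``assign_method``, groups the
    deduplicated accepted locations into tracks, and assigns every detection
    appearing in tracks with at least the round's minimum number of locations
    to its largest such track (ties broken by earlier first-call time).  The
    next round repeats the localization with assigned detections locked to
    their track.  A final pass with ``final_method`` produces the tracks.
    """
    gk = group_kwargs or {}
    if tt_grid is None:
        tt_grid = locate.build_search_grid(stations, curve, cfg)
    assignment: dict = {}
    for min_loc in thresholds:
        locs = locate.localize_all(detections, stations, curve, cfg,
                                   method=assign_method, assignment=assignment,
                                   tt_grid=tt_grid)
        locs = drop_repeat_locations(locs)
        tracks = group_into_tracks(locs, **gk)
        assignment = _assign_detections(tracks, min_loc)
        if log is not None:
            log.setdefault("rounds", []).append({
                "min_locations": int(min_loc),
                "localization_attempts": len(locs),
                "tracks": len(tracks),
                "assigned_detections": len(assignment),
            })
    locs = locate.localize_all(detections, stations, curve, cfg,
                               method=final_method, assignment=assignment,
                               tt_grid=tt_grid)
    locs = drop_repeat_locations(locs)
    tracks = group_into_tracks(locs, **gk)
    # every detection belongs to at most one final track: keep each
    # localization only in the track its detections are assigned to
    det_track: dict = {}
    best: dict = {}
    for t in tracks:
        key = (-t.n_locations, t.first_time)
        for det in t.detection_ids:
            if det not in best or key < best[det]:
                best[det] = key
                det_track[det] = t.id
    pruned = []
    for t in tracks:
        members = [l for l in t.localizations
                   if all(det_track.get(d, t.id) == t.id for d in l.fitted_ids)]
        if members:
            pruned.append(Track(t.id, members))
    if log is not None:
        log["detections_modeled"] = int(sum(len(l.fitted) for l in locs))
        log["calls_in_tracks"] = int(sum(t.n_locations for t in pruned))
        log["calls_in_tracks_ge20"] = int(sum(t.n_locations for t in pruned
                                              if t.n_locations >= 20))
    return pruned


def track_diagnostics(track: Track, stations: pd.DataFrame,
                      detections: pd.DataFrame, pre_s: float = 60.0,
                      post_s: float = 120.0, range_step_km: float = 25.0,
                      reliable_range_km: float = 75.0,
                      min_reliable_locations: int = 20,
                      ici_bin_s: float = 10.0, ratio_cap: float = 99.0) -> dict:
    """Reliability diagnostics for one track.

    For each call, stations are ranked by range from the location and
    labelled included (their detection is in the fitted set) or
    missing-with-activity (not fitted but recording at least one detection
    from pre_s before the first fitted arrival to post_s after).  Reliable
    tracks keep the cumulative included/missing ratio above one out to
    ~75-100 km and contain at least 20 locations; the inter-call-interval
    histogram of successive origin times should peak at a song cadence.
    """
    st_lon = stations["lon"].to_numpy()
    st_lat = stations["lat"].to_numpy()
    st_ids = stations["id"].to_list()
    det_t = detections["time"].to_numpy(dtype=float)
    det_st = detections["station"].to_numpy()
    inc_ranges, miss_ranges = [], []
    for loc in track.localizations:
        fitted_stations = {f.station for f in loc.fitted}
        t_first = min(f.time for f in loc.fitted)
        active = set(det_st[(det_t >= t_first - pre_s) & (det_t <= t_first + post_s)])
        d = geo.great_circle_km(st_lon, st_lat, loc.x_star[0], loc.x_star[1])
        for sid, r in zip(st_ids, d):
            if sid in fitted_stations:
                inc_ranges.append(r)
            elif sid in active:
                miss_ranges.append(r)
    edges = np.arange(0.0, 300.0 + range_step_km, range_step_km)
    inc_cum = np.cumsum(np.histogram(inc_ranges, bins=edges)[0])
    miss_cum = np.cumsum(np.histogram(miss_ranges, bins=edges)[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(miss_cum > 0, inc_cum / np.maximum(miss_cum, 1e-12),
                         np.where(inc_cum > 0, ratio_cap, np.nan))
    ratio = np.minimum(ratio, ratio_cap)
    times = np.sort(track.origin_times)
    ici = np.diff(times)
    ici_edges = np.arange(-ici_bin_s / 2.0, 600.0 + ici_bin_s, ici_bin_s)
    ici_counts, _ = np.histogram(ici, bins=ici_edges)
    ici_centers = 0.5 * (ici_edges[:-1] + ici_edges[1:])
    mode = float(ici_centers[int(np.argmax(ici_counts))]) if ici.size else np.nan
    k = int(np.searchsorted(edges, reliable_range_km, side="right")) - 1
    ratio_ok = bool(np.all(ratio[1:k + 1][~np.isnan(ratio[1:k + 1])] > 1.0)) \
        if k >= 1 else False
    return {
        "n_locations": track.n_locations,
        "range_edges_km": edges,
        "included_cumulative": inc_cum,
        "missing_cumulative": miss_cum,
        "ratio": ratio,
        "ici_s": ici,
        "ici_bin_centers_s": ici_centers,
        "ici_counts": ici_counts,
        "ici_mode_s": mode,
        "reliable": bool(ratio_ok and track.n_locations >= min_reliable_locations),
    }
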