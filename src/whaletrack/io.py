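"""File formats: the detection-log CSV schema, station tables, config, outputs.

The detection log follows the field's distribution schema: one row per
detection with station name, station longitude and latitude in decimal
degrees, date as "mm/dd/yy", UTC time as "HH:MM:SS.SSS", the peak recognition
score, the duration, and the estimated true-positive probability.  All
internal times are UTC epoch seconds; two-digit years map to 2000-2069.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .geo import TravelTimeCurve

DETECTION_COLUMNS = ["station", "lon", "lat", "date", "time", "rs",
                     "duration", "p_true"]
_EPOCH = _dt.datetime(1970, 1, 1, tzinfo=_dt.timezone.utc)


def _parse_row_time(date_str: str, time_str: str) -> float:
    mm, dd, yy = (int(v) for v in date_str.strip().split("/"))
    year = 2000 + yy if yy < 70 else 1900 + yy
    hh, mi, ss = time_str.strip().split(":")
    sec = float(ss)
    t = _dt.datetime(year, mm, dd, int(hh), int(mi), tzinfo=_dt.timezone.utc)
    return (t - _EPOCH).total_seconds() + sec


def _format_row_time(epoch_s: float):
    t = _EPOCH + _dt.timedelta(seconds=float(epoch_s))
    frac = f"{t.second + t.microsecond / 1e6:06.3f}"
    return f"{t.month:02d}/{t.day:02d}/{t.year % 100:02d}", \
        f"{t.hour:02d}:{t.minute:02d}:{frac}"


def read_detections(path):
    """Read a detection-log CSV; returns (detections, stations) DataFrames.

    Detections carry station, time (epoch s), rs, duration, p_true; the
    station table is deduplicated from the per-row coordinates.  Malformed
    dates/times raise an InputError naming the row; inconsistent coordinates
    for one station id are an error.
    """
    raw = pd.read_csv(path, header=0, names=DETECTION_COLUMNS, dtype=str,
                      skipinitialspace=True)
    det_rows, st_coords = [], {}
    for k, row in enumerate(raw.itertuples(index=False), start=2):
        try:
            t = _parse_row_time(row.date, row.time)
        except (ValueError, AttributeError) as exc:
            raise InputError(f"{path}: line {k}: bad date/time "
                             f"({row.date!r} {row.time!r}): {exc}") from None
        sid = str(row.station).strip()
        lon, lat = float(row.lon), float(row.lat)
        if sid in st_coords:
            lon0, lat0 = st_coords[sid]
            if abs(lon0 - lon) > 1e-6 or abs(lat0 - lat) > 1e-6:
                raise InputError(f"{path}: line {k}: station {sid} has "
                                 "inconsistent coordinates")
        else:
            st_coords[sid] = (lon, lat)
        det_rows.append({"station": sid, "time": t, "rs": float(row.rs),
                         "duration": float(row.duration),
                         "p_true": float(row.p_true)})
    det = pd.DataFrame(det_rows, columns=["station", "time", "rs", "duration",
                                          "p_true"])
    stations = pd.DataFrame([{"id": s, "lon": c[0], "lat": c[1]}
                             for s, c in st_coords.items()])
    return det, stations


def write_detections(detections: pd.DataFrame, stations: pd.DataFrame, path):
    """Write detections (and station coordinates) in the S1-style CSV schema."""
    st = stations.set_index("id")
    rows = []
    for row in detections.itertuples():
        date, time = _format_row_time(row.time)
        rows.append({
            "station name": row.station,
            "station longitude": f"{st.loc[row.station, 'lon']:.6f}",
            "station latitude": f"{st.loc[row.station, 'lat']:.6f}",
            "date": date, "UTC time": time,
            "peak recognition score": f"{row.rs:.4f}",
            "duration": f"{row.duration:.3f}",
            "probability": f"{row.p_true:.4f}",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"station_id", "lon", "lat"} <= set(df.columns):
        raise InputError(f"{path}: station table needs station_id,lon,lat columns")
    return df.rename(columns={"station_id": "id"})[["id", "lon", "lat"]]


def write_stations(stations: pd.DataFrame, path) -> None:
    stations.rename(columns={"id": "station_id"}).to_csv(path, index=False)


def curve_from_config(block: Optional[dict]) -> TravelTimeCurve:
    """Travel-time curve from a config block.

    Accepts {"coeffs": [...], "max_range_km": ...} or
    {"samples_file": <csv of range_km,time_s>}; defaults to the isospeed
    1.48 km/s curve.
    """
    if not block:
        return TravelTimeCurve.isospeed()
    max_range = float(block.get("max_range_km", 300.0))
    if "coeffs" in block:
        coeffs = np.asarray(block["coeffs"], dtype=float)
        padded = np.zeros(4)
        padded[: len(coeffs)] = coeffs
        return TravelTimeCurve(padded, max_range)
    if "samples_file" in block:
        samples = pd.read_csv(block["samples_file"]).to_numpy(dtype=float)
        return TravelTimeCurve.fit(samples, max_range)
    if "speed_km_s" in block:
        return TravelTimeCurve.isospeed(float(block["speed_km_s"]), max_range)
    raise InputError("travel_time config needs coeffs, samples_file or speed_km_s")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a YAML mapping")
    return cfg


def write_localizations(locs: Sequence, path) -> None:
    rows = []
    for loc in locs:
        rows.append({
            "master_idx": loc.master_idx,
            "master_station": loc.master_station,
            "method": loc.method,
            "lon_star": loc.x_star[0] if loc.x_star else np.nan,
            "lat_star": loc.x_star[1] if loc.x_star else np.nan,
            "lon_mean": loc.mean[0] if loc.mean else np.nan,
            "lat_mean": loc.mean[1] if loc.mean else np.nan,
            "cov_xx_km2": loc.cov_km2[0, 0] if loc.cov_km2 is not None else np.nan,
            "cov_xy_km2": loc.cov_km2[0, 1] if loc.cov_km2 is not None else np.nan,
            "cov_yy_km2": loc.cov_km2[1, 1] if loc.cov_km2 is not None else np.nan,
            "origin_time": loc.origin_time,
            "n_stations": loc.n_stations,
            "n_fitted": len(loc.fitted),
            "accepted": loc.accepted,
            "reasons": ";".join(loc.reasons),
            "fitted_ids": ";".join(str(i) for i in sorted(loc.fitted_ids)),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_track(track, path_csv, path_json=None, diagnostics: Optional[dict] = None):
    rows = []
    for k, loc in enumerate(track.localizations):
        rows.append({
            "call_index": k,
            "origin_time": loc.origin_time,
            "lon": loc.x_star[0], "lat": loc.x_star[1],
            "cov_xx_km2": loc.cov_km2[0, 0],
            "cov_xy_km2": loc.cov_km2[0, 1],
            "cov_yy_km2": loc.cov_km2[1, 1],
            "n_stations": len(loc.fitted),
        })
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    if path_json is not None and diagnostics is not None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in diagnostics.items()}
        with open(path_json, "w") as fh:
            json.dump(payload, fh, indent=1)


def write_stage_summary(path, stage: str, **counts) -> None:
    """Machine-readable per-stage JSON summary (bookkeeping counts, config echo)."""
    with open(path, "w") as fh:
        json.dump({"stage": stage, **counts}, fh, indent=1, default=str)
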