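"""Geodesy, the travel-time curve, and station-to-grid travel-time tables.

All localization in this package rests on three primitives: great-circle
horizontal range on a spherical Earth, a single travel-time-versus-range curve
(a cubic polynomial standing in for full acoustic propagation modeling), and
per-station tables of predicted travel times on a latitude-longitude grid.

The default curve assumes an effective sound-channel speed of 1.48 km/s,
``t = d / 1.48``.  Site-specific curves (e.g. derived from ray tracing through
a measured sound-speed profile) can be supplied either as polynomial
coefficients or as (range, time) samples to which a cubic is fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FitError, InputError

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0  # ~111.19 km per degree of arc


@dataclass(frozen=True)
class Station:
    """A single seafloor sensor."""

    id: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise InputError(f"station {self.id}: longitude {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise InputError(f"station {self.id}: latitude {self.lat} outside [-90, 90]")


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between two lon/lat points (array-aware).

    Haversine formula on a sphere of radius 6371 km.  Whale depths are a few
    tens of metres and ranges are tens of kilometres, so the horizontal
    great-circle range is used as the "straight-line" source-station distance.
    """
    lat1 = np.asarray(lat1, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    lon1 = np.asarray(lon1, dtype=float)
    lon2 = np.asarray(lon2, dtype=float)
    if np.any(np.abs(lat1) > 90.0) or np.any(np.abs(lat2) > 90.0):
        raise InputError("latitude magnitude exceeds 90 degrees")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = np.radians(lon2 - lon1)
    a = np.sin(dlat / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.shape else float(d)


def default_model_sigma(range_km):
    """Travel-time modeling uncertainty (s) versus range.

    Linear from 1.25 s at 75 km to 2.5 s at 150 km, constant outside that
    interval.  Exposed so that a network-specific table can be substituted.
    """
    return np.interp(range_km, [75.0, 150.0], [1.25, 2.5])


@dataclass
class TravelTimeCurve:
    """Cubic travel time (s) as a function of horizontal range (km).

    coeffs are in ascending order (c0 + c1*d + c2*d**2 + c3*d**3); the curve
    must be strictly increasing on (0, max_range_km].
    """

    coeffs: np.ndarray
    max_range_km: float = 300.0
    model_sigma: Callable = default_model_sigma
    fit_rms_s: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (4,):
            raise InputError("travel-time curve needs exactly 4 polynomial coefficients")
        self._validate_monotonic()

    def _validate_monotonic(self) -> None:
        d = np.linspace(0.0, self.max_range_km, 2001)
        t = np.polynomial.polynomial.polyval(d, self.coeffs)
        if t[0] < -1e-9:
            raise FitError(f"travel time at 0 km is negative ({t[0]:.3f} s)")
        dt = np.diff(t)
        if np.any(dt <= 0.0):
            bad = d[1:][dt <= 0.0]
            raise FitError(
                "fitted travel-time curve is non-monotonic on (0, "
                f"{self.max_range_km}] km; first violation near {bad[0]:.1f} km"
            )

    @classmethod
    def isospeed(cls, speed_km_s: float = 1.48, max_range_km: float = 300.0) -> "TravelTimeCurve":
        """Default curve ``t = d / speed`` (effective sound-channel speed)."""
        return cls(np.array([0.0, 1.0 / speed_km_s, 0.0, 0.0]), max_range_km)

    @classmethod
    def fit(cls, samples: Sequence, max_range_km: float = 300.0,
            model_sigma: Callable = default_model_sigma) -> "TravelTimeCurve":
        """Least-squares cubic fit to (range km, time s) samples.

        Requires >= 4 samples; the fitted curve is validated for monotonicity
        on a dense grid and the residual RMS is recorded on the instance.
        """
        arr = np.asarray(samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
            raise FitError("need at least 4 (range, time) samples to fit a cubic")
        d, t = arr[:, 0], arr[:, 1]
        # Polynomial.fit scales into a working window, then coefficients are
        # converted back; this keeps the Vandermonde system well conditioned.
        poly = np.polynomial.Polynomial.fit(d, t, deg=3).convert()
        coeffs = np.zeros(4)
        coeffs[: len(poly.coef)] = poly.coef
        resid = t - np.polynomial.polynomial.polyval(d, coeffs)
        curve = cls(coeffs, max_range_km, model_sigma)
        curve.fit_rms_s = float(np.sqrt(np.mean(resid**2)))
        return curve

    def predict(self, range_km, check: bool = True):
        """Predicted travel time (s) at the given range(s)."""
        r = np.asarray(range_km, dtype=float)
        if check and np.any((r < 0) | (r > self.max_range_km)):
            raise InputError(
                f"range outside [0, {self.max_range_km}] km; the caller must "
                "exclude stations beyond the curve's working range"
            )
        t = np.polynomial.polynomial.polyval(r, self.coeffs)
        return t if t.shape else float(t)

    def predict_masked(self, range_km):
        """As predict(), but NaN (not an error) beyond max_range_km."""
        r = np.asarray(range_km, dtype=float)
        t = np.polynomial.polynomial.polyval(r, self.coeffs)
        return np.where(r <= self.max_range_km, t, np.nan)

    def slope(self, range_km):
        """d(travel time)/d(range) in s/km, used for relocation derivatives."""
        r = np.asarray(range_km, dtype=float)
        dcoef = np.polynomial.polynomial.polyder(self.coeffs)
        s = np.polynomial.polynomial.polyval(r, dcoef)
        return s if s.shape else float(s)

    def sigma(self, range_km):
        """Modeling uncertainty (s) at the given range(s)."""
        return self.model_sigma(range_km)


@dataclass
class TravelTimeGrid:
    """Per-station travel-time tables on a lat/lon grid.

    times[s] holds curve(range(node, station_s)) with NaN beyond the curve's
    working range.  Axes are strictly increasing.
    """

    lat_axis: np.ndarray
    lon_axis: np.ndarray
    station_ids: list
    times: np.ndarray    # (n_station, n_lat, n_lon), NaN beyond max range
    ranges: np.ndarray   # (n_station, n_lat, n_lon)
    curve: TravelTimeCurve = field(repr=False, default=None)

    @property
    def shape(self):
        return len(self.lat_axis), len(self.lon_axis)

    def station_index(self, station_id: str) -> int:
        return self.station_ids.index(station_id)

    def cell_area_km2(self) -> np.ndarray:
        """Node cell areas (km^2), latitude dependent, for quadrature."""
        dlat = float(np.mean(np.diff(self.lat_axis)))
        dlon = float(np.mean(np.diff(self.lon_axis)))
        dy = dlat * KM_PER_DEG
        dx = dlon * KM_PER_DEG * np.cos(np.radians(self.lat_axis))
        return np.outer(dy * dx, np.ones(len(self.lon_axis)))


def precompute_travel_time_grid(curve: TravelTimeCurve, stations: pd.DataFrame,
                                bbox: Sequence[float],
                                spacing: Sequence[float] = (0.005, 0.01)) -> TravelTimeGrid:
    """Precompute travel times from each station onto a lat/lon grid.

    bbox is (lon_min, lon_max, lat_min, lat_max) and must enclose all
    stations; spacing is (dlat, dlon) in degrees, defaulting to 0.005 deg of
    latitude (~550 m) by 0.01 deg of longitude.
    """
    if len(stations) == 0:
        raise InputError("empty station list")
    lon_min, lon_max, lat_min, lat_max = [float(v) for v in bbox]
    if (stations["lon"].min() < lon_min or stations["lon"].max() > lon_max
            or stations["lat"].min() < lat_min or stations["lat"].max() > lat_max):
        raise InputError("bounding box does not enclose all stations")
    dlat, dlon = float(spacing[0]), float(spacing[1])
    lat_axis = np.arange(lat_min, lat_max + dlat / 2.0, dlat)
    lon_axis = np.arange(lon_min, lon_max + dlon / 2.0, dlon)
    glon, glat = np.meshgrid(lon_axis, lat_axis)
    ids, times, ranges = [], [], []
    for row in stations.itertuples():
        r = great_circle_km(glon, glat, row.lon, row.lat)
        ids.append(row.id)
        ranges.append(r)
        times.append(curve.predict_masked(r))
    return TravelTimeGrid(lat_axis, lon_axis, ids, np.array(times), np.array(ranges), curve)


def stations_frame(stations: Sequence[Station]) -> pd.DataFrame:
    """Station table as a DataFrame with unique-id validation."""
    df = pd.DataFrame([{"id": s.id, "lon": s.lon, "lat": s.lat} for s in stations])
    if df["id"].duplicated().any():
        raise InputError("duplicate station ids in network")
    return df


def local_km_frame(lons, lats, lon0: float, lat0: float):
    """Equirectangular (east, north) km offsets about (lon0, lat0)."""
    x = (np.asarray(lons, dtype=float) - lon0) * KM_PER_DEG * np.cos(np.radians(lat0))
    y = (np.asarray(lats, dtype=float) - lat0) * KM_PER_DEG
    return x, y


def from_local_km(x, y, lon0: float, lat0: float):
    """Inverse of local_km_frame."""
    lon = lon0 + np.asarray(x, dtype=float) / (KM_PER_DEG * np.cos(np.radians(lat0)))
    lat = lat0 + np.asarray(y, dtype=float) / KM_PER_DEG
    return lon, lat
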