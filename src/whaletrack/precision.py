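"""Seasonal precision calibration of the detector.

Northeast Pacific blue whale B calls are strongly seasonal.  Assuming the
false-detection rate is invariant through the year and that whales do not
call outside the calling season, the excess detection rate during the calling
season equals the true-positive rate, so per recognition-score bin

    precision = (r_c - r_nc) / r_c

with r_c and r_nc the detection rates (per day) in the calling and
non-calling seasons.  The calling season itself is inferred per station as
the smallest set of 5-day bins containing 98% of the strong (score >= 6)
detections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import CalibrationError, InputError

#: Default recognition-score bin edges; bins are half-open [lo, hi).
DEFAULT_BIN_EDGES = (2.2, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0, np.inf)

#: Reference calibration for seafloor station J28A off the Pacific Northwest
#: (detections/day in the non-calling and calling seasons per score bin).
J28A_RATE_NONCALLING = (457.0, 370.0, 144.0, 47.0, 13.0, 3.7, 1.2, 0.09)
J28A_RATE_CALLING = (498.0, 438.0, 207.0, 94.0, 43.0, 21.0, 16.0, 7.3)

#: Network-average precision per score bin, usable as a generic default.
ALL_STATION_PRECISION = (0.07, 0.16, 0.38, 0.62, 0.79, 0.88, 0.95, 0.99)


@dataclass
class RateTable:
    """Per-bin detection rates (per day) in the calling and non-calling seasons."""

    edges: Sequence[float] = DEFAULT_BIN_EDGES
    r_c: np.ndarray = None
    r_nc: np.ndarray = None
    station_id: Optional[str] = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise InputError("rate-table bin edges must be strictly increasing")
        self.r_c = np.asarray(self.r_c, dtype=float)
        self.r_nc = np.asarray(self.r_nc, dtype=float)
        nbins = len(self.edges) - 1
        if self.r_c.shape != (nbins,) or self.r_nc.shape != (nbins,):
            raise InputError("rates must have one value per bin")
        if np.any(self.r_c < 0) or np.any(self.r_nc < 0):
            raise InputError("rates must be non-negative")

    @classmethod
    def j28a(cls) -> "RateTable":
        return cls(DEFAULT_BIN_EDGES, np.array(J28A_RATE_CALLING),
                   np.array(J28A_RATE_NONCALLING), station_id="J28A")


@dataclass
class PrecisionCurve:
    """Per-bin detector precision in [0, 1]; NaN where undefined (r_c = 0)."""

    edges: np.ndarray
    values: np.ndarray
    undefined: np.ndarray = field(default=None)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = np.isnan(self.values)
        ok = self.values[~self.undefined]
        if np.any((ok < 0) | (ok > 1)):
            raise InputError("precision values must lie in [0, 1]")

    @classmethod
    def j28a(cls) -> "PrecisionCurve":
        return estimate_precision(RateTable.j28a())

    @classmethod
    def all_stations(cls) -> "PrecisionCurve":
        return cls(np.asarray(DEFAULT_BIN_EDGES), np.asarray(ALL_STATION_PRECISION))

    def lookup(self, rs):
        """Precision of the bin containing each score (bins half-open [lo, hi))."""
        rs = np.atleast_1d(np.asarray(rs, dtype=float))
        idx = np.searchsorted(self.edges, rs, side="right") - 1
        if np.any(idx < 0):
            raise InputError(
                "recognition score below the lowest bin edge; such detections "
                "should not pass the detector threshold"
            )
        idx = np.minimum(idx, len(self.values) - 1)
        return self.values[idx]


@dataclass
class SeasonLabeling:
    bin_starts: np.ndarray    # epoch seconds, one per bin
    bin_days: float
    calling: np.ndarray       # bool per bin
    strong_counts: np.ndarray

    @property
    def calling_days(self) -> float:
        return float(np.sum(self.calling)) * self.bin_days

    @property
    def noncalling_days(self) -> float:
        return float(np.sum(~self.calling)) * self.bin_days

    def label_times(self, times) -> np.ndarray:
        """True where a time falls in a calling-season bin."""
        t = np.asarray(times, dtype=float)
        bin_s = self.bin_days * 86400.0
        idx = np.floor((t - self.bin_starts[0]) / bin_s).astype(int)
        idx = np.clip(idx, 0, len(self.calling) - 1)
        return self.calling[idx]


def infer_calling_season(times, rs, bin_days: float = 5.0, strong_rs: float = 6.0,
                         frac: float = 0.98) -> SeasonLabeling:
    """Label 5-day bins as calling vs non-calling season.

    Bins are sorted by their count of strong detections (score >= strong_rs),
    descending with ties broken by earlier date; the minimal prefix holding at
    least ``frac`` of all strong detections is the calling season.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(rs, dtype=float)
    if t.size == 0:
        raise CalibrationError("cannot calibrate station: no detections")
    bin_s = bin_days * 86400.0
    t0 = float(np.min(t))
    n_bins = int(np.floor((float(np.max(t)) - t0) / bin_s)) + 1
    if n_bins < 2:
        raise CalibrationError("record span shorter than two bins")
    idx = np.floor((t - t0) / bin_s).astype(int)
    strong = a >= strong_rs
    counts = np.bincount(idx[strong], minlength=n_bins)
    total = counts.sum()
    if total == 0:
        raise CalibrationError("cannot calibrate station: zero strong detections")
    order = np.lexsort((np.arange(n_bins), -counts))  # count desc, earlier first
    cum = np.cumsum(counts[order])
    k = int(np.searchsorted(cum, frac * total - 1e-9) + 1)
    calling = np.zeros(n_bins, dtype=bool)
    calling[order[:k]] = True
    starts = t0 + bin_s * np.arange(n_bins)
    return SeasonLabeling(starts, bin_days, calling, counts)


def build_rate_table(times, rs, season: SeasonLabeling,
                     edges: Sequence[float] = DEFAULT_BIN_EDGES,
                     station_id: Optional[str] = None) -> RateTable:
    """Count detections per score bin and divide by days of coverage per season.

    Rates use the days of data actually covered by each season's bins, not the
    calendar span, so record gaps do not bias them.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(rs, dtype=float)
    edges = np.asarray(edges, dtype=float)
    in_calling = season.label_times(t)
    finite_edges = np.where(np.isfinite(edges), edges, np.max(a, initial=0.0) + 1.0)
    c_counts, _ = np.histogram(a[in_calling], bins=finite_edges)
    nc_counts, _ = np.histogram(a[~in_calling], bins=finite_edges)
    cd, nd = season.calling_days, season.noncalling_days
    if cd <= 0 or nd <= 0:
        raise CalibrationError("both seasons need non-zero data coverage")
    return RateTable(edges, c_counts / cd, nc_counts / nd, station_id)


def estimate_precision(table: RateTable) -> PrecisionCurve:
    """Per-bin precision (r_c - r_nc)/r_c, clipped to [0, 1].

    Bins with r_c = 0 are flagged undefined (NaN), not zero.  Negative raw
    precision (r_nc > r_c) is clipped to 0 with a warning: the stationary
    false-positive assumption can fail in noisy records.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (table.r_c - table.r_nc) / table.r_c
    undefined = table.r_c == 0
    raw = np.where(undefined, np.nan, raw)
    if np.any(raw[~undefined] < 0):
        warnings.warn("negative raw precision clipped to 0 "
                      "(non-calling rate exceeds calling rate)", stacklevel=2)
    values = np.clip(raw, 0.0, 1.0)
    return PrecisionCurve(table.edges, values, undefined)


def assign_probabilities(detections, curve: PrecisionCurve):
    """Attach p_true to detections from the precision of their score bin.

    ``detections`` may be a pandas DataFrame with a ``rs`` column (a
    ``p_true`` column is added/overwritten, returning a copy) or a list of
    ``detect.Detection`` objects (mutated in place and returned).
    """
    import pandas as pd

    if isinstance(detections, pd.DataFrame):
        out = detections.copy()
        out["p_true"] = curve.lookup(out["rs"].to_numpy())
        return out
    for d in detections:
        d.p_true = float(curve.lookup(d.peak_rs)[0])
    return detections
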