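"""Raw-telemetry preprocessing.

Turns per-location Argos satellite fixes into the standardized analysis
table used by every downstream stage: one best-quality location per animal
per day, a binary east/west response, one-hot season indicators, z-scored
body length, and a track index that records where each individual's
contiguous block of rows starts.

Argos location classes carry very different positional errors, so when a
tag reports several fixes on one day only the most accurate is kept.  The
quality ranking, best to worst, is ``D, 3, 2, 1, 0, A, B, Z`` where ``D``
marks the deployment position (known exactly, hence ranked best) and
``A/B/Z`` carry no manufacturer accuracy estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARGOS_RANKS",
    "DEFAULT_CLASS_ERRORS_M",
    "StandardizationParams",
    "TrackIndex",
    "rank_argos_class",
    "filter_daily_best",
    "derive_response",
    "zscore",
    "apply_zscore",
    "encode_season",
    "build_track_index",
    "extract_grid_covariate",
]

#: Quality ranking of Argos location classes; lower rank = smaller error.
#: "D" is the deployment fix, treated as an exact position.
ARGOS_RANKS: dict[str, int] = {
    "D": 0, "3": 1, "2": 2, "1": 3, "0": 4, "A": 5, "B": 6, "Z": 7,
}

# Per-class (lon_err_m, lat_err_m) defaults for error-box covariate
# extraction.  Classes 3..1 span the observed error ranges of 742-3498 m
# longitude and 326-1265 m latitude (best class smallest); classes with no
# manufacturer accuracy estimate default to the range midpoint and should
# be overridden by the user when better information exists.
_LON_MID = (742.0 + 3498.0) / 2.0
_LAT_MID = (326.0 + 1265.0) / 2.0
DEFAULT_CLASS_ERRORS_M: dict[str, tuple[float, float]] = {
    "D": (0.0, 0.0),
    "3": (742.0, 326.0),
    "2": (_LON_MID, _LAT_MID),
    "1": (3498.0, 1265.0),
    "0": (_LON_MID, _LAT_MID),
    "A": (_LON_MID, _LAT_MID),
    "B": (_LON_MID, _LAT_MID),
    "Z": (_LON_MID, _LAT_MID),
}

#: Meters per degree of latitude (and of longitude at the equator).
METERS_PER_DEGREE = 111_320.0


@dataclass(frozen=True)
class StandardizationParams:
    """Sample mean and standard deviation used for a z-score transform."""

    variable: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(
                f"standard deviation for {self.variable!r} must be positive, "
                f"got {self.sd}"
            )


@dataclass(frozen=True)
class TrackIndex:
    """1-based cumulative row boundaries for contiguous per-animal blocks.

    ``boundaries`` has length ``n_groups + 1``; group ``j`` (1-based)
    occupies rows ``boundaries[j-1] .. boundaries[j] - 1`` and the final
    entry is ``total rows + 1``.
    """

    boundaries: np.ndarray
    group_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=np.int64)
        object.__setattr__(self, "boundaries", b)
        if b[0] != 1 or np.any(np.diff(b) < 0):
            raise ValueError("boundaries must start at 1 and be non-decreasing")

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_rows(self) -> int:
        return int(self.boundaries[-1] - 1)

    @property
    def counts(self) -> np.ndarray:
        """Rows per group (first differences of the boundaries)."""
        return np.diff(self.boundaries)

    @property
    def starts0(self) -> np.ndarray:
        """0-based start offset of each group, for ``np.add.reduceat``."""
        return self.boundaries[:-1] - 1

    def row_groups(self) -> np.ndarray:
        """0-based group id for every row."""
        return np.repeat(np.arange(self.n_groups), self.counts)


def rank_argos_class(cls: str) -> int:
    """Rank an Argos location class, lower = better quality."""
    try:
        return ARGOS_RANKS[str(cls)]
    except KeyError:
        raise ValueError(f"unknown Argos location class: {cls!r}") from None


def filter_daily_best(locations: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one location per tag per UTC calendar day.

    Within each (tag, day) the fix with the best Argos class is retained;
    rank ties go to the earliest timestamp.  Days with no fix stay absent —
    no interpolation is performed.

    Parameters
    ----------
    locations
        Columns ``tag_id, timestamp, lon, lat, argos_class``; timestamps
        parseable as UTC instants.
    """
    if locations.empty:
        return locations.copy()
    df = locations.copy()
    ts = pd.to_datetime(df["timestamp"], utc=True)
    df["_ts"] = ts
    df["_day"] = ts.dt.floor("D")
    df["_rank"] = df["argos_class"].map(rank_argos_class)
    df = df.sort_values(["tag_id", "_day", "_rank", "_ts"], kind="stable")
    kept = df.groupby(["tag_id", "_day"], sort=True).head(1)
    return (
        kept.sort_values(["tag_id", "_ts"], kind="stable")
        .drop(columns=["_ts", "_day", "_rank"])
        .reset_index(drop=True)
    )


def derive_response(longitude, boundary: float = -125.0):
    """Binary movement response: 1 west of the boundary meridian, else 0.

    The boundary longitude itself codes east (``z = 0``); "west" means
    strictly beyond the line.
    """
    lon = np.asarray(longitude, dtype=float)
    if not np.all(np.isfinite(lon)):
        raise ValueError("longitude must be finite")
    z = (lon < boundary).astype(np.int64)
    return int(z) if np.isscalar(longitude) else z


def zscore(values, variable: str = "x") -> tuple[np.ndarray, StandardizationParams]:
    """Standardize ``(x - mean) / sd`` with the sample (ddof=1) sd.

    Returns the standardized vector together with the parameters so the
    same transform can be replayed on new data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-score requires at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"cannot z-score constant vector {variable!r} (sd = 0)")
    params = StandardizationParams(variable, mean, sd)
    return (x - mean) / sd, params


def apply_zscore(values, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(values, dtype=float) - params.mean) / params.sd


_SEASON_OF_MONTH = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Fall", 10: "Fall", 11: "Fall",
}

SEASONS = ("Spring", "Summer", "Fall", "Winter")


def encode_season(timestamps) -> pd.DataFrame:
    """One-hot season indicators from Northern-Hemisphere meteorological
    seasons (Spring = Mar-May, Summer = Jun-Aug, Fall = Sep-Nov,
    Winter = Dec-Feb).  Exactly one indicator is 1 per row.
    """
    ts = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(timestamps, dtype=object))))
    season = ts.dt.month.map(_SEASON_OF_MONTH)
    out = pd.DataFrame(
        {s: (season == s).astype(np.int64).to_numpy() for s in SEASONS}
    )
    return out


def build_track_index(table: pd.DataFrame, group_col: str = "ptt") -> TrackIndex:
    """Cumulative-sum row boundaries for contiguous per-group blocks.

    The hierarchical model walks each individual's block of rows, so the
    table must be ordered with each group's rows contiguous; a group id
    that re-appears after another group is an error.
    """
    ids = table[group_col].to_numpy()
    if len(ids) == 0:
        raise ValueError("empty table")
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    starts = np.concatenate([[0], change])
    block_ids = ids[starts]
    seen: set = set()
    for pos, gid in zip(starts, block_ids):
        if gid in seen:
            raise ValueError(
                f"group ids not contiguous: {gid!r} re-appears at row {pos}; "
                f"sort the table by {group_col!r} first"
            )
        seen.add(gid)
    counts = np.diff(np.concatenate([starts, [len(ids)]]))
    boundaries = np.concatenate([[1], np.cumsum(counts) + 1])
    return TrackIndex(boundaries, tuple(block_ids))


def extract_grid_covariate(
    grid: np.ndarray,
    lon_axis: np.ndarray,
    lat_axis: np.ndarray,
    lon: float,
    lat: float,
    lon_err_m: float = 0.0,
    lat_err_m: float = 0.0,
) -> float:
    """Mean of non-missing grid cells inside a positional error box.

    The box is centered at ``(lon, lat)`` with half-widths given by the
    positional errors in meters, converted to degrees at that latitude
    (111,320 m per degree latitude, scaled by cos(lat) for longitude).
    Returns NaN (with a warning) when the point lies outside the grid or
    every intersecting cell is missing.

    ``grid`` is indexed ``[lon, lat]`` with monotone increasing axes.
    """
    if lon_err_m < 0 or lat_err_m < 0:
        raise ValueError("error radii must be non-negative")
    lon_axis = np.asarray(lon_axis, dtype=float)
    lat_axis = np.asarray(lat_axis, dtype=float)
    if not (lon_axis[0] <= lon <= lon_axis[-1] and lat_axis[0] <= lat <= lat_axis[-1]):
        warnings.warn(
            f"point ({lon}, {lat}) outside grid extent; covariate missing",
            stacklevel=2,
        )
        return float("nan")
    dlat = lat_err_m / METERS_PER_DEGREE
    coslat = max(np.cos(np.deg2rad(lat)), 1e-12)
    dlon = lon_err_m / (METERS_PER_DEGREE * coslat)
    ilo = np.searchsorted(lon_axis, lon - dlon, side="left")
    ihi = np.searchsorted(lon_axis, lon + dlon, side="right")
    jlo = np.searchsorted(lat_axis, lat - dlat, side="left")
    jhi = np.searchsorted(lat_axis, lat + dlat, side="right")
    if ihi <= ilo:  # box smaller than one cell: use the containing cell
        ilo = int(np.clip(np.abs(lon_axis - lon).argmin(), 0, len(lon_axis) - 1))
        ihi = ilo + 1
    if jhi <= jlo:
        jlo = int(np.clip(np.abs(lat_axis - lat).argmin(), 0, len(lat_axis) - 1))
        jhi = jlo + 1
    cells = np.asarray(grid, dtype=float)[ilo:ihi, jlo:jhi]
    if cells.size == 0 or np.all(np.isnan(cells)):
        warnings.warn(
            f"no valid grid cells in error box at ({lon}, {lat})", stacklevel=2
        )
        return float("nan")
    return float(np.nanmean(cells))
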