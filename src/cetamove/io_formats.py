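"""Readers, writers and run configuration for the telemetry pipeline.

External formats handled here:

* Argos location CSV exports (comma or semicolon separated; CLS header
  spellings vary, so column names are matched case-insensitively against an
  alias table).
* Gridded surface-current fields as NetCDF (time x lat x lon grids of the
  eastward/northward components ``u``/``v`` in m/s).
* Reconstructed tracks as CSV or GeoJSON.
* YAML run configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

#: Argos location-class quality order, best first.  Z is invalid.
QUALITY_ORDER = ["3", "2", "1", "0", "A", "B", "Z"]

#: Case-insensitive header aliases for Argos CSV exports.
ARGOS_COLUMN_ALIASES = {
    "timestamp": ["timestamp", "date", "datetime", "date time", "loc. date", "locdate"],
    "lon": ["lon", "longitude", "loc. lon"],
    "lat": ["lat", "latitude", "loc. lat"],
    "quality_class": ["quality_class", "lc", "loc. quality", "location class",
                      "location quality", "class", "lq"],
    "ellipse_semi_major": ["ellipse_semi_major", "semi major", "error semi-major axis",
                           "smaj", "semi_major_axis"],
    "ellipse_semi_minor": ["ellipse_semi_minor", "semi minor", "error semi-minor axis",
                           "smin", "semi_minor_axis"],
    "ellipse_orientation": ["ellipse_orientation", "ellipse orientation",
                            "error ellipse orientation", "eor", "orientation"],
}

MANDATORY_ARGOS_COLUMNS = ("timestamp", "lon", "lat", "quality_class")


class FormatError(ValueError):
    """A file does not conform to its documented layout."""


@dataclass(frozen=True)
class ArgosObservation:
    """One raw Argos satellite fix with quality class and error ellipse.

    The error ellipse (semi-major/semi-minor in metres, orientation in degrees
    clockwise from north) is the anisotropic positional uncertainty supplied
    by CLS for each fix; older exports omit it for low-quality classes.
    """

    timestamp: _dt.datetime
    lon: float
    lat: float
    quality_class: str
    ellipse_semi_major: float | None = None
    ellipse_semi_minor: float | None = None
    ellipse_orientation: float | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")
        if self.quality_class not in QUALITY_ORDER:
            raise ValueError(f"unknown Argos quality class: {self.quality_class!r}")
        smaj, smin = self.ellipse_semi_major, self.ellipse_semi_minor
        if smaj is not None and smin is not None and not (smaj >= smin >= 0):
            raise ValueError("ellipse axes must satisfy semi_major >= semi_minor >= 0")


@dataclass
class GriddedField:
    """A gridded surface-current field: u, v (m/s) on a time x lat x lon grid."""

    times: np.ndarray          # datetime64[ns], regular
    lats: np.ndarray           # ascending
    lons: np.ndarray           # ascending
    u: np.ndarray              # (time, lat, lon), NaN where missing
    v: np.ndarray

    def __post_init__(self):
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v shape {self.u.shape} inconsistent with axes {shape}")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("lat/lon axes must be strictly ascending")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell has no valid current (land / missing)."""
        return ~(np.isfinite(self.u) & np.isfinite(self.v))


@dataclass
class RunConfig:
    """Run-level configuration shared by the pipeline stages."""

    interval_hours: float = 6.0
    vmax: float = 9.0                     # m/s, speed-filter ceiling
    resting_threshold: float = 0.5        # m/s, resting vs transiting split
    projection_center: tuple[float, float] = (-20.0, 45.0)  # (lon, lat)
    bioenergetics: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.interval_hours <= 0 or self.vmax <= 0 or self.resting_threshold <= 0:
            raise ValueError("all thresholds and intervals must be positive")
        if 24.0 % self.interval_hours != 0:
            raise ValueError("prediction interval must divide 24 hours")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        center = raw.pop("projection_center", None)
        cfg = cls(**raw) if center is None else cls(projection_center=tuple(center), **raw)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["projection_center"] = list(d["projection_center"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map canonical field names to actual CSV column names (case-insensitive)."""
    lowered = {c.strip().lower(): c for c in columns}
    out = {}
    for canon, aliases in ARGOS_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                out[canon] = lowered[alias]
                break
    return out


def read_argos(path) -> list[ArgosObservation]:
    """Read an Argos location CSV into time-sorted observations.

    Accepts comma- or semicolon-separated files.  Rows are sorted by
    timestamp; rows sharing an identical timestamp are collapsed keeping the
    better quality class.  Unparseable rows raise with their line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    colmap = _resolve_columns(df.columns)
    missing = [c for c in MANDATORY_ARGOS_COLUMNS if c not in colmap]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")

    obs = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        ts = pd.to_datetime(row[colmap["timestamp"]], utc=True, errors="coerce")
        if pd.isna(ts):
            raise FormatError(
                f"{path.name}, line {line_no}: unparseable timestamp "
                f"{row[colmap['timestamp']]!r}"
            )

        def _opt(name):
            col = colmap.get(name)
            if col is None or pd.isna(row[col]):
                return None
            return float(row[col])

        obs.append(
            ArgosObservation(
                timestamp=ts.to_pydatetime(),
                lon=float(row[colmap["lon"]]),
                lat=float(row[colmap["lat"]]),
                quality_class=str(row[colmap["quality_class"]]).strip().upper(),
                ellipse_semi_major=_opt("ellipse_semi_major"),
                ellipse_semi_minor=_opt("ellipse_semi_minor"),
                ellipse_orientation=_opt("ellipse_orientation"),
            )
        )

    obs.sort(key=lambda o: o.timestamp)
    # collapse duplicate timestamps, keeping the better quality class
    collapsed: list[ArgosObservation] = []
    for o in obs:
        if collapsed and collapsed[-1].timestamp == o.timestamp:
            prev = collapsed[-1]
            if QUALITY_ORDER.index(o.quality_class) < QUALITY_ORDER.index(prev.quality_class):
                collapsed[-1] = o
        else:
            collapsed.append(o)
    return collapsed


def observations_to_frame(obs: Iterable[ArgosObservation]) -> pd.DataFrame:
    """Tabular view of observations (one row per fix)."""
    return pd.DataFrame([dataclasses.asdict(o) for o in obs])


def write_argos(obs: Iterable[ArgosObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, index=False)


_CM_PER_S = {"cm/s", "cm s-1", "cm s**-1", "centimeter/s", "cm/sec"}
_M_PER_S = {"m/s", "m s-1", "m s**-1", "meter/s", "m/sec", "m sec-1", ""}


def _to_m_per_s(da: xr.DataArray, name: str) -> np.ndarray:
    units = str(da.attrs.get("units", "")).strip().lower()
    vals = np.asarray(da.values, dtype=float)
    if units in _CM_PER_S:
        return vals / 100.0
    if units in _M_PER_S:
        return vals
    raise FormatError(f"variable {name!r}: unrecognised units {units!r}")


def read_gridded_field(path) -> GriddedField:
    """Read a NetCDF current field (u, v on time/lat/lon axes) as GriddedField.

    Descending latitude/longitude axes are reordered to ascending; cm/s data
    (per the units attribute) is converted to m/s.
    """
    ds = xr.open_dataset(path, engine="scipy")
    try:
        for var in ("u", "v"):
            if var not in ds:
                raise FormatError(f"{Path(path).name}: missing variable {var!r}")
        ds = ds.sortby("lat").sortby("lon")
        return GriddedField(
            times=np.asarray(ds["time"].values, dtype="datetime64[ns]"),
            lats=np.asarray(ds["lat"].values, dtype=float),
            lons=np.asarray(ds["lon"].values, dtype=float),
            u=_to_m_per_s(ds["u"], "u"),
            v=_to_m_per_s(ds["v"], "v"),
        )
    finally:
        ds.close()


def write_gridded_field(fieldobj: GriddedField, path) -> None:
    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), fieldobj.u, {"units": "m/s"}),
            "v": (("time", "lat", "lon"), fieldobj.v, {"units": "m/s"}),
        },
        coords={"time": fieldobj.times, "lat": fieldobj.lats, "lon": fieldobj.lons},
    )
    ds.to_netcdf(path, engine="scipy")


#: Columns a written track always carries (extra columns pass through).
TRACK_BASE_COLUMNS = ["timestamp", "lon", "lat"]


def write_track(track: pd.DataFrame, path, format: str = "csv") -> None:
    """Write a reconstructed track (one row per regular step) as CSV or GeoJSON.

    The GeoJSON output holds one LineString for the path plus one Point
    feature per step carrying all per-step columns as properties.
    Round-trip safe to >= 6 decimal places in the coordinates.
    """
    if len(track) == 0:
        raise ValueError("refusing to write an empty track")
    missing = [c for c in TRACK_BASE_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"track missing column(s): {missing}")
    path = Path(path)
    if format == "csv":
        track.to_csv(path, index=False)
    elif format == "geojson":
        def _props(row):
            out = {}
            for k, val in row.items():
                if k in ("lon", "lat"):
                    continue
                if isinstance(val, (pd.Timestamp, _dt.datetime)):
                    out[k] = pd.Timestamp(val).isoformat()
                elif isinstance(val, (np.floating, np.integer)):
                    out[k] = val.item()
                else:
                    out[k] = None if (isinstance(val, float) and np.isnan(val)) else val
            return out

        features = [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [round(float(r.lon), 8), round(float(r.lat), 8)]
                        for r in track.itertuples()
                    ],
                },
                "properties": {"name": "predicted_path"},
            }
        ]
        for _, row in track.iterrows():
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [round(float(row["lon"]), 8), round(float(row["lat"]), 8)],
                    },
                    "properties": _props(row),
                }
            )
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(path, format: str = "csv") -> pd.DataFrame:
    """Read back a track written by :func:`write_track`."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        return df
    if format == "geojson":
        gj = json.loads(path.read_text())
        rows = []
        for feat in gj["features"]:
            if feat["geometry"]["type"] != "Point":
                continue
            lon, lat = feat["geometry"]["coordinates"]
            rows.append({"lon": lon, "lat": lat, **feat["properties"]})
        df = pd.DataFrame(rows)
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
        return df
    raise ValueError(f"unknown track format {format!r}")


def read_s1_replay(path) -> pd.DataFrame:
    """Read a replay CSV of per-relocation outputs from a previous run.

    Expected columns (case-insensitive): a date-time, current-corrected speed
    (m/s), movement persistence, and the distance between relocations (m or
    km; a ``distance_km`` name or a km units hint selects kilometres).
    Returns a frame with columns timestamp/speed/gamma/distance_m.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    lowered = {c.strip().lower(): c for c in df.columns}

    def _find(*names):
        for n in names:
            if n in lowered:
                return lowered[n]
        return None

    ts_col = _find("timestamp", "date", "datetime", "date.time", "date time")
    sp_col = _find("speed", "corrected_speed", "speed_through_water", "v")
    g_col = _find("gamma", "g", "persistence", "move_persistence")
    d_col = _find("distance_m", "distance", "dist", "distance_km", "step_distance")
    if ts_col is None or sp_col is None:
        raise FormatError("replay CSV needs at least date-time and speed columns")
    out = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(df[ts_col], utc=True),
            "speed": df[sp_col].astype(float),
        }
    )
    if g_col is not None:
        out["gamma"] = df[g_col].astype(float)
    if d_col is not None:
        dist = df[d_col].astype(float)
        out["distance_m"] = dist * 1000.0 if "km" in d_col.lower() else dist
    return out.sort_values("timestamp").reset_index(drop=True)
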