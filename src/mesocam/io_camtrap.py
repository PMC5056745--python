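"""Tabular camera-trap IO, independent-detection filtering, effort and RAI.

Photo records and deployment/effort records arrive as delimited text (CSV/TSV)
or XLSX with arbitrary column names; a schema mapping translates them to the
canonical columns used throughout the package:

photo records
    ``station_id, species, timestamp, n_individuals``
deployments
    ``station_id, latitude, longitude, elevation, start, end, camera_speed,
    lure_dates``

All tables are plain :class:`pandas.DataFrame` objects.  Rows that fail to
parse are never silently dropped: readers return a ``(table, rejects)`` pair
where ``rejects`` carries the offending row index and a human-readable reason.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesocam.errors import ConfigurationError, DataConsistencyError, EmptyInputError

logger = logging.getLogger(__name__)

PHOTO_COLUMNS = ("station_id", "species", "timestamp", "n_individuals")
DEPLOYMENT_COLUMNS = (
    "station_id",
    "latitude",
    "longitude",
    "elevation",
    "start",
    "end",
    "camera_speed",
    "lure_dates",
)

#: months making up the winter season; everything else is the warm season
WINTER_MONTHS = frozenset({12, 1, 2})


def season_of_month(month: int | np.ndarray) -> str | np.ndarray:
    """Map calendar month(s) to ``"winter"`` (Dec-Feb) or ``"warm"`` (Mar-Nov)."""
    if np.isscalar(month):
        return "winter" if int(month) in WINTER_MONTHS else "warm"
    month = np.asarray(month)
    return np.where(np.isin(month, list(WINTER_MONTHS)), "winter", "warm")


def _read_table(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        return pd.read_excel(path, dtype=str)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def _apply_schema(raw: pd.DataFrame, schema: Mapping[str, str] | None,
                  required: Sequence[str], optional: Sequence[str] = ()) -> pd.DataFrame:
    """Rename columns per ``schema`` (canonical -> file column) and validate."""
    if schema:
        missing_src = [src for src in schema.values() if src not in raw.columns]
        if missing_src:
            raise ConfigurationError(
                f"schema maps to columns absent from file: {missing_src}; "
                f"file has {list(raw.columns)}"
            )
        raw = raw.rename(columns={src: dst for dst, src in schema.items()})
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) {missing} not found after schema mapping; "
            f"available: {list(raw.columns)}"
        )
    keep = [c for c in (*required, *optional) if c in raw.columns]
    return raw[keep].copy()


def read_photo_records(path, schema: Mapping[str, str] | None = None):
    """Read a photo-record table.

    Parameters
    ----------
    path
        CSV/TSV/XLSX file with one row per photograph.
    schema
        Optional mapping from canonical column names (``station_id``,
        ``species``, ``timestamp``, ``n_individuals``) to the file's column
        names.  Omitted when the file already uses canonical names.
        ``n_individuals`` may be absent from the file; it defaults to 1.

    Returns
    -------
    (records, rejects)
        ``records`` has canonical columns with ``timestamp`` parsed to
        datetime; ``rejects`` lists unparseable rows with a ``reason`` column.
    """
    raw = _read_table(path)
    if raw.empty:
        raise EmptyInputError(f"no rows in {path}")
    df = _apply_schema(raw, schema, ["station_id", "species", "timestamp"],
                       ["n_individuals"])
    if "n_individuals" not in df.columns:
        df["n_individuals"] = "1"

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    n_ind = pd.to_numeric(df["n_individuals"].fillna("1"), errors="coerce")

    bad_ts = ts.isna()
    bad_n = n_ind.isna() | (n_ind < 1)
    reasons = pd.Series("", index=df.index)
    reasons[bad_ts] = "unparseable timestamp: " + df.loc[bad_ts, "timestamp"].astype(str)
    reasons[bad_n & ~bad_ts] = "invalid n_individuals: " + df.loc[bad_n & ~bad_ts, "n_individuals"].astype(str)
    bad = bad_ts | bad_n

    rejects = df[bad].assign(reason=reasons[bad])
    records = df[~bad].assign(timestamp=ts[~bad], n_individuals=n_ind[~bad].astype(int))
    records = records.reset_index(drop=True)
    logger.info("read %d photo records (%d rejected) from %s",
                len(records), len(rejects), path)
    return records, rejects.reset_index(drop=True)


def _parse_lure_dates(cell) -> list:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return []
    return [pd.Timestamp(tok.strip()) for tok in str(cell).split(";") if tok.strip()]


def read_deployments(path, schema: Mapping[str, str] | None = None,
                     fallback_coords: tuple[float, float] | None = None):
    """Read a deployment/effort table into canonical columns.

    ``lure_dates`` is a ``;``-separated list of dates in the file and becomes a
    list of :class:`pandas.Timestamp` per row.  ``camera_speed`` must be
    ``fast`` or ``slow`` (case-insensitive).  Deployments with a non-positive
    span are rejected with reason ``"negative span"``.  Missing coordinates are
    an error unless ``fallback_coords`` (lat, lon) is given, in which case they
    are filled and a warning logged.
    """
    raw = _read_table(path)
    if raw.empty:
        raise EmptyInputError(f"no rows in {path}")
    df = _apply_schema(raw, schema, ["station_id", "start", "end"],
                       ["latitude", "longitude", "elevation", "camera_speed", "lure_dates"])
    for col in ("latitude", "longitude", "elevation", "camera_speed", "lure_dates"):
        if col not in df.columns:
            df[col] = None

    start = pd.to_datetime(df["start"], errors="coerce", format="mixed")
    end = pd.to_datetime(df["end"], errors="coerce", format="mixed")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")

    no_coords = lat.isna() | lon.isna()
    if no_coords.any():
        if fallback_coords is None:
            raise ConfigurationError(
                f"{int(no_coords.sum())} deployment(s) lack coordinates and no "
                "fallback centroid is configured (solar schedules need them)"
            )
        logger.warning("%d deployment(s) missing coordinates; using fallback %s",
                       int(no_coords.sum()), fallback_coords)
        lat = lat.fillna(fallback_coords[0])
        lon = lon.fillna(fallback_coords[1])

    bad_time = start.isna() | end.isna()
    neg_span = ~bad_time & (end <= start)
    reasons = pd.Series("", index=df.index)
    reasons[bad_time] = "unparseable start/end"
    reasons[neg_span] = "negative span"
    bad = bad_time | neg_span

    speed = df["camera_speed"].astype(str).str.strip().str.lower()
    speed = speed.where(speed.isin(["fast", "slow"]), "fast")

    out = df[~bad].assign(
        start=start[~bad], end=end[~bad],
        latitude=lat[~bad], longitude=lon[~bad],
        elevation=pd.to_numeric(df["elevation"], errors="coerce")[~bad],
        camera_speed=speed[~bad],
        lure_dates=df.loc[~bad, "lure_dates"].map(_parse_lure_dates),
    ).reset_index(drop=True)
    rejects = df[bad].assign(reason=reasons[bad]).reset_index(drop=True)
    logger.info("read %d deployments (%d rejected) from %s", len(out), len(rejects), path)
    return out, rejects


def independent_events(photos: pd.DataFrame, gap_minutes: float = 30.0) -> pd.DataFrame:
    """Collapse a photo stream into independent detection events.

    Within each (station, species) stream sorted by time, a new event starts
    iff the gap to the *previous photo* strictly exceeds ``gap_minutes`` (the
    standard >0.5 h independence rule).  Multiple individuals in one photograph
    count as a single detection; photos with identical timestamps collapse into
    one before the gap rule is applied.

    Returns a frame with ``station_id, species, event_time, month, season``.
    """
    cols = ["station_id", "species", "event_time", "month", "season"]
    if photos.empty:
        return pd.DataFrame(columns=cols)
    df = photos[["station_id", "species", "timestamp"]].drop_duplicates()
    df = df.sort_values(["station_id", "species", "timestamp"], kind="mergesort")
    gap = df.groupby(["station_id", "species"], sort=False)["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=gap_minutes))
    events = df[new_event].rename(columns={"timestamp": "event_time"}).copy()
    events["month"] = events["event_time"].dt.month
    events["season"] = season_of_month(events["month"].to_numpy())
    return events.reset_index(drop=True)[cols]


def effort_summary(deployments: pd.DataFrame) -> dict:
    """Camera-day effort per station-month, with season and overall totals.

    Per-deployment camera-days equal the deployment span in (fractional) days,
    apportioned to calendar months pro-rata by overlap.  Returns a dict with

    ``monthly``
        DataFrame ``station_id, year, month, camera_days``.
    ``by_season``
        ``{"warm": float, "winter": float}`` (warm = Mar-Nov).
    ``total``
        overall camera-days.
    """
    rows = []
    for dep in deployments.itertuples(index=False):
        t0, t1 = pd.Timestamp(dep.start), pd.Timestamp(dep.end)
        cursor = t0
        while cursor < t1:
            month_end = (cursor.normalize().replace(day=1) + pd.offsets.MonthBegin(1))
            chunk_end = min(month_end, t1)
            days = (chunk_end - cursor) / pd.Timedelta(days=1)
            rows.append((dep.station_id, cursor.year, cursor.month, days))
            cursor = chunk_end
    monthly = pd.DataFrame(rows, columns=["station_id", "year", "month", "camera_days"])
    if not monthly.empty:
        monthly = (monthly.groupby(["station_id", "year", "month"], as_index=False)
                   ["camera_days"].sum())
    season = season_of_month(monthly["month"].to_numpy()) if len(monthly) else np.array([])
    by_season = {
        "warm": float(monthly["camera_days"][season == "warm"].sum()) if len(monthly) else 0.0,
        "winter": float(monthly["camera_days"][season == "winter"].sum()) if len(monthly) else 0.0,
    }
    total = by_season["warm"] + by_season["winter"]
    logger.info("effort: %.1f camera-days total (%.1f warm, %.1f winter)",
                total, by_season["warm"], by_season["winter"])
    return {"monthly": monthly, "by_season": by_season, "total": total}


def monthly_rai(events: pd.DataFrame, effort: dict, species: str) -> pd.DataFrame:
    """Relative activity index per calendar month, pooled across years.

    RAI_j = 1000 * detections_j / camera_days_j.  Months with zero effort and
    zero detections get ``NaN`` (undefined); zero effort with detections is a
    data-consistency error.
    """
    eff = (effort["monthly"].groupby("month")["camera_days"].sum()
           .reindex(range(1, 13), fill_value=0.0))
    ev = events[events["species"] == species]
    det = ev.groupby("month").size().reindex(range(1, 13), fill_value=0)
    bad = (eff == 0) & (det > 0)
    if bad.any():
        raise DataConsistencyError(
            f"months {list(det.index[bad])} have detections of {species!r} but zero camera-days"
        )
    rai = np.where(eff > 0, 1000.0 * det / np.where(eff > 0, eff, 1.0), np.nan)
    return pd.DataFrame({
        "month": range(1, 13),
        "detections": det.to_numpy(),
        "camera_days": eff.to_numpy(),
        "rai": rai,
    })


def season_species_summary(events: pd.DataFrame, effort: dict) -> pd.DataFrame:
    """Survey-summary table: camera-days and per-species detections by season."""
    rows = [{"quantity": "camera_days", "warm": effort["by_season"]["warm"],
             "winter": effort["by_season"]["winter"], "total": effort["total"]}]
    for sp, grp in events.groupby("species"):
        warm = int((grp["season"] == "warm").sum())
        winter = int((grp["season"] == "winter").sum())
        rows.append({"quantity": sp, "warm": warm, "winter": winter,
                     "total": warm + winter})
    return pd.DataFrame(rows)
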