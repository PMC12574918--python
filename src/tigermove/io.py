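"""Reading/writing telemetry tables and the false-detection filter.

CSV dialects
------------
``receivers``: one row per deployment interval —
    station_id, array, latitude, longitude, depth_m, habitat,
    install_date, removal_date (blank = still deployed)
``tags``:
    shark_id, tag_id, tagging_datetime, tagging_array, fl_tagging_cm,
    sex, claspers_calcified, min_delay_s, max_delay_s
``detections``:
    timestamp (ISO-8601, UTC), tag_id, station_id

A thin mapping layer also accepts VUE-style detection exports with
columns "Date and Time (UTC)", "Transmitter" and "Receiver".

False-detection filter
----------------------
Rule A (impossible interval): a detection closer to the previous
*retained* detection of the same tag at the same station than the tag's
minimum transmission delay cannot be genuine and is removed.  Comparing
against the previous retained (not previous raw) record stops a burst of
spurious detections from shielding each other.
Rule B (isolated singleton): a detection with no other detection of the
same tag anywhere in the array within +/- ``isolation_window_h`` (24 h
default) is removed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "HABITAT_CLASSES",
    "read_receivers",
    "read_tags",
    "read_detections",
    "filter_false_detections",
    "write_table",
]

HABITAT_CLASSES = ("coral reef", "deep wall", "sand", "seagrass")

VUE_DETECTION_COLUMNS = {
    "Date and Time (UTC)": "timestamp",
    "Transmitter": "tag_id",
    "Receiver": "station_id",
}

_RECEIVER_COLUMNS = [
    "station_id",
    "array",
    "latitude",
    "longitude",
    "depth_m",
    "habitat",
    "install_date",
    "removal_date",
]
_TAG_COLUMNS = [
    "shark_id",
    "tag_id",
    "tagging_datetime",
    "tagging_array",
    "fl_tagging_cm",
    "sex",
    "claspers_calcified",
    "min_delay_s",
    "max_delay_s",
]
_DETECTION_COLUMNS = ["timestamp", "tag_id", "station_id"]


class SchemaError(ValueError):
    """A required column is missing or a field fails validation."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file missing column(s): {missing}")


def _parse_timestamps(series: pd.Series, what: str) -> pd.Series:
    parsed = pd.to_datetime(series, utc=True, format="mixed", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()
        raise SchemaError(
            f"{what}: unparseable timestamp(s) at data line(s) {lines[:10]}"
        )
    return parsed.dt.tz_localize(None)  # keep naive UTC internally


def read_receivers(path) -> pd.DataFrame:
    """Read receiver-station metadata; one row per deployment interval."""
    df = pd.read_csv(path)
    _require_columns(df, _RECEIVER_COLUMNS[:-1], "receivers")
    if "removal_date" not in df.columns:
        df["removal_date"] = pd.NaT
    bad_habitat = set(df["habitat"].dropna()) - set(HABITAT_CLASSES)
    if bad_habitat:
        raise SchemaError(
            f"receivers: unknown habitat class(es) {sorted(bad_habitat)}; "
            f"expected one of {HABITAT_CLASSES}"
        )
    df["install_date"] = _parse_timestamps(df["install_date"], "receivers")
    df["removal_date"] = pd.to_datetime(
        df["removal_date"], utc=True, format="mixed", errors="coerce"
    ).dt.tz_localize(None)
    if ((df["depth_m"] < 0) | (df["depth_m"] > 1000)).any():
        raise SchemaError("receivers: depth_m outside [0, 1000]")
    closed = df.dropna(subset=["removal_date"])
    if (closed["removal_date"] <= closed["install_date"]).any():
        raise SchemaError("receivers: removal_date must follow install_date")
    # deployments of one station must not overlap
    for sid, grp in df.sort_values("install_date").groupby("station_id"):
        ends = grp["removal_date"].fillna(pd.Timestamp.max)
        if (grp["install_date"].iloc[1:].to_numpy() < ends.iloc[:-1].to_numpy()).any():
            raise SchemaError(f"receivers: overlapping deployments for {sid}")
    return df.sort_values(["array", "station_id", "install_date"]).reset_index(
        drop=True
    )


def read_tags(path) -> pd.DataFrame:
    """Read tag/shark metadata."""
    df = pd.read_csv(path)
    _require_columns(df, _TAG_COLUMNS, "tags")
    df["tagging_datetime"] = _parse_timestamps(df["tagging_datetime"], "tags")
    if ((df["fl_tagging_cm"] < 50) | (df["fl_tagging_cm"] > 400)).any():
        raise SchemaError("tags: fl_tagging_cm outside plausibility window [50, 400]")
    if (df["min_delay_s"] > df["max_delay_s"]).any() or (df["min_delay_s"] <= 0).any():
        raise SchemaError("tags: require 0 < min_delay_s <= max_delay_s")
    return df.sort_values("shark_id").reset_index(drop=True)


def read_detections(
    path,
    tags: pd.DataFrame,
    quarantine_path=None,
) -> pd.DataFrame:
    """Read a detections CSV (native or VUE-style headers).

    Detections whose ``tag_id`` is absent from ``tags`` are quarantined:
    dropped from the returned frame with a warning and, if
    ``quarantine_path`` is given, written there.
    """
    df = pd.read_csv(path)
    if set(VUE_DETECTION_COLUMNS) <= set(df.columns):
        df = df.rename(columns=VUE_DETECTION_COLUMNS)
    _require_columns(df, _DETECTION_COLUMNS, "detections")
    df = df[_DETECTION_COLUMNS].copy()
    if len(df):
        df["timestamp"] = _parse_timestamps(df["timestamp"], "detections")
    else:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    known = set(tags["tag_id"])
    unknown_mask = ~df["tag_id"].isin(known)
    if unknown_mask.any():
        quarantined = df[unknown_mask]
        warnings.warn(
            f"{unknown_mask.sum()} detection(s) with unknown tag_id "
            f"{sorted(quarantined['tag_id'].unique())[:5]} quarantined",
            stacklevel=2,
        )
        if quarantine_path is not None:
            quarantined.to_csv(quarantine_path, index=False)
        df = df[~unknown_mask]
    df = df.sort_values(["timestamp", "tag_id", "station_id"]).reset_index(drop=True)
    df["qc_status"] = "raw"
    return df


def filter_false_detections(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    isolation_window_h: float = 24.0,
    same_station_only: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the two-rule false-detection filter.

    Returns ``(retained, removed, report)``; ``retained`` rows get
    ``qc_status="retained"`` and removed rows ``"removed_short_interval"``
    or ``"removed_isolated"``.  The union of the two frames is the input,
    and the filter is idempotent on its retained output.
    """
    det = detections.sort_values(["tag_id", "timestamp", "station_id"]).reset_index(
        drop=True
    )
    tag_ids = det["tag_id"].unique()
    delays = tags.set_index("tag_id")["min_delay_s"]
    missing = [t for t in tag_ids if t not in delays.index]
    if missing:
        raise SchemaError(f"tags without delay metadata: {sorted(missing)}")

    status = np.full(len(det), "retained", dtype=object)
    t_ns = det["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64")
    win_ns = int(isolation_window_h * 3600 * 1e9)

    stations_arr = det["station_id"].to_numpy()
    for tag, idx in det.groupby("tag_id", sort=False).indices.items():
        min_delay_ns = int(delays.loc[tag] * 1e9)
        idx = np.asarray(idx)
        # Rule A: impossible short intervals vs previous retained
        if same_station_only:
            by_station: dict = {}
            for i in idx:  # idx is time-ordered within tag
                by_station.setdefault(stations_arr[i], []).append(i)
            groups = list(by_station.values())
        else:
            groups = [idx]
        for g in groups:
            last_kept = None
            for i in g:
                if last_kept is not None and t_ns[i] - t_ns[last_kept] < min_delay_ns:
                    status[i] = "removed_short_interval"
                else:
                    last_kept = i
        # Rule B: isolated singletons among Rule-A survivors (array-wide)
        surv = idx[status[idx] == "retained"]
        if len(surv) == 0:
            continue
        ts = t_ns[surv]
        prev_gap = np.diff(ts, prepend=ts[0] - 2 * win_ns - 1)
        next_gap = np.diff(ts, append=ts[-1] + 2 * win_ns + 1)
        isolated = (prev_gap > win_ns) & (next_gap > win_ns)
        status[surv[isolated]] = "removed_isolated"

    det = det.assign(qc_status=status)
    retained = det[det["qc_status"] == "retained"].reset_index(drop=True)
    removed = det[det["qc_status"] != "retained"].reset_index(drop=True)
    report = (
        det.groupby("tag_id")["qc_status"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(
            columns=["retained", "removed_short_interval", "removed_isolated"],
            fill_value=0,
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    report["n_input"] = report[
        ["retained", "removed_short_interval", "removed_isolated"]
    ].sum(axis=1)
    return retained, removed, report


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy CSV deterministically (stable column order, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
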