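"""Detection days, residency index, station-residency runs, occupancy.

All metrics operate on *detection days*: calendar dates (in a
configurable timezone, default UTC) on which a shark was detected at a
station.  The residency index RI of a shark is its number of detection
days divided by its monitoring period — the inclusive day count from
first to last detection — so RI lies in (0, 1] and a single-day record
gives RI = 1.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "to_detection_days",
    "residency_summary",
    "residency_index",
    "station_residency_runs",
    "station_residency",
    "occupancy",
    "monthly_summary",
]


def to_detection_days(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    tz: str = "UTC",
) -> pd.DataFrame:
    """Reduce QC-retained detections to unique (shark, station, date) rows.

    ``first_time`` (earliest ping that day at that station) is kept for
    the deterministic same-day ordering used by run segmentation.
    """
    det = detections.merge(tags[["tag_id", "shark_id"]], on="tag_id", how="inner")
    ts = det["timestamp"]
    if tz != "UTC":
        ts = ts.dt.tz_localize("UTC").dt.tz_convert(tz).dt.tz_localize(None)
    det = det.assign(date=ts.dt.normalize())
    days = (
        det.groupby(["shark_id", "station_id", "date"], as_index=False)["timestamp"]
        .min()
        .rename(columns={"timestamp": "first_time"})
    )
    return days.sort_values(["shark_id", "date", "first_time", "station_id"]).reset_index(
        drop=True
    )


def residency_summary(detection_days: pd.DataFrame) -> pd.DataFrame:
    """Per-shark residency summary (first/last detection, RI)."""
    if detection_days.empty:
        return pd.DataFrame(
            columns=[
                "shark_id",
                "first_detection",
                "last_detection",
                "monitoring_days",
                "n_detection_days",
                "residency_index",
            ]
        )
    per = detection_days.groupby("shark_id").agg(
        first_detection=("date", "min"),
        last_detection=("date", "max"),
        n_detection_days=("date", "nunique"),
    )
    per["monitoring_days"] = (
        (per["last_detection"] - per["first_detection"]).dt.days + 1
    )
    per["residency_index"] = per["n_detection_days"] / per["monitoring_days"]
    return per.reset_index()[
        [
            "shark_id",
            "first_detection",
            "last_detection",
            "monitoring_days",
            "n_detection_days",
            "residency_index",
        ]
    ]


def residency_index(detection_days: pd.DataFrame, shark_id) -> pd.Series:
    """Residency summary row for one shark; raises if the shark is absent."""
    summ = residency_summary(detection_days)
    row = summ[summ["shark_id"] == shark_id]
    if row.empty:
        raise KeyError(f"shark {shark_id!r} has no detection days")
    return row.iloc[0]


def station_residency_runs(
    detection_days: pd.DataFrame, shark_id=None
) -> pd.DataFrame:
    """Segment detection days into consecutive-day runs per station.

    A run of consecutive detection days at one station ends when the
    shark is (a) detected at another station, or (b) absent for over
    24 h — at day resolution, a gap of at least one full calendar day —
    and re-detected at the same station.  Days with detections at
    several stations are ordered by earliest ping then station id: the
    earlier-visited station's run continues through that day and then
    closes, runs at the other stations start that day.
    """
    days = detection_days
    if shark_id is not None:
        days = days[days["shark_id"] == shark_id]
    runs = []
    for sid, grp in days.groupby("shark_id"):
        grp = grp.sort_values(["date", "first_time", "station_id"])
        cur_station = None
        cur_start = None
        cur_days: set = set()
        last_date = None

        def close(reason):
            runs.append(
                {
                    "shark_id": sid,
                    "station_id": cur_station,
                    "start_date": cur_start,
                    "length_days": len(cur_days),
                    "terminated_by": reason,
                }
            )

        for r in grp.itertuples():
            if cur_station is None:
                cur_station, cur_start, cur_days, last_date = (
                    r.station_id,
                    r.date,
                    {r.date},
                    r.date,
                )
                continue
            gap = (r.date - last_date).days
            if r.station_id == cur_station and gap <= 1:
                cur_days.add(r.date)
                last_date = r.date
            else:
                close("other_station" if r.station_id != cur_station else "gap_over_24h")
                cur_station, cur_start, cur_days, last_date = (
                    r.station_id,
                    r.date,
                    {r.date},
                    r.date,
                )
        if cur_station is not None:
            close("end_of_record")
    return pd.DataFrame(
        runs,
        columns=["shark_id", "station_id", "start_date", "length_days", "terminated_by"],
    )


def station_residency(runs: pd.DataFrame) -> pd.DataFrame:
    """Mean run length (days) per station, over all runs given."""
    if runs.empty:
        return pd.DataFrame(columns=["station_id", "station_residency_days"])
    out = (
        runs.groupby("station_id")["length_days"]
        .mean()
        .rename("station_residency_days")
        .reset_index()
    )
    return out


def occupancy(
    detection_days: pd.DataFrame,
    group: set,
    receivers: pd.DataFrame | None = None,
    detected_only: bool = False,
) -> pd.DataFrame:
    """Mean total detection days per station over a group of sharks.

    Group members with zero days at a station contribute zeros (the
    group-mean convention) unless ``detected_only`` is set.  When
    ``receivers`` is supplied, a zero only counts for members whose
    monitoring window overlapped one of the station's deployments.
    """
    group = set(group)
    if not group:
        raise ValueError("occupancy requires a non-empty shark group")
    days = detection_days[detection_days["shark_id"].isin(group)]
    counts = (
        days.groupby(["station_id", "shark_id"]).size().rename("days").reset_index()
    )
    stations = sorted(
        set(counts["station_id"])
        | (set(receivers["station_id"]) if receivers is not None else set())
    )
    spans = (
        days.groupby("shark_id")["date"].agg(["min", "max"])
        if receivers is not None
        else None
    )
    rows = []
    for st in stations:
        at = counts[counts["station_id"] == st].set_index("shark_id")["days"]
        if detected_only:
            members = set(at.index)
        elif receivers is None:
            members = group
        else:
            deps = receivers[receivers["station_id"] == st]
            members = set()
            for sid in group:
                if sid in at.index:
                    members.add(sid)
                    continue
                if sid not in spans.index:
                    continue
                lo, hi = spans.loc[sid, "min"], spans.loc[sid, "max"]
                for d in deps.itertuples():
                    rem = d.removal_date if pd.notna(d.removal_date) else pd.Timestamp.max
                    if d.install_date <= hi and rem >= lo:
                        members.add(sid)
                        break
        if not members:
            continue
        total = sum(at.get(sid, 0) for sid in members)
        rows.append(
            {
                "station_id": st,
                "occupancy_days": total / len(members),
                "n_members": len(members),
            }
        )
    return pd.DataFrame(rows, columns=["station_id", "occupancy_days", "n_members"])


def monthly_summary(
    detection_days: pd.DataFrame,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Month-of-year x group table of mean detection days per shark.

    For each shark, detection days are totalled per calendar month
    (pooled across years) and averaged over the sharks of each group.
    ``groups`` maps shark_id -> label; omitted sharks form group "all".
    """
    days = detection_days.copy()
    days["month"] = days["date"].dt.month
    label = (
        days["shark_id"].map(groups).fillna("all") if groups else "all"
    )
    days["group"] = label
    per_shark = (
        days.drop_duplicates(["shark_id", "date"])
        .groupby(["group", "shark_id", "month"])
        .size()
        .rename("days")
        .reset_index()
    )
    n_per_group = per_shark.groupby("group")["shark_id"].nunique()
    table = (
        per_shark.groupby(["group", "month"])["days"].sum().reset_index()
    )
    table["mean_detection_days"] = table.apply(
        lambda r: r["days"] / n_per_group[r["group"]], axis=1
    )
    return (
        table.pivot(index="month", columns="group", values="mean_detection_days")
        .reindex(range(1, 13))
        .fillna(0.0)
    )
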