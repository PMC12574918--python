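"""End-to-end orchestration: simulate → QC → residency → staging → networks → models.

`run_cohort` executes the full chain on either simulated or loaded
data and returns an in-memory bundle of tidy tables; `write_bundle`
serialises the bundle (plus the run configuration) to CSV/YAML for a
resumable, archivable run.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth, io, models, network, residency
from .simulate import SimConfig, emit_detections, simulate_array, simulate_cohort_and_tracks

__all__ = ["run_cohort", "build_motility_records", "write_bundle"]


def build_motility_records(
    retained: pd.DataFrame,
    tags: pd.DataFrame,
    receivers: pd.DataFrame,
    staged: pd.DataFrame,
    directed: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-shark, per-array motility records plus the network objects.

    One record per (shark, array-with-detections); the ``primary``
    column flags each shark's main array (most detection days) — the
    record used for motility modelling, with ``island`` set to that
    array.
    """
    days = residency.to_detection_days(retained, tags)
    summary = residency.residency_summary(days)
    station_arrays = receivers.drop_duplicates("station_id").set_index("station_id")[
        "array"
    ]
    det = retained.merge(tags[["tag_id", "shark_id"]], on="tag_id")
    staged_ix = staged.set_index("shark_id") if len(staged) else None

    records = []
    nets: dict[tuple, network.MovementNetwork] = {}
    for row in summary.itertuples():
        sid = row.shark_id
        active = network.active_stations(
            row.first_detection, row.last_detection, receivers
        )
        shark_det = det[det["shark_id"] == sid]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shark_nets = network.build_networks(shark_det, sid, active, station_arrays)
        shark_days = days[days["shark_id"] == sid]
        days_per_array = (
            shark_days.assign(array=shark_days["station_id"].map(station_arrays))
            .groupby("array")
            .size()
        )
        for arr, net in shark_nets.items():
            if not net.visited:
                continue
            nets[(sid, arr)] = net
            rec = network.motility(net, directed=directed)
            rec.update(
                {
                    "shark_id": sid,
                    "island": arr,
                    "detection_days": int(days_per_array.get(arr, 0)),
                }
            )
            if staged_ix is not None and sid in staged_ix.index:
                rec["sex"] = staged_ix.loc[sid, "sex"]
                rec["fl_first_detection_cm"] = staged_ix.loc[
                    sid, "fl_first_detection_cm"
                ]
            records.append(rec)
    motility = pd.DataFrame(records)
    if len(motility):
        primary_idx = (
            motility.sort_values(
                ["detection_days", "array"], ascending=[False, True]
            )
            .groupby("shark_id")
            .head(1)
            .index
        )
        motility["primary"] = motility.index.isin(primary_idx)
        motility = motility.sort_values(["shark_id", "array"]).reset_index(drop=True)
    return motility, nets


def run_cohort(
    config: SimConfig,
    null_reps: int = 200,
    directed: bool = True,
    fit_models: bool = True,
) -> dict:
    """Run the full synthetic pipeline; returns a bundle of results."""
    receivers = simulate_array(config)
    tags, truths = simulate_cohort_and_tracks(config, receivers)
    detections = emit_detections(truths, receivers, config, tags)
    raw = detections.drop(columns=["truth_flag"]).assign(qc_status="raw")
    retained, removed, qc_report = io.filter_false_detections(
        raw, tags, isolation_window_h=config.isolation_window_h
    )
    days = residency.to_detection_days(retained, tags)
    summary = residency.residency_summary(days)
    runs = residency.station_residency_runs(days)
    staged, reclass_report = growth.restage_cohort(
        tags, retained, config.growth_schedule
    )
    motility, nets = build_motility_records(
        retained, tags, receivers, staged, directed=directed
    )

    null_rows = []
    rng = np.random.default_rng([config.seed, 4])
    for (sid, arr), net in nets.items():
        if net.n_movements == 0 or len(net.nodes) < 2:
            continue
        g = network.to_graph(net)
        observed = network.node_metrics(net)["betweenness"].to_numpy()
        null = network.random_network_null(
            len(g.nodes), len(g.edges), reps=null_reps, seed=rng
        )
        res = network.compare_to_null(observed, null)
        null_rows.append(
            {
                "shark_id": sid,
                "array": arr,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    null_tests = pd.DataFrame(null_rows)

    bundle = {
        "config": config,
        "receivers": receivers,
        "tags": tags,
        "truths": truths,
        "detections": detections,
        "retained": retained,
        "removed": removed,
        "qc_report": qc_report,
        "detection_days": days,
        "residency": summary,
        "runs": runs,
        "staged": staged,
        "reclassification_report": reclass_report,
        "motility": motility,
        "networks": nets,
        "null_tests": null_tests,
        "movers": network.count_movers(motility)
        if len(motility)
        else {"per_array": {}, "total": 0},
    }
    if fit_models and len(motility):
        primary = motility[motility["primary"]].dropna(
            subset=["sex", "fl_first_detection_cm"]
        )
        if len(primary) >= 10:
            fits = models.fit_candidates(primary)
            table = models.model_selection_table(fits)
            bundle["model_fits"] = fits
            bundle["model_table"] = table
            bundle["selected_model"] = models.select_model(table)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    """Archive the run: tidy CSVs, config YAML, and a small manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = [
        "receivers", "tags", "detections", "retained", "removed", "qc_report",
        "detection_days", "residency", "runs", "staged",
        "reclassification_report", "motility", "null_tests",
    ]
    written = []
    for name in tables:
        df = bundle.get(name)
        if isinstance(df, pd.DataFrame):
            io.write_table(df, out / f"{name}.csv")
            written.append(f"{name}.csv")
    if "model_table" in bundle:
        io.write_table(bundle["model_table"], out / "model_selection.csv")
        written.append("model_selection.csv")
    cfg = dataclasses.asdict(bundle["config"])
    cfg["growth_schedule"] = bundle["config"].growth_schedule.to_frame().to_dict(
        "records"
    )
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, default_flow_style=False)
    manifest = {"files": written}
    if "selected_model" in bundle:
        manifest["selected_model"] = bundle["selected_model"]
    if "movers" in bundle:
        manifest["movers"] = bundle["movers"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
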