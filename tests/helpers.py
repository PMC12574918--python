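"""Shared test utilities and independent brute-force oracles.

The oracles deliberately use naive enumeration (O(n^2) scans, explicit
2^n sign enumeration, all-shortest-path listing) so they share no code
path with the implementations they check.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sp_stats


def make_detections(rows):
    """rows: (timestamp, tag_id, station_id) triples -> raw detection frame."""
    df = pd.DataFrame(rows, columns=["timestamp", "tag_id", "station_id"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["qc_status"] = "raw"
    return df.sort_values(["timestamp", "tag_id", "station_id"]).reset_index(drop=True)


def brute_force_filter(det, min_delay_s, window_h=24.0):
    """O(n^2) pairwise-interval oracle for the false-detection filter."""
    det = det.sort_values(["tag_id", "timestamp", "station_id"]).reset_index(drop=True)
    status = {}
    for tag, grp in det.groupby("tag_id"):
        rows = list(grp.itertuples())
        kept_a = []
        for r in rows:
            prev = [k for k in kept_a if k.station_id == r.station_id]
            if prev and (r.timestamp - prev[-1].timestamp).total_seconds() < min_delay_s:
                status[r.Index] = "removed_short_interval"
            else:
                kept_a.append(r)
                status[r.Index] = "retained"
        for r in kept_a:
            others = [
                k
                for k in kept_a
                if k.Index != r.Index
                and abs((k.timestamp - r.timestamp).total_seconds())
                <= window_h * 3600
            ]
            if not others:
                status[r.Index] = "removed_isolated"
    return pd.Series(status)


def brute_force_betweenness(g: nx.DiGraph) -> dict:
    """All-pairs shortest-path enumeration with fractional tie credit."""
    btw = {v: 0.0 for v in g.nodes}
    for s, t in itertools.permutations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                btw[v] += 1.0 / len(paths)
    return btw


def brute_force_wilcoxon_p(d):
    """Two-sided exact Wilcoxon p by explicit 2^n sign enumeration."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sp_stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean = ranks.sum() / 2.0
    dev = abs(w_obs - mean)
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mean) >= dev - 1e-9:
            count += 1
    return count / total
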