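"""Per-individual movement networks over acoustic receiver arrays.

Receivers are nodes; movements — consecutive retained detections of one
shark at two different stations — are directed, weighted edges.  Because
not every receiver was recording for every shark, each shark's network
is built over its *active stations*: receivers whose deployment interval
overlapped the shark's own monitoring window (first to last detection)
by at least one day.  Node density (fraction of active stations visited)
and edge density (fraction of possible ordered station pairs traversed)
summarise an individual's motility on an array.

Transitions that span the two arrays are tallied separately as
inter-array connectivity and are not edges of either array network —
the arrays are analysed as separate networks.

Observed per-node metrics are tested against Erdős–Rényi G(n, m) random
directed graphs with matching node and edge counts, using a one-sample
Wilcoxon signed-rank test of the observed values against the null mean.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .stats import WilcoxonResult, wilcoxon_signed_rank

__all__ = [
    "MovementNetwork",
    "active_stations",
    "build_networks",
    "build_network",
    "node_metrics",
    "motility",
    "random_network_null",
    "compare_to_null",
    "to_graph",
    "count_movers",
]


@dataclass
class MovementNetwork:
    """Directed weighted movement graph of one owner on one array."""

    owner: str
    array: str
    nodes: frozenset  # active stations
    edges: Counter  # (src, dst) -> movement count, src != dst
    visited: frozenset  # stations with >= 1 retained detection
    n_movements: int
    inter_array_movements: int = 0
    off_active_visits: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        assert all(s != d for s, d in self.edges), "self-loops are not movements"
        assert self.n_movements == sum(self.edges.values())


def active_stations(
    first_detection,
    last_detection,
    receivers: pd.DataFrame,
) -> dict[str, frozenset]:
    """Stations active during a shark's monitoring window, per array.

    A station is active if any of its deployment intervals overlaps
    ``[first_detection, last_detection]`` by at least one day (closed
    intervals at day resolution).
    """
    lo = pd.Timestamp(first_detection).normalize()
    hi = pd.Timestamp(last_detection).normalize()
    out: dict[str, set] = {}
    for r in receivers.itertuples():
        install = pd.Timestamp(r.install_date).normalize()
        removal = (
            pd.Timestamp(r.removal_date).normalize()
            if pd.notna(r.removal_date)
            else pd.Timestamp.max
        )
        if install <= hi and removal >= lo:
            out.setdefault(r.array, set()).add(r.station_id)
    return {a: frozenset(s) for a, s in out.items()}


def build_networks(
    detections: pd.DataFrame,
    owner: str,
    active: dict[str, frozenset],
    station_arrays: pd.Series,
) -> dict[str, MovementNetwork]:
    """Build one MovementNetwork per array from a shark's retained detections.

    ``station_arrays`` maps station_id -> array label.  Consecutive
    detections at different stations of the same array increment that
    directed edge; consecutive detections spanning arrays increment the
    inter-array tally of both networks; repeat detections at one station
    add nothing.
    """
    det = detections.sort_values("timestamp")
    stations = det["station_id"].tolist()
    arrays = [station_arrays[s] for s in stations]
    edges: dict[str, Counter] = {a: Counter() for a in active}
    visited: dict[str, set] = {a: set() for a in active}
    inter = 0
    for s, a in zip(stations, arrays):
        visited.setdefault(a, set()).add(s)
    for (s1, a1), (s2, a2) in zip(zip(stations, arrays), zip(stations[1:], arrays[1:])):
        if s1 == s2:
            continue
        if a1 == a2:
            edges.setdefault(a1, Counter())[(s1, s2)] += 1
        else:
            inter += 1
    nets = {}
    for arr in sorted(set(active) | set(visited)):
        act = active.get(arr, frozenset())
        vis = frozenset(visited.get(arr, set()))
        off = vis - act
        if off:
            warnings.warn(
                f"{owner}: detections at non-active station(s) {sorted(off)} "
                f"on array {arr}",
                stacklevel=2,
            )
        e = edges.get(arr, Counter())
        nets[arr] = MovementNetwork(
            owner=owner,
            array=arr,
            nodes=act,
            edges=e,
            visited=vis,
            n_movements=sum(e.values()),
            inter_array_movements=inter,
            off_active_visits=frozenset(off),
        )
    return nets


def build_network(
    detections: pd.DataFrame,
    owner: str,
    active: frozenset,
    array: str = "array",
) -> MovementNetwork:
    """Single-array convenience wrapper around :func:`build_networks`."""
    station_arrays = pd.Series(
        {s: array for s in set(detections["station_id"]) | set(active)}
    )
    return build_networks(detections, owner, {array: active}, station_arrays)[array]


def to_graph(network: MovementNetwork) -> nx.DiGraph:
    """Unweighted-shortest-path view of the network (weights kept as attrs)."""
    g = nx.DiGraph()
    g.add_nodes_from(sorted(network.nodes | network.visited))
    for (s, d), w in sorted(network.edges.items()):
        g.add_edge(s, d, weight=w)
    return g


def write_graphml(network: MovementNetwork, path) -> None:
    """Export a movement network (edge weights as attributes) to GraphML."""
    g = to_graph(network)
    g.graph["owner"] = str(network.owner)
    g.graph["array"] = str(network.array)
    nx.write_graphml(g, path)


def node_metrics(
    network: MovementNetwork,
    detection_days: pd.DataFrame | None = None,
    runs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Connectivity and betweenness per station, joined with residency.

    Connectivity is the number of distinct stations linked by at least
    one edge in either direction (each neighbour counted once).
    Betweenness is raw (unnormalised) shortest-path counting on the
    unweighted directed graph, with fractional credit for tied shortest
    paths.
    """
    g = to_graph(network)
    btw = nx.betweenness_centrality(g, normalized=False)
    rows = []
    for node in g.nodes:
        neigh = (set(g.successors(node)) | set(g.predecessors(node))) - {node}
        rows.append(
            {
                "station_id": node,
                "connectivity": len(neigh),
                "betweenness": btw[node],
            }
        )
    out = pd.DataFrame(rows).sort_values("station_id").reset_index(drop=True)
    if detection_days is not None:
        occ = (
            detection_days.groupby("station_id")
            .size()
            .rename("occupancy_days")
            .reset_index()
        )
        out = out.merge(occ, on="station_id", how="left").fillna(
            {"occupancy_days": 0}
        )
    if runs is not None and len(runs):
        sr = (
            runs.groupby("station_id")["length_days"]
            .mean()
            .rename("station_residency_days")
            .reset_index()
        )
        out = out.merge(sr, on="station_id", how="left").fillna(
            {"station_residency_days": 0.0}
        )
    return out


def motility(network: MovementNetwork, directed: bool = True) -> dict:
    """Node and edge density of one shark's network on one array.

    node_density = |visited stations| / |active stations|;
    edge_density = |distinct traversed station pairs| / n(n-1) with n
    active stations (ordered pairs under the directed convention, or
    n(n-1)/2 unordered pairs with ``directed=False``).  With fewer than
    two active stations edge density is undefined and reported as 0 with
    ``edge_density_defined=False``.
    """
    n_active = len(network.nodes)
    if n_active < 1:
        raise ValueError("motility needs at least one active station")
    node_density = len(network.visited) / n_active
    if directed:
        pairs = set(network.edges)
        denom = n_active * (n_active - 1)
    else:
        pairs = {frozenset(e) for e in network.edges}
        denom = n_active * (n_active - 1) // 2
    defined = denom > 0
    edge_density = len(pairs) / denom if defined else 0.0
    return {
        "owner": network.owner,
        "array": network.array,
        "n_active_stations": n_active,
        "node_density": node_density,
        "edge_density": edge_density,
        "edge_density_defined": defined,
        "n_movements": network.n_movements,
        "n_distinct_pairs": len(pairs),
    }


def random_network_null(
    n_nodes: int,
    n_edges: int,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    metric: str = "betweenness",
) -> np.ndarray:
    """Per-node metric samples from G(n, m) directed random graphs.

    Returns an array of shape ``(reps, n_nodes)``; node labels in a
    G(n, m) draw are exchangeable, so the null mean is the grand mean.
    """
    if not 0 <= n_edges <= n_nodes * (n_nodes - 1):
        raise ValueError("n_edges outside [0, n(n-1)] for a simple directed graph")
    if reps < 100:
        raise ValueError("use at least 100 null replicates")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.empty((reps, n_nodes))
    for k in range(reps):
        g = nx.gnm_random_graph(
            n_nodes, n_edges, seed=int(rng.integers(2**31)), directed=True
        )
        if metric == "betweenness":
            vals = nx.betweenness_centrality(g, normalized=False)
        elif metric == "connectivity":
            und = g.to_undirected()
            vals = {n: und.degree(n) for n in g.nodes}
        else:
            raise ValueError(f"unknown metric {metric!r}")
        out[k] = [vals[n] for n in range(n_nodes)]
    return out


def compare_to_null(observed, null: np.ndarray) -> WilcoxonResult:
    """Wilcoxon signed-rank of observed per-node values vs the null mean."""
    return wilcoxon_signed_rank(np.asarray(observed, float), mu=float(null.mean()))


def group_network(
    members: list[MovementNetwork], label: str
) -> MovementNetwork:
    """Pool member networks (e.g. one life stage) on one array.

    Edge counts are summed over members and the node set is the union
    of member active sets; members must share an array label.
    """
    if not members:
        raise ValueError("group_network needs at least one member network")
    arrays = {m.array for m in members}
    if len(arrays) > 1:
        raise ValueError(f"members span several arrays: {sorted(arrays)}")
    edges: Counter = Counter()
    for m in members:
        edges.update(m.edges)
    return MovementNetwork(
        owner=label,
        array=members[0].array,
        nodes=frozenset().union(*(m.nodes for m in members)),
        edges=edges,
        visited=frozenset().union(*(m.visited for m in members)),
        n_movements=sum(edges.values()),
        inter_array_movements=sum(m.inter_array_movements for m in members),
    )


def count_movers(motility_records: pd.DataFrame) -> dict:
    """Count sharks with >= 1 movement, per array and overall.

    A shark moving in several arrays is counted once in the total
    (overall = union of per-array mover sets).
    """
    col = "shark_id" if "shark_id" in motility_records.columns else "owner"
    moved = motility_records[motility_records["n_movements"] > 0]
    per_array = {
        a: int(n) for a, n in moved.groupby("array")[col].nunique().items()
    }
    return {"per_array": per_array, "total": int(moved[col].nunique())}
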