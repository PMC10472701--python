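"""The nine egocentric sociometric variables, computed per student.

Conventions (each resolves an ambiguity in how egocentric friendship metrics
are usually reported; all surface in the pipeline manifest):

* The "friend set" for reciprocity, homophily and friends' AP is the set of
  OUT-neighbors -- the classmates the ego nominated -- because all three are
  phrased from the nominator's viewpoint. A mutual-only variant is available.
* Homophily is the *negated* mean absolute AP difference between ego and
  each nominated friend, so that larger values mean greater similarity.
  The raw (positive) mean absolute difference is exposed alongside.
* Network size counts classmates tied to the ego in either direction;
  density is that count as a percentage of all possible classmates
  (roster - 1).
* Cluster of friends counts triangles containing the ego on the symmetrized
  graph (any-direction ties); a directed transitive-triad variant is
  available behind ``triangle_variant="directed"``.
* Centrality is unnormalized directed betweenness with fractional credit
  across tied geodesics (the Freeman/Brandes convention, UCINET's default).

Ratio metrics are missing (NaN) for egos with an empty friend set; count
metrics are zero for isolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .records import ClassroomGraph

METRIC_COLUMNS = [
    "social_activity",
    "popularity",
    "reciprocity",
    "homophily",
    "friends_ap",
    "network_size",
    "network_density",
    "cluster_of_friends",
    "centrality",
]

FRIEND_SETS = ("out", "mutual")
TRIANGLE_VARIANTS = ("symmetrized", "directed")


@dataclass(frozen=True)
class MetricConventions:
    friend_set: str = "out"
    triangle_variant: str = "symmetrized"

    def validate(self) -> None:
        if self.friend_set not in FRIEND_SETS:
            raise ValueError(f"friend_set must be one of {FRIEND_SETS}")
        if self.triangle_variant not in TRIANGLE_VARIANTS:
            raise ValueError(f"triangle_variant must be one of {TRIANGLE_VARIANTS}")


def _check_ego(graph: ClassroomGraph, ego: str) -> None:
    if ego not in graph.graph:
        raise KeyError(f"{ego!r} is not on the roster of classroom {graph.classroom_id}")


def _friends(graph: ClassroomGraph, ego: str, friend_set: str = "out") -> set[str]:
    out = set(graph.graph.successors(ego))
    if friend_set == "out":
        return out
    return out & set(graph.graph.predecessors(ego))


def social_activity(graph: ClassroomGraph, ego: str) -> int:
    """Number of nominations made (out-degree)."""
    _check_ego(graph, ego)
    return graph.graph.out_degree(ego)


def popularity(graph: ClassroomGraph, ego: str) -> int:
    """Number of nominations received (in-degree)."""
    _check_ego(graph, ego)
    return graph.graph.in_degree(ego)


def reciprocity(graph: ClassroomGraph, ego: str, friend_set: str = "out") -> float:
    """Proportion of ego's nominations that the alter returned; NaN if none made."""
    _check_ego(graph, ego)
    friends = _friends(graph, ego, friend_set)
    if not friends:
        return math.nan
    returned = sum(1 for f in friends if graph.graph.has_edge(f, ego))
    return returned / len(friends)


def homophily(
    graph: ClassroomGraph, ego: str, friend_set: str = "out", signed: bool = True
) -> float:
    """Academic similarity to nominated friends.

    The statistic is the mean absolute AP difference between ego and each
    friend, negated by default so higher = more similar. Friends with missing
    AP are excluded; NaN when no usable friend remains (or ego's own AP is
    missing).
    """
    _check_ego(graph, ego)
    ego_ap = graph.ap(ego)
    if math.isnan(ego_ap):
        return math.nan
    diffs = [
        abs(ego_ap - graph.ap(f))
        for f in _friends(graph, ego, friend_set)
        if not math.isnan(graph.ap(f))
    ]
    if not diffs:
        return math.nan
    raw = sum(diffs) / len(diffs)
    return -raw if signed else raw


def friends_ap(graph: ClassroomGraph, ego: str, friend_set: str = "out") -> float:
    """Mean AP over nominated friends; NaN when the friend set is empty."""
    _check_ego(graph, ego)
    aps = [
        graph.ap(f)
        for f in _friends(graph, ego, friend_set)
        if not math.isnan(graph.ap(f))
    ]
    return sum(aps) / len(aps) if aps else math.nan


def network_size(graph: ClassroomGraph, ego: str) -> int:
    """Number of classmates tied to ego in either direction (set semantics)."""
    _check_ego(graph, ego)
    return len(set(graph.graph.successors(ego)) | set(graph.graph.predecessors(ego)))


def network_density(graph: ClassroomGraph, ego: str) -> float:
    """Network size as a percentage of the ego's potential ties (roster - 1)."""
    _check_ego(graph, ego)
    if graph.n < 2:
        raise ValueError("network_density needs a roster of at least 2")
    return 100.0 * network_size(graph, ego) / (graph.n - 1)


def cluster_of_friends(
    graph: ClassroomGraph, ego: str, triangle_variant: str = "symmetrized"
) -> int:
    """Number of friendship triangles the ego belongs to.

    ``symmetrized`` counts unordered classmate pairs {a, b} where all three
    dyads carry a tie in at least one direction. ``directed`` counts ordered
    distinct triples (i, j, k) containing the ego whose edges i->j, j->k,
    i->k are all present (transitive directed triads).
    """
    _check_ego(graph, ego)
    if triangle_variant == "symmetrized":
        und = graph.graph.to_undirected()
        return nx.triangles(und, ego)
    if triangle_variant == "directed":
        return _directed_triads(graph)[ego]
    raise ValueError(f"triangle_variant must be one of {TRIANGLE_VARIANTS}")


def _directed_triads(graph: ClassroomGraph) -> dict[str, int]:
    """Transitive directed triad membership counts for every ego."""
    g = graph.graph
    counts = dict.fromkeys(g.nodes, 0)
    for i in g.nodes:
        succ_i = set(g.successors(i))
        for j in succ_i:
            # edges i->j and j->k and i->k
            for k in set(g.successors(j)) & succ_i:
                for member in (i, j, k):
                    counts[member] += 1
    return counts


def centrality(graph: ClassroomGraph, ego: str) -> float:
    """Unnormalized directed betweenness of the ego in the classroom digraph."""
    _check_ego(graph, ego)
    return betweenness_all(graph)[ego]


def betweenness_all(graph: ClassroomGraph) -> dict[str, float]:
    return nx.betweenness_centrality(graph.graph, normalized=False)


def compute_all(
    graph: ClassroomGraph, conventions: MetricConventions = MetricConventions()
) -> pd.DataFrame:
    """All nine metrics for every roster member of one classroom.

    Returns one row per student with the nine metric columns plus
    ``homophily_raw`` (the un-negated mean absolute AP difference).
    Deterministic given the graph.
    """
    conventions.validate()
    graph.validate()
    bc = betweenness_all(graph)
    if conventions.triangle_variant == "directed":
        tri = _directed_triads(graph)
    else:
        tri = nx.triangles(graph.graph.to_undirected())
    rows = []
    for ego in graph.roster:
        rows.append(
            {
                "student_id": ego,
                "classroom_id": graph.classroom_id,
                "social_activity": social_activity(graph, ego),
                "popularity": popularity(graph, ego),
                "reciprocity": reciprocity(graph, ego, conventions.friend_set),
                "homophily": homophily(graph, ego, conventions.friend_set),
                "homophily_raw": homophily(
                    graph, ego, conventions.friend_set, signed=False
                ),
                "friends_ap": friends_ap(graph, ego, conventions.friend_set),
                "network_size": network_size(graph, ego),
                "network_density": network_density(graph, ego),
                "cluster_of_friends": tri[ego],
                "centrality": bc[ego],
            }
        )
    return pd.DataFrame(rows)


def compute_cohort_metrics(
    graphs: list[ClassroomGraph], conventions: MetricConventions = MetricConventions()
) -> pd.DataFrame:
    frames = [compute_all(g, conventions) for g in graphs]
    return pd.concat(frames, ignore_index=True)


def write_metrics_csv(metrics: pd.DataFrame, path) -> None:
    """Write metrics with exactly the documented columns; missing as empty."""
    cols = ["student_id", "classroom_id"] + METRIC_COLUMNS
    metrics[cols].to_csv(path, index=False)
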