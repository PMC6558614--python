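"""Node centralities and threshold-based hub selection.

Conventions follow the Cytoscape NetworkAnalyzer defaults, under which the
published thresholds (e.g. betweenness >= 0.01251, closeness >= 0.4547)
live in [0, 1]:

* degree — number of incident edges;
* betweenness — Brandes accumulation over all shortest paths, normalized
  by (n-1)(n-2)/2 for an undirected graph;
* closeness — computed within each connected component and scaled by the
  Wasserman–Faust factor (reachable-1)/(n-1).

Shortest paths are unweighted throughout: PPI confidence scores act only
as a pre-filter, never as distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx
import pandas as pd

from netpharm.model import Network, ValidationError

Threshold = Union[float, str, None]  # a number, "mean", or absent


def centralities(net: Network) -> pd.DataFrame:
    """Per-node degree, normalized betweenness and closeness.

    Returns
    -------
    DataFrame indexed by node with columns ``role``, ``degree``,
    ``betweenness``, ``closeness``.
    """
    if net.n_nodes == 0:
        raise ValidationError("cannot compute centralities of an empty network")
    g = net.graph
    bet = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=True)
    nodes = sorted(g.nodes)
    return pd.DataFrame(
        {
            "role": [net.role(n) for n in nodes],
            "degree": [g.degree(n) for n in nodes],
            "betweenness": [bet[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def mean_of(values) -> float:
    """Arithmetic mean of a non-empty metric selection.

    Reported values are conventionally rounded to 2 decimals; comparisons
    inside the pipeline always use the unrounded mean.
    """
    values = pd.Series(list(values), dtype=float)
    if values.empty:
        raise ValidationError("mean of an empty selection")
    return float(values.mean())


@dataclass
class HubCriteria:
    """Inclusive (>=) thresholds for hub selection.

    Each threshold may be a number, the string ``"mean"`` (resolved to the
    arithmetic mean of that metric over the role-filtered nodes), or
    ``None`` (criterion absent).  ``role_filter`` restricts both the
    candidate set and the mean resolution.
    """

    degree_min: Threshold = "mean"
    betweenness_min: Threshold = None
    closeness_min: Threshold = None
    role_filter: str = "any"

    def __post_init__(self):
        if self.degree_min is None and self.betweenness_min is None and self.closeness_min is None:
            raise ValidationError("at least one hub criterion must be present")


def resolve_thresholds(table: pd.DataFrame, criteria: HubCriteria) -> dict:
    """Resolve "mean" thresholds against the role-filtered table."""
    sub = table if criteria.role_filter == "any" else table[table["role"] == criteria.role_filter]
    if sub.empty:
        raise ValidationError(f"no nodes with role {criteria.role_filter!r}")
    resolved = {}
    for metric, threshold in (
        ("degree", criteria.degree_min),
        ("betweenness", criteria.betweenness_min),
        ("closeness", criteria.closeness_min),
    ):
        if threshold is None:
            continue
        resolved[metric] = mean_of(sub[metric]) if threshold == "mean" else float(threshold)
    return resolved


def select_hubs(table: pd.DataFrame, criteria: HubCriteria) -> list:
    """Nodes meeting ALL present criteria, sorted by degree descending
    with lexicographic tie-break."""
    sub = table if criteria.role_filter == "any" else table[table["role"] == criteria.role_filter]
    if sub.empty:
        raise ValidationError(f"no nodes with role {criteria.role_filter!r}")
    resolved = resolve_thresholds(table, criteria)
    mask = pd.Series(True, index=sub.index)
    for metric, threshold in resolved.items():
        mask &= sub[metric] >= threshold
    hubs = sub[mask]
    order = hubs.sort_values("degree", ascending=False, kind="stable")
    # stable sort on descending degree, then node id among ties
    return sorted(order.index, key=lambda n: (-table.loc[n, "degree"], n))
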