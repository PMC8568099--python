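"""Emergent information-diffusion networks from exchange events.

Nodes are agents; each individual giver->receiver exchange event is a
directed multi-edge carrying (hour, place, resource). Networks are kept as
light edge-array containers (a full run can produce millions of edges);
:meth:`DiffusionNetwork.to_networkx` exports a ``networkx.MultiDiGraph``
for external analysis or GraphML serialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiffusionNetwork",
    "NetworkSummary",
    "build_network",
    "degree_distribution",
    "stratify",
    "write_graphml",
    "write_edge_list",
]


@dataclass
class DiffusionNetwork:
    """Directed multigraph of exchange events in a half-open hour window."""

    edges: pd.DataFrame  # hour, giver, receiver, place_id, resource_id
    window: tuple[int, int]

    @property
    def nodes(self) -> np.ndarray:
        """Agents appearing in at least one event (isolates excluded)."""
        if not len(self.edges):
            return np.empty(0, dtype=np.int64)
        return np.unique(
            np.concatenate([self.edges["giver"].to_numpy(), self.edges["receiver"].to_numpy()])
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_degrees(self) -> pd.Series:
        """in+out degree per node (repeat exchanges count separately)."""
        both = np.concatenate(
            [self.edges["giver"].to_numpy(), self.edges["receiver"].to_numpy()]
        )
        if not len(both):
            return pd.Series(dtype=np.int64, name="degree").rename_axis("agent_id")
        ids, counts = np.unique(both, return_counts=True)
        return pd.Series(counts, index=pd.Index(ids, name="agent_id"), name="degree")

    def summary(self) -> "NetworkSummary":
        deg = self.total_degrees()
        n_nodes = len(deg)
        comp = 0
        if n_nodes:
            from scipy.sparse import coo_matrix
            from scipy.sparse.csgraph import connected_components

            ids = deg.index.to_numpy()
            remap = {a: i for i, a in enumerate(ids)}
            g = self.edges["giver"].map(remap).to_numpy()
            r = self.edges["receiver"].map(remap).to_numpy()
            adj = coo_matrix((np.ones(len(g)), (g, r)), shape=(n_nodes, n_nodes))
            comp = int(connected_components(adj, directed=True, connection="weak")[0])
        return NetworkSummary(
            n_nodes=n_nodes,
            n_edges=self.n_edges,
            max_degree=int(deg.max()) if n_nodes else 0,
            mean_degree=float(deg.mean()) if n_nodes else 0.0,
            n_weak_components=comp,
        )

    def to_networkx(self, simple: bool = False):
        """Export as a networkx MultiDiGraph (or collapsed DiGraph with an
        edge ``weight`` counting repeat exchanges if ``simple``)."""
        import networkx as nx

        if simple:
            g = nx.DiGraph()
            pairs = self.edges.groupby(["giver", "receiver"]).size()
            g.add_weighted_edges_from(
                (int(a), int(b), int(w)) for (a, b), w in pairs.items()
            )
            return g
        g = nx.MultiDiGraph()
        for e in self.edges.itertuples(index=False):
            g.add_edge(int(e.giver), int(e.receiver), hour=int(e.hour),
                       place_id=int(e.place_id), resource_id=int(e.resource_id))
        return g


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    max_degree: int
    mean_degree: float
    n_weak_components: int


def build_network(events: pd.DataFrame, window: tuple[int, int]) -> DiffusionNetwork:
    """One edge per exchange event with window[0] <= hour < window[1]."""
    h0, h1 = window
    if h1 <= h0:
        raise ValueError(f"inverted or empty hour window {window}")
    cols = ["hour", "giver", "receiver", "place_id", "resource_id"]
    if not len(events):
        return DiffusionNetwork(edges=pd.DataFrame(columns=cols), window=(h0, h1))
    hours = events["hour"].to_numpy()
    sel = events.loc[(hours >= h0) & (hours < h1), cols].reset_index(drop=True)
    return DiffusionNetwork(edges=sel, window=(h0, h1))


def degree_distribution(net: DiffusionNetwork) -> pd.DataFrame:
    """Table degree -> node count (total = in + out degree)."""
    deg = net.total_degrees()
    if not len(deg):
        return pd.DataFrame({"degree": pd.Series(dtype=np.int64),
                             "n_nodes": pd.Series(dtype=np.int64)})
    vals, counts = np.unique(deg.to_numpy(), return_counts=True)
    return pd.DataFrame({"degree": vals, "n_nodes": counts})


def stratify(net: DiffusionNetwork, agents: pd.DataFrame, attribute: str,
              induced: bool = False):
    """Attach a node attribute (e.g. age band) and optionally split.

    Returns (node_table, cross_tab) where cross_tab counts edges by
    (giver stratum, receiver stratum); with ``induced`` also returns a dict
    stratum -> induced DiffusionNetwork of within-stratum edges.
    """
    if attribute == "age_band" and "age_band" not in agents.columns:
        from .world import age_band

        agents = agents.assign(age_band=age_band(agents["age"].to_numpy()))
    if attribute not in agents.columns:
        raise ValueError(f"unknown agent attribute {attribute!r}")
    attr = agents.set_index("agent_id")[attribute]
    nodes = net.nodes
    missing = set(nodes) - set(attr.index)
    if missing:
        raise ValueError(f"attribute unresolvable for nodes {sorted(missing)[:5]}...")
    node_table = pd.DataFrame({"agent_id": nodes, attribute: attr.loc[nodes].to_numpy()})
    e = net.edges
    if len(e):
        gs = attr.loc[e["giver"]].to_numpy()
        rs = attr.loc[e["receiver"]].to_numpy()
        cross = pd.crosstab(pd.Series(gs, name="giver_stratum"),
                            pd.Series(rs, name="receiver_stratum"))
    else:
        gs = rs = np.array([])
        cross = pd.DataFrame()
    if not induced:
        return node_table, cross
    subs = {}
    for s in node_table[attribute].unique():
        mask = (gs == s) & (rs == s) if len(e) else np.array([], dtype=bool)
        subs[s] = DiffusionNetwork(edges=e.loc[mask].reset_index(drop=True),
                                   window=net.window)
    return node_table, cross, subs


def write_edge_list(net: DiffusionNetwork, path) -> None:
    net.edges.to_csv(path, index=False)


def write_graphml(net: DiffusionNetwork, path, agents: pd.DataFrame | None = None) -> None:
    """GraphML export with optional node age-band attributes."""
    import networkx as nx

    g = net.to_networkx()
    if agents is not None and len(g):
        from .world import age_band

        bands = dict(zip(agents["agent_id"], age_band(agents["age"].to_numpy())))
        nx.set_node_attributes(g, {a: str(bands.get(a, "")) for a in g.nodes}, "age_band")
    nx.write_graphml(g, path)
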