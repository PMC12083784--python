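"""Patient-sharing prescriber networks.

Nodes are physicians (every physician with at least one prescription in the
year, isolates included), with a ``client_load`` attribute counting their
distinct clients. An edge joins two physicians who prescribed to at least
one common client; its integer ``weight`` is the number of distinct shared
clients (or, for the shared-episode variant, distinct clients with at least
one treatment episode in which both physicians dispensed).

Tie definitions thin the base network:

* absolute threshold k — drop edges with fewer than k shared clients;
* relative threshold p — each physician ranks its incident edges by weight
  (descending, equal weights broken by lexicographic neighbour ID) and
  marks the top ``ceil(p/100 * degree)``; an edge survives only if marked
  by BOTH endpoints;
* shared episode — reweight by shared-episode clients instead.

Thresholding never removes nodes, so every prescribing physician keeps
participating in pair-level evaluation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .episodes import label_episodes

log = logging.getLogger(__name__)


def _pair_weights(incidence: pd.DataFrame) -> pd.DataFrame:
    """Distinct-client counts per unordered physician pair from a distinct
    (client_id, physician_id) incidence table."""
    merged = incidence.merge(incidence, on="client_id")
    merged = merged[merged["physician_id_x"] < merged["physician_id_y"]]
    return (
        merged.groupby(["physician_id_x", "physician_id_y"], observed=True)
        .size()
        .reset_index(name="weight")
    )


def _base_graph(incidence: pd.DataFrame, year: int | None) -> nx.Graph:
    G = nx.Graph(year=year)
    loads = incidence.groupby("physician_id", observed=True)["client_id"].nunique()
    for p, load in loads.items():
        G.add_node(str(p), client_load=int(load))
    for row in _pair_weights(incidence).itertuples(index=False):
        G.add_edge(str(row.physician_id_x), str(row.physician_id_y), weight=int(row.weight))
    return G


def build_shared_client_network(records: pd.DataFrame, year: int | None = None) -> nx.Graph:
    """Weighted shared-client network from one calendar year of records.

    The ``clinic_id`` column is never read here: the network sees only
    clients, physicians and dates.
    """
    if records.empty:
        log.warning("building network from empty record set")
        return nx.Graph(year=year)
    inc = records[["client_id", "physician_id"]].astype(str).drop_duplicates()
    if year is None:
        years = pd.to_datetime(records["dispense_date"]).dt.year.unique()
        year = int(years[0]) if len(years) == 1 else None
    return _base_graph(inc, year)


def build_shared_episode_network(
    records: pd.DataFrame, episodes: pd.DataFrame | None = None, year: int | None = None
) -> nx.Graph:
    """Network whose edge weights count clients sharing a treatment episode.

    Two physicians are tied through a client only if some single episode of
    that client contains dispensations from both. Node set and client loads
    are identical to the shared-client network on the same records.
    """
    if records.empty:
        log.warning("building episode network from empty record set")
        return nx.Graph(year=year)
    if episodes is not None and "physician_ids" in episodes.columns:
        inc = episodes[["client_id", "drug", "episode", "physician_ids"]].copy()
        inc["physician_ids"] = inc["physician_ids"].map(sorted)
        inc = inc.explode("physician_ids").rename(columns={"physician_ids": "physician_id"})
    else:
        lab = label_episodes(records)
        inc = lab[["client_id", "drug", "episode", "physician_id"]]
    inc = inc.astype(str).drop_duplicates()
    merged = inc.merge(inc, on=["client_id", "drug", "episode"])
    merged = merged[merged["physician_id_x"] < merged["physician_id_y"]]
    pair_clients = merged[["client_id", "physician_id_x", "physician_id_y"]].drop_duplicates()
    weights = (
        pair_clients.groupby(["physician_id_x", "physician_id_y"], observed=True)
        .size()
        .reset_index(name="weight")
    )
    inc_all = records[["client_id", "physician_id"]].astype(str).drop_duplicates()
    G = nx.Graph(year=year)
    loads = inc_all.groupby("physician_id", observed=True)["client_id"].nunique()
    for p, load in loads.items():
        G.add_node(str(p), client_load=int(load))
    for row in weights.itertuples(index=False):
        G.add_edge(row.physician_id_x, row.physician_id_y, weight=int(row.weight))
    return G


def apply_absolute_threshold(network: nx.Graph, k: int) -> nx.Graph:
    """Drop edges with weight < k; nodes (and their attributes) are kept."""
    if k < 1:
        raise ValueError(f"absolute threshold k must be >= 1, got {k}")
    G = network.copy()
    G.remove_edges_from([(u, v) for u, v, w in G.edges(data="weight") if w < k])
    return G


def apply_relative_threshold(network: nx.Graph, p: float) -> nx.Graph:
    """Keep an edge only if it ranks in the top p% of BOTH endpoints' ties.

    Each physician ranks incident edges by weight descending (equal weights
    broken by lexicographic neighbour ID) and marks the top
    ``ceil(p/100 * degree)``. Deterministic and order-invariant.
    """
    if not (0 < p <= 100):
        raise ValueError(f"relative threshold p must lie in (0, 100], got {p}")
    marked: set[tuple[str, str]] = set()
    for node in network.nodes:
        nbrs = sorted(
            network[node].items(), key=lambda kv: (-kv[1].get("weight", 1), kv[0])
        )
        top = math.ceil(p / 100.0 * len(nbrs))
        for nbr, _ in nbrs[:top]:
            marked.add((node, nbr))
    G = network.copy()
    G.remove_edges_from(
        [(u, v) for u, v in G.edges if (u, v) not in marked or (v, u) not in marked]
    )
    return G


@dataclass(frozen=True)
class TieDefinition:
    """One of the three tie-definition families: ``absolute`` (parameter k),
    ``relative`` (parameter p, percent), or ``shared_episode``."""

    variant: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.variant == "absolute":
            if self.parameter is None or self.parameter < 1 or self.parameter != int(self.parameter):
                raise ValueError(f"absolute tie definition needs integer k >= 1, got {self.parameter}")
        elif self.variant == "relative":
            if self.parameter is None or not (0 < self.parameter <= 100):
                raise ValueError(f"relative tie definition needs p in (0, 100], got {self.parameter}")
        elif self.variant == "shared_episode":
            if self.parameter is not None:
                raise ValueError("shared_episode tie definition takes no parameter")
        else:
            raise ValueError(f"unknown tie definition variant {self.variant!r}")

    @classmethod
    def parse(cls, text: str) -> "TieDefinition":
        """Parse e.g. ``absolute:5``, ``relative:80`` or ``shared_episode``."""
        if ":" in text:
            variant, param = text.split(":", 1)
            return cls(variant.strip(), float(param))
        return cls(text.strip())

    def __str__(self) -> str:
        if self.parameter is None:
            return self.variant
        return f"{self.variant}:{self.parameter:g}"

    def build(
        self,
        records: pd.DataFrame,
        base: nx.Graph | None = None,
        episodes: pd.DataFrame | None = None,
        year: int | None = None,
    ) -> nx.Graph:
        """Construct the thresholded network for one year of records.

        ``base`` (a prebuilt shared-client network) and ``episodes`` are
        optional caches used by the grid runner.
        """
        if self.variant == "shared_episode":
            return build_shared_episode_network(records, episodes, year=year)
        if base is None:
            base = build_shared_client_network(records, year=year)
        if self.variant == "absolute":
            return apply_absolute_threshold(base, int(self.parameter))
        return apply_relative_threshold(base, self.parameter)


def export_network(network: nx.Graph, edge_path, node_path) -> None:
    """Edge and node CSVs, with the log transforms used for figure support
    (edge thickness = log(shared clients + 1), vertex size =
    log(client load + 1))."""
    edges = pd.DataFrame(
        [
            (u, v, w, float(np.log(w + 1)))
            for u, v, w in sorted(network.edges(data="weight"))
        ],
        columns=["physician_a", "physician_b", "weight", "log_weight_plus_1"],
    )
    nodes = pd.DataFrame(
        [
            (n, d.get("client_load", 0), float(np.log(d.get("client_load", 0) + 1)))
            for n, d in sorted(network.nodes(data=True))
        ],
        columns=["physician_id", "client_load", "log_load_plus_1"],
    )
    edges.to_csv(edge_path, index=False)
    nodes.to_csv(node_path, index=False)
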