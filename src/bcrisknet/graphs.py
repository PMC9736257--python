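"""Per-profile affiliation graphs: woman nodes, characteristic nodes, and edges.

Construction rules: one node per woman, one node per characteristic carried by
at least one woman, an edge from each woman to every characteristic she
carries, and an edge between two characteristics whenever at least one woman
carries both.  The graph is simple, undirected and analyzed unweighted; the
number of women sharing each characteristic pair is kept as an optional
``weight`` attribute for auditing but ignored by default downstream.

Woman node ids are prefixed ``W:`` so they can never collide with
characteristic labels.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import networkx as nx
import pandas as pd

__all__ = [
    "WOMAN_PREFIX",
    "build_affiliation_graph",
    "woman_nodes",
    "characteristic_nodes",
    "export_graph",
    "load_graph",
]

WOMAN_PREFIX = "W:"


def woman_nodes(graph: nx.Graph) -> list:
    return [n for n, d in graph.nodes(data=True) if d.get("kind") == "woman"]


def characteristic_nodes(graph: nx.Graph) -> list:
    return [n for n, d in graph.nodes(data=True) if d.get("kind") == "characteristic"]


def build_affiliation_graph(assignments: pd.DataFrame, profile_id: int) -> nx.Graph:
    """Build the profile's affiliation graph from a long assignment frame.

    ``assignments`` needs columns ``id`` and ``label`` (the output of
    :meth:`bcrisknet.catalog.ProfileCategorizer.transform`); if a ``profile``
    column is present it must match ``profile_id``.  An empty frame yields an
    empty graph.  Duplicate (id, label) pairs collapse; the same label listed
    under two variables for one woman is a catalog error upstream.
    """
    G = nx.Graph(profile_id=profile_id)
    if len(assignments) == 0:
        return G
    if "profile" in assignments.columns:
        other = set(assignments["profile"].unique()) - {profile_id}
        if other:
            raise ValueError(
                f"assignments contain profiles {sorted(other)}, expected {profile_id}"
            )
    if "variable" in assignments.columns:
        dup = assignments.duplicated(subset=["id", "variable"])
        if dup.any():
            raise ValueError("duplicate (woman, variable) assignment rows")

    per_woman = assignments.groupby("id", sort=True)["label"].apply(
        lambda s: sorted(set(s))
    )
    labels_seen = sorted(set(assignments["label"]))
    for w in per_woman.index:
        G.add_node(WOMAN_PREFIX + str(w), kind="woman")
    for lab in labels_seen:
        G.add_node(lab, kind="characteristic")

    cooc: dict = {}
    for w, labs in per_woman.items():
        wn = WOMAN_PREFIX + str(w)
        for lab in labs:
            G.add_edge(wn, lab)
        for a, b in itertools.combinations(labs, 2):
            cooc[(a, b)] = cooc.get((a, b), 0) + 1
    for (a, b), count in cooc.items():
        G.add_edge(a, b, weight=count)
    return G


def export_graph(graph: nx.Graph, path, fmt: str = None) -> None:
    """Write GEXF or GraphML (Gephi-compatible); format inferred from suffix."""
    fmt = _resolve_format(path, fmt)
    if fmt == "gexf":
        nx.write_gexf(graph, path)
    else:
        nx.write_graphml(graph, path)


def load_graph(path, fmt: str = None) -> nx.Graph:
    fmt = _resolve_format(path, fmt)
    if fmt == "gexf":
        G = nx.read_gexf(path)
    else:
        G = nx.read_graphml(path)
    return G


def _resolve_format(path, fmt):
    if fmt is None:
        s = str(path).lower()
        if s.endswith(".gexf"):
            fmt = "gexf"
        elif s.endswith(".graphml"):
            fmt = "graphml"
        else:
            raise ValueError(f"cannot infer graph format from {path!r}")
    fmt = fmt.lower()
    if fmt not in ("gexf", "graphml"):
        raise ValueError(f"unknown graph format {fmt!r} (use 'gexf' or 'graphml')")
    return fmt
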