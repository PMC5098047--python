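"""PTM-type coincidence networks over mixed-type MAPs.

A MAP carrying two or more distinct PTM types is a coincident position;
every unordered pair of its types contributes one edge occurrence. The
relative edge count — edge count over the sum of the two endpoint node
occurrences — compares pairs without bias toward abundant types such as
phosphorylation. Edges are typical when the two types can chemically modify
the same residue, atypical otherwise; unusually frequent edges are flagged
by Tukey's upper fence within each class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .maps import MAP
from .types import DisorderTrack

# Residue chemistry each PTM type can target (one-letter codes); overridable.
DEFAULT_COMPATIBILITY: dict[str, frozenset[str]] = {
    "Phosphorylation": frozenset("STY"),
    "Ubiquitination": frozenset("K"),
    "Sumoylation": frozenset("K"),
    "Neddylation": frozenset("K"),
    "Acetylation": frozenset("K"),
    "Methylation": frozenset("KR"),
    "Citrullination": frozenset("R"),
    "N-linked Glycosylation": frozenset("N"),
    "O-linked Glycosylation": frozenset("ST"),
    "Hydroxylation": frozenset("PK"),
    "S-Nitrosylation": frozenset("C"),
    "Palmitoylation": frozenset("C"),
    "Prenylation": frozenset("C"),
    "Disulfide": frozenset("C"),
    "Myristoylation": frozenset("G"),
    "Succinylation": frozenset("K"),
}


@dataclass
class CoincidenceNetwork:
    """PTM-type nodes and pairwise coincidence edges from mixed-type MAPs."""

    graph: nx.Graph  # nodes: occurrence, percent; edges: count, relative, typical
    n_coincident_maps: int
    type_totals: dict[str, int]  # occurrences of each type over the full MAP set

    @property
    def nodes(self) -> dict[str, dict]:
        return {n: dict(d) for n, d in self.graph.nodes(data=True)}

    @property
    def edges(self) -> dict[tuple[str, str], dict]:
        return {tuple(sorted((a, b))): dict(d) for a, b, d in self.graph.edges(data=True)}


def build_coincidence_network(maps: list[MAP]) -> CoincidenceNetwork:
    """Tabulate type pairs over MAPs with >= 2 distinct PTM types.

    Node occurrence counts the coincident MAPs containing the type; the
    node percent is that count over the type's occurrences in the whole
    dataset. A MAP with k types contributes all C(k, 2) pairs.
    """
    type_totals: dict[str, int] = {}
    for m in maps:
        for t in m.ptm_types:
            type_totals[t] = type_totals.get(t, 0) + 1
    mixed = [m for m in maps if len(m.ptm_types) >= 2]
    if not mixed:
        warnings.warn("no mixed-type MAPs: coincidence network is empty")
    g = nx.Graph()
    for m in mixed:
        types = sorted(m.ptm_types)
        for t in types:
            if t in g:
                g.nodes[t]["occurrence"] += 1
            else:
                g.add_node(t, occurrence=1)
        for a, b in combinations(types, 2):
            if g.has_edge(a, b):
                g.edges[a, b]["count"] += 1
            else:
                g.add_edge(a, b, count=1)
    for t in g.nodes:
        g.nodes[t]["percent"] = 100.0 * g.nodes[t]["occurrence"] / type_totals[t]
    return CoincidenceNetwork(g, len(mixed), type_totals)


def relative_edge_count(network: CoincidenceNetwork, scale: float = 1.0) -> dict:
    """Edge count over the sum of endpoint occurrences, per edge.

    ``scale`` is a display-only multiplier (default 1); analysis uses the
    unscaled ratio.
    """
    g = network.graph
    out = {}
    for a, b, d in g.edges(data=True):
        value = d["count"] / (g.nodes[a]["occurrence"] + g.nodes[b]["occurrence"])
        d["relative"] = value * scale
        out[tuple(sorted((a, b)))] = value * scale
    return out


def classify_edges_typical(
    network: CoincidenceNetwork,
    compatibility: dict[str, frozenset[str]] | None = None,
) -> dict[tuple[str, str], bool]:
    """Typical iff the two types' modifiable-residue sets intersect."""
    table = DEFAULT_COMPATIBILITY if compatibility is None else compatibility
    missing = [t for t in network.graph.nodes if t not in table]
    if missing:
        raise KeyError(f"no residue-compatibility entry for types: {missing}")
    out = {}
    for a, b, d in network.graph.edges(data=True):
        typical = bool(table[a] & table[b])
        d["typical"] = typical
        out[tuple(sorted((a, b)))] = typical
    return out


def tukey_upper_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values above Q3 + 1.5·IQR (quartiles linearly interpolated)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("fewer than 4 values: outlier fence undefined")
        return np.zeros(len(values), dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return values > fence


def detect_outlier_edges(
    network: CoincidenceNetwork, by: str = "relative"
) -> dict[bool, list[tuple[str, str]]]:
    """Outlier edges per typical/atypical group by the Tukey upper fence."""
    groups: dict[bool, list[tuple[tuple[str, str], float]]] = {True: [], False: []}
    for a, b, d in network.graph.edges(data=True):
        groups[d["typical"]].append((tuple(sorted((a, b))), d[by]))
    out: dict[bool, list[tuple[str, str]]] = {}
    for typical, items in groups.items():
        if not items:
            out[typical] = []
            continue
        mask = tukey_upper_outliers(np.array([v for _, v in items]))
        out[typical] = [edge for (edge, _), flag in zip(items, mask) if flag]
    return out


def coincident_disorder_distribution(
    maps: list[MAP], disorder: dict[str, DisorderTrack]
) -> pd.DataFrame:
    """Disorder-tendency summary of modified residues per MAP type-count class.

    For each class (number of distinct PTM types >= 2) reports the member
    PTM residues' tendencies and the ordered fraction (tendency <= 0.5).
    Classes with no MAPs are omitted.
    """
    by_class: dict[int, list[float]] = {}
    for m in maps:
        k = len(m.ptm_types)
        if k < 2:
            continue
        for o in m.observations:
            track = disorder.get(o.uid)
            if track is not None:
                by_class.setdefault(k, []).append(track[o.native_position])
    rows = []
    for k in sorted(by_class):
        vals = np.array(by_class[k])
        rows.append(
            {
                "type_count": k,
                "n_residues": len(vals),
                "mean_tendency": float(vals.mean()),
                "ordered_fraction": float((vals <= 0.5).mean()),
            }
        )
    return pd.DataFrame(rows)


def export_network(network: CoincidenceNetwork, nodes_path, edges_path) -> None:
    """Write node/edge TSVs loadable by standard graph viewers."""
    node_rows = [
        {"id": t, "label": t, "occurrence": d["occurrence"], "percent": d["percent"]}
        for t, d in network.graph.nodes(data=True)
    ]
    edge_rows = [
        {
            "source": a,
            "target": b,
            "count": d["count"],
            "relative_edge_count": d.get("relative", np.nan),
            "typical": d.get("typical", ""),
        }
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    pd.DataFrame(edge_rows).to_csv(edges_path, sep="\t", index=False)
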