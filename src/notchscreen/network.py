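"""Annotation-class summaries and the physical-interaction subnetwork.

Hit lists are summarized per annotation class (GO class or cellular
localization): gene count, percentage of the list, median z-score, and the
standard-normal tail probability of that median — the tail probability
locates a class's typical score within the genome-wide z distribution
(e.g. a class median of −2.9 sits in the extreme 0.2% tail).

The interaction network is the subgraph of a physical-interaction table
induced on the screen hits plus the core pathway nodes (the receptor N,
Su(H) and the repressor complex H/CtBP/gro by default): an edge is kept
iff both endpoints are hits or core genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

#: default core pathway nodes: receptor, CSL factor, repressor complex
CORE_GENES = ("N", "Su(H)", "H", "CtBP", "gro")

GROUPINGS = ("localization", "go_class")


def normal_tail_percent(z: float) -> float:
    """Standard-normal tail probability of ``z`` as a percentage.

    100·Φ(z) for z < 0 and 100·(1−Φ(z)) for z ≥ 0 — i.e. how far into its
    own tail a z-score sits. Unrounded; round only for presentation.
    """
    z = float(z)
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return 100.0 * (stats.norm.cdf(z) if z < 0 else stats.norm.sf(z))


def summarize_classes(hits: pd.DataFrame, annotations: pd.DataFrame,
                      grouping: str = "localization") -> pd.DataFrame:
    """Summarize a hit list per annotation class.

    ``hits`` needs gene_id and z columns; genes without an annotation fall
    in "unknown". Returns count, percent of the list (one decimal),
    median z and its unrounded tail percent per class, plus a TOTAL row.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    if len(hits) == 0:
        raise ValueError("empty hit list")
    label_of = (
        annotations.drop_duplicates("gene_id").set_index("gene_id")[grouping]
    )
    df = hits[["gene_id", "z"]].copy()
    df["class_label"] = df["gene_id"].map(label_of).replace("", np.nan).fillna("unknown")
    total = len(df)
    rows = []
    for label, grp in df.groupby("class_label", sort=True):
        med = float(np.median(grp["z"]))
        rows.append(
            dict(
                class_label=label,
                count=len(grp),
                percent=round(100.0 * len(grp) / total, 1),
                median_z=med,
                tail_percent=normal_tail_percent(med),
            )
        )
    med_all = float(np.median(df["z"]))
    rows.append(
        dict(class_label="TOTAL", count=total, percent=100.0,
             median_z=med_all, tail_percent=normal_tail_percent(med_all))
    )
    return pd.DataFrame(rows)


def build_interaction_network(
    hit_genes: Iterable[str] | pd.DataFrame,
    interactions: pd.DataFrame,
    core_genes: Iterable[str] = CORE_GENES,
    keep_isolates: bool = False,
    hit_attributes: Mapping[str, Mapping] | pd.DataFrame | None = None,
) -> nx.Graph:
    """Induced physical-interaction subgraph over hits and core genes.

    An edge of the interaction table survives iff both endpoints are in
    hits ∪ core; self-loops are dropped; nodes left without any edge are
    dropped unless ``keep_isolates``. ``hit_genes`` may be a plain
    iterable of gene ids or an overlap table (gene_id/area/z_con/z_m3),
    whose columns become node attributes; node roles are CORE for core
    genes and HIT otherwise.
    """
    attrs: dict[str, dict] = {}
    if isinstance(hit_genes, pd.DataFrame):
        for rec in hit_genes.itertuples(index=False):
            d = rec._asdict()
            attrs[d.pop("gene_id")] = d
        hits = set(attrs)
    else:
        hits = set(hit_genes)
    if isinstance(hit_attributes, pd.DataFrame):
        for rec in hit_attributes.itertuples(index=False):
            d = rec._asdict()
            attrs.setdefault(d.pop("gene_id"), {}).update(d)
    elif hit_attributes:
        for g, d in hit_attributes.items():
            attrs.setdefault(g, {}).update(d)

    core = set(core_genes)
    keep = hits | core
    g = nx.Graph()
    for n in sorted(keep):
        g.add_node(n, role="CORE" if n in core else "HIT", **attrs.get(n, {}))
    if len(interactions):
        for rec in interactions.itertuples(index=False):
            a, b = rec.gene_a, rec.gene_b
            if a == b:
                continue
            if a in keep and b in keep:
                g.add_edge(a, b, source_tag=getattr(rec, "source_tag", ""))
    if not keep_isolates:
        g.remove_nodes_from([n for n, d in dict(g.degree()).items() if d == 0])
    return g


def network_stats(graph: nx.Graph) -> dict:
    """Node/edge counts and per-node degrees (deterministically ordered).

    Returns a dict with n_nodes, n_edges, a degree DataFrame sorted by
    descending degree then name, and the degrees of the core nodes.
    """
    deg = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    degree_table = pd.DataFrame(deg, columns=["gene_id", "degree"])
    core_deg = {
        n: d for n, d in deg if graph.nodes[n].get("role") == "CORE"
    }
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "degree_table": degree_table,
        "core_degrees": core_deg,
    }
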