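"""ceRNA triad screening and network assembly.

A candidate (lncRNA, miRNA, mRNA) triple is accepted when

1. the miRNA has predicted targeting links to both the lncRNA and the
   mRNA in the supplied interaction tables,
2. all three members are differentially expressed in the comparison,
3. Spearman(miRNA, lncRNA) <= -0.7 and Spearman(miRNA, mRNA) <= -0.7,
4. Pearson(lncRNA, mRNA) > 0.9 (strict), and
5. the overlap of the full miRNA sets targeting the lncRNA and the mRNA
   is hypergeometrically significant (p < 0.05) against the universe of
   all miRNAs appearing in either interaction table.

Accepted triads are collapsed into a typed, deduplicated graph whose only
edge classes are miRNA-lncRNA and miRNA-mRNA (the lncRNA-mRNA coupling is
indirect, so no such edge is drawn).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import Thresholds
from .enrich import hypergeom_upper_tail
from .errors import AlignmentError, ParameterError
from .targets import pearson, spearman

TRIAD_COLUMNS = [
    "lncrna_id", "mirna_id", "mrna_id",
    "scc_lnc_mirna", "scc_mrna_mirna", "pcc_lnc_mrna",
    "shared_mirna_count", "hypergeom_p",
]

EDGE_MIRNA_LNCRNA = "miRNA-lncRNA"
EDGE_MIRNA_MRNA = "miRNA-mRNA"


def shared_mirna_pvalue(
    lnc_mirna_set: Iterable[str],
    mrna_mirna_set: Iterable[str],
    mirna_universe: Iterable[str],
) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p for two miRNA sets."""
    universe = set(mirna_universe)
    if not universe:
        raise ParameterError("empty miRNA universe")
    a = set(lnc_mirna_set)
    b = set(mrna_mirna_set)
    if not a <= universe or not b <= universe:
        raise ParameterError("miRNA sets must be subsets of the universe")
    k = len(a & b)
    p = hypergeom_upper_tail(len(universe), len(a), len(b), k)
    return k, p


def screen_ok(
    scc_lnc_mirna: float,
    scc_mrna_mirna: float,
    pcc_lnc_mrna: float,
    hypergeom_p: float,
    thresholds: Thresholds | None = None,
) -> bool:
    """The triad acceptance predicate on already-computed statistics."""
    thr = thresholds or Thresholds()
    return (
        scc_lnc_mirna <= thr.scc_max
        and scc_mrna_mirna <= thr.scc_max
        and pcc_lnc_mrna > thr.pcc_min
        and hypergeom_p < thr.hypergeom_p
    )


def build_triads(
    de_lncrnas: Iterable[str],
    de_mirnas: Iterable[str],
    de_mrnas: Iterable[str],
    mirna_lncrna: pd.DataFrame,
    mirna_mrna: pd.DataFrame,
    lncrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Screen every candidate triple and return the accepted triads.

    Interaction tables have columns ``mirna_id`` and ``target_id``.
    Expression matrices (features x samples, all sharing the same sample
    columns) should be on the scale correlations are meant on — the
    pipeline passes log1p library-size-normalized counts.  Every recorded
    statistic is recomputed exactly by :func:`ceranet.targets.pearson` /
    :func:`ceranet.targets.spearman` on the same matrices.
    """
    thr = thresholds or Thresholds()
    de_lnc = sorted(set(de_lncrnas))
    de_mir = set(de_mirnas)
    de_mrna = sorted(set(de_mrnas))
    for ids, expr, what in (
        (de_lnc, lncrna_expr, "lncRNA"),
        (de_mir, mirna_expr, "miRNA"),
        (de_mrna, mrna_expr, "mRNA"),
    ):
        missing = [i for i in ids if i not in expr.index]
        if missing:
            raise AlignmentError(
                f"DE {what}s missing from expression matrix: {missing[:5]}"
            )
    if not (
        list(lncrna_expr.columns) == list(mirna_expr.columns) == list(mrna_expr.columns)
    ):
        raise AlignmentError("expression matrices must share sample columns")

    lnc_sets = {
        lnc: frozenset(grp["mirna_id"])
        for lnc, grp in mirna_lncrna.groupby("target_id", sort=False)
    }
    mrna_sets = {
        mr: frozenset(grp["mirna_id"])
        for mr, grp in mirna_mrna.groupby("target_id", sort=False)
    }
    universe = set(mirna_lncrna["mirna_id"]) | set(mirna_mrna["mirna_id"])

    scc_cache: dict[tuple[str, str], float] = {}

    def scc(mir: str, fid: str, expr: pd.DataFrame) -> float:
        key = (mir, fid)
        if key not in scc_cache:
            rho, _ = spearman(
                mirna_expr.loc[mir].to_numpy(), expr.loc[fid].to_numpy()
            )
            scc_cache[key] = rho
        return scc_cache[key]

    rows = []
    for lnc in de_lnc:
        lnc_set = lnc_sets.get(lnc)
        if not lnc_set:
            continue
        lnc_vec = lncrna_expr.loc[lnc].to_numpy()
        for mr in de_mrna:
            mr_set = mrna_sets.get(mr)
            if not mr_set:
                continue
            shared_de = sorted(lnc_set & mr_set & de_mir)
            if not shared_de:
                continue
            k, hyp_p = shared_mirna_pvalue(lnc_set, mr_set, universe)
            if hyp_p >= thr.hypergeom_p:
                continue
            pcc, _ = pearson(lnc_vec, mrna_expr.loc[mr].to_numpy())
            if pcc <= thr.pcc_min:
                continue
            for mir in shared_de:
                s1 = scc(mir, lnc, lncrna_expr)
                s2 = scc(mir, mr, mrna_expr)
                if screen_ok(s1, s2, pcc, hyp_p, thr):
                    rows.append(
                        {
                            "lncrna_id": lnc,
                            "mirna_id": mir,
                            "mrna_id": mr,
                            "scc_lnc_mirna": s1,
                            "scc_mrna_mirna": s2,
                            "pcc_lnc_mrna": pcc,
                            "shared_mirna_count": k,
                            "hypergeom_p": hyp_p,
                        }
                    )
    return pd.DataFrame(rows, columns=TRIAD_COLUMNS)


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

_NODE_CLASS = {"lncrna_id": "lncRNA", "mirna_id": "miRNA", "mrna_id": "mRNA"}


def assemble_network(
    triads: pd.DataFrame,
    de_direction_map: Mapping[str, str] | None = None,
    comparison: str = "",
) -> nx.Graph:
    """Collapse accepted triads into a typed, deduplicated graph."""
    de_direction_map = de_direction_map or {}
    g = nx.Graph(comparison=comparison)
    for row in triads.itertuples(index=False):
        for col, cls in _NODE_CLASS.items():
            fid = getattr(row, col)
            g.add_node(
                fid,
                node_class=cls,
                regulation=de_direction_map.get(fid, "none"),
            )
        g.add_edge(row.mirna_id, row.lncrna_id, interaction=EDGE_MIRNA_LNCRNA)
        g.add_edge(row.mirna_id, row.mrna_id, interaction=EDGE_MIRNA_MRNA)
    return g


def network_stats(network: nx.Graph) -> dict:
    """Node/edge counts, per-class regulation tallies and max-degree hubs."""
    by_class: dict[str, dict[str, int]] = {}
    for _, data in network.nodes(data=True):
        cls = data.get("node_class", "unknown")
        d = by_class.setdefault(cls, {"n": 0, "up": 0, "down": 0})
        d["n"] += 1
        reg = data.get("regulation")
        if reg in ("up", "down"):
            d[reg] += 1
    degrees = pd.DataFrame(
        [
            {
                "id": node,
                "node_class": network.nodes[node].get("node_class", "unknown"),
                "degree": deg,
            }
            for node, deg in network.degree()
        ],
        columns=["id", "node_class", "degree"],
    ).sort_values(["node_class", "degree", "id"], ascending=[True, False, True])
    degrees = degrees.reset_index(drop=True)
    hubs: dict[str, list[str]] = {}
    for cls, grp in degrees.groupby("node_class"):
        top = grp["degree"].max()
        hubs[cls] = sorted(grp.loc[grp["degree"] == top, "id"])
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "classes": by_class,
        "degree_table": degrees,
        "hubs": hubs,
    }


# ---------------------------------------------------------------------------
# Export / import (Cytoscape-friendly)
# ---------------------------------------------------------------------------

def export_network(
    network: nx.Graph,
    destination: str | Path,
    formats: Iterable[str] = ("tsv", "sif"),
) -> list[Path]:
    """Write edge/node attribute tables and/or a SIF file.

    ``tsv`` emits ``edges.tsv`` (source, interaction, target; source is the
    miRNA) and ``nodes.tsv`` (id, node_class, regulation); ``sif`` emits
    ``network.sif``.  Reading the TSV pair back with :func:`read_network`
    reproduces the graph exactly.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    edge_rows = []
    for u, v, data in network.edges(data=True):
        interaction = data.get("interaction", "")
        # the miRNA is always the source node of a targeting edge
        if network.nodes[u].get("node_class") == "miRNA":
            src, dst = u, v
        else:
            src, dst = v, u
        edge_rows.append({"source": src, "interaction": interaction, "target": dst})
    edges = pd.DataFrame(
        edge_rows, columns=["source", "interaction", "target"]
    ).sort_values(["source", "interaction", "target"]).reset_index(drop=True)
    nodes = pd.DataFrame(
        [
            {
                "id": n,
                "node_class": d.get("node_class", "unknown"),
                "regulation": d.get("regulation", "none"),
            }
            for n, d in network.nodes(data=True)
        ],
        columns=["id", "node_class", "regulation"],
    ).sort_values("id").reset_index(drop=True)
    written = []
    for fmt in formats:
        if fmt == "tsv":
            edges.to_csv(destination / "edges.tsv", sep="\t", index=False)
            nodes.to_csv(destination / "nodes.tsv", sep="\t", index=False)
            written += [destination / "edges.tsv", destination / "nodes.tsv"]
        elif fmt == "sif":
            with open(destination / "network.sif", "w") as fh:
                for row in edges.itertuples(index=False):
                    fh.write(f"{row.source}\t{row.interaction}\t{row.target}\n")
            written.append(destination / "network.sif")
        else:
            raise ParameterError(f"unknown export format {fmt!r}")
    return written


def read_network(destination: str | Path) -> nx.Graph:
    """Rebuild a network from the ``edges.tsv`` / ``nodes.tsv`` pair."""
    destination = Path(destination)
    edges = pd.read_csv(destination / "edges.tsv", sep="\t")
    nodes = pd.read_csv(destination / "nodes.tsv", sep="\t")
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.id, node_class=row.node_class, regulation=row.regulation)
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, interaction=row.interaction)
    return g


def networks_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Field-by-field equality of nodes, node attributes and edges."""
    if set(a.nodes) != set(b.nodes):
        return False
    for n in a.nodes:
        da = {k: v for k, v in a.nodes[n].items()}
        db = {k: v for k, v in b.nodes[n].items()}
        if da != db:
            return False
    ea = {frozenset((u, v)): d.get("interaction") for u, v, d in a.edges(data=True)}
    eb = {frozenset((u, v)): d.get("interaction") for u, v, d in b.edges(data=True)}
    return ea == eb


# ---------------------------------------------------------------------------
# Scoring against planted truth
# ---------------------------------------------------------------------------

def score_triads(
    accepted: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity and precision of accepted triads against a truth table.

    Both frames carry ``lncrna_id``, ``mirna_id``, ``mrna_id``; a triad
    counts as recovered only if all three members match.
    """
    acc = set(
        map(tuple, accepted[["lncrna_id", "mirna_id", "mrna_id"]].itertuples(index=False))
    )
    tru = set(
        map(tuple, truth[["lncrna_id", "mirna_id", "mrna_id"]].itertuples(index=False))
    )
    tp = len(acc & tru)
    sensitivity = tp / len(tru) if tru else float("nan")
    precision = tp / len(acc) if acc else float("nan")
    return {
        "n_accepted": len(acc),
        "n_true": len(tru),
        "n_recovered": tp,
        "sensitivity": sensitivity,
        "precision": precision,
    }
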