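"""Linking coexpression modules to dependence and across tissues.

A module is called CIE-related if it is enriched for differentially
expressed genes (one-sided hypergeometric test) or if its eigengene
correlates with dependence status, consumption, or preference.  CIE-related
modules from different tissues are joined into a meta-network whose edges
are significant gene overlaps; a blood module overlapping CIE modules from
at least two distinct brain regions marks a cluster of conserved
"blood-brain" modules.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hypergeometric_tail",
    "module_deg_enrichment",
    "eigengene_trait_association",
    "select_cie_modules",
    "gene_set_overrepresentation",
    "cross_tissue_overlap",
    "build_meta_network",
    "MetaNetwork",
    "read_gmt",
    "write_gmt",
]


def hypergeometric_tail(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """P(X >= overlap) for the overlap of two sets drawn from a universe.

    X ~ Hypergeometric(universe, size_a, size_b); computed in log space by
    scipy's survival function.
    """
    if min(overlap, size_a, size_b, universe) < 0:
        raise ValueError("negative arguments")
    if size_a > universe or size_b > universe:
        raise ValueError("set size exceeds universe")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds the smaller set")
    if overlap < max(0, size_a + size_b - universe):
        raise ValueError("overlap impossible for these sizes")
    # sf(k) = P(X > k), so shift by one for the inclusive tail
    p = float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def module_deg_enrichment(
    assignment,
    degs_up,
    degs_down,
    universe: frozenset | set,
    alpha: float = 0.05,
    strong_alpha: float = 1e-5,
) -> pd.DataFrame:
    """Per-module DEG over-representation, split by regulation direction.

    Parameters
    ----------
    assignment : ModuleAssignment (gene -> module labels; 0 = unassigned).
    degs_up, degs_down : GeneSets of up- and down-regulated genes.
    universe : genes in the network (the expressed background).

    Returns a table with one row per module: overlap counts and one-sided
    hypergeometric p for all/up/down DEGs, the dominant regulation direction
    (sign of the more significant directional enrichment) and an intensity
    label (strong below ``strong_alpha``, weak below ``alpha``).
    """
    universe = frozenset(universe)
    up = frozenset(degs_up.genes) & universe
    down = frozenset(degs_down.genes) & universe
    all_degs = up | down
    n_uni = len(universe)

    rows = []
    for module in assignment.module_labels():
        members = frozenset(assignment.genes_in(module)) & universe
        row = {"module": module, "size": len(members)}
        for tag, degset in (("all", all_degs), ("up", up), ("down", down)):
            ov = len(members & degset)
            p = hypergeometric_tail(ov, len(members), len(degset), n_uni) if degset else 1.0
            row[f"overlap_{tag}"] = ov
            row[f"p_{tag}"] = p
        if row["p_up"] <= row["p_down"]:
            row["direction"] = "up"
            p_dir = row["p_up"]
        else:
            row["direction"] = "down"
            p_dir = row["p_down"]
        row["intensity"] = (
            "strong" if p_dir < strong_alpha else "weak" if p_dir < alpha else "none"
        )
        rows.append(row)
    columns = ["module", "size", "overlap_all", "p_all", "overlap_up", "p_up",
               "overlap_down", "p_down", "direction", "intensity"]
    return pd.DataFrame(rows, columns=columns)


def eigengene_trait_association(
    eigengenes: pd.DataFrame,
    metadata: pd.DataFrame,
    traits: tuple[str, ...] = ("group", "consumption", "preference"),
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    ``eigengenes`` is samples x modules; ``metadata`` has one row per sample
    in the same order (group coded 0/1 automatically if categorical).
    Constant traits are flagged and excluded.
    """
    if len(eigengenes) != len(metadata):
        raise ValueError("eigengenes and metadata must cover the same samples")
    n = len(eigengenes)
    rows = []
    for trait in traits:
        vec = metadata[trait]
        if vec.dtype == object or str(vec.dtype) == "category":
            codes = pd.factorize(vec, sort=True)[0].astype(float)
        else:
            codes = vec.to_numpy(dtype=float)
        if np.nanstd(codes) == 0:
            warnings.warn(f"trait {trait!r} is constant; skipped")
            continue
        for module in eigengenes.columns:
            r, p = stats.pearsonr(eigengenes[module].to_numpy(), codes)
            rows.append({"module": module, "trait": trait, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def select_cie_modules(
    enrichment: pd.DataFrame,
    association: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Modules related to dependence: DEG-enriched OR trait-correlated.

    Returns a table with the selected modules and which criterion fired.
    """
    by_deg = (
        set(enrichment.loc[enrichment["p_all"] < alpha, "module"])
        if len(enrichment)
        else set()
    )
    by_trait = (
        set(association.loc[association["p"] < alpha, "module"])
        if len(association)
        else set()
    )
    rows = []
    for module in sorted(by_deg | by_trait):
        rows.append(
            {
                "module": module,
                "deg_enriched": module in by_deg,
                "trait_correlated": module in by_trait,
            }
        )
    return pd.DataFrame(rows, columns=["module", "deg_enriched", "trait_correlated"])


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Read a GMT gene-set collection (name, description, tab-separated genes)."""
    sets: dict[str, frozenset] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, frozenset | set], path: str | Path,
              description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(map(str, genes))])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def gene_set_overrepresentation(
    queries: dict[str, frozenset | set],
    collections: dict[str, frozenset | set],
    universe: frozenset | set,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of query sets in GMT collections.

    Every set is first restricted to the expressed-gene universe; collection
    sets with empty intersection are skipped with a warning.  Bonferroni
    correction multiplies by the number of (query, set) tests performed.
    """
    if not collections:
        raise ValueError("empty gene-set collection")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    universe = frozenset(universe)
    n_uni = len(universe)

    usable = {}
    for name, genes in collections.items():
        inter = frozenset(genes) & universe
        if not inter:
            warnings.warn(f"gene set {name!r} has no genes in the universe; skipped")
            continue
        usable[name] = inter

    rows = []
    for qname, qgenes in queries.items():
        q = frozenset(qgenes) & universe
        for sname, sgenes in usable.items():
            ov = len(q & sgenes)
            p = hypergeometric_tail(ov, len(q), len(sgenes), n_uni)
            rows.append(
                {
                    "query": qname,
                    "set": sname,
                    "query_size": len(q),
                    "set_size": len(sgenes),
                    "overlap": ov,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    m = len(table)
    if correction == "bonferroni" and m:
        table["p_adj"] = np.minimum(1.0, table["p"] * m)
    elif m:
        table["p_adj"] = table["p"]
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def cross_tissue_overlap(assign_a, assign_b) -> pd.DataFrame:
    """Hypergeometric overlap of every module pair across two tissue networks.

    The universe is the intersection of genes measured in both tissues
    (membership in both modules is only defined there); unassigned genes
    (label 0) form no module.
    """
    shared = frozenset(assign_a.genes()) & frozenset(assign_b.genes())
    if not shared:
        raise ValueError("no shared genes between the two assignments")
    n_uni = len(shared)
    rows = []
    for ma in assign_a.module_labels():
        ga = frozenset(assign_a.genes_in(ma)) & shared
        if not ga:
            continue
        for mb in assign_b.module_labels():
            gb = frozenset(assign_b.genes_in(mb)) & shared
            if not gb:
                continue
            ov = len(ga & gb)
            p = hypergeometric_tail(ov, len(ga), len(gb), n_uni)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(ga),
                    "size_b": len(gb),
                    "universe": n_uni,
                    "overlap": ov,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class MetaNetwork:
    """Cross-tissue module-overlap graph with blood-brain cluster flags."""

    graph: nx.Graph
    blood_brain_clusters: list[set]

    def blood_brain_nodes(self) -> set:
        return set().union(*self.blood_brain_clusters) if self.blood_brain_clusters else set()

    def write_sif(self, path: str | Path) -> None:
        lines = [
            f"{a[0]}.{a[1]}\toverlap\t{b[0]}.{b[1]}" for a, b in self.graph.edges()
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(f"{node[0]}.{node[1]}", **data)
        for a, b, data in self.graph.edges(data=True):
            g.add_edge(f"{a[0]}.{a[1]}", f"{b[0]}.{b[1]}", **data)
        nx.write_graphml(g, path)


def build_meta_network(
    overlaps: dict[tuple[str, str], pd.DataFrame],
    cie_modules: dict[str, set],
    blood_tissue: str = "BLD",
    edge_alpha: float = 0.05,
    node_attrs: dict[tuple[str, int], dict] | None = None,
) -> MetaNetwork:
    """Assemble the cross-tissue meta-network of CIE-related modules.

    Parameters
    ----------
    overlaps : mapping (tissue_a, tissue_b) -> table from
        :func:`cross_tissue_overlap` (module_a refers to tissue_a).
    cie_modules : tissue -> set of CIE-related module labels; only these
        become nodes.
    blood_tissue : name of the blood tissue for blood-brain calling.
    edge_alpha : overlap significance threshold for edges.
    node_attrs : optional extra attributes per (tissue, module) node.

    A blood module whose significant overlaps reach modules from at least
    two distinct brain regions (region identity counts, not module
    multiplicity) defines a blood-brain cluster: the blood node together
    with its brain neighbours.  Only those nodes carry the flag; other
    modules that merely share a connected component do not.
    """
    g = nx.Graph()
    for tissue in sorted(cie_modules):
        for module in sorted(cie_modules[tissue]):
            node = (tissue, int(module))
            attrs = (node_attrs or {}).get(node, {})
            g.add_node(node, tissue=tissue, module=int(module), **attrs)

    for (ta, tb), table in sorted(overlaps.items()):
        if ta == tb:
            raise ValueError("overlap tables must link different tissues")
        for row in table.itertuples(index=False):
            na, nb = (ta, int(row.module_a)), (tb, int(row.module_b))
            if na not in g or nb not in g:
                continue
            if row.p < edge_alpha:
                g.add_edge(na, nb, overlap=int(row.overlap), p=float(row.p),
                           weight=float(-np.log10(row.p)))

    clusters = []
    for node in g.nodes:
        if node[0] != blood_tissue:
            continue
        neighbours = set(g.neighbors(node))
        brain_regions = {nb[0] for nb in neighbours if nb[0] != blood_tissue}
        if len(brain_regions) >= 2:
            clusters.append({node} | neighbours)
    for cluster in clusters:
        for node in cluster:
            g.nodes[node]["blood_brain"] = True
    for node in g.nodes:
        g.nodes[node].setdefault("blood_brain", False)
    return MetaNetwork(g, clusters)
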