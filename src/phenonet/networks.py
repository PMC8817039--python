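"""Cross-phenotype associations and the bipartite projection networks.

A cross-phenotype association (CPA) is a single variant associated with two
or more phenotypes below the exploratory threshold.  The phenotype network
joins phenotypes sharing at least one such locus; the gene network joins
genes sharing at least one phenotype.  "Locus" is operationalized as a
single variant id; an optional clump-collapse pre-pass can merge correlated
loci first.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .annotation import VariantAnnotation
from .phewas import EXPLORATORY_P, PheWASRun

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrossPhenotypeAssociation:
    variant_id: str
    phenotype_set: frozenset
    gene_symbols: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.phenotype_set) < 2:
            raise ValueError("a cross-phenotype association needs >= 2 phenotypes")


def extract_cpa(
    run: PheWASRun,
    annotations: Dict[str, VariantAnnotation],
    p_threshold: float = EXPLORATORY_P,
) -> List[CrossPhenotypeAssociation]:
    """Variants associated with >= 2 phenotypes at the exploratory threshold."""
    hits: Dict[str, Set[str]] = {}
    for rec in run.records:
        if rec.p_value < p_threshold:
            hits.setdefault(rec.variant_id, set()).add(rec.phenotype_name)
    out = []
    for vid in sorted(hits):
        phenos = hits[vid]
        if len(phenos) < 2:
            continue
        ann = annotations.get(vid)
        out.append(
            CrossPhenotypeAssociation(
                variant_id=vid,
                phenotype_set=frozenset(phenos),
                gene_symbols=ann.gene_symbols if ann else (),
            )
        )
    return out


def build_phenotype_network(
    cpas: Sequence[CrossPhenotypeAssociation],
    categories: Optional[Dict[str, str]] = None,
) -> nx.Graph:
    """Phenotype graph: an edge per pair sharing >= 1 locus.

    Edge attributes: ``shared_loci`` (sorted variant ids), ``shared_genes``,
    ``weight`` (= number of shared loci).  Node attribute ``category`` when
    provided.  Node degree in the graph is the phenotype degree.
    """
    g = nx.Graph()
    for cpa in cpas:
        for pheno in cpa.phenotype_set:
            if pheno not in g:
                g.add_node(pheno, category=(categories or {}).get(pheno))
        for a, b in itertools.combinations(sorted(cpa.phenotype_set), 2):
            if g.has_edge(a, b):
                g[a][b]["shared_loci"].add(cpa.variant_id)
                g[a][b]["shared_genes"].update(cpa.gene_symbols)
            else:
                g.add_edge(
                    a,
                    b,
                    shared_loci={cpa.variant_id},
                    shared_genes=set(cpa.gene_symbols),
                )
    for _, _, data in g.edges(data=True):
        data["weight"] = len(data["shared_loci"])
    return g


def build_gene_network(
    cpas: Sequence[CrossPhenotypeAssociation],
    annotations: Dict[str, VariantAnnotation],
    run: PheWASRun,
    p_threshold: float = EXPLORATORY_P,
) -> nx.Graph:
    """Gene graph: an edge per gene pair sharing >= 1 phenotype.

    Nodes carry ``phenotype_degree`` = number of phenotypes with at least
    one sub-threshold variant mapped to the gene; graph degree is the gene
    degree.  Sub-threshold variants without any gene contribute nothing
    (their count is logged).
    """
    gene_phenos: Dict[str, Set[str]] = {}
    n_unmapped = 0
    for rec in run.records:
        if rec.p_value >= p_threshold:
            continue
        ann = annotations.get(rec.variant_id)
        if ann is None or not ann.gene_symbols:
            n_unmapped += 1
            continue
        for gene in ann.gene_symbols:
            gene_phenos.setdefault(gene, set()).add(rec.phenotype_name)
    if n_unmapped:
        logger.info("%d sub-threshold records had no gene mapping", n_unmapped)
    g = nx.Graph()
    for gene, phenos in gene_phenos.items():
        g.add_node(gene, phenotype_degree=len(phenos))
    for a, b in itertools.combinations(sorted(gene_phenos), 2):
        shared = gene_phenos[a] & gene_phenos[b]
        if shared:
            g.add_edge(a, b, shared_phenotypes=sorted(shared), weight=len(shared))
    return g


def phenotype_intersection_sets(
    network: nx.Graph, focus_phenotypes: Sequence[str]
) -> Dict[frozenset, List[str]]:
    """Partition neighbours of the focus set by which foci they connect to.

    Every node connected to at least one focus phenotype lands in exactly
    one of the 2^k - 1 non-empty membership classes (keyed by the frozenset
    of foci it touches).  Focus phenotypes themselves are excluded.
    """
    focus = list(dict.fromkeys(focus_phenotypes))
    if len(focus) > 6:
        raise ValueError("more than 6 focus phenotypes refused")
    for f in focus:
        if f not in network:
            raise ValueError(f"focus phenotype {f!r} not in network")
    membership: Dict[str, Set[str]] = {}
    for f in focus:
        for nb in network.neighbors(f):
            if nb in focus:
                continue
            membership.setdefault(nb, set()).add(f)
    out: Dict[frozenset, List[str]] = {}
    for node, foci in membership.items():
        out.setdefault(frozenset(foci), []).append(node)
    for lst in out.values():
        lst.sort()
    return out


def cross_phenotype_map(
    network: nx.Graph, core_phenotype: str
) -> Dict[str, List[Tuple[str, List[str]]]]:
    """Star subgraph of the core: neighbours grouped by category code.

    Returns category -> list of (phenotype, shared loci).  Nodes with no
    category label fall under "??".
    """
    if core_phenotype not in network:
        raise ValueError(f"unknown core phenotype {core_phenotype!r}")
    grouped: Dict[str, List[Tuple[str, List[str]]]] = {}
    for nb in network.neighbors(core_phenotype):
        cat = network.nodes[nb].get("category") or "??"
        loci = sorted(network[core_phenotype][nb]["shared_loci"])
        grouped.setdefault(cat, []).append((nb, loci))
    for lst in grouped.values():
        lst.sort()
    return grouped


# ---------------------------------------------------------------------------
# export


def write_edge_list(graph: nx.Graph, path: str) -> None:
    """Tab-separated edge list with shared-item annotations."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tshared_items\n")
        for a, b, data in graph.edges(data=True):
            items = data.get("shared_loci") or data.get("shared_phenotypes") or []
            fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\t{','.join(sorted(items))}\n")


def write_graphml(graph: nx.Graph, path: str) -> None:
    g = nx.Graph()
    for node, data in graph.nodes(data=True):
        g.add_node(node, **{k: v for k, v in data.items() if v is not None})
    for a, b, data in graph.edges(data=True):
        attrs = {"weight": data.get("weight", 1)}
        items = data.get("shared_loci") or data.get("shared_phenotypes")
        if items:
            attrs["shared_items"] = ",".join(sorted(items))
        g.add_edge(a, b, **attrs)
    nx.write_graphml(g, path)
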