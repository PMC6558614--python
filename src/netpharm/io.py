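"""Readers and writers for the tabular and graph formats the pipeline touches.

Tabular dialects (tab-separated, mandatory header row):

* compound table   — ``compound_id  name  smiles  herb``
* compound-target  — ``compound_id  target_symbol  source``
* PPI              — ``protein_a  protein_b  combined_score``
* gene sets        — standard GMT (``term_id  description  gene1  gene2 ...``),
  with the annotation category encoded as a ``BP|``/``MF|``/``CC|``/
  ``pathway|`` prefix on the description
* networks         — SIF, GraphML (``role`` node attribute) or edge-table TSV

All gene symbols are upper-cased at parse time.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from netpharm.model import (
    Compound,
    CompoundTargetEdge,
    FormatError,
    GeneSet,
    Network,
    PPIEdge,
    ValidationError,
    dedupe_ct_edges,
    dedupe_ppi_edges,
    normalize_symbol,
    ROLE_COMPOUND,
    ROLE_HERB,
    ROLE_PATHWAY,
    ROLE_TARGET,
)

# SIF interaction labels, keyed by the (role, role) pair of the endpoints
# in the order they are written.
_SIF_LABELS = {
    (ROLE_COMPOUND, ROLE_TARGET): "ct",
    (ROLE_TARGET, ROLE_TARGET): "pp",
    (ROLE_HERB, ROLE_COMPOUND): "hc",
    (ROLE_TARGET, ROLE_PATHWAY): "tp",
}
_SIF_ROLES = {label: roles for roles, label in _SIF_LABELS.items()}

NETWORK_FORMATS = ("sif", "graphml", "edge-table")


def _read_rows(path, required: Sequence[str]):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        yield from reader


def read_compound_table(path) -> list:
    """Read a compound TSV; blank smiles/herb fields become ``None``."""
    compounds = []
    for row in _read_rows(path, ("compound_id", "name", "smiles", "herb")):
        compounds.append(
            Compound(
                compound_id=row["compound_id"].strip(),
                name=row["name"].strip(),
                smiles=row["smiles"].strip() or None,
                herb=row["herb"].strip() or None,
            )
        )
    return compounds


def write_compound_table(compounds: Iterable[Compound], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "name", "smiles", "herb"])
        for c in compounds:
            w.writerow([c.compound_id, c.name, c.smiles or "", c.herb or ""])


def parse_edge_table(path, kind: str = "compound-target"):
    """Parse a compound-target or PPI edge TSV.

    Duplicate rows are collapsed; for PPI tables, unordered-pair duplicates
    keep the maximum combined score.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    kind
        ``"compound-target"`` or ``"ppi"``.

    Returns
    -------
    list of CompoundTargetEdge or PPIEdge
    """
    if kind == "compound-target":
        edges = []
        for row in _read_rows(path, ("compound_id", "target_symbol")):
            edges.append(
                CompoundTargetEdge(
                    compound_id=row["compound_id"].strip(),
                    symbol=normalize_symbol(row["target_symbol"]),
                    provenance=(row.get("source") or "").strip() or None,
                )
            )
        return dedupe_ct_edges(edges)
    if kind == "ppi":
        edges = []
        for i, row in enumerate(
            _read_rows(path, ("protein_a", "protein_b", "combined_score")), start=2
        ):
            try:
                score = float(row["combined_score"])
            except ValueError:
                raise FormatError(
                    f"{path}:{i}: non-numeric combined_score "
                    f"{row['combined_score']!r}"
                ) from None
            if not (0.0 <= score <= 1.0):
                raise ValidationError(
                    f"{path}:{i}: combined_score {score} outside [0, 1]"
                )
            edges.append(
                PPIEdge(
                    a=normalize_symbol(row["protein_a"]),
                    b=normalize_symbol(row["protein_b"]),
                    score=score,
                )
            )
        return dedupe_ppi_edges(edges)
    raise ValueError(f"unknown edge-table kind {kind!r}")


def write_ct_edges(edges: Iterable[CompoundTargetEdge], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "target_symbol", "source"])
        for e in edges:
            w.writerow([e.compound_id, e.symbol, e.provenance or ""])


def write_ppi_edges(edges: Iterable[PPIEdge], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["protein_a", "protein_b", "combined_score"])
        for e in edges:
            w.writerow([e.a, e.b, f"{e.score:.6g}"])


def parse_gene_list(path) -> list:
    """One gene symbol per line; blank lines ignored; upper-cased."""
    with open(path) as fh:
        return [normalize_symbol(line) for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def parse_gene_sets(path, default_category: str = "pathway") -> list:
    """Parse a GMT file into GeneSets.

    The annotation category is read from a ``CATEGORY|description`` prefix
    on the GMT description field; descriptions without a recognized prefix
    fall back to ``default_category``.
    """
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{i}: GMT line has {len(fields)} fields, expected >= 3"
                )
            term_id, desc = fields[0], fields[1]
            if "|" in desc and desc.split("|", 1)[0] in ("BP", "MF", "CC", "pathway"):
                category, term_name = desc.split("|", 1)
            else:
                category, term_name = default_category, desc
            genes = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{i}: term {term_id} has no genes")
            sets.append(GeneSet(term_id, term_name, category, genes))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.term_id}\t{s.category}|{s.term_name}\t{genes}\n")


# ---------------------------------------------------------------------
# Network interchange (Cytoscape-importable formats)
# ---------------------------------------------------------------------


def _sif_label(net: Network, u: str, v: str) -> tuple:
    """Return (ordered endpoints, label) for one edge."""
    ru, rv = net.role(u), net.role(v)
    if (ru, rv) in _SIF_LABELS:
        return (u, v), _SIF_LABELS[(ru, rv)]
    if (rv, ru) in _SIF_LABELS:
        return (v, u), _SIF_LABELS[(rv, ru)]
    raise ValidationError(f"no interaction label for roles ({ru}, {rv})")


def export_network(net: Network, path, format: str = "sif") -> None:
    """Write a network as SIF, GraphML, or an edge-table TSV.

    Round-trip guarantee: :func:`parse_network` on the written file
    reconstructs the same node set, node roles, and edge set.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(net.edge_set()):
                (a, b), label = _sif_label(net, u, v)
                fh.write(f"{a}\t{label}\t{b}\n")
    elif format == "graphml":
        g = nx.Graph(name=net.name, kind=net.kind)
        g.add_nodes_from(net.graph.nodes(data=True))
        g.add_edges_from(net.graph.edges())
        nx.write_graphml(g, path)
    elif format == "edge-table":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "interaction", "target", "source_role", "target_role"])
            for u, v in sorted(net.edge_set()):
                (a, b), label = _sif_label(net, u, v)
                w.writerow([a, label, b, net.role(a), net.role(b)])
    else:
        raise ValueError(f"unknown network format {format!r}")


def _infer_kind(graph: nx.Graph) -> str:
    roles = {d["role"] for _, d in graph.nodes(data=True)}
    if roles <= {ROLE_TARGET}:
        return "unipartite"
    if roles <= {ROLE_COMPOUND, ROLE_TARGET}:
        return "bipartite"
    return "heterogeneous"


def parse_network(path, format: str = "sif", name: Optional[str] = None) -> Network:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) != 3:
                    raise FormatError(f"{path}:{i}: expected 'node label node'")
                a, label, b = fields
                if label not in _SIF_ROLES:
                    raise FormatError(f"{path}:{i}: unknown interaction {label!r}")
                ra, rb = _SIF_ROLES[label]
                g.add_node(a, role=ra)
                g.add_node(b, role=rb)
                g.add_edge(a, b)
        return Network(name or path.stem, _infer_kind(g), g)
    if format == "graphml":
        g = nx.read_graphml(path)
        g2 = nx.Graph()
        for n, d in g.nodes(data=True):
            g2.add_node(str(n), role=d["role"])
        g2.add_edges_from((str(u), str(v)) for u, v in g.edges())
        kind = g.graph.get("kind") or _infer_kind(g2)
        return Network(name or g.graph.get("name", path.stem), kind, g2)
    if format == "edge-table":
        g = nx.Graph()
        for row in _read_rows(
            path, ("source", "interaction", "target", "source_role", "target_role")
        ):
            g.add_node(row["source"], role=row["source_role"])
            g.add_node(row["target"], role=row["target_role"])
            g.add_edge(row["source"], row["target"])
        return Network(name or path.stem, _infer_kind(g), g)
    raise ValueError(f"unknown network format {format!r}")
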