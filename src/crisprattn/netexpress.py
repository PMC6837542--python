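"""Cell-specific network-based gene property: the NetExpress score.

For a gene *g* in a weighted gene–gene interaction network (STRING-style)
and a cell line's expression profile *e*, the score is the one-hop
confidence-weighted sum of neighbour expression::

    NetExpress(g) = sum over neighbours j of g:  w(g, j) * e[j]

It summarises how strongly a gene's interaction partners are expressed in a
given cell — a proxy for the gene's systemic importance in that cellular
context. Neighbours missing from the expression profile contribute 0 by
default (the common STRING/CCLE gene-set mismatch case); ``strict=True``
raises instead. Raw STRING combined scores (0–1000) are auto-rescaled to
(0, 1] on file ingest when the maximum confidence exceeds 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import LookupError_, ParseError, ValidationError

__all__ = [
    "GeneNetwork",
    "ExpressionProfile",
    "NetExpressScore",
    "compute_netexpress",
    "compute_all",
    "read_network",
    "read_expression",
]

log = logging.getLogger(__name__)


@dataclass
class GeneNetwork:
    """Undirected weighted gene graph; duplicate edges keep the max confidence."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges) -> "GeneNetwork":
        """Build from (geneA, geneB, confidence) triples."""
        g = nx.Graph()
        for a, b, w in edges:
            w = float(w)
            if a == b:
                continue  # self-loops carry no neighbour information
            if w <= 0:
                raise ValidationError(f"edge ({a}, {b}) has non-positive confidence {w}")
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def neighbors(self, gene: str) -> list[tuple[str, float]]:
        if gene not in self.graph:
            raise LookupError_(f"gene {gene!r} not in network")
        return [(j, self.graph[gene][j]["weight"]) for j in self.graph.neighbors(gene)]

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class ExpressionProfile:
    """Per-cell-line gene -> expression mapping."""

    cell_line: str
    values: dict[str, float]

    def __post_init__(self):
        for g, v in self.values.items():
            if not np.isfinite(v):
                raise ValidationError(f"non-finite expression for gene {g!r}")


@dataclass
class NetExpressScore:
    gene: str
    cell_line: str
    score: float


def compute_netexpress(
    gene: str, net: GeneNetwork, expr: ExpressionProfile, strict: bool = False
) -> NetExpressScore:
    """Confidence-weighted sum of a gene's neighbours' expression.

    Raises ``LookupError_`` if ``gene`` is absent from the network (distinct
    from the isolated-gene case, which scores 0).
    """
    total = 0.0
    missing = 0
    for j, w in net.neighbors(gene):
        if j in expr.values:
            total += w * expr.values[j]
        elif strict:
            raise LookupError_(f"neighbour {j!r} of {gene!r} missing from expression profile")
        else:
            missing += 1
    if missing:
        log.debug("gene %s: %d neighbours without expression contributed 0", gene, missing)
    return NetExpressScore(gene=gene, cell_line=expr.cell_line, score=total)


def compute_all(
    net: GeneNetwork, expr: ExpressionProfile, strict: bool = False
) -> dict[str, NetExpressScore]:
    """Vectorised scores for every network gene; equals per-gene calls exactly."""
    genes = list(net.graph.nodes)
    if not genes:
        return {}
    idx = {g: i for i, g in enumerate(genes)}
    e = np.zeros(len(genes))
    present = np.zeros(len(genes), dtype=bool)
    for g, i in idx.items():
        if g in expr.values:
            e[i] = expr.values[g]
            present[i] = True
    if strict and not present.all():
        # only neighbours that would actually be summed matter in strict mode
        for a, b in net.graph.edges:
            for g, j in ((a, b), (b, a)):
                if j not in expr.values:
                    raise LookupError_(
                        f"neighbour {j!r} of {g!r} missing from expression profile"
                    )
    a = nx.to_scipy_sparse_array(net.graph, nodelist=genes, weight="weight", format="csr")
    scores = a @ e
    return {
        g: NetExpressScore(gene=g, cell_line=expr.cell_line, score=float(scores[idx[g]]))
        for g in genes
    }


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_network(path: str | Path, rescale_string_scores: bool = True) -> GeneNetwork:
    """Read a STRING-style 3-column edge list (geneA, geneB, confidence).

    A header row is detected when the third column is non-numeric. Duplicate
    edges (either orientation) collapse to the maximum confidence. Raw STRING
    combined scores are divided by 1000 when the maximum exceeds 1 (disable
    with ``rescale_string_scores=False``).
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"expected 3 columns, got {len(parts)}", line=lineno)
            if lineno == 1 and not _is_number(parts[2]):
                continue  # header
            if not _is_number(parts[2]):
                raise ParseError(f"non-numeric confidence {parts[2]!r}", line=lineno)
            w = float(parts[2])
            if w <= 0:
                raise ParseError(f"non-positive confidence {w}", line=lineno)
            rows.append((parts[0], parts[1], w))
    if rescale_string_scores and rows and max(w for _, _, w in rows) > 1.0:
        log.info("confidence scores exceed 1; interpreting as raw STRING scores (/1000)")
        rows = [(a, b, w / 1000.0) for a, b, w in rows]
    return GeneNetwork.from_edges(rows)


def read_expression(
    path: str | Path, cell_line: str | None = None, log2: bool = False
) -> ExpressionProfile:
    """Read an expression table.

    Two layouts are accepted: a 2-column (gene, value) TSV, or a wide
    gene x cell-line matrix with a header naming the cell lines, in which
    case ``cell_line`` selects the column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"expression table {path} needs at least 2 columns")
    df = df.set_index(df.columns[0])
    if cell_line is not None and cell_line in df.columns:
        col = df[cell_line]
        name = cell_line
    elif df.shape[1] == 1:
        col = df.iloc[:, 0]
        name = cell_line or df.columns[0]
    else:
        raise ParseError(
            f"cell line {cell_line!r} not found among columns {list(df.columns)}"
        )
    values = col.astype(float)
    if log2:
        values = np.log2(values + 1.0)
    return ExpressionProfile(cell_line=str(name), values=values.to_dict())
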