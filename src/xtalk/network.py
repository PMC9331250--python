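"""Edge selection, bipartite network assembly, and cross-study concordance.

Edges are retained when their VIM lies strictly above a high empirical
percentile (default the 99th, linear-interpolation definition) of all entries
of the source x target matrix; because the matrix is already restricted to
liver sources and aorta targets, every retained edge runs liver -> aorta by
construction, and the bipartite contract is re-asserted at assembly time.

Cross-study validation calls each regulator up/down in the second study by a
strict +/-cutoff on its log2 fold change (default 0.4) and counts directional
agreement with the first study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import BipartiteViolationError, DesignError, DuplicateRegulatorError
from .grn import VimMatrix
from .io import GeneSetCollection

__all__ = [
    "select_edges",
    "assemble_network",
    "network_tables",
    "concordance",
    "KEY_REGULATORS",
]

#: Hepatic key regulators reported for real-data runs of this analysis.
KEY_REGULATORS = (
    "LCAT", "ACAT2", "SC5D", "HMGCR", "SQLE", "MVK",
    "IL1A", "VCAM1", "NFKB2", "PDGFD", "SELP",
    "APOA2", "APOC4", "C1R", "APCS", "COL3A1", "FGG",
)

EDGE_COLUMNS = ["source", "target", "vim", "percentile_rank"]


def select_edges(vim: VimMatrix | pd.DataFrame, percentile: float = 99.0) -> pd.DataFrame:
    """Retain source->target edges strictly above a VIM percentile.

    The threshold is the empirical ``percentile`` (linear interpolation) of
    all source x target entries; entries equal to the threshold are dropped
    (strict inequality). Returns an edge table sorted by descending VIM then
    gene ids, with each edge's mid-rank percentile among all entries.
    """
    frame = vim.frame if isinstance(vim, VimMatrix) else vim
    if frame.size == 0:
        raise DesignError("empty VIM matrix")
    if not (0.0 <= percentile < 100.0):
        raise DesignError("percentile must lie in [0, 100)")
    values = frame.to_numpy(dtype=float).ravel()
    threshold = float(np.percentile(values, percentile))
    n = values.size
    rows = []
    for i, source in enumerate(frame.index):
        for j, target in enumerate(frame.columns):
            v = float(frame.iat[i, j])
            if v > threshold:
                below = np.count_nonzero(values < v)
                equal = np.count_nonzero(values == v)
                rows.append(
                    {
                        "source": source,
                        "target": target,
                        "vim": v,
                        "percentile_rank": 100.0 * (below + 0.5 * equal) / n,
                    }
                )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(
        ["vim", "source", "target"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


def assemble_network(
    edges: pd.DataFrame,
    sets: GeneSetCollection | None = None,
    label: str = "lipid_fibrosis",
) -> nx.DiGraph:
    """Bipartite liver->aorta network with pathway annotations.

    Every edge must run from a liver source to an aorta target; an edge whose
    source also appears among the targets violates the bipartite contract.
    Each node is annotated with the names of every gene set containing it
    ("unassigned" when none) and with its tissue side.
    """
    sources = set(edges["source"]) if len(edges) else set()
    targets = set(edges["target"]) if len(edges) else set()
    overlap = sources & targets
    if overlap:
        raise BipartiteViolationError(
            f"genes appear as both source and target: {sorted(overlap)}"
        )
    g = nx.DiGraph(analysis_label=label)
    for gene in sorted(sources):
        g.add_node(gene, tissue="liver", bipartite=0, pathways=_annotate(gene, sets))
    for gene in sorted(targets):
        g.add_node(gene, tissue="aorta", bipartite=1, pathways=_annotate(gene, sets))
    for row in edges.itertuples():
        g.add_edge(
            row.source, row.target, vim=row.vim, percentile_rank=row.percentile_rank
        )
    return g


def _annotate(gene: str, sets: GeneSetCollection | None) -> list[str]:
    if sets is None:
        return ["unassigned"]
    names = sets.sets_containing(gene)
    return names if names else ["unassigned"]


def network_tables(g: nx.DiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables of an assembled network, for TSV export."""
    node_rows = [
        {
            "gene": n,
            "tissue": d["tissue"],
            "pathways": ";".join(d["pathways"]),
        }
        for n, d in sorted(g.nodes(data=True))
    ]
    edge_rows = [
        {
            "source": u,
            "target": v,
            "vim": d["vim"],
            "percentile_rank": d["percentile_rank"],
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    return (
        pd.DataFrame(node_rows, columns=["gene", "tissue", "pathways"]),
        pd.DataFrame(edge_rows, columns=EDGE_COLUMNS),
    )


CONCORDANCE_COLUMNS = [
    "gene",
    "direction_study1",
    "log2fc_study2",
    "called_study2",
    "concordant",
]


@dataclass(frozen=True)
class ConcordanceReport:
    table: pd.DataFrame
    n_concordant: int
    n_discordant: int
    n_not_de: int

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def concordance(
    regulators: Sequence[tuple[str, str]],
    deg2: pd.DataFrame,
    fc_cutoff: float = 0.4,
) -> ConcordanceReport:
    """Directional cross-study concordance of key regulators.

    ``regulators`` pairs each gene with its first-study direction ("up" or
    "down"); ``deg2`` is a DEG-style table of the second study with columns
    gene_id and log2fc (one row per gene). A regulator is called up in the
    second study iff log2fc > fc_cutoff, down iff log2fc < -fc_cutoff, and
    not_de otherwise (strict inequalities) or when absent; concordance is
    directional agreement, n/a for not_de.
    """
    genes = [g for g, _ in regulators]
    if len(genes) != len(set(genes)):
        dup = sorted({g for g in genes if genes.count(g) > 1})
        raise DuplicateRegulatorError(f"duplicate regulators: {dup}")
    if deg2["gene_id"].duplicated().any():
        raise DuplicateRegulatorError("deg2 has duplicate gene_id rows")
    lfc = deg2.set_index("gene_id")["log2fc"]
    rows = []
    for gene, direction in regulators:
        if direction not in ("up", "down"):
            raise DesignError(f"direction must be up/down, got {direction!r}")
        if gene in lfc.index:
            value = float(lfc[gene])
            if value > fc_cutoff:
                called = "up"
            elif value < -fc_cutoff:
                called = "down"
            else:
                called = "not_de"
        else:
            value = float("nan")
            called = "not_de"
        concordant = "n/a" if called == "not_de" else str(called == direction).lower()
        rows.append(
            {
                "gene": gene,
                "direction_study1": direction,
                "log2fc_study2": value,
                "called_study2": called,
                "concordant": concordant,
            }
        )
    table = pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)
    return ConcordanceReport(
        table=table,
        n_concordant=int((table["concordant"] == "true").sum()),
        n_discordant=int((table["concordant"] == "false").sum()),
        n_not_de=int((table["concordant"] == "n/a").sum()),
    )
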