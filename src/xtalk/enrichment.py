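"""Gene-set enrichment per tissue and timepoint.

Fisher exact (hypergeometric upper-tail) over-representation of DEGs in each
gene set, a sign-consistency activation z-score for sets carrying expected
per-gene directions, differentially-expressed-pathway (DEP) overlap between
tissues, and time-resolved process-category dynamics over the top pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .io import CATEGORIES, GeneSet, GeneSetCollection

__all__ = [
    "fisher_enrich",
    "activation_z",
    "enrich_all",
    "dep_overlap",
    "process_dynamics",
]

Z_CALL_THRESHOLD = 2.0


def fisher_enrich(deg_genes: set, gene_set: set, universe: set) -> tuple[int, int, int, int, float]:
    """One-sided over-representation p for a DEG set in a gene set.

    Returns ``(k, K, n, N, p)`` where k is the overlap, K the set size within
    the universe, n the DEG count, N the universe size, and
    ``p = P(X >= k)`` under Hypergeometric(N, K, n).
    """
    if not universe:
        raise DesignError("empty universe")
    universe = set(universe)
    deg = set(deg_genes) & universe
    members = set(gene_set) & universe
    k = len(deg & members)
    K, n, N = len(members), len(deg), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(p, 1.0)


def activation_z(deg_subset: pd.DataFrame, gene_set: GeneSet) -> float | None:
    """Sign-consistency activation z-score.

    Over the m significant genes of the set that carry an expected direction,
    ``z = sum(sign(log2fc) * expected_direction) / sqrt(m)``; |z| > 2 is read
    as predicted activation (positive) or inhibition (negative). Returns None
    when no overlapping DEG carries a direction.
    """
    if not gene_set.expected_direction:
        return None
    sub = deg_subset[deg_subset["gene_id"].isin(gene_set.expected_direction)]
    sub = sub[sub["significant"] & (sub["log2fc"] != 0)]
    m = len(sub)
    if m == 0:
        return None
    agree = sum(
        float(np.sign(r.log2fc)) * gene_set.expected_direction[r.gene_id]
        for r in sub.itertuples()
    )
    return agree / math.sqrt(m)


ENRICH_COLUMNS = [
    "set_name",
    "category",
    "tissue",
    "time_weeks",
    "k",
    "K",
    "n",
    "N",
    "p_fisher",
    "neg_log10_p",
    "z",
    "dep",
]


def enrich_all(
    deg_table: pd.DataFrame,
    sets: GeneSetCollection,
    universe: set,
    enrich_p: float = 0.01,
) -> pd.DataFrame:
    """Enrichment records for every (set, tissue, timepoint) cell.

    ``universe`` is the set of genes eligible for testing (conventionally the
    tissue's count matrix after dropping all-zero genes); the DEG table is
    restricted to it. A record is a DEP when its Fisher p is below
    ``enrich_p``.
    """
    rows = []
    for (tissue, t), sub in deg_table.groupby(["tissue", "time_weeks"], sort=True):
        sub = sub[sub["gene_id"].isin(universe)]
        deg_genes = set(sub.loc[sub["significant"], "gene_id"])
        for s in sets:
            k, K, n, N, p = fisher_enrich(deg_genes, set(s.genes), universe)
            z = activation_z(sub, s)
            rows.append(
                {
                    "set_name": s.name,
                    "category": s.category,
                    "tissue": tissue,
                    "time_weeks": t,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_fisher": p,
                    "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
                    "z": np.nan if z is None else z,
                    "dep": bool(p < enrich_p),
                }
            )
    return pd.DataFrame(rows, columns=ENRICH_COLUMNS)


@dataclass(frozen=True)
class DepOverlap:
    n_liver: int
    n_aorta: int
    n_shared: int
    aorta_shared_fraction: float


def dep_overlap(
    liver: pd.DataFrame, aorta: pd.DataFrame, time_weeks: int
) -> DepOverlap:
    """Overlap of DEP set names between the two tissues at one timepoint."""
    lsets = set(
        liver.loc[(liver["time_weeks"] == time_weeks) & liver["dep"], "set_name"]
    )
    asets = set(
        aorta.loc[(aorta["time_weeks"] == time_weeks) & aorta["dep"], "set_name"]
    )
    shared = lsets & asets
    frac = len(shared) / len(asets) if asets else 0.0
    return DepOverlap(len(lsets), len(asets), len(shared), frac)


def process_dynamics(records: pd.DataFrame, top_cutoff: float = 5.0) -> pd.DataFrame:
    """Category shares of top pathways per (tissue, timepoint).

    Restricts to records with ``neg_log10_p > top_cutoff``; the share of a
    category is its fraction of the passing pathway count. Cells with no
    passing pathway get all-zero shares.
    """
    rows = []
    for (tissue, t), sub in records.groupby(["tissue", "time_weeks"], sort=True):
        passing = sub[sub["neg_log10_p"] > top_cutoff]
        total = len(passing)
        for cat in CATEGORIES:
            share = (
                (passing["category"] == cat).sum() / total if total > 0 else 0.0
            )
            rows.append(
                {
                    "tissue": tissue,
                    "category": cat,
                    "time_weeks": t,
                    "n_top": total,
                    "share": float(share),
                }
            )
    return pd.DataFrame(rows, columns=["tissue", "category", "time_weeks", "n_top", "share"])
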