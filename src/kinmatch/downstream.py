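"""Clustering and network reconstruction over kinase-substrate matches.

Two downstream views of a match table:

* a peptide x kinase matrix of background percentiles, hierarchically
  clustered on both axes with Ward's method on Euclidean distances (the
  heatmap of phosphosites grouped by the kinases that can phosphorylate
  them); and
* a directed kinome network whose edges are predicted phosphorylation
  events: source = matching kinase family, target = the protein carrying
  the phosphosite, kept when the match percentile reaches the (possibly
  stricter) network threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import scipy.cluster.hierarchy as sch

from .errors import ValidationError
from .io_formats import PhosphoPeptide
from .orthology import KinaseCatalog
from .scoring import MatchTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Percentile matrix + Ward clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchMatrix:
    """Peptide x kinase-family percentile matrix for the clustered heatmap.

    Rows are peptides with at least one above-threshold match, columns are
    families with at least one; cells hold the percentile of every scored
    pair, above threshold or not, so the heatmap shows gradation. Pairs
    never scored (class-incompatible) are filled with 0 and flagged False
    in ``scored_mask``.
    """

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray
    scored_mask: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("match matrix dimensions inconsistent")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValidationError("percentile values outside [0, 100]")


def build_match_matrix(match_table: MatchTable) -> MatchMatrix:
    """Pivot the match table into the percentile matrix."""
    matched_rows = sorted(
        {r.peptide_id for r in match_table.results if r.is_match}
    )
    matched_cols = sorted(
        {r.kinase_family_id for r in match_table.results if r.is_match}
    )
    if not matched_rows:
        raise ValidationError("no above-threshold matches; nothing to cluster")
    row_index = {pid: i for i, pid in enumerate(matched_rows)}
    col_index = {fid: j for j, fid in enumerate(matched_cols)}
    values = np.zeros((len(matched_rows), len(matched_cols)))
    scored = np.zeros_like(values, dtype=bool)
    for r in match_table.results:
        i = row_index.get(r.peptide_id)
        j = col_index.get(r.kinase_family_id)
        if i is not None and j is not None:
            values[i, j] = r.percentile
            scored[i, j] = True
    return MatchMatrix(
        row_ids=tuple(matched_rows),
        col_ids=tuple(matched_cols),
        values=values,
        scored_mask=scored,
    )


def ward_linkage(
    matrix: MatchMatrix, axis: str = "rows"
) -> tuple[np.ndarray, list[int]]:
    """Ward/Euclidean agglomerative clustering of one matrix axis.

    Returns the ``(n-1, 4)`` merge table (left, right, height, size — the
    standard linkage-matrix convention, heights non-decreasing) and the
    dendrogram leaf ordering. A single-item axis yields an empty merge
    table and the trivial ordering.
    """
    if axis not in ("rows", "columns"):
        raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = matrix.values if axis == "rows" else matrix.values.T
    n = data.shape[0]
    if n == 0:
        raise ValidationError("cannot cluster an empty axis")
    if n == 1:
        return np.empty((0, 4)), [0]
    Z = sch.linkage(data, method="ward", metric="euclidean")
    leaves = [int(i) for i in sch.leaves_list(Z)]
    return Z, leaves


# ---------------------------------------------------------------------------
# Kinome network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkEdge:
    """A predicted phosphorylation event, collapsed per (kinase, protein)."""

    source_kinase_family_id: str
    target_protein_id: str
    percentile: float  # max over this target's matched sites
    target_is_kinase: bool
    is_self_loop: bool = False
    target_site_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class KinomeNetwork:
    nodes: tuple[str, ...]
    edges: tuple[NetworkEdge, ...]
    threshold: float

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with percentile edge weights (kinase targets are
        represented by their family node; non-kinase targets by protein id)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(
                e.source_kinase_family_id,
                e.target_protein_id,
                percentile=e.percentile,
                target_is_kinase=e.target_is_kinase,
                self_loop=e.is_self_loop,
            )
        return g


def build_kinome_network(
    match_table: MatchTable,
    peptides: Sequence[PhosphoPeptide],
    catalog: KinaseCatalog,
    selected: Sequence[str] | None = None,
    threshold: float | None = None,
    include_nonkinase: bool = True,
) -> KinomeNetwork:
    """Reconstruct the kinase-substrate network from matches.

    Edges run from the matching kinase family to the protein owning the
    phosphosite, filtered at ``threshold`` (defaults to the match-table
    threshold; may be stricter). Multiple matched sites on one target
    collapse into a single edge carrying the maximum percentile, with the
    per-site positions retained on the edge. When ``selected`` kinase
    families are given, edges touching a selected family are kept — which
    pulls in non-selected kinases that phosphorylate a selected one — and
    everything else is dropped. Non-kinase targets require
    ``include_nonkinase``.
    """
    peptide_of = {p.peptide_id: p for p in peptides}
    if not any(p.protein_id for p in peptide_of.values()):
        raise ValidationError(
            "kinome network needs peptides with protein IDs; none present"
        )
    t = match_table.threshold if threshold is None else float(threshold)
    if not 0.0 <= t <= 100.0:
        raise ValidationError(f"network threshold {t} outside [0, 100]")

    selected_set = set(selected) if selected is not None else None
    if selected_set is not None:
        unknown = selected_set - set(catalog.family_ids)
        if unknown:
            raise ValidationError(
                f"selected kinases not in catalog: {sorted(unknown)}"
            )

    # site-level hits above the network threshold
    best: dict[tuple[str, str], float] = {}
    sites: dict[tuple[str, str], set[int]] = {}
    for r in match_table.results:
        if r.percentile < t:
            continue
        p = peptide_of.get(r.peptide_id)
        if p is None or p.protein_id is None:
            continue
        key = (r.kinase_family_id, p.protein_id)
        best[key] = max(best.get(key, 0.0), r.percentile)
        if p.site_position is not None:
            sites.setdefault(key, set()).add(p.site_position)

    edges: list[NetworkEdge] = []
    for (fid, prot), pct in sorted(best.items()):
        is_kinase = catalog.is_kinase_gene(prot)
        if not is_kinase and not include_nonkinase:
            continue
        target_families = catalog.families_of_gene(prot)
        if selected_set is not None:
            touches = fid in selected_set or bool(
                selected_set.intersection(target_families)
            )
            if not touches:
                continue
        edges.append(
            NetworkEdge(
                source_kinase_family_id=fid,
                target_protein_id=prot,
                percentile=pct,
                target_is_kinase=is_kinase,
                is_self_loop=prot in catalog[fid].family.member_gene_ids,
                target_site_positions=tuple(sorted(sites.get((fid, prot), ()))),
            )
        )

    nodes: set[str] = set()
    if selected_set is not None:
        nodes |= selected_set
    for e in edges:
        nodes.add(e.source_kinase_family_id)
        nodes.add(e.target_protein_id)
    logger.info(
        "kinome network at threshold %.4g: %d nodes, %d edges",
        t, len(nodes), len(edges),
    )
    return KinomeNetwork(
        nodes=tuple(sorted(nodes)), edges=tuple(edges), threshold=t
    )
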