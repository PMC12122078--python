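"""Percentile matrix, Ward clustering and kinome network reconstruction."""

from __future__ import annotations

import numpy as np
import pytest

import kinmatch as km
from kinmatch.downstream import MatchMatrix
from kinmatch.errors import ValidationError
from .conftest import make_uniform_pssm


class TestBuildMatchMatrix:
    def test_rows_and_columns_need_at_least_one_match(self, small_sim):
        matrix = km.build_match_matrix(small_sim["match_table"])
        table = small_sim["match_table"]
        matched_rows = {r.peptide_id for r in table.results if r.is_match}
        matched_cols = {r.kinase_family_id for r in table.results if r.is_match}
        assert set(matrix.row_ids) == matched_rows
        assert set(matrix.col_ids) == matched_cols
        assert matrix.values.min() >= 0 and matrix.values.max() <= 100

    def test_cells_equal_recomputed_percentiles(self, small_sim):
        matrix = km.build_match_matrix(small_sim["match_table"])
        peptide_of = {p.peptide_id: p for p in small_sim["peptides"]}
        catalog = small_sim["catalog"]
        backgrounds = small_sim["backgrounds"]
        rng = np.random.default_rng(0)
        for _ in range(50):
            i = int(rng.integers(len(matrix.row_ids)))
            j = int(rng.integers(len(matrix.col_ids)))
            if not matrix.scored_mask[i, j]:
                assert matrix.values[i, j] == 0.0  # class-incompatible fill
                continue
            p = peptide_of[matrix.row_ids[i]]
            fid = matrix.col_ids[j]
            score = km.score_peptide(catalog[fid].pssm, p.window)
            assert matrix.values[i, j] == km.percentile_of(
                score, backgrounds[fid]
            )

    def test_two_peptides_one_kinase(self):
        results = (
            km.MatchResult("p1", "A", 0.0, 95.0, True),
            km.MatchResult("p2", "A", 0.0, 92.0, True),
        )
        table = km.MatchTable(results, 90.0, frozenset({"p1", "p2"}),
                              frozenset())
        matrix = km.build_match_matrix(table)
        assert matrix.values.shape == (2, 1)

    def test_subthreshold_cells_kept_for_gradation(self):
        results = (
            km.MatchResult("p1", "A", 0.0, 95.0, True),
            km.MatchResult("p1", "B", 0.0, 50.0, False),
            km.MatchResult("p2", "B", 0.0, 91.0, True),
        )
        table = km.MatchTable(results, 90.0, frozenset({"p1", "p2"}),
                              frozenset())
        matrix = km.build_match_matrix(table)
        i, j = matrix.row_ids.index("p1"), matrix.col_ids.index("B")
        assert matrix.values[i, j] == 50.0

    def test_no_matches_fatal(self):
        table = km.MatchTable((), 90.0, frozenset(), frozenset({"p"}))
        with pytest.raises(ValidationError, match="no above-threshold"):
            km.build_match_matrix(table)


def matrix_from(values, prefix=("r", "c")):
    values = np.asarray(values, dtype=float)
    return MatchMatrix(
        row_ids=tuple(f"{prefix[0]}{i}" for i in range(values.shape[0])),
        col_ids=tuple(f"{prefix[1]}{j}" for j in range(values.shape[1])),
        values=values,
        scored_mask=np.ones_like(values, dtype=bool),
    )


class TestWardLinkage:
    def test_collinear_points_merge_nearest_pair_first(self):
        """1-D points {0, 1, 10}: Ward's objective joins {0,1} first."""
        Z, _ = km.ward_linkage(matrix_from([[0.0], [1.0], [10.0]]), "rows")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_identical_rows_merge_at_height_zero(self):
        Z, _ = km.ward_linkage(matrix_from([[5.0, 1.0], [5.0, 1.0],
                                            [50.0, 20.0]]), "rows")
        assert Z[0, 2] == 0.0

    def test_heights_non_decreasing_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            m = matrix_from(rng.uniform(0, 100, size=(rng.integers(3, 12),
                                                      rng.integers(2, 6))))
            Z, leaves = km.ward_linkage(m, "rows")
            assert np.all(np.diff(Z[:, 2]) >= 0)
            assert sorted(leaves) == list(range(len(m.row_ids)))

    def test_column_axis_clusters_transpose(self):
        m = matrix_from([[0.0, 0.1, 10.0], [0.0, 0.1, 10.0]])
        Z, _ = km.ward_linkage(m, "columns")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_single_item_axis_trivial_tree(self):
        m = matrix_from([[1.0, 2.0]])
        Z, leaves = km.ward_linkage(m, "rows")
        assert Z.shape == (0, 4) and leaves == [0]


def network_fixture():
    """Three S/T kinases A, B, C; peptides placing sites on their genes.

    A matches a site on B's protein at 95 and one on a non-kinase protein
    at 92; C matches a site on A's protein at 91; B matches its own
    protein at 99 (autophosphorylation).
    """
    pssms = [make_uniform_pssm(k) for k in "ABC"]
    catalog = km.build_kinase_set(km.passthrough_families(pssms), pssms)
    peptides = [
        km.PhosphoPeptide("p1", "AAAAASAAAA", "S", protein_id="B",
                          site_position=10),
        km.PhosphoPeptide("p2", "AAAAATAAAA", "T", protein_id="prot1",
                          site_position=20),
        km.PhosphoPeptide("p3", "CCCCCSCCCC", "S", protein_id="A",
                          site_position=30),
        km.PhosphoPeptide("p4", "DDDDDSDDDD", "S", protein_id="B",
                          site_position=40),
    ]
    results = (
        km.MatchResult("p1", "A", 0.0, 95.0, True),
        km.MatchResult("p2", "A", 0.0, 92.0, True),
        km.MatchResult("p3", "C", 0.0, 91.0, True),
        km.MatchResult("p4", "B", 0.0, 99.0, True),
        km.MatchResult("p4", "A", 0.0, 45.0, False),
    )
    matched = frozenset({"p1", "p2", "p3", "p4"})
    table = km.MatchTable(results, 90.0, matched, frozenset())
    return catalog, peptides, table


class TestKinomeNetwork:
    def test_edges_and_kinase_flags(self):
        catalog, peptides, table = network_fixture()
        net = km.build_kinome_network(table, peptides, catalog)
        edges = {(e.source_kinase_family_id, e.target_protein_id): e
                 for e in net.edges}
        assert set(edges) == {("A", "B"), ("A", "prot1"), ("C", "A"),
                              ("B", "B")}
        assert edges[("A", "B")].target_is_kinase
        assert not edges[("A", "prot1")].target_is_kinase
        assert edges[("B", "B")].is_self_loop

    def test_multiple_sites_collapse_to_max_percentile(self):
        catalog, peptides, table = network_fixture()
        extra = table.results + (km.MatchResult("p4b", "A", 0.0, 97.0, True),)
        peptides = peptides + [
            km.PhosphoPeptide("p4b", "EEEEESEEEE", "S", protein_id="B",
                              site_position=50)
        ]
        table = km.MatchTable(extra, 90.0,
                              table.matched_peptide_ids | {"p4b"}, frozenset())
        net = km.build_kinome_network(table, peptides, catalog)
        edge = next(e for e in net.edges
                    if (e.source_kinase_family_id, e.target_protein_id) == ("A", "B"))
        assert edge.percentile == 97.0
        assert edge.target_site_positions == (10, 50)

    def test_edge_set_monotone_in_threshold(self):
        catalog, peptides, table = network_fixture()
        def edge_set(t):
            net = km.build_kinome_network(table, peptides, catalog, threshold=t)
            return {(e.source_kinase_family_id, e.target_protein_id)
                    for e in net.edges}
        assert edge_set(99.0) <= edge_set(95.0) <= edge_set(90.0)

    def test_upstream_kinase_added_for_selected_target(self):
        """A non-selected kinase enters the network by phosphorylating a
        selected one."""
        catalog, peptides, table = network_fixture()
        net = km.build_kinome_network(table, peptides, catalog, selected=["B"])
        assert "A" in net.nodes          # A targets selected B
        pairs = {(e.source_kinase_family_id, e.target_protein_id)
                 for e in net.edges}
        assert ("A", "B") in pairs and ("B", "B") in pairs
        assert ("C", "A") not in pairs   # touches neither selected kinase

    def test_nonkinase_targets_toggle(self):
        catalog, peptides, table = network_fixture()
        net = km.build_kinome_network(table, peptides, catalog,
                                      include_nonkinase=False)
        assert all(e.target_is_kinase for e in net.edges)

    def test_every_edge_backed_by_a_match(self, small_sim):
        table = small_sim["match_table"]
        net = km.build_kinome_network(table, small_sim["peptides"],
                                      small_sim["catalog"])
        prot_of = {p.peptide_id: p.protein_id for p in small_sim["peptides"]}
        for e in net.edges:
            assert any(
                r.kinase_family_id == e.source_kinase_family_id
                and prot_of.get(r.peptide_id) == e.target_protein_id
                and r.percentile >= net.threshold
                for r in table.results
            )

    def test_no_protein_ids_fatal(self):
        catalog, _, table = network_fixture()
        bare = [km.PhosphoPeptide("p1", "AAAAASAAAA", "S")]
        with pytest.raises(ValidationError, match="protein ID"):
            km.build_kinome_network(table, bare, catalog)

    def test_to_networkx_carries_percentiles(self):
        catalog, peptides, table = network_fixture()
        g = km.build_kinome_network(table, peptides, catalog).to_networkx()
        assert g.edges[("A", "B")]["percentile"] == 95.0
        assert g.is_directed()
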