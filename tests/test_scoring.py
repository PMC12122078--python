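"""PSSM scoring, background percentiles and match calling."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinmatch as km
from kinmatch.errors import ValidationError
from kinmatch.io_formats import AA_INDEX, AMINO_ACIDS, FLANK_OFFSETS, FLANK_SLOTS
from kinmatch.scoring import percentiles_of
from .conftest import make_catalog, make_uniform_pssm, random_window


def product_score(pssm, window, use_favorability=True):
    """Direct product-space oracle for the PSSM score."""
    prod = 1.0
    for row, slot in enumerate(FLANK_SLOTS):
        aa = window[slot]
        if aa in AA_INDEX:
            prod *= pssm.flank_weights[row, AA_INDEX[aa]]
    if pssm.kinase_class == "ST" and use_favorability:
        total = pssm.w0_s + pssm.w0_t
        prod *= (pssm.w0_s if window[5] == "S" else pssm.w0_t) / total
    return prod


class TestScorePeptide:
    def test_uniform_pssm_scores_zero_without_favorability(self):
        pssm = make_uniform_pssm()
        assert km.score_peptide(pssm, "ACDEFSTVWY", use_favorability=False) == 0.0

    def test_equal_favorability_gives_log_half(self):
        pssm = make_uniform_pssm()
        score = km.score_peptide(pssm, "ACDEFSTVWY", use_favorability=True)
        assert score == pytest.approx(math.log(0.5), abs=1e-12)

    def test_neutral_symbols_contribute_nothing(self):
        pssm = km.gen_pssm(km.SimConfig(seed=9))[0]
        full = km.score_peptide(pssm, "ACDEFSTVWY")
        padded = km.score_peptide(pssm, "_CDEFSTVW_")
        expected = full - math.log(pssm.flank_weights[0, AA_INDEX["A"]]) \
            - math.log(pssm.flank_weights[8, AA_INDEX["Y"]])
        assert padded == pytest.approx(expected, rel=1e-12)

    def test_class_acceptor_mismatch_is_fatal_at_scoring_level(self):
        with pytest.raises(ValidationError, match="incompatible"):
            km.score_peptide(make_uniform_pssm(), "ACDEFYTVWY")

    @given(st.integers(0, 2**31 - 1), st.integers(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_exp_log_score_matches_product_oracle(self, seed, n_pad):
        rng = np.random.default_rng(seed)
        cfg = km.SimConfig(seed=seed % 2**31, n_kinases_st=1, n_kinases_y=1)
        pssm = km.gen_pssm(cfg)[rng.integers(2)]
        acceptor = "Y" if pssm.kinase_class == "Y" else ("S", "T")[rng.integers(2)]
        window = random_window(rng, acceptor=acceptor, n_pad=n_pad)
        fav = bool(rng.integers(2))
        log_score = km.score_peptide(pssm, window, use_favorability=fav)
        assert math.exp(log_score) == pytest.approx(
            product_score(pssm, window, fav), rel=1e-9
        )


class TestBackground:
    def test_identical_windows_identical_scores(self):
        pssm = make_uniform_pssm()
        bg = km.compute_background(pssm, ["ACDEFSTVWY"] * 150, min_n=100)
        assert bg.n == 150
        assert np.all(bg.sorted_log_scores == bg.sorted_log_scores[0])

    def test_sorted_multiset_invariant_to_permutation(self):
        rng = np.random.default_rng(1)
        windows = [random_window(rng, acceptor="S") for _ in range(200)]
        pssm = km.gen_pssm(km.SimConfig(seed=2))[0]
        a = km.compute_background(pssm, windows)
        b = km.compute_background(pssm, windows[::-1])
        np.testing.assert_array_equal(a.sorted_log_scores, b.sorted_log_scores)

    def test_incompatible_windows_skipped_and_counted(self):
        rng = np.random.default_rng(2)
        windows = [random_window(rng, acceptor="S") for _ in range(120)] + [
            random_window(rng, acceptor="Y") for _ in range(30)
        ]
        bg = km.compute_background(make_uniform_pssm(), windows, min_n=100)
        assert (bg.n, bg.n_skipped) == (120, 30)

    def test_below_floor_is_fatal_with_counts(self):
        rng = np.random.default_rng(3)
        windows = [random_window(rng, acceptor="Y") for _ in range(150)]
        with pytest.raises(ValidationError, match="only 0 compatible"):
            km.compute_background(make_uniform_pssm(), windows, min_n=100)


class TestPercentile:
    def bg(self, scores):
        return km.BackgroundDistribution("K", "ST", np.sort(scores))

    def test_boundaries(self):
        bg = self.bg(np.arange(1000, dtype=float))
        assert km.percentile_of(1e9, bg) == 100.0
        assert km.percentile_of(0.0, bg) == 0.0   # equal to the minimum
        assert km.percentile_of(-5.0, bg) == 0.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_binary_search_equals_linear_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 2000))
        scores = np.round(rng.normal(size=n), 2)  # rounding forces ties
        bg = self.bg(scores)
        q = float(rng.choice(np.concatenate([scores, rng.normal(size=10)])))
        brute = 100.0 * np.sum(scores < q) / n
        assert km.percentile_of(q, bg) == brute

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_percentile_monotone_in_score(self, seed):
        rng = np.random.default_rng(seed)
        bg = self.bg(rng.normal(size=500))
        qs = np.sort(rng.normal(size=50))
        pcts = [km.percentile_of(q, bg) for q in qs]
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=400)
        q = rng.normal(size=30)
        for f in (lambda x: 3.0 * x + 2.0, lambda x: x ** 3):
            bg_raw = self.bg(scores)
            bg_t = self.bg(f(np.sort(scores)))
            for x in q:
                assert km.percentile_of(x, bg_raw) == km.percentile_of(
                    f(x), bg_t
                )


class TestMatchPeptides:
    def make_study(self, seed=21, threshold=90.0):
        cfg = km.SimConfig(seed=seed, n_background=800, n_null_peptides=120,
                           n_planted=30)
        pssms = km.gen_pssm(cfg)
        catalog = make_catalog(pssms)
        backgrounds = km.compute_backgrounds(catalog, km.gen_background_sites(cfg))
        rng = np.random.default_rng(seed)
        peptides = [
            km.PhosphoPeptide(f"p{i}", w := random_window(rng), w[5])
            for i in range(60)
        ]
        return peptides, catalog, backgrounds, km.match_peptides(
            peptides, catalog, backgrounds, threshold=threshold
        )

    def test_empty_catalog_fatal(self, small_sim):
        with pytest.raises(ValidationError, match="catalog"):
            km.match_peptides(small_sim["peptides"],
                              km.KinaseCatalog({}), {})

    def test_threshold_zero_matches_every_compatible_pair(self):
        _, _, _, table = self.make_study(threshold=0.0)
        assert all(r.is_match for r in table.results)
        assert not table.unmatched_peptide_ids

    def test_threshold_100_requires_outscoring_entire_background(self):
        peptides, catalog, backgrounds, _ = self.make_study()
        table = km.match_peptides(peptides, catalog, backgrounds,
                                  threshold=100.0)
        for r in table.results:
            bg = backgrounds[r.kinase_family_id]
            assert r.is_match == (r.log_score > bg.sorted_log_scores[-1])

    def test_class_segregation(self, small_sim):
        acceptor_of = {p.peptide_id: p.acceptor for p in small_sim["peptides"]}
        catalog = small_sim["catalog"]
        for r in small_sim["match_table"].results:
            kclass = catalog[r.kinase_family_id].kinase_class
            assert (kclass == "Y") == (acceptor_of[r.peptide_id] == "Y")

    def test_self_background_match_fraction_is_one_tenth(self):
        cfg = km.SimConfig(seed=33, n_kinases_st=1, n_kinases_y=1,
                           n_background=2000)
        pssm = km.gen_pssm(cfg)[0]
        windows = km.gen_background_sites(cfg)["ST"]
        bg = km.compute_background(pssm, windows)
        assert np.unique(bg.sorted_log_scores).size == bg.n  # distinct scores
        pcts = percentiles_of(bg.sorted_log_scores, bg)
        assert np.sum(pcts >= 90.0) == bg.n // 10

    def test_planted_windows_match_their_kinase(self, small_sim):
        """Windows sampled from a sharp PSSM profile are recognised by it."""
        truth = small_sim["truth_df"]
        planted_ids = set(truth.loc[truth.is_planted == "true", "peptide_id"])
        fam = "g_stk1"  # family inheriting the planted kinase's PSSM
        hits = {
            r.peptide_id
            for r in small_sim["match_table"].results
            if r.kinase_family_id == fam and r.is_match
        }
        rate = len(hits & planted_ids) / len(planted_ids)
        assert rate >= 0.8

    def test_unmatched_peptides_flagged(self, small_sim):
        table = small_sim["match_table"]
        ids = {p.peptide_id for p in small_sim["peptides"]}
        assert table.matched_peptide_ids | table.unmatched_peptide_ids == ids
        assert not table.matched_peptide_ids & table.unmatched_peptide_ids
        for pid in table.unmatched_peptide_ids:
            assert not any(
                r.is_match for r in table.results if r.peptide_id == pid
            )
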