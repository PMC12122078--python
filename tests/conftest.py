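"""Shared fixtures: small synthetic study sets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import kinmatch as km
from kinmatch.io_formats import AMINO_ACIDS, ST_CLASS, Y_CLASS


def make_uniform_pssm(kinase_id: str = "UNI", kinase_class: str = ST_CLASS,
                      w0_s: float = 1.0, w0_t: float = 1.0) -> km.PSSM:
    """PSSM with every flank weight 1 (log-score contribution 0)."""
    weights = np.ones((9, 20))
    if kinase_class == ST_CLASS:
        return km.PSSM(kinase_id, ST_CLASS, weights, w0_s=w0_s, w0_t=w0_t)
    return km.PSSM(kinase_id, Y_CLASS, weights)


def make_catalog(pssms) -> km.KinaseCatalog:
    """Human-passthrough catalog over the given PSSMs."""
    return km.build_kinase_set(km.passthrough_families(pssms), pssms)


def peptides_from_df(df) -> list[km.PhosphoPeptide]:
    out = []
    for r in df.itertuples():
        out.append(km.PhosphoPeptide(
            peptide_id=r.peptide_id, window=r.sequence, acceptor=r.sequence[5],
            protein_id=getattr(r, "protein_id", None),
            site_position=getattr(r, "site_position", None),
            log2fc=getattr(r, "log2fc", None),
            pvalue=getattr(r, "pvalue", None),
        ))
    return out


def random_window(rng: np.random.Generator, acceptor: str | None = None,
                  n_pad: int = 0) -> str:
    """Random 10-mer with the given acceptor and n_pad padded flank slots."""
    flanks = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=9)]
    for slot in rng.choice(9, size=n_pad, replace=False):
        flanks[slot] = "_"
    acc = acceptor or "STY"[rng.integers(3)]
    return "".join(flanks[:5]) + acc + "".join(flanks[5:])


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated study shared by read-only tests."""
    cfg = km.SimConfig(seed=7, n_background=1000, n_null_peptides=300,
                       n_planted=30)
    pssms = km.gen_pssm(cfg)
    families = km.collapse_families(km.gen_ortholog_table(cfg), "one_to_one")
    catalog = km.build_kinase_set(families, pssms)
    backgrounds = km.compute_backgrounds(catalog, km.gen_background_sites(cfg))
    peptide_df, truth_df = km.gen_experiment(cfg, pssms)
    peptides = peptides_from_df(peptide_df)
    match_table = km.match_peptides(peptides, catalog, backgrounds)
    return {
        "config": cfg, "pssms": pssms, "catalog": catalog,
        "backgrounds": backgrounds, "peptide_df": peptide_df,
        "truth_df": truth_df, "peptides": peptides,
        "match_table": match_table,
    }


@pytest.fixture()
def sim_dir(tmp_path):
    """Simulation written to disk for file-based tests."""
    cfg = km.SimConfig(seed=11, n_background=600, n_null_peptides=150,
                       n_planted=20)
    paths = km.write_simulation(cfg, tmp_path / "sim")
    return cfg, paths
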