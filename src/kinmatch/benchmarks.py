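"""Self-check benchmarks: statistical and numerical validation runs.

Each function builds its own synthetic inputs, runs the corresponding part
of the pipeline from scratch and returns a measured quantity: a
self-consistency percentage, an oracle disagreement count, an empirical
error rate, or a recovery rate. They are reused by the repository's
validation script and the test suite.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import (
    SimConfig,
    build_kinase_set,
    collapse_families,
    compute_background,
    compute_backgrounds,
    gen_background_sites,
    gen_experiment,
    gen_ortholog_table,
    gen_pssm,
    infer_activity,
    match_peptides,
    percentile_of,
    score_peptide,
    write_simulation,
)
from .downstream import MatchMatrix, build_kinome_network, ward_linkage
from .io_formats import AA_INDEX, FLANK_SLOTS, PhosphoPeptide, ST_CLASS
from .pipeline import RunConfig, run_pipeline
from .scoring import BackgroundDistribution, MatchResult, MatchTable, percentiles_of
from .synthetic import sample_windows_from_pssm

_MOD = 2**31  # keep derived seeds within a signed 32-bit range


def _seed(base: int, tag: int, rep: int = 0) -> int:
    return (base * 1_000_003 + tag * 7919 + rep) % _MOD


def run_study(cfg: SimConfig, orthology_mode: str = "one_to_one"):
    """Full in-memory synthetic study: simulate, build catalog, match."""
    pssms = gen_pssm(cfg)
    families = collapse_families(gen_ortholog_table(cfg), orthology_mode)
    catalog = build_kinase_set(families, pssms)
    backgrounds = compute_backgrounds(catalog, gen_background_sites(cfg))
    peptide_df, truth_df = gen_experiment(cfg, pssms)
    peptides = [
        PhosphoPeptide(
            peptide_id=r.peptide_id, window=r.sequence, acceptor=r.sequence[5],
            protein_id=r.protein_id, site_position=r.site_position,
            log2fc=r.log2fc, pvalue=r.pvalue,
        )
        for r in peptide_df.itertuples()
    ]
    match_table = match_peptides(peptides, catalog, backgrounds)
    return {
        "pssms": pssms, "catalog": catalog, "backgrounds": backgrounds,
        "peptides": peptides, "truth": truth_df, "match_table": match_table,
    }


def background_self_match_percent(seed: int, n_background: int = 10_000) -> float:
    """Score a background against itself; percent called at threshold 90.

    With distinct scores and the strict-below percentile, exactly the top
    tenth of the background reaches the 90th percentile.
    """
    cfg = SimConfig(seed=_seed(seed, 1), n_kinases_st=1, n_kinases_y=1,
                    n_background=n_background)
    pssm = gen_pssm(cfg)[0]
    windows = gen_background_sites(cfg)[ST_CLASS]
    bg = compute_background(pssm, windows)
    if np.unique(bg.sorted_log_scores).size != bg.n:
        raise RuntimeError("background scores unexpectedly tied")
    pcts = percentiles_of(bg.sorted_log_scores, bg)
    return 100.0 * float(np.mean(pcts >= 90.0))


def percentile_oracle_mismatches(seed: int, n_instances: int = 1000) -> int:
    """Binary-search percentile vs brute-force strict-below count."""
    rng = np.random.default_rng(_seed(seed, 2))
    mismatches = 0
    for _ in range(n_instances):
        n = int(rng.integers(100, 3000))
        scores = np.round(rng.normal(size=n), 2)  # rounding creates ties
        bg = BackgroundDistribution("K", ST_CLASS, np.sort(scores))
        q = float(rng.choice(np.concatenate([scores, rng.normal(size=5)])))
        brute = 100.0 * int(np.sum(scores < q)) / n
        if percentile_of(q, bg) != brute:
            mismatches += 1
    return mismatches


def score_product_max_rel_err(seed: int, n_pairs: int = 1000) -> float:
    """exp(log-score) vs the direct product of PSSM weights."""
    rng = np.random.default_rng(_seed(seed, 3))
    worst = 0.0
    for rep in range(n_pairs):
        if rep % 50 == 0:
            cfg = SimConfig(seed=_seed(seed, 3, rep), n_kinases_st=2,
                            n_kinases_y=1)
            pssms = gen_pssm(cfg)
        pssm = pssms[int(rng.integers(len(pssms)))]
        if pssm.kinase_class == ST_CLASS:
            acc = "ST"[int(rng.integers(2))]
        else:
            acc = "Y"
        window = sample_windows_from_pssm(pssm, 1, rng)[0]
        window = window[:5] + acc + window[6:]
        fav = bool(rng.integers(2))
        log_score = score_peptide(pssm, window, use_favorability=fav)
        prod = 1.0
        for row, slot in enumerate(FLANK_SLOTS):
            prod *= pssm.flank_weights[row, AA_INDEX[window[slot]]]
        if pssm.kinase_class == ST_CLASS and fav:
            total = pssm.w0_s + pssm.w0_t
            prod *= (pssm.w0_s if acc == "S" else pssm.w0_t) / total
        worst = max(worst, abs(np.exp(log_score) - prod) / prod)
    return float(worst)


def ztest_null_rejection_rate(
    seed: int,
    n_peptides: int = 2000,
    m: int = 10,
    n_reps: int = 1000,
    alpha: float = 0.05,
    reps_per_dataset: int = 50,
) -> float:
    """Type-I error of the activity z-test on null data.

    Independent standard-normal log2FC; each replicate tests one random
    size-``m`` substrate set. Replicates are grouped into independent
    datasets so the empirical rate carries (almost) pure binomial noise.
    """
    rng = np.random.default_rng(_seed(seed, 4))
    from .activity import kinase_zscore

    hits = total = 0
    n_datasets = n_reps // reps_per_dataset
    for _ in range(n_datasets):
        fc = rng.normal(size=n_peptides)
        peptides = [
            PhosphoPeptide(f"p{i}", "AAAAASAAAA", "S", log2fc=float(x))
            for i, x in enumerate(fc)
        ]
        results = []
        for j in range(reps_per_dataset):
            for i in rng.choice(n_peptides, size=m, replace=False):
                results.append(MatchResult(f"p{i}", f"K{j:03d}", 0.0, 95.0, True))
        table = MatchTable(
            results=tuple(results), threshold=90.0,
            matched_peptide_ids=frozenset(r.peptide_id for r in results),
            unmatched_peptide_ids=frozenset(),
        )
        for act in kinase_zscore(table, peptides, min_substrates=1):
            total += 1
            hits += act.p_one_sided <= alpha
    return hits / total


def planted_recovery_rate(seed: int, n_reps: int = 100,
                          fdr: float = 0.10) -> float:
    """Fraction of replicates where the planted kinase reaches BH p <= fdr.

    Study conditions: the generator defaults (delta 1, sigma 1, 50 planted
    among 2000 null peptides, concentration 0.1).
    """
    hits = 0
    for rep in range(n_reps):
        study = run_study(SimConfig(seed=_seed(seed, 5, rep)))
        activities = infer_activity(study["match_table"], study["peptides"],
                                    fdr=fdr)
        by_id = {a.kinase_family_id: a for a in activities}
        planted_family = "g_stk1"
        a = by_id.get(planted_family)
        if a is not None and a.p_adj <= fdr:
            hits += 1
    return hits / n_reps


def ward_height_violations(seed: int, n_matrices: int = 100) -> int:
    """Count Ward merge tables with decreasing heights (expected 0)."""
    rng = np.random.default_rng(_seed(seed, 6))
    violations = 0
    for _ in range(n_matrices):
        values = rng.uniform(0, 100, size=(int(rng.integers(3, 15)),
                                           int(rng.integers(2, 8))))
        m = MatchMatrix(
            row_ids=tuple(f"r{i}" for i in range(values.shape[0])),
            col_ids=tuple(f"c{j}" for j in range(values.shape[1])),
            values=values,
            scored_mask=np.ones_like(values, dtype=bool),
        )
        Z, _ = ward_linkage(m, "rows")
        if np.any(np.diff(Z[:, 2]) < 0):
            violations += 1
    return violations


def network_threshold_violations(seed: int, strict: float = 99.0,
                                 loose: float = 90.0) -> tuple[int, int]:
    """Edges present at the strict threshold but absent at the loose one.

    Returns ``(violations, n_strict_edges)``; monotonicity demands 0.
    """
    study = run_study(SimConfig(seed=_seed(seed, 7)))
    def edge_set(t):
        net = build_kinome_network(study["match_table"], study["peptides"],
                                   study["catalog"], threshold=t)
        return {(e.source_kinase_family_id, e.target_protein_id)
                for e in net.edges}
    strict_edges = edge_set(strict)
    loose_edges = edge_set(loose)
    return len(strict_edges - loose_edges), len(strict_edges)


def pipeline_determinism_mismatches(seed: int,
                                    work_dir: str | Path | None = None) -> tuple[int, int]:
    """Run the full file-based pipeline twice; count differing outputs.

    Returns ``(mismatched_files, files_compared)``.
    """
    ctx = (tempfile.TemporaryDirectory() if work_dir is None else None)
    base = Path(ctx.name) if ctx else Path(work_dir)
    try:
        cfg = SimConfig(seed=_seed(seed, 8), n_background=1000,
                        n_null_peptides=300, n_planted=30)
        paths = write_simulation(cfg, base / "sim")
        outs = []
        for run in ("run1", "run2"):
            run_pipeline(RunConfig(
                peptide_table=paths["peptides"], pssm_table=paths["pssms"],
                background_st=paths["background_st"],
                background_y=paths["background_y"],
                ortholog_table=paths["orthologs"], out_dir=base / run,
            ))
            outs.append(sorted((base / run).iterdir()))
        names1 = [p.name for p in outs[0]]
        names2 = [p.name for p in outs[1]]
        if names1 != names2:
            return max(len(names1), len(names2)), max(len(names1), len(names2))
        mismatched = sum(
            a.read_bytes() != b.read_bytes() for a, b in zip(*outs)
        )
        return mismatched, len(names1)
    finally:
        if ctx:
            ctx.cleanup()
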