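"""Kinase-activity inference from substrate fold changes (KSEA z-test).

For each kinase family with at least ``min_substrates`` matched,
quantified substrates, the activity statistic compares the mean log2
fold-change of its predicted substrates with the mean over the analysed
population:

    z = (mean_fc(substrates) - mean_fc(all)) * sqrt(m) / sd(all)

where ``m`` is the substrate count and ``sd`` is the population standard
deviation (denominator ``n``) of the log2FC over *all* quantified peptides
in the experiment, which is the reference population of the KSEA z
statistic. Substrate sets themselves only ever contain matched peptides;
sequences below threshold for every kinase contribute to the reference
population but can never be substrates.

The reported one-sided p-value is the upper-tail probability
``p = 1 - Phi(z)``, i.e. it tests for *increased* substrate
phosphorylation (kinase activation); ``direction`` carries the sign of z
so inhibition shows up as a direction of -1 with p near 1. The fixed tail
keeps the p-value uniform under the null hypothesis, which a
direction-of-observed-effect p-value would not be. Multiple-testing
correction across the tested families uses Benjamini-Hochberg step-up at
a configurable FDR (default 0.10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import PhosphoPeptide
from .scoring import MatchTable

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.10
DEFAULT_MIN_SUBSTRATES = 3

_P_FLOOR = 1e-300  # keep p strictly positive for downstream -log10


@dataclass(frozen=True)
class KinaseActivity:
    """Activity statistics of one kinase family."""

    kinase_family_id: str
    m: int
    mean_fc: float
    z: float
    p_one_sided: float
    direction: int
    p_adj: float = float("nan")
    significant: bool = False


def kinase_zscore(
    match_table: MatchTable,
    peptides: Sequence[PhosphoPeptide],
    min_substrates: int = DEFAULT_MIN_SUBSTRATES,
) -> list[KinaseActivity]:
    """Per-family z statistics and raw one-sided p-values (no correction).

    Families with fewer than ``min_substrates`` matched quantified
    peptides are excluded (logged); they stay in the match table but are
    not tested.
    """
    fc_of = {
        p.peptide_id: p.log2fc for p in peptides if p.log2fc is not None
    }
    if len(fc_of) < 2:
        raise ValidationError(
            "activity analysis needs at least 2 peptides with log2FC; "
            f"found {len(fc_of)}"
        )
    # fixed aggregation order: results are exactly permutation-invariant
    population = np.array([fc_of[pid] for pid in sorted(fc_of)])
    mu = float(population.mean())
    sd = float(population.std(ddof=0))
    if sd == 0.0:
        raise ValidationError(
            "log2FC of analysed peptides has zero variance; z-test undefined"
        )

    substrate_ids: dict[str, set[str]] = {}
    for r in match_table.results:
        if r.is_match and r.peptide_id in fc_of:
            substrate_ids.setdefault(r.kinase_family_id, set()).add(r.peptide_id)
    substrate_fc = {
        fid: [fc_of[pid] for pid in sorted(ids)]
        for fid, ids in substrate_ids.items()
    }

    activities: list[KinaseActivity] = []
    n_excluded = 0
    for fid in sorted(substrate_fc):
        values = substrate_fc[fid]
        m = len(values)
        if m < min_substrates:
            n_excluded += 1
            logger.info(
                "kinase %s excluded from activity test: %d < %d quantified "
                "substrates", fid, m, min_substrates,
            )
            continue
        mean_fc = float(np.mean(values))
        z = (mean_fc - mu) * np.sqrt(m) / sd
        p = float(np.clip(norm.sf(z), _P_FLOOR, 1.0))
        activities.append(
            KinaseActivity(
                kinase_family_id=fid,
                m=m,
                mean_fc=mean_fc,
                z=float(z),
                p_one_sided=p,
                direction=int(np.sign(z)) if z != 0 else 0,
            )
        )
    if not activities:
        logger.warning(
            "no kinase passed the min_substrates=%d floor; empty activity result",
            min_substrates,
        )
    return activities


def bh_adjust(
    p_values: Sequence[float], q: float = DEFAULT_FDR
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment with significance flags.

    Returns ``(adjusted, significant)`` in the original order, with
    ``significant = adjusted <= q``.
    """
    if not 0.0 < q < 1.0:
        raise ValidationError(f"FDR threshold {q} outside (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def infer_activity(
    match_table: MatchTable,
    peptides: Sequence[PhosphoPeptide],
    fdr: float = DEFAULT_FDR,
    min_substrates: int = DEFAULT_MIN_SUBSTRATES,
) -> list[KinaseActivity]:
    """Full activity analysis: z-test per family, then BH correction."""
    activities = kinase_zscore(match_table, peptides, min_substrates)
    if not activities:
        return []
    p_adj, flags = bh_adjust([a.p_one_sided for a in activities], q=fdr)
    return [
        replace(a, p_adj=float(adj), significant=bool(sig))
        for a, adj, sig in zip(activities, p_adj, flags)
    ]
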