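"""PSSM scoring of phosphosite windows and empirical percentile matching.

A kinase's fit to a 10-residue phosphosite window is the product of its
PSSM weights at the flank positions (-5..-1, +1..+4), multiplied by a
central phosphoacceptor term. For serine/threonine kinases the central
term is the *favorability* ratio ``w0_S / (w0_S + w0_T)`` (or the T
counterpart), expressing the kinase's relative preference for serine
versus threonine at position 0; tyrosine kinases have no central
preference and their central factor is 1. Padded or unknown flank symbols
contribute a neutral factor of 1.

Scores are computed and stored in natural-log space: a product of nine
weights that are individually far below one underflows quickly, while the
percentile step only consumes ranks, which the (monotone) log transform
preserves.

Raw scores are not comparable between kinases, so each kinase's score is
ranked against that kinase's *background distribution* — its PSSM applied
to a large reference set of phosphosites of the matching class. The
percentile is the strict-below rank ``100 * #{background < score} / n``;
a peptide is called a target of the kinase when its percentile reaches the
match threshold (default 90, i.e. the top 10 percent of the background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import (
    CENTER,
    FLANK_SLOTS,
    NEUTRAL_INDEX,
    PSSM,
    PhosphoPeptide,
    ST_CLASS,
    Y_CLASS,
    windows_to_indices,
)
from .orthology import KinaseCatalog

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 90.0
#: Minimum number of compatible background sites for usable percentiles.
DEFAULT_MIN_BACKGROUND = 100

_FLANK_SLOTS = np.array(FLANK_SLOTS, dtype=np.intp)
_ROW_INDEX = np.arange(len(FLANK_SLOTS), dtype=np.intp)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Sorted log-scores of one kinase's PSSM over its class background."""

    kinase_id: str
    kinase_class: str
    sorted_log_scores: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.sorted_log_scores, dtype=float)
        object.__setattr__(self, "sorted_log_scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValidationError(
                f"background for {self.kinase_id!r} must be a non-empty vector"
            )
        if np.any(np.diff(scores) < 0):
            raise ValidationError(
                f"background for {self.kinase_id!r} is not sorted ascending"
            )

    @property
    def n(self) -> int:
        return int(self.sorted_log_scores.size)


@dataclass(frozen=True)
class MatchResult:
    """One scored (peptide, kinase family) pair."""

    peptide_id: str
    kinase_family_id: str
    log_score: float
    percentile: float
    is_match: bool


@dataclass(frozen=True)
class MatchTable:
    """All scored pairs of a run, plus bookkeeping the pipeline reports."""

    results: tuple[MatchResult, ...]
    threshold: float
    matched_peptide_ids: frozenset[str]
    unmatched_peptide_ids: frozenset[str]
    n_skipped_pairs: int = 0

    @property
    def matches(self) -> list[MatchResult]:
        return [r for r in self.results if r.is_match]


def _compatible(kinase_class: str, acceptor: str) -> bool:
    return (kinase_class == Y_CLASS) == (acceptor == "Y")


def _log_weight_table(pssm: PSSM) -> np.ndarray:
    """(9, 21) log-weight table with a zero column for neutral symbols."""
    table = np.zeros((len(FLANK_SLOTS), NEUTRAL_INDEX + 1))
    table[:, :NEUTRAL_INDEX] = np.log(pssm.flank_weights)
    return table


def _central_log_terms(
    pssm: PSSM, acceptors: np.ndarray, use_favorability: bool
) -> np.ndarray:
    """Per-window log of the central phosphoacceptor factor."""
    if pssm.kinase_class != ST_CLASS or not use_favorability:
        return np.zeros(acceptors.shape[0])
    total = pssm.w0_s + pssm.w0_t
    log_s = np.log(pssm.w0_s / total)
    log_t = np.log(pssm.w0_t / total)
    return np.where(acceptors == "S", log_s, log_t)


def score_windows(
    pssm: PSSM, windows: Sequence[str], use_favorability: bool = True
) -> np.ndarray:
    """Vectorised log-scores of many windows against one PSSM.

    Every window's acceptor must be compatible with the PSSM class
    (S/T for ST kinases, Y for Y kinases).
    """
    if len(windows) == 0:
        return np.empty(0)
    acceptors = np.array([w[CENTER] for w in windows])
    ok = np.array([_compatible(pssm.kinase_class, a) for a in acceptors])
    if not ok.all():
        bad = windows[int(np.argmin(ok))]
        raise ValidationError(
            f"window {bad!r} acceptor incompatible with {pssm.kinase_class} "
            f"kinase {pssm.kinase_id!r}"
        )
    idx = windows_to_indices(windows)[:, _FLANK_SLOTS]
    table = _log_weight_table(pssm)
    flank = table[_ROW_INDEX[None, :], idx].sum(axis=1)
    return flank + _central_log_terms(pssm, acceptors, use_favorability)


def score_peptide(pssm: PSSM, window: str, use_favorability: bool = True) -> float:
    """Log-score of a single normalised 10-mer window against one PSSM."""
    return float(score_windows(pssm, [window], use_favorability)[0])


def compute_background(
    pssm: PSSM,
    background_windows: Sequence[str],
    use_favorability: bool = True,
    min_n: int = DEFAULT_MIN_BACKGROUND,
) -> BackgroundDistribution:
    """Score a class background set and return the sorted distribution.

    Windows whose acceptor does not fit the PSSM class are skipped and
    counted; fewer than ``min_n`` compatible windows is fatal.
    """
    compatible = [
        w for w in background_windows if _compatible(pssm.kinase_class, w[CENTER])
    ]
    n_skipped = len(background_windows) - len(compatible)
    if len(compatible) < min_n:
        raise ValidationError(
            f"background for kinase {pssm.kinase_id!r}: only {len(compatible)} "
            f"compatible windows of {len(background_windows)} "
            f"(floor {min_n}); {n_skipped} skipped"
        )
    scores = np.sort(score_windows(pssm, compatible, use_favorability))
    return BackgroundDistribution(
        kinase_id=pssm.kinase_id,
        kinase_class=pssm.kinase_class,
        sorted_log_scores=scores,
        n_skipped=n_skipped,
    )


def percentile_of(log_score: float, bg: BackgroundDistribution) -> float:
    """Strict-below empirical percentile of a score in a background.

    ``100 * #{background scores < log_score} / n``, found by binary search
    on the sorted score vector. A score above the whole background gives
    100.0; a score at or below the minimum gives 0.0.
    """
    below = int(np.searchsorted(bg.sorted_log_scores, log_score, side="left"))
    return 100.0 * below / bg.n


def percentiles_of(log_scores: np.ndarray, bg: BackgroundDistribution) -> np.ndarray:
    """Vectorised :func:`percentile_of`."""
    below = np.searchsorted(bg.sorted_log_scores, log_scores, side="left")
    return 100.0 * below / bg.n


def compute_backgrounds(
    catalog: KinaseCatalog,
    class_sites: Mapping[str, Sequence[str]],
    use_favorability: bool = True,
    min_n: int = DEFAULT_MIN_BACKGROUND,
) -> dict[str, BackgroundDistribution]:
    """Background distribution per catalog family.

    Families inheriting the same human PSSM share one computed
    distribution. ``class_sites`` maps ``"ST"``/``"Y"`` to the
    corresponding background window sets.
    """
    cache: dict[str, BackgroundDistribution] = {}
    out: dict[str, BackgroundDistribution] = {}
    for fid, entry in catalog.items():
        source = entry.pssm.kinase_id
        if source not in cache:
            sites = class_sites.get(entry.kinase_class)
            if sites is None:
                raise ValidationError(
                    f"no background site set for class {entry.kinase_class}"
                )
            cache[source] = compute_background(
                entry.pssm, sites, use_favorability, min_n
            )
        out[fid] = cache[source]
    return out


def match_peptides(
    peptides: Sequence[PhosphoPeptide],
    catalog: KinaseCatalog,
    backgrounds: Mapping[str, BackgroundDistribution],
    threshold: float = DEFAULT_THRESHOLD,
    use_favorability: bool = True,
) -> MatchTable:
    """Score every compatible (peptide, family) pair and call matches.

    A pair is a match when its percentile is at or above ``threshold``.
    Peptides matching no family at all are flagged unmatched; downstream
    analyses (activity, clustering, network) ignore them.
    """
    if len(catalog) == 0:
        raise ValidationError("kinase catalog is empty; nothing to match against")
    if not 0.0 <= threshold <= 100.0:
        raise ValidationError(f"threshold {threshold} outside [0, 100]")

    by_class: dict[str, list[PhosphoPeptide]] = {ST_CLASS: [], Y_CLASS: []}
    for p in peptides:
        by_class[p.kinase_class].append(p)

    results: list[MatchResult] = []
    matched: set[str] = set()
    n_skipped = 0
    for fid, entry in catalog.items():
        group = by_class[entry.kinase_class]
        n_skipped += len(peptides) - len(group)
        if not group:
            continue
        bg = backgrounds.get(fid)
        if bg is None:
            raise ValidationError(f"no background distribution for family {fid!r}")
        scores = score_windows(entry.pssm, [p.window for p in group],
                               use_favorability)
        pcts = percentiles_of(scores, bg)
        for p, s, pct in zip(group, scores, pcts):
            hit = bool(pct >= threshold)
            if hit:
                matched.add(p.peptide_id)
            results.append(
                MatchResult(
                    peptide_id=p.peptide_id,
                    kinase_family_id=fid,
                    log_score=float(s),
                    percentile=float(pct),
                    is_match=hit,
                )
            )
    all_ids = {p.peptide_id for p in peptides}
    unmatched = all_ids - matched
    if unmatched:
        logger.info(
            "%d of %d peptides matched no kinase at threshold %.4g; "
            "excluded from downstream analyses",
            len(unmatched), len(all_ids), threshold,
        )
    return MatchTable(
        results=tuple(results),
        threshold=threshold,
        matched_peptide_ids=frozenset(matched),
        unmatched_peptide_ids=frozenset(unmatched),
        n_skipped_pairs=n_skipped,
    )
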