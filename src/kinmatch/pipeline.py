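"""End-to-end batch pipeline: parse -> orthology -> match -> analyses.

Stateless orchestration of the library modules. Every product is written
as a deterministic TSV and a ``run_summary.txt`` of ``key=value`` lines
records the counts at each stage, so two runs on identical inputs and
configuration produce byte-identical output trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import activity as activity_mod
from . import downstream, io_formats, orthology, scoring
from .errors import ValidationError
from .io_formats import PhosphoPeptide, ST_CLASS, Y_CLASS
from .orthology import KinaseCatalog
from .scoring import MatchTable

logger = logging.getLogger(__name__)

HUMAN_PASSTHROUGH = "human_passthrough"
MODEL_ORGANISM = "model_organism"


@dataclass(frozen=True)
class RunConfig:
    """All inputs and tunables of one pipeline run."""

    peptide_table: Path
    pssm_table: Path
    background_st: Path
    background_y: Path
    out_dir: Path
    ortholog_table: Path | None = None
    organism_mode: str = MODEL_ORGANISM
    orthology_mode: str = orthology.ONE_TO_ONE
    threshold: float = scoring.DEFAULT_THRESHOLD
    network_threshold: float | None = None
    use_favorability: bool = True
    fdr: float = activity_mod.DEFAULT_FDR
    min_substrates: int = activity_mod.DEFAULT_MIN_SUBSTRATES
    min_background: int = scoring.DEFAULT_MIN_BACKGROUND
    selected_kinases: tuple[str, ...] | None = None
    include_nonkinase: bool = True
    column_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 100.0:
            raise ValidationError(f"threshold {self.threshold} outside [0, 100]")
        if self.network_threshold is not None and not (
            0.0 <= self.network_threshold <= 100.0
        ):
            raise ValidationError(
                f"network threshold {self.network_threshold} outside [0, 100]"
            )
        if not 0.0 < self.fdr < 1.0:
            raise ValidationError(f"FDR {self.fdr} outside (0, 1)")
        if self.organism_mode not in (HUMAN_PASSTHROUGH, MODEL_ORGANISM):
            raise ValidationError(
                f"unknown organism mode {self.organism_mode!r}"
            )
        if self.organism_mode == MODEL_ORGANISM and self.ortholog_table is None:
            raise ValidationError(
                "model_organism mode requires an ortholog table "
                "(use human_passthrough for human data)"
            )


@dataclass
class PipelineResult:
    """Everything a run computed, plus the stage-count summary."""

    peptides: list[PhosphoPeptide]
    rejected: list[io_formats.RejectedRow]
    catalog: KinaseCatalog
    match_table: MatchTable | None = None
    activities: list | None = None
    matrix: downstream.MatchMatrix | None = None
    row_linkage: tuple[np.ndarray, list[int]] | None = None
    col_linkage: tuple[np.ndarray, list[int]] | None = None
    network: downstream.KinomeNetwork | None = None
    summary: dict[str, object] = field(default_factory=dict)
    written: dict[str, Path] = field(default_factory=dict)


def _build_catalog(config: RunConfig, pssms) -> KinaseCatalog:
    if config.organism_mode == HUMAN_PASSTHROUGH:
        families = orthology.passthrough_families(pssms)
    else:
        records = io_formats.read_ortholog_table(config.ortholog_table)
        families = orthology.collapse_families(records, config.orthology_mode)
        known = {p.kinase_id for p in pssms}
        dropped = [f for f in families if f.source_human_kinase not in known]
        if dropped:
            logger.warning(
                "%d families reference human kinases without PSSMs; dropped: %s",
                len(dropped), ", ".join(f.family_id for f in dropped[:5]),
            )
            families = [f for f in families if f.source_human_kinase in known]
    if not families:
        raise ValidationError("no kinase families after orthology collapsing")
    return orthology.build_kinase_set(families, pssms)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every applicable stage and write all outputs.

    Stages that lack their optional inputs (log2FC for activity, protein
    IDs for the network) are skipped with a logged notice rather than
    failing the run.
    """
    peptides, rejected = io_formats.parse_peptide_table(
        config.peptide_table,
        column_map=config.column_map,
        organism_mode=config.organism_mode,
    )
    if not peptides:
        raise ValidationError("no peptide rows survived validation")
    pssms = io_formats.read_pssm_set(config.pssm_table)
    catalog = _build_catalog(config, pssms)
    class_sites = {
        ST_CLASS: io_formats.read_background_sites(config.background_st),
        Y_CLASS: io_formats.read_background_sites(config.background_y),
    }
    backgrounds = scoring.compute_backgrounds(
        catalog, class_sites,
        use_favorability=config.use_favorability,
        min_n=config.min_background,
    )
    match_table = scoring.match_peptides(
        peptides, catalog, backgrounds,
        threshold=config.threshold,
        use_favorability=config.use_favorability,
    )
    result = PipelineResult(
        peptides=peptides, rejected=rejected, catalog=catalog,
        match_table=match_table,
    )
    counts = catalog.class_counts()
    summary: dict[str, object] = {
        "n_input_rows": len(peptides) + len(rejected),
        "n_accepted": len(peptides),
        "n_rejected": len(rejected),
        "n_families": len(catalog),
        "n_families_st": counts[ST_CLASS],
        "n_families_y": counts[Y_CLASS],
        "n_background_st": len(class_sites[ST_CLASS]),
        "n_background_y": len(class_sites[Y_CLASS]),
        "threshold": config.threshold,
        "use_favorability": config.use_favorability,
        "orthology_mode": (config.orthology_mode
                           if config.organism_mode == MODEL_ORGANISM
                           else HUMAN_PASSTHROUGH),
        "n_scored_pairs": len(match_table.results),
        "n_matches": len(match_table.matches),
        "n_matched_peptides": len(match_table.matched_peptide_ids),
        "n_unmatched_peptides": len(match_table.unmatched_peptide_ids),
    }

    # activity: needs quantified peptides
    quantified = [p for p in peptides if p.log2fc is not None]
    if len(quantified) >= 2:
        result.activities = activity_mod.infer_activity(
            match_table, peptides,
            fdr=config.fdr, min_substrates=config.min_substrates,
        )
        summary["n_tested_kinases"] = len(result.activities)
        summary["n_significant_kinases"] = sum(
            a.significant for a in result.activities
        )
        summary["fdr"] = config.fdr
    else:
        logger.info("activity stage skipped: fewer than 2 quantified peptides")
        summary["n_tested_kinases"] = 0

    # clustering: needs at least one match
    if match_table.matches:
        result.matrix = downstream.build_match_matrix(match_table)
        result.row_linkage = downstream.ward_linkage(result.matrix, "rows")
        result.col_linkage = downstream.ward_linkage(result.matrix, "columns")
        summary["matrix_rows"] = len(result.matrix.row_ids)
        summary["matrix_cols"] = len(result.matrix.col_ids)

    # network: needs protein IDs on matched peptides
    if any(p.protein_id for p in peptides) and match_table.matches:
        result.network = downstream.build_kinome_network(
            match_table, peptides, catalog,
            selected=config.selected_kinases,
            threshold=config.network_threshold,
            include_nonkinase=config.include_nonkinase,
        )
        summary["n_network_nodes"] = len(result.network.nodes)
        summary["n_network_edges"] = len(result.network.edges)
        summary["network_threshold"] = result.network.threshold
    else:
        logger.info("network stage skipped: no protein IDs on matched peptides")

    result.summary = summary
    result.written = io_formats.write_outputs(result, config.out_dir)
    _write_summary(summary, Path(config.out_dir) / "run_summary.txt")
    result.written["run_summary"] = Path(config.out_dir) / "run_summary.txt"
    _write_rejected(rejected, Path(config.out_dir) / "rejected_rows.tsv")
    result.written["rejected_rows"] = Path(config.out_dir) / "rejected_rows.tsv"
    orthology.write_catalog(catalog, Path(config.out_dir) / "kinase_catalog.tsv")
    result.written["kinase_catalog"] = Path(config.out_dir) / "kinase_catalog.tsv"
    return result


def _write_summary(summary: Mapping[str, object], path: Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}={summary[key]}\n")


def _write_rejected(rejected: Sequence[io_formats.RejectedRow], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("row_index\treason\traw_sequence\n")
        for r in rejected:
            fh.write(f"{r.row_index}\t{r.reason}\t{r.raw_sequence or ''}\n")
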