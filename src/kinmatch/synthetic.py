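"""Synthetic PSSMs, background site sets, ortholog tables and experiments.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable end-to-end without external downloads.

The generative model:

* **PSSMs** — per kinase and flank position, residue weights are drawn
  from a symmetric Dirichlet and rescaled to mean 1. The ``concentration``
  parameter controls specificity sharpness: small values (default 0.1)
  concentrate mass on a few residues per position, mimicking a selective
  kinase; large values approach the uninformative uniform matrix. S/T
  kinases draw their central (w0_S, w0_T) pair the same way over two
  outcomes.
* **Backgrounds** — flank residues uniform over the 20 amino acids, the
  acceptor S or T with equal probability (ST class) or Y. Uniform
  composition is the simplest null with known properties; real proteome
  composition is deliberately not emulated.
* **Experiments** — ``n_planted`` peptides whose windows are sampled
  residue-by-residue from the planted kinase's weight profile (acceptor by
  its favorability ratio) with log2FC ~ Normal(delta, sigma), mixed with
  ``n_null_peptides`` uniform windows with log2FC ~ Normal(0, sigma). A
  configurable fraction of planted peptides sit on model-organism kinase
  genes so the network stage has kinase-kinase edges to find.

All draws derive from ``SimConfig.seed`` through per-generator seed
sequences, so each artifact is reproducible independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io_formats import (
    AMINO_ACIDS,
    FLANK_OFFSETS,
    PSSM,
    OrthologRecord,
    ST_CLASS,
    Y_CLASS,
    write_background_sites,
    write_ortholog_table,
    write_pssm_set,
)

_WEIGHT_FLOOR = 1e-12  # Dirichlet draws can underflow to exact 0 at small alpha

# independent seed-sequence tags per generator
_TAG_PSSM, _TAG_BACKGROUND, _TAG_ORTHOLOG, _TAG_EXPERIMENT = 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 0
    n_kinases_st: int = 6
    n_kinases_y: int = 2
    concentration: float = 0.1
    n_background: int = 5000
    n_null_peptides: int = 2000
    n_planted: int = 50
    delta: float = 1.0
    sigma: float = 1.0
    planted_kinase: str = "STK1"
    kinase_target_fraction: float = 0.3
    protein_length: int = 500

    def __post_init__(self) -> None:
        if min(self.n_kinases_st, self.n_kinases_y, self.n_background,
               self.n_null_peptides, self.n_planted) <= 0:
            raise ValidationError("all synthetic counts must be positive")
        if self.sigma <= 0 or self.concentration <= 0:
            raise ValidationError("sigma and concentration must be positive")
        if not 0.0 <= self.kinase_target_fraction <= 1.0:
            raise ValidationError("kinase_target_fraction must lie in [0, 1]")


def kinase_names(config: SimConfig) -> list[str]:
    return [f"STK{i + 1}" for i in range(config.n_kinases_st)] + [
        f"TYK{i + 1}" for i in range(config.n_kinases_y)
    ]


def model_gene_for(kinase_id: str) -> str:
    """Deterministic model-organism gene name for a synthetic human kinase."""
    return f"g_{kinase_id.lower()}"


def _rng(config: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def gen_pssm(config: SimConfig) -> list[PSSM]:
    """Draw one synthetic PSSM per kinase (S/T kinases first)."""
    rng = _rng(config, _TAG_PSSM)
    alpha = np.full(len(AMINO_ACIDS), config.concentration)
    pssms: list[PSSM] = []
    for name in kinase_names(config):
        weights = rng.dirichlet(alpha, size=len(FLANK_OFFSETS)) * len(AMINO_ACIDS)
        weights = np.clip(weights, _WEIGHT_FLOOR, None)
        if name.startswith("STK"):
            central = np.clip(
                rng.dirichlet([config.concentration] * 2) * 2, _WEIGHT_FLOOR, None
            )
            pssms.append(
                PSSM(kinase_id=name, kinase_class=ST_CLASS,
                     flank_weights=weights,
                     w0_s=float(central[0]), w0_t=float(central[1]))
            )
        else:
            pssms.append(
                PSSM(kinase_id=name, kinase_class=Y_CLASS, flank_weights=weights)
            )
    return pssms


def _assemble(flank_idx: np.ndarray, acceptors: Sequence[str]) -> list[str]:
    """Build window strings from (n, 9) flank indices and acceptors."""
    windows = []
    for row, acc in zip(flank_idx, acceptors):
        left = "".join(AMINO_ACIDS[i] for i in row[:5])
        right = "".join(AMINO_ACIDS[i] for i in row[5:])
        windows.append(left + acc + right)
    return windows


def gen_background_sites(config: SimConfig) -> dict[str, list[str]]:
    """Uniform-composition background windows, one set per kinase class."""
    rng = _rng(config, _TAG_BACKGROUND)
    out: dict[str, list[str]] = {}
    for kclass in (ST_CLASS, Y_CLASS):
        flanks = rng.integers(0, len(AMINO_ACIDS),
                              size=(config.n_background, len(FLANK_OFFSETS)))
        if kclass == ST_CLASS:
            acceptors = np.where(rng.random(config.n_background) < 0.5, "S", "T")
        else:
            acceptors = np.full(config.n_background, "Y")
        out[kclass] = _assemble(flanks, acceptors)
    return out


def gen_ortholog_table(config: SimConfig) -> list[OrthologRecord]:
    """One-to-one gene per kinase, plus a paralog pair on the last S/T kinase.

    The extra paralog exercises family collapsing: in ambiguous mode the
    last S/T kinase becomes a two-member family, in one-to-one mode it is
    excluded entirely.
    """
    records: list[OrthologRecord] = []
    names = kinase_names(config)
    duplicated = f"STK{config.n_kinases_st}" if config.n_kinases_st > 1 else None
    for name in names:
        gene = model_gene_for(name)
        if name == duplicated:
            records.append(OrthologRecord(gene, name, is_one_to_one=False))
            records.append(OrthologRecord(gene + "b", name, is_one_to_one=False))
        else:
            records.append(OrthologRecord(gene, name, is_one_to_one=True))
    return records


def sample_windows_from_pssm(
    pssm: PSSM, n: int, rng: np.random.Generator
) -> list[str]:
    """Sample windows residue-by-residue from a PSSM's weight profile.

    Each flank position uses the normalised weights as a categorical
    distribution; the acceptor follows the favorability ratio (S/T
    kinases) or is Y.
    """
    profile = pssm.flank_weights / pssm.flank_weights.sum(axis=1, keepdims=True)
    flanks = np.empty((n, len(FLANK_OFFSETS)), dtype=np.intp)
    for pos in range(len(FLANK_OFFSETS)):
        flanks[:, pos] = rng.choice(len(AMINO_ACIDS), size=n, p=profile[pos])
    if pssm.kinase_class == ST_CLASS:
        p_s = pssm.w0_s / (pssm.w0_s + pssm.w0_t)
        acceptors = np.where(rng.random(n) < p_s, "S", "T")
    else:
        acceptors = np.full(n, "Y")
    return _assemble(flanks, acceptors)


def gen_experiment(
    config: SimConfig, pssms: Sequence[PSSM]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted-signal experiment: returns (peptide table, ground truth).

    The peptide table has the columns the default peptide reader expects
    (windows written centered). Ground truth marks which peptide ids carry
    the planted kinase's signal.
    """
    by_id = {p.kinase_id: p for p in pssms}
    planted = by_id.get(config.planted_kinase)
    if planted is None:
        raise ValidationError(
            f"planted kinase {config.planted_kinase!r} not among the PSSMs"
        )
    rng = _rng(config, _TAG_EXPERIMENT)

    planted_windows = sample_windows_from_pssm(planted, config.n_planted, rng)
    null_flanks = rng.integers(0, len(AMINO_ACIDS),
                               size=(config.n_null_peptides, len(FLANK_OFFSETS)))
    null_acceptors = rng.choice(list("STY"), size=config.n_null_peptides)
    null_windows = _assemble(null_flanks, null_acceptors)

    n_total = config.n_planted + config.n_null_peptides
    log2fc = np.concatenate([
        rng.normal(config.delta, config.sigma, config.n_planted),
        rng.normal(0.0, config.sigma, config.n_null_peptides),
    ])
    pvalues = 2.0 * norm.sf(np.abs(log2fc) / config.sigma)

    kinase_genes = sorted({model_gene_for(k) for k in kinase_names(config)})
    n_kinase_targets = int(round(config.kinase_target_fraction * config.n_planted))
    protein_ids = []
    for i in range(n_total):
        if i < n_kinase_targets:
            protein_ids.append(kinase_genes[int(rng.integers(len(kinase_genes)))])
        else:
            protein_ids.append(f"prot{i:05d}")
    site_positions = rng.integers(6, config.protein_length, size=n_total)

    order = rng.permutation(n_total)
    is_planted = np.arange(n_total) < config.n_planted
    rows = []
    for rank, i in enumerate(order):
        rows.append({
            "peptide_id": f"pep{rank:05d}",
            "sequence": (planted_windows[i] if is_planted[i]
                         else null_windows[i - config.n_planted]),
            "protein_id": protein_ids[i],
            "site_position": int(site_positions[i]),
            "log2fc": float(log2fc[i]),
            "pvalue": float(pvalues[i]),
        })
    peptide_df = pd.DataFrame(rows)
    truth_df = pd.DataFrame({
        "peptide_id": peptide_df["peptide_id"],
        "is_planted": ["true" if is_planted[i] else "false" for i in order],
        "planted_kinase": [config.planted_kinase if is_planted[i] else ""
                           for i in order],
    })
    return peptide_df, truth_df


def write_simulation(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture set for one configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pssms = gen_pssm(config)
    backgrounds = gen_background_sites(config)
    orthologs = gen_ortholog_table(config)
    peptide_df, truth_df = gen_experiment(config, pssms)

    paths = {
        "pssms": out_dir / "pssms.tsv",
        "background_st": out_dir / "background_ST.txt",
        "background_y": out_dir / "background_Y.txt",
        "orthologs": out_dir / "orthologs.tsv",
        "peptides": out_dir / "peptides.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_pssm_set(pssms, paths["pssms"])
    write_background_sites(backgrounds[ST_CLASS], paths["background_st"])
    write_background_sites(backgrounds[Y_CLASS], paths["background_y"])
    write_ortholog_table(orthologs, paths["orthologs"])
    peptide_df.to_csv(paths["peptides"], sep="\t", index=False,
                      float_format="%.10g")
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
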