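"""Input/output formats for phosphoproteomics kinase matching.

This module defines the core domain records (phosphopeptides, kinase
position-specific scoring matrices, ortholog pairs) and the readers and
writers for the plain-text tables the pipeline consumes and produces.

Conventions
-----------
* A phosphosite *window* is exactly 10 residues covering positions -5..+4
  relative to the phosphoacceptor; the acceptor sits at string index 5
  (position 0). Longer input sequences are trimmed symmetrically around the
  acceptor; missing flank positions (protein termini) are padded with ``_``.
* ``_`` — and any symbol outside the 20-letter amino-acid alphabet found in
  a flank — carries no information and contributes nothing during scoring.
* Input sequences mark the phosphoacceptor either by centering it (length
  >= 10, acceptor at ``len // 2``) or with a single ``*`` immediately after
  the phosphorylated residue.
* All output tables are tab-separated with fixed column orders and sort
  orders, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed column order used everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: Padding / no-information symbol for flank positions outside the protein.
PAD = "_"
#: Residue index used for neutral (padded or unknown) flank symbols.
NEUTRAL_INDEX = len(AMINO_ACIDS)

WINDOW_LENGTH = 10
#: String index of the phosphoacceptor (signed position 0) in a window.
CENTER = 5
#: Signed flank positions scored by a PSSM, in matrix row order.
FLANK_OFFSETS = (-5, -4, -3, -2, -1, 1, 2, 3, 4)
#: Window string indices corresponding to FLANK_OFFSETS.
FLANK_SLOTS = (0, 1, 2, 3, 4, 6, 7, 8, 9)

ACCEPTOR_RESIDUES = frozenset("STY")
ST_CLASS = "ST"
Y_CLASS = "Y"
KINASE_CLASSES = (ST_CLASS, Y_CLASS)

_PSSM_CELL_RE = re.compile(r"^(-?\d+)([A-Z])$")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhosphoPeptide:
    """One measured phosphosite with its aligned 10-residue window."""

    peptide_id: str
    window: str
    acceptor: str
    protein_id: str | None = None
    site_position: int | None = None
    log2fc: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LENGTH:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: window {self.window!r} is not "
                f"{WINDOW_LENGTH} symbols long"
            )
        if self.acceptor not in ACCEPTOR_RESIDUES:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: acceptor {self.acceptor!r} is not S/T/Y"
            )
        if self.window[CENTER] != self.acceptor:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: window center "
                f"{self.window[CENTER]!r} does not equal acceptor {self.acceptor!r}"
            )
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(
                f"peptide {self.peptide_id!r}: p-value {self.pvalue} outside [0, 1]"
            )
        if self.site_position is not None and self.site_position < 1:
            raise ValidationError(
                f"peptide {self.peptide_id!r}: site position must be 1-based positive"
            )

    @property
    def kinase_class(self) -> str:
        """Kinase class whose PSSMs can score this peptide."""
        return Y_CLASS if self.acceptor == "Y" else ST_CLASS


@dataclass(frozen=True, eq=False)
class PSSM:
    """One kinase's specificity as strictly positive position weights.

    ``flank_weights`` has one row per signed position in
    :data:`FLANK_OFFSETS` and one column per residue in
    :data:`AMINO_ACIDS`. Serine/threonine kinases additionally carry the
    central-column pair ``(w0_s, w0_t)`` whose normalised ratio is the
    phosphoacceptor favorability; tyrosine kinases have no central
    preference (their central factor is defined as 1).
    """

    kinase_id: str
    kinase_class: str
    flank_weights: np.ndarray
    w0_s: float | None = None
    w0_t: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.flank_weights, dtype=float)
        object.__setattr__(self, "flank_weights", w)
        if w.shape != (len(FLANK_OFFSETS), len(AMINO_ACIDS)):
            raise ValidationError(
                f"PSSM {self.kinase_id!r}: weight matrix shape {w.shape} != "
                f"({len(FLANK_OFFSETS)}, {len(AMINO_ACIDS)})"
            )
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            pos, res = np.argwhere(~(np.isfinite(w) & (w > 0)))[0]
            raise ValidationError(
                f"PSSM {self.kinase_id!r}: non-positive weight at position "
                f"{FLANK_OFFSETS[pos]}, residue {AMINO_ACIDS[res]}"
            )
        if self.kinase_class == ST_CLASS:
            if self.w0_s is None or self.w0_t is None:
                raise ValidationError(
                    f"PSSM {self.kinase_id!r}: S/T kinase missing central "
                    "(w0_S, w0_T) weights"
                )
            if self.w0_s <= 0 or self.w0_t <= 0:
                raise ValidationError(
                    f"PSSM {self.kinase_id!r}: central weights must be positive"
                )
        elif self.kinase_class == Y_CLASS:
            if self.w0_s is not None or self.w0_t is not None:
                raise ValidationError(
                    f"PSSM {self.kinase_id!r}: Y kinase must not carry central "
                    "S/T weights"
                )
        else:
            raise ValidationError(
                f"PSSM {self.kinase_id!r}: unknown kinase class "
                f"{self.kinase_class!r} (expected ST or Y)"
            )


@dataclass(frozen=True)
class OrthologRecord:
    """One model-organism gene -> human kinase ortholog assignment."""

    model_gene_id: str
    human_kinase_id: str
    is_one_to_one: bool
    evidence_weight: float | None = None

    def __post_init__(self) -> None:
        if self.evidence_weight is not None and self.evidence_weight < 0:
            raise ValidationError(
                f"ortholog {self.model_gene_id}->{self.human_kinase_id}: "
                "evidence weight must be non-negative"
            )


@dataclass(frozen=True)
class RejectedRow:
    """A data row that could not be turned into a valid peptide."""

    row_index: int
    reason: str
    raw_sequence: str | None = None


# ---------------------------------------------------------------------------
# Sequence normalisation
# ---------------------------------------------------------------------------

def normalize_sequence(sequence: str) -> tuple[str, str]:
    """Normalise a raw phosphosite sequence to a 10-residue window.

    Supports both acceptor conventions: a single ``*`` directly after the
    phosphorylated residue, or a centered sequence of length >= 10 whose
    acceptor sits at index ``len // 2``. Returns ``(window, acceptor)``.

    Raises
    ------
    ValueError
        With a human-readable reason when the sequence cannot be
        normalised; callers turn this into a rejected-row report.
    """
    s = str(sequence).strip().upper()
    if not s or s in {"NAN", "NONE"}:
        raise ValueError("empty sequence")

    n_stars = s.count("*")
    if n_stars > 1:
        raise ValueError("more than one '*' acceptor marker")
    if n_stars == 1:
        star = s.index("*")
        if star == 0:
            raise ValueError("'*' has no preceding residue")
        core = s.replace("*", "")
        acc_idx = star - 1
    else:
        core = s
        if len(core) < WINDOW_LENGTH:
            raise ValueError(
                f"sequence of length {len(core)} < {WINDOW_LENGTH} with no "
                "acceptor marker"
            )
        acc_idx = len(core) // 2

    acceptor = core[acc_idx]
    if acceptor not in ACCEPTOR_RESIDUES:
        raise ValueError(f"acceptor not S/T/Y (found {acceptor!r})")

    chars = []
    for offset in range(-CENTER, WINDOW_LENGTH - CENTER):
        j = acc_idx + offset
        c = core[j] if 0 <= j < len(core) else PAD
        if offset != 0 and c not in AA_INDEX:
            c = PAD  # unknown flank symbol carries no information
        chars.append(c)
    return "".join(chars), acceptor


def windows_to_indices(windows: Sequence[str]) -> np.ndarray:
    """Encode windows as an ``(n, 10)`` int array of residue indices.

    Neutral symbols (``_`` or anything outside the alphabet) map to
    :data:`NEUTRAL_INDEX`.
    """
    if len(windows) == 0:
        return np.empty((0, WINDOW_LENGTH), dtype=np.intp)
    table = np.full(256, NEUTRAL_INDEX, dtype=np.intp)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
    flat = "".join(windows)
    if len(flat) != WINDOW_LENGTH * len(windows):
        raise ValidationError("all windows must be exactly 10 symbols long")
    raw = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
    return table[raw].reshape(len(windows), WINDOW_LENGTH)


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

#: Logical field -> default column name in peptide tables.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "sequence": "sequence",
    "peptide_id": "peptide_id",
    "protein_id": "protein_id",
    "site_position": "site_position",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
}


def _read_table(path: Path, sep: str | None) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        return pd.read_excel(path)
    if sep is None:
        sep = "," if suffix == ".csv" else "\t"
    # round_trip parsing: floats survive write->read exactly
    return pd.read_csv(path, sep=sep, dtype={0: str}, keep_default_na=True,
                       float_precision="round_trip")


def _opt_float(value, what: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "" or value.lower() in {"na", "nan", "none"}:
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {what}: {value!r}") from None


def parse_peptide_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    organism_mode: str = "model_organism",
    sep: str | None = None,
) -> tuple[list[PhosphoPeptide], list[RejectedRow]]:
    """Read a phosphopeptide table and normalise every sequence.

    Parameters
    ----------
    path
        TSV/CSV (or .xlsx) file with one row per measured phosphosite.
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP`; only ``sequence`` is
        required to exist in the file. Missing optional columns simply
        leave the corresponding fields unset.
    organism_mode
        Recorded for provenance (``human_passthrough`` or
        ``model_organism``); parsing itself is organism-agnostic.
    sep
        Explicit delimiter; by default inferred from the file extension.

    Returns
    -------
    (accepted, rejected)
        Valid peptides, and a report for every row that could not be
        normalised (never a silent drop): accepted + rejected counts equal
        the number of data rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"peptide table not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = _read_table(path, sep)
    if cmap["sequence"] not in df.columns:
        raise ValidationError(
            f"peptide table {path} lacks required sequence column "
            f"{cmap['sequence']!r} (found: {list(df.columns)})"
        )

    def col(row, key):
        name = cmap.get(key)
        if name is None or name not in df.columns:
            return None
        v = row[name]
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    peptides: list[PhosphoPeptide] = []
    rejected: list[RejectedRow] = []
    seen_ids: set[str] = set()
    for i, (_, row) in enumerate(df.iterrows()):
        raw_seq = row[cmap["sequence"]]
        pid = col(row, "peptide_id")
        pid = str(pid) if pid is not None else f"pep{i:06d}"
        try:
            if pid in seen_ids:
                raise ValueError(f"duplicate peptide_id {pid!r}")
            window, acceptor = normalize_sequence(raw_seq)
            site = col(row, "site_position")
            prot = col(row, "protein_id")
            peptide = PhosphoPeptide(
                peptide_id=pid,
                window=window,
                acceptor=acceptor,
                protein_id=str(prot) if prot is not None else None,
                site_position=int(site) if site is not None else None,
                log2fc=_opt_float(col(row, "log2fc"), "log2fc"),
                pvalue=_opt_float(col(row, "pvalue"), "p-value"),
            )
        except (ValueError, ValidationError) as exc:
            rejected.append(
                RejectedRow(row_index=i, reason=str(exc),
                            raw_sequence=None if raw_seq is None else str(raw_seq))
            )
            continue
        seen_ids.add(pid)
        peptides.append(peptide)

    logger.info(
        "parsed %s: %d accepted, %d rejected (mode=%s)",
        path, len(peptides), len(rejected), organism_mode,
    )
    return peptides, rejected


def write_peptide_table(peptides: Iterable[PhosphoPeptide], path: str | Path) -> None:
    """Write peptides in the same dialect :func:`parse_peptide_table` reads."""
    rows = [
        {
            "peptide_id": p.peptide_id,
            "sequence": p.window,
            "protein_id": p.protein_id if p.protein_id is not None else "",
            "site_position": p.site_position if p.site_position is not None else "",
            "log2fc": _fmt_opt(p.log2fc),
            "pvalue": _fmt_opt(p.pvalue),
        }
        for p in peptides
    ]
    df = pd.DataFrame(
        rows,
        columns=["peptide_id", "sequence", "protein_id", "site_position",
                 "log2fc", "pvalue"],
    )
    df.to_csv(path, sep="\t", index=False)


def _fmt_opt(x: float | None) -> str:
    # 17 significant digits: optional floats survive a write/parse round trip
    return "" if x is None else format(float(x), ".17g")


# ---------------------------------------------------------------------------
# PSSM tables
# ---------------------------------------------------------------------------

def read_pssm_set(path: str | Path) -> list[PSSM]:
    """Read a wide PSSM table: one row per kinase, one column per cell.

    Matrix columns are named ``<position><residue>`` (e.g. ``-5P``, ``4Y``)
    with the central S/T pair as ``0S`` / ``0T``. A ``class`` column (values
    ``ST``/``Y``) is honoured when present; otherwise the class is inferred
    from whether the central columns are filled.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"PSSM table not found: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    kin_col = next((c for c in ("kinase", "kinase_id") if c in df.columns), None)
    if kin_col is None:
        raise ValidationError(f"PSSM table {path} lacks a 'kinase' column")
    class_col = next((c for c in ("class", "kinase_class") if c in df.columns), None)

    cells: dict[tuple[int, str], str] = {}
    for c in df.columns:
        m = _PSSM_CELL_RE.match(str(c))
        if m:
            cells[(int(m.group(1)), m.group(2))] = c
    missing = [
        f"{pos}{aa}"
        for pos in FLANK_OFFSETS
        for aa in AMINO_ACIDS
        if (pos, aa) not in cells
    ]
    if missing:
        raise ValidationError(
            f"PSSM table {path} missing matrix columns: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )

    pssms: list[PSSM] = []
    for _, row in df.iterrows():
        kinase = str(row[kin_col])
        w0_s = row[cells[(0, "S")]] if (0, "S") in cells else float("nan")
        w0_t = row[cells[(0, "T")]] if (0, "T") in cells else float("nan")
        has_central = not (pd.isna(w0_s) or pd.isna(w0_t))
        if class_col is not None and not pd.isna(row[class_col]):
            kclass = str(row[class_col]).strip().upper()
            if kclass not in KINASE_CLASSES:
                raise ValidationError(
                    f"PSSM {kinase!r}: unknown class {kclass!r} (expected ST or Y)"
                )
        else:
            kclass = ST_CLASS if has_central else Y_CLASS
        weights = np.empty((len(FLANK_OFFSETS), len(AMINO_ACIDS)))
        for pi, pos in enumerate(FLANK_OFFSETS):
            for ai, aa in enumerate(AMINO_ACIDS):
                v = row[cells[(pos, aa)]]
                if pd.isna(v) or float(v) <= 0:
                    raise ValidationError(
                        f"PSSM {kinase!r}: non-positive or missing weight at "
                        f"position {pos}, residue {aa}"
                    )
                weights[pi, ai] = float(v)
        pssms.append(
            PSSM(
                kinase_id=kinase,
                kinase_class=kclass,
                flank_weights=weights,
                w0_s=float(w0_s) if kclass == ST_CLASS else None,
                w0_t=float(w0_t) if kclass == ST_CLASS else None,
            )
        )
    return pssms


def write_pssm_set(pssms: Iterable[PSSM], path: str | Path) -> None:
    """Write PSSMs in the wide format :func:`read_pssm_set` reads.

    Weights are serialised with 17 significant digits so that a write/read
    round trip reproduces them exactly.
    """
    rows = []
    for p in pssms:
        row: dict[str, str] = {"kinase": p.kinase_id, "class": p.kinase_class}
        row["0S"] = _fmt17(p.w0_s)
        row["0T"] = _fmt17(p.w0_t)
        for pi, pos in enumerate(FLANK_OFFSETS):
            for ai, aa in enumerate(AMINO_ACIDS):
                row[f"{pos}{aa}"] = _fmt17(p.flank_weights[pi, ai])
        rows.append(row)
    columns = ["kinase", "class", "0S", "0T"] + [
        f"{pos}{aa}" for pos in FLANK_OFFSETS for aa in AMINO_ACIDS
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def _fmt17(x: float | None) -> str:
    return "" if x is None else format(float(x), ".17g")


# ---------------------------------------------------------------------------
# Background site sets
# ---------------------------------------------------------------------------

def read_background_sites(path: str | Path) -> list[str]:
    """Read a background site set: one 10-residue window per line."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"background site file not found: {path}")
    windows: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            w = line.strip().upper()
            if not w:
                continue
            if len(w) != WINDOW_LENGTH:
                raise ValidationError(
                    f"{path}:{ln}: background window {w!r} is not "
                    f"{WINDOW_LENGTH} symbols long"
                )
            if w[CENTER] not in ACCEPTOR_RESIDUES:
                raise ValidationError(
                    f"{path}:{ln}: background window {w!r} has non-S/T/Y acceptor"
                )
            windows.append(w)
    return windows


def write_background_sites(windows: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(w + "\n")


# ---------------------------------------------------------------------------
# Ortholog tables
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"true", "1", "yes", "t", "y"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n"}


def read_ortholog_table(path: str | Path) -> list[OrthologRecord]:
    """Read a flattened ortholog table (model gene -> human kinase)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"ortholog table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"model_gene_id", "human_kinase_id", "is_one_to_one"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"ortholog table {path} needs columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    records: list[OrthologRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        key = (str(row["model_gene_id"]), str(row["human_kinase_id"]))
        if key in seen:
            raise ValidationError(
                f"ortholog table {path}: duplicate pair {key[0]} -> {key[1]}"
            )
        seen.add(key)
        token = str(row["is_one_to_one"]).strip().lower()
        if token in _TRUE_TOKENS:
            one = True
        elif token in _FALSE_TOKENS:
            one = False
        else:
            raise ValidationError(
                f"ortholog table {path} row {i}: unknown boolean token "
                f"{row['is_one_to_one']!r} for is_one_to_one"
            )
        ev = None
        if "evidence_weight" in df.columns and not pd.isna(row["evidence_weight"]):
            ev = float(row["evidence_weight"])
        records.append(
            OrthologRecord(
                model_gene_id=key[0],
                human_kinase_id=key[1],
                is_one_to_one=one,
                evidence_weight=ev,
            )
        )
    return records


def write_ortholog_table(records: Iterable[OrthologRecord], path: str | Path) -> None:
    rows = [
        {
            "model_gene_id": r.model_gene_id,
            "human_kinase_id": r.human_kinase_id,
            "is_one_to_one": "true" if r.is_one_to_one else "false",
            "evidence_weight": _fmt_opt(r.evidence_weight),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["model_gene_id", "human_kinase_id", "is_one_to_one",
                 "evidence_weight"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_match_table(matches, peptides: Sequence[PhosphoPeptide],
                      path: str | Path) -> None:
    """Three-column match table: peptide, window, sorted kinase list."""
    window_of = {p.peptide_id: p.window for p in peptides}
    by_peptide: dict[str, list[str]] = {}
    for r in matches:
        if r.is_match:
            by_peptide.setdefault(r.peptide_id, []).append(r.kinase_family_id)
    with open(path, "w") as fh:
        fh.write("peptide_id\twindow\tkinases\n")
        for pid in sorted(by_peptide):
            kinases = ";".join(sorted(by_peptide[pid]))
            fh.write(f"{pid}\t{window_of.get(pid, '')}\t{kinases}\n")


def write_matches_long(matches, path: str | Path) -> None:
    """Long-format table of every scored (peptide, kinase) pair."""
    rows = sorted(matches, key=lambda r: (r.peptide_id, r.kinase_family_id))
    with open(path, "w") as fh:
        fh.write("peptide_id\tkinase_family_id\tlog_score\tpercentile\n")
        for r in rows:
            fh.write(
                f"{r.peptide_id}\t{r.kinase_family_id}\t"
                f"{r.log_score:.6f}\t{r.percentile:.4f}\n"
            )


def write_activity_table(activities, path: str | Path) -> None:
    """Per-kinase activity statistics, sorted by family id."""
    rows = sorted(activities, key=lambda a: a.kinase_family_id)
    with open(path, "w") as fh:
        fh.write("kinase\tm\tmean_log2fc\tz\tp\tp_adj\tsignificant_at_fdr\n")
        for a in rows:
            fh.write(
                f"{a.kinase_family_id}\t{a.m}\t{a.mean_fc:.6f}\t{a.z:.6f}\t"
                f"{a.p_one_sided:.6g}\t{a.p_adj:.6g}\t"
                f"{'true' if a.significant else 'false'}\n"
            )


def write_network_edges(edges, path: str | Path) -> None:
    rows = sorted(edges, key=lambda e: (e.source_kinase_family_id,
                                        e.target_protein_id))
    with open(path, "w") as fh:
        fh.write("source_kinase\ttarget_protein\tmax_percentile\ttarget_is_kinase\n")
        for e in rows:
            fh.write(
                f"{e.source_kinase_family_id}\t{e.target_protein_id}\t"
                f"{e.percentile:.4f}\t{'true' if e.target_is_kinase else 'false'}\n"
            )


def write_linkage(Z: np.ndarray, leaf_ids: Sequence[str],
                  leaf_order: Sequence[int], path: str | Path) -> None:
    """Write a merge tree (one row per merge) plus the leaf ordering.

    Leaves are numbered 0..n-1 in input order; internal nodes continue the
    numbering as in the usual linkage-matrix convention.
    """
    with open(path, "w") as fh:
        fh.write("# leaves\t" + "\t".join(leaf_ids) + "\n")
        fh.write("# leaf_order\t" + "\t".join(str(i) for i in leaf_order) + "\n")
        fh.write("merge\tleft\tright\theight\tsize\n")
        for i, (a, b, h, size) in enumerate(np.asarray(Z)):
            fh.write(f"{i}\t{int(a)}\t{int(b)}\t{h:.6g}\t{int(size)}\n")


def write_outputs(results, out_dir: str | Path) -> dict[str, Path]:
    """Write every available pipeline product into ``out_dir``.

    ``results`` is a :class:`kinmatch.pipeline.PipelineResult` (or any
    object with the same attributes); stages that did not run are simply
    skipped. Returns a name -> path map of the files written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot write to output directory {out_dir}: {exc}")
    written: dict[str, Path] = {}

    if results.match_table is not None:
        p = out_dir / "match_table.tsv"
        write_match_table(results.match_table.results, results.peptides, p)
        written["match_table"] = p
        p = out_dir / "matches_long.tsv"
        write_matches_long(results.match_table.results, p)
        written["matches_long"] = p
    if results.activities is not None:
        p = out_dir / "activity.tsv"
        write_activity_table(results.activities, p)
        written["activity"] = p
    if results.network is not None:
        p = out_dir / "network_edges.tsv"
        write_network_edges(results.network.edges, p)
        written["network_edges"] = p
    if results.matrix is not None and results.row_linkage is not None:
        p = out_dir / "linkage_rows.tsv"
        write_linkage(results.row_linkage[0], results.matrix.row_ids,
                      results.row_linkage[1], p)
        written["linkage_rows"] = p
    if results.matrix is not None and results.col_linkage is not None:
        p = out_dir / "linkage_cols.tsv"
        write_linkage(results.col_linkage[0], results.matrix.col_ids,
                      results.col_linkage[1], p)
        written["linkage_cols"] = p
    return written
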