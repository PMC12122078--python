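"""Transfer of human kinase specificities to a model organism.

Kinase substrate specificity is strongly conserved across orthologs, so a
model-organism kinase inherits the empirically determined PSSM of its
human ortholog. When several model-organism genes map to the same human
kinase their inferred specificities cannot be disambiguated; they are
collapsed into a single *kinase family* that is scored and reported as one
unit.

Two coverage modes are offered:

``one_to_one``
    Conservative: only unambiguous pairs, i.e. records flagged one-to-one
    whose human kinase is hit by exactly one model gene (counted over the
    full ortholog table) and whose model gene maps to exactly one human
    kinase.
``ambiguous``
    Additionally emits one family per human kinase grouping *all* model
    genes that map to it. A gene with complex orthology may appear in one
    family per human kinase it maps to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .io_formats import PSSM, OrthologRecord, ST_CLASS, Y_CLASS

logger = logging.getLogger(__name__)

ONE_TO_ONE = "one_to_one"
AMBIGUOUS = "ambiguous"
MODES = (ONE_TO_ONE, AMBIGUOUS)


@dataclass(frozen=True)
class KinaseFamily:
    """A group of model-organism kinases sharing one inherited specificity."""

    family_id: str
    member_gene_ids: frozenset[str]
    source_human_kinase: str
    mode_tag: str

    def __post_init__(self) -> None:
        if not self.member_gene_ids:
            raise ValidationError(f"family {self.family_id!r} has no members")
        if self.mode_tag not in MODES:
            raise ValidationError(
                f"family {self.family_id!r}: unknown mode tag {self.mode_tag!r}"
            )


def family_id_for(members: Iterable[str]) -> str:
    """Deterministic family name: sorted members joined with '/'."""
    return "/".join(sorted(members))


def collapse_families(
    records: Sequence[OrthologRecord], mode: str
) -> list[KinaseFamily]:
    """Collapse ortholog records into kinase families under ``mode``.

    In ``one_to_one`` mode a model gene mapping to two or more human
    kinases is excluded (logged, not fatal). Families are returned sorted
    by family id.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown orthology mode {mode!r}; expected {MODES}")

    genes_of: dict[str, set[str]] = {}   # human kinase -> model genes
    kinases_of: dict[str, set[str]] = {}  # model gene -> human kinases
    flagged: dict[tuple[str, str], bool] = {}
    for r in records:
        genes_of.setdefault(r.human_kinase_id, set()).add(r.model_gene_id)
        kinases_of.setdefault(r.model_gene_id, set()).add(r.human_kinase_id)
        flagged[(r.model_gene_id, r.human_kinase_id)] = r.is_one_to_one

    def qualifies_one_to_one(gene: str, kinase: str) -> bool:
        return (
            flagged[(gene, kinase)]
            and len(genes_of[kinase]) == 1
            and len(kinases_of[gene]) == 1
        )

    families: list[KinaseFamily] = []
    if mode == ONE_TO_ONE:
        for r in records:
            if not r.is_one_to_one:
                continue
            if len(kinases_of[r.model_gene_id]) > 1:
                logger.warning(
                    "one_to_one mode: gene %s maps to %d human kinases; excluded",
                    r.model_gene_id, len(kinases_of[r.model_gene_id]),
                )
                continue
            if len(genes_of[r.human_kinase_id]) > 1:
                logger.info(
                    "one_to_one mode: human kinase %s hit by %d model genes; "
                    "pair with %s excluded",
                    r.human_kinase_id, len(genes_of[r.human_kinase_id]),
                    r.model_gene_id,
                )
                continue
            families.append(
                KinaseFamily(
                    family_id=r.model_gene_id,
                    member_gene_ids=frozenset({r.model_gene_id}),
                    source_human_kinase=r.human_kinase_id,
                    mode_tag=ONE_TO_ONE,
                )
            )
    else:
        for kinase in sorted(genes_of):
            members = genes_of[kinase]
            only = next(iter(members)) if len(members) == 1 else None
            tag = (
                ONE_TO_ONE
                if only is not None and qualifies_one_to_one(only, kinase)
                else AMBIGUOUS
            )
            families.append(
                KinaseFamily(
                    family_id=family_id_for(members),
                    member_gene_ids=frozenset(members),
                    source_human_kinase=kinase,
                    mode_tag=tag,
                )
            )
    return sorted(families, key=lambda f: f.family_id)


def passthrough_families(pssms: Sequence[PSSM]) -> list[KinaseFamily]:
    """Identity families for human data: one family per loaded PSSM."""
    return [
        KinaseFamily(
            family_id=p.kinase_id,
            member_gene_ids=frozenset({p.kinase_id}),
            source_human_kinase=p.kinase_id,
            mode_tag=ONE_TO_ONE,
        )
        for p in sorted(pssms, key=lambda p: p.kinase_id)
    ]


@dataclass(frozen=True)
class CatalogEntry:
    family: KinaseFamily
    pssm: PSSM  # shared reference to the inherited human PSSM

    @property
    def kinase_class(self) -> str:
        return self.pssm.kinase_class


class KinaseCatalog:
    """Organism kinase set: family id -> inherited specificity."""

    def __init__(self, entries: Mapping[str, CatalogEntry]):
        self._entries = dict(entries)
        gene_map: dict[str, set[str]] = {}
        for fid, entry in self._entries.items():
            for gene in entry.family.member_gene_ids:
                gene_map.setdefault(gene, set()).add(fid)
        self._gene_to_families = gene_map

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries))

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._entries

    def __getitem__(self, family_id: str) -> CatalogEntry:
        return self._entries[family_id]

    def items(self):
        return ((fid, self._entries[fid]) for fid in sorted(self._entries))

    @property
    def family_ids(self) -> list[str]:
        return sorted(self._entries)

    def is_kinase_gene(self, protein_id: str) -> bool:
        """Whether a protein id belongs to any family's member set."""
        return protein_id in self._gene_to_families

    def families_of_gene(self, protein_id: str) -> list[str]:
        return sorted(self._gene_to_families.get(protein_id, ()))

    def class_counts(self) -> dict[str, int]:
        counts = {ST_CLASS: 0, Y_CLASS: 0}
        for entry in self._entries.values():
            counts[entry.kinase_class] += 1
        return counts


def build_kinase_set(
    families: Sequence[KinaseFamily], pssms: Sequence[PSSM]
) -> KinaseCatalog:
    """Attach each family to its inherited human PSSM.

    Raises a fatal error naming every family whose source human kinase has
    no loaded PSSM. Member sets of distinct families must be disjoint,
    except in ambiguous mode where a multi-ortholog gene legitimately
    appears under several human kinases.
    """
    pssm_by_id = {p.kinase_id: p for p in pssms}
    if len(pssm_by_id) != len(pssms):
        raise ValidationError("duplicate kinase ids in PSSM set")
    missing = sorted(
        {f.source_human_kinase for f in families} - set(pssm_by_id)
    )
    if missing:
        raise ValidationError(
            f"no PSSM loaded for source human kinase(s): {', '.join(missing)}"
        )
    entries: dict[str, CatalogEntry] = {}
    for f in families:
        if f.family_id in entries:
            raise ValidationError(f"duplicate family id {f.family_id!r}")
        entries[f.family_id] = CatalogEntry(family=f, pssm=pssm_by_id[f.source_human_kinase])
    catalog = KinaseCatalog(entries)
    counts = catalog.class_counts()
    logger.info(
        "kinase catalog: %d families (%d S/T, %d Y)",
        len(catalog), counts[ST_CLASS], counts[Y_CLASS],
    )
    return catalog


def write_catalog(catalog: KinaseCatalog, path: str | Path) -> None:
    """Write the catalog as a TSV (family, members, source, class, mode)."""
    with open(path, "w") as fh:
        fh.write("family_id\tmembers\tsource_human_kinase\tclass\tmode_tag\n")
        for fid, entry in catalog.items():
            members = ";".join(sorted(entry.family.member_gene_ids))
            fh.write(
                f"{fid}\t{members}\t{entry.family.source_human_kinase}\t"
                f"{entry.kinase_class}\t{entry.family.mode_tag}\n"
            )
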