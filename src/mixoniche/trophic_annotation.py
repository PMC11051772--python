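"""Taxon exclusion rules and trophic-mode assignment.

Lineages are annotated into three trophic groups — constitutive mixotrophs
(M: pigmented eukaryotes with phagocytosis capability), autotrophs (A:
pigmented, no phagocytosis evidence) and heterotrophs (H: no inherent
chloroplasts) — by looking a lineage's species name up in a curated
annotation database, falling back to its genus and then family when the
species is not covered. Groups dominated by large or parasitic taxa
(ciliates, radiolarians, foraminifers; fungi, amoebae, syndinians, unknown
eukaryotes) are excluded up front so the analysis targets small constitutive
mixotrophs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .tables import AbundanceTable, TaxonomyTable

MODES = ("M", "A", "H")
ANNOTATION_RANKS = ("species", "genus", "family")

#: Taxa from large-size-fraction groups, dropped at any rank.
DEFAULT_EXCLUDED = frozenset({"Ciliophora", "Radiolaria", "Foraminifera"})

#: Taxa that cannot be trophically annotated (parasites, fungi, unresolved
#: eukaryotes), likewise removed from the analysis pool.
DEFAULT_UNANNOTATABLE = frozenset({"Fungi", "Amoebozoa", "Syndiniales", "Eukaryota_X"})


def _norm(name: str) -> str:
    """Whitespace-normalized, case-sensitive taxon key."""
    return " ".join(str(name).split())


class AnnotationConflictError(ValueError):
    """A taxon mapped to two different modes at the same rank."""


@dataclass
class TrophicAnnotationDB:
    """Taxon-name -> trophic-mode lookup at species, genus and family rank."""

    entries: dict[str, dict[str, str]] = field(
        default_factory=lambda: {r: {} for r in ANNOTATION_RANKS}
    )
    sources: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, taxon: str, rank: str, mode: str, source: str = "") -> None:
        if rank not in ANNOTATION_RANKS:
            raise ValueError(f"rank must be one of {ANNOTATION_RANKS}, got {rank!r}")
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        key = _norm(taxon)
        existing = self.entries[rank].get(key)
        if existing is not None and existing != mode:
            raise AnnotationConflictError(
                f"taxon {taxon!r} at rank {rank!r} mapped to both "
                f"{existing!r} and {mode!r}"
            )
        self.entries[rank][key] = mode
        self.sources[(rank, key)] = source

    def lookup(self, taxon: str, rank: str) -> str | None:
        return self.entries[rank].get(_norm(taxon))

    def __len__(self) -> int:
        return sum(len(d) for d in self.entries.values())

    def to_tsv(self, path) -> None:
        """Write a ``taxon<TAB>rank<TAB>mode<TAB>source`` TSV."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("taxon\trank\tmode\tsource\n")
            for rank in ANNOTATION_RANKS:
                for taxon, mode in sorted(self.entries[rank].items()):
                    source = self.sources.get((rank, taxon), "")
                    fh.write(f"{taxon}\t{rank}\t{mode}\t{source}\n")

    @classmethod
    def from_tsv(cls, path) -> "TrophicAnnotationDB":
        """Load a ``taxon<TAB>rank<TAB>mode<TAB>source`` TSV."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        needed = {"taxon", "rank", "mode"}
        if not needed.issubset(df.columns):
            raise ValueError(f"{path}: annotation TSV needs columns {sorted(needed)}")
        db = cls()
        for row in df.itertuples():
            db.add(row.taxon, row.rank, row.mode, getattr(row, "source", ""))
        return db


@dataclass
class ExclusionPolicy:
    """Which taxa are removed before trophic analysis."""

    excluded_taxa: frozenset[str] = DEFAULT_EXCLUDED
    unannotatable_taxa: frozenset[str] = DEFAULT_UNANNOTATABLE
    lineage_blocklist: frozenset[str] = frozenset()

    def all_taxa(self) -> dict[str, str]:
        out = {t: "excluded" for t in self.excluded_taxa}
        out.update({t: "unannotatable" for t in self.unannotatable_taxa})
        return out


@dataclass
class ModeAssignment:
    """Per-lineage trophic mode plus the rank the annotation resolved at."""

    modes: dict[str, str]  # lineage_id -> M | A | H | unknown
    resolution_rank: dict[str, str]  # lineage_id -> species | genus | family | none

    def mode_of(self, lineage_id: str) -> str:
        return self.modes[lineage_id]

    def lineages_of(self, mode: str) -> list[str]:
        return [l for l, m in self.modes.items() if m == mode]

    def counts(self) -> dict[str, int]:
        out = {m: 0 for m in (*MODES, "unknown")}
        for m in self.modes.values():
            out[m] += 1
        return out


def apply_exclusions(
    table: AbundanceTable,
    taxonomy: TaxonomyTable,
    policy: ExclusionPolicy | None = None,
) -> tuple[AbundanceTable, dict[str, list[str]]]:
    """Drop lineages whose ranked path contains an excluded taxon.

    Returns the filtered table and a report mapping each triggering taxon
    (or ``"blocklist"``) to the lineage ids it removed.
    """
    policy = policy or ExclusionPolicy()
    trigger_taxa = policy.all_taxa()
    report: dict[str, list[str]] = {}
    keep = []
    for lid in table.lineage_ids:
        path = [_norm(p) for p in taxonomy.ranked_path(lid)]
        hit = None
        if lid in policy.lineage_blocklist:
            hit = "blocklist"
        else:
            for taxon in path:
                if taxon in trigger_taxa:
                    hit = taxon
                    break
        if hit is None:
            keep.append(lid)
        else:
            report.setdefault(hit, []).append(lid)
    if not keep:
        import warnings

        warnings.warn("exclusion policy removed every lineage", stacklevel=2)
        # AbundanceTable forbids empty matrices; keep an all-zero placeholder
        # would be misleading, so signal via the report and raise downstream.
        raise ValueError("exclusion policy removed every lineage")
    return table.subset_lineages(keep), report


def assign_modes(taxonomy: TaxonomyTable, db: TrophicAnnotationDB) -> ModeAssignment:
    """Annotate every lineage, species -> genus -> family, first hit wins."""
    if len(db) == 0:
        raise ValueError("empty trophic annotation database")
    modes: dict[str, str] = {}
    ranks: dict[str, str] = {}
    for lid in taxonomy.lineage_ids:
        row = taxonomy.data.loc[lid]
        assigned = None
        for rank in ANNOTATION_RANKS:
            hit = db.lookup(str(row[rank]), rank)
            if hit is not None:
                assigned = (hit, rank)
                break
        if assigned is None:
            modes[lid], ranks[lid] = "unknown", "none"
        else:
            modes[lid], ranks[lid] = assigned
    return ModeAssignment(modes=modes, resolution_rank=ranks)


def demo_annotation_db() -> TrophicAnnotationDB:
    """Small shipped annotation DB covering well-known open-ocean taxa.

    A starting point for demos and tests only; real analyses should supply a
    fuller database compiled from the trophic-mode literature.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("mixoniche.data") / "demo_annotations.tsv"
    ) as p:
        return TrophicAnnotationDB.from_tsv(p)


def write_report(report: Mapping[str, list[str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump({k: sorted(v) for k, v in report.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
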