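"""Set algebra over the strain x gene-family presence/absence matrix.

Core genome (families in every strain), accessory genome (the complement),
per-species cores, species-specific and strain-unique families, flower-plot
count tables, and per-strain genome summaries (size / CDS count / GC%).
Presence means member count >= 1: paralogy is ignored for set algebra
because families (clusters), not members, are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceRecord, SpeciesMap

__all__ = [
    "PresenceAbsenceMatrix",
    "GenomeSummary",
    "core_families",
    "accessory_families",
    "species_core",
    "species_specific",
    "strain_unique",
    "flower_counts",
    "core_percentage",
    "genome_summary",
]


@dataclass
class PresenceAbsenceMatrix:
    """Member counts per (strain, family) plus the strain -> species map."""

    strains: list[str]
    families: list[int]
    counts: np.ndarray  # shape (n_strains, n_families), non-negative ints
    species_map: SpeciesMap

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.strains), len(self.families)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strains)} strains x {len(self.families)} families"
            )
        if (self.counts < 0).any():
            raise ValueError("member counts must be non-negative")

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= 1

    def strain_index(self, strain: str) -> int:
        try:
            return self.strains.index(strain)
        except ValueError:
            raise KeyError(f"unknown strain {strain!r}") from None

    def species_rows(self, species: str) -> np.ndarray:
        members = set(self.species_map.strains_of(species))
        rows = np.array([s in members for s in self.strains])
        if not rows.any():
            raise KeyError(f"species {species!r} has no strains in the matrix")
        return rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.families)


def _family_array(pa: PresenceAbsenceMatrix, mask: np.ndarray) -> set[int]:
    return {pa.families[i] for i in np.nonzero(mask)[0]}


def core_families(pa: PresenceAbsenceMatrix) -> set[int]:
    """Families present in every strain (the genus core genome)."""
    if not pa.strains:
        raise ValueError("presence/absence matrix has no strains")
    return _family_array(pa, pa.presence.all(axis=0))


def accessory_families(pa: PresenceAbsenceMatrix) -> set[int]:
    """All families not in the core; |core| + |accessory| = |families|."""
    return _family_array(pa, ~pa.presence.all(axis=0))


def species_core(pa: PresenceAbsenceMatrix, species: str) -> set[int]:
    """Families present in every strain of ``species``."""
    rows = pa.species_rows(species)
    return _family_array(pa, pa.presence[rows].all(axis=0))


def species_specific(
    pa: PresenceAbsenceMatrix, species: str, mode: str = "all_others", other: str | None = None
) -> set[int]:
    """Species-core families absent from other species.

    mode="all_others": absent from every strain of every other species (the
    flower-plot petals). mode="pairwise": absent from every strain of the one
    named ``other`` species (the two-species core comparison).
    """
    rows = pa.species_rows(species)
    in_core = pa.presence[rows].all(axis=0)
    if mode == "all_others":
        others = ~rows
    elif mode == "pairwise":
        if other is None:
            raise ValueError("mode='pairwise' requires the other species")
        others = pa.species_rows(other)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not others.any():
        return _family_array(pa, in_core)
    absent_elsewhere = ~pa.presence[others].any(axis=0)
    return _family_array(pa, in_core & absent_elsewhere)


def strain_unique(pa: PresenceAbsenceMatrix, strain: str) -> set[int]:
    """Families whose presence is confined to ``strain`` across the whole dataset."""
    i = pa.strain_index(strain)
    pres = pa.presence
    only_here = pres[i] & (pres.sum(axis=0) == 1)
    return _family_array(pa, only_here)


def flower_counts(pa: PresenceAbsenceMatrix, level: str = "genus") -> dict:
    """Counts behind a flower plot.

    level="genus": center = genus core size, petals = species-specific
    (all_others) counts per species. level=<species name>: center = that
    species' core size, petals = strain-unique counts for each of its strains
    (uniqueness judged against the whole dataset).
    """
    if level == "genus":
        return {
            "center": len(core_families(pa)),
            "petals": {
                sp: len(species_specific(pa, sp, mode="all_others"))
                for sp in pa.species_map.species
            },
        }
    species = level
    return {
        "center": len(species_core(pa, species)),
        "petals": {
            strain: len(strain_unique(pa, strain))
            for strain in pa.species_map.strains_of(species)
        },
    }


def core_percentage(n_core: int, n_total: int) -> int:
    """Core genome share of all families, as the nearest-integer percent."""
    if n_total <= 0:
        raise ValueError("total family count must be positive")
    return int(np.floor(100.0 * n_core / n_total + 0.5))


@dataclass(frozen=True)
class GenomeSummary:
    strain: str
    genome_size_bp: int
    cds_count: int
    gc_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_percent <= 100.0):
            raise ValueError("gc_percent must be within [0, 100]")
        if self.cds_count < 0:
            raise ValueError("cds_count must be >= 0")


def genome_summary(
    contigs: list[SequenceRecord], cds_records: list[SequenceRecord], strain: str
) -> GenomeSummary:
    """Genome size, retained CDS count and GC% for one strain.

    GC% is 100*(G+C)/(A+C+G+T) over all contigs; ambiguity codes are excluded
    from numerator and denominator. Genome size counts all contig residues.
    """
    mine = [c for c in contigs if c.strain == strain]
    if not mine:
        raise ValueError(f"no contigs for strain {strain!r}")
    size = sum(len(c) for c in mine)
    gc = at = 0
    for c in mine:
        gc += c.residues.count("G") + c.residues.count("C")
        at += c.residues.count("A") + c.residues.count("T")
    if gc + at == 0:
        raise ValueError(f"strain {strain!r}: contigs contain no unambiguous bases")
    cds_count = sum(1 for r in cds_records if r.strain == strain)
    return GenomeSummary(
        strain=strain,
        genome_size_bp=size,
        cds_count=cds_count,
        gc_percent=100.0 * gc / (gc + at),
    )
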