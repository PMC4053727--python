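"""Readers and writers for the plain-text formats used throughout the package.

Three formats cover everything: multi-record FASTA (proteomes, contigs),
Newick with integer bootstrap labels on internal nodes, and headered TSV
tables (species map, COG labels, phenotype measurements, cluster tables).
All readers validate and reject malformed input rather than repairing it;
FASTA and TSV round-trips are lossless.

FASTA headers follow the ``>strain|gene_id [description]`` convention: every
sequence is attributed to a strain, and strains map to species through a
:class:`SpeciesMap` loaded from a two-column TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd

__all__ = [
    "SequenceRecord",
    "SpeciesMap",
    "FastaError",
    "TableError",
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_species_map",
    "write_newick",
    "SPECIES_MAP_SCHEMA",
    "COG_SCHEMA",
    "PHENOTYPE_SCHEMA",
    "CLUSTER_SCHEMA",
]

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# A,C,G,T,N plus the IUPAC two/three-base ambiguity letters.
NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_FASTA_WRAP = 60


class FastaError(ValueError):
    """Malformed FASTA input."""


class TableError(ValueError):
    """Malformed TSV table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One gene, protein, or contig with its strain/species attribution.

    ``id`` is the full FASTA identifier (``strain|gene_id``); ``strain`` is
    the part before the first ``|`` (empty if the header carries none) and
    ``species`` is filled from a :class:`SpeciesMap`, never guessed from the
    sequence itself.
    """

    id: str
    residues: str
    alphabet: str = "protein"  # "protein" | "nucleotide"
    strain: str = ""
    species: str = ""
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SpeciesMap:
    """Total mapping strain -> species name."""

    entries: dict[str, str] = field(default_factory=dict)

    def species_of(self, strain: str) -> str:
        try:
            return self.entries[strain]
        except KeyError:
            raise KeyError(f"strain {strain!r} is not in the species map") from None

    @property
    def strains(self) -> list[str]:
        return list(self.entries)

    @property
    def species(self) -> list[str]:
        """Distinct species names, in first-appearance order."""
        return list(dict.fromkeys(self.entries.values()))

    def strains_of(self, species: str) -> list[str]:
        hits = [s for s, sp in self.entries.items() if sp == species]
        if not hits:
            raise KeyError(f"species {species!r} is not in the species map")
        return hits

    def __contains__(self, strain: str) -> bool:
        return strain in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def _validate_residues(rec_id: str, residues: str, alphabet: str) -> None:
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else NUCLEOTIDE_ALPHABET
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise FastaError(
                f"record {rec_id!r}: residue {ch!r} at position {pos + 1} is not a "
                f"valid {alphabet} symbol"
            )


def read_fasta(
    path: str | Path,
    alphabet: str = "protein",
    species_map: SpeciesMap | None = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased, multi-line entries concatenated, and ``U``
    mapped to ``T`` for nucleotide input. Order is preserved. Duplicate ids,
    residues outside the alphabet, entries with no sequence, and empty files
    are all errors.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rec_id, _, description = header.partition(" ")
        if not rec_id:
            raise FastaError(f"{path}: header with empty identifier")
        if rec_id in seen:
            raise FastaError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        residues = "".join(chunks).upper()
        if alphabet == "nucleotide":
            residues = residues.replace("U", "T")
        if not residues:
            raise FastaError(f"{path}: record {rec_id!r} has an empty sequence")
        _validate_residues(rec_id, residues, alphabet)
        strain = rec_id.partition("|")[0] if "|" in rec_id else ""
        species = ""
        if species_map is not None and strain:
            species = species_map.species_of(strain)
        records.append(
            SequenceRecord(
                id=rec_id,
                residues=residues,
                alphabet=alphabet,
                strain=strain,
                species=species,
                description=description.strip(),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FastaError(f"{path}: sequence data before first '>' header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapping sequence lines at 60 columns."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), _FASTA_WRAP):
                fh.write(rec.residues[i : i + _FASTA_WRAP] + "\n")


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

# Schemas: column name -> (type, nullable). "NA" is the only missing token and
# is accepted only in nullable columns.
SPECIES_MAP_SCHEMA = {"strain": (str, False), "species": (str, False)}
COG_SCHEMA = {"gene_id": (str, False), "category": (str, True)}
PHENOTYPE_SCHEMA = {
    "strain": (str, False),
    "host_genotype": (str, False),
    "trait": (str, False),
    "replicate": (int, False),
    "value": (float, False),
}
CLUSTER_SCHEMA = {
    "family_id": (int, False),
    "representative": (str, False),
    "member": (str, False),
    "strain": (str, False),
}


def read_table(path: str | Path, schema: dict[str, tuple[type, bool]]) -> pd.DataFrame:
    """Read a headered TSV against ``schema``, typing columns and checking values.

    Raises :class:`TableError` naming any missing required column, and any
    non-numeric value in a numeric column with its (1-based, data) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, quoting=3)
    for col in schema:
        if col not in df.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    df = df[list(schema)]
    for col, (typ, nullable) in schema.items():
        vals = df[col]
        is_na = vals == "NA"
        if is_na.any() and not nullable:
            row = int(is_na.idxmax()) + 1
            raise TableError(f"{path}: 'NA' not permitted in column {col!r} (row {row})")
        if typ in (int, float):
            converted = pd.to_numeric(vals.mask(is_na), errors="coerce")
            bad = converted.isna() & ~is_na
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise TableError(
                    f"{path}: non-numeric value {vals[bad.idxmax()]!r} in numeric "
                    f"column {col!r} (row {row})"
                )
            df[col] = converted.astype("Int64" if typ is int and is_na.any() else typ)
        else:
            df[col] = vals.mask(is_na, None) if nullable else vals
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as unquoted TSV with 'NA' for missing values."""
    out = df.copy()
    # Render floats without trailing noise so read/write round-trips exactly.
    for col in out.columns:
        if out[col].dtype == float:
            out[col] = out[col].map(
                lambda x: "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else repr(x)
            )
    out.to_csv(path, sep="\t", index=False, na_rep="NA", quoting=3)


def read_species_map(path: str | Path) -> SpeciesMap:
    df = read_table(path, SPECIES_MAP_SCHEMA)
    dups = df["strain"][df["strain"].duplicated()]
    if not dups.empty:
        raise TableError(f"{path}: duplicate strain {dups.iloc[0]!r} in species map")
    return SpeciesMap(dict(zip(df["strain"], df["species"])))


# --------------------------------------------------------------------------
# Newick
# --------------------------------------------------------------------------


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.10g}"


def _newick_node(node: dendropy.Node, include_support: bool) -> str:
    if node.is_leaf():
        label = node.taxon.label if node.taxon is not None else (node.label or "")
        out = label
    else:
        inner = ",".join(_newick_node(c, include_support) for c in node.child_nodes())
        support = ""
        if include_support and node.label is not None:
            support = str(node.label)
        out = f"({inner}){support}"
    if node.edge.length is not None:
        out += f":{_format_length(node.edge.length)}"
    return out


def write_newick(tree: dendropy.Tree, path: str | Path, include_support: bool = True) -> None:
    """Serialize a tree to Newick.

    Bootstrap supports (stored as internal node labels) are written as
    internal node labels; polytomies come out as multifurcations. A 2-leaf
    tree is emitted as a plain cherry.
    """
    text = _newick_node(tree.seed_node, include_support)
    with open(path, "w") as fh:
        fh.write(text + ";\n")


def newick_string(tree: dendropy.Tree, include_support: bool = True) -> str:
    """Newick serialization as a string (same format as :func:`write_newick`)."""
    return _newick_node(tree.seed_node, include_support) + ";"
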