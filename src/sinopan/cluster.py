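"""Greedy identity-threshold protein clustering (CD-HIT-style) and the short-CDS filter.

The pan-genome pivot: all protein CDSs are clustered into gene families at a
fractional-identity threshold (default 70%). Identity between two sequences is
computed on a unit-cost Needleman-Wunsch global alignment (minimum edit
distance, via edlib) as

    identity(a, b) = (# identical aligned residue pairs) / (alignment columns)

The alignment-column denominator is scale-free: unrelated random proteins
score ~0.2 regardless of their length ratio (a shorter-sequence denominator
degenerates for length-discordant pairs, where a global alignment can match
most of the short sequence into the long one), while indel-free homologs
with a fraction k/L of substituted positions score exactly (L-k)/L.
Greedy clustering processes
records in decreasing-length order; each record joins the existing
representative of highest identity >= threshold, or founds a new family.
Unlike CD-HIT's k-mer heuristic, every candidate representative is screened
with an exact bound, so output is a deterministic function of the input set
(invariant to record order).

The screen: for ANY global alignment of sequences with shorter length Ls,
longer length Ll and unit-cost edit distance d, the number of identical
aligned pairs m satisfies  m <= Ls - (d - (Ll - Ls)) / 2,  and the alignment
has at least Ll columns, so identity <= (Ls - (d - dL)/2) / Ll. Candidates
whose bound falls below the running best are skipped without computing a
traceback (length-discordant pairs are skipped with no alignment at all);
edlib's banded mode (``k``) abandons hopeless distance computations early.
This is a provable cutoff, not a heuristic: results equal brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .io import SequenceRecord, SpeciesMap

__all__ = [
    "ClusteringConfig",
    "ClusterTable",
    "filter_short_cds",
    "global_identity",
    "identity_bound_from_distance",
    "greedy_cluster",
    "presence_matrix",
]


@dataclass(frozen=True)
class ClusteringConfig:
    """Parameters of the clustering stage.

    identity_threshold: minimum fractional identity to join a family (0, 1].
    min_aa_length: shortest protein kept by the CDS filter (inclusive).
    """

    identity_threshold: float = 0.70
    min_aa_length: int = 11

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_aa_length < 1:
            raise ValueError("min_aa_length must be >= 1")


def filter_short_cds(
    records: list[SequenceRecord], min_aa_length: int = 11
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split records into (kept, removed) by the minimum-length rule.

    Proteins shorter than ``min_aa_length`` residues (annotation fragments)
    are removed before clustering; a length of exactly ``min_aa_length`` is
    kept.
    """
    kept = [r for r in records if len(r) >= min_aa_length]
    removed = [r for r in records if len(r) < min_aa_length]
    return kept, removed


def _match_count(cigar: str) -> int:
    """Sum of '=' run lengths in an edlib extended CIGAR."""
    total = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            if ch == "=":
                total += num
            num = 0
    return total


def _cigar_identity(cigar: str) -> float:
    """(identical pairs) / (alignment columns) from an edlib extended CIGAR."""
    matches = 0
    columns = 0
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            columns += num
            if ch == "=":
                matches += num
            num = 0
    return matches / columns


def global_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Fractional identity of the global alignment of ``a`` and ``b``.

    Symmetric, 1.0 for identical sequences, and 0.0 when no residue pair can
    be matched. Raises ``ValueError`` on empty input or mismatched alphabets.
    """
    sa, sb = _residues(a), _residues(b)
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    if (
        isinstance(a, SequenceRecord)
        and isinstance(b, SequenceRecord)
        and a.alphabet != b.alphabet
    ):
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    if sa == sb:
        return 1.0
    # The optimal edit path is not unique; fix a canonical argument order so
    # the tie-break (and hence the identity) is symmetric in (a, b).
    if (len(sb), sb) < (len(sa), sa):
        sa, sb = sb, sa
    res = edlib.align(sa, sb, mode="NW", task="path")
    return _cigar_identity(res["cigar"])


def _residues(x: SequenceRecord | str) -> str:
    return x.residues if isinstance(x, SequenceRecord) else x


def identity_bound_from_distance(d: int, len_a: int, len_b: int) -> float:
    """Upper bound on global-alignment identity given unit-cost edit distance.

    Valid for any global alignment: matches m <= Ls - (d - dL)/2 with
    Ls = min length, dL = |len_a - len_b|, over at least Ll columns.
    """
    ls, ll = min(len_a, len_b), max(len_a, len_b)
    return (ls - (d - (ll - ls)) / 2.0) / ll


def _screened_identity(sa: str, sb: str, floor: float) -> float | None:
    """Exact identity if it can reach ``floor``; None if provably below it.

    Length-discordant pairs are rejected outright; the rest get a banded
    distance-only alignment, and only candidates whose identity bound
    reaches ``floor`` get a full traceback.
    """
    if (len(sb), sb) < (len(sa), sa):  # canonical order, as in global_identity
        sa, sb = sb, sa
    ls, ll = min(len(sa), len(sb)), max(len(sa), len(sb))
    # identity <= Ls/Ll outright (matches <= Ls over >= Ll columns)
    if floor * ll > ls:
        return None
    # identity >= floor further requires d <= 2*(Ls - floor*Ll) + dL
    k = int(2 * (ls - floor * ll)) + (ll - ls)
    if k < 0:
        return None
    res = edlib.align(sa, sb, mode="NW", task="distance", k=k)
    if res["editDistance"] < 0:
        return None
    if res["editDistance"] == 0:
        return 1.0
    res = edlib.align(sa, sb, mode="NW", task="path")
    return _cigar_identity(res["cigar"])


@dataclass
class ClusterTable:
    """The gene-family partition: ordered clusters plus a gene -> family index.

    Each cluster is (family_id, representative id, member ids). The
    representative is the longest member (ties broken by lexicographically
    smallest id), and every member has identity >= threshold to it.
    """

    clusters: list[tuple[int, str, list[str]]] = field(default_factory=list)
    family_of: dict[str, int] = field(default_factory=dict)
    strain_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_genes(self) -> int:
        return len(self.family_of)

    def members(self, family_id: int) -> list[str]:
        return self.clusters[family_id][2]

    def representative(self, family_id: int) -> str:
        return self.clusters[family_id][1]


def greedy_cluster(
    records: list[SequenceRecord], config: ClusteringConfig | None = None
) -> ClusterTable:
    """Cluster length-filtered protein records into gene families.

    Records are sorted by decreasing length (ties: lexicographic id); the
    first unassigned record founds a new family and becomes its
    representative; each later record joins the representative with the
    highest identity >= threshold (ties: lowest family id), else founds a new
    family. Deterministic and order-invariant for a fixed record set.
    """
    config = config or ClusteringConfig()
    theta = config.identity_threshold
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    ids = set()
    for r in ordered:
        if r.id in ids:
            raise ValueError(f"duplicate record id {r.id!r}")
        ids.add(r.id)

    table = ClusterTable()
    rep_seqs: list[str] = []
    for rec in ordered:
        best_fam = -1
        best_ident = 0.0
        for fam, rep in enumerate(rep_seqs):
            # The bound must reach theta, and beat the best hit so far
            # (strictly: on a tie we keep the lowest family id).
            ident = _screened_identity(rec.residues, rep, max(theta, best_ident))
            if ident is not None and ident >= theta and ident > best_ident:
                best_fam, best_ident = fam, ident
        if best_fam >= 0:
            table.clusters[best_fam][2].append(rec.id)
            table.family_of[rec.id] = best_fam
        else:
            fam = len(rep_seqs)
            table.clusters.append((fam, rec.id, [rec.id]))
            table.family_of[rec.id] = fam
            rep_seqs.append(rec.residues)
        table.strain_of[rec.id] = rec.strain
    return table


def presence_matrix(table: ClusterTable, species_map: SpeciesMap):
    """Strain x family member-count matrix (presence = count >= 1).

    Every gene's strain must appear in the species map. Returns a
    :class:`~sinopan.pangenome.PresenceAbsenceMatrix`.
    """
    from .pangenome import PresenceAbsenceMatrix
    import numpy as np

    strains = species_map.strains
    index = {s: i for i, s in enumerate(strains)}
    counts = np.zeros((len(strains), len(table)), dtype=np.int32)
    for gene, fam in table.family_of.items():
        strain = table.strain_of[gene]
        if strain not in index:
            raise KeyError(f"gene {gene!r}: strain {strain!r} is not in the species map")
        counts[index[strain], fam] += 1
    return PresenceAbsenceMatrix(
        strains=strains,
        families=[fam for fam, _, _ in table.clusters],
        counts=counts,
        species_map=species_map,
    )
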