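"""Distance-based phylogeny from concatenated nucleotide alignments.

The pipeline mirrors the classic PHYLIP workflow: pairwise evolutionary
distances under the F84 substitution model (dnadist), a neighbor-joining tree
(neighbor, Saitou-Nei agglomeration with the Studier-Keppler Q-criterion),
split supports from column-bootstrap replicates (seqboot + sumtrees-style
mapping onto the full-data tree), and collapse of poorly supported splits
into polytomies.

F84 distinguishes transitions from transversions with unequal base
frequencies. With P and Q the proportions of sites differing by a transition
and a transversion, and empirical frequencies pi, define

    piR = piA + piG,  piY = piC + piT
    A = piC*piT/piY + piA*piG/piR,  B = piC*piT + piA*piG,  C = piR*piY

    d = -2A * ln(1 - P/(2A) - (A-B)*Q/(2AC)) + 2(A-B-C) * ln(1 - Q/(2C))

the method-of-moments form used by dnadist. Base frequencies are pooled over
the whole alignment by default; sites with a non-ACGT symbol in either
sequence of a pair are skipped (pairwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .cluster import ClusterTable, _screened_identity
from .io import SequenceRecord

import edlib

__all__ = [
    "Alignment",
    "F84Observed",
    "DistanceMatrix",
    "SaturationError",
    "select_single_copy_families",
    "bidirectional_best_hits",
    "f84_distance",
    "distance_matrix",
    "neighbor_joining",
    "tree_splits",
    "bootstrap_supports",
    "annotate_supports",
    "collapse_low_support",
    "build_tree",
    "path_length_matrix",
]

# nucleotide codes: A=0, C=1, G=2, T=3, anything else 4 (skipped pairwise)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class SaturationError(ValueError):
    """Distance undefined: observed divergence at or beyond model saturation."""

    def __init__(self, taxon_i: str, taxon_j: str, detail: str = ""):
        self.pair = (taxon_i, taxon_j)
        msg = f"saturated F84 distance for pair ({taxon_i!r}, {taxon_j!r})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class Alignment:
    """Equal-length nucleotide alignment held as a coded numpy matrix."""

    def __init__(self, taxa: list[str], matrix: np.ndarray):
        if len(taxa) != matrix.shape[0]:
            raise ValueError("one row per taxon required")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        self.taxa = list(taxa)
        self.matrix = np.asarray(matrix, dtype=np.uint8)

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "Alignment":
        taxa = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        (length,) = lengths
        if length == 0:
            raise ValueError("alignment has zero columns")
        mat = np.empty((len(taxa), length), dtype=np.uint8)
        for i, t in enumerate(taxa):
            mat[i] = _CODE[np.frombuffer(seqs[t].upper().encode(), dtype=np.uint8)]
        return cls(taxa, mat)

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "Alignment":
        return cls.from_sequences({r.id: r.residues for r in records})

    @classmethod
    def concat(cls, alignments: list["Alignment"]) -> "Alignment":
        """Append columns of several alignments sharing the same taxon set."""
        if not alignments:
            raise ValueError("nothing to concatenate")
        taxa = alignments[0].taxa
        mats = []
        for aln in alignments:
            if set(aln.taxa) != set(taxa):
                raise ValueError("alignments do not share a taxon set")
            order = [aln.taxa.index(t) for t in taxa]
            mats.append(aln.matrix[order])
        return cls(taxa, np.concatenate(mats, axis=1))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.matrix[self.taxa.index(taxon)]
        return "".join("ACGTN"[c] for c in row)


@dataclass(frozen=True)
class F84Observed:
    """Observed pair statistics feeding the F84 distance formula."""

    P: float  # proportion of comparable sites differing by a transition
    Q: float  # proportion differing by a transversion
    freqs: tuple[float, float, float, float]  # empirical piA, piC, piG, piT

    @property
    def A(self) -> float:
        a, c, g, t = self.freqs
        r, y = a + g, c + t
        return c * t / y + a * g / r

    @property
    def B(self) -> float:
        a, c, g, t = self.freqs
        return c * t + a * g

    @property
    def C(self) -> float:
        a, c, g, t = self.freqs
        return (a + g) * (c + t)


def _f84_from_observed(obs: F84Observed, pair: tuple[str, str]) -> float:
    A, B, C = obs.A, obs.B, obs.C
    arg1 = 1.0 - obs.P / (2.0 * A) - (A - B) * obs.Q / (2.0 * A * C)
    arg2 = 1.0 - obs.Q / (2.0 * C)
    if arg1 <= 0.0 or arg2 <= 0.0:
        raise SaturationError(pair[0], pair[1], f"log argument <= 0 (P={obs.P:.4g}, Q={obs.Q:.4g})")
    return -2.0 * A * math.log(arg1) + 2.0 * (A - B - C) * math.log(arg2)


_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}


def _pooled_freqs(matrix: np.ndarray, weights: np.ndarray | None = None) -> tuple:
    counts = np.zeros(4)
    for b in range(4):
        mask = matrix == b
        counts[b] = (mask * weights).sum() if weights is not None else mask.sum()
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    if (counts == 0).any():
        raise ValueError("F84 frequencies require all four bases to occur")
    return tuple(counts / total)


def _encode(seq: SequenceRecord | str) -> np.ndarray:
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    return _CODE[np.frombuffer(s.upper().encode(), dtype=np.uint8)]


def f84_distance(
    seq_i: SequenceRecord | str,
    seq_j: SequenceRecord | str,
    frequencies: tuple[float, float, float, float] | None = None,
    names: tuple[str, str] = ("seq_i", "seq_j"),
) -> float:
    """F84 distance between two equal-length aligned nucleotide sequences.

    Sites where either sequence has a non-ACGT symbol are skipped. With
    ``frequencies`` omitted, base frequencies are pooled over the two
    sequences. Raises :class:`SaturationError` when the log arguments are
    non-positive, and ``ValueError`` with zero comparable sites.
    """
    ci, cj = _encode(seq_i), _encode(seq_j)
    if ci.shape != cj.shape:
        raise ValueError("sequences must be aligned to equal length")
    valid = (ci < 4) & (cj < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError(f"no comparable sites for pair {names}")
    vi, vj = ci[valid], cj[valid]
    diff = vi != vj
    transition = diff & (((vi == 0) & (vj == 2)) | ((vi == 2) & (vj == 0))
                         | ((vi == 1) & (vj == 3)) | ((vi == 3) & (vj == 1)))
    P = float(transition.sum()) / n
    Q = float((diff & ~transition).sum()) / n
    if frequencies is None:
        frequencies = _pooled_freqs(np.stack([vi, vj]))
    obs = F84Observed(P=P, Q=Q, freqs=tuple(frequencies))
    if P == 0.0 and Q == 0.0:
        return 0.0
    return _f84_from_observed(obs, names)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


class _PairStats:
    """Per-pair site-category masks enabling fast reweighted distance matrices.

    For every taxon pair the columns are classified once (comparable /
    transition / transversion); a bootstrap replicate is then just a
    reweighting of columns, so each replicate's distance matrix costs three
    matrix-vector products instead of a fresh scan of the alignment.
    """

    def __init__(self, aln: Alignment):
        self.aln = aln
        n = aln.n_taxa
        self.pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        mat = aln.matrix
        valid = mat < 4
        P_rows, Q_rows, V_rows = [], [], []
        for i, j in self.pairs:
            v = valid[i] & valid[j]
            diff = v & (mat[i] != mat[j])
            ts = diff & (
                ((mat[i] == 0) & (mat[j] == 2)) | ((mat[i] == 2) & (mat[j] == 0))
                | ((mat[i] == 1) & (mat[j] == 3)) | ((mat[i] == 3) & (mat[j] == 1))
            )
            V_rows.append(v)
            P_rows.append(ts)
            Q_rows.append(diff & ~ts)
        self.V = np.array(V_rows, dtype=np.float64)
        self.P = np.array(P_rows, dtype=np.float64)
        self.Q = np.array(Q_rows, dtype=np.float64)
        self.base_counts = np.stack([
            ((mat == b) & valid).sum(axis=0).astype(np.float64) for b in range(4)
        ])

    def distance_matrix(self, weights: np.ndarray | None = None) -> DistanceMatrix:
        n = self.aln.n_taxa
        if weights is None:
            weights = np.ones(self.aln.n_sites)
        counts = self.base_counts @ weights
        total = counts.sum()
        if total == 0 or (counts == 0).any():
            raise ValueError("F84 frequencies require all four bases to occur")
        freqs = tuple(counts / total)
        vc = self.V @ weights
        pc = self.P @ weights
        qc = self.Q @ weights
        d = np.zeros((n, n))
        for k, (i, j) in enumerate(self.pairs):
            if vc[k] == 0:
                raise ValueError(
                    f"no comparable sites for pair ({self.aln.taxa[i]!r}, {self.aln.taxa[j]!r})"
                )
            P, Q = pc[k] / vc[k], qc[k] / vc[k]
            if P == 0.0 and Q == 0.0:
                continue
            obs = F84Observed(P=P, Q=Q, freqs=freqs)
            d[i, j] = d[j, i] = _f84_from_observed(
                obs, (self.aln.taxa[i], self.aln.taxa[j])
            )
        return DistanceMatrix(list(self.aln.taxa), d)


def distance_matrix(aln: Alignment, frequency_mode: str = "pooled") -> DistanceMatrix:
    """All-pairs F84 distances for an alignment.

    frequency_mode="pooled" (default, dnadist behaviour) estimates base
    frequencies once over the whole alignment; "pairwise" re-estimates them
    per pair from the two sequences.
    """
    if frequency_mode == "pooled":
        return _PairStats(aln).distance_matrix()
    if frequency_mode != "pairwise":
        raise ValueError(f"unknown frequency_mode {frequency_mode!r}")
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = f84_distance(
                "".join("ACGTN"[c] for c in aln.matrix[i]),
                "".join("ACGTN"[c] for c in aln.matrix[j]),
                names=(aln.taxa[i], aln.taxa[j]),
            )
    return DistanceMatrix(list(aln.taxa), d)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Deterministic: among Q-minimal pairs the lexicographically smallest pair
    (keyed by the smallest leaf name under each node) is joined. Negative
    branch-length estimates are clamped to zero with the deficit moved to the
    sibling edge (PHYLIP-compatible). Returns an unrooted tree whose seed
    node is the final trifurcation (bifurcation for 2-3 taxa).
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    d = np.array(dm.d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")

    ns = dendropy.TaxonNamespace(dm.taxa)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: list[dendropy.Node] = []
    for t in dm.taxa:
        node = dendropy.Node(taxon=ns.get_taxon(t))
        nodes.append(node)
    keys = list(dm.taxa)  # smallest leaf name under each active node
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tol = 1e-9 * (1.0 + abs(qmin))
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + tol:
                    key = tuple(sorted((keys[active[a]], keys[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    seed = dendropy.Node()
    if len(active) == 2:
        i, j = active
        dij = d[i, j]
        for k, length in ((i, dij / 2.0), (j, dij / 2.0)):
            seed.add_child(nodes[k])
            nodes[k].edge.length = length
    else:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, length in ((i, li), (j, lj), (k, lk)):
            seed.add_child(nodes[idx])
            nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def path_length_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree (the additive metric it encodes)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(taxa)
    d = np.zeros((n, n))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax[taxa[i]], tax[taxa[j]])
    return DistanceMatrix(taxa, d)


# --------------------------------------------------------------------------
# Splits, bootstrap, collapse
# --------------------------------------------------------------------------


def tree_splits(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Non-trivial bipartitions of the leaf set, canonically keyed.

    Each internal edge induces a split; the key is the frozenset of leaf
    names on the side NOT containing the reference taxon (the
    lexicographically smallest leaf name), so keys are comparable across
    trees on the same leaf set regardless of rooting.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    splits: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            splits[side] = node
    return splits


def bootstrap_supports(
    aln: Alignment,
    n_reps: int = 1000,
    seed: int | None = None,
    tree: dendropy.Tree | None = None,
) -> tuple[dict[frozenset, float], int]:
    """Split support percentages from column-bootstrap replicates.

    Columns are resampled with replacement per replicate and the full
    distance + neighbor-joining pipeline is rerun. Returns (split -> percent,
    number of skipped replicates); replicates whose distance matrix saturates
    are skipped, not retried, and removed from the denominator. Supports are
    for all splits seen in any replicate; map them onto a reference tree with
    :func:`annotate_supports`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    stats = _PairStats(aln)
    counts: dict[frozenset, int] = {}
    skipped = 0
    L = aln.n_sites
    for _ in range(n_reps):
        weights = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float64)
        try:
            dm = stats.distance_matrix(weights)
            rep_tree = neighbor_joining(dm)
        except (SaturationError, ValueError):
            skipped += 1
            continue
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    denom = n_reps - skipped
    if denom == 0:
        raise SaturationError("*", "*", "every bootstrap replicate saturated")
    return {s: 100.0 * c / denom for s, c in counts.items()}, skipped


def annotate_supports(tree: dendropy.Tree, supports: dict[frozenset, float]) -> None:
    """Write integer supports onto the matching internal nodes of ``tree``.

    Splits of the tree absent from ``supports`` get support 0.
    """
    for split, node in tree_splits(tree).items():
        node.label = str(int(round(supports.get(split, 0.0))))


def collapse_low_support(tree: dendropy.Tree, threshold: int = 60) -> dendropy.Tree:
    """Collapse internal edges with support strictly below ``threshold``.

    Supports are read from the integer internal-node labels written by
    :func:`annotate_supports`. Endpoints of collapsed edges merge into
    polytomies; the leaf set is unchanged.
    """
    doomed = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf() or node.label is None:
            continue
        if int(node.label) < threshold:
            doomed.append(node)
    for node in doomed:
        node.edge.collapse()
    return tree


def build_tree(
    aln: Alignment,
    outgroup: str | None = None,
    n_reps: int = 1000,
    collapse_threshold: int = 60,
    seed: int | None = None,
) -> tuple[dendropy.Tree, dict[frozenset, float], int]:
    """Full-data NJ tree with bootstrap supports and sub-threshold collapse.

    Returns (tree, supports, skipped replicates). The tree is rooted at the
    outgroup leaf for reporting only; all computation is on unrooted trees.
    """
    dm = distance_matrix(aln)
    tree = neighbor_joining(dm)
    supports, skipped = bootstrap_supports(aln, n_reps=n_reps, seed=seed)
    annotate_supports(tree, supports)
    collapse_low_support(tree, collapse_threshold)
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        length = node.edge.length or 0.0
        tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    return tree, supports, skipped


# --------------------------------------------------------------------------
# Ortholog selection for the concatenated alignment
# --------------------------------------------------------------------------


def select_single_copy_families(table: ClusterTable, strains: list[str]) -> set[int]:
    """Families with exactly one member in every strain of ``strains``."""
    wanted = set(strains)
    out: set[int] = set()
    for fam, _rep, members in table.clusters:
        per_strain: dict[str, int] = {}
        for gene in members:
            s = table.strain_of[gene]
            if s in wanted:
                per_strain[s] = per_strain.get(s, 0) + 1
        if len(per_strain) == len(wanted) and all(c == 1 for c in per_strain.values()):
            out.add(fam)
    return out


def bidirectional_best_hits(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
) -> list[tuple[str, str]]:
    """Reciprocal unique best-identity hits between two proteomes.

    A pair (a, b) is reported iff b is a's unique best-identity hit and vice
    versa, identity >= ``min_identity`` (strictly below is rejected), and the
    aligned span (aligned residue pairs) covers >= ``min_coverage`` of BOTH
    sequence lengths. Identity is global-alignment identity as in
    :func:`sinopan.cluster.global_identity`.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    def alignment_stats(sa: str, sb: str) -> tuple[float, float, float]:
        """(identity, coverage_a, coverage_b); exact when identity can reach
        min_identity, else identity reported as 0."""
        ident = _screened_identity(sa, sb, min_identity)
        if ident is None:
            return 0.0, 0.0, 0.0
        res = edlib.align(sa, sb, mode="NW", task="path")
        matches = columns = span = num = 0
        for ch in res["cigar"]:
            if ch.isdigit():
                num = num * 10 + ord(ch) - 48
            else:
                columns += num
                if ch in "=X":
                    span += num
                if ch == "=":
                    matches += num
                num = 0
        return matches / columns, span / len(sa), span / len(sb)

    def best_hits(src: list[SequenceRecord], dst: list[SequenceRecord]) -> dict:
        hits: dict[str, tuple[str, float, float, float]] = {}
        for a in src:
            best: tuple[str, float, float, float] | None = None
            unique = True
            for b in dst:
                ident, cov_a, cov_b = alignment_stats(a.residues, b.residues)
                if ident < min_identity:
                    continue
                if best is None or ident > best[1]:
                    best = (b.id, ident, cov_a, cov_b)
                    unique = True
                elif ident == best[1]:
                    unique = False
            if best is not None and unique:
                hits[a.id] = best
        return hits

    fwd = best_hits(proteome_a, proteome_b)
    rev = best_hits(proteome_b, proteome_a)
    pairs = []
    for a_id, (b_id, _ident, cov_a, cov_b) in sorted(fwd.items()):
        if rev.get(b_id, (None,))[0] == a_id and cov_a >= min_coverage and cov_b >= min_coverage:
            pairs.append((a_id, b_id))
    return pairs
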