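"""Synthetic pan-genomes, F84-evolved alignments, and phenotype tables with planted truth.

Every generator is a pure function of its configuration (including the seed)
and returns, next to the data, a truth table sufficient to score every
downstream stage: the planted family partition and family classes for
clustering and pan-genome set algebra, the generating tree for phylogeny,
and the planted phenotype-cluster labels for the phenotype stage.

The pan-genome generator emulates the structure of a multi-species bacterial
collection: gene families partitioned into genus-core / species-core /
species-specific / strain-unique classes, within-family identity held above
the 70% clustering threshold and between-family identity below it. Family
ancestors are i.i.d. uniform random proteins (rejection-sampled for pairwise
separation) and members are ancestors with point substitutions only, so the
planted identity is exact by construction: k substitutions on length L give
identity (L - k) / L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import SequenceRecord, SpeciesMap
from .phylo import Alignment

__all__ = [
    "PangenomeConfig",
    "SyntheticTruth",
    "F84Params",
    "PhenotypeConfig",
    "generate_pangenome",
    "f84_rate_matrix",
    "f84_transition_matrix",
    "simulate_f84_alignment",
    "random_binary_tree",
    "generate_strain_tree",
    "generate_phenotypes",
    "generate_contigs",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
CLUSTERING_THRESHOLD = 0.70  # the identity cut-off the planted structure must straddle

# COG category weights for planted-core vs planted-accessory families,
# reproducing the canonical enrichment pattern: core genomes lean towards
# translation/energy/envelope housekeeping (C, F, H, M, J, V), accessory
# genomes towards regulation and secondary metabolism (Q, D, K, L).
DEFAULT_CORE_COG_WEIGHTS = {
    "C": 2.0, "F": 2.0, "H": 2.0, "M": 2.0, "J": 2.0, "V": 2.0,
    "Q": 1.0, "D": 1.0, "K": 1.0, "L": 1.0, "G": 1.0, "E": 1.0,
}
DEFAULT_ACCESSORY_COG_WEIGHTS = {
    "C": 1.0, "F": 1.0, "H": 1.0, "M": 1.0, "J": 1.0, "V": 1.0,
    "Q": 2.0, "D": 2.0, "K": 2.0, "L": 2.0, "G": 1.0, "E": 1.0,
}


@dataclass(frozen=True)
class PangenomeConfig:
    """Planted pan-genome structure.

    Defaults describe a desk-scale collection: 5 species with a skewed
    strain distribution (20 strains), ~600 gene families dominated by
    accessory classes, within-family identity 0.90 (well above the 0.70
    clustering threshold) and between-family identity at most 0.30 (well
    below it).
    """

    strains_per_species: tuple[int, ...] = (8, 5, 3, 2, 2)
    n_genus_core: int = 40
    n_species_core_extra: int = 20  # per species, on top of the genus core
    n_species_specific: int = 40  # per species
    n_strain_unique: tuple[int, int] = (10, 16)  # inclusive range per strain
    n_symbiosis: int = 0  # families present exactly in symbiosis_strains
    symbiosis_strains: tuple[str, ...] = ()
    within_family_identity: float = 0.90
    between_family_identity_max: float = 0.30
    protein_length: tuple[int, int] = (80, 400)
    fragmentation_rate: float = 0.01
    cog_assigned_fraction: float = 0.8
    cog_core_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_CORE_COG_WEIGHTS.items())
    cog_accessory_weights: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_ACCESSORY_COG_WEIGHTS.items()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.strains_per_species):
            raise ValueError("each species needs at least one strain")
        for name in ("n_genus_core", "n_species_core_extra", "n_species_specific", "n_symbiosis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (CLUSTERING_THRESHOLD < self.within_family_identity <= 1.0):
            raise ValueError(
                "within_family_identity must exceed the clustering threshold "
                f"{CLUSTERING_THRESHOLD}"
            )
        if not (0.0 < self.between_family_identity_max < CLUSTERING_THRESHOLD):
            raise ValueError(
                "between_family_identity_max must lie below the clustering threshold"
            )
        if self.protein_length[0] < 11 or self.protein_length[0] > self.protein_length[1]:
            raise ValueError("protein_length range must be valid and >= 11")
        if not (0.0 <= self.fragmentation_rate < 1.0):
            raise ValueError("fragmentation_rate must be in [0, 1)")

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(len(self.strains_per_species))]

    def strain_names(self) -> list[str]:
        out = []
        for i, n in enumerate(self.strains_per_species):
            out += [f"sp{i + 1}s{j + 1:02d}" for j in range(n)]
        return out

    def species_map(self) -> SpeciesMap:
        entries = {}
        for i, n in enumerate(self.strains_per_species):
            for j in range(n):
                entries[f"sp{i + 1}s{j + 1:02d}"] = f"sp{i + 1}"
        return SpeciesMap(entries)


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring every downstream stage."""

    family_of_gene: dict[str, int] = field(default_factory=dict)
    family_class: dict[int, str] = field(default_factory=dict)
    family_cog: dict[int, str | None] = field(default_factory=dict)
    family_ancestor: dict[int, str] = field(default_factory=dict)
    fragment_genes: set[str] = field(default_factory=set)

    def families_of_class(self, prefix: str) -> set[int]:
        return {f for f, c in self.family_class.items() if c.split(":")[0] == prefix}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _mutate(rng: np.random.Generator, ancestor: str, identity: float) -> str:
    """Point-substitute the ancestor down to exactly the target identity."""
    L = len(ancestor)
    k = int(round((1.0 - identity) * L))
    if k == 0:
        return ancestor
    positions = rng.choice(L, size=k, replace=False)
    seq = np.array([_AA_INDEX[c] for c in ancestor])
    # replacement drawn uniformly from the 19 residues != the original
    seq[positions] = (seq[positions] + 1 + rng.integers(0, 19, size=k)) % 20
    return "".join(AMINO_ACIDS[seq])


def _draw_separated_ancestors(
    rng: np.random.Generator,
    lengths: list[int],
    max_identity: float,
    max_retries: int = 50,
) -> list[str]:
    """i.i.d. uniform ancestors, rejection-sampled to pairwise identity <= bound."""
    import edlib

    from .cluster import _cigar_identity

    def separated(cand: str, other: str) -> bool:
        ls, ll = min(len(cand), len(other)), max(len(cand), len(other))
        if max_identity * ll > ls:  # identity <= Ls/Ll outright
            return True
        res = edlib.align(cand, other, mode="NW", task="path")
        return _cigar_identity(res["cigar"]) <= max_identity

    ancestors: list[str] = []
    for L in lengths:
        for attempt in range(max_retries):
            cand = _random_protein(rng, L)
            if all(separated(cand, a) for a in ancestors):
                ancestors.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place a family ancestor below identity "
                f"{max_identity} after {max_retries} retries"
            )
    return ancestors


def generate_pangenome(
    config: PangenomeConfig,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Generate per-strain proteomes with a planted family partition.

    Each family has one ancestral protein; members are the ancestor with
    point substitutions taking them to the configured within-family identity.
    Fragments (< 11 aa truncations) are emitted per ``fragmentation_rate``
    and recorded in the truth as filterable. Deterministic for a fixed
    config.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species_names
    smap = config.species_map()
    truth = SyntheticTruth()

    # family roster: (class label, member strains)
    roster: list[tuple[str, list[str]]] = []
    all_strains = config.strain_names()
    for _ in range(config.n_genus_core):
        roster.append(("genus_core", all_strains))
    for sp in species:
        members = smap.strains_of(sp)
        for _ in range(config.n_species_core_extra):
            roster.append((f"species_core:{sp}", members))
        for _ in range(config.n_species_specific):
            roster.append((f"species_specific:{sp}", members))
    for strain in all_strains:
        n_unique = int(rng.integers(config.n_strain_unique[0], config.n_strain_unique[1] + 1))
        for _ in range(n_unique):
            roster.append((f"strain_unique:{strain}", [strain]))
    for _ in range(config.n_symbiosis):
        if not config.symbiosis_strains:
            raise ValueError("n_symbiosis > 0 requires symbiosis_strains")
        roster.append(("symbiosis", list(config.symbiosis_strains)))

    lengths = [int(rng.integers(config.protein_length[0], config.protein_length[1] + 1))
               for _ in roster]
    ancestors = _draw_separated_ancestors(rng, lengths, config.between_family_identity_max)
    truth.family_ancestor = dict(enumerate(ancestors))

    core_w = dict(config.cog_core_weights)
    acc_w = dict(config.cog_accessory_weights)
    for fam, (cls, _members) in enumerate(roster):
        truth.family_class[fam] = cls
        if rng.random() < config.cog_assigned_fraction:
            weights = core_w if cls.split(":")[0] in ("genus_core", "species_core") else acc_w
            cats = list(weights)
            p = np.array([weights[c] for c in cats], dtype=float)
            truth.family_cog[fam] = str(rng.choice(cats, p=p / p.sum()))
        else:
            truth.family_cog[fam] = None

    records: list[SequenceRecord] = []
    counter = 0
    per_strain: dict[str, list[SequenceRecord]] = {s: [] for s in all_strains}
    for fam, (cls, members) in enumerate(roster):
        for strain in members:
            counter += 1
            gene_id = f"{strain}|g{counter:05d}"
            seq = _mutate(rng, ancestors[fam], config.within_family_identity)
            rec = SequenceRecord(
                id=gene_id,
                residues=seq,
                alphabet="protein",
                strain=strain,
                species=smap.species_of(strain),
            )
            per_strain[strain].append(rec)
            truth.family_of_gene[gene_id] = fam
            if rng.random() < config.fragmentation_rate:
                counter += 1
                frag_id = f"{strain}|g{counter:05d}"
                frag_len = int(rng.integers(3, 11))
                frag = SequenceRecord(
                    id=frag_id,
                    residues=ancestors[fam][:frag_len],
                    alphabet="protein",
                    strain=strain,
                    species=smap.species_of(strain),
                )
                per_strain[strain].append(frag)
                truth.fragment_genes.add(frag_id)
    for strain in all_strains:
        records.extend(per_strain[strain])
    return records, truth


# --------------------------------------------------------------------------
# F84 simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class F84Params:
    """F84 model parameters: base frequencies and transition bias kappa.

    The rate matrix is the standard two-process form: general exchange at a
    rate proportional to the target base frequency, plus an extra
    within-purine / within-pyrimidine rate scaled by kappa, normalized to
    one expected substitution per unit branch length.
    """

    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    kappa: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if (f <= 0).any():
            raise ValueError("base frequencies must be positive")
        if abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def f84_rate_matrix(params: F84Params) -> np.ndarray:
    """Calibrated F84 rate matrix Q (rows sum to 0, expected rate 1)."""
    pi = np.asarray(params.freqs, dtype=float)
    piR = pi[0] + pi[2]
    piY = pi[1] + pi[3]
    group = np.array([piR, piY, piR, piY])
    purine = np.array([True, False, True, False])
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if purine[i] == purine[j]:
                rate += params.kappa * pi[j] / group[j]
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def f84_transition_matrix(params: F84Params, t: float) -> np.ndarray:
    """Substitution-probability matrix P(t) = exp(Qt) for branch length t.

    Computed through the symmetric eigendecomposition of the
    time-reversible rate matrix (pi^1/2 Q pi^-1/2 is symmetric), so rows sum
    to 1, the stationary frequencies are preserved, and detailed balance
    holds to machine precision.
    """
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    pi = np.asarray(params.freqs, dtype=float)
    Q = f84_rate_matrix(params)
    sq = np.sqrt(pi)
    S = (sq[:, None] * Q) / sq[None, :]
    S = (S + S.T) / 2.0  # symmetrize away rounding noise
    w, V = np.linalg.eigh(S)
    P = (V * np.exp(w * t)) @ V.T
    P = P / sq[:, None] * sq[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def simulate_f84_alignment(
    tree: dendropy.Tree,
    params: F84Params,
    n_sites: int,
    seed: int | None = None,
) -> Alignment:
    """Evolve an alignment down ``tree`` under F84, site-independently.

    The root sequence is sampled from the stationary frequencies; every
    branch applies :func:`f84_transition_matrix` of its length. Branch
    lengths are expected substitutions per site. Returns the leaf alignment.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    pi = np.asarray(params.freqs, dtype=float)
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(4, size=n_sites, p=pi)
    leaf_seqs: dict[str, np.ndarray] = {}
    matrices: dict[float, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        else:
            t = node.edge.length or 0.0
            if t not in matrices:
                matrices[t] = f84_transition_matrix(params, t)
            P = matrices[t]
            parent_state = states[id(node.parent_node)]
            cum = np.cumsum(P, axis=1)
            u = rng.random(n_sites)
            child = (u[:, None] > cum[parent_state]).sum(axis=1)
            states[id(node)] = child.astype(np.int64)
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = states[id(node)]
    bases = np.array(list("ACGT"))
    return Alignment.from_sequences(
        {name: "".join(bases[s]) for name, s in leaf_seqs.items()}
    )


def random_binary_tree(
    labels: list[str],
    seed: int | None = None,
    blen_range: tuple[float, float] = (0.01, 0.2),
) -> dendropy.Tree:
    """Random rooted binary tree over ``labels`` with uniform branch lengths."""
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(nodes[k])
            nodes[k].edge.length = float(rng.uniform(*blen_range))
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    return tree


def generate_strain_tree(
    species_map: SpeciesMap,
    seed: int | None = None,
    within_blen: tuple[float, float] = (0.005, 0.02),
    between_blen: tuple[float, float] = (0.05, 0.15),
    outgroup: str | None = None,
    outgroup_blen: float = 0.25,
) -> dendropy.Tree:
    """Random species-structured strain tree: short branches within species
    clades, longer branches joining them, optionally an outgroup leaf."""
    rng = np.random.default_rng(seed)
    labels = species_map.strains + ([outgroup] if outgroup else [])
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)

    def join_all(nodes: list[dendropy.Node], blen: tuple[float, float]) -> dendropy.Node:
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            for k in (i, j):
                parent.add_child(nodes[k])
                nodes[k].edge.length = float(rng.uniform(*blen))
            nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
        return nodes[0]

    clades = []
    for sp in species_map.species:
        leaves = [dendropy.Node(taxon=ns.get_taxon(s)) for s in species_map.strains_of(sp)]
        clades.append(join_all(leaves, within_blen))
    root = join_all(clades, between_blen)
    if outgroup:
        og = dendropy.Node(taxon=ns.get_taxon(outgroup))
        og.edge.length = outgroup_blen
        new_root = dendropy.Node()
        new_root.add_child(root)
        root.edge.length = float(rng.uniform(*between_blen))
        new_root.add_child(og)
        root = new_root
    tree.seed_node = root
    return tree


# --------------------------------------------------------------------------
# Phenotypes
# --------------------------------------------------------------------------

DEFAULT_TRAITS = {
    # trait -> (baseline, noise sd); magnitudes emulate greenhouse symbiosis
    # assays: nodule counts ~tens, masses in mg, heights in cm, SPAD units.
    "nodule_number": (50.0, 5.0),
    "nodule_dry_mass_mg": (6.0, 0.6),
    "plant_dry_mass_mg": (180.0, 18.0),
    "plant_height_cm": (10.0, 1.0),
    "chlorophyll_spad": (40.0, 4.0),
}


@dataclass(frozen=True)
class PhenotypeConfig:
    """Planted two-group phenotype experiment.

    Measurements follow value = scale[g] * (base + effect_size*sd*[strain in
    PC I] + Normal(0, sd)), clipped at zero; replicates are i.i.d. The
    per-genotype multiplicative scale forces the per-genotype normalization
    to matter. effect_size is the standardized (per-sd) shift of the
    compatible group.
    """

    strains: tuple[str, ...]
    pc1_strains: tuple[str, ...]
    host_genotypes: int = 27
    replicates: int = 3
    traits: tuple[tuple[str, tuple[float, float]], ...] = tuple(DEFAULT_TRAITS.items())
    effect_size: float = 3.0
    genotype_scale: tuple[float, ...] | None = None  # default: drawn U(0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.host_genotypes < 1:
            raise ValueError("host_genotypes must be >= 1")
        if not set(self.pc1_strains) <= set(self.strains):
            raise ValueError("pc1_strains must be a subset of strains")
        if self.genotype_scale is not None:
            if len(self.genotype_scale) != self.host_genotypes:
                raise ValueError("genotype_scale must have one entry per genotype")
            if any(s <= 0 for s in self.genotype_scale):
                raise ValueError("genotype_scale entries must be positive")


def generate_phenotypes(config: PhenotypeConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Long-format phenotype table plus the planted PC labels per strain."""
    rng = np.random.default_rng(config.seed)
    genotypes = [f"HM{i + 1:03d}" for i in range(config.host_genotypes)]
    if config.genotype_scale is not None:
        scale = dict(zip(genotypes, config.genotype_scale))
    else:
        scale = dict(zip(genotypes, rng.uniform(0.5, 1.5, size=len(genotypes))))
    pc1 = set(config.pc1_strains)
    rows = []
    for strain in config.strains:
        boost = 1.0 if strain in pc1 else 0.0
        for genotype in genotypes:
            for trait, (base, sd) in config.traits:
                mean = base + config.effect_size * sd * boost
                for rep in range(1, config.replicates + 1):
                    value = scale[genotype] * (mean + rng.normal(0.0, sd))
                    rows.append((strain, genotype, trait, rep, max(value, 0.0)))
    table = pd.DataFrame(
        rows, columns=["strain", "host_genotype", "trait", "replicate", "value"]
    )
    labels = {s: ("PC_I" if s in pc1 else "PC_II") for s in config.strains}
    return table, labels


def generate_contigs(
    species_map: SpeciesMap,
    seed: int | None = None,
    n_contigs: tuple[int, int] = (2, 5),
    genome_size: tuple[int, int] = (60_000, 80_000),
    gc_range: tuple[float, float] = (0.60, 0.635),
) -> list[SequenceRecord]:
    """Random nucleotide contigs per strain with a strain-specific GC content."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    for strain in species_map.strains:
        gc = rng.uniform(*gc_range)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        total = int(rng.integers(*genome_size))
        k = int(rng.integers(n_contigs[0], n_contigs[1] + 1))
        cuts = np.sort(rng.choice(total - 1, size=k - 1, replace=False)) + 1 if k > 1 else []
        sizes = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
        for c, size in enumerate(sizes):
            seq = "".join(rng.choice(bases, size=size, p=p))
            records.append(
                SequenceRecord(
                    id=f"{strain}|contig{c + 1:02d}",
                    residues=seq,
                    alphabet="nucleotide",
                    strain=strain,
                    species=species_map.species_of(strain),
                )
            )
    return records
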