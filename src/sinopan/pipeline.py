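"""End-to-end pipeline: simulate -> cluster -> pan-genome -> COG -> phylogeny -> phenotype.

One global seed is fanned out to per-stage seeds by fixed offsets, so a
single integer reproduces every stage byte-for-byte. Each stage writes its
outputs under the run directory and a manifest records parameters, seeds,
input checksums and the headline metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .cluster import ClusteringConfig, filter_short_cds, greedy_cluster, presence_matrix
from .cog import cog_proportions, family_cog_label
from .io import (
    SpeciesMap,
    newick_string,
    write_fasta,
    write_newick,
    write_table,
)
from .pangenome import (
    accessory_families,
    core_families,
    core_percentage,
    flower_counts,
    genome_summary,
    species_core,
    species_specific,
    strain_unique,
)
from .phenotype import (
    average_replicates,
    cluster_strains,
    minmax_normalize,
    presence_proportion_table,
    strain_profiles,
)
from .phylo import (
    Alignment,
    bidirectional_best_hits,
    build_tree,
    select_single_copy_families,
)
from .simulate import (
    AMINO_ACIDS,
    F84Params,
    PangenomeConfig,
    PhenotypeConfig,
    _mutate,
    generate_contigs,
    generate_pangenome,
    generate_phenotypes,
    generate_strain_tree,
    simulate_f84_alignment,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets: one global seed reproduces everything
_STAGE_OFFSETS = {
    "pangenome": 1,
    "contigs": 2,
    "tree": 3,
    "alignment": 4,
    "outgroup": 5,
    "bootstrap": 6,
    "phenotype": 7,
}


@dataclass
class PipelineConfig:
    """Everything the `run` command needs; YAML-overridable."""

    outdir: Path
    seed: int = 0
    pangenome: PangenomeConfig | None = None
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    n_bootstrap: int = 200
    collapse_threshold: int = 60
    sites_per_family: int = 300
    outgroup_identity: float = 0.80
    phenotype_effect_size: float = 3.0
    k_phenotype_clusters: int = 2
    n_symbiosis_families: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if outdir is not None:
            raw["outdir"] = outdir
        if "pangenome" in raw and raw["pangenome"] is not None:
            pg = dict(raw["pangenome"])
            for key in ("strains_per_species", "n_strain_unique", "protein_length"):
                if key in pg:
                    pg[key] = tuple(pg[key])
            raw["pangenome"] = PangenomeConfig(**pg)
        if "clustering" in raw and raw["clustering"] is not None:
            raw["clustering"] = ClusteringConfig(**raw["clustering"])
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 131 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cluster_table_frame(table) -> pd.DataFrame:
    rows = []
    for fam, rep, members in table.clusters:
        for m in members:
            rows.append((fam, rep, m, table.strain_of[m]))
    return pd.DataFrame(rows, columns=["family_id", "representative", "member", "strain"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic pan-genome and score against the truth.

    Returns the report dictionary (also written to ``manifest.json``): family
    counts, planted-structure recovery metrics, tree comparison, and
    phenotype-cluster recovery.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # ---- stage 1: synthetic pan-genome -----------------------------------
    pg_config = config.pangenome
    if pg_config is None:
        pg_config = PangenomeConfig(seed=_stage_seed(seed, "pangenome"))
    smap = pg_config.species_map()
    # phenotyped strains: the two best-sampled species, emulating the paired
    # focal species of the collection; PC I = first 60% of them, and the
    # planted symbiosis families are present exactly in the PC I strains.
    pheno_strains = smap.strains_of(pg_config.species_names[0]) + smap.strains_of(
        pg_config.species_names[1]
    )
    pc1 = tuple(pheno_strains[: max(2, int(0.6 * len(pheno_strains)))])
    if config.n_symbiosis_families and not pg_config.n_symbiosis:
        pg_config = dataclasses.replace(
            pg_config,
            n_symbiosis=config.n_symbiosis_families,
            symbiosis_strains=pc1,
        )
    logger.info("simulating pan-genome (%d strains)", len(smap))
    records, truth = generate_pangenome(pg_config)
    write_fasta(records, out / "proteins.fasta")
    write_table(
        pd.DataFrame(
            {"strain": smap.strains, "species": [smap.species_of(s) for s in smap.strains]}
        ),
        out / "species.tsv",
    )
    cog_of_gene = {
        gene: truth.family_cog[fam] for gene, fam in truth.family_of_gene.items()
    }
    write_table(
        pd.DataFrame(
            {
                "gene_id": list(cog_of_gene),
                "category": [c if c is not None else "NA" for c in cog_of_gene.values()],
            }
        ),
        out / "cogs.tsv",
    )
    contigs = generate_contigs(smap, seed=_stage_seed(seed, "contigs"))
    write_fasta(contigs, out / "contigs.fasta")

    # ---- stage 2: filter + cluster ---------------------------------------
    kept, removed = filter_short_cds(records, config.clustering.min_aa_length)
    logger.info("clustering %d proteins (%d fragments removed)", len(kept), len(removed))
    table = greedy_cluster(kept, config.clustering)
    write_table(_cluster_table_frame(table), out / "clusters.tsv")
    genes = sorted(g for g in truth.family_of_gene if g not in truth.fragment_genes)
    clustering_ari = adjusted_rand_score(
        [truth.family_of_gene[g] for g in genes], [table.family_of[g] for g in genes]
    )

    # ---- stage 3: pan-genome set algebra ---------------------------------
    pa = presence_matrix(table, smap)
    core = core_families(pa)
    accessory = accessory_families(pa)
    report_rows = [("all", "total_families", len(table))]
    report_rows.append(("all", "core", len(core)))
    report_rows.append(("all", "accessory", len(accessory)))
    report_rows.append(("all", "core_percent", core_percentage(len(core), len(table))))
    for sp in smap.species:
        report_rows.append((sp, "species_core", len(species_core(pa, sp))))
        report_rows.append(
            (sp, "species_specific", len(species_specific(pa, sp, mode="all_others")))
        )
    for strain in smap.strains:
        report_rows.append((strain, "strain_unique", len(strain_unique(pa, strain))))
    write_table(
        pd.DataFrame(report_rows, columns=["group", "quantity", "count"]),
        out / "pangenome.tsv",
    )
    genus_flower = flower_counts(pa, level="genus")
    summaries = pd.DataFrame(
        [
            dataclasses.asdict(genome_summary(contigs, kept, s))
            for s in smap.strains
        ]
    )
    write_table(summaries, out / "genome_summaries.tsv")

    # truth-table comparison of the planted classes
    def _recovered(planted_fams: set[int]) -> set[int]:
        return {
            table.family_of[g]
            for g, f in truth.family_of_gene.items()
            if f in planted_fams and g in table.family_of
        }

    planted_core = truth.families_of_class("genus_core")
    core_exact = _recovered(planted_core) == core if clustering_ari == 1.0 else False

    # ---- stage 4: COG profile --------------------------------------------
    labels = family_cog_label(table, cog_of_gene)
    profile = cog_proportions(labels, {"core": core, "accessory": accessory})
    profile_out = profile.reset_index()
    write_table(profile_out, out / "cog_profile.tsv")

    # ---- stage 5: phylogeny ----------------------------------------------
    strains = smap.strains
    single_copy = sorted(select_single_copy_families(table, strains))
    rng = np.random.default_rng(_stage_seed(seed, "outgroup"))
    reps = [r for r in kept if r.id in {table.representative(f) for f in single_copy}]
    outgroup_proteome = [
        dataclasses.replace(
            r,
            id=f"outgroup|{r.id.split('|')[1]}",
            strain="outgroup",
            species="outgroup",
            residues=_mutate(rng, r.residues, config.outgroup_identity),
        )
        for r in reps
    ]
    bbh = bidirectional_best_hits(reps, outgroup_proteome)
    anchored_reps = {a for a, _ in bbh}
    anchored = sorted(
        f for f in single_copy if table.representative(f) in anchored_reps
    )
    logger.info(
        "phylogeny: %d single-copy families, %d anchored to the outgroup",
        len(single_copy),
        len(anchored),
    )
    truth_tree = generate_strain_tree(
        smap, seed=_stage_seed(seed, "tree"), outgroup="outgroup"
    )
    aln_rng_seed = _stage_seed(seed, "alignment")
    family_alignments = [
        simulate_f84_alignment(
            truth_tree, F84Params(), config.sites_per_family, seed=aln_rng_seed + i
        )
        for i in range(len(anchored))
    ]
    concat = Alignment.concat(family_alignments)
    tree, supports, skipped = build_tree(
        concat,
        outgroup="outgroup",
        n_reps=config.n_bootstrap,
        collapse_threshold=config.collapse_threshold,
        seed=_stage_seed(seed, "bootstrap"),
    )
    write_newick(tree, out / "tree.nwk")
    # topology comparison against the generating tree (unrooted splits)
    ns = dendropy.TaxonNamespace()
    t_inferred = dendropy.Tree.get(
        data=newick_string(tree, include_support=False),
        schema="newick",
        taxon_namespace=ns,
    )
    t_truth = dendropy.Tree.get(
        data=truth_tree.as_string(schema="newick"), schema="newick", taxon_namespace=ns
    )
    t_inferred.encode_bipartitions()
    t_truth.encode_bipartitions()
    rf = dendropy.calculate.treecompare.symmetric_difference(t_truth, t_inferred)
    min_support = min(supports.values()) if supports else 0.0

    # ---- stage 6: phenotypes ---------------------------------------------
    pheno_config = PhenotypeConfig(
        strains=tuple(pheno_strains),
        pc1_strains=pc1,
        effect_size=config.phenotype_effect_size,
        seed=_stage_seed(seed, "phenotype"),
    )
    pheno_table, pheno_truth = generate_phenotypes(pheno_config)
    write_table(pheno_table, out / "phenotypes.tsv")
    profiles = strain_profiles(minmax_normalize(average_replicates(pheno_table)))
    assignment = cluster_strains(profiles, k=config.k_phenotype_clusters)
    phenotype_ari = adjusted_rand_score(
        [pheno_truth[s] for s in profiles.index],
        [assignment.labels[s] for s in profiles.index],
    )
    write_table(
        pd.DataFrame(
            {
                "strain": list(assignment.labels),
                "cluster": list(assignment.labels.values()),
            }
        ),
        out / "phenotype_clusters.tsv",
    )
    presence = pd.DataFrame(
        pa.presence, index=pa.strains, columns=pa.families
    )
    gene_sets = {}
    planted_symbiosis = truth.families_of_class("symbiosis")
    if planted_symbiosis:
        gene_sets["symbiosis"] = sorted(_recovered(planted_symbiosis))
    gene_sets["genus_core_probe"] = sorted(_recovered(planted_core))[:1]
    assoc = presence_proportion_table(presence, assignment, smap, gene_sets)
    flat = assoc.copy()
    flat.columns = [f"{sp}:{pc}" for sp, pc in assoc.columns]
    write_table(flat.reset_index(), out / "association.tsv")

    # ---- manifest ---------------------------------------------------------
    report = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {k: _stage_seed(seed, k) for k in _STAGE_OFFSETS},
        "n_proteins": len(records),
        "n_fragments_removed": len(removed),
        "n_families": len(table),
        "clustering_ari": float(clustering_ari),
        "core_families": len(core),
        "accessory_families": len(accessory),
        "core_percent": core_percentage(len(core), len(table)),
        "planted_core_recovered_exactly": bool(core_exact),
        "flower_center": genus_flower["center"],
        "flower_petals": genus_flower["petals"],
        "n_single_copy_families": len(single_copy),
        "n_anchored_families": len(anchored),
        "tree_rf_distance": int(rf),
        "min_split_support": float(min_support),
        "bootstrap_replicates_skipped": int(skipped),
        "phenotype_ari": float(phenotype_ari),
        "input_sha256": {
            name: _sha256(out / name)
            for name in ("proteins.fasta", "species.tsv", "cogs.tsv", "phenotypes.tsv")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
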