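"""Synthetic-data generators: planted pan-genomes, F84 evolution, phenotypes."""

import io as _io

import numpy as np
import pytest
from scipy.linalg import expm

from sinopan.cluster import global_identity
from sinopan.io import write_fasta
from sinopan.phylo import f84_distance
from sinopan.simulate import (
    F84Params,
    PangenomeConfig,
    PhenotypeConfig,
    f84_rate_matrix,
    f84_transition_matrix,
    generate_contigs,
    generate_pangenome,
    generate_phenotypes,
    generate_strain_tree,
    random_binary_tree,
    simulate_f84_alignment,
)

TINY = dict(
    strains_per_species=(2,),
    n_genus_core=3,
    n_species_core_extra=0,
    n_species_specific=0,
    n_strain_unique=(0, 0),
    protein_length=(40, 80),
    fragmentation_rate=0.0,
)


class TestPangenomeConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PangenomeConfig(within_family_identity=0.65)  # below threshold
        with pytest.raises(ValueError):
            PangenomeConfig(between_family_identity_max=0.75)  # above threshold
        with pytest.raises(ValueError):
            PangenomeConfig(strains_per_species=(0, 3))
        with pytest.raises(ValueError):
            PangenomeConfig(n_genus_core=-1)

    def test_species_map_layout(self):
        config = PangenomeConfig(strains_per_species=(2, 1))
        smap = config.species_map()
        assert smap.species == ["sp1", "sp2"]
        assert smap.strains_of("sp1") == ["sp1s01", "sp1s02"]


class TestGeneratePangenome:
    def test_minimal_counts(self):
        records, truth = generate_pangenome(PangenomeConfig(**TINY, seed=0))
        assert len(records) == 6  # 3 families x 2 strains
        assert len(truth.family_class) == 3
        assert set(truth.family_of_gene.values()) == {0, 1, 2}

    def test_same_seed_is_byte_identical(self):
        def fasta_bytes(seed):
            records, _ = generate_pangenome(PangenomeConfig(seed=seed, **TINY))
            buf = _io.StringIO()
            for r in records:
                buf.write(f">{r.id}\n{r.residues}\n")
            return buf.getvalue()

        assert fasta_bytes(5) == fasta_bytes(5)
        assert fasta_bytes(5) != fasta_bytes(6)

    def test_realized_identity_near_target(self):
        config = PangenomeConfig(
            strains_per_species=(3, 2),
            n_genus_core=5,
            n_species_core_extra=2,
            n_species_specific=2,
            n_strain_unique=(1, 2),
            protein_length=(60, 120),
            fragmentation_rate=0.0,
            seed=2,
        )
        records, truth = generate_pangenome(config)
        for rec in records:
            fam = truth.family_of_gene[rec.id]
            ident = global_identity(rec.residues, truth.family_ancestor[fam])
            assert abs(ident - config.within_family_identity) <= 0.03

    def test_ancestors_pairwise_separated(self):
        _records, truth = generate_pangenome(
            PangenomeConfig(
                strains_per_species=(2,),
                n_genus_core=8,
                n_species_core_extra=0,
                n_species_specific=0,
                n_strain_unique=(0, 0),
                protein_length=(50, 100),
                fragmentation_rate=0.0,
                seed=3,
            )
        )
        ancs = list(truth.family_ancestor.values())
        for i in range(len(ancs)):
            for j in range(i + 1, len(ancs)):
                assert global_identity(ancs[i], ancs[j]) <= 0.30

    def test_fragments_marked_and_short(self):
        config = PangenomeConfig(**{**TINY, "fragmentation_rate": 0.5}, seed=4)
        records, truth = generate_pangenome(config)
        frags = [r for r in records if r.id in truth.fragment_genes]
        assert frags, "expected some fragments at rate 0.5"
        assert all(len(f) < 11 for f in frags)
        assert all(r.id in truth.family_of_gene for r in records
                   if r.id not in truth.fragment_genes)

    def test_class_counts_match_config(self):
        config = PangenomeConfig(
            strains_per_species=(2, 2),
            n_genus_core=4,
            n_species_core_extra=3,
            n_species_specific=2,
            n_strain_unique=(1, 1),
            protein_length=(40, 60),
            fragmentation_rate=0.0,
            seed=5,
        )
        _records, truth = generate_pangenome(config)
        assert len(truth.families_of_class("genus_core")) == 4
        assert len(truth.families_of_class("species_core")) == 6
        assert len(truth.families_of_class("species_specific")) == 4
        assert len(truth.families_of_class("strain_unique")) == 4


class TestF84TransitionMatrix:
    PARAMS = F84Params(freqs=(0.3, 0.2, 0.25, 0.25), kappa=2.0)

    def test_zero_time_is_identity(self):
        assert np.allclose(f84_transition_matrix(self.PARAMS, 0.0), np.eye(4))

    def test_long_time_reaches_stationarity(self):
        P = f84_transition_matrix(self.PARAMS, 50.0)
        for row in P:
            assert np.allclose(row, self.PARAMS.freqs, atol=1e-8)

    def test_matches_matrix_exponential(self):
        Q = f84_rate_matrix(self.PARAMS)
        for t in (0.01, 0.1, 1.0):
            assert np.abs(
                f84_transition_matrix(self.PARAMS, t) - expm(Q * t)
            ).max() < 1e-10

    def test_detailed_balance_and_row_sums(self):
        pi = np.array(self.PARAMS.freqs)
        P = f84_transition_matrix(self.PARAMS, 0.3)
        assert np.allclose(P.sum(axis=1), 1.0)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)
        assert np.allclose(pi @ P, pi, atol=1e-12)

    def test_rate_calibration(self):
        Q = f84_rate_matrix(self.PARAMS)
        pi = np.array(self.PARAMS.freqs)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            f84_transition_matrix(self.PARAMS, -0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            F84Params(freqs=(0.5, 0.5, 0.0, 0.0))
        with pytest.raises(ValueError):
            F84Params(kappa=-1.0)


class TestSimulateAlignment:
    def test_zero_length_branches_copy_the_root(self):
        tree = random_binary_tree(["a", "b", "c"], seed=1, blen_range=(0.0, 0.0))
        aln = simulate_f84_alignment(tree, F84Params(), 500, seed=2)
        seqs = {t: aln.sequence(t) for t in aln.taxa}
        assert len(set(seqs.values())) == 1

    def test_same_seed_same_alignment(self):
        tree = random_binary_tree(["a", "b", "c"], seed=1)
        a1 = simulate_f84_alignment(tree, F84Params(), 300, seed=7)
        a2 = simulate_f84_alignment(tree, F84Params(), 300, seed=7)
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_distance_estimator_recovers_branch_length(self):
        # two leaves at total distance 0.2; moderate length here, the
        # tight-tolerance L=200,000 check lives in the acceptance suite
        tree = random_binary_tree(["x", "y"], seed=3, blen_range=(0.1, 0.1))
        aln = simulate_f84_alignment(tree, F84Params(), 50_000, seed=4)
        d = f84_distance(aln.sequence("x"), aln.sequence("y"))
        assert d == pytest.approx(0.2, abs=0.02)

    def test_bad_site_count_rejected(self):
        tree = random_binary_tree(["a", "b"], seed=1)
        with pytest.raises(ValueError):
            simulate_f84_alignment(tree, F84Params(), 0)


class TestStrainTree:
    def test_leafset_and_outgroup(self):
        config = PangenomeConfig(strains_per_species=(3, 2), **{
            k: v for k, v in TINY.items() if k != "strains_per_species"})
        smap = config.species_map()
        tree = generate_strain_tree(smap, seed=9, outgroup="out")
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        assert leaves == set(smap.strains) | {"out"}


class TestPhenotypes:
    def test_no_effect_no_noise_gives_identical_profiles(self):
        config = PhenotypeConfig(
            strains=("a", "b", "c"),
            pc1_strains=("a",),
            host_genotypes=3,
            replicates=2,
            traits=(("nodule_number", (50.0, 0.0)),),
            effect_size=0.0,
            seed=1,
        )
        table, _ = generate_phenotypes(config)
        assert table.groupby("strain")["value"].apply(tuple).nunique() == 1

    def test_same_seed_same_table(self):
        config = PhenotypeConfig(
            strains=("a", "b"), pc1_strains=("a",), host_genotypes=2, seed=3
        )
        t1, _ = generate_phenotypes(config)
        t2, _ = generate_phenotypes(config)
        assert t1.equals(t2)

    def test_values_non_negative_and_labels_planted(self):
        config = PhenotypeConfig(
            strains=("a", "b", "c", "d"),
            pc1_strains=("a", "b"),
            host_genotypes=4,
            seed=4,
        )
        table, labels = generate_phenotypes(config)
        assert (table["value"] >= 0).all()
        assert labels == {"a": "PC_I", "b": "PC_I", "c": "PC_II", "d": "PC_II"}

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeConfig(strains=("a",), pc1_strains=("b",))
        with pytest.raises(ValueError):
            PhenotypeConfig(strains=("a",), pc1_strains=(), replicates=0)
        with pytest.raises(ValueError):
            PhenotypeConfig(
                strains=("a",),
                pc1_strains=(),
                host_genotypes=2,
                genotype_scale=(1.0, -0.5),
            )


class TestContigs:
    def test_gc_in_configured_range(self, tmp_path):
        config = PangenomeConfig(**TINY)
        contigs = generate_contigs(
            config.species_map(), seed=5, genome_size=(20_000, 25_000)
        )
        write_fasta(contigs, tmp_path / "c.fasta")  # valid nucleotide FASTA
        from sinopan.pangenome import genome_summary

        for strain in config.species_map().strains:
            s = genome_summary(contigs, [], strain)
            assert 58.0 < s.gc_percent < 65.5
            assert 20_000 <= s.genome_size_bp <= 25_000
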