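"""Determinism and statistical calibration of the synthetic-data generator."""

import hashlib
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuprofile.orthology import bidirectional_best_hit, detect_fusions, Proteome
from cuprofile.synthetic import (
    FusionPlant,
    PlantModel,
    emit_dataset,
    generate_dataset,
    phi_from_table,
    plant_presence,
    sample_copresence_pair,
    simulate_tree,
    synthetic_seed_proteins,
    _mutate,
)


def _tree_hash(path: Path) -> dict:
    return {
        p.relative_to(path).as_posix(): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.rglob("*"))
        if p.is_file()
    }


SMALL = dict(n_genera=4, genomes_per_genus=(1, 2), decoys_per_genome=3)


class TestTree:
    def test_two_genera_is_a_cherry(self):
        tree = dendropy.Tree.get(data=simulate_tree(2, seed=1), schema="newick")
        assert len(tree.leaf_nodes()) == 2

    def test_same_seed_same_newick(self):
        assert simulate_tree(12, seed=5) == simulate_tree(12, seed=5)
        assert simulate_tree(12, seed=5) != simulate_tree(12, seed=6)

    def test_binary_tree_node_count(self):
        tree = dendropy.Tree.get(data=simulate_tree(79, seed=0), schema="newick")
        leaves = len(tree.leaf_nodes())
        internal = len(tree.internal_nodes())
        assert leaves == 79 and internal == 78

    def test_fewer_than_two_genera_is_invalid(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestPlantPresence:
    def test_block_members_copresent_when_dropout_is_off(self):
        model = PlantModel(
            seed=3, within_block_presence=1.0, background_activation=0.0, **SMALL
        )
        truth = plant_presence(model, simulate_tree(model.n_genera, model.seed))
        for _, row in truth.presence.iterrows():
            for block, members in model.blocks.items():
                vals = {row[m] for m in members}
                assert len(vals) == 1  # all present or all absent together

    def test_stated_2x2_table_gives_phi_08(self):
        assert phi_from_table(0.45, 0.05, 0.05, 0.45) == pytest.approx(0.8)

    def test_empirical_phi_close_to_closed_form(self):
        mat = sample_copresence_pair(0.45, 0.05, 0.05, 0.45, n_genomes=500, seed=2)
        r = np.corrcoef(mat["seed_a"], mat["seed_b"])[0, 1]
        assert abs(r - 0.8) < 0.05

    def test_independent_columns_have_zero_expected_phi(self):
        # p11 = pa*pb factorises: closed-form phi is exactly 0
        assert phi_from_table(0.25, 0.25, 0.25, 0.25) == pytest.approx(0.0)

    def test_clades_partition_genera_contiguously(self):
        model = PlantModel(seed=9, **SMALL)
        tree = simulate_tree(model.n_genera, model.seed)
        truth = plant_presence(model, tree)
        leaf_order = [
            l.taxon.label
            for l in dendropy.Tree.get(data=tree, schema="newick").leaf_node_iter()
        ]
        labels = [truth.clades[g] for g in leaf_order]
        # clade labels change at most n_clades - 1 times along the tree order
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == len(set(labels)) - 1


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        seq = synthetic_seed_proteins()[0].sequence
        assert _mutate(seq, 0.0, rng) == seq

    def test_substitution_count_within_binomial_bounds(self, rng):
        seq = "A" * 300
        trials = 30
        counts = [
            sum(a != b for a, b in zip(seq, _mutate(seq, 0.1, rng)))
            for _ in range(trials)
        ]
        # each draw within very wide per-draw bounds ...
        lo, hi = stats.binom.ppf([1e-6, 1 - 1e-6], 300, 0.1)
        assert all(lo <= c <= hi for c in counts)
        # ... and the total within the 99% band of Binomial(300*trials, 0.1)
        tlo, thi = stats.binom.ppf([0.005, 0.995], 300 * trials, 0.1)
        assert tlo <= sum(counts) <= thi

    def test_length_and_alphabet_preserved(self, rng):
        seq = synthetic_seed_proteins()[1].sequence
        mut = _mutate(seq, 0.3, rng)
        assert len(mut) == len(seq)
        assert set(mut) <= set("ACDEFGHIKLMNPQRSTVWY")


class TestDataset:
    def test_identical_models_emit_byte_identical_outputs(self, tmp_path):
        model = PlantModel(seed=17, **SMALL)
        a = emit_dataset(generate_dataset(model), tmp_path / "a")
        b = emit_dataset(generate_dataset(model), tmp_path / "b")
        assert _tree_hash(a) == _tree_hash(b)

    def test_zero_mutation_emits_exact_seed_copies(self):
        model = PlantModel(seed=2, mutation_rate=0.0, **SMALL)
        ds = generate_dataset(model)
        seed_seqs = {s.name: s.sequence for s in ds.seeds}
        found = 0
        for p in ds.proteomes:
            present = ds.truth.presence.loc[p.genome_id]
            seqs = {seq for _, seq in p.proteins}
            for name in present[present == 1].index:
                assert seed_seqs[name] in seqs
                found += 1
        assert found > 0

    def test_truth_is_consistent_with_annotation_and_taxonomy(self, small_dataset):
        ds = small_dataset
        genomes = {p.genome_id for p in ds.proteomes}
        assert set(ds.truth.presence.index) == genomes
        assert set(ds.taxonomy.table["genome_id"]) == genomes
        for p in ds.proteomes:
            for gid, _ in p.proteins:
                ds.annotation.locus(p.genome_id, gid)  # must resolve

    def test_planted_operon_blocks_get_consecutive_ranks(self, small_dataset):
        ds = small_dataset
        for p in ds.proteomes[:6]:
            present = ds.truth.presence.loc[p.genome_id]
            # map emitted genes back to seeds via order of construction
            gene_seed = {}
            seed_seqs = {s.name: s.sequence for s in ds.seeds}
            for gid, seq in p.proteins:
                for name, sseq in seed_seqs.items():
                    if len(seq) == len(sseq) and present[name]:
                        ident = sum(a == b for a, b in zip(seq, sseq)) / len(seq)
                        if ident > 0.6:
                            gene_seed[gid] = name
            for block, members in ds.model.blocks.items():
                genes = [g for g, s in gene_seed.items() if s in members]
                if len(genes) > 1:
                    ranks = sorted(
                        ds.annotation.locus(p.genome_id, g).rank for g in genes
                    )
                    assert ranks == list(range(ranks[0], ranks[0] + len(ranks)))

    def test_planted_fusion_is_found_by_detect_fusions(self):
        model = PlantModel(
            seed=23,
            fusions=(FusionPlant("CusB", "CusF", count=1),),
            n_genera=4,
            genomes_per_genus=(1, 2),
            decoys_per_genome=3,
        )
        ds = generate_dataset(model)
        assert len(ds.truth.fusions) == 1
        planted = ds.truth.fusions[0]
        genome = next(
            p for p in ds.proteomes if p.genome_id == planted["genome_id"]
        )
        seeds = [s for s in ds.seeds if s.name in ("CusB", "CusF")]
        seed_proteome = Proteome("seeds", [(s.name, s.sequence) for s in ds.seeds])
        calls = [bidirectional_best_hit(s, seed_proteome, genome) for s in seeds]
        fusions = detect_fusions(calls)
        assert len(fusions) == 1
        assert fusions[0].gene_id == planted["gene_id"]
        assert {fusions[0].seed_a, fusions[0].seed_b} == {"CusB", "CusF"}
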