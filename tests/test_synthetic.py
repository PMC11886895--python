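"""Generator correctness: planted structure, determinism, self-consistency."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from cernarisk import cerna, io, synthetic
from cernarisk.synthetic import (
    BundleParams,
    generate_bundle,
    generate_expression,
    generate_genome_and_variants,
    generate_interactome,
    generate_programs,
)


def bundle_hashes(paths):
    return {k: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for k, p in paths.items()}


class TestInteractome:
    def test_planted_pairs_share_min_mirnas(self):
        interactions, truth = generate_interactome(10, 30, 10, 0.1, 5, 3, seed=0)
        circ_map, gene_map = cerna.build_bipartite(interactions)
        for c, g in truth.planted_pairs:
            assert len(circ_map[c] & gene_map[g]) >= 3

    def test_zero_background_recovery_is_exact(self):
        interactions, truth = generate_interactome(10, 30, 10, 0.0, 5, 3, seed=1)
        circ_map, gene_map = cerna.build_bipartite(interactions)
        pairs = cerna.enumerate_cerna_pairs(circ_map, gene_map, 3)
        assert {(p.circ_id, p.gene_id) for p in pairs} == truth.planted_pairs
        assert len(cerna.expand_triplets(pairs)) == 15

    def test_dedicated_mirnas_not_reused(self):
        _, truth = generate_interactome(10, 30, 10, 0.2, 5, 3, seed=2)
        all_mirnas = [m for ms in truth.planted_pair_mirnas.values() for m in ms]
        assert len(all_mirnas) == len(set(all_mirnas)) == 15

    def test_all_confidences_above_threshold(self):
        interactions, _ = generate_interactome(10, 30, 10, 0.3, 2, 3, seed=3)
        assert all(i.confidence > 0.3 for i in interactions)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_interactome(2, 5, 2, 0.1, 5, 3, seed=0)  # 15 dedicated > 5
        with pytest.raises(ValueError):
            generate_interactome(2, 50, 2, 0.1, 5, 3, seed=0)  # 5 pairs > 4

    def test_determinism(self):
        a, _ = generate_interactome(10, 30, 10, 0.2, 3, 3, seed=9)
        b, _ = generate_interactome(10, 30, 10, 0.2, 3, 3, seed=9)
        assert a == b


class TestGenomeAndVariants:
    ids = ([f"c{i}" for i in range(5)], [f"g{i}" for i in range(20)])

    def test_exactly_n_inside_hits(self):
        feats, variants, truth = generate_genome_and_variants(
            *self.ids, n_variants=15, chrom_length=2_000_000, window_bp=10_000,
            n_inside_hits=2, seed=0)
        circ = [f for f in feats if f.feature_type == "circRNA"]
        by_id = {f.id: f for f in circ}
        inside = [(v.rsid, f.id) for v in variants for f in circ if f.contains(v.pos)]
        assert len(inside) == 2
        assert dict(inside) == truth.planted_variant_hits
        for rsid, fid in inside:
            f = by_id[fid]
            v = next(v for v in variants if v.rsid == rsid)
            assert f.start <= v.pos < f.end

    def test_features_do_not_overlap(self):
        feats, _, _ = generate_genome_and_variants(
            *self.ids, n_variants=5, chrom_length=1_000_000, window_bp=0,
            n_inside_hits=1, seed=1)
        ordered = sorted(feats, key=lambda f: f.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start

    def test_zero_window_truth_equals_inside_or_touching(self):
        feats, variants, truth = generate_genome_and_variants(
            *self.ids, n_variants=10, chrom_length=2_000_000, window_bp=0,
            n_inside_hits=1, seed=2)
        for v in variants:
            expected = {f.id for f in feats if f.chrom == v.chrom
                        and (f.contains(v.pos) or f.start - v.pos == 0
                             or v.pos - (f.end - 1) == 0)}
            assert set(truth.within_window[v.rsid]) == expected

    def test_chromosome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_genome_and_variants(
                *self.ids, n_variants=5, chrom_length=10_000, window_bp=0,
                n_inside_hits=1, seed=0)

    def test_determinism(self):
        a = generate_genome_and_variants(*self.ids, n_variants=10,
                                         chrom_length=2_000_000, window_bp=500,
                                         n_inside_hits=1, seed=5)
        b = generate_genome_and_variants(*self.ids, n_variants=10,
                                         chrom_length=2_000_000, window_bp=500,
                                         n_inside_hits=1, seed=5)
        assert a[0] == b[0] and a[1] == b[1]


class TestExpression:
    def test_planted_mean_difference_unbiased(self):
        # Monte-Carlo check of the generator itself: mean |bias| < 0.5
        diffs = []
        for rep in range(100):
            mat, truth = generate_expression(
                [f"f{i}" for i in range(20)], 10, 10, 5,
                effect_log2=2.0, noise_sd=0.5, seed=1000 + rep)
            case, ctrl = mat.group("case"), mat.group("control")
            delta = case.mean(axis=1) - ctrl.mean(axis=1)
            for i, fid in enumerate(mat.feature_ids):
                if fid in truth.planted_de_features:
                    diffs.append(delta[i] - truth.planted_de_features[fid])
        assert abs(np.mean(diffs)) < 0.5

    def test_no_de_empty_truth(self):
        _, truth = generate_expression([f"f{i}" for i in range(5)], 3, 3, 0, seed=0)
        assert truth.planted_de_features == {}

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            generate_expression(["f1"], 1, 5, 0, seed=0)

    def test_determinism(self):
        a, _ = generate_expression([f"f{i}" for i in range(10)], 4, 4, 2, seed=3)
        b, _ = generate_expression([f"f{i}" for i in range(10)], 4, 4, 2, seed=3)
        assert a.values.equals(b.values)


class TestPrograms:
    pool = [f"g{i}" for i in range(120)]

    def test_shapes(self):
        programs, _ = generate_programs(13, 20, self.pool, 8, 6, seed=0)
        assert len(programs) == 13
        assert all(len(m) == 20 for m in programs.values())

    def test_frequency_filter_recovers_designated_exactly(self):
        from cernarisk.circuits import common_genes

        programs, truth = generate_programs(13, 20, self.pool, 8, 6, seed=1)
        assert common_genes(programs, 6) == truth.planted_common_genes
        assert len(truth.planted_common_genes) == 8

    def test_min_count_above_n_programs_rejected(self):
        with pytest.raises(ValueError):
            generate_programs(13, 20, self.pool, 8, 14, seed=0)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_programs(13, 50, self.pool[:40], 5, 6, seed=0)


class TestBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        params = BundleParams.small()
        p1, _ = generate_bundle(params, seed=7, out_dir=tmp_path / "a")
        p2, _ = generate_bundle(params, seed=7, out_dir=tmp_path / "b")
        assert bundle_hashes(p1) == bundle_hashes(p2)

    def test_different_seed_differs(self, tmp_path):
        params = BundleParams.small()
        p1, _ = generate_bundle(params, seed=7, out_dir=tmp_path / "a")
        p2, _ = generate_bundle(params, seed=8, out_dir=tmp_path / "b")
        assert bundle_hashes(p1) != bundle_hashes(p2)

    def test_self_consistency_all_ids_exist(self, small_bundle):
        _, paths, truth = small_bundle
        circ_ids = {f.id for f in io.read_bed(paths["circ_bed"], "circRNA")}
        gene_ids = {f.id for f in io.read_bed(paths["gene_bed"], "gene")}
        interactions = io.read_interactions(paths["interactions"], 0.0)
        mirna_ids = set()
        for r in interactions:
            if r.source_type == "circRNA":
                assert r.source_id in circ_ids
                mirna_ids.add(r.target_id)
            else:
                assert r.target_id in gene_ids
                mirna_ids.add(r.source_id)
        for members in io.read_gmt(paths["programs"]).values():
            assert members <= gene_ids
        assert io.read_id_list(paths["known_circ"]) <= circ_ids
        assert io.read_id_list(paths["known_mirna"]) <= mirna_ids
        assert io.read_id_list(paths["known_gene"]) <= gene_ids
        for c, g in truth.planted_pairs:
            assert c in circ_ids and g in gene_ids

    def test_truth_round_trips_through_json(self, small_bundle):
        _, paths, truth = small_bundle
        loaded = synthetic.PlantedTruth.from_json(paths["truth"])
        assert loaded.planted_pairs == truth.planted_pairs
        assert loaded.planted_common_genes == truth.planted_common_genes
        assert loaded.planted_variant_hits == truth.planted_variant_hits
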