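import numpy as np
import pytest

from dupmodes.cross_species_ec import OrthologFrame, ec_scores
from dupmodes.dup_classifier import DuplicationMode, classify_all
from dupmodes.expression import pearson_r
from dupmodes.genome_io import read_anchors, read_blast_tab, read_gff
from dupmodes.synthetic_data import (
    PlantedPair,
    SimulationConfig,
    simulate_expression,
    simulate_families,
    simulate_genome,
    simulate_methylation,
    simulate_sequences,
    simulate_two_species,
)

SMALL = dict(events_per_mode=8, genes_per_chromosome=120)


class TestGenomeGeneration:
    def test_bit_reproducible_under_fixed_seed(self):
        a = simulate_genome(SimulationConfig(seed=42, **SMALL))
        b = simulate_genome(SimulationConfig(seed=42, **SMALL))
        assert a.truth.pairs == b.truth.pairs
        assert a.hits == b.hits
        assert [g for g in a.annotation.gene_ids] == [g for g in b.annotation.gene_ids]

    def test_zero_events_gives_all_singletons(self):
        sim = simulate_genome(SimulationConfig(seed=1, events_per_mode=0))
        res = classify_all(sim.annotation, sim.hits, sim.anchors)
        assert res.pairs == []
        assert res.singletons == set(sim.annotation.gene_ids)

    def test_every_mode_planted_in_requested_numbers(self):
        sim = simulate_genome(SimulationConfig(seed=3, **SMALL))
        for mode in (
            DuplicationMode.WGD,
            DuplicationMode.TANDEM,
            DuplicationMode.PROXIMAL,
            DuplicationMode.RETROTRANSPOSED,
            DuplicationMode.DNA_TRANSPOSED,
            DuplicationMode.DISPERSED,
        ):
            assert len(sim.truth.pairs_of_mode(mode)) == 8

    def test_self_audit_files_reproduce_truth(self, tmp_path):
        # emitted files re-loaded through genome_io reproduce the planted
        # relations exactly
        sim = simulate_genome(SimulationConfig(seed=9, **SMALL))
        paths = sim.write(tmp_path)
        ann = read_gff(paths["gff"])
        anchors = read_anchors(paths["anchors"], ortholog_path=paths["ortholog_anchors"])
        hits = read_blast_tab(paths["blast"])
        res = classify_all(ann, hits, anchors)
        truth = {frozenset(p.genes): p.mode for p in sim.truth.pairs}
        assert {frozenset(p.genes): p.mode for p in res.pairs} == truth
        assert res.origins == sim.truth.origins
        # parental copies of transposed pairs point at the ancestral gene
        parents = {
            frozenset(p.genes): p.parental_copy
            for p in res.pairs
            if p.mode in (DuplicationMode.RETROTRANSPOSED, DuplicationMode.DNA_TRANSPOSED)
        }
        for p in sim.truth.pairs:
            if p.parental_copy is not None:
                assert parents[frozenset(p.genes)] == p.parental_copy

    def test_interference_plants_tandem_partners_of_wgd_genes(self):
        cfg = SimulationConfig(seed=4, interference=True, n_interference=5, **SMALL)
        sim = simulate_genome(cfg)
        tandem = sim.truth.pairs_of_mode(DuplicationMode.TANDEM)
        wgd_genes = {g for p in sim.truth.pairs_of_mode(DuplicationMode.WGD) for g in p.genes}
        overlapping = [p for p in tandem if set(p.genes) & wgd_genes]
        assert len(overlapping) == 5
        for p in overlapping:
            shared = (set(p.genes) & wgd_genes).pop()
            assert sim.truth.origins[shared] == DuplicationMode.WGD
            other = (set(p.genes) - {shared}).pop()
            assert sim.truth.origins[other] == DuplicationMode.TANDEM

    def test_overplanting_raises(self):
        with pytest.raises(RuntimeError, match="available loci"):
            simulate_genome(SimulationConfig(seed=0, events_per_mode=200, genes_per_chromosome=60))


class TestExpressionGeneration:
    def test_target_r_one_is_exact(self):
        cfg = SimulationConfig(seed=5, n_samples=50, mode_target_r={DuplicationMode.WGD: 1.0})
        pairs = [PlantedPair("a", "b", DuplicationMode.WGD)]
        m = simulate_expression(cfg, pairs, ["a", "b"])
        assert pearson_r(m.profile("a"), m.profile("b")) == pytest.approx(1.0)

    def test_mean_sample_r_near_target(self):
        # sampling distribution of r: mean within 0.5 +/- 0.02 over 1,000
        # pairs at 500 samples
        cfg = SimulationConfig(
            seed=6, n_samples=500, mode_target_r={DuplicationMode.WGD: 0.5}
        )
        pairs = [PlantedPair(f"a{i}", f"b{i}", DuplicationMode.WGD) for i in range(1000)]
        genes = [g for p in pairs for g in p.genes]
        m = simulate_expression(cfg, pairs, genes)
        rs = [pearson_r(m.profile(p.gene_a), m.profile(p.gene_b)) for p in pairs]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.02)

    def test_reproducible(self):
        cfg = SimulationConfig(seed=7, n_samples=20)
        pairs = [PlantedPair("a", "b", DuplicationMode.TANDEM)]
        m1 = simulate_expression(cfg, pairs, ["a", "b", "c"])
        m2 = simulate_expression(cfg, pairs, ["a", "b", "c"])
        assert np.array_equal(m1.values, m2.values)


class TestSequenceGeneration:
    def test_zero_pressure_gives_identical_copies(self):
        cfg = SimulationConfig(
            seed=8,
            mode_p_syn={DuplicationMode.WGD: 0.0},
            mode_p_nonsyn={DuplicationMode.WGD: 0.0},
            promoter_p=0.0,
        )
        seqs = simulate_sequences(cfg, [PlantedPair("a", "b", DuplicationMode.WGD)])
        assert seqs.cds["a"] == seqs.cds["b"]
        assert seqs.promoter["a"] == seqs.promoter["b"]

    def test_proteins_translate_cds(self):
        from dupmodes.seq_divergence import CODON_TO_AA

        cfg = SimulationConfig(seed=9, n_codons=60)
        seqs = simulate_sequences(cfg, [PlantedPair("a", "b", DuplicationMode.DISPERSED)])
        for g in ("a", "b"):
            cds = seqs.cds[g]
            assert seqs.protein[g] == "".join(
                CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds), 3)
            )

    def test_bad_target_p_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(promoter_p=0.9)


class TestTwoSpecies:
    def test_zero_perturbation_gives_ec_one_everywhere(self):
        cfg = SimulationConfig(
            seed=10,
            n_orthologs_per_class=5,
            ortholog_samples=20,
            class_sigma={"S-S": 0.0, "S-D": 0.0, "D-D": 0.0},
        )
        frame, _ = simulate_two_species(cfg)
        scores = ec_scores(frame)
        assert np.allclose(scores["ec"], 1.0)
        assert np.allclose(scores["d"], 0.0, atol=1e-12)

    def test_permuted_ortholog_map_destroys_conservation(self, rng):
        cfg = SimulationConfig(seed=11, n_orthologs_per_class=40, ortholog_samples=50)
        frame, _ = simulate_two_species(cfg)
        perm = rng.permutation(frame.k)
        shuffled = OrthologFrame(
            genes_a=frame.genes_a,
            genes_b=[frame.genes_b[i] for i in perm],
            matrix_a=frame.matrix_a,
            matrix_b=frame.matrix_b[perm],
            class_a=frame.class_a,
            class_b=[frame.class_b[i] for i in perm],
        )
        assert abs(float(ec_scores(shuffled)["ec"].mean())) < 0.1

    def test_class_labels_follow_construction(self):
        cfg = SimulationConfig(seed=12, n_orthologs_per_class=3, ortholog_samples=10)
        frame, _ = simulate_two_species(cfg)
        assert [frame.pair_class(i) for i in range(frame.k)] == (
            ["S-S"] * 3 + ["S-D"] * 3 + ["D-D"] * 3
        )


class TestAncillaryGenerators:
    def test_methylation_probes_on_grid(self):
        sim = simulate_genome(SimulationConfig(seed=13, **SMALL))
        track = simulate_methylation(sim.config, sim.annotation)
        states = track.probes_in("chr1", 1, 10_000)
        assert states.size == 10_000 // sim.config.probe_spacing

    def test_families_plant_origin_bias(self):
        sim = simulate_genome(SimulationConfig(seed=14))
        families, planted = simulate_families(sim.config, sim.truth.origins)
        assert len(planted) == sim.config.n_families
        biased = [f for f, m in planted.items() if m is not None]
        assert biased
        for fam in biased:
            members = families.genes_with(fam)
            target = planted[fam]
            frac = np.mean([sim.truth.origins[g] == target for g in members])
            assert frac >= 0.5
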