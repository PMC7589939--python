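import numpy as np
import pytest

from methanocosm import synthetic_community as sc
from methanocosm.formats_io import CdsRecord, Scaffold
from methanocosm.genotype_derep import pairwise_protein_identity


class TestSimulateGenomes:
    def test_small_study_layout(self):
        spec = sc.TaxonSpec(
            name="T1",
            lineage=("Bacteria",) * 6,
            genome_length_bp=10_000,
            n_scaffolds=1,
            families={},
            background_cds=3,
        )
        fasta, scaffolds, cdss, fams, weights = sc.simulate_genomes([spec], seed=5)
        assert len(scaffolds) == 1 and len(cdss) == 3
        assert sum(len(seq) for _, seq in fasta) == 10_000
        for c in cdss:
            assert 300 <= c.length_bp <= 1500 and c.length_bp % 3 == 0
            assert c.end <= scaffolds[0].length_bp

    def test_cds_do_not_overlap_within_scaffold(self, default_study):
        by_scaffold = {}
        for c in default_study["cdss"]:
            by_scaffold.setdefault(c.scaffold_id, []).append(c)
        for cdss in by_scaffold.values():
            cdss.sort(key=lambda c: c.start)
            for a, b in zip(cdss, cdss[1:]):
                assert a.end < b.start

    def test_determinism(self):
        specs = sc.default_taxon_specs()
        out1 = sc.simulate_genomes(specs, seed=3)
        out2 = sc.simulate_genomes(specs, seed=3)
        assert out1 == out2

    def test_family_copy_counts_match_spec(self, default_study):
        by_taxon_family = {}
        for c in default_study["cdss"]:
            if c.family:
                by_taxon_family.setdefault((c.taxon, c.family), []).append(c)
        for spec in default_study["specs"]:
            for fam, ws in spec.families.items():
                assert len(by_taxon_family[(spec.name, fam)]) == len(ws)

    def test_four_distinct_rank_paths(self, default_study):
        paths = {s.taxonomy for s in default_study["scaffolds"]}
        assert len(paths) == 4

    def test_capacity_error(self):
        spec = sc.TaxonSpec(
            name="tiny",
            lineage=("Bacteria",),
            genome_length_bp=1000,
            n_scaffolds=1,
            background_cds=10,
        )
        with pytest.raises(ValueError, match="exceeds|place"):
            sc.simulate_genomes([spec], seed=1)


class TestMutateSequence:
    def test_zero_divergence_is_identity(self):
        seq = "ACGT" * 100
        out, realized = sc.mutate_sequence(seq, 0.0, 0.0, seed=1)
        assert out == seq and realized == 0.0

    def test_substitution_fraction_concentrates(self):
        rng = np.random.default_rng(0)
        seq = rng.choice(sc._NT, size=100_000).tobytes().decode()
        out, realized = sc.mutate_sequence(seq, 0.02, 0.0, seed=2)
        hamming = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert hamming == pytest.approx(realized)
        assert 0.018 <= hamming <= 0.022  # binomial tail bound at n = 1e5

    def test_protein_variant_identity_matches_divergence(self):
        rng = np.random.default_rng(1)
        prot = rng.choice(sc._AA, size=400).tobytes().decode()
        var, realized = sc.mutate_sequence(prot, 0.08, 0.0, seed=3, alphabet="aa")
        ident = pairwise_protein_identity(prot, var)
        # terminal substitutions may be trimmed by the free-end-gap
        # alignment, so allow a small slack around the realized value
        assert ident == pytest.approx(100 * (1 - realized), abs=0.5)
        assert 88 <= ident <= 96  # ~92% expected

    def test_indels_change_length(self):
        seq = "ACGT" * 1000
        out, _ = sc.mutate_sequence(seq, 0.0, 0.05, seed=4)
        assert out != seq and len(out) != len(seq)

    def test_bad_divergence_rejected(self):
        with pytest.raises(ValueError):
            sc.mutate_sequence("ACGT", 1.0)
        with pytest.raises(ValueError):
            sc.mutate_sequence("ACGT", 0.1, indel_rate=0.5)


class TestSimulateDynamics:
    def test_default_design_has_88_samples(self):
        metas, props = sc.simulate_dynamics(sc.default_dynamics_spec(), seed=1)
        assert len(metas) == 88
        assert len({m.sample_id for m in metas}) == 88
        for m in metas:
            assert m.post_switch == (m.week > 10)
        for p in props.values():
            assert sum(p.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_zero_effect_uniform(self):
        spec = sc.DynamicsSpec(
            taxa=("a", "b", "c"),
            baseline=(0.0, 0.0, 0.0),
            lo_effect=(0.0, 0.0, 0.0),
            noise_sd=0.0,
        )
        _, props = sc.simulate_dynamics(spec, seed=1)
        for p in props.values():
            for v in p.values():
                assert v == pytest.approx(1 / 3)

    def test_lo_effect_raises_lo_mean(self):
        spec = sc.DynamicsSpec(
            taxa=("up", "flat"),
            baseline=(0.0, 0.0),
            lo_effect=(2.0, 0.0),
            noise_sd=0.2,
        )
        metas, props = sc.simulate_dynamics(spec, seed=2)
        pre = [m for m in metas if not m.post_switch]
        lo = np.mean([props[m.sample_id]["up"] for m in pre if m.condition_initial == "LO"])
        ho = np.mean([props[m.sample_id]["up"] for m in pre if m.condition_initial == "HO"])
        assert lo > ho


class TestSimulateReads:
    def setup_tables(self):
        scaffolds = [Scaffold("t1_s1", 1000, ("B",)), Scaffold("t2_s1", 1000, ("B",))]
        cdss = [
            CdsRecord("t1_c1", "t1_s1", 1, 300, "+", taxon="t1"),
            CdsRecord("t2_c1", "t2_s1", 1, 300, "+", taxon="t2"),
        ]
        taxon_of = {"t1_s1": "t1", "t2_s1": "t2"}
        return scaffolds, cdss, taxon_of

    def test_zero_depth_gives_all_zero(self):
        scaffolds, cdss, taxon_of = self.setup_tables()
        props = {"s": {"t1": 0.5, "t2": 0.5}}
        dna, rna, _ = sc.simulate_reads(
            props, scaffolds, cdss, {}, taxon_of, n_dna_reads=0, n_rna_reads=0, seed=1
        )
        assert dna["s"].total_reads() == 0 and rna["s"].total_reads() == 0

    def test_single_taxon_takes_all_reads(self):
        scaffolds, cdss, taxon_of = self.setup_tables()
        props = {"s": {"t1": 1.0, "t2": 0.0}}
        dna, _, _ = sc.simulate_reads(
            props, scaffolds, cdss, {}, taxon_of, n_dna_reads=1000, n_rna_reads=10, seed=1
        )
        assert dna["s"].counts["t1_s1"].reads == 1000
        assert dna["s"].counts["t2_s1"].reads == 0

    def test_read_share_tracks_proportion(self):
        scaffolds, cdss, taxon_of = self.setup_tables()
        props = {"s": {"t1": 0.8, "t2": 0.2}}
        dna, _, _ = sc.simulate_reads(
            props, scaffolds, cdss, {}, taxon_of, n_dna_reads=100_000, n_rna_reads=10, seed=2
        )
        share = dna["s"].counts["t1_s1"].reads / 100_000
        assert abs(share - 0.8) <= 0.01  # ~8 binomial SEs

    def test_expression_fractions_sum_to_one(self, default_study):
        for fr in default_study["truth"].expression_fractions.values():
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_bad_proportions_rejected(self):
        scaffolds, cdss, taxon_of = self.setup_tables()
        with pytest.raises(ValueError, match="sum"):
            sc.simulate_reads(
                {"s": {"t1": 0.6, "t2": 0.6}}, scaffolds, cdss, {}, taxon_of, seed=1
            )
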