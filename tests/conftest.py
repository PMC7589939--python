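import numpy as np
import pytest

from methanocosm import synthetic_community as sc


@pytest.fixture(scope="session")
def default_study():
    """One simulated study at the default design, shared across tests."""
    specs = sc.default_taxon_specs()
    genome_fasta, scaffolds, cdss, family_proteins, weights = sc.simulate_genomes(
        specs, seed=11
    )
    dyn = sc.default_dynamics_spec()
    metas, proportions = sc.simulate_dynamics(dyn, seed=11)
    taxon_of_scaffold = {s.scaffold_id: s.scaffold_id.rsplit("_s", 1)[0] for s in scaffolds}
    dna, rna, truth = sc.simulate_reads(
        proportions,
        scaffolds,
        cdss,
        weights,
        taxon_of_scaffold,
        n_dna_reads=50_000,
        n_rna_reads=50_000,
        seed=11,
    )
    return {
        "specs": specs,
        "genome_fasta": genome_fasta,
        "scaffolds": scaffolds,
        "cdss": cdss,
        "family_proteins": family_proteins,
        "weights": weights,
        "metas": metas,
        "proportions": proportions,
        "dna": dna,
        "rna": rna,
        "truth": truth,
        "taxon_of_scaffold": taxon_of_scaffold,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
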