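"""Mock methanotroph-microcosm study generator with full ground truth.

Emulates the two-oxygen-regime microcosm design: 2 regimes (LO = low
oxygen, HO = high oxygen) x 4 replicates x weekly samples from week 4
through week 14, with the regimes swapped after week 10.  Genomes,
scaffolds, CDSs and gene-family genotypes are generated de novo; DNA and
RNA read counts are drawn multinomially so that per-scaffold coverage is
proportional to taxon abundance and per-CDS read mass is proportional to
abundance x expression weight x CDS length.

Ground truth (taxon proportions, expression fractions, realized pairwise
divergences) is recorded for every sample so downstream estimators can be
tested for recovery.  Downstream modules consume only the emitted
standard-format files; the simulator has no private channel to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import CdsRecord, CountSet, SampleMeta, Scaffold, UnitCount

_NT = np.frombuffer(b"ACGT", dtype="S1")
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")

# stage indices for fanning the global seed out to independent streams
_STAGE_GENOMES = 1
_STAGE_DYNAMICS = 2
_STAGE_READS = 3
_STAGE_MUTATE = 4


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(seed + stage)


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: genome layout and gene-family content.

    ``families`` maps a gene-family label (e.g. ``xoxF``) to the relative
    expression weight of each copy carried; a taxon with three xoxF copies
    at equal expression uses ``{"xoxF": (1.0, 1.0, 1.0)}``.
    ``background_cds`` adds unlabelled CDSs, each with weight
    ``background_weight``.
    """

    name: str
    lineage: tuple[str, ...]  # domain..genus path, coarse to fine
    genome_length_bp: int = 50_000
    n_scaffolds: int = 5
    families: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    background_cds: int = 10
    background_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.genome_length_bp < self.n_scaffolds:
            raise ValueError(f"{self.name}: genome shorter than its scaffold count")
        for fam, weights in self.families.items():
            if any(w < 0 for w in weights):
                raise ValueError(f"{self.name}/{fam}: expression weights must be >= 0")
        if self.background_weight < 0:
            raise ValueError(f"{self.name}: background weight must be >= 0")


@dataclass(frozen=True)
class DynamicsSpec:
    """Per-taxon abundance dynamics across the two-regime design.

    Per-sample taxon proportions are ``softmax(baseline + effect + noise)``
    where ``effect`` (the LO-vs-HO log-abundance offset) is added only when
    the regime in effect at sampling time is LO, and the regime flips after
    ``switch_week``.
    """

    taxa: tuple[str, ...]
    baseline: tuple[float, ...]
    lo_effect: tuple[float, ...]
    noise_sd: float = 0.3
    weeks: tuple[int, ...] = tuple(range(4, 15))
    replicates: int = 4
    switch_week: int = 10

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(self.baseline) != n or len(self.lo_effect) != n:
            raise ValueError("baseline and lo_effect must match the taxon list")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows that an estimator must recover."""

    #: sample_id -> {taxon: true proportion}
    proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    #: sample_id -> {cds_id: true expression fraction} (TPM scale / 1e6)
    expression_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    #: (family, id_a, id_b) -> realized protein divergence fraction
    protein_divergence: dict[tuple[str, str, str], float] = field(default_factory=dict)
    #: (genome_a, genome_b) -> realized nucleotide divergence fraction
    nucleotide_divergence: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

_PRODUCT_OF = {
    "xoxF": "XoxF lanthanide-dependent methanol dehydrogenase",
    "mxaF": "MxaF calcium-dependent methanol dehydrogenase, large subunit",
    "pmoA": "particulate methane monooxygenase, subunit A",
    "icl": "isocitrate lyase",
}

_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _random_seq(rng: np.random.Generator, n: int, alphabet: np.ndarray) -> str:
    return rng.choice(alphabet, size=n).tobytes().decode()


def simulate_genomes(
    taxon_specs: Sequence[TaxonSpec],
    seed: int,
    cds_length_range: tuple[int, int] = (300, 1500),
) -> tuple[
    list[tuple[str, str]],
    list[Scaffold],
    list[CdsRecord],
    dict[str, list[tuple[str, str]]],
    dict[str, float],
]:
    """Generate genomes, scaffold/CDS tables and per-family protein FASTA.

    Returns ``(genome_fasta, scaffolds, cds_records, family_proteins,
    cds_weights)`` where ``genome_fasta`` holds one record per scaffold,
    ``family_proteins`` maps family label to protein records, and
    ``cds_weights`` maps cds_id to its relative expression weight.
    Deterministic given ``seed``.
    """
    rng = _stage_rng(seed, _STAGE_GENOMES)
    lo, hi = cds_length_range
    if lo < 3 or hi < lo:
        raise ValueError("invalid CDS length range")

    genome_fasta: list[tuple[str, str]] = []
    scaffolds: list[Scaffold] = []
    cds_records: list[CdsRecord] = []
    family_proteins: dict[str, list[tuple[str, str]]] = {}
    cds_weights: dict[str, float] = {}

    for spec in taxon_specs:
        # plan CDSs: (family or None, weight, length multiple of 3)
        plan: list[tuple[str | None, float]] = []
        for fam in sorted(spec.families):
            for w in spec.families[fam]:
                plan.append((fam, float(w)))
        plan.extend((None, spec.background_weight) for _ in range(spec.background_cds))
        lengths = (rng.integers(lo // 3, hi // 3 + 1, size=len(plan)) * 3).tolist()

        # near-equal scaffold split
        base = spec.genome_length_bp // spec.n_scaffolds
        sizes = [base] * spec.n_scaffolds
        sizes[-1] += spec.genome_length_bp - base * spec.n_scaffolds
        total_cds = sum(lengths)
        if total_cds > spec.genome_length_bp:
            raise ValueError(
                f"{spec.name}: requested CDS content ({total_cds} bp) exceeds "
                f"genome capacity ({spec.genome_length_bp} bp)"
            )

        # assign CDSs to scaffolds first-fit, then lay out left to right with
        # random intergenic gaps
        per_scaffold: list[list[int]] = [[] for _ in range(spec.n_scaffolds)]
        free = sizes.copy()
        for ci, clen in enumerate(lengths):
            placed = False
            for si in range(spec.n_scaffolds):
                if free[si] >= clen:
                    per_scaffold[si].append(ci)
                    free[si] -= clen
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"{spec.name}: cannot place a {clen} bp CDS on any scaffold"
                )

        cds_seq: dict[int, str] = {}
        for ci, (fam, _w) in enumerate(plan):
            if fam is not None:
                prot = _random_seq(rng, lengths[ci] // 3, _AA)
                pid = f"{spec.name}_{fam}_{sum(1 for j in range(ci) if plan[j][0] == fam) + 1}"
                family_proteins.setdefault(fam, []).append((pid, prot))
                cds_seq[ci] = "".join(_CODON_OF[a] for a in prot)

        for si, scaffold_cds in enumerate(per_scaffold):
            sid = f"{spec.name}_s{si + 1}"
            slen = sizes[si]
            seq = list(_random_seq(rng, slen, _NT))
            slack = slen - sum(lengths[ci] for ci in scaffold_cds)
            # random gaps before each CDS and after the last
            cuts = np.sort(rng.integers(0, slack + 1, size=len(scaffold_cds)))
            pos = 0
            prev_cut = 0
            for k, ci in enumerate(scaffold_cds):
                pos += int(cuts[k] - prev_cut)
                prev_cut = int(cuts[k])
                start = pos + 1
                end = pos + lengths[ci]
                fam, w = plan[ci]
                if ci in cds_seq:
                    seq[pos : pos + lengths[ci]] = cds_seq[ci]
                if fam is not None:
                    cid = f"{spec.name}_{fam}_{sum(1 for j in range(ci) if plan[j][0] == fam) + 1}"
                    product = _PRODUCT_OF.get(fam, f"{fam} family protein")
                else:
                    cid = f"{spec.name}_cds{ci + 1}"
                    product = "hypothetical protein"
                strand = "+" if rng.random() < 0.5 else "-"
                cds_records.append(
                    CdsRecord(
                        cds_id=cid,
                        scaffold_id=sid,
                        start=start,
                        end=end,
                        strand=strand,
                        product=product,
                        family=fam,
                        taxon=spec.name,
                    )
                )
                cds_weights[cid] = w
                pos = end
            genome_fasta.append((sid, "".join(seq)))
            scaffolds.append(Scaffold(sid, slen, spec.lineage))

    return genome_fasta, scaffolds, cds_records, family_proteins, cds_weights


# ---------------------------------------------------------------------------
# sequence mutation
# ---------------------------------------------------------------------------


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    alphabet: str = "nt",
) -> tuple[str, float]:
    """Mutate ``seq`` at a per-site substitution rate of ``divergence``.

    Substitutions are drawn uniformly among the other symbols; indels of
    length 1-3 occur at ``indel_rate`` per site.  Returns
    ``(variant, realized_substitution_fraction)`` where the realized
    fraction counts substituted sites over the original length.
    """
    if not 0 <= divergence < 1:
        raise ValueError(f"divergence must be in [0, 1), got {divergence}")
    if not 0 <= indel_rate < 0.1:
        raise ValueError(f"indel_rate must be in [0, 0.1), got {indel_rate}")
    if not seq:
        raise ValueError("empty sequence")
    symbols = _NT if alphabet == "nt" else _AA
    rng = _stage_rng(seed, _STAGE_MUTATE)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = arr.size

    sub_mask = rng.random(n) < divergence
    n_sub = int(sub_mask.sum())
    if n_sub:
        k = symbols.size
        cur = arr[sub_mask]
        # uniform over the other k-1 symbols
        offsets = rng.integers(1, k, size=n_sub)
        sym_index = {s: i for i, s in enumerate(symbols)}
        cur_pos = np.array([sym_index[c] for c in cur])
        arr[sub_mask] = symbols[(cur_pos + offsets) % k]
    realized = n_sub / n

    out = arr.tobytes().decode()
    if indel_rate > 0:
        chars = list(out)
        events = np.nonzero(rng.random(len(chars)) < indel_rate)[0]
        for pos in events[::-1]:  # right to left so indices stay valid
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del chars[pos : pos + length]
            else:
                ins = _random_seq(rng, length, symbols)
                chars[pos:pos] = list(ins)
        out = "".join(chars)
    return out, realized


def make_family_genotypes(
    family: str,
    parent_id: str,
    parent_seq: str,
    divergences: Sequence[float],
    seed: int,
    truth: GroundTruth | None = None,
) -> list[tuple[str, str]]:
    """Derive variant genotypes of a parent protein at stated divergences."""
    records = [(parent_id, parent_seq)]
    for i, d in enumerate(divergences):
        vid = f"{parent_id}_var{i + 1}"
        var, realized = mutate_sequence(
            parent_seq, d, indel_rate=0.0, seed=seed + i, alphabet="aa"
        )
        records.append((vid, var))
        if truth is not None:
            truth.protein_divergence[(family, parent_id, vid)] = realized
    return records


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def simulate_dynamics(
    spec: DynamicsSpec, seed: int
) -> tuple[list[SampleMeta], dict[str, dict[str, float]]]:
    """Draw per-sample taxon proportions over the full microcosm design.

    Returns the sample metadata table and ``{sample_id: {taxon: p}}`` with
    each proportion vector summing to 1.  The default design yields
    2 conditions x 4 replicates x 11 weeks = 88 samples.
    """
    rng = _stage_rng(seed, _STAGE_DYNAMICS)
    baseline = np.asarray(spec.baseline, dtype=float)
    effect = np.asarray(spec.lo_effect, dtype=float)
    metas: list[SampleMeta] = []
    proportions: dict[str, dict[str, float]] = {}
    for condition in ("LO", "HO"):
        for rep in range(1, spec.replicates + 1):
            for week in spec.weeks:
                post = week > spec.switch_week
                if post:
                    current = "HO" if condition == "LO" else "LO"
                else:
                    current = condition
                logits = baseline + (effect if current == "LO" else 0.0)
                if spec.noise_sd > 0:
                    logits = logits + rng.normal(0.0, spec.noise_sd, size=logits.size)
                p = _softmax(logits)
                sid = f"{condition}{week}_R{rep}"
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        replicate=f"R{rep}",
                        condition_initial=condition,
                        week=int(week),
                        post_switch=post,
                    )
                )
                proportions[sid] = dict(zip(spec.taxa, p.tolist()))
    return metas, proportions


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def simulate_reads(
    proportions: Mapping[str, Mapping[str, float]],
    scaffolds: Sequence[Scaffold],
    cds_records: Sequence[CdsRecord],
    cds_weights: Mapping[str, float],
    taxon_of_scaffold: Mapping[str, str],
    n_dna_reads: int = 100_000,
    n_rna_reads: int = 100_000,
    read_length: int = 150,
    seed: int = 0,
) -> tuple[dict[str, CountSet], dict[str, CountSet], GroundTruth]:
    """Draw DNA and RNA read counts for every sample.

    DNA reads follow a multinomial over scaffolds with probability
    proportional to ``proportion(taxon) * scaffold_length``; RNA reads follow
    a multinomial over CDSs with probability proportional to
    ``proportion(taxon) * expression_weight * cds_length``.  Aligned bases
    are ``reads * read_length``.
    """
    if n_dna_reads < 0 or n_rna_reads < 0:
        raise ValueError("read depths must be >= 0")
    rng = _stage_rng(seed, _STAGE_READS)
    truth = GroundTruth()
    scaffold_ids = [s.scaffold_id for s in scaffolds]
    scaffold_len = np.array([s.length_bp for s in scaffolds], dtype=float)
    scaffold_taxon = [taxon_of_scaffold[sid] for sid in scaffold_ids]
    cds_ids = [c.cds_id for c in cds_records]
    cds_len = np.array([c.length_bp for c in cds_records], dtype=float)
    cds_taxon = [c.taxon for c in cds_records]
    w = np.array([cds_weights.get(cid, 1.0) for cid in cds_ids], dtype=float)

    dna_sets: dict[str, CountSet] = {}
    rna_sets: dict[str, CountSet] = {}
    for sid in sorted(proportions):
        p_taxon = proportions[sid]
        total = sum(p_taxon.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"sample {sid!r}: proportions sum to {total}, not 1")
        truth.proportions[sid] = dict(p_taxon)

        p_scaf = np.array([p_taxon.get(t, 0.0) for t in scaffold_taxon]) * scaffold_len
        if p_scaf.sum() <= 0:
            raise ValueError(f"sample {sid!r}: zero total scaffold probability")
        p_scaf = p_scaf / p_scaf.sum()
        dna = rng.multinomial(n_dna_reads, p_scaf)
        dna_sets[sid] = CountSet(
            sample_id=sid,
            unit="scaffold",
            counts={
                scaffold_ids[i]: UnitCount(int(dna[i]), int(dna[i]) * read_length)
                for i in range(len(scaffold_ids))
            },
            read_length_bp=read_length,
        )

        p_rna = np.array([p_taxon.get(t, 0.0) for t in cds_taxon]) * w * cds_len
        if p_rna.sum() <= 0:
            raise ValueError(f"sample {sid!r}: zero total CDS probability")
        p_rna = p_rna / p_rna.sum()
        rna = rng.multinomial(n_rna_reads, p_rna)
        rna_sets[sid] = CountSet(
            sample_id=sid,
            unit="cds",
            counts={
                cds_ids[i]: UnitCount(int(rna[i]), int(rna[i]) * read_length)
                for i in range(len(cds_ids))
            },
            read_length_bp=read_length,
        )

        # true expression fraction on the TPM scale: proportional to
        # abundance x weight (CDS length cancels after length normalization)
        expr = np.array([p_taxon.get(t, 0.0) for t in cds_taxon]) * w
        expr = expr / expr.sum()
        truth.expression_fractions[sid] = dict(zip(cds_ids, expr.tolist()))

    return dna_sets, rna_sets, truth


# ---------------------------------------------------------------------------
# default study
# ---------------------------------------------------------------------------


def default_taxon_specs() -> list[TaxonSpec]:
    """The four persistent guilds of a methane-fed freshwater microcosm.

    Methanotrophs (Methylococcaceae/Methylobacter), methylotrophs
    (Methylophilaceae/Methylotenera, carrying several xoxF genotypes),
    acetate-consuming Burkholderiales (Acidovorax) and biopolymer-degrading
    Bacteroidetes (Flavobacterium).  Equal scaffold counts per taxon make
    summed per-scaffold abundance equal to taxon abundance in expectation.
    """
    return [
        TaxonSpec(
            name="Methylobacter",
            lineage=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                     "Methylococcales", "Methylococcaceae", "Methylobacter"),
            families={"xoxF": (1.0,), "mxaF": (1.0,), "pmoA": (2.0,)},
        ),
        TaxonSpec(
            name="Methylotenera",
            lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                     "Nitrosomonadales", "Methylophilaceae", "Methylotenera"),
            families={"xoxF": (1.0, 1.0, 1.0), "mxaF": (1.0,)},
        ),
        TaxonSpec(
            name="Acidovorax",
            lineage=("Bacteria", "Proteobacteria", "Betaproteobacteria",
                     "Burkholderiales", "Comamonadaceae", "Acidovorax"),
            families={"icl": (1.5,)},
            background_cds=12,
        ),
        TaxonSpec(
            name="Flavobacterium",
            lineage=("Bacteria", "Bacteroidetes", "Flavobacteriia",
                     "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium"),
            background_cds=12,
        ),
    ]


def default_dynamics_spec(noise_sd: float = 0.3) -> DynamicsSpec:
    """Stated-world dynamics: methylotroph guilds favored under low oxygen."""
    return DynamicsSpec(
        taxa=("Methylobacter", "Methylotenera", "Acidovorax", "Flavobacterium"),
        baseline=(1.2, 0.6, -0.4, -0.8),
        lo_effect=(0.8, 0.3, -0.8, -0.3),
        noise_sd=noise_sd,
    )
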