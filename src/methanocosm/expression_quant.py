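"""TPM quantification, family-normalized expression and consensus genes.

TPM (transcripts per million) for a gene g:

    TPM_g = (rg * rl * 1e6) / (cl_g * T),   T = sum_g rg * rl / cl_g

with rg reads mapped to the gene, rl the read length and cl the CDS
length; per-sample TPMs sum to one million.  Family-normalized expression
rescales each gene's TPM by the summed TPM of its family aggregate
(e.g. Methylococcaceae-xoxF vs Methylococcaceae-mxaF), the quantity behind
methanol-dehydrogenase expression-ratio heatmaps.  Consensus-gene
expression sums reads over homolog groups within a genus before length
normalization, producing the ranked highly-expressed-gene lists.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import CdsRecord, CountSet

SCALE = 1e6

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    pass


def gene_tpm(count_set: CountSet, cds_table: Sequence[CdsRecord]) -> pd.Series:
    """TPM per CDS for one sample; values sum to one million.

    Uses aligned bases as the generalized ``rg * rl`` numerator so that
    variable-length reads are handled exactly.
    """
    if count_set.unit != "cds":
        raise QuantError(f"expected CDS counts, got unit={count_set.unit!r}")
    by_id = {c.cds_id: c for c in cds_table}
    unknown = sorted(set(count_set.counts) - set(by_id))
    if unknown:
        raise QuantError(f"counts reference unknown CDS ids: {unknown}")
    ids = [c.cds_id for c in cds_table]
    weights = np.array(
        [
            (count_set.counts[cid].aligned_bases if cid in count_set.counts else 0)
            / by_id[cid].length_bp
            for cid in ids
        ]
    )
    total = weights.sum()
    if total <= 0:
        raise QuantError(f"empty profile: sample {count_set.sample_id!r} has no CDS reads")
    return pd.Series(weights * SCALE / total, index=ids, name=count_set.sample_id)


def tpm_table(
    count_sets: Mapping[str, CountSet], cds_table: Sequence[CdsRecord]
) -> pd.DataFrame:
    """Stack per-sample TPM rows into a sample x CDS matrix."""
    rows = {sid: gene_tpm(cs, cds_table) for sid, cs in sorted(count_sets.items())}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def family_normalize(
    tpm_row: pd.Series,
    family_of: Mapping[str, str],
    rescale: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Within-family per-million expression and its log2 transform.

    ``family_of`` maps each gene to exactly one family aggregate (for
    example ``"Methylococcaceae/xoxF"``); genes absent from the mapping are
    ignored.  Each gene's TPM is divided by its family's summed TPM and,
    when ``rescale`` is set, multiplied by one million.  Zero cells are
    masked (NaN) rather than pseudo-counted — log2 is only taken of
    positive values; a family with zero total yields a fully masked block
    and a logged warning.

    Returns ``(linear, log2)`` Series indexed by gene.
    """
    genes = [g for g in tpm_row.index if g in family_of]
    fam_total: dict[str, float] = {}
    for g in genes:
        fam_total[family_of[g]] = fam_total.get(family_of[g], 0.0) + float(tpm_row[g])
    factor = SCALE if rescale else 1.0
    linear = {}
    for g in genes:
        tot = fam_total[family_of[g]]
        if tot <= 0:
            logger.warning("family %s has zero total TPM; cells masked", family_of[g])
            linear[g] = math.nan
        else:
            linear[g] = float(tpm_row[g]) / tot * factor
    lin = pd.Series(linear, name=tpm_row.name)
    log2 = lin.map(lambda v: math.log2(v) if v and v > 0 else math.nan)
    return lin, log2


def sum_genotypes(
    tpm_row: pd.Series, clusters: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Sum member TPM over genotype clusters of one gene family.

    ``clusters`` maps cluster id to member gene ids; members must not
    repeat across clusters.  Because addition is associative the family
    total is invariant to how members are split into genotypes.
    """
    seen: dict[str, str] = {}
    for cid, members in clusters.items():
        for g in members:
            if g in seen:
                raise QuantError(f"gene {g!r} appears in clusters {seen[g]!r} and {cid!r}")
            seen[g] = cid
    values = {
        cid: float(sum(tpm_row.get(g, 0.0) for g in members))
        for cid, members in clusters.items()
    }
    return pd.Series(values, name=tpm_row.name)


@dataclass(frozen=True)
class ConsensusGene:
    """One homolog group with its summed, length-normalized signal."""

    group_id: str
    normalized_reads: float
    summed_reads: int
    representative_length: float
    product: str


def consensus_expression(
    count_set: CountSet,
    cds_table: Sequence[CdsRecord],
    homolog_groups: Mapping[str, Sequence[str]],
    genus_scope: str,
    top_n: int = 50,
) -> list[ConsensusGene]:
    """Ranked consensus-gene expression within a genus scope.

    Reads over all homologs of a group are summed; the group's
    representative length is the arithmetic mean of member CDS lengths;
    the summed counts are length-normalized and expressed per million of
    the total signal classified to the genus.  Output is sorted by
    descending value, ties broken by ascending group id, truncated to
    ``top_n`` rows.
    """
    if count_set.unit != "cds":
        raise QuantError(f"expected CDS counts, got unit={count_set.unit!r}")
    by_id = {c.cds_id: c for c in cds_table}
    scope_cds = {c.cds_id for c in cds_table if c.taxon == genus_scope}
    if not scope_cds:
        raise QuantError(f"empty scope: no CDS annotated to {genus_scope!r}")
    grouped: set[str] = set()
    for gid, members in homolog_groups.items():
        for m in members:
            if m not in by_id:
                raise QuantError(f"group {gid!r} references unknown CDS {m!r}")
            if m in grouped:
                raise QuantError(f"CDS {m!r} appears in more than one homolog group")
            grouped.add(m)
        if not set(members) <= scope_cds:
            raise QuantError(f"group {gid!r} contains CDSs outside genus {genus_scope!r}")

    rows = []
    for gid in sorted(homolog_groups):
        members = homolog_groups[gid]
        reads = sum(count_set.counts[m].reads for m in members if m in count_set.counts)
        bases = sum(
            count_set.counts[m].aligned_bases for m in members if m in count_set.counts
        )
        cl_star = float(np.mean([by_id[m].length_bp for m in members]))
        product = by_id[members[0]].product
        rows.append((gid, reads, bases, cl_star, product))
    total = sum(bases / cl for _, _, bases, cl, _ in rows)
    if total <= 0:
        raise QuantError(f"no reads attributed to genus {genus_scope!r}")
    out = [
        ConsensusGene(
            group_id=gid,
            normalized_reads=(bases / cl) * SCALE / total,
            summed_reads=reads,
            representative_length=cl,
            product=product,
        )
        for gid, reads, bases, cl, product in rows
    ]
    out.sort(key=lambda c: (-c.normalized_reads, c.group_id))
    return out[:top_n]


def consensus_table(genes: Sequence[ConsensusGene]) -> pd.DataFrame:
    """Tabulate a ranked consensus list with the conventional column names."""
    df = pd.DataFrame(
        {
            "Consensus Gene": [g.group_id for g in genes],
            "Normalized Reads": [g.normalized_reads for g in genes],
            "Protein Annotation": [g.product for g in genes],
        }
    )
    df.index = pd.RangeIndex(1, len(genes) + 1, name="rank")
    return df
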