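"""Protein genotype dereplication at an identity threshold.

Gene-family sequences (e.g. the multiple xoxF copies carried by
Methylophilaceae) are sorted into genotypes: two sequences belong to the
same genotype when their global protein identity is at least the
threshold (default 95%, i.e. at most 5% divergence; exactly 95.000%
clusters together).  Clusters are the connected components of the
threshold graph — the unique order-independent closure of the pairwise
rule — and one representative (the longest member, ties by ascending id)
is selected per genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align


class DerepError(ValueError):
    pass


def _make_aligner() -> Align.PairwiseAligner:
    # identity alignment: match +1, mismatch -1, linear gap -2, free end gaps
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_protein_identity(a: str, b: str) -> float:
    """Percent identity of a global alignment, terminal gaps excluded.

    Identity is exact matches over alignment columns, where columns inside
    a terminal gap (ragged homolog ends from annotation) do not count.
    Symmetric; returns a value in [0, 100].
    """
    if not a or not b:
        raise DerepError("empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    ncol = len(sa)
    start, end = 0, ncol
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    arr_a = np.frombuffer(sa[start:end].encode(), dtype="S1")
    arr_b = np.frombuffer(sb[start:end].encode(), dtype="S1")
    matches = int(((arr_a == arr_b) & (arr_a != b"-")).sum())
    return 100.0 * matches / (end - start)


@dataclass(frozen=True)
class GenotypeCluster:
    """One genotype: member ids, the chosen representative, identities."""

    family: str
    members: tuple[str, ...]
    representative: str
    # pairwise identity over members, keyed (id_a, id_b) with id_a < id_b
    identities: dict[tuple[str, str], float]


def identity_matrix(seqs: Sequence[tuple[str, str]]) -> dict[tuple[str, str], float]:
    """All pairwise identities, keyed by sorted id pair."""
    out: dict[tuple[str, str], float] = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            (ida, sa), (idb, sb) = seqs[i], seqs[j]
            key = (ida, idb) if ida < idb else (idb, ida)
            out[key] = pairwise_protein_identity(sa, sb)
    return out


def cluster_genotypes(
    seqs: Sequence[tuple[str, str]],
    threshold_identity: float = 95.0,
    family: str = "",
) -> list[GenotypeCluster]:
    """Partition sequences into genotypes by single-linkage at a threshold.

    Edges connect pairs with identity >= ``threshold_identity``; genotypes
    are the connected components.  The partition is invariant to input
    order; clusters are returned sorted by their smallest member id.
    """
    if not seqs:
        raise DerepError("at least one sequence required")
    ids = [sid for sid, _ in seqs]
    if len(set(ids)) != len(ids):
        raise DerepError("duplicate sequence ids")
    idents = identity_matrix(seqs)

    parent = {sid: sid for sid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), ident in idents.items():
        if ident >= threshold_identity:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    components: dict[str, list[str]] = {}
    for sid in ids:
        components.setdefault(find(sid), []).append(sid)

    seq_of = dict(seqs)
    clusters = []
    for members in components.values():
        members_sorted = tuple(sorted(members))
        rep = min(members_sorted, key=lambda m: (-len(seq_of[m]), m))
        sub = {
            k: v
            for k, v in idents.items()
            if k[0] in members_sorted and k[1] in members_sorted
        }
        clusters.append(
            GenotypeCluster(
                family=family,
                members=members_sorted,
                representative=rep,
                identities=sub,
            )
        )
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def write_genotype_table(path, clusters: Sequence[GenotypeCluster]) -> None:
    """TSV export: family, genotype_id, member_id, is_representative."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("family\tgenotype_id\tmember_id\tis_representative\n")
        for i, c in enumerate(clusters, start=1):
            gid = f"{c.family or 'family'}_g{i}"
            for m in c.members:
                rep = "true" if m == c.representative else "false"
                fh.write(f"{c.family}\t{gid}\t{m}\t{rep}\n")
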