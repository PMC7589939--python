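"""Fragment-based average nucleotide identity (ANI) and alignment coverage.

The query genome is cut into consecutive 1020 bp fragments (the ANIb
convention; a final fragment shorter than half that is dropped) and each
fragment is aligned to the subject genome natively: exact 15-mer seeds
locate candidate diagonals, the best diagonal is scored ungapped, and a
gapped local alignment over a windowed region is attempted when the
ungapped route fails (indels shift diagonals).  A fragment is accepted
when its identity and aligned fraction clear the thresholds (70% / 0.7);
ANI is the mean identity of accepted fragments and coverage is the
fraction of fragmented query bases inside accepted alignments.

When no fragment is accepted the pair is reported as not comparable
(``ani`` is NaN) rather than as zero — zero would be a fake measurement.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align

DEFAULT_FRAGMENT_BP = 1020
DEFAULT_KMER = 15
DEFAULT_MIN_IDENTITY = 70.0
DEFAULT_MIN_ALN_FRAC = 0.7

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AniError(ValueError):
    pass


@dataclass(frozen=True)
class AniResult:
    """ANI%, alignment coverage% and fragment tally for an ordered pair."""

    query_id: str
    subject_id: str
    ani: float  # NaN when not comparable
    coverage: float
    n_fragments_used: int

    @property
    def comparable(self) -> bool:
        return not math.isnan(self.ani)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fragment_genome(seq: str, fragment_bp: int = DEFAULT_FRAGMENT_BP) -> list[str]:
    """Consecutive fragments; the final one is kept if >= fragment_bp / 2."""
    if len(seq) < fragment_bp / 2:
        raise AniError(
            f"genome of {len(seq)} bp is shorter than half a fragment ({fragment_bp / 2:.0f} bp)"
        )
    frags = [seq[i : i + fragment_bp] for i in range(0, len(seq), fragment_bp)]
    if len(frags[-1]) < fragment_bp / 2:
        frags.pop()
    return frags


def _index_kmers(seq: str, k: int, max_occ: int = 100) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return {km: pos for km, pos in index.items() if len(pos) <= max_occ}


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


_LOCAL = _make_local_aligner()


def _ungapped(frag: np.ndarray, subject: np.ndarray, diag: int) -> tuple[int, int]:
    """(matches, overlap length) of the fragment laid on the subject at offset diag."""
    f_start = max(0, -diag)
    f_end = min(frag.size, subject.size - diag)
    if f_end <= f_start:
        return 0, 0
    a = frag[f_start:f_end]
    b = subject[diag + f_start : diag + f_end]
    return int((a == b).sum()), f_end - f_start


def _gapped(frag: str, subject: str, diag: int, margin: int = 60) -> tuple[float, int]:
    """Local alignment of the fragment against a window around the diagonal.

    Returns (identity fraction over alignment columns, aligned query length).
    """
    lo = max(0, diag - margin)
    hi = min(len(subject), diag + len(frag) + margin)
    window = subject[lo:hi]
    if not window:
        return 0.0, 0
    alignments = _LOCAL.align(frag, window)
    if len(alignments) == 0:
        return 0.0, 0
    aln = alignments[0]
    sa, sb = str(aln[0]), str(aln[1])
    arr_a = np.frombuffer(sa.encode(), dtype="S1")
    arr_b = np.frombuffer(sb.encode(), dtype="S1")
    cols = arr_a.size
    if cols == 0:
        return 0.0, 0
    matches = int(((arr_a == arr_b) & (arr_a != b"-")).sum())
    q_aligned = int((arr_a != b"-").sum())
    return matches / cols, q_aligned


class _SubjectIndex:
    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.arr = np.frombuffer(seq.encode(), dtype="S1")
        self.k = k
        self.index = _index_kmers(seq, k)

    def best_diagonals(self, frag: str, top: int = 3) -> list[int]:
        votes: Counter[int] = Counter()
        k = self.k
        for i in range(0, len(frag) - k + 1):
            for pos in self.index.get(frag[i : i + k], ()):
                votes[pos - i] += 1
        return [d for d, _ in votes.most_common(top)]


def _align_fragment(
    frag: str,
    subject_idx: _SubjectIndex,
    min_identity: float,
    min_aln_frac: float,
) -> tuple[float, int] | None:
    """Best accepted alignment of one fragment: (identity%, aligned query bases)."""
    frag_arr = np.frombuffer(frag.encode(), dtype="S1")
    best: tuple[float, int] | None = None

    def consider(identity_pct: float, q_aligned: int) -> None:
        nonlocal best
        if identity_pct < min_identity or q_aligned / len(frag) < min_aln_frac:
            return
        if best is None or identity_pct * q_aligned > best[0] * best[1]:
            best = (identity_pct, q_aligned)

    diagonals = subject_idx.best_diagonals(frag)
    for diag in diagonals:
        matches, overlap = _ungapped(frag_arr, subject_idx.arr, diag)
        if overlap == 0:
            continue
        identity = 100.0 * matches / overlap
        if identity >= min_identity and overlap / len(frag) >= min_aln_frac:
            consider(identity, overlap)
        else:
            ident_frac, q_aligned = _gapped(frag, subject_idx.seq, diag)
            consider(100.0 * ident_frac, q_aligned)
    return best


def ani_pair(
    query: tuple[str, str],
    subject: tuple[str, str],
    fragment_bp: int = DEFAULT_FRAGMENT_BP,
    min_frag_identity: float = DEFAULT_MIN_IDENTITY,
    min_frag_aln_frac: float = DEFAULT_MIN_ALN_FRAC,
    kmer: int = DEFAULT_KMER,
) -> AniResult:
    """Fragment-based ANI of ``query`` against ``subject``.

    Both arguments are ``(id, sequence)``.  Each query fragment is aligned
    in both orientations and the better accepted hit is kept.  Coverage is
    accepted aligned query bases over total fragmented query bases, so a
    self-comparison yields exactly 100 / 100.
    """
    qid, qseq = query
    sid, sseq = subject
    if not qseq or not sseq:
        raise AniError("empty genome sequence")
    frags = fragment_genome(qseq.upper(), fragment_bp)
    subject_idx = _SubjectIndex(sseq.upper(), kmer)

    identities: list[float] = []
    aligned_bases = 0
    total_bases = sum(len(f) for f in frags)
    for frag in frags:
        fwd = _align_fragment(frag, subject_idx, min_frag_identity, min_frag_aln_frac)
        rev = _align_fragment(
            _revcomp(frag), subject_idx, min_frag_identity, min_frag_aln_frac
        )
        hit = max(
            (h for h in (fwd, rev) if h is not None),
            key=lambda h: h[0] * h[1],
            default=None,
        )
        if hit is not None:
            identities.append(hit[0])
            aligned_bases += hit[1]
    if not identities:
        return AniResult(qid, sid, math.nan, 0.0, 0)
    return AniResult(
        query_id=qid,
        subject_id=sid,
        ani=float(np.mean(identities)),
        coverage=100.0 * min(aligned_bases / total_bases, 1.0),
        n_fragments_used=len(identities),
    )


def ani_matrix(
    genomes: Sequence[tuple[str, str]], **kwargs
) -> dict[tuple[str, str], AniResult]:
    """All ordered pairwise ANI results over a genome collection."""
    ids = [gid for gid, _ in genomes]
    if len(set(ids)) != len(ids):
        raise AniError("duplicate genome ids")
    if len(genomes) < 2:
        raise AniError("at least two genomes required")
    results: dict[tuple[str, str], AniResult] = {}
    for i, q in enumerate(genomes):
        for j, s in enumerate(genomes):
            if i == j:
                continue
            results[(q[0], s[0])] = ani_pair(q, s, **kwargs)
    return results


def dual_triangle(
    genomes: Sequence[tuple[str, str]],
    results: dict[tuple[str, str], AniResult],
) -> "pd.DataFrame":
    """ANI in the upper-right triangle, coverage lower-left, diagonal 100.

    Cell (i, j) reports the (genome_i as query, genome_j as subject)
    comparison; a not-comparable pair shows NaN.  Row/column order follows
    the input order.
    """
    import pandas as pd

    ids = [gid for gid, _ in genomes]
    mat = np.full((len(ids), len(ids)), np.nan)
    np.fill_diagonal(mat, 100.0)
    for i, qid in enumerate(ids):
        for j, sid in enumerate(ids):
            if i == j:
                continue
            r = results[(qid, sid)]
            mat[i, j] = r.ani if i < j else (r.coverage if r.comparable else np.nan)
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_ani_tables(path_matrix, path_long, genomes, results) -> None:
    """Write the dual-triangle matrix and a tidy long-format table."""
    import pandas as pd

    dual_triangle(genomes, results).to_csv(
        path_matrix, sep="\t", float_format="%.2f", lineterminator="\n"
    )
    rows = [
        {
            "query": r.query_id,
            "subject": r.subject_id,
            "ani": r.ani,
            "coverage": r.coverage,
            "n_fragments": r.n_fragments_used,
        }
        for _, r in sorted(results.items())
    ]
    pd.DataFrame(rows).to_csv(
        path_long, sep="\t", index=False, float_format="%.4f", lineterminator="\n"
    )
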