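"""Scaffold-length-normalized taxonomic abundance (TA).

Per-scaffold abundance is the scaffold's read signal divided by scaffold
length, rescaled so the per-sample total is one million:

    TA_s = (rn_s * rl * 1e6) / (sl_s * T),   T = sum_s rn_s * rl / sl_s

where rn is reads mapped to the scaffold, rl the read length and sl the
scaffold length.  When per-read lengths vary, rn*rl generalizes to the
aligned base count; the uniform-read-length formula is the special case.
Taxon abundance at a rank is the sum of per-scaffold TA over scaffolds
annotated to that taxon, so taxon TAs partition the per-million total.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import RANKS, UNCLASSIFIED, CountSet, SampleMeta, Scaffold

SCALE = 1e6


class ProfileError(ValueError):
    pass


def scaffold_ta(
    count_set: CountSet, scaffolds: Sequence[Scaffold]
) -> dict[str, float]:
    """Per-scaffold TA for one sample; values sum to one million.

    Scaffolds with zero reads contribute 0 and are kept (tables stay
    rectangular).  All-zero counts are a hard error.
    """
    if count_set.unit != "scaffold":
        raise ProfileError(f"expected scaffold counts, got unit={count_set.unit!r}")
    by_id = {s.scaffold_id: s for s in scaffolds}
    missing = sorted(set(count_set.counts) - set(by_id))
    if missing:
        raise ProfileError(f"counted scaffolds missing from the scaffold table: {missing}")
    weights: dict[str, float] = {}
    for s in scaffolds:
        c = count_set.counts.get(s.scaffold_id)
        bases = c.aligned_bases if c else 0
        weights[s.scaffold_id] = bases / s.length_bp
    total = sum(weights.values())
    if total <= 0:
        raise ProfileError(f"empty profile: sample {count_set.sample_id!r} has no mapped reads")
    return {sid: w * SCALE / total for sid, w in weights.items()}


def aggregate_ta(
    per_scaffold_ta: Mapping[str, float],
    scaffolds: Sequence[Scaffold],
    rank: str,
) -> dict[str, float]:
    """Sum per-scaffold TA within each taxon at ``rank``.

    Scaffolds without a label at that rank pool into ``"unclassified"``,
    so the output remains an exact partition of the per-million total.
    """
    if rank not in RANKS:
        raise ProfileError(f"unknown rank {rank!r}; expected one of {RANKS}")
    by_id = {s.scaffold_id: s for s in scaffolds}
    out: dict[str, float] = {}
    for sid, ta in per_scaffold_ta.items():
        taxon = by_id[sid].taxon_at(rank) if sid in by_id else UNCLASSIFIED
        out[taxon] = out.get(taxon, 0.0) + ta
    return out


def aggregate_guilds(
    per_scaffold_ta: Mapping[str, float],
    scaffolds: Sequence[Scaffold],
    guilds: Mapping[str, tuple[str, str]],
) -> dict[str, float]:
    """Aggregate TA into named guilds that may live at different ranks.

    ``guilds`` maps an output label to ``(rank, taxon_name)`` — the core
    community of a methanotroph microcosm mixes ranks (families
    Methylococcaceae and Methylophilaceae, order Burkholderiales, phylum
    Bacteroidetes).  A scaffold matching several guilds is counted in the
    first match (mapping order); unmatched scaffolds pool into "other".
    """
    by_id = {s.scaffold_id: s for s in scaffolds}
    out: dict[str, float] = {label: 0.0 for label in guilds}
    out["other"] = 0.0
    for sid, ta in per_scaffold_ta.items():
        s = by_id.get(sid)
        label = "other"
        if s is not None:
            for g, (rank, name) in guilds.items():
                if s.taxon_at(rank) == name:
                    label = g
                    break
        out[label] += ta
    return out


def profile_sample(
    count_set: CountSet, scaffolds: Sequence[Scaffold], rank: str = "family"
) -> dict[str, float]:
    """Convenience: scaffold TA then aggregation in one call."""
    return aggregate_ta(scaffold_ta(count_set, scaffolds), scaffolds, rank)


def build_timeseries(
    abundance_tables: Mapping[str, Mapping[str, float]],
    sample_meta: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Assemble per-sample taxon TAs into one sample x taxon matrix.

    Rows are ordered by (initial condition, replicate, week); taxa missing
    from a sample are filled with 0.  This is the table behind stacked
    community-dynamics displays.
    """
    ids = [m.sample_id for m in sample_meta]
    if len(set(ids)) != len(ids):
        raise ProfileError("duplicate sample_id in metadata")
    missing = sorted(set(abundance_tables) - set(ids))
    if missing:
        raise ProfileError(f"abundance tables for unknown samples: {missing}")
    order = sorted(
        (m for m in sample_meta if m.sample_id in abundance_tables),
        key=lambda m: (m.condition_initial, m.replicate, m.week),
    )
    taxa = sorted({t for tab in abundance_tables.values() for t in tab})
    data = {
        m.sample_id: [abundance_tables[m.sample_id].get(t, 0.0) for t in taxa]
        for m in order
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=taxa)
    df.index.name = "sample_id"
    return df


def write_abundance_table(path, table: pd.DataFrame) -> None:
    """Write a sample x taxon TSV with per-million values at 2 decimals."""
    table.to_csv(path, sep="\t", float_format="%.2f", lineterminator="\n")


def read_abundance_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
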