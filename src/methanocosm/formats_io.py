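"""Readers and writers for the external formats the pipeline touches.

All coordinates are 1-based inclusive (the SAM convention); no 0-based
representation is exposed.  Every writer emits a header line, tab
delimiters, UTF-8 and LF line endings, so that reader(writer(x)) == x.
"""

from __future__ import annotations

import collections
import io
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: ordered taxonomic ranks carried by a scaffold's semicolon path
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scaffold:
    """A contiguous assembled sequence: the unit of taxonomic abundance.

    ``taxonomy`` is an ordered coarse-to-fine rank path (domain..genus,
    semicolon-delimited); missing ranks are empty strings.
    """

    scaffold_id: str
    length_bp: int
    taxonomy: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise FormatError(
                f"scaffold {self.scaffold_id!r}: length must be >= 1, got {self.length_bp}"
            )
        if len(self.taxonomy) > len(RANKS):
            raise FormatError(
                f"scaffold {self.scaffold_id!r}: taxonomy path longer than {len(RANKS)} ranks"
            )

    def taxon_at(self, rank: str) -> str:
        """Taxon label at ``rank``, or ``"unclassified"`` if absent/empty."""
        try:
            i = RANKS.index(rank)
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        if i >= len(self.taxonomy) or not self.taxonomy[i]:
            return UNCLASSIFIED
        return self.taxonomy[i]

    @property
    def taxonomy_str(self) -> str:
        return ";".join(self.taxonomy)


@dataclass(frozen=True)
class CdsRecord:
    """A protein-coding gene; the unit of TPM quantification."""

    cds_id: str
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    product: str = ""
    family: str | None = None
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"CDS {self.cds_id!r}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise FormatError(f"CDS {self.cds_id!r}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise FormatError(f"CDS {self.cds_id!r}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


UnitCount = collections.namedtuple("UnitCount", ["reads", "aligned_bases"])


@dataclass
class CountSet:
    """Read counts (and aligned bases) per scaffold or per CDS for one sample."""

    sample_id: str
    unit: str  # "scaffold" | "cds"
    counts: dict[str, UnitCount] = field(default_factory=dict)
    read_length_bp: int = 150

    def __post_init__(self) -> None:
        if self.unit not in ("scaffold", "cds"):
            raise FormatError(f"unit must be 'scaffold' or 'cds', got {self.unit!r}")
        if self.read_length_bp < 1:
            raise FormatError("read_length_bp must be positive")
        for uid, (reads, bases) in self.counts.items():
            if reads < 0 or bases < 0:
                raise FormatError(f"negative count for {uid!r}")
            if reads > 0 and bases < reads:
                raise FormatError(
                    f"unit {uid!r}: aligned_bases ({bases}) < reads ({reads}); "
                    "each mapped read must contribute at least one base"
                )

    def total_reads(self) -> int:
        return sum(c.reads for c in self.counts.values())


@dataclass(frozen=True)
class SampleMeta:
    """One microcosm sample: replicate, initial regime, sampling week."""

    sample_id: str
    replicate: str  # R1..R4
    condition_initial: str  # LO | HO
    week: int
    post_switch: bool

    def __post_init__(self) -> None:
        if self.condition_initial not in ("LO", "HO"):
            raise FormatError(f"condition must be LO or HO, got {self.condition_initial!r}")
        if self.post_switch != (self.week > 10):
            raise FormatError(
                f"sample {self.sample_id!r}: post_switch must hold exactly when week > 10"
            )

    @property
    def condition_current(self) -> str:
        """Regime in effect when the sample was taken (switch after week 10)."""
        if not self.post_switch:
            return self.condition_initial
        return "HO" if self.condition_initial == "LO" else "LO"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike, alphabet: str = "nt") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    ``alphabet`` is ``"nt"`` (A/C/G/T/N) or ``"aa"`` (20 amino acids + X).
    Duplicate ids and illegal characters are hard errors.
    """
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} of record {current_id!r}"
                )
        records.append((current_id, seq))

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise FormatError("FASTA record with empty id")
                if current_id in seen:
                    raise FormatError(f"duplicate FASTA id {current_id!r}")
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip().upper())
        flush()
    return records


def write_fasta(
    path: str | os.PathLike, records: Iterable[tuple[str, str]], width: int = 60
) -> None:
    """Write FASTA wrapped at ``width`` columns; LF line endings."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# scaffold / CDS / sample tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty table")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}; header was {header}")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def read_scaffold_table(path: str | os.PathLike) -> list[Scaffold]:
    """Read the scaffold TSV (scaffold_id, length, taxonomy)."""
    header, rows = _read_tsv(path, ["scaffold_id", "length", "taxonomy"])
    idx = {c: header.index(c) for c in header}
    out: list[Scaffold] = []
    seen: set[str] = set()
    for row in rows:
        sid = row[idx["scaffold_id"]]
        if sid in seen:
            raise FormatError(f"duplicate scaffold_id {sid!r}")
        seen.add(sid)
        try:
            length = int(row[idx["length"]])
        except ValueError:
            raise FormatError(f"scaffold {sid!r}: non-integer length {row[idx['length']]!r}")
        taxonomy = tuple(row[idx["taxonomy"]].split(";")) if row[idx["taxonomy"]] else ()
        out.append(Scaffold(sid, length, taxonomy))
    return out


def write_scaffold_table(path: str | os.PathLike, scaffolds: Iterable[Scaffold]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("scaffold_id\tlength\ttaxonomy\n")
        for s in scaffolds:
            fh.write(f"{s.scaffold_id}\t{s.length_bp}\t{s.taxonomy_str}\n")


def read_cds_table(path: str | os.PathLike) -> list[CdsRecord]:
    """Read the CDS TSV (cds_id, scaffold_id, start, end, strand, product, family, taxon)."""
    header, rows = _read_tsv(
        path, ["cds_id", "scaffold_id", "start", "end", "strand"]
    )
    idx = {c: header.index(c) for c in header}
    out: list[CdsRecord] = []
    seen: set[str] = set()
    for row in rows:
        cid = row[idx["cds_id"]]
        if cid in seen:
            raise FormatError(f"duplicate cds_id {cid!r}")
        seen.add(cid)

        def col(name: str) -> str | None:
            if name not in idx or idx[name] >= len(row):
                return None
            return row[idx[name]] or None

        out.append(
            CdsRecord(
                cds_id=cid,
                scaffold_id=row[idx["scaffold_id"]],
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                strand=row[idx["strand"]],
                product=col("product") or "",
                family=col("family"),
                taxon=col("taxon"),
            )
        )
    return out


def write_cds_table(path: str | os.PathLike, cdss: Iterable[CdsRecord]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cds_id\tscaffold_id\tstart\tend\tstrand\tproduct\tfamily\ttaxon\n")
        for c in cdss:
            fh.write(
                f"{c.cds_id}\t{c.scaffold_id}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{c.product}\t{c.family or ''}\t{c.taxon or ''}\n"
            )


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    header, rows = _read_tsv(
        path, ["sample_id", "replicate", "condition_initial", "week", "post_switch"]
    )
    idx = {c: header.index(c) for c in header}
    out = []
    seen: set[str] = set()
    for row in rows:
        sid = row[idx["sample_id"]]
        if sid in seen:
            raise FormatError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        out.append(
            SampleMeta(
                sample_id=sid,
                replicate=row[idx["replicate"]],
                condition_initial=row[idx["condition_initial"]],
                week=int(row[idx["week"]]),
                post_switch=row[idx["post_switch"]].lower() in ("true", "1"),
            )
        )
    return out


def write_sample_meta(path: str | os.PathLike, metas: Iterable[SampleMeta]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\treplicate\tcondition_initial\tweek\tpost_switch\n")
        for m in metas:
            fh.write(
                f"{m.sample_id}\t{m.replicate}\t{m.condition_initial}\t{m.week}\t"
                f"{str(m.post_switch).lower()}\n"
            )


# ---------------------------------------------------------------------------
# counts: TSV and SAM ingestion
# ---------------------------------------------------------------------------


def write_counts(path: str | os.PathLike, count_set: CountSet) -> None:
    """Write a per-unit count table; sample metadata rides in a comment line."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            f"# sample_id={count_set.sample_id} unit={count_set.unit} "
            f"read_length={count_set.read_length_bp}\n"
        )
        fh.write("unit_id\treads\taligned_bases\n")
        for uid in sorted(count_set.counts):
            c = count_set.counts[uid]
            fh.write(f"{uid}\t{c.reads}\t{c.aligned_bases}\n")


def _read_counts_tsv(
    path: str | os.PathLike,
    unit: str,
    sample_id: str | None,
    read_length: int | None,
) -> CountSet:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:
            body.append(ln)
    if not body:
        raise FormatError(f"{path}: empty counts table")
    header = body[0].split("\t")
    for col in ("unit_id", "reads", "aligned_bases"):
        if col not in header:
            raise FormatError(f"{path}: counts table missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    counts: dict[str, UnitCount] = {}
    for ln in body[1:]:
        row = ln.split("\t")
        uid = row[idx["unit_id"]]
        if uid in counts:
            raise FormatError(f"{path}: duplicate unit_id {uid!r}")
        counts[uid] = UnitCount(int(row[idx["reads"]]), int(row[idx["aligned_bases"]]))
    rl = read_length or (int(meta["read_length"]) if "read_length" in meta else None)
    if rl is None:
        # infer from any nonzero row: simulated alignments have bases = reads * rl
        rl = next(
            (round(c.aligned_bases / c.reads) for c in counts.values() if c.reads > 0), 150
        )
    sid = sample_id or meta.get("sample_id") or Path(path).stem
    return CountSet(sample_id=sid, unit=meta.get("unit", unit), counts=counts, read_length_bp=rl)


class _CdsLocator:
    """Locate the CDS containing a 1-based position, per scaffold."""

    def __init__(self, cds_table: Sequence[CdsRecord]):
        by_scaffold: dict[str, list[CdsRecord]] = collections.defaultdict(list)
        for c in cds_table:
            by_scaffold[c.scaffold_id].append(c)
        self._starts: dict[str, list[int]] = {}
        self._cds: dict[str, list[CdsRecord]] = {}
        for sid, lst in by_scaffold.items():
            lst.sort(key=lambda c: (c.start, c.cds_id))
            self._starts[sid] = [c.start for c in lst]
            self._cds[sid] = lst

    def locate(self, scaffold_id: str, pos: int) -> CdsRecord | None:
        starts = self._starts.get(scaffold_id)
        if not starts:
            return None
        i = bisect_right(starts, pos) - 1
        while i >= 0:
            c = self._cds[scaffold_id][i]
            if c.start <= pos <= c.end:
                return c
            i -= 1  # earlier CDS could still span pos if CDSs overlap
        return None


def _read_sam(
    path: str | os.PathLike,
    unit: str,
    cds_table: Sequence[CdsRecord] | None,
    scaffolds: Sequence[Scaffold] | None,
    sample_id: str | None,
) -> CountSet:
    if unit == "cds" and cds_table is None:
        raise FormatError("unit='cds' requires a cds_table")
    locator = _CdsLocator(cds_table) if unit == "cds" else None
    known_scaffolds = {s.scaffold_id for s in scaffolds} if scaffolds is not None else None
    counts: dict[str, UnitCount] = {}
    lengths: collections.Counter[int] = collections.Counter()
    MATCH_OPS = {0, 7, 8}  # CIGAR M, =, X: reference match columns
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rname = rec.reference_name
            if known_scaffolds is not None and rname not in known_scaffolds:
                raise FormatError(f"alignment to unknown scaffold {rname!r}")
            if rec.cigartuples is None:
                raise FormatError(f"mapped record {rec.query_name!r} lacks a CIGAR")
            aligned = sum(n for op, n in rec.cigartuples if op in MATCH_OPS)
            qlen = rec.query_length or rec.infer_query_length() or aligned
            lengths[qlen] += 1
            if unit == "scaffold":
                uid = rname
            else:
                cds = locator.locate(rname, rec.reference_start + 1)  # leftmost aligned base
                if cds is None:
                    continue  # intergenic read: attributed to no CDS
                uid = cds.cds_id
            prev = counts.get(uid, UnitCount(0, 0))
            counts[uid] = UnitCount(prev.reads + 1, prev.aligned_bases + aligned)
    if lengths:
        read_length = lengths.most_common(1)[0][0]
    else:
        read_length = 150
    return CountSet(
        sample_id=sample_id or Path(path).stem,
        unit=unit,
        counts=counts,
        read_length_bp=read_length,
    )


def read_alignment(
    path: str | os.PathLike,
    format: str,
    unit: str = "scaffold",
    cds_table: Sequence[CdsRecord] | None = None,
    scaffolds: Sequence[Scaffold] | None = None,
    sample_id: str | None = None,
    read_length: int | None = None,
) -> CountSet:
    """Ingest an external aligner's output into a :class:`CountSet`.

    ``format`` is ``"sam"`` or ``"counts_tsv"``.  SAM mode excludes unmapped,
    secondary and supplementary records, counts aligned bases as the sum of
    CIGAR M/=/X lengths, and (for ``unit='cds'``) attributes each record to
    the CDS containing its leftmost aligned base, strand-blind.
    """
    if unit not in ("scaffold", "cds"):
        raise FormatError(f"unit must be 'scaffold' or 'cds', got {unit!r}")
    if format == "counts_tsv":
        cs = _read_counts_tsv(path, unit, sample_id, read_length)
        if scaffolds is not None and cs.unit == "scaffold":
            known = {s.scaffold_id for s in scaffolds}
            unknown = sorted(set(cs.counts) - known)
            if unknown:
                raise FormatError(f"counts reference unknown scaffolds: {unknown}")
        if cds_table is not None and cs.unit == "cds":
            known = {c.cds_id for c in cds_table}
            unknown = sorted(set(cs.counts) - known)
            if unknown:
                raise FormatError(f"counts reference unknown CDS ids: {unknown}")
        return cs
    if format == "sam":
        return _read_sam(path, unit, cds_table, scaffolds, sample_id)
    raise FormatError(f"unknown alignment format {format!r}")
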