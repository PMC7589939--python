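import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanocosm import formats_io as fio


def write(path, text):
    path.write_text(textwrap.dedent(text), newline="\n")


class TestFasta:
    def test_wrapped_records_concatenate(self, tmp_path):
        p = tmp_path / "a.fna"
        write(p, ">" + "s1\n" + "ACGT\nACGT\n>s2\nNNNN\n")
        recs = fio.read_fasta(p)
        assert recs == [("s1", "ACGTACGT"), ("s2", "NNNN")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fna"
        p.write_text("")
        assert fio.read_fasta(p) == []

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fna"
        write(p, ">x\nAC\n>x\nGT\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_fasta(p)

    def test_illegal_character_names_record_and_position(self, tmp_path):
        p = tmp_path / "bad.fna"
        write(p, ">ok\nACGT\n>bad\nACZT\n")
        with pytest.raises(fio.FormatError, match=r"'Z'.*position 3.*'bad'"):
            fio.read_fasta(p)

    def test_round_trip_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.fna", tmp_path / "b.fna"
        write(p1, ">s1\n" + "ACGTN" * 30 + "\n>s2\nAC\n")
        fio.write_fasta(p2, fio.read_fasta(p1), width=60)
        fio.write_fasta(p1, fio.read_fasta(p2), width=60)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 10**6),
                st.text(alphabet="ACGTN", min_size=1, max_size=200),
            ),
            min_size=0,
            max_size=6,
            unique_by=lambda t: t[0],
        )
    )
    def test_round_trip_property(self, tmp_path_factory, records):
        recs = [(f"id{n}", seq) for n, seq in records]
        p = tmp_path_factory.mktemp("fasta") / "r.fna"
        fio.write_fasta(p, recs)
        assert fio.read_fasta(p) == recs


class TestScaffoldTable:
    def test_missing_rank_kept_empty(self, tmp_path):
        p = tmp_path / "s.tsv"
        write(
            p,
            "scaffold_id\tlength\ttaxonomy\n"
            "s1\t1000\tBacteria;Proteobacteria;;Methylococcales;Methylococcaceae;Methylobacter\n",
        )
        (s,) = fio.read_scaffold_table(p)
        assert s.taxon_at("class") == fio.UNCLASSIFIED
        assert s.taxon_at("family") == "Methylococcaceae"

    def test_zero_length_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        write(p, "scaffold_id\tlength\ttaxonomy\ns1\t0\tBacteria\n")
        with pytest.raises(fio.FormatError, match="length"):
            fio.read_scaffold_table(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        write(p, "scaffold_id\tlength\ttaxonomy\ns1\t10\t\ns1\t20\t\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_scaffold_table(p)

    def test_order_preserved_and_round_trip(self, tmp_path):
        scaffolds = [
            fio.Scaffold("s3", 10, ("Bacteria",)),
            fio.Scaffold("s1", 20, ("Bacteria", "Bacteroidetes")),
            fio.Scaffold("s2", 30, ()),
        ]
        p = tmp_path / "s.tsv"
        fio.write_scaffold_table(p, scaffolds)
        assert fio.read_scaffold_table(p) == scaffolds


class TestCdsTable:
    def test_round_trip(self, tmp_path):
        cdss = [
            fio.CdsRecord("c1", "s1", 10, 309, "+", "methanol dehydrogenase", "xoxF", "T1"),
            fio.CdsRecord("c2", "s1", 400, 702, "-", "", None, None),
        ]
        p = tmp_path / "c.tsv"
        fio.write_cds_table(p, cdss)
        back = fio.read_cds_table(p)
        assert back == cdss
        assert back[0].length_bp == 300

    def test_start_after_end_rejected(self):
        with pytest.raises(fio.FormatError, match="start"):
            fio.CdsRecord("c", "s", 10, 5, "+")


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:s1\tLN:2000\n@SQ\tSN:s2\tLN:1000\n"


def sam_line(name, flag, rname, pos, cigar, seq_len=100):
    seq = "A" * seq_len if rname != "*" else "*"
    return f"{name}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"


class TestReadAlignment:
    def scaffolds(self):
        return [fio.Scaffold("s1", 2000, ("Bacteria",)), fio.Scaffold("s2", 1000, ())]

    def test_simple_match_and_unmapped_excluded(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(
            SAM_HEADER
            + sam_line("r1", 0, "s1", 1, "100M")
            + sam_line("r2", 4, "*", 0, "*")
        )
        cs = fio.read_alignment(p, "sam", unit="scaffold", scaffolds=self.scaffolds())
        assert cs.counts == {"s1": fio.UnitCount(1, 100)}
        assert cs.read_length_bp == 100

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(
            SAM_HEADER
            + sam_line("r1", 0, "s1", 1, "100M")
            + sam_line("r1", 256, "s2", 1, "100M")
            + sam_line("r1", 2048, "s2", 50, "40M", seq_len=40)
        )
        cs = fio.read_alignment(p, "sam", unit="scaffold")
        assert cs.counts == {"s1": fio.UnitCount(1, 100)}

    def test_insertion_consumes_query_not_reference_columns(self, tmp_path):
        # 50M2I48M: only the 98 M columns are reference matches
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_line("r1", 0, "s1", 5, "50M2I48M", seq_len=100))
        cs = fio.read_alignment(p, "sam", unit="scaffold")
        assert cs.counts["s1"] == fio.UnitCount(1, 98)

    def test_cds_attribution_by_leftmost_base(self, tmp_path):
        cdss = [
            fio.CdsRecord("c1", "s1", 101, 400, "+"),
            fio.CdsRecord("c2", "s1", 401, 700, "+"),
        ]
        p = tmp_path / "a.sam"
        p.write_text(
            SAM_HEADER
            + sam_line("r1", 0, "s1", 150, "100M")  # inside c1
            + sam_line("r2", 0, "s1", 390, "100M")  # spans c1/c2 boundary -> c1
            + sam_line("r3", 0, "s1", 10, "50M", seq_len=50)  # intergenic -> dropped
        )
        cs = fio.read_alignment(p, "sam", unit="cds", cds_table=cdss)
        assert cs.counts == {"c1": fio.UnitCount(2, 200)}

    def test_cds_mode_requires_table(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_line("r1", 0, "s1", 1, "100M"))
        with pytest.raises(fio.FormatError, match="cds_table"):
            fio.read_alignment(p, "sam", unit="cds")

    def test_unknown_scaffold_listed(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_line("r1", 0, "s2", 1, "100M"))
        with pytest.raises(fio.FormatError, match="s2"):
            fio.read_alignment(
                p, "sam", unit="scaffold", scaffolds=[fio.Scaffold("s1", 2000, ())]
            )

    def test_sam_and_counts_tsv_agree(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("r1", 0, "s1", 1, "100M")
            + sam_line("r2", 0, "s1", 300, "100M")
            + sam_line("r3", 0, "s2", 1, "100M")
        )
        from_sam = fio.read_alignment(sam, "sam", unit="scaffold", sample_id="x")
        tsv = tmp_path / "a.tsv"
        fio.write_counts(tsv, from_sam)
        from_tsv = fio.read_alignment(tsv, "counts_tsv", unit="scaffold")
        assert from_tsv == from_sam

    def test_counts_round_trip(self, tmp_path):
        cs = fio.CountSet(
            "LO4_R1",
            "scaffold",
            {"s1": fio.UnitCount(5, 500), "s2": fio.UnitCount(0, 0)},
            read_length_bp=100,
        )
        p = tmp_path / "c.tsv"
        fio.write_counts(p, cs)
        assert fio.read_alignment(p, "counts_tsv", unit="scaffold") == cs


class TestSampleMeta:
    def test_post_switch_consistency_enforced(self):
        with pytest.raises(fio.FormatError, match="post_switch"):
            fio.SampleMeta("x", "R1", "LO", 12, False)

    def test_condition_current_flips_after_switch(self):
        pre = fio.SampleMeta("a", "R1", "LO", 9, False)
        post = fio.SampleMeta("b", "R1", "LO", 12, True)
        assert pre.condition_current == "LO"
        assert post.condition_current == "HO"

    def test_round_trip(self, tmp_path):
        metas = [
            fio.SampleMeta("LO4_R1", "R1", "LO", 4, False),
            fio.SampleMeta("HO14_R3", "R3", "HO", 14, True),
        ]
        p = tmp_path / "m.tsv"
        fio.write_sample_meta(p, metas)
        assert fio.read_sample_meta(p) == metas
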