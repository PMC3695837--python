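import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envpath.core_formats import (
    STAGES,
    ParametersFile,
    read_fasta,
    read_gff_orf_features,
    read_parameters,
    read_tabular_hits,
    write_fasta,
    write_gff_orf_features,
    write_tabular_hits,
    SequenceRecord,
)
from envpath.errors import ConfigError, FormatError
from envpath.orfcall import OrfCall


class TestReadFasta:
    def test_case_normalization(self):
        records = read_fasta(io.StringIO(">a\nacgt"))
        assert len(records) == 1
        assert records[0].seq_id == "a"
        assert records[0].residues == "ACGT"

    def test_empty_stream(self):
        assert read_fasta(io.StringIO("")) == []

    def test_multiline_and_multiple_records(self):
        records = read_fasta(io.StringIO(">a\nAC\nGT\n>b\nTT"))
        assert [len(r) for r in records] == [4, 2]

    def test_header_token_before_whitespace(self):
        records = read_fasta(io.StringIO(">seq1 description here\nAA"))
        assert records[0].seq_id == "seq1"

    def test_first_nonblank_line_must_be_header(self):
        with pytest.raises(FormatError, match="line 2"):
            read_fasta(io.StringIO("\nACGT\n>a\nAC"))

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=1, max_size=50),
            min_size=0,
            max_size=5,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_write_read_round_trip(self, seqs):
        records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        buf = io.StringIO()
        write_fasta(records, buf, width=7)
        out = read_fasta(io.StringIO(buf.getvalue()))
        assert [(r.seq_id, r.residues) for r in out] == [
            (r.seq_id, r.residues) for r in records
        ]


class TestReadTabularHits:
    LINE = "o1\tsp|P1\t98.0\t100\t2\t0\t1\t100\t1\t100\t1e-50\t200.1"

    def test_basic_parse(self):
        hits = read_tabular_hits(io.StringIO(self.LINE), "kegg")
        assert len(hits) == 1
        h = hits[0]
        assert h.evalue == 1e-50
        assert h.bit_score == 200.1
        assert h.source_db == "kegg"
        assert h.subject_description == "sp|P1"  # falls back to subject id

    def test_comment_only(self):
        assert read_tabular_hits(io.StringIO("# comment\n")) == []

    def test_eleven_columns_names_line(self):
        bad = "\t".join(self.LINE.split("\t")[:11])
        with pytest.raises(FormatError, match="line 1"):
            read_tabular_hits(io.StringIO(bad))

    def test_bad_evalue(self):
        cols = self.LINE.split("\t")
        cols[10] = "not-a-number"
        with pytest.raises(FormatError, match="line 1"):
            read_tabular_hits(io.StringIO("\t".join(cols)))

    def test_description_column_retained(self):
        hits = read_tabular_hits(io.StringIO(self.LINE + "\tmalate dehydrogenase"))
        assert hits[0].subject_description == "malate dehydrogenase"

    def test_order_preserved_and_write_round_trip(self):
        text = self.LINE + "\n" + self.LINE.replace("o1", "o2")
        hits = read_tabular_hits(io.StringIO(text))
        assert [h.query_id for h in hits] == ["o1", "o2"]
        buf = io.StringIO()
        write_tabular_hits(hits, buf)
        again = read_tabular_hits(io.StringIO(buf.getvalue()))
        assert again == hits


GFF_ROW = "c1\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={id}"


class TestReadGff:
    def test_coordinate_convention(self):
        row = GFF_ROW.format(start=1, end=9, strand="+", id="o1")
        calls = read_gff_orf_features(io.StringIO(row))
        assert (calls[0].start, calls[0].end, calls[0].strand) == (0, 9, "+")

    def test_missing_strand_rejected(self):
        row = "c1\tsrc\tCDS\t1\t9\t.\t.\t0\tID=o1"
        with pytest.raises(FormatError):
            read_gff_orf_features(io.StringIO(row))

    def test_end_before_start_rejected(self):
        row = GFF_ROW.format(start=9, end=1, strand="+", id="o1")
        with pytest.raises(FormatError):
            read_gff_orf_features(io.StringIO(row))

    def test_missing_id_rejected(self):
        row = "c1\tsrc\tCDS\t1\t9\t.\t+\t0\tName=x"
        with pytest.raises(FormatError):
            read_gff_orf_features(io.StringIO(row))

    def test_two_rows_preserve_order(self):
        text = (
            GFF_ROW.format(start=1, end=9, strand="+", id="o1")
            + "\n"
            + GFF_ROW.format(start=20, end=40, strand="-", id="o2")
        )
        calls = read_gff_orf_features(io.StringIO(text))
        assert [c.orf_id for c in calls] == ["o1", "o2"]

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("start,end", [(0, 9), (5, 305), (2, 8)])
    def test_round_trip_identity(self, strand, start, end):
        orf = OrfCall("o1", "c1", start, end, strand, partial_5=True)
        buf = io.StringIO()
        write_gff_orf_features([orf], buf)
        back = read_gff_orf_features(io.StringIO(buf.getvalue()))[0]
        assert (back.start, back.end, back.strand) == (start, end, strand)
        assert back.partial_5 and not back.partial_3


class TestReadParameters:
    def test_stage_flag(self):
        params = read_parameters(io.StringIO("annotation skip\n"))
        assert params.stages["annotation"] == "skip"

    def test_empty_file_all_defaults(self):
        params = read_parameters(io.StringIO(""))
        assert all(params.stages[s] == "yes" for s in STAGES)
        assert params.min_orf_aa == 60
        assert params.min_bsr == 0.4

    def test_bad_flag(self):
        with pytest.raises(ConfigError, match="qc"):
            read_parameters(io.StringIO("qc maybe\n"))

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="no_such_key"):
            read_parameters(io.StringIO("no_such_key 3\n"))

    def test_colon_separator_and_case(self):
        params = read_parameters(io.StringIO("Min_BSR: 0.5\nqc: grid\n"))
        assert params.min_bsr == 0.5
        assert params.stages["qc"] == "grid"

    def test_duplicate_stage_rejected(self):
        with pytest.raises(ConfigError, match="qc"):
            read_parameters(io.StringIO("qc yes\nqc skip\n"))

    def test_db_list(self):
        params = read_parameters(io.StringIO("dbs kegg, cog ,refseq\n"))
        assert params.dbs == ("kegg", "cog", "refseq")


def test_hit_parser_total_on_simulator_tables(community, tmp_path):
    """The hit parser accepts everything the fixture emulator emits."""
    from envpath.simulate import ShotgunSimConfig, simulate_shotgun

    _reads, truth = simulate_shotgun(
        community.genomes, ShotgunSimConfig(coverage_fraction=0.1, seed=5)
    )
    hits, _scores = community.emulate_hits(truth, noise=0.3, seed=5)
    path = tmp_path / "hits.tsv"
    write_tabular_hits(hits, path)
    parsed = read_tabular_hits(path, "refdb")
    assert len(parsed) == len(hits)
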