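import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envpath.annotate import (
    Annotation,
    HitFilterThresholds,
    ParsedHitRow,
    RrnaThresholds,
    bsr,
    classify_rrna,
    extract_ec_numbers,
    filter_hits,
    information_score,
    read_refscores,
    select_annotation,
    self_bit_score,
    summarize_hierarchy,
    write_refscores,
)
from envpath.core_formats import HomologyHit
from envpath.errors import AnnotationError, EnvPathError


def make_hit(query="o1", subject="s1", evalue=1e-20, bits=100.0, aln=100,
             desc="", db="kegg", identity=90.0):
    return HomologyHit(
        query_id=query, subject_id=subject, pct_identity=identity,
        aln_length=aln, mismatches=0, gap_opens=0, q_start=1, q_end=aln,
        s_start=1, s_end=aln, evalue=evalue, bit_score=bits,
        subject_description=desc or subject, source_db=db,
    )


class TestSelfBitScore:
    def test_hand_computed_acde(self):
        # BLOSUM62 diagonal: A=4, C=9, D=6, E=5 -> raw 24
        expected = (0.267 * 24 - math.log(0.041)) / math.log(2)
        assert self_bit_score("ACDE") == pytest.approx(expected)
        assert self_bit_score("ACDE") == pytest.approx(13.85, abs=0.01)

    def test_bits_affine_in_raw_score(self):
        single = self_bit_score("ACDE")
        double = self_bit_score("ACDEACDE")
        # doubling the sequence doubles the raw score; bits are affine
        offset = -math.log(0.041) / math.log(2)
        assert double - offset == pytest.approx(2 * (single - offset))

    def test_x_contributes_minus_one(self):
        raw = 4 - 1  # A then X
        expected = (0.267 * raw - math.log(0.041)) / math.log(2)
        assert self_bit_score("AX") == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(EnvPathError):
            self_bit_score("")

    def test_refscores_file_round_trip(self, tmp_path):
        path = tmp_path / "x.refscores"
        write_refscores({"o1": 123.45, "o2": 67.0}, path)
        scores = read_refscores(path)
        assert scores == {"o1": 123.45, "o2": 67.0}


class TestBsr:
    def test_self_hit_is_one(self):
        assert bsr(500.0, 500.0) == 1.0

    def test_cutoff_arithmetic(self):
        assert bsr(200.0, 500.0) == pytest.approx(0.4)
        assert bsr(199.0, 500.0) == pytest.approx(0.398)

    def test_nonpositive_self_errors(self):
        with pytest.raises(EnvPathError):
            bsr(10.0, 0.0)


class TestFilterHits:
    SELF = {"o1": 500.0}

    def test_bsr_boundary_inclusive(self):
        kept = filter_hits([make_hit(bits=200.0)], self.SELF)  # bsr 0.40
        assert len(kept) == 1 and kept[0].bsr == pytest.approx(0.4)
        excluded = filter_hits([make_hit(bits=195.0)], self.SELF)  # bsr 0.39
        assert excluded == []

    def test_evalue_threshold(self):
        hits = [make_hit(evalue=1e-3, bits=400.0)]
        assert filter_hits(hits, self.SELF, HitFilterThresholds(max_evalue=1e-5)) == []

    def test_empty_input(self):
        assert filter_hits([], {}) == []

    def test_missing_self_score_names_query(self):
        with pytest.raises(AnnotationError, match="orphan"):
            filter_hits([make_hit(query="orphan")], self.SELF)

    def test_sorted_within_query(self):
        hits = [
            make_hit(evalue=1e-10, bits=300.0, subject="b"),
            make_hit(evalue=1e-20, bits=400.0, subject="a"),
            make_hit(evalue=1e-10, bits=350.0, subject="c"),
        ]
        rows = filter_hits(hits, self.SELF)
        assert [r.subject_id for r in rows] == ["a", "c", "b"]

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0, max_value=1e-3),
                st.floats(min_value=1, max_value=600),
            ),
            max_size=30,
        ),
        st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_subset_and_monotone_in_min_bsr(self, pairs, min_bsr):
        hits = [make_hit(subject=f"s{i}", evalue=e, bits=b) for i, (e, b) in enumerate(pairs)]
        loose = filter_hits(hits, self.SELF, HitFilterThresholds(min_bsr=min_bsr))
        tight = filter_hits(hits, self.SELF, HitFilterThresholds(min_bsr=min_bsr + 0.05))
        loose_ids = {r.subject_id for r in loose}
        assert {r.subject_id for r in tight} <= loose_ids
        assert loose_ids <= {h.subject_id for h in hits}


class TestInformationScore:
    def test_hypothetical_protein_is_zero(self):
        assert information_score("hypothetical protein") == 0

    def test_ec_bonus(self):
        assert information_score("methanol dehydrogenase (EC 1.1.99.8)") == 12

    def test_distinctness(self):
        assert information_score("dehydrogenase dehydrogenase") == 1

    def test_empty(self):
        assert information_score("") == 0

    def test_single_ec_bonus_even_with_multiple_ecs(self):
        one = information_score("kinase (EC 2.7.1.1)")
        two = information_score("kinase (EC 2.7.1.1) (EC 2.7.1.2)")
        assert one == 11 and two == 11

    def test_short_tokens_dropped(self):
        assert information_score("na k atpase") == 1  # only 'atpase' counts

    def test_partial_ec_with_dashes(self):
        assert extract_ec_numbers("thing (EC 2.7.-.-)") == {"2.7.-.-"}

    @given(st.lists(st.sampled_from(["malate", "kinase", "synthase", "protein", "of"]), max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_order_and_repetition_invariant(self, words):
        base = information_score(" ".join(words))
        assert information_score(" ".join(reversed(words))) == base
        assert information_score(" ".join(words + words)) == base


def make_row(query="o1", subject="s", evalue=1e-20, bits=100.0, desc="", db="kegg"):
    hit = make_hit(query=query, subject=subject, evalue=evalue, bits=bits, desc=desc, db=db)
    return ParsedHitRow(**vars(hit), bsr=0.8)


class TestSelectAnnotation:
    def test_highest_score_wins(self):
        hits = {
            "kegg": [make_row(desc="methanol dehydrogenase (EC 1.1.99.8)", db="kegg")],
            "refseq": [make_row(desc="oxidoreductase malate citrate", db="refseq")],
        }
        ann = select_annotation("o1", hits, ("kegg", "refseq"))
        assert ann.source_db == "kegg"
        assert ann.info_score == 12
        assert ann.ec_numbers == {"1.1.99.8"}

    def test_no_hits_hypothetical(self):
        ann = select_annotation("o1", {}, ())
        assert ann.product == "hypothetical protein"
        assert ann.info_score == 0 and ann.best_hit is None

    def test_tie_breaks_by_priority(self):
        hits = {
            "refseq": [make_row(desc="malate kinase", db="refseq")],
            "kegg": [make_row(desc="citrate synthase", db="kegg")],
            "cog": [make_row(desc="glycerol oxidase", db="cog")],
        }
        ann = select_annotation("o1", hits, ("kegg", "cog", "refseq"))
        assert ann.source_db == "kegg"

    def test_per_db_candidate_is_lowest_evalue(self):
        hits = {
            "kegg": [
                make_row(desc="weak annotation word", evalue=1e-5),
                make_row(desc="malate dehydrogenase kinase synthase", evalue=1e-50),
            ]
        }
        ann = select_annotation("o1", hits, ("kegg",))
        assert "malate" in ann.product

    def test_deterministic(self):
        hits = {
            "a": [make_row(desc="malate kinase", db="a")],
            "b": [make_row(desc="citrate synthase", db="b")],
        }
        first = select_annotation("o1", hits, ("b", "a"))
        for _ in range(5):
            assert select_annotation("o1", hits, ("b", "a")) == first


class TestSummarizeHierarchy:
    TABLE = {
        "s1": ("Metabolism", "Carbohydrate"),
        "s2": ("Metabolism", "Energy"),
        "s3": ("Genetic Information", "Translation"),
    }

    def _ann(self, subject, db="kegg"):
        row = make_row(subject=subject, db=db)
        return Annotation("o_" + subject, "p", frozenset(), db, 1, row)

    def test_level_counts(self):
        anns = [self._ann("s1"), self._ann("s2"), self._ann("s3")]
        levels = summarize_hierarchy(anns, self.TABLE, "kegg")
        assert levels[1] == {"Metabolism": 2, "Genetic Information": 1}
        assert levels[2]["Carbohydrate"] == 1

    def test_empty(self):
        assert summarize_hierarchy([], self.TABLE, "kegg") == {}

    def test_unmapped_subject_unknown(self):
        levels = summarize_hierarchy([self._ann("nope")], self.TABLE, "kegg")
        assert levels[1] == {"Unknown": 1}


class TestClassifyRrna:
    def test_passing_hit(self):
        hits = [make_hit(identity=99.0, bits=200.0, evalue=1e-30, desc="Escherichia coli")]
        rows = classify_rrna(hits)
        assert len(rows) == 1 and rows[0].taxon == "Escherichia coli"

    def test_below_identity_dropped(self):
        hits = [make_hit(identity=50.0, bits=200.0, evalue=1e-30)]
        assert classify_rrna(hits, RrnaThresholds(min_identity=90)) == []

    def test_best_bits_retained_per_query(self):
        hits = [
            make_hit(identity=95.0, bits=100.0, desc="worse"),
            make_hit(identity=95.0, bits=300.0, desc="better"),
        ]
        rows = classify_rrna(hits)
        assert len(rows) == 1 and rows[0].taxon == "better"
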