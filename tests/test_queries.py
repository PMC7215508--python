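"""Linked-query parsing and distance-constrained chain/tandem search."""

import pytest

from cassarray.queries import (
    CASSANDRA_QUERY,
    CASSANDRA_TANDEM_QUERY,
    GapRange,
    LinkedQuery,
    QueryParseError,
    TandemQuery,
    format_query,
    parse_query,
    search_linked,
    search_tandem,
)
from cassarray.sequences import revcomp

from _oracles import naive_collapsed_chains
from conftest import cassandra_construct, random_seq

PATTERNS = ["RGTTAAGYRHGY", "RRRATRGGTRACY", "TGGTATCAGAGC"]
GAPS = [(15, 25), (5, 200)]


class TestParse:
    def test_consensus_query_with_header_and_en_dashes(self):
        q = parse_query(
            ">Cassandra RGTTAAGYRHGY[15–25]RRRATRGGTRACY[5–200]TGGTATCAGAGC"
        )
        assert isinstance(q, LinkedQuery)
        assert q.name == "Cassandra"
        assert [m.pattern for m in q.motifs] == PATTERNS
        assert [(g.min_gap, g.max_gap) for g in q.gaps] == GAPS

    def test_round_bracket_dialect(self):
        q = parse_query("RGTTAAGYRHGY(15-25)RRRATRGGTRACY")
        assert [(g.min_gap, g.max_gap) for g in q.gaps] == [(15, 25)]

    def test_inverted_range_is_an_error(self):
        with pytest.raises(QueryParseError):
            parse_query("ACGT[25-15]ACGT")

    def test_unknown_character_reports_position(self):
        with pytest.raises(QueryParseError, match="position"):
            parse_query("ACGT[1-5]AXGT")

    def test_empty_motif_is_an_error(self):
        with pytest.raises(QueryParseError):
            parse_query("[5-10]ACGT")

    def test_tandem_canonical_form(self):
        q = parse_query(CASSANDRA_TANDEM_QUERY)
        assert isinstance(q, TandemQuery)
        assert (q.unit_gap.min_gap, q.unit_gap.max_gap) == (200, 1000)
        assert q.min_repeats == 2
        assert [m.pattern for m in q.unit.motifs] == PATTERNS

    def test_tandem_doubled_unit_form_folds(self):
        text = (
            "RGTTAAGYRHGY[15–25]RRRATRGGTRACY(5–200)TGGTATCAGAGC"
            "[200–1000]"
            "RGTTAAGYRHGY[15–25]RRRATRGGTRACY[5–200]TGGTATCAGAGC"
        )
        q = parse_query(text)
        assert isinstance(q, TandemQuery)
        assert (q.unit_gap.min_gap, q.unit_gap.max_gap) == (200, 1000)

    @pytest.mark.parametrize(
        "text",
        [
            CASSANDRA_QUERY,
            "ACGT",
            CASSANDRA_TANDEM_QUERY,
            "(ACGT[3-9]TTTT)[50-90]n",
        ],
    )
    def test_format_parse_round_trip(self, text):
        q = parse_query(text)
        assert parse_query(format_query(q)) == q

    def test_canonical_format_normalizes_dialects(self):
        q = parse_query(">Cassandra RGTTAAGYRHGY(15–25)RRRATRGGTRACY(5–200)TGGTATCAGAGC")
        assert format_query(q) == CASSANDRA_QUERY


class TestSearchLinked:
    def test_exact_construct_single_chain(self, cassandra_query):
        construct = cassandra_construct()
        assert len(construct) == 85
        hits = search_linked(construct, cassandra_query)
        assert len(hits) == 1
        h = hits[0]
        assert (h.span_start, h.span_end, h.strand, h.total_mismatches) == (0, 85, "+", 0)
        assert h.span_start == h.motif_sites[0].start
        assert h.span_end == h.motif_sites[-1].end

    def test_out_of_range_gap_rejected(self, cassandra_query):
        construct = cassandra_construct(gap_ab=30)  # 30 not in [15, 25]
        assert search_linked(construct, cassandra_query) == []

    def test_minus_strand_chain_mapped_back(self, cassandra_query):
        construct = cassandra_construct()
        pad = random_seq(5, 200)
        seq = pad + revcomp(construct) + pad
        hits = search_linked(seq, cassandra_query)
        assert [(h.strand, h.span_start, h.span_end) for h in hits] == [
            ("-", 200, 285)
        ]

    def test_two_planted_constructs_match_bruteforce(self, cassandra_query):
        construct = cassandra_construct()
        filler = random_seq(42, 5000)
        seq = construct + filler + construct
        hits = search_linked(seq, cassandra_query, strand_mode="plus")
        expected = naive_collapsed_chains(seq, PATTERNS, GAPS)
        assert [(h.span_start, h.span_end, h.total_mismatches) for h in hits] == [
            (s, e, mm) for s, e, mm, _ in expected
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_bruteforce_equivalence_with_fuzzy_budget(self, seed, cassandra_query):
        # mismatch budget 1 per motif creates overlapping candidate chains,
        # exercising the collapse rule against full enumeration
        seq = random_seq(seed, 4000) + cassandra_construct() + random_seq(seed + 1, 4000)
        hits = search_linked(seq, cassandra_query, max_mismatch=1, strand_mode="plus")
        expected = naive_collapsed_chains(seq, PATTERNS, GAPS, budget=1)
        assert [(h.span_start, h.span_end, h.total_mismatches) for h in hits] == [
            (s, e, mm) for s, e, mm, _ in expected
        ]

    def test_chain_gaps_and_span_bounds(self, cassandra_query):
        # [57, 262] = sum of motif lengths + min/max gaps of the query
        assert (cassandra_query.min_span, cassandra_query.max_span) == (57, 262)
        seq = cassandra_construct(gap_ab=15, gap_cp=5) + "T" * 50 + cassandra_construct(
            gap_ab=25, gap_cp=200
        )
        for h in search_linked(seq, cassandra_query):
            assert 57 <= h.span_length <= 262
            for site_a, site_b, gap in zip(
                h.motif_sites, h.motif_sites[1:], cassandra_query.gaps
            ):
                observed = (
                    site_b.start - site_a.end
                    if h.strand == "+"
                    else site_a.start - site_b.end
                )
                assert gap.min_gap <= observed <= gap.max_gap


class TestSearchTandem:
    def _three_unit_seq(self, gap=300):
        unit = cassandra_construct()
        return ("G" * 100) + (unit + "C" * gap) * 2 + unit + ("G" * 100)

    def test_three_units_one_array(self, tandem_query):
        arrays = search_tandem(self._three_unit_seq(), tandem_query)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.n_units == 3
        assert a.inter_unit_gaps == (300, 300)

    def test_distant_units_do_not_chain(self, tandem_query):
        unit = cassandra_construct()
        seq = unit + "C" * 1500 + unit
        assert search_tandem(seq, tandem_query) == []

    def test_min_repeats_one_reduces_to_linked_search(self, cassandra_query, tandem_query):
        seq = self._three_unit_seq(gap=1500)  # no unit chains into arrays
        chains = search_linked(seq, cassandra_query)
        arrays = search_tandem(seq, tandem_query, min_repeats=1)
        assert sorted(c.span_start for c in chains) == sorted(
            a.unit_chains[0].span_start for a in arrays
        )
        assert all(a.n_units == 1 for a in arrays)

    def test_arrays_are_maximal(self, tandem_query):
        # two arrays separated by an out-of-range gap must not merge
        unit = cassandra_construct()
        block = unit + "C" * 300 + unit
        seq = block + "C" * 2000 + block
        arrays = search_tandem(seq, tandem_query)
        assert [a.n_units for a in arrays] == [2, 2]
        gap_between = arrays[1].span_start - arrays[0].span_end
        assert gap_between > tandem_query.unit_gap.max_gap

    def test_minus_strand_array(self, tandem_query):
        seq = revcomp(self._three_unit_seq())
        arrays = search_tandem(seq, tandem_query)
        assert len(arrays) == 1
        assert arrays[0].strand == "-"
        assert arrays[0].n_units == 3
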