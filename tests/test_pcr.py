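"""In silico PCR: binding sites, amplicon enumeration, ladder arithmetic."""

import warnings

import pytest

from cassarray.elements import annotate_element, decompose_array, unit_period
from cassarray.pcr import (
    Primer,
    enumerate_amplicons,
    find_binding_sites,
    predict_ladder,
    render_gel,
    render_gel_svg,
)
from cassarray.queries import parse_query, search_tandem
from cassarray.simulate import UnitSpec, make_5s_unit, make_array, make_unit

from _oracles import naive_amplicons
from conftest import random_seq


def _divergent_primers(unit, fwd_five=153, rev_five=39, length=21):
    """Divergent internal-domain primers with declared 5' offsets."""
    fwd = Primer.from_template(unit.seq, unit.spec.ltr_len + fwd_five, length, "+", "fwd")
    rev = Primer.from_template(unit.seq, unit.spec.ltr_len + rev_five, length, "-", "rev")
    return fwd, rev


class TestBindingSites:
    def test_exact_plus_strand_site(self):
        tpl = random_seq(1, 300)
        primer = Primer("p", tpl[100:121])
        sites = find_binding_sites(tpl, primer, max_mismatch=0)
        plus = [s for s in sites if s.strand == "+"]
        assert [(s.position, s.mismatches) for s in plus] == [(100, 0)]

    def test_internal_mismatch_tolerated_with_intact_anchor(self):
        tpl = random_seq(2, 300)
        word = tpl[50:71]
        mutated = word[:5] + ("A" if word[5] != "A" else "C") + word[6:]
        sites = find_binding_sites(tpl, Primer("p", mutated), max_mismatch=2)
        assert any(s.position == 50 and s.mismatches == 1 for s in sites)

    def test_three_prime_anchor_mismatch_rejected(self):
        tpl = random_seq(3, 300)
        word = tpl[50:71]
        mutated = word[:-1] + ("A" if word[-1] != "A" else "C")
        sites = find_binding_sites(tpl, Primer("p", mutated), max_mismatch=2)
        assert not any(s.position == 50 for s in sites)

    def test_minus_strand_site_five_prime_is_rightmost(self):
        tpl = random_seq(4, 300)
        primer = Primer.from_template(tpl, 120, 20, "-")
        sites = find_binding_sites(tpl, primer, max_mismatch=0)
        minus = [s for s in sites if s.strand == "-"]
        assert [(s.position, s.five_prime) for s in minus] == [(101, 120)]


class TestEnumerateAmplicons:
    def test_convergent_pair_length_includes_both_footprints(self):
        # 20 nt primers flanking a 100 nt insert: product is 140 nt
        pad = random_seq(5, 30)
        fwd_word = random_seq(6, 20)
        insert = random_seq(7, 100)
        rev_word = random_seq(8, 20)
        tpl = pad + fwd_word + insert + rev_word + pad
        fwd = Primer("f", fwd_word)
        rev = Primer("r", Primer.from_template(tpl, 30 + 20 + 100 + 19, 20, "-").sequence)
        f_sites = find_binding_sites(tpl, fwd, max_mismatch=0)
        r_sites = find_binding_sites(tpl, rev, max_mismatch=0)
        amps = enumerate_amplicons(f_sites, r_sites)
        assert [a.length for a in amps] == [140]

    def test_divergent_pair_needs_a_junction(self, avena_unit):
        fwd, rev = _divergent_primers(avena_unit)
        tpl = avena_unit.seq  # single unit: no downstream minus-strand partner
        amps = enumerate_amplicons(
            find_binding_sites(tpl, fwd), find_binding_sites(tpl, rev)
        )
        assert amps == []

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_divergent_count_is_n_choose_2(self, avena_unit, n):
        fwd, rev = _divergent_primers(avena_unit)
        tpl = make_array(avena_unit.seq, n, avena_unit.ltr)
        amps = enumerate_amplicons(
            find_binding_sites(tpl, fwd),
            find_binding_sites(tpl, rev),
            max_len=None,
        )
        assert len(amps) == n * (n - 1) // 2

    def test_matches_all_pairs_bruteforce(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        f_sites = find_binding_sites(avena_array, fwd)
        r_sites = find_binding_sites(avena_array, rev)
        amps = enumerate_amplicons(f_sites, r_sites, max_len=None)
        expected = naive_amplicons(
            [s.position for s in f_sites if s.strand == "+"],
            len(fwd),
            [s.five_prime for s in r_sites if s.strand == "-"],
            len(rev),
        )
        assert [(a.start, a.end - 1, a.length) for a in amps] == expected

    def test_junction_counting(self, avena_unit):
        fwd, rev = _divergent_primers(avena_unit)
        tpl = make_array(avena_unit.seq, 3, avena_unit.ltr)
        boundaries = [481, 962]
        amps = enumerate_amplicons(
            find_binding_sites(tpl, fwd),
            find_binding_sites(tpl, rev),
            unit_boundaries=boundaries,
        )
        assert sorted(a.junctions_spanned for a in amps) == [1, 1, 2]


class TestLadders:
    def test_avena_band_series(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        ladder = predict_ladder(avena_array, fwd, rev)
        assert ladder.lengths[:4] == (368, 849, 1330, 1811)
        assert ladder.base == 368
        assert ladder.period == 481
        assert ladder.formula_text == "368 + (481)_n"

    def test_alternative_reverse_primer_shifts_base_not_period(
        self, avena_unit, avena_array
    ):
        fwd, rev = _divergent_primers(avena_unit)
        _, rev_alt = _divergent_primers(avena_unit, rev_five=28)
        lad = predict_ladder(avena_array, fwd, rev)
        lad_alt = predict_ladder(avena_array, fwd, rev_alt)
        assert lad_alt.lengths[:4] == (357, 838, 1319, 1800)
        assert (lad.base, lad_alt.base) == (368, 357)
        assert lad.period == lad_alt.period == 481

    def test_5s_cluster_band_series(self):
        # 121 nt gene + 190 nt spacer, convergent in-gene primers
        unit_seq, truth = make_5s_unit(seed=3)
        tpl = make_array(unit_seq, 8)
        fwd = Primer.from_template(tpl, 1, 21, "+", "f")
        rev = Primer.from_template(tpl, 119, 21, "-", "r")
        ladder = predict_ladder(tpl, fwd, rev, max_len=2500)
        assert ladder.lengths == (119, 430, 741, 1052, 1363, 1674, 1985, 2296)
        assert ladder.formula_text == "119 + (311)_n"

    def test_hordeum_period_equals_unit_length(self):
        unit = make_unit(UnitSpec(ltr_len=200, internal_len=261, seed=7))
        tpl = make_array(unit.seq, 5, unit.ltr)
        fwd = Primer.from_template(tpl, 200 + 130, 21, "+", "f981")
        rev = Primer.from_template(tpl, 200 + 29, 21, "-", "r982")
        ladder = predict_ladder(tpl, fwd, rev)
        assert ladder.period == 461
        assert ladder.formula_text == "361 + (461)_n"

    def test_single_unit_convergent_has_one_rung(self):
        unit_seq, _ = make_5s_unit(seed=3)
        fwd = Primer.from_template(unit_seq, 1, 21, "+")
        rev = Primer.from_template(unit_seq, 119, 21, "-")
        ladder = predict_ladder(unit_seq, fwd, rev)
        assert ladder.lengths == (119,)
        assert ladder.period == 0

    def test_no_binding_gives_flagged_empty_ladder(self):
        ladder = predict_ladder(random_seq(9, 500), Primer("f", "ACGT" * 6), Primer("r", "TTGCA" * 5))
        assert ladder.is_empty
        assert ladder.base is None

    def test_period_matches_annotation_unit_period(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        ladder = predict_ladder(avena_array, fwd, rev)
        arrays = search_tandem(
            avena_array,
            parse_query("(RGTTAAGYRHGY[15-25]RRRATRGGTRACY[5-200]TGGTATCAGAGC)[200-1000]n"),
        )
        ta = decompose_array(
            arrays[0], [annotate_element(c) for c in arrays[0].unit_chains]
        )
        assert unit_period(ta)[0] == ladder.period


class TestGelRendering:
    def test_bands_and_lanes(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        lad = predict_ladder(avena_array, fwd, rev)
        one = render_gel([lad], ["avena"])
        assert one.count("━━━━━") == len(lad.lengths)
        two = render_gel([lad, lad], ["a", "b"])
        assert two.count("━━━━━") == 2 * len(lad.lengths)
        assert render_gel([lad], ["x"]) == render_gel([lad], ["x"])  # deterministic

    def test_out_of_range_band_clipped_with_warning(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        lad = predict_ladder(avena_array, fwd, rev)
        with pytest.warns(UserWarning, match="clipped"):
            text = render_gel([lad], ["avena"], min_len=400, max_len=2000)
        assert text.count("━━━━━") == sum(1 for x in lad.lengths if 400 <= x <= 2000)

    def test_svg_contains_a_line_per_visible_band(self, avena_unit, avena_array):
        fwd, rev = _divergent_primers(avena_unit)
        lad = predict_ladder(avena_array, fwd, rev)
        svg = render_gel_svg([lad], ["avena"])
        assert svg.startswith("<svg") and svg.endswith("</svg>")
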