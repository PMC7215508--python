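"""In silico PCR amplicon ladders on tandem templates.

Divergent (inverted) primers inside one repeat unit amplify only
across unit junctions, so an n-unit array yields the arithmetic ladder
base + period*(rung-1) with period equal to the unit length. This
example reproduces two published band series on synthetic templates:
the 481 nt Cassandra unit (rungs 368, 849, 1330, 1811, ...) and the
311 nt 5S rDNA cluster (rungs 119, 430, ..., 1985), and draws a text
virtual gel.
"""

from cassarray import (
    Primer,
    UnitSpec,
    make_5s_unit,
    make_array,
    make_unit,
    predict_ladder,
    render_gel,
)

# Cassandra, Avena geometry: 229 nt LTR + 252 nt internal domain
unit = make_unit(UnitSpec(seed=11))
template = make_array(unit.seq, 6, unit.ltr)
ltr = unit.spec.ltr_len
fwd = Primer.from_template(template, ltr + 153, 21, "+", "3802")
rev = Primer.from_template(template, ltr + 39, 21, "-", "3801")
cassandra = predict_ladder(template, fwd, rev)
print("Cassandra ladder:", cassandra.lengths)
print("formula:         ", cassandra.formula_text)

# 5S rDNA cluster: 121 nt gene + 190 nt spacer, convergent in-gene primers
unit5s, _ = make_5s_unit(seed=3)
template5s = make_array(unit5s, 8)
f5 = Primer.from_template(template5s, 1, 21, "+", "1803")
r5 = Primer.from_template(template5s, 119, 21, "-", "1804")
five_s = predict_ladder(template5s, f5, r5, max_len=2500)
print("5S ladder:       ", five_s.lengths)
print("formula:         ", five_s.formula_text)

print()
print(render_gel([cassandra, five_s], ["Cassandra", "5S rDNA"]))
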