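"""Tandem-array detection and LTR/internal-domain decomposition.

Builds a clean 13-unit Cassandra-like array (481 nt units with a
closing LTR, mirroring the longest array isolated by long-distance
PCR), finds it with the tandem query, and decomposes it into the
alternating LTR-internal pattern: 13 LTRs bounding 12 internal
domains, unit period 481 nt with zero spread.
"""

from cassarray import (
    CASSANDRA_TANDEM_QUERY,
    UnitSpec,
    annotate_element,
    decompose_array,
    make_array,
    make_unit,
    search_tandem,
    unit_period,
)

unit = make_unit(UnitSpec(seed=1))
array_seq = make_array(unit.seq, 13, unit.ltr)
print(f"template: 13 x {len(unit.seq)} nt units + {len(unit.ltr)} nt closing LTR "
      f"= {len(array_seq):,} nt")

arrays = search_tandem(array_seq, CASSANDRA_TANDEM_QUERY)
arr = arrays[0]
print(f"tandem hit: {arr.n_units} units, span {arr.span_start}-{arr.span_end}, "
      f"inter-unit chain gaps {set(arr.inter_unit_gaps)}")

ta = decompose_array(arr, [annotate_element(c) for c in arr.unit_chains])
period, spread = unit_period(ta)
print(f"decomposition: {ta.n_ltrs} LTRs alternating with {ta.n_internal} "
      f"internal domains")
print(f"unit period {period:g} nt (spread {spread:g} nt), "
      f"truncated terminal unit: {ta.truncated_last}")
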