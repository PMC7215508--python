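"""Cassandra element models on top of linked-search hits.

A chain hit from the Cassandra query (boxA, boxC, PBS in element order)
is interpreted as an element: the LTR extends from boxA (minus an
optional 5' flank) to the PBS start, and the internal domain begins at
the PBS. A tandem-array hit decomposes into the alternating
LTR / internal-domain segmentation, with unit-period statistics taken
from consecutive LTR start distances.

Intervals are (start, end) tuples, 0-based half-open, plus-strand
coordinates; minus-strand elements are mirrored accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .queries import ArrayHit, ChainHit

__all__ = [
    "AnnotationError",
    "CassandraElement",
    "TandemArray",
    "annotate_element",
    "decompose_array",
    "unit_period",
]

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """A hit cannot be interpreted as a Cassandra element structure."""


@dataclass(frozen=True)
class CassandraElement:
    """An annotated Cassandra element (or its 5' LTR + PBS part).

    ``ltr3`` is only available when the caller knows the element's other
    end (e.g. from generator truth or a following unit); a single chain
    hit delimits the 5' LTR and where the internal domain begins.
    ``pbs_offset`` is the distance from boxC end to PBS start along the
    element's orientation.
    """

    seq_id: str
    strand: str
    ltr5: Interval
    internal: Interval
    pbs: Interval
    boxA: Interval
    boxC: Interval
    pbs_offset: int
    ltr3: Interval | None = None


@dataclass(frozen=True)
class TandemArray:
    """Alternating LTR / internal-domain segmentation of an array hit.

    ``segments`` alternate ("LTR", start, end) and ("internal", start,
    end) in the element's biological order. ``periods`` are consecutive
    LTR-start distances; a complete n-unit array has n LTRs and n-1
    internal segments between them.
    """

    seq_id: str
    strand: str
    segments: tuple[tuple[str, int, int], ...]
    n_ltrs: int
    n_internal: int
    ltr_starts: tuple[int, ...]
    periods: tuple[int, ...]
    truncated_last: bool


def annotate_element(
    chain: ChainHit,
    *,
    ltr_5prime_flank: int = 0,
    ltr3: Interval | None = None,
) -> CassandraElement:
    """Interpret a Cassandra-query chain hit as an element model.

    The 5' LTR is approximated as [boxA start - flank, PBS start); no
    LTR-edge rule beyond boxA is inferable from the motif chain alone,
    so the default flank is 0 and the LTR is reported from boxA.
    """
    if len(chain.motif_sites) != 3:
        raise AnnotationError(
            "incompatible query: expected a boxA, boxC, PBS chain, got "
            f"{len(chain.motif_sites)} motif sites"
        )
    a, c, p = chain.motif_sites
    if chain.strand == "+":
        ltr5 = (max(a.start - ltr_5prime_flank, 0), p.start)
        internal = (p.start, chain.span_end)
        pbs_offset = p.start - c.end
    else:
        ltr5 = (p.end, a.end + ltr_5prime_flank)
        internal = (chain.span_start, p.end)
        pbs_offset = c.start - p.end
    return CassandraElement(
        seq_id=chain.seq_id,
        strand=chain.strand,
        ltr5=ltr5,
        internal=internal,
        pbs=(p.start, p.end),
        boxA=(a.start, a.end),
        boxC=(c.start, c.end),
        pbs_offset=pbs_offset,
        ltr3=ltr3,
    )


def decompose_array(
    array: ArrayHit,
    elements: Sequence[CassandraElement],
    *,
    truncation_frac: float = 0.8,
) -> TandemArray:
    """Alternating LTR/internal segmentation of a tandem-array hit.

    ``elements`` must be the annotations of the array's unit chains. The
    terminal unit is flagged as truncated when the last inter-LTR period
    falls below ``truncation_frac`` times the median period.
    """
    if len(elements) != array.n_units:
        raise AnnotationError(
            f"{array.n_units}-unit array but {len(elements)} element annotations"
        )
    if any(e.strand != array.strand for e in elements):
        raise AnnotationError("element strands do not match the array strand")
    plus = array.strand == "+"
    # biological order: left-to-right on plus, right-to-left on minus
    els = sorted(elements, key=lambda e: e.ltr5[0], reverse=not plus)

    segments: list[tuple[str, int, int]] = []
    ltr_starts: list[int] = []
    for i, el in enumerate(els):
        segments.append(("LTR", *el.ltr5))
        ltr_starts.append(el.ltr5[0] if plus else el.ltr5[1])
        if i + 1 < len(els):
            nxt = els[i + 1]
            if plus:
                internal = (el.pbs[0], nxt.ltr5[0])
            else:
                internal = (nxt.ltr5[1], el.pbs[1])
            if internal[0] >= internal[1]:
                raise AnnotationError(
                    "non-alternating segmentation: internal segment "
                    f"{internal} is empty or inverted"
                )
            segments.append(("internal", *internal))

    periods = tuple(abs(b - a) for a, b in zip(ltr_starts, ltr_starts[1:]))
    truncated = bool(
        len(periods) >= 2 and periods[-1] < truncation_frac * median(periods)
    )
    return TandemArray(
        seq_id=array.seq_id,
        strand=array.strand,
        segments=tuple(segments),
        n_ltrs=len(els),
        n_internal=len(els) - 1,
        ltr_starts=tuple(ltr_starts),
        periods=periods,
        truncated_last=truncated,
    )


def unit_period(array: TandemArray) -> tuple[float, float]:
    """Median and spread (max - min) of consecutive LTR-start distances."""
    if array.n_ltrs < 2:
        raise AnnotationError("unit period undefined for a single-unit array")
    return float(median(array.periods)), float(max(array.periods) - min(array.periods))
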