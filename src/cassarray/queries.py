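"""Linked (distance-constrained) degenerate-motif queries.

A linked query is an ordered list of degenerate motifs joined by allowed
gap ranges; it matches when all motifs occur in order on one strand with
every inter-motif distance inside its range. The tandem form repeats a
unit chain with a bounded inter-unit gap and describes head-to-tail
repeat arrays such as the Cassandra TRIM arrays whose consensus query
is ``RGTTAAGYRHGY[15-25]RRRATRGGTRACY[5-200]TGGTATCAGAGC`` (boxA and
boxC of the LTR-borne 5S promoter, then the PBS).

Gaps count intervening nucleotides: for consecutive sites the distance
is ``next.start - previous.end``.
"""

from __future__ import annotations

import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence, Union

from .sequences import (
    AlphabetError,
    DegenerateMotif,
    MatchSite,
    clean_seq,
    find_motif,
    revcomp,
)

__all__ = [
    "BOXA", "BOXC", "PBS",
    "CASSANDRA_QUERY", "CASSANDRA_TANDEM_QUERY",
    "GapRange", "LinkedQuery", "TandemQuery", "ChainHit", "ArrayHit",
    "QueryParseError", "parse_query", "format_query",
    "search_linked", "search_tandem",
]

#: boxA internal RNA pol III promoter element of the 5S domain.
BOXA = "RGTTAAGYRHGY"
#: boxC internal RNA pol III promoter element of the 5S domain.
BOXC = "RRRATRGGTRACY"
#: primer binding site consensus just inside the 5' LTR.
PBS = "TGGTATCAGAGC"

#: consensus linked query for a single Cassandra element.
CASSANDRA_QUERY = f"{BOXA}[15-25]{BOXC}[5-200]{PBS}"
#: tandem-array form: the unit chain repeated with a 200-1000 nt unit gap.
CASSANDRA_TANDEM_QUERY = f"({CASSANDRA_QUERY})[200-1000]n"

#: default inter-unit gap when a "(UNIT)n" query omits one.
DEFAULT_UNIT_GAP = (200, 1000)

_DASH = r"[-–−]"  # hyphen, en dash, minus sign
_GAP_RE = re.compile(rf"([\[\(]\s*\d+\s*{_DASH}\s*\d+\s*[\]\)])")
_GAP_PARSE = re.compile(rf"[\[\(]\s*(\d+)\s*{_DASH}\s*(\d+)\s*[\]\)]")


class QueryParseError(ValueError):
    """The query text does not follow the linked-query syntax."""


@dataclass(frozen=True)
class GapRange:
    """Allowed number of intervening nucleotides between two motifs."""

    min_gap: int
    max_gap: int

    def __post_init__(self) -> None:
        if not 0 <= self.min_gap <= self.max_gap:
            raise QueryParseError(
                f"invalid gap range [{self.min_gap}-{self.max_gap}]: "
                "need 0 <= min <= max"
            )

    def __contains__(self, gap: int) -> bool:
        return self.min_gap <= gap <= self.max_gap


@dataclass(frozen=True)
class LinkedQuery:
    """Ordered motifs with inter-motif gap ranges (one fewer than motifs)."""

    name: str
    motifs: tuple[DegenerateMotif, ...]
    gaps: tuple[GapRange, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise QueryParseError("a linked query needs at least one motif")
        if len(self.gaps) != len(self.motifs) - 1:
            raise QueryParseError(
                f"{len(self.motifs)} motifs require {len(self.motifs) - 1} "
                f"gap ranges, got {len(self.gaps)}"
            )

    @property
    def min_span(self) -> int:
        return sum(m.length for m in self.motifs) + sum(g.min_gap for g in self.gaps)

    @property
    def max_span(self) -> int:
        return sum(m.length for m in self.motifs) + sum(g.max_gap for g in self.gaps)


@dataclass(frozen=True)
class TandemQuery:
    """A unit chain repeated head-to-tail with a bounded inter-unit gap.

    The unit gap is measured from the end of a unit's last motif to the
    start of the next unit's first motif.
    """

    name: str
    unit: LinkedQuery
    unit_gap: GapRange
    min_repeats: int = 2

    def __post_init__(self) -> None:
        if self.min_repeats < 1:
            raise QueryParseError("min_repeats must be >= 1")


@dataclass(frozen=True)
class ChainHit:
    """A located occurrence of a linked query on one strand.

    ``motif_sites`` are in query order; for minus-strand chains that
    order runs right to left in plus coordinates, and the span is the
    outer envelope of the sites.
    """

    seq_id: str
    strand: str
    motif_sites: tuple[MatchSite, ...]
    span_start: int
    span_end: int
    total_mismatches: int

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start

    @classmethod
    def from_sites(cls, seq_id: str, strand: str, sites: Sequence[MatchSite]) -> "ChainHit":
        return cls(
            seq_id=seq_id,
            strand=strand,
            motif_sites=tuple(sites),
            span_start=min(s.start for s in sites),
            span_end=max(s.end for s in sites),
            total_mismatches=sum(s.mismatches for s in sites),
        )


@dataclass(frozen=True)
class ArrayHit:
    """A maximal same-strand run of unit chains with in-range unit gaps."""

    seq_id: str
    strand: str
    unit_chains: tuple[ChainHit, ...]
    n_units: int
    inter_unit_gaps: tuple[int, ...]
    span_start: int
    span_end: int


# ---------------------------------------------------------------------------
# parsing / formatting


def _parse_flat(body: str, name: str, offset: int) -> LinkedQuery:
    parts = _GAP_RE.split(body)
    motifs: list[DegenerateMotif] = []
    gaps: list[GapRange] = []
    pos = offset
    for i, part in enumerate(parts):
        if i % 2 == 0:  # motif token
            if not part:
                raise QueryParseError(f"empty motif at position {pos} in query {name!r}")
            try:
                motifs.append(DegenerateMotif(part))
            except AlphabetError:
                for j, c in enumerate(part.upper().replace("U", "T")):
                    if c not in "ACGTRYSWKMBDHVN":
                        raise QueryParseError(
                            f"unknown character {c!r} at position {pos + j} "
                            f"in query {name!r}"
                        ) from None
                raise
        else:  # gap token
            m = _GAP_PARSE.fullmatch(part)
            assert m is not None
            gaps.append(GapRange(int(m.group(1)), int(m.group(2))))
        pos += len(part)
    return LinkedQuery(name=name, motifs=tuple(motifs), gaps=tuple(gaps))


_TANDEM_RE = re.compile(
    rf"\(\s*(?P<inner>.+?)\s*\)\s*(?P<gap>[\[\(]\s*\d+\s*{_DASH}\s*\d+\s*[\]\)])?\s*n(?P<reps>\d+)?",
    re.IGNORECASE,
)


def parse_query(text: str) -> Union[LinkedQuery, TandemQuery]:
    """Parse one linked or tandem query record.

    Accepts an optional FASTA-style ``>name`` header, both square- and
    round-bracket gap dialects, and hyphen/en-dash/minus range
    separators. A parenthesized unit with a trailing ``n`` marks a
    tandem query, e.g. ``(BOXA[15-25]BOXC)[200-1000]n``; the doubled-unit
    dialect (unit, unit gap, unit again) is folded into the same
    structure.
    """
    text = text.strip()
    name = "query"
    if text.startswith(">"):
        lines = text[1:].split("\n", 1)
        header = lines[0].strip()
        name = header.split()[0] if header.split() else "query"
        rest = header.split(None, 1)[1] if len(header.split(None, 1)) > 1 else ""
        body = (rest + " " + (lines[1] if len(lines) > 1 else "")).strip()
    else:
        body = text
    body = re.sub(r"\s+", "", body)
    if not body:
        raise QueryParseError("empty query")

    m = _TANDEM_RE.fullmatch(body)
    if m is not None:
        unit = _parse_flat(m.group("inner"), name, body.index(m.group("inner")))
        if m.group("gap"):
            g = _GAP_PARSE.fullmatch(m.group("gap"))
            unit_gap = GapRange(int(g.group(1)), int(g.group(2)))
        else:
            unit_gap = GapRange(*DEFAULT_UNIT_GAP)
        reps = int(m.group("reps")) if m.group("reps") else 2
        return TandemQuery(name=name, unit=unit, unit_gap=unit_gap, min_repeats=reps)

    query = _parse_flat(body, name, 0)
    folded = _fold_doubled_unit(query)
    return folded if folded is not None else query


def _fold_doubled_unit(query: LinkedQuery) -> TandemQuery | None:
    """Detect the doubled-unit tandem dialect written as UNIT[gap]UNIT."""
    k, n = len(query.motifs) // 2, len(query.motifs)
    if n < 2 or n % 2:
        return None
    first, second = query.motifs[:k], query.motifs[k:]
    if any(a.pattern != b.pattern for a, b in zip(first, second)):
        return None
    unit_gaps, mid, tail = query.gaps[:k - 1], query.gaps[k - 1], query.gaps[k:]
    if unit_gaps != tail:
        return None
    unit = LinkedQuery(name=query.name, motifs=first, gaps=unit_gaps)
    return TandemQuery(name=query.name, unit=unit, unit_gap=mid, min_repeats=2)


def format_query(query: Union[LinkedQuery, TandemQuery]) -> str:
    """Canonical square-bracket, hyphen form; ``parse(format(q))`` == q."""
    if isinstance(query, TandemQuery):
        g = query.unit_gap
        return f"({format_query(query.unit)})[{g.min_gap}-{g.max_gap}]n"
    out = [query.motifs[0].pattern]
    for gap, motif in zip(query.gaps, query.motifs[1:]):
        out.append(f"[{gap.min_gap}-{gap.max_gap}]")
        out.append(motif.pattern)
    return "".join(out)


# ---------------------------------------------------------------------------
# searching


def _normalize_budgets(max_mismatch, k: int) -> list[int]:
    if isinstance(max_mismatch, int):
        return [max_mismatch] * k
    budgets = list(max_mismatch)
    if len(budgets) != k:
        raise ValueError(f"expected {k} per-motif budgets, got {len(budgets)}")
    return budgets


def _enumerate_chains(
    site_lists: Sequence[Sequence[MatchSite]], gaps: Sequence[GapRange]
) -> list[tuple[MatchSite, ...]]:
    """All full motif-site tuples satisfying every gap constraint.

    Interval chaining over start-sorted site lists with binary search on
    the admissible gap window; sites may be shared between chains here,
    collapsing happens afterwards.
    """
    starts = [[s.start for s in lst] for lst in site_lists]
    chains: list[tuple[MatchSite, ...]] = []

    def extend(prefix: list[MatchSite], level: int) -> None:
        if level == len(site_lists):
            chains.append(tuple(prefix))
            return
        prev = prefix[-1]
        gap = gaps[level - 1]
        lo = bisect_left(starts[level], prev.end + gap.min_gap)
        hi = bisect_right(starts[level], prev.end + gap.max_gap)
        for site in site_lists[level][lo:hi]:
            prefix.append(site)
            extend(prefix, level + 1)
            prefix.pop()

    for first in site_lists[0]:
        extend([first], 1)
    return chains


def collapse_chains(chains: list[ChainHit]) -> list[ChainHit]:
    """Resolve chains sharing motif sites.

    Chains are ranked by (fewest mismatches, leftmost start, smallest
    span) and accepted greedily so that no two reported chains share a
    motif site.
    """
    kept: list[ChainHit] = []
    used: set[tuple[int, int, str]] = set()
    ranked = sorted(chains, key=lambda c: (c.total_mismatches, c.span_start, c.span_length))
    for chain in ranked:
        ids = {(i, s.start, s.strand) for i, s in enumerate(chain.motif_sites)}
        if ids & used:
            continue
        kept.append(chain)
        used |= ids
    kept.sort(key=lambda c: (c.span_start, c.strand))
    return kept


def _chains_one_orientation(
    seq: str, query: LinkedQuery, budgets: Sequence[int], seq_id: str, strand: str
) -> list[ChainHit]:
    site_lists = [
        find_motif(seq, motif, budget, strand_mode="plus", seq_id=seq_id)
        for motif, budget in zip(query.motifs, budgets)
    ]
    if any(not lst for lst in site_lists):
        return []
    return [
        ChainHit.from_sites(seq_id, strand, sites)
        for sites in _enumerate_chains(site_lists, query.gaps)
    ]


def _map_chain_to_plus(chain: ChainHit, length: int) -> ChainHit:
    """Map a chain found on the reverse complement back to plus coordinates."""
    sites = tuple(
        MatchSite(s.seq_id, length - s.end, length - s.start, "-", s.mismatches)
        for s in chain.motif_sites
    )
    return ChainHit.from_sites(chain.seq_id, "-", sites)


def search_linked(
    seq: str,
    query: Union[LinkedQuery, str],
    *,
    seq_id: str = "seq",
    max_mismatch: int | Sequence[int] = 0,
    strand_mode: str = "both",
) -> list[ChainHit]:
    """Find all (collapsed) occurrences of a linked query.

    Minus-strand chains are found by scanning the reverse complement and
    mapping coordinates back; reported gaps therefore satisfy the query
    along the element's own orientation. Chains sharing any motif site
    are collapsed by :func:`collapse_chains`.
    """
    if isinstance(query, str):
        query = parse_query(query)
    if isinstance(query, TandemQuery):
        raise TypeError("search_linked takes a LinkedQuery; use search_tandem")
    budgets = _normalize_budgets(max_mismatch, len(query.motifs))
    for motif, budget in zip(query.motifs, budgets):
        if budget >= motif.length:
            raise ValueError(
                f"mismatch budget {budget} not below motif length {motif.length}"
            )
    if strand_mode not in ("plus", "both"):
        raise ValueError(f"strand_mode must be 'plus' or 'both', got {strand_mode!r}")
    s = clean_seq(seq)
    chains = _chains_one_orientation(s, query, budgets, seq_id, "+")
    if strand_mode == "both":
        rc = revcomp(s)
        chains += [
            _map_chain_to_plus(c, len(s))
            for c in _chains_one_orientation(rc, query, budgets, seq_id, "-")
        ]
    return collapse_chains(chains)


def search_tandem(
    seq: str,
    query: Union[TandemQuery, str],
    *,
    seq_id: str = "seq",
    max_mismatch: int | Sequence[int] = 0,
    strand_mode: str = "both",
    min_repeats: int | None = None,
) -> list[ArrayHit]:
    """Find maximal head-to-tail runs of a unit chain.

    Unit chains are located with :func:`search_linked`, then chained
    greedily left to right into maximal same-strand runs whose
    consecutive end-to-start gaps lie inside the unit gap range. Runs
    shorter than ``min_repeats`` are discarded (with ``min_repeats=1``
    isolated units are returned as single-unit arrays). Arrays are
    sorted by (seq_id, span start).
    """
    if isinstance(query, str):
        query = parse_query(query)
    if isinstance(query, LinkedQuery):
        raise TypeError("search_tandem takes a TandemQuery; use search_linked")
    min_r = query.min_repeats if min_repeats is None else min_repeats
    if min_r < 1:
        raise ValueError("min_repeats must be >= 1")
    units = search_linked(
        seq, query.unit, seq_id=seq_id, max_mismatch=max_mismatch, strand_mode=strand_mode
    )
    arrays: list[ArrayHit] = []
    for strand in "+-":
        run: list[ChainHit] = []
        for chain in sorted(
            (c for c in units if c.strand == strand), key=lambda c: c.span_start
        ):
            if run and (chain.span_start - run[-1].span_end) in query.unit_gap:
                run.append(chain)
            else:
                arrays.extend(_finish_run(run, query, min_r))
                run = [chain]
        arrays.extend(_finish_run(run, query, min_r))
    arrays.sort(key=lambda a: (a.seq_id, a.span_start, a.strand))
    return arrays


def _finish_run(run: list[ChainHit], query: TandemQuery, min_r: int) -> list[ArrayHit]:
    if not run or len(run) < min_r:
        return []
    gaps = tuple(b.span_start - a.span_end for a, b in zip(run, run[1:]))
    return [
        ArrayHit(
            seq_id=run[0].seq_id,
            strand=run[0].strand,
            unit_chains=tuple(run),
            n_units=len(run),
            inter_unit_gaps=gaps,
            span_start=run[0].span_start,
            span_end=run[-1].span_end,
        )
    ]
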