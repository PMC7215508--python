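"""In silico PCR on templates carrying tandem repeats.

Primer binding sites are matched with a mismatch budget but a perfect
3'-terminal anchor (polymerase extension is intolerant of 3' mismatches).
Amplicons pair a plus-strand (forward-pointing) site with a downstream
minus-strand site.

Length convention: an amplicon runs from the forward primer's 5' base to
the reverse primer's 5' base inclusive, i.e. 5'-to-5' distance + 1 -- the
quantity a gel reports, with both primer footprints included. On a clean
tandem template a divergent (inverted) primer pair placed inside one
repeat unit yields products only across unit junctions, producing the
arithmetic ladder ``base + period * (rung - 1)`` whose period is the
tandem unit length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .sequences import IUPAC_MASK, clean_seq, encode, revcomp, scan_pattern

__all__ = [
    "Primer",
    "BindingSite",
    "Amplicon",
    "Ladder",
    "find_binding_sites",
    "enumerate_amplicons",
    "predict_ladder",
    "render_gel",
    "render_gel_svg",
]


@dataclass(frozen=True)
class Primer:
    """A PCR primer: identifier plus 5'->3' sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_seq(self.sequence))
        if not self.sequence:
            raise ValueError(f"primer {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_template(
        cls, template: str, five_prime: int, length: int, strand: str, id: str = "primer"
    ) -> "Primer":
        """Carve a primer out of a template.

        ``five_prime`` is the plus-strand coordinate of the primer's 5'
        base: a plus-strand primer's footprint is [five_prime,
        five_prime + length); a minus-strand primer's footprint is
        (five_prime - length, five_prime] and its sequence is the
        reverse complement of that plus-strand slice.
        """
        t = clean_seq(template)
        if strand == "+":
            seq = t[five_prime:five_prime + length]
        elif strand == "-":
            seq = revcomp(t[five_prime - length + 1:five_prime + 1])
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if len(seq) != length:
            raise ValueError("primer window extends beyond the template")
        return cls(id=id, sequence=seq)


@dataclass(frozen=True)
class BindingSite:
    """A primer footprint on the plus strand of a template."""

    position: int          # 0-based start of the footprint, plus strand
    strand: str
    mismatches: int
    primer_len: int
    anchor_ok: bool = True

    @property
    def five_prime(self) -> int:
        """Plus-strand coordinate of the primer's 5' base."""
        return self.position if self.strand == "+" else self.position + self.primer_len - 1

    @property
    def end(self) -> int:
        return self.position + self.primer_len


@dataclass(frozen=True)
class Amplicon:
    """A predicted product: half-open plus-strand interval, 5' to 5' inclusive."""

    start: int
    end: int
    junctions_spanned: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Ladder:
    """The deduplicated, sorted product lengths of one primer pair."""

    lengths: tuple[int, ...]
    base: int | None
    period: float
    formula_text: str
    amplicons: tuple[Amplicon, ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.lengths


def _compatible(a: str, b: str) -> bool:
    return bool(IUPAC_MASK[a] & IUPAC_MASK[b])


def find_binding_sites(
    template: str,
    primer: Primer,
    *,
    max_mismatch: int = 2,
    anchor_len: int = 3,
    strand_mode: str = "both",
) -> list[BindingSite]:
    """Primer binding sites with a perfect 3'-terminal anchor.

    Plus-strand sites are left-to-right matches of the primer;
    minus-strand sites are matches of its reverse complement (primer 3'
    end pointing leftward on the plus strand). Sites exceed neither
    ``max_mismatch`` in total nor zero mismatches within the 3'-terminal
    ``anchor_len`` bases.
    """
    if anchor_len > len(primer):
        raise ValueError("anchor_len cannot exceed the primer length")
    if max_mismatch >= len(primer):
        raise ValueError("max_mismatch must be below the primer length")
    t = clean_seq(template)
    enc = encode(t)
    sites: list[BindingSite] = []

    def anchor_clean(pos: int, pattern: str, idx: range) -> bool:
        return all(_compatible(t[pos + j], pattern[j]) for j in idx)

    if strand_mode in ("plus", "both"):
        pat = primer.sequence
        anchor_idx = range(len(pat) - anchor_len, len(pat))
        for pos, mm in scan_pattern(enc, pat, max_mismatch):
            if anchor_clean(pos, pat, anchor_idx):
                sites.append(BindingSite(pos, "+", mm, len(primer)))
    if strand_mode in ("minus", "both"):
        pat = revcomp(primer.sequence)
        anchor_idx = range(anchor_len)  # primer 3' end is leftmost on plus
        for pos, mm in scan_pattern(enc, pat, max_mismatch):
            if anchor_clean(pos, pat, anchor_idx):
                sites.append(BindingSite(pos, "-", mm, len(primer)))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def enumerate_amplicons(
    fwd_sites: Sequence[BindingSite],
    rev_sites: Sequence[BindingSite],
    max_len: int | None = 10_000,
    unit_boundaries: Sequence[int] | None = None,
) -> list[Amplicon]:
    """All products of (plus-strand site, downstream minus-strand site) pairs.

    Primers must not overlap; products longer than ``max_len`` are
    dropped (pass ``None`` for no limit). ``unit_boundaries`` are
    plus-strand coordinates of tandem-unit junctions used to count the
    junctions each product spans.
    """
    boundaries = sorted(unit_boundaries) if unit_boundaries else []
    out: list[Amplicon] = []
    for f in fwd_sites:
        if f.strand != "+":
            continue
        for r in rev_sites:
            if r.strand != "-" or r.position < f.position + f.primer_len:
                continue
            end = r.five_prime + 1
            if max_len is not None and end - f.position > max_len:
                continue
            junctions = sum(1 for b in boundaries if f.position < b < end)
            out.append(Amplicon(f.position, end, junctions))
    out.sort(key=lambda a: (a.length, a.start))
    return out


def predict_ladder(
    template: str,
    fwd: Primer,
    rev: Primer,
    *,
    max_mismatch: int = 2,
    anchor_len: int = 3,
    max_len: int | None = 10_000,
    unit_boundaries: Sequence[int] | None = None,
) -> Ladder:
    """Predict the amplicon ladder of a primer pair on a template.

    Both pairings of orientations are enumerated (forward-plus with
    reverse-minus and vice versa), products are deduplicated by length
    (a gel cannot separate equal lengths), and the ladder arithmetic is
    fitted: base = smallest rung, period = median consecutive-rung
    difference (0 with fewer than 2 rungs), rendered as
    ``"base + (period)_n"``. An empty ladder is returned as a flagged
    result, not an exception.
    """
    kw = dict(max_mismatch=max_mismatch, anchor_len=anchor_len)
    f_sites = find_binding_sites(template, fwd, **kw)
    r_sites = find_binding_sites(template, rev, **kw)
    amplicons = enumerate_amplicons(f_sites, r_sites, max_len, unit_boundaries)
    amplicons += enumerate_amplicons(r_sites, f_sites, max_len, unit_boundaries)

    by_length: dict[int, Amplicon] = {}
    for a in sorted(amplicons, key=lambda a: (a.length, a.start)):
        by_length.setdefault(a.length, a)
    lengths = tuple(sorted(by_length))
    if not lengths:
        return Ladder(lengths=(), base=None, period=0.0, formula_text="")
    base = lengths[0]
    diffs = [b - a for a, b in zip(lengths, lengths[1:])]
    period = float(median(diffs)) if diffs else 0.0
    ptxt = f"{period:g}"
    return Ladder(
        lengths=lengths,
        base=base,
        period=period,
        formula_text=f"{base} + ({ptxt})_n",
        amplicons=tuple(by_length[l] for l in lengths),
    )


# ---------------------------------------------------------------------------
# virtual gel rendering

_MARKER = (100, 250, 500, 1000, 2500, 5000, 10_000)


def _band_rows(lengths, min_len, max_len, height, label):
    rows = {}
    for ln in lengths:
        if not (min_len <= ln <= max_len):
            warnings.warn(
                f"band of {ln} bp outside the {min_len}-{max_len} bp gel "
                f"range in lane {label!r}; clipped"
            )
            continue
        frac = (math.log(max_len) - math.log(ln)) / (math.log(max_len) - math.log(min_len))
        rows.setdefault(round(frac * (height - 1)), []).append(ln)
    return rows


def render_gel(
    ladders: Sequence[Ladder],
    labels: Sequence[str] | None = None,
    *,
    min_len: int = 100,
    max_len: int = 10_000,
    height: int = 24,
) -> str:
    """Deterministic text rendering of one lane per ladder.

    Bands are placed monotonically by log(length), largest products on
    top, next to a size-marker lane; bands outside the range are clipped
    with a warning.
    """
    if not ladders:
        raise ValueError("need at least one ladder to render")
    labels = list(labels) if labels is not None else [f"lane{i+1}" for i in range(len(ladders))]
    lane_w = 9
    marker_rows = _band_rows(
        [m for m in _MARKER if min_len <= m <= max_len], min_len, max_len, height, "marker"
    )
    lanes = [
        _band_rows(lad.lengths, min_len, max_len, height, lab)
        for lad, lab in zip(ladders, labels)
    ]
    header = "bp".rjust(7) + " " + "".join(lab[:lane_w].center(lane_w) for lab in ["M"] + labels)
    lines = [header]
    for row in range(height):
        tick = str(max(marker_rows[row])) if row in marker_rows else ""
        cells = ["───".center(lane_w) if row in marker_rows else " " * lane_w]
        for lane in lanes:
            cells.append("━━━━━".center(lane_w) if row in lane else " " * lane_w)
        lines.append(tick.rjust(7) + " " + "".join(cells))
    return "\n".join(lines)


def render_gel_svg(
    ladders: Sequence[Ladder],
    labels: Sequence[str] | None = None,
    *,
    min_len: int = 100,
    max_len: int = 10_000,
    width_per_lane: int = 60,
    height: int = 360,
) -> str:
    """Minimal SVG rendering of the virtual gel (deterministic text)."""
    if not ladders:
        raise ValueError("need at least one ladder to render")
    labels = list(labels) if labels is not None else [f"lane{i+1}" for i in range(len(ladders))]
    top, bottom = 30, height - 10
    span = math.log(max_len) - math.log(min_len)

    def y_of(ln: int) -> float:
        return top + (math.log(max_len) - math.log(ln)) / span * (bottom - top)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{(len(ladders) + 1) * width_per_lane + 20}" height="{height}">',
        f'<rect width="100%" height="100%" fill="#111"/>',
    ]
    for i, m in enumerate(_MARKER):
        if min_len <= m <= max_len:
            y = y_of(m)
            parts.append(
                f'<line x1="10" x2="{width_per_lane - 10}" y1="{y:.1f}" y2="{y:.1f}" '
                f'stroke="#888" stroke-width="3"/>'
            )
            parts.append(
                f'<text x="12" y="{y - 3:.1f}" fill="#aaa" font-size="9">{m}</text>'
            )
    for k, (lad, lab) in enumerate(zip(ladders, labels)):
        x0 = (k + 1) * width_per_lane + 10
        parts.append(
            f'<text x="{x0}" y="20" fill="#ddd" font-size="10">{lab}</text>'
        )
        for ln in lad.lengths:
            if min_len <= ln <= max_len:
                y = y_of(ln)
                parts.append(
                    f'<line x1="{x0}" x2="{x0 + width_per_lane - 20}" '
                    f'y1="{y:.1f}" y2="{y:.1f}" stroke="#eee" stroke-width="4"/>'
                )
    parts.append("</svg>")
    return "\n".join(parts)
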