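"""IUPAC nucleotide alphabet services.

Degenerate-code matching, reverse complementation, and single-motif
scanning with a mismatch budget on either or both strands. All
coordinates are 0-based half-open on the plus strand of the scanned
sequence, regardless of the strand a site was found on.

Scanning is vectorized with numpy bitmask arithmetic: each IUPAC code is
a 4-bit set over {A, C, G, T}, and a template position matches a motif
position when the two sets intersect. A degenerate code matching its set
is therefore never a mismatch, on either side of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import prod
from typing import Iterator

import numpy as np

__all__ = [
    "IUPAC_MASK",
    "IUPAC_COMPLEMENT",
    "AlphabetError",
    "DegenerateMotif",
    "MatchSite",
    "clean_seq",
    "revcomp",
    "motif_degeneracy",
    "expand_motif",
    "find_motif",
]

#: 4-bit base set per IUPAC code (bit 0 = A, 1 = C, 2 = G, 3 = T).
IUPAC_MASK: dict[str, int] = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

#: concrete A/C/G/T expansions of each code, in alphabetical order.
CODE_BASES: dict[str, tuple[str, ...]] = {
    code: tuple(b for b in "ACGT" if IUPAC_MASK[code] & IUPAC_MASK[b])
    for code in IUPAC_MASK
}

_VALID = frozenset(IUPAC_MASK)

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _ENCODE_LUT[ord(_c)] = _m

_COMPLEMENT_TABLE = str.maketrans(IUPAC_COMPLEMENT)


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def clean_seq(seq: str) -> str:
    """Upper-case ``seq``, coerce U to T, and validate the IUPAC alphabet.

    Raises :class:`AlphabetError` naming the first offending position;
    malformed input is never silently skipped.
    """
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        for i, c in enumerate(s):
            if c not in _VALID:
                raise AlphabetError(f"invalid nucleotide {c!r} at position {i}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC codes complemented (R<->Y, K<->M, ...).

    An involution: ``revcomp(revcomp(s)) == s`` for any valid ``s``.
    """
    return clean_seq(seq).translate(_COMPLEMENT_TABLE)[::-1]


@dataclass(frozen=True)
class DegenerateMotif:
    """A short pattern over the 15-letter IUPAC nucleotide alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern", clean_seq(self.pattern))
        if not self.pattern:
            raise AlphabetError("motif pattern must be non-empty")

    @property
    def length(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MatchSite:
    """One motif occurrence; coordinates on the plus strand, half-open."""

    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def motif_degeneracy(motif: DegenerateMotif | str) -> int:
    """Number of distinct concrete A/C/G/T strings matching the motif."""
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    return prod(len(CODE_BASES[c]) for c in motif.pattern)


def expand_motif(motif: DegenerateMotif | str) -> Iterator[str]:
    """Yield every concrete A/C/G/T string matching the motif.

    Intended for small motifs; the number of expansions is
    :func:`motif_degeneracy` and grows multiplicatively.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    for bases in product(*(CODE_BASES[c] for c in motif.pattern)):
        yield "".join(bases)


def encode(seq: str) -> np.ndarray:
    """Encode a cleaned sequence as a uint8 array of IUPAC bitmasks."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_pattern(seq_enc: np.ndarray, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) where ``pattern`` matches the encoded sequence.

    A position mismatches when the pattern's and template's IUPAC base
    sets are disjoint.
    """
    n, m = len(seq_enc), len(pattern)
    if n < m:
        return []
    mm = np.zeros(n - m + 1, dtype=np.int32)
    for j, c in enumerate(pattern):
        mm += (seq_enc[j:j + n - m + 1] & IUPAC_MASK[c]) == 0
    hits = np.nonzero(mm <= max_mismatch)[0]
    return [(int(p), int(mm[p])) for p in hits]


def find_motif(
    seq: str,
    motif: DegenerateMotif | str,
    max_mismatch: int = 0,
    strand_mode: str = "both",
    seq_id: str = "seq",
) -> list[MatchSite]:
    """Scan ``seq`` for a degenerate motif with a mismatch budget.

    Every occurrence is reported, including overlapping ones. Minus-strand
    sites are matches of the reverse-complemented motif, reported in plus
    coordinates; mismatch counts are identical to scanning the reverse
    complement of the sequence. Sites are sorted by (start, strand).

    Parameters
    ----------
    max_mismatch
        Number of positions allowed to violate the motif's IUPAC sets;
        must be smaller than the motif length.
    strand_mode
        ``"plus"`` or ``"both"``.
    """
    if isinstance(motif, str):
        motif = DegenerateMotif(motif)
    if max_mismatch < 0 or max_mismatch >= motif.length:
        raise ValueError(
            f"max_mismatch must be in [0, {motif.length - 1}] for a "
            f"{motif.length} nt motif, got {max_mismatch}"
        )
    if strand_mode not in ("plus", "both"):
        raise ValueError(f"strand_mode must be 'plus' or 'both', got {strand_mode!r}")
    s = clean_seq(seq)
    if not s:
        return []
    enc = encode(s)
    m = motif.length
    sites = [
        MatchSite(seq_id, p, p + m, "+", k)
        for p, k in scan_pattern(enc, motif.pattern, max_mismatch)
    ]
    if strand_mode == "both":
        rc = revcomp(motif.pattern)
        sites += [
            MatchSite(seq_id, p, p + m, "-", k)
            for p, k in scan_pattern(enc, rc, max_mismatch)
        ]
    sites.sort(key=lambda t: (t.start, t.strand))
    return sites
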