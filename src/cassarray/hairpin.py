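"""Palindromic stem potential of LTR sequences.

Cassandra transcripts are predicted to fold into super-hairpins in
which the two LTRs pair with each other. This module scores that
potential without thermodynamic folding: a sequence is globally aligned
against its own reverse complement (match +1, mismatch -1, gap -2), so
a match column represents a base pair of the folded-back strand. G*U
wobble pairs count by default (transcripts are RNA); a documented
switch restricts scoring to Watson-Crick pairs, in which mode the score
is exactly symmetric under reverse complementation (a wobble pair is
not complement-invariant: the complementary strand has C*A there, which
cannot pair).

The pairing fraction is paired columns over all alignment columns.
Because several alignments can share the optimal score, the alignment
is chosen by the lexicographic objective (score, most paired columns,
fewest columns), which makes the reported fraction well defined and,
in Watson-Crick mode, strand symmetric. 1.0 is attained exactly on
perfect reverse-complement palindromes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import CassandraElement
from .sequences import clean_seq, revcomp

__all__ = [
    "StemReport",
    "palindromic_stem_score",
    "pairing_score",
    "element_hairpin_report",
]


@dataclass(frozen=True)
class StemReport:
    """Self-pairing summary of one sequence."""

    pairing_fraction: float
    best_stem_len: int
    alignment_columns: int
    paired_columns: int
    score: float


def _match_matrix(wobble: bool) -> dict[tuple[str, str], bool]:
    """Pairedness of a column (x from seq, y from the reverse complement).

    x == y encodes a Watson-Crick fold pair; a G*U fold pair appears as
    the column (G, A) or (T, C) after complementation.
    """
    pairs = {(b, b): True for b in "ACGT"}
    if wobble:
        pairs[("G", "A")] = True
        pairs[("T", "C")] = True
    return pairs


# lexicographic weights: 1 unit of score outranks any paired-column
# difference, which outranks any column-count difference
_B = 1 << 14          # > max alignment columns supported (2 * 8191)
_A = _B * (_B // 2)   # > max |B*paired - cols|
_MAX_LEN = _B // 2 - 1


def _align(a: str, b: str, wobble: bool, match: int, mismatch: int, gap: int):
    """Global alignment of a against b maximizing (score, paired, -cols).

    Returns (score, paired_columns, total_columns, column_flags).
    """
    n, m = len(a), len(b)
    paired = _match_matrix(wobble)
    # per-transition combined weights
    w_gap = _A * gap - 1
    diag = [
        [_A * (match if paired.get((x, y), False) else mismatch)
         + _B * (1 if paired.get((x, y), False) else 0) - 1
         for y in b]
        for x in a
    ]
    NEG = -(1 << 60)
    prev = [j * w_gap for j in range(m + 1)]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0=diag 1=up 2=left
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        row_d = diag[i - 1]
        cur = [prev[0] + w_gap] + [NEG] * m
        ptr[i, 0] = 1
        for j in range(1, m + 1):
            d = prev[j - 1] + row_d[j - 1]
            u = prev[j] + w_gap
            l = cur[j - 1] + w_gap
            best = d
            p = 0
            if u > best:
                best, p = u, 1
            if l > best:
                best, p = l, 2
            cur[j] = best
            ptr[i, j] = p
        prev = cur

    # traceback for per-column paired flags (in alignment order)
    flags: list[bool] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            flags.append(paired.get((a[i - 1], b[j - 1]), False))
            i, j = i - 1, j - 1
        elif p == 1 and i > 0:
            flags.append(False)
            i -= 1
        else:
            flags.append(False)
            j -= 1
    flags.reverse()

    combined = prev[m]
    # decompose combined = A*score + B*paired - cols
    q = combined % _A
    score = combined // _A
    if q > _A - _B:  # negative (B*paired - cols) wrapped below the A block
        q -= _A
        score += 1
    n_paired = -(-q // _B) if q % _B else q // _B  # ceil for cols in (0, B)
    cols = _B * n_paired - q
    if cols == 0:  # degenerate empty alignment
        cols = len(flags)
    return int(score), int(n_paired), int(cols), flags


def pairing_score(
    seq_a: str,
    seq_b: str,
    *,
    wobble: bool = True,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> StemReport:
    """How well ``seq_a`` can base-pair antiparallel with ``seq_b``.

    ``seq_a`` is globally aligned against ``revcomp(seq_b)``; a match
    column is a Watson-Crick (or, by default, also G*U) pair between
    the two strands. Deterministic for fixed scores.
    """
    a = clean_seq(seq_a)
    b = revcomp(seq_b)
    if len(a) < 4 or len(b) < 4:
        raise ValueError("sequences must be at least 4 nt for stem scoring")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValueError(f"sequences longer than {_MAX_LEN} nt are not supported")
    score, paired, cols, flags = _align(a, b, wobble, match, mismatch, gap)
    assert cols == len(flags) and paired == sum(flags)
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return StemReport(
        pairing_fraction=paired / cols,
        best_stem_len=best,
        alignment_columns=cols,
        paired_columns=paired,
        score=float(score),
    )


def palindromic_stem_score(seq: str, *, wobble: bool = True, **scores) -> StemReport:
    """Score a sequence's ability to fold back and pair with itself."""
    return pairing_score(seq, seq, wobble=wobble, **scores)


def element_hairpin_report(
    element: CassandraElement, seq: str, *, wobble: bool = True
) -> dict[str, float | None]:
    """Per-LTR palindromic scores plus the 5'-LTR x 3'-LTR pairing score.

    A solo-LTR element (no annotated 3' LTR) yields a partial report
    with the absent scores set to None.
    """
    s = clean_seq(seq)
    ltr5 = s[element.ltr5[0]:element.ltr5[1]]
    if element.strand == "-":
        ltr5 = revcomp(ltr5)
    report: dict[str, float | None] = {
        "ltr5_score": palindromic_stem_score(ltr5, wobble=wobble).pairing_fraction,
        "ltr3_score": None,
        "cross_ltr_score": None,
    }
    if element.ltr3 is not None:
        ltr3 = s[element.ltr3[0]:element.ltr3[1]]
        if element.strand == "-":
            ltr3 = revcomp(ltr3)
        report["ltr3_score"] = palindromic_stem_score(ltr3, wobble=wobble).pairing_fraction
        report["cross_ltr_score"] = pairing_score(ltr5, ltr3, wobble=wobble).pairing_fraction
    return report
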