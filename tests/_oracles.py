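"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: position-by-position scanning,
exhaustive tuple enumeration, all-pairs products. No code is shared
with the package's vectorized / interval-chaining implementations.
"""

from itertools import product

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
        "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
        "N": "N"}


def naive_revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq.upper()))


def naive_mismatches(window, pattern):
    return sum(
        1 for w, p in zip(window, pattern)
        if not (IUPAC_SETS[w] & IUPAC_SETS[p])
    )


def naive_scan(seq, pattern, budget):
    """(start, mismatches) of every window within the mismatch budget."""
    m = len(pattern)
    out = []
    for i in range(len(seq) - m + 1):
        mm = 0
        for w, p in zip(seq[i:i + m], pattern):
            if not (IUPAC_SETS[w] & IUPAC_SETS[p]):
                mm += 1
                if mm > budget:
                    break
        else:
            out.append((i, mm))
    return out


def naive_find_motif(seq, pattern, budget, strand_mode="both"):
    """(start, end, strand, mismatches) tuples, sorted by (start, strand)."""
    seq = seq.upper()
    m = len(pattern)
    sites = [(p, p + m, "+", mm) for p, mm in naive_scan(seq, pattern, budget)]
    if strand_mode == "both":
        rc = naive_revcomp(pattern)
        sites += [(p, p + m, "-", mm) for p, mm in naive_scan(seq, rc, budget)]
    return sorted(sites, key=lambda s: (s[0], s[2]))


def naive_chain_tuples(seq, patterns, gap_ranges, budget=0):
    """All plus-strand site tuples of a linked query, by full enumeration."""
    site_lists = [naive_scan(seq.upper(), pat, budget) for pat in patterns]
    lengths = [len(p) for p in patterns]
    chains = []
    for combo in product(*site_lists):
        ok = True
        for k, (lo, hi) in enumerate(gap_ranges):
            gap = combo[k + 1][0] - (combo[k][0] + lengths[k])
            if not lo <= gap <= hi:
                ok = False
                break
        if ok:
            chains.append(combo)
    return chains


def naive_collapsed_chains(seq, patterns, gap_ranges, budget=0):
    """Collapsed plus-strand chains: rank by (mismatches, start, span) and
    greedily keep chains not sharing a site with an accepted chain."""
    lengths = [len(p) for p in patterns]
    raw = []
    for combo in naive_chain_tuples(seq, patterns, gap_ranges, budget):
        start = combo[0][0]
        end = combo[-1][0] + lengths[-1]
        mm = sum(c[1] for c in combo)
        raw.append((mm, start, end - start, combo))
    kept, used = [], set()
    for mm, start, span, combo in sorted(raw, key=lambda r: r[:3]):
        ids = {(k, c[0]) for k, c in enumerate(combo)}
        if ids & used:
            continue
        kept.append((start, start + span, mm, combo))
        used |= ids
    return sorted(kept)


def naive_amplicons(fwd_positions, fwd_len, rev_five_primes, rev_len, max_len=None):
    """All-pairs product lengths: (fwd 5', rev 5') with rev downstream,
    non-overlapping footprints; length = rev5' - fwd5' + 1."""
    out = []
    for f in fwd_positions:
        for r5 in rev_five_primes:
            if r5 - rev_len + 1 < f + fwd_len:
                continue
            length = r5 - f + 1
            if max_len is not None and length > max_len:
                continue
            out.append((f, r5, length))
    return sorted(out, key=lambda t: t[2])


def welch_t(a, b):
    """Hand-rolled Welch t statistic and degrees of freedom."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / se2 ** 0.5
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df
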