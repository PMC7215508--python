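"""Palindromic stem scoring: the super-hairpin signal without folding.

Scores how well a sequence can fold back and pair with itself
(alignment against its own reverse complement; G*U wobble counted by
default). A perfect reverse-complement palindrome scores 1.0; random
sequence scores well below. On an element with both LTRs annotated,
the cross-LTR score measures the inter-LTR pairing that underlies the
predicted super-hairpin.
"""

import numpy as np

from cassarray import palindromic_stem_score
from cassarray.hairpin import pairing_score
from cassarray.sequences import revcomp


def random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


half = random_seq(1, 60)
palindrome = half + revcomp(half)
rep = palindromic_stem_score(palindrome)
print(f"palindrome (120 nt): pairing fraction {rep.pairing_fraction:.3f}, "
      f"best stem {rep.best_stem_len} nt")

rnd = random_seq(2, 120)
rep = palindromic_stem_score(rnd)
print(f"random     (120 nt): pairing fraction {rep.pairing_fraction:.3f}, "
      f"best stem {rep.best_stem_len} nt")

ltr5 = random_seq(3, 100)
cross = pairing_score(ltr5, revcomp(ltr5))  # an LTR vs its complement pairs fully
print(f"LTR vs its reverse complement: pairing fraction "
      f"{cross.pairing_fraction:.3f}")
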