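# Methods

## Model and scope

`cassarray` treats a Cassandra TRIM element as a motif geometry rather
than a full sequence model: each LTR carries the 5S-derived RNA pol III
promoter boxes boxA (`RGTTAAGYRHGY`) and boxC (`RRRATRGGTRACY`) separated
by 15–25 nt, and the internal domain begins at the PBS
(`TGGTATCAGAGC`) 5–200 nt downstream of boxC. An element is therefore
detectable as a *linked chain* of three degenerate motifs with bounded
gaps; a tandem array is a same-strand run of such chains whose
end-to-start distances fall in 200–1000 nt. No probabilistic motif model
(PWM) and no indel-tolerant matching is attempted: the consensus boxes
are short and highly conserved, and the distance constraints carry most
of the specificity.

## Motif matching and chaining

Degenerate codes are 4-bit base sets; a template position matches a
motif position when the sets intersect, so degenerate codes on either
side are never mismatches. Scanning is vectorized (one numpy pass per
motif position), and minus-strand sites are matches of the
reverse-complemented motif — identical, position for position, to
scanning the reverse complement of the sequence. The default mismatch
budget is 0: the published queries are consensus-level, and the original
tool's fuzziness is not quantified, so fuzzy budgets are explicit
opt-ins per motif.

Chains are enumerated by interval chaining (sites sorted by start,
binary search over each gap window), which has an obvious brute-force
oracle: exhaustive enumeration over all motif-site tuples. Chains that
share a motif site are collapsed by ranking (fewest mismatches, leftmost
start, smallest span) and greedy acceptance; the rule is this package's
own choice, since multiplicity handling in the original tool is
undocumented. Tandem runs are greedy-maximal left to right; alternative
nested decompositions are not enumerated, and chains on opposite strands
never join one array (head-to-tail implies same strand).

## Annotation conventions

A chain fixes the 5′ LTR only between boxA and the PBS. Since no
LTR-edge rule beyond boxA is inferable from the motif chain, the LTR is
reported from the boxA start (configurable 5′ flank, default 0), and the
internal domain from the PBS start. For an n-chain array the alternation
is n LTRs bounding n−1 internal segments; the unit period is the median
consecutive LTR-start distance and the spread is max − min. A terminal
repeat unit is flagged truncated when the last period falls below 0.8×
the median — no threshold is published; 0.8 cleanly separates the ~60%
truncations the generator produces from jitter while not flagging intact
arrays. A bare closing LTR (no downstream PBS) cannot itself form a
chain, so terminal truncation is measurable only when a further chained
LTR bounds it; the tests construct arrays accordingly. PPT annotation is
available only as a user-supplied motif (no consensus is given for this
family), and solo-LTR calls are out of the default path.

## In silico PCR

Binding sites allow up to 2 mismatches (default) but none in the
3′-terminal 3 bases — polymerase extension is intolerant of 3′
mismatches; both defaults are configurable since primer-to-target
identity in real assays is assay-specific. No melting-temperature model
is applied: Tm constraints are a primer-design concern, not a
product-prediction one. An amplicon pairs a plus-strand site with a
downstream, non-overlapping minus-strand site; its length is the
5′-to-5′ distance inclusive of both footprints, the quantity a gel
reports. Products longer than 10 kb are dropped by default (the longest
observed tandem product is ~6 kb; the margin is deliberate). Ladders
deduplicate by length (a gel cannot separate equal lengths); the base is
the smallest rung and the period the median consecutive-rung difference,
rendered as `base + (period)_n`. On a clean n-unit tandem a divergent
pair yields exactly n(n−1)/2 products before length filtering.
Preferential amplification of short fragments and concatemer artifacts
at saturation are not simulated.

## Quantification

The standard curve is an ordinary least-squares fit of Ct on log₁₀
concentration; efficiency is 10^(−1/slope), so a perfect doubling series
gives slope −1/log₁₀2 = −3.3219 and efficiency 2. Relative
quantification inverts the curve and scales by a reference of known
copies at known concentration; Cts outside the calibrated range are
flagged, not rejected. Dot-blot copies per ng follow the count-ratio
formula; the per-genome conversion uses 978 Mbp/pg explicitly. The
mass-fraction worked example uses floor rounding (0.0005·4.8×10⁹/388 =
6185.57 → 6185). Group comparison defaults to Welch's t (a pooled
switch exists) because copy-number variances between populations are not
credibly equal; three or more groups use one-way ANOVA. Zero-variance
groups are handled explicitly (identical → t=0, p=1; shifted constants →
the p→0 limit, flagged degenerate).

## Hairpin stem score

Thermodynamic folding is deliberately replaced by an alignment score:
the published fold predictions are qualitative figures, not reproducible
numbers. A sequence is globally aligned against its own reverse
complement (match +1, mismatch −1, linear gap −2), so a match column is
a base pair of the folded-back strand; G·U wobble counts by default (the
transcripts are RNA). Because co-optimal alignments can differ in how
many columns pair, the alignment is chosen by the lexicographic
objective (score, most paired columns, fewest columns), making the
pairing fraction well defined. In Watson–Crick-only mode the score is
exactly symmetric under reverse complementation; with wobble it is not,
and genuinely so — a G·U pair maps to C·A on the complementary strand,
which cannot pair. Perfect reverse-complement palindromes score exactly
1.0; seeded random 200-mers average ≈0.59.

## Synthetic data

The generator emulates the study's geometries, not plant genomes: the
default unit is 229 nt LTR + 252 nt internal (the 481 nt oat-like
period), with boxA at LTR offset 50, boxC 18 nt after boxA, and the PBS
at the internal-domain start (boxC→PBS gap 136 nt, inside the query
window); 5S-style units are 121 nt gene + 190 nt spacer (311 nt period).
Each degenerate position is fixed to one concrete base per seed so
exact-match search recovers planted features at budget 0. Backgrounds
are uniform-random; substitution mutations apply only within planted
features; indels, nested insertions, base-composition structure and
solo-LTR recombination are not simulated — so passing recovery tests
demonstrate correctness of the search arithmetic, not sensitivity on
real, diverged genomic copies. Features are placed by distributing free
space with a seeded multinomial around a fixed 1100 nt minimum margin
(larger than the 1000 nt tandem-gap ceiling, so separate features can
never chain); infeasible specs fail fast instead of retrying. All
randomness flows through numpy's PCG64 `default_rng`, making every
output byte-reproducible per seed across platforms.

## Problem sizes and numerics

The test and acceptance workloads are sized for a single CPU: oracle
equivalence runs 200 seeded sequences of 2–20 kb against full
brute-force enumeration; planted-element recovery uses 200 seeded 20 kb
genomes (plus 100-seed mutation-rate sweeps at 0/0.02/0.05); the ladder
reproductions use 5–8-unit arrays, where every published rung already
appears. Coordinates are 0-based half-open internally with conversion
only at the GFF3/BED boundary; gaps count intervening nucleotides
(`next.start − prev.end`); ladder periods are medians, so a single
aberrant rung does not shift the reported period.

## Known limitations

Chain detection requires all three motifs — heavily diverged or 5′
truncated elements are invisible at budget 0; array unit counts are
chain counts, which undercount units whose PBS is lost; the LTR 5′
boundary is a convention, not an inference; and the quantification
module reproduces arithmetic, not plate-level noise models.
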