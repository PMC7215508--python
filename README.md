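# cassarray

Detection and analysis of **Cassandra TRIM retroelements** and their long
tandem arrays in plant genome sequences.

Cassandra is a terminal-repeat retrotransposon in miniature (TRIM): a tiny
non-autonomous LTR retroelement whose LTRs each carry a 5S rDNA-derived
sequence with internal RNA polymerase III promoter elements (boxA and boxC)
and whose internal domain is a short non-coding stuffer starting at the
primer binding site (PBS). In many plants Cassandra elements occur not only
as dispersed singletons but as long head-to-tail tandem arrays of
alternating LTRs and internal domains — LTR–internal–LTR–internal–…–LTR —
structurally mimicking the cellular 5S rRNA gene clusters (121 bp gene +
untranscribed spacer).

`cassarray` implements the computational side of that biology:

- **Linked (associated) search** — distance-constrained chains of IUPAC
  degenerate motifs. The consensus element query is

  ```text
  RGTTAAGYRHGY[15-25]RRRATRGGTRACY[5-200]TGGTATCAGAGC
      boxA      gap       boxC       gap      PBS
  ```

  with gaps counted in intervening nucleotides, an optional per-motif
  mismatch budget, and both strands scanned. The tandem form
  `(UNIT)[200-1000]n` chains unit hits into maximal head-to-tail arrays.
- **Element annotation** — LTR / internal-domain segmentation of chain
  hits, PBS offsets, alternation counts of arrays (n LTRs bounding n−1
  internal domains), unit period (median LTR-to-LTR distance) and
  truncated-terminal-unit flags.
- **In silico PCR** — primer binding with a perfect 3′ anchor, amplicon
  enumeration, and ladder arithmetic. A divergent (inverted) primer pair
  inside one repeat unit amplifies only across unit junctions of a tandem
  array, giving product lengths `base + period·(rung−1)` where the period
  equals the tandem unit length; lengths follow the gel convention,
  forward-primer 5′ base to reverse-primer 5′ base inclusive.
- **Copy-number arithmetic** — qPCR standard curves
  (Ct = a + s·log₁₀ conc; efficiency 10^(−1/s); a perfect doubling series
  has s = −1/log₁₀2 ≈ −3.32), relative quantification against a reference,
  dot-blot absolute copies
  (copies/ng = genomic cpm/ng × fragment copies/fragment cpm, converted per
  genome at 978 Mbp/pg), the singleton = total − tandem decomposition, and
  Welch t / ANOVA group comparisons.
- **Hairpin stem score** — a quantitative stand-in for the predicted LTR
  super-hairpin: global alignment of a sequence against its own reverse
  complement (match +1, mismatch −1, gap −2, G·U wobble counted for RNA).
- **Synthetic data** — a fully seeded generator of Cassandra-like units,
  arrays, 5S-style clusters and planted genomes with truth annotations, so
  everything is testable without downloading assemblies.

## Worked example

Divergent internal-domain primers on a clean 6-unit tandem array with the
oat-like geometry (229 nt LTR + 252 nt internal domain, 481 nt unit):

```python
from cassarray import Primer, UnitSpec, make_array, make_unit, predict_ladder

unit = make_unit(UnitSpec(seed=11))          # 481 nt unit
template = make_array(unit.seq, 6, unit.ltr) # 6 units + closing LTR
fwd = Primer.from_template(template, 229 + 153, 21, "+", "3802")
rev = Primer.from_template(template, 229 + 39, 21, "-", "3801")
ladder = predict_ladder(template, fwd, rev)
print(ladder.lengths)
print(ladder.formula_text)
```

prints

```text
(368, 849, 1330, 1811, 2292)
368 + (481)_n
```

i.e. the smallest product (368 bp) spans one unit junction, and every
further rung adds exactly one 481 nt tandem unit — the band ladder a gel
of the inverted-PCR products shows. `examples/` contains similar short
scripts for linked search on planted genomes, tandem-array decomposition,
copy-number arithmetic, and hairpin scoring; a thin CLI exposes the same
operations (`cassarray scan|tandem|annotate|ladder|quantify|simulate|hairpin`).

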