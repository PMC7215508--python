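"""Seeded generator of Cassandra-like units, arrays, and planted genomes.

Deterministic synthetic data so that every other module is testable
without downloads: a repeat unit is an LTR (carrying concrete boxA and
boxC instantiations and followed by the PBS at the head of the internal
domain) plus an internal-domain stuffer; arrays concatenate units
head-to-tail with a closing LTR for the LTR-internal-LTR alternation; a
planted genome embeds singleton elements and arrays in uniform-random
background with truth annotations.

All randomness flows through numpy's PCG64 ``default_rng`` seeded per
spec, so outputs are byte-identical across runs and platforms. Each
degenerate motif position is fixed to one concrete base per seed so
that exact-match search at budget 0 recovers every planted feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .queries import BOXA, BOXC, PBS
from .sequences import CODE_BASES, clean_seq, revcomp

__all__ = [
    "SpecError",
    "UnitSpec",
    "Unit",
    "GenomeSpec",
    "PlantedFeature",
    "PlantedGenome",
    "FIVE_S_GENE_LEN",
    "make_unit",
    "make_5s_unit",
    "make_array",
    "plant_genome",
    "mutate",
]

#: length of the 5S rRNA gene itself.
FIVE_S_GENE_LEN = 121

# geometry defaults give an Avena-like 481 nt unit (229 nt LTR + 252 nt
# internal domain) with boxA->boxC gap 18 and boxC->PBS gap inside [5, 200]
_BOXA_OFFSET = 50
_BOXC_OFFSET = _BOXA_OFFSET + len(BOXA) + 18

#: minimum distance kept between planted features (and to the genome
#: edges); larger than the 1000 nt tandem unit-gap ceiling so separate
#: features can never chain into one array.
PLACEMENT_MARGIN = 1100


class SpecError(ValueError):
    """A generator spec is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class UnitSpec:
    """Geometry of one Cassandra-like repeat unit.

    ``boxA_offset``/``boxC_offset`` position the promoter boxes within
    the LTR; ``pbs_offset`` positions the PBS after the start of the
    internal side (0 = immediately after the LTR). Placements must
    respect the consensus query windows: boxA->boxC gap in [15, 25] and
    boxC->PBS gap in [5, 200].
    """

    ltr_len: int = 229
    internal_len: int = 252
    boxA_offset: int = _BOXA_OFFSET
    boxC_offset: int = _BOXC_OFFSET
    pbs_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        gap_ac = self.boxC_offset - (self.boxA_offset + len(BOXA))
        gap_cp = self.ltr_len - (self.boxC_offset + len(BOXC)) + self.pbs_offset
        if self.boxA_offset < 0 or self.boxC_offset + len(BOXC) > self.ltr_len:
            raise SpecError("promoter boxes must lie inside the LTR")
        if not 15 <= gap_ac <= 25:
            raise SpecError(f"boxA->boxC gap {gap_ac} outside [15, 25]")
        if not 5 <= gap_cp <= 200:
            raise SpecError(f"boxC->PBS gap {gap_cp} outside [5, 200]")
        if self.pbs_offset + len(PBS) > self.internal_len:
            raise SpecError("PBS does not fit in the internal domain")

    @property
    def unit_len(self) -> int:
        return self.ltr_len + self.internal_len


@dataclass(frozen=True)
class Unit:
    """A concrete unit sequence with its motif truth annotation.

    Truth intervals are 0-based half-open within the unit; ``internal``
    starts at the LTR end.
    """

    spec: UnitSpec
    seq: str
    ltr: str
    internal: str
    boxA: tuple[int, int]
    boxC: tuple[int, int]
    pbs: tuple[int, int]

    @property
    def chain_span(self) -> tuple[int, int]:
        """Expected linked-search chain span (boxA start to PBS end)."""
        return self.boxA[0], self.pbs[1]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]) if n else ""


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate pattern, fixed per seed."""
    return "".join(
        bases[rng.integers(0, len(bases))] for bases in (CODE_BASES[c] for c in pattern)
    )


def make_unit(spec: UnitSpec = UnitSpec()) -> Unit:
    """Build one repeat unit: LTR with boxA/boxC, then internal domain with PBS."""
    rng = np.random.default_rng(spec.seed)
    boxa = _instantiate(BOXA, rng)
    boxc = _instantiate(BOXC, rng)
    ltr = list(_random_bases(rng, spec.ltr_len))
    ltr[spec.boxA_offset:spec.boxA_offset + len(BOXA)] = boxa
    ltr[spec.boxC_offset:spec.boxC_offset + len(BOXC)] = boxc
    internal = list(_random_bases(rng, spec.internal_len))
    internal[spec.pbs_offset:spec.pbs_offset + len(PBS)] = PBS
    ltr_s, internal_s = "".join(ltr), "".join(internal)
    pbs_start = spec.ltr_len + spec.pbs_offset
    return Unit(
        spec=spec,
        seq=ltr_s + internal_s,
        ltr=ltr_s,
        internal=internal_s,
        boxA=(spec.boxA_offset, spec.boxA_offset + len(BOXA)),
        boxC=(spec.boxC_offset, spec.boxC_offset + len(BOXC)),
        pbs=(pbs_start, pbs_start + len(PBS)),
    )


def make_5s_unit(
    gene_len: int = FIVE_S_GENE_LEN, spacer_len: int = 190, seed: int = 0
) -> tuple[str, dict[str, tuple[int, int]]]:
    """A 5S rDNA-style tandem unit: gene followed by untranscribed spacer.

    The default geometry (121 nt gene + 190 nt spacer = 311 nt unit)
    mirrors the cellular 5S clusters that Cassandra arrays resemble.
    Returns the unit sequence and truth intervals.
    """
    if gene_len <= 0 or spacer_len < 0:
        raise SpecError("gene_len must be positive and spacer_len non-negative")
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, gene_len + spacer_len)
    return seq, {"gene": (0, gene_len), "spacer": (gene_len, gene_len + spacer_len)}


def make_array(unit_seq: str, n: int, closing_seq: str = "") -> str:
    """Head-to-tail concatenation of ``n`` units, plus an optional closing
    segment (the terminal LTR of an LTR-internal alternation)."""
    if n < 1:
        raise SpecError("an array needs n >= 1 units")
    return clean_seq(unit_seq) * n + clean_seq(closing_seq)


def mutate(seq: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Independent per-site substitution to a uniformly chosen other base."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    s = clean_seq(seq)
    if rate == 0 or not s:
        return s
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hit = np.nonzero(rng.random(len(s)) < rate)[0]
    if not len(hit):
        return s
    out = list(s)
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    # non-ACGT codes mutate to a uniform base
    shifts = rng.integers(0, 3, len(hit))
    for pos, k in zip(hit, shifts):
        base = out[pos]
        out[pos] = others[base][k] if base in others else "ACGT"[k]
    return "".join(out)


@dataclass(frozen=True)
class GenomeSpec:
    """A background genome with planted singleton elements and tandem arrays.

    ``arrays`` lists the unit counts of the arrays to plant. Mutations
    (substitutions at ``mutation_rate`` per site) apply only within
    planted features; the background is already random.
    ``inter_unit_gap`` inserts extra spacer between array units (0 =
    strict head-to-tail).
    """

    length: int = 100_000
    n_singletons: int = 5
    arrays: tuple[int, ...] = (3,)
    mutation_rate: float = 0.0
    inter_unit_gap: int = 0
    minus_fraction: float = 0.0
    unit: UnitSpec = field(default_factory=UnitSpec)
    seq_id: str = "synthetic_genome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SpecError("genome length must be positive")
        if self.n_singletons < 0 or any(n < 1 for n in self.arrays):
            raise SpecError("feature counts must be sensible")
        if not 0 <= self.mutation_rate < 1:
            raise SpecError("mutation_rate must be in [0, 1)")
        if not 0 <= self.minus_fraction <= 1:
            raise SpecError("minus_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedFeature:
    """Truth record for one planted feature, plus-strand coordinates."""

    kind: str                 # "singleton" or "array"
    start: int
    end: int
    strand: str
    n_units: int
    chain_spans: tuple[tuple[int, int], ...]  # expected linked-search spans


@dataclass(frozen=True)
class PlantedGenome:
    seq_id: str
    seq: str
    features: tuple[PlantedFeature, ...]
    spec: GenomeSpec


def _feature_seq(unit: Unit, n_units: int, inter_gap: int, rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """Element/array sequence with per-unit chain spans (local coordinates)."""
    spacer = _random_bases(rng, inter_gap) if inter_gap else ""
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    offset = 0
    for i in range(n_units):
        parts.append(unit.seq)
        a, b = unit.chain_span
        spans.append((offset + a, offset + b))
        offset += len(unit.seq)
        if i + 1 < n_units and spacer:
            parts.append(spacer)
            offset += len(spacer)
    parts.append(unit.ltr)  # closing LTR completes the alternation
    return "".join(parts), spans


def plant_genome(spec: GenomeSpec = GenomeSpec()) -> PlantedGenome:
    """Generate a background genome with planted features and truth.

    Features are placed non-overlapping with at least
    :data:`PLACEMENT_MARGIN` nt of background between them (and to the
    edges) by distributing the free space with a seeded multinomial;
    a spec that cannot fit raises :class:`SpecError`. Fully reproducible
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    unit = make_unit(replace(spec.unit, seed=spec.seed))

    plan: list[tuple[str, int]] = [("singleton", 1)] * spec.n_singletons
    plan += [("array", n) for n in spec.arrays]
    rng.shuffle(plan_idx := np.arange(len(plan)))
    plan = [plan[i] for i in plan_idx]

    built: list[tuple[str, int, str, str, list[tuple[int, int]]]] = []
    for kind, n_units in plan:
        seq, spans = _feature_seq(unit, n_units, spec.inter_unit_gap, rng)
        seq = mutate(seq, spec.mutation_rate, rng)
        strand = "-" if rng.random() < spec.minus_fraction else "+"
        if strand == "-":
            L = len(seq)
            seq = revcomp(seq)
            spans = sorted((L - b, L - a) for a, b in spans)
        built.append((kind, n_units, strand, seq, spans))

    if not built:
        return PlantedGenome(
            seq_id=spec.seq_id,
            seq=_random_bases(rng, spec.length),
            features=(),
            spec=spec,
        )
    total_feat = sum(len(b[3]) for b in built)
    n_slots = len(built) + 1
    free = spec.length - total_feat - n_slots * PLACEMENT_MARGIN
    if free < 0:
        raise SpecError(
            f"cannot place {len(built)} features ({total_feat} nt) with "
            f"{PLACEMENT_MARGIN} nt margins in a {spec.length} nt genome"
        )
    extra = rng.multinomial(free, [1.0 / n_slots] * n_slots) if built else [free]

    chunks: list[str] = []
    features: list[PlantedFeature] = []
    pos = 0
    for i, (kind, n_units, strand, seq, spans) in enumerate(built):
        gap = PLACEMENT_MARGIN + int(extra[i])
        chunks.append(_random_bases(rng, gap))
        pos += gap
        chunks.append(seq)
        features.append(
            PlantedFeature(
                kind=kind,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                n_units=n_units,
                chain_spans=tuple((pos + a, pos + b) for a, b in spans),
            )
        )
        pos += len(seq)
    tail = spec.length - pos
    chunks.append(_random_bases(rng, tail))
    genome = "".join(chunks)
    assert len(genome) == spec.length
    features.sort(key=lambda f: f.start)
    return PlantedGenome(
        seq_id=spec.seq_id, seq=genome, features=tuple(features), spec=spec
    )
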