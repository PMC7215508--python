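"""Copy-number estimation arithmetic.

qPCR standard curves (Ct against log10 concentration; a perfect
doubling assay has slope -1/log10(2) = -3.32 and efficiency
10**(-1/slope) = 2), relative quantification against a reference of
known copy number, dot-blot absolute copy number from hybridization
count ratios, the total/tandem/singleton decomposition, and simple
group-comparison statistics.

Mass-to-length conversion uses 978 Mbp per pg of double-stranded DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BP_PER_PG",
    "DilutionPoint",
    "StandardCurve",
    "Reference",
    "CopiesResult",
    "DotBlotMeasurement",
    "DotBlotResult",
    "CopyNumberEstimate",
    "GroupComparison",
    "FitError",
    "fit_standard_curve",
    "copies_from_ct",
    "dot_blot_copies",
    "copies_per_genome_from_fraction",
    "singleton_count",
    "compare_groups",
]

#: base pairs of double-stranded DNA per picogram.
BP_PER_PG = 978e6


class FitError(ValueError):
    """A calibration fit cannot be performed on the given data."""


@dataclass(frozen=True)
class DilutionPoint:
    """One point of a dilution series: template mass (ng) and its Ct."""

    concentration: float
    ct: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration line: Ct = intercept + slope * log10(concentration)."""

    slope: float
    intercept: float
    r2: float
    efficiency: float
    ct_min: float
    ct_max: float


@dataclass(frozen=True)
class Reference:
    """A calibrator of known copy number at a known concentration."""

    copies: float
    concentration: float


@dataclass(frozen=True)
class CopiesResult:
    copies: float
    concentration: float
    extrapolated: bool


@dataclass(frozen=True)
class DotBlotMeasurement:
    """Inputs of an absolute dot-blot copy-number estimate.

    Hybridization counts for the genomic spot and a control spot of a
    probe-matched fragment with a known number of copies.
    """

    genomic_cpm: float
    genomic_ng: float
    fragment_copies: float
    fragment_cpm: float
    probe_len: int
    genome_size: float

    def __post_init__(self) -> None:
        for name in ("genomic_ng", "fragment_copies", "probe_len", "genome_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.genomic_cpm < 0:
            raise ValueError("genomic_cpm must be non-negative")
        if self.fragment_cpm <= 0:
            raise ZeroDivisionError("control fragment cpm must be positive")


@dataclass(frozen=True)
class DotBlotResult:
    copies_per_ng: float
    copies_per_genome: float


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Total / tandem / singleton copies per genome (singleton = total - tandem)."""

    total: float
    tandem: float

    def __post_init__(self) -> None:
        if self.tandem < 0 or self.total < self.tandem:
            raise ValueError("need total >= tandem >= 0")

    @property
    def singleton(self) -> float:
        return self.total - self.tandem


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    means: tuple[float, ...]
    test: str
    degenerate: bool = False


def fit_standard_curve(points: Sequence[DilutionPoint]) -> StandardCurve:
    """Least-squares line of Ct versus log10(concentration).

    Needs at least 3 points with distinct concentrations. The
    amplification efficiency (fold per cycle) is 10**(-1/slope) for a
    negative slope; 2.0 means perfect doubling.
    """
    if len(points) < 3:
        raise FitError("need at least 3 dilution points")
    x = np.log10([p.concentration for p in points])
    y = np.array([p.ct for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("dilution series has zero variance in concentration")
    fit = stats.linregress(x, y)
    efficiency = 10 ** (-1.0 / fit.slope) if fit.slope < 0 else math.nan
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
        ct_min=float(y.min()),
        ct_max=float(y.max()),
    )


def copies_from_ct(
    ct: float, curve: StandardCurve, reference: Reference, *, ct_tolerance: float = 0.0
) -> CopiesResult:
    """Relative quantification of a sample Ct against a standard curve.

    The curve is inverted to a concentration, then scaled by the
    reference's copies-per-concentration. A Ct by more than
    ``ct_tolerance`` outside the calibrated range is flagged as
    extrapolated (not fatal).
    """
    if curve.slope == 0:
        raise FitError("cannot invert a flat standard curve")
    concentration = 10 ** ((ct - curve.intercept) / curve.slope)
    copies = reference.copies * concentration / reference.concentration
    extrapolated = not (
        curve.ct_min - ct_tolerance <= ct <= curve.ct_max + ct_tolerance
    )
    return CopiesResult(copies=copies, concentration=concentration, extrapolated=extrapolated)


def dot_blot_copies(meas: DotBlotMeasurement) -> DotBlotResult:
    """Absolute copy number from hybridization count ratios.

    copies per ng = (genomic cpm / ng) x (fragment copies / fragment
    cpm); per-genome copies scale by the haploid genome mass derived
    from ``genome_size`` at 978 Mbp/pg.
    """
    per_ng = (meas.genomic_cpm / meas.genomic_ng) * (
        meas.fragment_copies / meas.fragment_cpm
    )
    genome_mass_ng = meas.genome_size / BP_PER_PG / 1000.0  # pg -> ng
    return DotBlotResult(copies_per_ng=per_ng, copies_per_genome=per_ng * genome_mass_ng)


def copies_per_genome_from_fraction(
    mass_fraction: float, genome_size: float, probe_len: int
) -> int:
    """Copies per genome implied by a genomic mass fraction of the probe.

    floor(mass_fraction * genome_size / probe_len): a probe making up
    0.05% of a 4.8 Gbp genome at 388 nt per copy is 6,185 copies.
    """
    if not 0 <= mass_fraction < 1:
        raise ValueError("mass_fraction must be in [0, 1)")
    if probe_len <= 0 or genome_size <= 0:
        raise ValueError("genome_size and probe_len must be positive")
    return math.floor(mass_fraction * genome_size / probe_len)


def singleton_count(total: float, tandem: float) -> float:
    """Singleton copies by subtracting the tandems from the total."""
    if tandem < 0 or total < tandem:
        raise ValueError(
            f"tandem copies ({tandem}) cannot exceed total copies ({total})"
        )
    return total - tandem


def compare_groups(
    *groups: Sequence[float], equal_var: bool = False
) -> GroupComparison:
    """Two-sample t test (Welch by default) or one-way ANOVA for >= 3 groups.

    Zero-variance degeneracies are handled explicitly: identical
    constant groups give t = 0, p = 1; constant groups with different
    means give the p -> 0 limit, flagged as degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    means = tuple(float(a.mean()) for a in arrays)
    if len(arrays) > 2:
        stat, p = stats.f_oneway(*arrays)
        return GroupComparison(float(stat), float(p), means, "anova")
    a, b = arrays
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if means[0] == means[1]:
            return GroupComparison(0.0, 1.0, means, "degenerate", degenerate=True)
        sign = 1.0 if means[0] > means[1] else -1.0
        return GroupComparison(sign * math.inf, 0.0, means, "degenerate", degenerate=True)
    stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        float(stat), float(p), means, "student_t" if equal_var else "welch_t"
    )
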