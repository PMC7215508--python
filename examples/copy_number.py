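"""Copy-number arithmetic: qPCR calibration, dot blot, singleton split.

Fits a standard curve to a noiseless perfect-doubling dilution series
(slope -3.32, efficiency 2.0), quantifies a sample Ct against a
reference, evaluates the dot-blot worked example (a probe at 0.05% of
a 4.8 Gbp genome, 388 nt per copy, is 6,185 copies), and splits total
copies into tandem and singleton fractions with a Welch t comparison
between two slope populations.
"""

import math

from cassarray import (
    DilutionPoint,
    Reference,
    compare_groups,
    copies_from_ct,
    copies_per_genome_from_fraction,
    fit_standard_curve,
    singleton_count,
)

points = [DilutionPoint(10 / 2 ** k, 20 + k) for k in range(8)]
curve = fit_standard_curve(points)
print(f"standard curve: slope {curve.slope:.4f} cycles/log10, "
      f"efficiency {curve.efficiency:.3f}, r2 {curve.r2:.4f}")

ref = Reference(copies=1000, concentration=10.0)
sample_ct = curve.intercept + curve.slope * math.log10(2.5)
result = copies_from_ct(sample_ct, curve, ref)
print(f"sample at Ct {sample_ct:.2f}: {result.copies:.0f} copies "
      f"(extrapolated: {result.extrapolated})")

copies = copies_per_genome_from_fraction(0.0005, 4.8e9, 388)
print(f"dot-blot worked example: {copies} copies per genome")

total, tandem = 3182, 431
print(f"singleton copies: {total} total - {tandem} tandem = "
      f"{singleton_count(total, tandem)}")

south = [3100, 3300, 3150, 3250]
north = [2500, 2700, 2600, 2640]
cmp = compare_groups(south, north)
print(f"south vs north slope: means {cmp.means[0]:.0f} vs {cmp.means[1]:.0f}, "
      f"Welch t = {cmp.statistic:.2f}, p = {cmp.pvalue:.4f}")
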