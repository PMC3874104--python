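"""Mendelian viability and cortical morphometry statistics.

A heterozygote intercross should yield 1:2:1 wild-type : het : homozygote
offspring. A deficit of homozygotes quantifies lethality: chi-square tests
the segregation, and penetrance = 1 - observed/expected missing-class ratio.
Morphometric group comparisons use mean +- SEM, an equal-variance t-test and
signed percent change.
"""

from lincscreen import (
    CrossCounts,
    compare_groups,
    mendelian_test,
    penetrance_percent,
    percent_change,
    survival_proportion,
)
from lincscreen.synthetic import gen_morphometry

# a weaning census with a clear homozygote deficit (total 128)
cross = CrossCounts("autosomal_het_x_het", {"+/+": 45, "+/-": 70, "-/-": 13})
res = mendelian_test(cross)
print("observed:", res.observed)
print("expected:", {k: round(v, 1) for k, v in res.expected.items()})
print(f"chi-square = {res.chi_square:.3f} (df={res.df}), p = {res.p:.2e}")
print(f"lethality penetrance = {100 * res.penetrance_of_lethality:.0f}%")
print(f"(a census of 68 with 6 homozygotes gives {penetrance_percent(6, 17)}%)")

print(f"\npostnatal survival: 5/10 deaths = {survival_proportion(5, 10):.0f}% mortality")

# neuron counts per section: mutant vs wild type
counts = gen_morphometry({"mutant": 1432.0, "wild_type": 1176.0}, 60.0, 10, seed=2)
comp = compare_groups(
    counts.loc[counts.group == "mutant", "value"],
    counts.loc[counts.group == "wild_type", "value"],
    "mutant", "wild_type",
)
print(f"\nmutant  : mean = {comp.mean[0]:.0f} +- {comp.sem[0]:.0f} (n={comp.n[0]})")
print(f"wildtype: mean = {comp.mean[1]:.0f} +- {comp.sem[1]:.0f} (n={comp.n[1]})")
print(f"t = {comp.t:.2f} (df={comp.df}), p = {comp.p:.1e}, "
      f"change = {comp.percent_change:+.2f}%")
print(f"from the printed group means alone: {percent_change(1432, 1176):+.2f}%")
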