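"""Mendelian segregation, penetrance, survival and morphometric statistics.

Genotype counts from an intercross are compared with Mendelian expectations
by a chi-square goodness-of-fit test; missing homozygous mutants quantify the
penetrance of lethality, 1 - observed/expected. Group morphometry (layer
thicknesses, cell counts) is summarised as mean +- SEM and compared with an
unpaired, equal-variance Student's t-test; effect sizes are reported as
signed percent change against the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

# Mendelian class proportions per cross design. The X-linked preset covers a
# heterozygous female x wild-type male cross (uniform quarters over female
# +/+ and +/- and male +/Y and -/Y); other designs go through custom ratios.
CROSS_PROPORTIONS: Dict[str, Dict[str, float]] = {
    "autosomal_het_x_het": {"+/+": 0.25, "+/-": 0.5, "-/-": 0.25},
    "xlinked_hetfemale_x_wtmale": {
        "F+/+": 0.25,
        "F+/-": 0.25,
        "M+/Y": 0.25,
        "M-/Y": 0.25,
    },
    "hom_x_hom": {"-/-": 1.0},
}

# the genotype class subject to lethality in each cross design
NULL_CLASS: Dict[str, str] = {
    "autosomal_het_x_het": "-/-",
    "xlinked_hetfemale_x_wtmale": "M-/Y",
    "hom_x_hom": "-/-",
}


@dataclass
class CrossCounts:
    """Observed genotype-class counts from one intercross census."""

    cross_type: str
    counts: Dict[str, int]
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cross_type not in CROSS_PROPORTIONS:
            raise ValueError(f"unknown cross_type {self.cross_type!r}")
        expected_classes = set(CROSS_PROPORTIONS[self.cross_type])
        if set(self.counts) != expected_classes:
            raise ValueError(
                f"genotype classes {sorted(self.counts)} do not match "
                f"cross {self.cross_type!r} ({sorted(expected_classes)})"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("genotype counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class MendelianResult:
    cross_type: str
    observed: Dict[str, int]
    expected: Dict[str, float]
    chi_square: float
    df: int
    p: float
    penetrance_of_lethality: Optional[float]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n: Tuple[int, int]
    mean: Tuple[float, float]
    sem: Tuple[float, float]
    t: float
    df: int
    p: float
    percent_change: float  # 100*(mean_a - mean_b)/mean_b, b the reference


def expected_mendelian(
    total: int,
    cross_type: str,
    ratios: Optional[Dict[str, float]] = None,
) -> Dict[str, float]:
    """Unrounded expected counts per genotype class for a census of ``total``.

    ``ratios`` overrides the preset proportions for non-standard designs.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if ratios is None:
        if cross_type not in CROSS_PROPORTIONS:
            raise ValueError(f"unknown cross_type {cross_type!r}")
        ratios = CROSS_PROPORTIONS[cross_type]
    norm = sum(ratios.values())
    return {cls: total * frac / norm for cls, frac in ratios.items()}


def chi_square_goodness(
    observed: Dict[str, int], expected: Dict[str, float]
) -> Tuple[float, int, float]:
    """Chi-square goodness of fit: sum (obs-exp)^2/exp, df = classes - 1."""
    if set(observed) != set(expected):
        raise ValueError("observed and expected class sets differ")
    classes = sorted(observed)
    exp = np.array([expected[c] for c in classes], dtype=float)
    if (exp <= 0).any():
        raise ValueError("expected counts must all be > 0")
    obs = np.array([observed[c] for c in classes], dtype=float)
    statistic, p = stats.chisquare(obs, exp)
    return float(statistic), len(classes) - 1, float(p)


def penetrance_of_lethality(observed_hom: int, expected_hom: float) -> float:
    """Fraction of expected mutants missing: max(0, 1 - observed/expected).

    Clamped at 0 because sampling noise can push observed above expected.
    """
    if expected_hom <= 0:
        raise ValueError("expected_hom must be > 0")
    if observed_hom < 0:
        raise ValueError("observed_hom must be >= 0")
    return max(0.0, 1.0 - observed_hom / expected_hom)


def penetrance_percent(observed_hom: int, expected_hom: float) -> int:
    """Penetrance as a percent rounded to the nearest integer."""
    return round(100.0 * penetrance_of_lethality(observed_hom, expected_hom))


def estimate_penetrance(cross: CrossCounts) -> Optional[float]:
    """Penetrance estimated from a census alone.

    The expected count of the lethality-prone class is inferred from the
    unaffected classes (they are untouched by lethality), e.g. (wt + het)/3
    for an autosomal het x het cross; None when the design leaves no
    unaffected class (hom x hom).
    """
    null_class = NULL_CLASS[cross.cross_type]
    props = CROSS_PROPORTIONS[cross.cross_type]
    p_null = props[null_class]
    others = sum(v for c, v in cross.counts.items() if c != null_class)
    if others == 0 or p_null >= 1.0:
        return None
    expected_null = others * p_null / (1.0 - p_null)
    return penetrance_of_lethality(cross.counts[null_class], expected_null)


def mendelian_test(cross: CrossCounts) -> MendelianResult:
    """Chi-square against Mendelian expectations plus lethality penetrance.

    Expected counts follow the usual census convention: the observed total
    redistributed at the cross's Mendelian proportions.
    """
    expected = expected_mendelian(cross.total, cross.cross_type)
    if len(expected) < 2:
        raise ValueError("chi-square needs >= 2 genotype classes")
    statistic, df, p = chi_square_goodness(cross.counts, expected)
    null_class = NULL_CLASS[cross.cross_type]
    exp_null = expected[null_class]
    penetrance = (
        penetrance_of_lethality(cross.counts[null_class], exp_null)
        if exp_null > 0
        else None
    )
    return MendelianResult(
        cross_type=cross.cross_type,
        observed=dict(cross.counts),
        expected=expected,
        chi_square=statistic,
        df=df,
        p=p,
        penetrance_of_lethality=penetrance,
    )


def survival_proportion(deaths: int, at_risk: int) -> float:
    """Percent of animals dying, 100*deaths/at_risk (raw, unrounded)."""
    if at_risk < 1:
        raise ValueError("at_risk must be >= 1")
    if not (0 <= deaths <= at_risk):
        raise ValueError("deaths must lie in [0, at_risk]")
    return 100.0 * deaths / at_risk


def group_summary(values: Sequence[float]) -> Tuple[int, float, float]:
    """(n, mean, SEM) with SEM = sample sd (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need n >= 2 per group")
    return n, float(values.mean()), float(values.std(ddof=1) / np.sqrt(n))


def ttest_equal_var(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t-test, two-sided.

    Zero pooled variance: equal means give (t=0, p=1); unequal means give an
    infinite-t sentinel with p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in each group")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def percent_change(mean_test: float, mean_reference: float) -> float:
    """Signed percent change, 100*(test - reference)/reference."""
    if mean_reference == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_test - mean_reference) / mean_reference


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "mutant",
    label_b: str = "wild_type",
) -> GroupComparison:
    """Mean +- SEM per group, equal-variance t-test, percent change vs B."""
    n_a, mean_a, sem_a = group_summary(values_a)
    n_b, mean_b, sem_b = group_summary(values_b)
    t, df, p = ttest_equal_var(values_a, values_b)
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n=(n_a, n_b),
        mean=(mean_a, mean_b),
        sem=(sem_a, sem_b),
        t=t,
        df=df,
        p=p,
        percent_change=percent_change(mean_a, mean_b),
    )
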