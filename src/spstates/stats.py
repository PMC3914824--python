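"""Study-level statistics: Spearman correlation, chance-model chi-square,
and percent changes.

The chance model for the universality split treats each cluster's
occurrence across C conditions as Binomial(C, 0.5) conditioned on at
least one occurrence (only observed clusters enter the table; the
unconditioned model would allow an unobservable zero-count category —
``conditioned=False`` switches it off). Its mass is aggregated into the
unique/optional/universal ranges and compared to the observed category
counts with a chi-square goodness-of-fit test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CategoryNull",
    "spearman",
    "category_null",
    "chisq_gof",
    "percent_change",
]

CATEGORIES = ("unique", "optional", "universal")


@dataclass(frozen=True)
class CategoryNull:
    """Chance distribution of cluster categories across conditions.

    expected_probs are ordered (unique, optional, universal) and sum
    to 1; the unconditioned expected occurrence count is
    n_conditions * p_occurrence (6.5 for 13 conditions at chance 0.5).
    """

    n_conditions: int
    p_occurrence: float
    expected_probs: tuple[float, float, float]

    @property
    def expected_mean_occurrences(self) -> float:
        return self.n_conditions * self.p_occurrence


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson of average ranks, ties averaged)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(sps.spearmanr(x, y).statistic)


def category_null(
    n_conditions: int,
    p_occurrence: float = 0.5,
    universal_fraction: float = 0.85,
    conditioned: bool = True,
) -> CategoryNull:
    """Chance probabilities of the unique/optional/universal categories.

    Counts follow Binomial(n_conditions, p_occurrence), conditioned on
    >= 1 by default. unique aggregates count 1, universal counts
    >= ceil(universal_fraction * n_conditions), optional the rest.
    """
    if n_conditions < 2:
        raise ValueError("need at least two conditions")
    counts = np.arange(1, n_conditions + 1)
    pmf = sps.binom.pmf(counts, n_conditions, p_occurrence)
    if conditioned:
        pmf = pmf / (1.0 - sps.binom.pmf(0, n_conditions, p_occurrence))
    uni_cut = math.ceil(universal_fraction * n_conditions)
    p_unique = float(pmf[counts == 1].sum())
    p_universal = float(pmf[counts >= uni_cut].sum())
    p_optional = float(pmf[(counts > 1) & (counts < uni_cut)].sum())
    return CategoryNull(n_conditions, p_occurrence,
                        (p_unique, p_optional, p_universal))


def chisq_gof(observed, null: CategoryNull, total: int) -> tuple[float, float]:
    """Chi-square goodness of fit of observed category counts to the null.

    X^2 = sum (obs - exp)^2 / exp with exp = total * expected_probs;
    p from chi-square with k-1 degrees of freedom.
    """
    observed = np.asarray(observed, float)
    expected = total * np.asarray(null.expected_probs, float)
    if observed.size != expected.size:
        raise ValueError("category count mismatch")
    if not np.isclose(observed.sum(), total):
        raise ValueError("observed counts must sum to the cluster total")
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    stat = float(np.sum((observed - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=observed.size - 1))
    return stat, p


def percent_change(reference: float, other: float) -> float:
    """100 * (other - reference) / reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (other - reference) / reference
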