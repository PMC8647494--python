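"""Liability-threshold categorical traits.

A k-category threshold trait is configured by k-1 incidences counted from the
upper tail of the liability (the remainder forms the last category).  The
liability is assumed standard normal, so the thresholds are the single-tailed
normal deviates t_j = Phi^{-1}(1 - cumulative incidence).  In simulation the
liability is the trait's continuous phenotype standardized by its sample mean
and SD, which keeps realized incidences calibrated regardless of the trait's
phenotypic variance.  Category 1 is the upper (affected) tail; boundary values
go to the lower category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import ValidationError


@dataclass
class CategoricalPhenotypes:
    """Standardized liabilities with their category labels in {1..k}."""

    liability: np.ndarray
    category: np.ndarray
    n_categories: int

    def __post_init__(self):
        self.liability = np.asarray(self.liability, dtype=float)
        self.category = np.asarray(self.category, dtype=np.int32)
        if self.liability.shape != self.category.shape:
            raise ValidationError("liability and category columns must align")


def thresholds_from_incidences(incidences) -> np.ndarray:
    """Threshold values (ascending) for upper-tail incidences (pi_1..pi_{k-1})."""
    inc = np.atleast_1d(np.asarray(incidences, dtype=float))
    if inc.size == 0:
        raise ValidationError("a threshold trait needs at least one incidence (k >= 2)")
    if np.any((inc <= 0.0) | (inc >= 1.0)):
        raise ValidationError("incidences must lie strictly in (0, 1)")
    cum = np.cumsum(inc)
    if cum[-1] >= 1.0:
        raise ValidationError(
            f"cumulative incidence {cum[-1]:.3f} must be < 1 "
            "(the remainder forms the last category)"
        )
    # categories counted from the upper tail: t_j = Phi^-1(1 - cum_j)
    t = stats.norm.ppf(1.0 - cum)
    return np.sort(t)


def categorize(
    liability: np.ndarray,
    thresholds: np.ndarray,
    standardize: bool = True,
) -> CategoricalPhenotypes:
    """Assign categories (1 = upper tail) by comparing liability to thresholds.

    With *standardize* (default) the input is first standardized by its sample
    mean and SD; pass ``standardize=False`` if the column is already on the
    liability scale.  A value exactly equal to a threshold falls in the lower
    category (strict inequality is required for the upper one).
    """
    liab = np.asarray(liability, dtype=float)
    t = np.sort(np.atleast_1d(np.asarray(thresholds, dtype=float)))
    if t.size == 0:
        raise ValidationError("at least one threshold is required (k >= 2)")
    if standardize:
        sd = liab.std()
        if sd == 0:
            raise ValidationError("cannot standardize a constant liability column")
        liab = (liab - liab.mean()) / sd
    k = t.size + 1
    below = np.searchsorted(t, liab, side="left")  # thresholds strictly < value
    category = k - below
    return CategoricalPhenotypes(liab, category, k)


def estimate_incidence(categories: CategoricalPhenotypes) -> np.ndarray:
    """Observed category proportions, ordered category 1 (upper tail) first."""
    if categories.category.size == 0:
        raise ValidationError("no categorical records")
    counts = np.bincount(categories.category, minlength=categories.n_categories + 1)
    return counts[1:] / categories.category.size
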