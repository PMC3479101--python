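"""Summary statistics and dosing arithmetic.

Every group comparison in this package reports mean ± SEM and a two-tailed
paired Student t test on per-replicate values; when group sizes differ a
Welch unpaired test is used as an explicit fallback. Significance is flagged
with the usual star thresholds (0.05, 0.01, 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "sem",
    "significance_flag",
    "paired_t_test",
    "welch_t_test",
    "supplement_molarity",
]

#: p-value thresholds and their flags, from most to least stringent.
FLAG_THRESHOLDS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass
class GroupComparison:
    """Result of a two-group comparison (means in the units of the input)."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significance_flag: str = "none"
    test: str = "paired"  # "paired" | "welch" | "non-computable"
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def sem(values) -> float:
    """Standard error of the mean: sample SD (n-1 denominator) / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError("sem requires at least 2 values")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def significance_flag(p_value: float) -> str:
    """Map a p-value to the star convention used in the figures."""
    if not np.isfinite(p_value):
        return "none"
    for threshold, flag in FLAG_THRESHOLDS:
        if p_value < threshold:
            return flag
    return "none"


def _summaries(a: np.ndarray, b: np.ndarray):
    return float(np.mean(a)), float(np.mean(b)), sem(a), sem(b)


def paired_t_test(a, b) -> GroupComparison:
    """Two-tailed paired Student t test on differences d = a - b.

    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1. Zero-variance differences with
    a nonzero mean are reported with p flagged "<1e-12" rather than dividing
    by zero; zero-variance with zero mean is t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            "paired_t_test requires equal-length 1-D samples; "
            "use welch_t_test for unequal group sizes"
        )
    n = a.size
    if n < 2:
        raise ValueError("paired_t_test requires at least 2 pairs")
    d = a - b
    mean_a, mean_b, sem_a, sem_b = _summaries(a, b)
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if float(np.mean(d)) == 0.0:
            return GroupComparison(mean_a, mean_b, sem_a, sem_b,
                                   0.0, df, 1.0, "none", "paired")
        t = np.inf if np.mean(d) > 0 else -np.inf
        return GroupComparison(
            mean_a, mean_b, sem_a, sem_b, t, df, 0.0, "p<0.001", "paired",
            note="zero-variance paired differences; p flagged <1e-12",
        )
    t = float(np.mean(d) / (sd_d / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(mean_a, mean_b, sem_a, sem_b, t, df, p,
                           significance_flag(p), "paired")


def welch_t_test(a, b) -> GroupComparison:
    """Two-tailed Welch (unequal-variance, unpaired) t test."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per group")
    res = sps.ttest_ind(a, b, equal_var=False)
    mean_a, mean_b, sem_a, sem_b = _summaries(a, b)
    p = float(res.pvalue)
    return GroupComparison(mean_a, mean_b, sem_a, sem_b, float(res.statistic),
                           float(res.df), p, significance_flag(p), "welch")


def supplement_molarity(mass_mg: float, molar_mass_g_per_mol: float,
                        volume_L: float) -> float:
    """Concentration in µM of mass_mg of a compound dissolved in volume_L.

    Used for vitamin-supplement dosing arithmetic, e.g. 5 mg niacin
    (123.11 g/mol) in 6 L of blood is 6.77 µM.
    """
    if mass_mg <= 0 or molar_mass_g_per_mol <= 0 or volume_L <= 0:
        raise ValueError("mass, molar mass, and volume must all be positive")
    mol = (mass_mg / 1000.0) / molar_mass_g_per_mol
    return mol / volume_L * 1e6


#: Molar mass of niacin / nicotinic acid (g/mol), for dosing examples.
NIACIN_G_PER_MOL = 123.11
#: Molar mass of beta-NAD (g/mol).
BETA_NAD_G_PER_MOL = 663.43
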