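"""Statistical summaries for selection outcomes and validation assays.

Three independent readouts:

* genus-enrichment testing: Pearson chi-squared (df=1, no continuity
  correction) on a 2x2 table of recovered vs background genera crossed with
  Cas9 carriage;
* plasmid-protection assays: per-construct mean and SEM of
  log10(Kan^R / total cfu), equal-variance two-sample t-tests between named
  comparison pairs, Bonferroni-corrected;
* T7 endonuclease I indel quantification from gel band intensities:
  indel% = 100 * (1 - sqrt(1 - fraction cleaved)); fraction cleaved =
  sum(cleavage bands) / (sum(cleavage bands) + parent band).  The square
  root is the standard heteroduplex-fraction derivation; a literal
  "multiply by 0.5" reading (which would assign 50% indels to an uncut
  control) is available behind a flag for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PSEUDOCOUNT_CFU = 0.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = group membership, cols = trait presence."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d,
                self.a + self.c, self.b + self.d)


def chi_squared_enrichment(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the two-sided p-value
    comes from the chi-squared survival function.
    """
    r1, r2, c1, c2 = table.marginals
    if 0 in (r1, r2, c1, c2):
        raise ValueError("chi-squared undefined with a zero marginal")
    num = table.n * (table.a * table.d - table.b * table.c) ** 2
    chi2 = num / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def recovered_vs_background_table(recovered_with_trait: int,
                                  recovered_total: int,
                                  background_with_trait: int,
                                  background_total: int) -> ContingencyTable2x2:
    """Non-overlapping 2x2 construction for an enrichment test.

    The recovered genera are members of the reference set, so the second row
    is the *remaining* background (background minus recovered).
    """
    return ContingencyTable2x2(
        a=recovered_with_trait,
        b=recovered_total - recovered_with_trait,
        c=background_with_trait - recovered_with_trait,
        d=(background_total - recovered_total)
          - (background_with_trait - recovered_with_trait),
    )


def bonferroni(p_values: list[float]) -> list[float]:
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


@dataclass
class ProtectionAssay:
    """Replicate CFU counts for one construct under one condition."""

    construct: str
    condition: str  # "induced" / "uninduced"
    kanr_cfu: list[float]
    total_cfu: list[float]
    pseudocount_used: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        if len(self.kanr_cfu) != len(self.total_cfu):
            raise ValueError("replicate lists must have equal length")
        if len(self.kanr_cfu) < 2:
            raise ValueError("need >= 2 replicates for testing")
        if any(k > t for k, t in zip(self.kanr_cfu, self.total_cfu)):
            raise ValueError("kanr_cfu cannot exceed total_cfu")

    def log10_proportions(self) -> np.ndarray:
        """log10(Kan^R / total); zero Kan^R counts get a 0.5-cfu pseudocount."""
        kanr = np.asarray(self.kanr_cfu, dtype=float)
        if (kanr == 0).any():
            self.pseudocount_used = True
            kanr = np.where(kanr == 0, PSEUDOCOUNT_CFU, kanr)
        return np.log10(kanr / np.asarray(self.total_cfu, dtype=float))


def protection_summary(assays: list[ProtectionAssay],
                       comparisons: list[tuple[tuple[str, str], tuple[str, str]]],
                       alpha: float = 0.01,
                       equal_var: bool = True) -> pd.DataFrame:
    """Summarize plasmid-protection assays and test the named comparisons.

    ``comparisons`` lists pairs of (construct, condition) keys; each pair
    gets an equal-variance (Student's) two-sided t-test by default, Welch
    with ``equal_var=False``.  p-values are Bonferroni-corrected over the
    comparison family and flagged significant at ``alpha``.
    """
    by_key = {(a.construct, a.condition): a for a in assays}
    rows, raw_p = [], []
    for key_a, key_b in comparisons:
        xa = by_key[key_a].log10_proportions()
        xb = by_key[key_b].log10_proportions()
        if np.allclose(xa.var(ddof=1) + xb.var(ddof=1), 0.0) \
                and np.isclose(xa.mean(), xb.mean()):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        rows.append({
            "construct_a": key_a[0], "condition_a": key_a[1],
            "construct_b": key_b[0], "condition_b": key_b[1],
            "mean_log10_a": float(xa.mean()),
            "sem_log10_a": float(stats.sem(xa)),
            "mean_log10_b": float(xb.mean()),
            "sem_log10_b": float(stats.sem(xb)),
            "t_statistic": float(t_stat),
            "p_value": float(p),
            "pseudocount_used": (by_key[key_a].pseudocount_used
                                 or by_key[key_b].pseudocount_used),
        })
        raw_p.append(float(p))
    adj = bonferroni(raw_p)
    df = pd.DataFrame(rows)
    df["p_adjusted"] = adj
    df["significant"] = df["p_adjusted"] < alpha
    return df


@dataclass(frozen=True)
class GelQuantification:
    """Band intensities from one T7E1 lane."""

    cleavage_band_intensities: tuple[float, ...]
    parent_band_intensity: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cleavage_band_intensities) \
                or self.parent_band_intensity < 0:
            raise ValueError("band intensities must be non-negative")

    @property
    def fraction_cleaved(self) -> float | None:
        cleaved = sum(self.cleavage_band_intensities)
        total = cleaved + self.parent_band_intensity
        if total == 0:
            return None
        return cleaved / total


def indel_percent(gel: GelQuantification, literal_half: bool = False
                  ) -> float | None:
    """Indel frequency (%) from a T7E1 gel lane; None for an all-zero lane.

    Default: 100 * (1 - sqrt(1 - fraction cleaved)), the standard
    heteroduplex correction.  ``literal_half=True`` instead multiplies
    (1 - fraction cleaved) by 0.5.
    """
    fc = gel.fraction_cleaved
    if fc is None:
        return None
    if literal_half:
        return 100.0 * (1.0 - (1.0 - fc) * 0.5)
    return 100.0 * (1.0 - math.sqrt(1.0 - fc))
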