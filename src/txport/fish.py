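"""Nuclear polyA-RNA retention quantification from FISH cell tallies.

Cells hybridized with an oligo-dT probe are scored manually for visible
nuclear polyA RNA accumulation (an mRNA export defect); the input here is
the per-strain tally of cells scored and cells retaining. Retention is
reported as a percentage with a Wilson score interval, and strains are
compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError


@dataclass(frozen=True)
class CellTally:
    strain: str
    n_scored: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_scored < 1:
            raise ValidationError("n_scored must be >= 1")
        if not 0 <= self.n_retained <= self.n_scored:
            raise ValidationError(
                f"n_retained must be in [0, n_scored], got "
                f"{self.n_retained}/{self.n_scored}")


def retention_fraction(t: CellTally, ci_level: float = 0.95
                       ) -> tuple[float, float, float]:
    """Percent of cells with nuclear polyA retention, with a Wilson score
    confidence interval (robust at 0/n and small n, unlike Wald)."""
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must be in (0, 1)")
    p = t.n_retained / t.n_scored
    lo, hi = proportion_confint(t.n_retained, t.n_scored,
                                alpha=1 - ci_level, method="wilson")
    # guard against floating-point dust at the 0/n and n/n boundaries
    lo = min(max(lo, 0.0), p)
    hi = max(min(hi, 1.0), p)
    return 100.0 * p, 100.0 * lo, 100.0 * hi


def compare_retention(a: CellTally, b: CellTally) -> float:
    """Two-sided Fisher exact p-value for a difference in retention
    between two strains (2x2 table of retained/not x strain)."""
    table = [[a.n_retained, a.n_scored - a.n_retained],
             [b.n_retained, b.n_scored - b.n_retained]]
    return float(fisher_exact(table, alternative="two-sided")[1])
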