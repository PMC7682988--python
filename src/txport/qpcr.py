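"""ChIP-qPCR percent-of-input quantification and 3'/5' processivity.

Enrichment at an amplicon is expressed as the percent of the input
chromatin recovered in the immunoprecipitate, computed from qPCR cycle
thresholds:

    percent = 100 * 2**(Ct_input - c - Ct_IP),   c = log2(1/input_fraction)

With the standard 1% input aliquot c = log2(100) = 6.644, i.e. the familiar
``100*2^(Ct_input - 6.644 - Ct_IP)``. RNAPII processivity over a long gene
is then the ratio of the percent of input at a 3' amplicon to that at a 5'
amplicon: a polymerase that fails to reach the gene end gives a ratio
below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ComputationError, ValidationError

Amplicon = str  # "five_prime" | "three_prime" | other labels


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR threshold-cycle pair (input aliquot and IP) for an amplicon."""

    amplicon: Amplicon
    ct_input: float
    ct_ip: float
    input_fraction: float = 0.01
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_input) and math.isfinite(self.ct_ip)):
            raise ValidationError("Ct values must be finite")
        if not 0 < self.input_fraction <= 1:
            raise ValidationError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}")


def percent_input(ct: CtMeasurement) -> float:
    """Percent of input recovered in the IP for one measurement."""
    c = math.log2(1.0 / ct.input_fraction)
    return 100.0 * 2.0 ** (ct.ct_input - c - ct.ct_ip)


def qpcr_processivity(pi_5: float, pi_3: float) -> float:
    """3'/5' percent-of-input ratio (1 = fully processive)."""
    if pi_5 <= 0:
        raise ComputationError("5' percent of input must be positive")
    return pi_3 / pi_5


def processivity_from_measurements(
        measurements: Iterable[CtMeasurement],
        five_prime: Amplicon = "five_prime",
        three_prime: Amplicon = "three_prime") -> float:
    """Processivity from replicate Ct measurements.

    Percent-of-input values are averaged per amplicon across replicates
    first; the ratio of the replicate-mean percents is returned (ratio of
    means, not mean of ratios).
    """
    by_amp: dict[Amplicon, list[float]] = {}
    for ct in measurements:
        by_amp.setdefault(ct.amplicon, []).append(percent_input(ct))
    for amp in (five_prime, three_prime):
        if amp not in by_amp:
            raise ComputationError(f"no measurements for amplicon {amp!r}")
    return qpcr_processivity(float(np.mean(by_amp[five_prime])),
                             float(np.mean(by_amp[three_prime])))
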