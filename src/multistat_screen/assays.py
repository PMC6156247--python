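"""Closed-form calculators for the wet-lab readouts.

ΔΔCt fold change for qRT-PCR (reference-gene normalized, efficiency 2 by
default), percent-of-input for ChIP qPCR (with the standard log2 dilution
correction of the input Ct), and the distance-based wound-closure
percentage for scratch assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "QpcrMeasurement",
    "WoundMeasurement",
    "ddct_fold_change",
    "percent_input",
    "wound_closure",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Paired target/reference Ct values for one sample (reference: ACTB)."""

    sample_id: str
    target_gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target),
                         ("ct_reference", self.ct_reference)):
            if not 0.0 < ct < 45.0:
                raise ValueError(f"{self.sample_id}: {name}={ct} outside (0, 45)")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class WoundMeasurement:
    """Gap widths (μm) measured across one scratch image (typically 20)."""

    dish_id: str
    timepoint: float  # hours
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.distances) < 1:
            raise ValueError("need at least one distance")
        if any(d < 0 for d in self.distances):
            raise ValueError("distances must be ≥ 0")


def ddct_fold_change(
    treated: QpcrMeasurement,
    control: QpcrMeasurement,
    efficiency: float = 2.0,
) -> float:
    """Relative expression of treated vs control: efficiency**(−ΔΔCt).

    ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt = ΔCt(treated) −
    ΔCt(control).  One cycle earlier in the treated sample doubles the
    estimate at the default efficiency of 2.
    """
    if treated.target_gene != control.target_gene:
        raise ValueError(
            f"gene mismatch: {treated.target_gene} vs {control.target_gene}"
        )
    if not efficiency > 1.0:
        raise ValueError("amplification efficiency must be > 1")
    return efficiency ** (-(treated.dct - control.dct))


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP signal as percent of input chromatin.

    The input reaction ran on only ``input_fraction`` of the chromatin, so
    its Ct overestimates the full-chromatin Ct by log2(1/input_fraction);
    the standard correction is ct_input − log2(1/input_fraction).  The IP
    signal is then 100 · 2**(adjusted input Ct − IP Ct).
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (ct_input_adjusted - ct_ip)


def wound_closure(t: WoundMeasurement, t0: WoundMeasurement) -> float:
    """Percent of the initial gap closed between t0 and t.

    100 · (1 − mean(gap at t) / mean(gap at t0)); negative when the gap
    widened.  Unit-free: any consistent length unit works.
    """
    if t.dish_id != t0.dish_id:
        raise ValueError("wound_closure: measurements from different dishes")
    if not t0.timepoint < t.timepoint:
        raise ValueError("t0 must precede t")
    mean0 = sum(t0.distances) / len(t0.distances)
    if mean0 == 0:
        raise ValueError("initial gap width is zero")
    mean_t = sum(t.distances) / len(t.distances)
    return 100.0 * (1.0 - mean_t / mean0)
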