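"""Spectrophotometric assay arithmetic for MDAR/DHAR activities.

Converts a raw absorbance slope into a specific activity via Beer-Lambert:

    rate [mM min-1] = |slope| / (epsilon * path)
    activity [umol min-1 mg-1] = rate * V_reaction / (V_extract * c_protein)

MDAR is followed as NADH oxidation (falling A340, epsilon = 6.2 mM-1 cm-1),
DHAR as ascorbate formation (rising A265, epsilon = 14 mM-1 cm-1). A slope
of the wrong sign for the declared direction indicates a non-enzymatic
artifact and is rejected rather than silently rectified. Also provides the
ascorbate redox bookkeeping: DHA = total - ASC.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

EPSILON_MDAR = 6.2  # mM-1 cm-1, NADH at 340 nm
EPSILON_DHAR = 14.0  # mM-1 cm-1, ascorbate at 265 nm


@dataclass(frozen=True)
class AssayMeasurement:
    slope: float  # absorbance units per minute, signed
    epsilon: float  # mM-1 cm-1
    wavelength: float = 340.0  # nm, informational
    path: float = 1.0  # cm
    reaction_volume: float = 1.0  # mL, total assay volume
    extract_volume: float = 0.05  # mL of extract added
    protein_conc: float = 1.0  # mg protein per mL extract

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.path <= 0:
            raise ValueError("path length must be positive")
        if self.reaction_volume <= 0 or self.extract_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")


def specific_activity(m: AssayMeasurement, direction: str) -> float:
    """Specific activity in umol min-1 mg-1 protein.

    ``direction`` declares the expected absorbance change ("decrease" for
    MDAR/NADH, "increase" for DHAR/ascorbate); a nonzero slope of the
    opposite sign raises.
    """
    if direction not in ("decrease", "increase"):
        raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    if direction == "decrease" and m.slope > 0:
        raise ValueError(
            "rising absorbance in a 'decrease' assay: non-enzymatic artifact"
        )
    if direction == "increase" and m.slope < 0:
        raise ValueError(
            "falling absorbance in an 'increase' assay: non-enzymatic artifact"
        )
    rate_mm_per_min = abs(m.slope) / (m.epsilon * m.path)
    return rate_mm_per_min * m.reaction_volume / (m.extract_volume * m.protein_conc)


def redox_state(asc: float, total: float) -> tuple[float, float]:
    """DHA content and ascorbate redox ratio from ASC and total pools.

    DHA = total - ASC; ratio = ASC / total. Requires 0 <= asc <= total and
    total > 0.
    """
    if total <= 0:
        raise ValueError("total ascorbate pool must be positive")
    if asc < 0 or asc > total:
        raise ValueError("ASC must satisfy 0 <= ASC <= total")
    return total - asc, asc / total


def mean_se(values) -> tuple[float, float]:
    """Mean and standard error of a set of replicate measurements."""
    vals = list(values)
    n = len(vals)
    if n == 0:
        raise ValueError("no values")
    mean = sum(vals) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return mean, math.sqrt(var / n)
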