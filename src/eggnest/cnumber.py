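"""The C number: dimensionless eggshell stiffness.

``C = (K / W) * (A^2 / B)`` along the long axis, where ``K`` (N/m) is the
absolute axial compression stiffness, ``W`` (N) the egg weight, ``A`` the
breadth and ``B`` the length (m). Along the short axis the geometric factor
is the harmonic-mean diameter, ``C = (K / W) * 2AB / (A + B)``. Both forms
reduce to ``K D / W`` for a sphere of diameter ``D``. Dividing out weight
and the size factor removes egg-size and geometry-induced rigidity, so C
compares shell stiffness across species spanning orders of magnitude in
egg size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CNumber", "c_number"]


@dataclass(frozen=True)
class CNumber:
    value: float
    axis: str           # "long" | "short"
    log10_value: float


def c_number(stiffness: float, weight: float, breadth: float, length: float,
             axis: str = "long") -> CNumber:
    """Dimensionless C number from stiffness K (N/m), weight W (N) and the
    egg's breadth A and length B (m)."""
    if min(stiffness, weight, breadth, length) <= 0:
        raise ValueError("all arguments must be positive")
    if axis == "long":
        geom = breadth ** 2 / length
    elif axis == "short":
        geom = 2.0 * breadth * length / (breadth + length)
    else:
        raise ValueError("axis must be 'long' or 'short'")
    value = (stiffness / weight) * geom
    return CNumber(value=value, axis=axis, log10_value=math.log10(value))
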