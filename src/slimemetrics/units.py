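"""Explicit unit conversions used at type boundaries.

Internal conventions: cell-scale lengths in micrometres (um), gland/body
scale lengths in millimetres (mm), volumes in cubic millimetres (mm^3)
with millilitres (ml) used for fluid bookkeeping.  1 ml == 1000 mm^3.
Angles are radians internally and degrees at every public surface.
"""

from __future__ import annotations

UM_PER_MM = 1000.0
MM3_PER_ML = 1000.0
CM_PER_MM = 0.1
MM2_PER_CM2 = 100.0


def um_to_mm(x: float) -> float:
    return x / UM_PER_MM


def mm_to_um(x: float) -> float:
    return x * UM_PER_MM


def ml_to_mm3(v: float) -> float:
    return v * MM3_PER_ML


def mm3_to_ml(v: float) -> float:
    return v / MM3_PER_ML
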