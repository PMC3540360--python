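"""Body-surface-area based dose calculation.

Porcine BSA is estimated allometrically as ``0.0734 * weight_kg**0.656``
(m^2) and the absolute dose is that area times the dose intensity in
mg/m^2.  Computation keeps full precision; reports round to 1 decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError

__all__ = ["DoseCalcParams", "DEFAULT_DOSE_PARAMS", "body_surface_area", "compute_dose"]


@dataclass(frozen=True)
class DoseCalcParams:
    """Allometric BSA coefficients (m^2 per kg**exponent)."""

    coefficient: float = 0.0734
    exponent: float = 0.656

    def __post_init__(self):
        if not (self.coefficient > 0 and self.exponent > 0):
            raise DomainError("BSA coefficient and exponent must be > 0")


DEFAULT_DOSE_PARAMS = DoseCalcParams()


def body_surface_area(weight_kg: float, params: DoseCalcParams = DEFAULT_DOSE_PARAMS) -> float:
    """Estimated body surface area in m^2 for a body weight in kg."""
    if not weight_kg > 0:
        raise DomainError(f"weight_kg must be > 0, got {weight_kg!r}")
    return params.coefficient * weight_kg**params.exponent


def compute_dose(
    weight_kg: float,
    dose_per_m2_mg: float,
    params: DoseCalcParams = DEFAULT_DOSE_PARAMS,
) -> float:
    """Absolute dose in mg: BSA(weight) * dose intensity (mg/m^2)."""
    if not dose_per_m2_mg >= 0:
        raise DomainError(f"dose_per_m2_mg must be >= 0, got {dose_per_m2_mg!r}")
    return body_surface_area(weight_kg, params) * dose_per_m2_mg
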