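"""Anthropometric inputs: total blood volume and body surface area.

The compartment model is individualized through two closed-form
anthropometric quantities:

* **Total blood volume (TBV)** via Nadler's sex-specific regression on
  height and weight (height in metres, weight in kg, result in litres):

  - male:   ``0.3669 h^3 + 0.03219 w + 0.6041``
  - female: ``0.3561 h^3 + 0.03308 w + 0.1833``

* **Body surface area (BSA)** via Du Bois (default) or Mosteller.

Both are strictly increasing in height and weight, which the test suite
asserts on a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "PatientProfile",
    "BodyComposition",
    "nadler_blood_volume",
    "body_surface_area",
    "body_composition",
    "NADLER_COEFFICIENTS",
]

#: Sex -> (height^3 coefficient, weight coefficient, intercept).
#: Height in metres, weight in kg, blood volume in litres.
NADLER_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}

_HEIGHT_BOUNDS_CM = (100.0, 230.0)
_WEIGHT_BOUNDS_KG = (30.0, 250.0)
_PULSE_BOUNDS_BPM = (30.0, 150.0)

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


def _check_open_interval(name: str, value: float, bounds: tuple[float, float]) -> None:
    lo, hi = bounds
    if not (lo < value < hi) or not math.isfinite(value):
        raise ValidationError(
            f"{name}={value!r} outside plausible range ({lo}, {hi})"
        )


@dataclass(frozen=True)
class PatientProfile:
    """Minimal per-patient record used to individualize the model.

    Parameters
    ----------
    height_cm : float
        Standing height in centimetres, open interval (100, 230).
    weight_kg : float
        Body weight in kilograms, open interval (30, 250).
    sex : str
        ``"male"`` / ``"female"`` (``"M"`` / ``"F"`` accepted).
    pulse_bpm : float
        Resting heart rate in beats per minute, open interval (30, 150).
    id : str
        Opaque subject label.
    """

    height_cm: float
    weight_kg: float
    sex: str
    pulse_bpm: float
    id: str = ""

    def __post_init__(self) -> None:
        _check_open_interval("height_cm", self.height_cm, _HEIGHT_BOUNDS_CM)
        _check_open_interval("weight_kg", self.weight_kg, _WEIGHT_BOUNDS_KG)
        _check_open_interval("pulse_bpm", self.pulse_bpm, _PULSE_BOUNDS_BPM)
        sex = _SEX_ALIASES.get(str(self.sex).strip().lower())
        if sex is None:
            raise ValidationError(
                f"sex={self.sex!r} not recognised; expected male/female (M/F)"
            )
        object.__setattr__(self, "sex", sex)

    @property
    def height_m(self) -> float:
        return self.height_cm / 100.0


@dataclass(frozen=True)
class BodyComposition:
    """Derived anthropometry: total blood volume and body surface area."""

    total_blood_volume_l: float
    bsa_m2: float
    bsa_formula: str = "du_bois"


def nadler_blood_volume(profile: PatientProfile,
                        coefficients: dict[str, tuple[float, float, float]] | None = None,
                        ) -> float:
    """Total blood volume in litres from Nadler's regression.

    ``coefficients`` may override the built-in table (same layout as
    :data:`NADLER_COEFFICIENTS`), e.g. for sensitivity analyses.
    """
    table = NADLER_COEFFICIENTS if coefficients is None else coefficients
    try:
        a, b, c = table[profile.sex]
    except KeyError:  # pragma: no cover - profile validation normally prevents this
        raise ValidationError(f"no Nadler coefficients for sex={profile.sex!r}")
    h = profile.height_m
    return a * h ** 3 + b * profile.weight_kg + c


def body_surface_area(profile: PatientProfile, formula: str = "du_bois") -> float:
    """Body surface area in m**2 (Du Bois by default, Mosteller optional)."""
    h, w = profile.height_cm, profile.weight_kg
    if formula == "du_bois":
        return 0.007184 * h ** 0.725 * w ** 0.425
    if formula == "mosteller":
        return math.sqrt(h * w / 3600.0)
    raise ValidationError(f"unknown BSA formula {formula!r}; use du_bois or mosteller")


def body_composition(profile: PatientProfile, bsa_formula: str = "du_bois",
                     nadler_coefficients: dict[str, tuple[float, float, float]] | None = None,
                     ) -> BodyComposition:
    """Bundle TBV and BSA for a profile."""
    return BodyComposition(
        total_blood_volume_l=nadler_blood_volume(profile, nadler_coefficients),
        bsa_m2=body_surface_area(profile, bsa_formula),
        bsa_formula=bsa_formula,
    )
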