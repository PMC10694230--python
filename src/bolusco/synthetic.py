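"""Synthetic cohorts and time-density curves.

Generates virtual subjects whose anthropometry matches the pooled marginal
statistics of the clinical cohort the analysis emulates (height 172.89 +/-
10.28 cm, weight 84.16 +/- 19.83 kg, pulse 59.24 +/- 8.98 bpm, true cardiac
output 5.05 +/- 1.13 L/min), draws each subject's TDC from the forward
compartment model at the subject's true CO, and then degrades it the way a
real test-bolus acquisition does: resampling at 2-s intervals, additive
Gaussian HU noise, a scan delay that clips the early baseline, and a limited
scan duration that clips the tail.

Every draw flows from a single integer seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .anthropometry import BodyComposition, PatientProfile, body_composition
from .compartment import (
    CalibrationConstant,
    InjectionProtocol,
    build_default_model,
    simulate,
)
from .errors import EmptyCurveError, ValidationError
from .estimation import TimeDensityCurve

__all__ = ["CohortSpec", "SyntheticSubject", "generate_cohort", "apply_regime",
           "DEFAULT_MARGINALS"]

#: (mean, SD) per generated variable; pooled cohort values.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "height": (172.89, 10.28),
    "weight": (84.16, 19.83),
    "pulse": (59.24, 8.98),
    "co_true": (5.05, 1.13),
}

#: Truncation bounds for the marginal draws (profile construction bounds for
#: anthropometry; model validity bounds for cardiac output).
_TRUNCATION_BOUNDS: dict[str, tuple[float, float]] = {
    "height": (100.0, 230.0),
    "weight": (30.0, 250.0),
    "pulse": (30.0, 150.0),
    "co_true": (1.0, 15.0),
}

_REGIMES = ("complete", "clipped_start", "clipped_end", "clipped_both")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``scan_delay_s`` is the first acquisition time used by the start-clipping
    regimes (a typical test-bolus protocol triggers the first image 10-15 s
    after injection start to spare radiation dose); ``duration_s`` is the
    total scan window, and ``noise_sd_hu`` the aortic ROI noise level.

    ``baseline_sd_hu`` is the between-subject spread of unenhanced blood-pool
    attenuation (haematocrit-dependent, typically several HU).  It is what
    makes a start-clipped curve genuinely harder: an estimator that cannot
    measure the baseline must assume one, and the assumption is wrong by a
    subject-specific amount.
    """

    n: int
    seed: int
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    sex_ratio: float = 0.5
    regime: str = "complete"
    noise_sd_hu: float = 10.0
    baseline_sd_hu: float = 7.0
    sampling_interval_s: float = 2.0
    scan_delay_s: float = 12.0
    duration_s: float = 40.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if self.regime not in _REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if self.sampling_interval_s <= 0:
            raise ValidationError("sampling interval must be > 0")
        if self.noise_sd_hu < 0 or self.baseline_sd_hu < 0:
            raise ValidationError("noise and baseline SDs must be >= 0")
        for name, (mu, sd) in self.marginals.items():
            if sd <= 0:
                raise ValidationError(f"marginal SD for {name!r} must be > 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValidationError("sex_ratio must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSubject:
    """One virtual patient: profile, ground-truth CO, and observed TDC."""

    profile: PatientProfile
    body: BodyComposition
    injection: InjectionProtocol
    co_true_l_min: float
    tdc: TimeDensityCurve
    baseline_true_hu: float = 40.0


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    bounds: tuple[float, float]) -> float:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def apply_regime(tdc: TimeDensityCurve, regime: str, scan_delay_s: float,
                 duration_s: float) -> TimeDensityCurve:
    """Clip a curve to an acquisition regime and set its truncation flag.

    ``complete`` returns the curve unchanged (baseline retained);
    ``clipped_start`` drops samples before ``scan_delay_s``; ``clipped_end``
    drops samples after ``duration_s``; ``clipped_both`` does both.  Clipping
    that removes the peak is permitted -- downstream estimators raise
    peak-not-captured errors on such curves.
    """
    if regime not in _REGIMES:
        raise ValidationError(f"unknown regime {regime!r}")
    if regime == "complete":
        return replace(tdc, complete_flag="complete")
    keep = np.ones(tdc.times.size, dtype=bool)
    if regime in ("clipped_start", "clipped_both"):
        keep &= tdc.times >= scan_delay_s - 1e-9
    if regime in ("clipped_end", "clipped_both"):
        keep &= tdc.times <= duration_s + 1e-9
    if not np.any(keep):
        raise EmptyCurveError(
            f"regime {regime!r} with delay {scan_delay_s} s / duration "
            f"{duration_s} s removed every sample")
    times = tdc.times[keep]
    return TimeDensityCurve(
        times=times, hu=tdc.hu[keep], scan_delay_s=float(times[0]),
        baseline_hu=tdc.baseline_hu, complete_flag=regime)


def generate_cohort(spec: CohortSpec,
                    injection: InjectionProtocol | None = None,
                    calib: CalibrationConstant | None = None,
                    dt: float = 0.05) -> list[SyntheticSubject]:
    """Draw a cohort of virtual subjects with forward-simulated TDCs.

    Anthropometry and true CO come from independent truncated normals at the
    spec's marginals; the TDC is the compartment simulation at the subject's
    true CO, resampled on the acquisition grid, noised, and clipped per the
    spec's regime.  Deterministic given ``spec.seed``.
    """
    injection = injection if injection is not None else InjectionProtocol()
    calib = calib if calib is not None else CalibrationConstant()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sim_duration = max(30.0, spec.duration_s + 5.0)
    grid = np.arange(0.0, spec.duration_s + 1e-9, spec.sampling_interval_s)

    subjects: list[SyntheticSubject] = []
    for i in range(spec.n):
        height = _truncnorm_draw(rng, *spec.marginals["height"],
                                 _TRUNCATION_BOUNDS["height"])
        weight = _truncnorm_draw(rng, *spec.marginals["weight"],
                                 _TRUNCATION_BOUNDS["weight"])
        pulse = _truncnorm_draw(rng, *spec.marginals["pulse"],
                                _TRUNCATION_BOUNDS["pulse"])
        co_true = _truncnorm_draw(rng, *spec.marginals["co_true"],
                                  _TRUNCATION_BOUNDS["co_true"])
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        profile = PatientProfile(height_cm=height, weight_kg=weight, sex=sex,
                                 pulse_bpm=pulse, id=f"S{i + 1:03d}")
        body = body_composition(profile)
        model = build_default_model(profile, body, co_true)
        sim = simulate(model, injection, calib, duration_s=sim_duration, dt=dt)
        hu = np.interp(grid, sim.times, sim.hu)
        baseline_true = calib.baseline_hu
        if spec.baseline_sd_hu > 0:
            baseline_true += float(rng.normal(0.0, spec.baseline_sd_hu))
            hu = hu + (baseline_true - calib.baseline_hu)
        if spec.noise_sd_hu > 0:
            hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.size)
        full = TimeDensityCurve(times=grid.copy(), hu=hu, scan_delay_s=0.0,
                                baseline_hu=None, complete_flag="complete")
        tdc = apply_regime(full, spec.regime, spec.scan_delay_s, spec.duration_s)
        subjects.append(SyntheticSubject(profile=profile, body=body,
                                         injection=injection,
                                         co_true_l_min=co_true, tdc=tdc,
                                         baseline_true_hu=baseline_true))
    return subjects
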