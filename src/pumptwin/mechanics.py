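"""Screw-drive mechanics: insulin dose -> plunger travel -> encoder pulses.

A plunger pump delivers a volume V = dose / concentration; the plunger
advance is x = 4 V / (pi d^2) for a reservoir of inner diameter d; the
lead screw converts advance to screw revolutions x / p (pitch p), the
gear train multiplies by the reduction ratio i, and the optical encoder
produces quadrature_factor * N0 counts per motor revolution:

    pulses = quadrature * N0 * i * (4 V / (pi d^2)) / p

The minimum effective dose is limited by a lumped dead volume (reservoir
and line elasticity, friction, transmission backlash): no liquid leaves
the needle until the commanded volume exceeds the dead volume plus one
pulse-quantum of volume.

Two presets are shipped, ``one_stage`` and ``two_stage``, representing a
conventional single lead screw and a telescoping two-stage screw with a
finer effective transmission.  Their dead volumes are calibration
fixtures chosen so that the presets reproduce bench-measured minimum
effective doses of 0.095 U and 0.047 U; they are not measurements of any
particular device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

__all__ = [
    "PumpConfig",
    "StageComparison",
    "dose_to_volume",
    "encoder_pulses_for_dose",
    "quantize_pulses",
    "pulse_quantum_volume",
    "pulse_quantum_dose",
    "min_effective_dose",
    "compare_stage_configs",
    "one_stage_preset",
    "two_stage_preset",
]

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class PumpConfig:
    """Geometry and transmission constants of one pump build."""

    name: str
    stages: int  # 1 or 2
    reservoir_inner_diameter: float  # mm
    screw_pitch: float  # mm per screw revolution
    gear_ratio: float  # motor revs per screw rev
    encoder_lines: int  # optical lines on the code disc
    quadrature_factor: int = 4  # counts per line (quadrature decoding)
    insulin_concentration: float = 100.0  # U/mL (U-100)
    dead_volume: float = 0.0  # mL lumped backlash/elastic loss
    max_stroke: float = 60.0  # mm usable plunger travel

    def __post_init__(self) -> None:
        if self.stages not in (1, 2):
            raise ValueError(f"stages must be 1 or 2, got {self.stages}")
        for f in ("reservoir_inner_diameter", "screw_pitch", "gear_ratio",
                  "insulin_concentration", "max_stroke"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")
        if self.encoder_lines <= 0:
            raise ValueError("encoder_lines must be > 0")
        if self.quadrature_factor not in (1, 2, 4):
            raise ValueError(f"quadrature_factor must be 1, 2 or 4, got {self.quadrature_factor}")
        if self.dead_volume < 0:
            raise ValueError("dead_volume must be >= 0")

    @property
    def piston_area(self) -> float:
        """Reservoir cross-section in mm^2."""
        return math.pi * self.reservoir_inner_diameter**2 / 4.0

    @property
    def pulses_per_screw_rev(self) -> float:
        return self.quadrature_factor * self.encoder_lines * self.gear_ratio


def dose_to_volume(dose: float, concentration: float = 100.0) -> float:
    """Dose in U -> volume in mL at the given concentration (U/mL).

    At U-100, 0.1 U is 1 uL, i.e. about 0.001 g of water surrogate.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return dose / concentration


def advance_for_dose(config: PumpConfig, dose: float) -> float:
    """Axial plunger advance in mm for a commanded dose."""
    volume_mm3 = dose_to_volume(dose, config.insulin_concentration) * MM3_PER_ML
    return volume_mm3 / config.piston_area


def encoder_pulses_for_dose(config: PumpConfig, dose: float) -> float:
    """Encoder pulse count (real-valued) needed to deliver ``dose``.

    Exactly linear in dose with zero intercept.  Raises if the required
    plunger advance exceeds the usable stroke.
    """
    advance = advance_for_dose(config, dose)
    if advance > config.max_stroke:
        raise ValueError(
            f"dose {dose} U needs {advance:.2f} mm of travel; "
            f"{config.name} has only {config.max_stroke} mm of stroke"
        )
    screw_revs = advance / config.screw_pitch
    return screw_revs * config.pulses_per_screw_rev


def quantize_pulses(pulses: float) -> int:
    """Whole pulses actually commandable (floor of the real count)."""
    return int(math.floor(pulses))


def pulse_quantum_volume(config: PumpConfig) -> float:
    """Volume in mL displaced by a single encoder pulse."""
    advance_per_pulse = config.screw_pitch / config.pulses_per_screw_rev
    return advance_per_pulse * config.piston_area / MM3_PER_ML


def pulse_quantum_dose(config: PumpConfig) -> float:
    """Dose in U delivered per single encoder pulse."""
    return pulse_quantum_volume(config) * config.insulin_concentration


def min_effective_dose(config: PumpConfig) -> float:
    """Smallest commanded dose (U) producing measurable liquid output.

    The commanded volume must exceed the lumped dead volume plus one
    pulse-quantum of volume; the threshold itself is returned.  The
    result is nondecreasing in dead_volume and nonincreasing as pulse
    resolution increases.
    """
    threshold_ml = config.dead_volume + pulse_quantum_volume(config)
    return threshold_ml * config.insulin_concentration


@dataclass(frozen=True)
class StageComparison:
    dose: float
    pulses: dict[str, float]
    pulse_quantum_dose: dict[str, float]
    min_effective_dose: dict[str, float]
    finer: str | None  # config name with more pulses per unit dose; None on tie

    def to_frame(self) -> pd.DataFrame:
        names = list(self.pulses)
        return pd.DataFrame(
            {
                "config_name": names,
                "dose_U": [self.dose] * len(names),
                "pulses": [self.pulses[n] for n in names],
                "pulse_quantum_U": [self.pulse_quantum_dose[n] for n in names],
                "min_effective_dose_U": [self.min_effective_dose[n] for n in names],
            }
        )


def compare_stage_configs(c1: PumpConfig, c2: PumpConfig, dose: float) -> StageComparison:
    """Side-by-side dosing-resolution report for two pump builds."""
    n1, n2 = (c1.name, c2.name) if c1.name != c2.name else (c1.name + "_a", c2.name + "_b")
    p1 = encoder_pulses_for_dose(c1, dose)
    p2 = encoder_pulses_for_dose(c2, dose)
    if math.isclose(p1, p2, rel_tol=1e-12, abs_tol=1e-12):
        finer = None
    else:
        finer = n2 if p2 > p1 else n1
    return StageComparison(
        dose=dose,
        pulses={n1: p1, n2: p2},
        pulse_quantum_dose={n1: pulse_quantum_dose(c1), n2: pulse_quantum_dose(c2)},
        min_effective_dose={n1: min_effective_dose(c1), n2: min_effective_dose(c2)},
        finer=finer,
    )


def _calibrated(config: PumpConfig, target_min_dose: float) -> PumpConfig:
    """Set dead_volume so min_effective_dose(config) == target exactly."""
    dead = target_min_dose / config.insulin_concentration - pulse_quantum_volume(config)
    if dead < 0:
        raise ValueError("target minimum dose below one pulse quantum")
    return replace(config, dead_volume=dead)


def one_stage_preset() -> PumpConfig:
    """Single lead-screw build; dead volume calibrated to a 0.095 U
    minimum effective dose (calibration fixture, not a measurement)."""
    base = PumpConfig(
        name="one_stage",
        stages=1,
        reservoir_inner_diameter=9.5,
        screw_pitch=0.5,
        gear_ratio=100.0,
        encoder_lines=16,
    )
    return _calibrated(base, 0.095)


def two_stage_preset() -> PumpConfig:
    """Telescoping two-stage screw build with a finer transmission; dead
    volume calibrated to a 0.047 U minimum effective dose (calibration
    fixture, not a measurement)."""
    base = PumpConfig(
        name="two_stage",
        stages=2,
        reservoir_inner_diameter=9.5,
        screw_pitch=0.5,
        gear_ratio=500.0,
        encoder_lines=16,
        max_stroke=100.0,
    )
    return _calibrated(base, 0.047)
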