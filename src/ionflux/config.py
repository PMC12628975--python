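"""Acquisition and geometry configuration shared across modules."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass(frozen=True)
class GeometrySpec:
    """Shape of the studied tissue, for surface-referenced flux distances.

    ``radius`` is the tissue radius a (m), required for cylinder/sphere;
    ``gap0`` is the distance from the tissue surface to measurement position 0
    (m).  Flat geometry ignores both curvature corrections.
    """

    shape: str = "flat"  # flat | cylinder | sphere
    radius: float | None = None
    gap0: float = 0.0

    def __post_init__(self):
        if self.shape not in ("flat", "cylinder", "sphere"):
            raise ConfigError(f"unknown geometry shape {self.shape!r}")
        if self.shape != "flat":
            if self.radius is None or not self.radius > 0:
                raise ConfigError(f"{self.shape} geometry requires radius > 0")
        if self.gap0 < 0:
            raise ConfigError("gap0 must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and movement parameters of the self-referencing acquisition.

    Defaults reproduce the standard protocol: 10 ms sampling, 10 s position
    loops of 1000 samples each, a 50 um scan between the two positions, and a
    5 s settling period before samples enter the regressions (the electrode's
    exponential response is considered settled after 5 s).
    """

    sample_interval: float = 0.01  # s
    loop_duration: float = 10.0  # s
    scan_distance: float = 50e-6  # m
    scan_angle: float = 0.0  # degrees from horizontal
    manipulator_side: str = "left"
    start_fit: float = 5.0  # s into each loop
    ise2_active: bool = False
    volt1_active: bool = False
    volt2_active: bool = False
    n_samples_per_loop: int = field(init=False)

    def __post_init__(self):
        if not self.sample_interval > 0 or not self.loop_duration > 0:
            raise ConfigError("sample_interval and loop_duration must be > 0")
        n = round(self.loop_duration / self.sample_interval)
        if abs(n * self.sample_interval - self.loop_duration) > 1e-9:
            raise ConfigError(
                "loop_duration must be an integer multiple of sample_interval"
            )
        object.__setattr__(self, "n_samples_per_loop", n)
        if not 0 <= self.start_fit < self.loop_duration:
            raise ConfigError("start_fit must satisfy 0 <= start_fit < loop_duration")
        if not self.scan_distance > 0:
            raise ConfigError("scan_distance must be > 0")
        if not 0 <= self.scan_angle < 90:
            raise ConfigError("scan_angle must satisfy 0 <= angle < 90 degrees")
        if self.manipulator_side not in ("left", "right"):
            raise ConfigError("manipulator_side must be 'left' or 'right'")

    @property
    def normal_displacement(self) -> float:
        """Surface-normal component of the scan movement, m.

        A scan at angle theta from horizontal moves the tip
        scan_distance * cos(theta) along the surface normal; the recorded
        position column always stores the full travel distance.
        """
        return self.scan_distance * math.cos(math.radians(self.scan_angle))
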