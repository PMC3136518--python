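"""Experiment configuration objects and their JSON round-trip.

Two pydantic models describe one polarization-modulation experiment:

``AcquisitionConfig``
    everything the microscope fixes — frame interval, polarizer angular
    rate, UV-flash timing, stage temperature, camera geometry and noise.

``PopulationParams``
    everything the molecular population determines — how many molecules,
    what fraction responds to ATP photorelease, the rotation-angle mixture,
    photobleaching rate and single-molecule brightness.

Angles are always degrees, times seconds, intensities camera counts (a.u.).
Unknown keys are rejected on load so stale config files fail loudly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: Photobleaching rate constants (s^-1) measured at the two reference
#: temperatures; used when PopulationParams.bleach_rate is left unset.
BLEACH_RATE_23C = 0.052
BLEACH_RATE_50C = 0.051

#: Mean single-molecule peak intensities (a.u.) at the two reference
#: temperatures; the thermal-quenching model interpolates between them.
PEAK_INTENSITY_23C = 170.0
PEAK_INTENSITY_50C = 86.0


class AcquisitionConfig(BaseModel):
    """Timing, optics and camera constants of one acquisition."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    frame_interval: float = Field(0.2, gt=0.0, description="seconds per frame")
    n_frames: int = Field(300, ge=1)
    omega: float = Field(20.01, gt=0.0, description="polarizer rate, deg/s")
    flash_time: float = Field(30.0, ge=0.0, description="UV flash onset, s")
    flash_duration: float = Field(0.5, ge=0.0, description="UV pulse length, s")
    temperature: float = Field(50.0, description="stage temperature, deg C")
    image_shape: Tuple[int, int] = Field((512, 512), description="rows, cols")
    pixel_noise_floor: float = Field(2.0, ge=0.0, description="read noise sd, a.u.")
    background_level: float = Field(20.0, ge=0.0, description="a.u. per pixel")

    @model_validator(mode="after")
    def _flash_inside_movie(self) -> "AcquisitionConfig":
        if self.flash_time > self.duration:
            raise ValueError(
                f"flash_time={self.flash_time} s lies outside the movie "
                f"(duration {self.duration} s)"
            )
        if min(self.image_shape) < 16:
            raise ValueError("image_shape must be at least 16x16 pixels")
        return self

    @property
    def duration(self) -> float:
        """Total movie length in seconds."""
        return self.n_frames * self.frame_interval

    @property
    def flash_end(self) -> float:
        """Time at which the UV pulse is over (s)."""
        return self.flash_time + self.flash_duration

    @property
    def half_period(self) -> float:
        """Modulation half-period 180/omega (s) — the cos^2 repeat time."""
        return 180.0 / self.omega

    @property
    def half_period_frames(self) -> int:
        """Frames spanning one modulation half-period, rounded up."""
        return math.ceil(self.half_period / self.frame_interval)

    def frame_times(self):
        """Mid-exposure time stamp of every frame (s).

        The polarizer rotates continuously, so the interval midpoint is the
        unbiased phase reference for each frame.
        """
        import numpy as np

        return (np.arange(self.n_frames) + 0.5) * self.frame_interval


class PopulationParams(BaseModel):
    """Statistical description of the simulated molecular population."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_molecules: int = Field(136, ge=0)
    active_fraction: float = Field(0.10, ge=0.0, le=1.0)
    rotation_means: Tuple[float, ...] = Field(
        (34.0, -35.0), description="responder rotation-peak centers, deg"
    )
    rotation_sd: float = Field(5.0, ge=0.0, description="responder spread, deg")
    orientation_jitter_sd: float = Field(
        5.0, ge=0.0, description="null-component apparent-rotation spread, deg"
    )
    mean_peak_intensity: float = Field(
        170.0, gt=0.0, description="mean brightness at 23 deg C, a.u."
    )
    intensity_sd: float = Field(40.0, ge=0.0, description="brightness sd at 23 deg C")
    bleach_rate: Optional[float] = Field(
        None, ge=0.0, description="s^-1; None resolves from temperature"
    )
    psf_sigma: float = Field(1.3, gt=0.0, description="PSF Gaussian sd, px")
    seed: int = Field(0, ge=0)

    def resolved_bleach_rate(self, temperature: float) -> float:
        """Bleach rate to use at ``temperature``.

        Explicit values win; otherwise the measured constant at the nearer
        of the two calibration temperatures (23 / 50 deg C) is used.
        """
        if self.bleach_rate is not None:
            return self.bleach_rate
        return (
            BLEACH_RATE_23C
            if abs(temperature - 23.0) < abs(temperature - 50.0)
            else BLEACH_RATE_50C
        )


def read_acquisition(path) -> AcquisitionConfig:
    """Load an :class:`AcquisitionConfig` from JSON, rejecting unknown keys."""
    with open(path) as fh:
        payload = json.load(fh)
    return AcquisitionConfig.model_validate(payload)


def write_acquisition(config: AcquisitionConfig, path) -> None:
    """Write ``config`` as JSON (lossless round-trip with read_acquisition)."""
    Path(path).write_text(config.model_dump_json(indent=2) + "\n")


def read_population(path) -> PopulationParams:
    with open(path) as fh:
        payload = json.load(fh)
    return PopulationParams.model_validate(payload)


def write_population(params: PopulationParams, path) -> None:
    Path(path).write_text(params.model_dump_json(indent=2) + "\n")
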