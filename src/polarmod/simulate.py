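"""Synthetic polarization-modulation movies with ground truth.

The generator emulates a single-molecule experiment in which surface-
immobilized fluorophores are excited by a linearly polarized beam whose
polarization rotates continuously at ``omega`` deg/s.  An immobile dipole
at orientation theta then emits

    I(t) = A * cos^2(omega * t - theta) + offset,

periodic in t with period 180/omega (a dipole is apolar, so theta lives in
[0, 180)).  A UV flash photoreleases caged ATP part-way through the movie;
a small *active fraction* of molecules responds by rotating its dipole by
an angle drawn from a two-sided mixture (upper/lower ring of the
chaperonin), while every other molecule only jitters by a small
zero-centered angle that stands in for measurement scatter.

Photophysics:

* brightness per molecule ~ Normal(mean, sd), thermally quenched with
  temperature by a single-exponential law calibrated so the 23 °C mean of
  170 a.u. becomes 86 a.u. at 50 °C;
* photobleaching ~ Exponential(bleach_rate) measured from frame 0;
* Poisson shot noise on expected counts plus Gaussian read noise,
  rendered into 16-bit frames through an isotropic Gaussian PSF.

Brightness is parametrized as the intensity collected in the standard
5x5-pixel analysis ROI, so a noiseless rendered molecule round-trips
exactly through trajectory extraction.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import erf

from .config import (
    AcquisitionConfig,
    PEAK_INTENSITY_23C,
    PEAK_INTENSITY_50C,
    PopulationParams,
)

__all__ = [
    "MoleculeTruth",
    "intensity_model",
    "thermal_scale",
    "sample_population",
    "render_movie",
    "write_truth_csv",
    "read_truth_csv",
]

#: Thermal-quenching decay constant (1/degC), calibrated so that the mean
#: single-molecule intensity falls from 170 a.u. at 23 degC to 86 a.u. at 50 degC.
THERMAL_DECAY_PER_C = math.log(PEAK_INTENSITY_23C / PEAK_INTENSITY_50C) / (50.0 - 23.0)

#: Half-width of the analysis ROI (5x5 pixels); the PSF stamp is normalized
#: so the brightness parameter equals the ROI-collected intensity.
ROI_HALF_WIDTH = 2

#: Half-width of the rendered PSF stamp in pixels.
_STAMP_HALF = 6


@dataclass(frozen=True)
class MoleculeTruth:
    """Ground truth for one simulated molecule."""

    molecule_id: int
    position: Tuple[float, float]  # (row, col), subpixel
    theta0: float  # deg, in [0, 180)
    rotated: bool  # drawn from a responder component?
    delta_true: float  # deg, in (-90, 90]
    bleach_time: float  # s; inf if never bleaches
    brightness: float  # a.u., ROI-collected peak intensity


def intensity_model(t, A, omega, theta, offset=0.0):
    """Expected fluorescence of an immobile dipole under rotating polarization.

    Parameters
    ----------
    t : array_like
        Time in seconds.
    A : float
        Modulation amplitude (a.u.), ``A >= 0``.
    omega : float
        Polarizer angular rate in deg/s.
    theta : float
        Dipole orientation in degrees; the intensity peaks whenever the
        polarizer angle ``omega*t`` is parallel to ``theta`` (mod 180).
    offset : float, optional
        Additive background (a.u.).

    Returns
    -------
    ndarray or float
        ``A * cos^2(omega*t - theta) + offset``.
    """
    phase = np.deg2rad(np.multiply(omega, t) - theta)
    return A * np.cos(phase) ** 2 + offset


def thermal_scale(temperature: float, ref_intensity: float = PEAK_INTENSITY_23C) -> float:
    """Thermally quenched intensity at ``temperature`` (deg C).

    Single-exponential quenching ``I(T) = ref * exp(-k_T (T - 23))`` with
    ``k_T`` fixed by the calibration pair (23 °C, 170 a.u.) → (50 °C, 86 a.u.).
    Exact at both calibration points; temperatures outside the calibrated
    20–70 °C span are extrapolated with a warning.
    """
    if not (20.0 <= temperature <= 70.0):
        warnings.warn(
            f"temperature {temperature} degC outside the calibrated 20-70 degC "
            "range; extrapolating the quenching exponential",
            stacklevel=2,
        )
    return ref_intensity * math.exp(-THERMAL_DECAY_PER_C * (temperature - 23.0))


def _wrap_delta(delta: float) -> float:
    """Reduce an angle difference modulo 180 into (-90, 90]."""
    r = delta % 180.0
    if r > 90.0:
        r -= 180.0
    return r


def _molecule_rng(seed: int, molecule_id: int) -> np.random.Generator:
    """Per-molecule substream, stable under changes to n_molecules."""
    return np.random.default_rng(np.random.SeedSequence((seed, molecule_id)))


def _grid_positions(
    n: int, shape: Tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Jittered-grid molecule positions with pairwise distance >= 10 px.

    Cells of 12 px with +/-1 px jitter guarantee a minimum separation of
    2x the 5-px ROI side, the non-overlap contract of the simulator.
    """
    spacing = 2 * (2 * ROI_HALF_WIDTH + 1) + 2  # 12 px
    margin = _STAMP_HALF + 8  # keep stamps and background annuli in-bounds
    rows = np.arange(margin, shape[0] - margin, spacing, dtype=float)
    cols = np.arange(margin, shape[1] - margin, spacing, dtype=float)
    if rows.size * cols.size < n:
        raise ValueError(
            f"image {shape} too small to place {n} molecules at >= {spacing} px spacing"
        )
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)
    chosen = grid[rng.permutation(grid.shape[0])[:n]]
    return chosen + rng.uniform(-1.0, 1.0, size=chosen.shape)


def sample_population(
    params: PopulationParams, acq: AcquisitionConfig
) -> List[MoleculeTruth]:
    """Draw a molecular population for one movie.

    Orientations are uniform on [0, 180); bleach times exponential with the
    temperature-appropriate rate (measured from frame 0, ``inf`` when the
    rate is zero); each molecule responds to the flash with probability
    ``active_fraction``, rotating by Normal(m, rotation_sd) with ``m``
    uniform over ``rotation_means``; non-responders move by
    Normal(0, orientation_jitter_sd).  Deterministic for a fixed seed, and
    per-molecule draws are stable under changes of ``n_molecules``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 2718281)))
    positions = _grid_positions(params.n_molecules, acq.image_shape, rng)
    rate = params.resolved_bleach_rate(acq.temperature)
    scale = thermal_scale(acq.temperature, 1.0)
    mean_b = params.mean_peak_intensity * scale
    sd_b = params.intensity_sd * scale

    truths: List[MoleculeTruth] = []
    for mid in range(params.n_molecules):
        mrng = _molecule_rng(params.seed, mid)
        theta0 = mrng.uniform(0.0, 180.0)
        bleach = mrng.exponential(1.0 / rate) if rate > 0 else math.inf
        rotated = bool(mrng.random() < params.active_fraction)
        if rotated:
            m = params.rotation_means[mrng.integers(len(params.rotation_means))]
            delta = mrng.normal(m, params.rotation_sd)
        else:
            delta = mrng.normal(0.0, params.orientation_jitter_sd)
        brightness = mean_b + sd_b * mrng.standard_normal()
        brightness = max(brightness, 0.05 * mean_b)  # no negative emitters
        truths.append(
            MoleculeTruth(
                molecule_id=mid,
                position=(float(positions[mid, 0]), float(positions[mid, 1])),
                theta0=float(theta0),
                rotated=rotated,
                delta_true=float(_wrap_delta(delta)),
                bleach_time=float(bleach),
                brightness=float(brightness),
            )
        )
    return truths


def _psf_stamp(psf_sigma: float, dy: float, dx: float) -> np.ndarray:
    """Pixel-integrated Gaussian stamp centered at subpixel offset (dy, dx).

    Normalized so the central (2*ROI_HALF_WIDTH+1)^2 patch sums to 1: the
    molecule's brightness parameter is the ROI-collected intensity.
    """
    edges = np.arange(-_STAMP_HALF, _STAMP_HALF + 2) - 0.5
    s = psf_sigma * math.sqrt(2.0)
    cy = 0.5 * np.diff(erf((edges - dy) / s))
    cx = 0.5 * np.diff(erf((edges - dx) / s))
    stamp = np.outer(cy, cx)
    c = _STAMP_HALF
    roi = stamp[
        c - ROI_HALF_WIDTH : c + ROI_HALF_WIDTH + 1,
        c - ROI_HALF_WIDTH : c + ROI_HALF_WIDTH + 1,
    ]
    return stamp / roi.sum()


def render_movie(
    truths: Sequence[MoleculeTruth],
    acq: AcquisitionConfig,
    params: PopulationParams,
    noise: bool = True,
) -> np.ndarray:
    """Render a 16-bit movie of the population.

    Each frame is ``background_level`` plus every molecule's PSF stamp
    scaled by :func:`intensity_model` at the frame-midpoint time; the
    orientation switches from ``theta0`` to ``theta0 + delta_true`` at the
    end of the UV flash, and the molecule goes dark after its bleach time.
    With ``noise=True``, Poisson shot noise is applied to expected counts
    followed by Gaussian read noise; the result is clipped to uint16.

    Returns
    -------
    ndarray, shape (n_frames, H, W), dtype uint16
    """
    times = acq.frame_times()
    h, w = acq.image_shape
    per_molecule = []  # (expected stamp block over alive frames, y0, x0)
    max_expected = float(acq.background_level)

    for tr in truths:
        theta = np.where(times >= acq.flash_end, tr.theta0 + tr.delta_true, tr.theta0)
        inten = intensity_model(times, tr.brightness, acq.omega, theta)
        n_alive = int(np.searchsorted(times, tr.bleach_time))
        iy, ix = int(round(tr.position[0])), int(round(tr.position[1]))
        dy, dx = tr.position[0] - iy, tr.position[1] - ix
        stamp = _psf_stamp(params.psf_sigma, dy, dx).astype(np.float32)
        y0, x0 = iy - _STAMP_HALF, ix - _STAMP_HALF
        if y0 < 0 or x0 < 0 or y0 + stamp.shape[0] > h or x0 + stamp.shape[1] > w:
            raise ValueError(
                f"molecule {tr.molecule_id} at {tr.position} too close to the "
                "image edge for its PSF stamp"
            )
        block = inten[:n_alive, None].astype(np.float32) * stamp.ravel()
        per_molecule.append((block.reshape(-1, *stamp.shape), y0, x0))
        if n_alive:
            max_expected = max(max_expected, acq.background_level + float(block.max()))

    if max_expected > 0.99 * np.iinfo(np.uint16).max:
        warnings.warn("expected intensity approaches the 16-bit range; saturating", stacklevel=2)

    if noise:
        # SFC64: a fast generator; the stream is fully determined by
        # (params.seed, stream tag) so renders are bit-reproducible.
        # Poisson additivity lets the constant background use the fast
        # scalar-rate path, with per-molecule shot noise drawn only on the
        # PSF stamp while the molecule is alive.
        nrng = np.random.Generator(
            np.random.SFC64(np.random.SeedSequence((params.seed, 31415926)))
        )
        frames = nrng.poisson(
            float(acq.background_level), size=(acq.n_frames, h, w)
        ).astype(np.float32)
        for block, y0, x0 in per_molecule:
            if block.size:
                frames[: block.shape[0], y0 : y0 + block.shape[1], x0 : x0 + block.shape[2]] += (
                    nrng.poisson(block)
                )
        if acq.pixel_noise_floor > 0:
            frames += acq.pixel_noise_floor * nrng.standard_normal(
                size=frames.shape, dtype=np.float32
            )
    else:
        frames = np.full((acq.n_frames, h, w), float(acq.background_level), dtype=np.float32)
        for block, y0, x0 in per_molecule:
            frames[: block.shape[0], y0 : y0 + block.shape[1], x0 : x0 + block.shape[2]] += block
    return np.clip(np.rint(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)


_TRUTH_COLUMNS = [
    "molecule_id",
    "x",
    "y",
    "theta0_deg",
    "rotated",
    "delta_true_deg",
    "bleach_time_s",
    "brightness",
]


def write_truth_csv(truths: Sequence[MoleculeTruth], path) -> None:
    """Write the ground-truth sidecar (x = column, y = row, as imaged)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRUTH_COLUMNS)
        for tr in truths:
            writer.writerow(
                [
                    tr.molecule_id,
                    f"{tr.position[1]:.4f}",
                    f"{tr.position[0]:.4f}",
                    f"{tr.theta0:.4f}",
                    int(tr.rotated),
                    f"{tr.delta_true:.4f}",
                    "inf" if math.isinf(tr.bleach_time) else f"{tr.bleach_time:.4f}",
                    f"{tr.brightness:.4f}",
                ]
            )


def read_truth_csv(path) -> List[MoleculeTruth]:
    truths = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            truths.append(
                MoleculeTruth(
                    molecule_id=int(row["molecule_id"]),
                    position=(float(row["y"]), float(row["x"])),
                    theta0=float(row["theta0_deg"]),
                    rotated=bool(int(row["rotated"])),
                    delta_true=float(row["delta_true_deg"]),
                    bleach_time=float(row["bleach_time_s"]),
                    brightness=float(row["brightness"]),
                )
            )
    return truths
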