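"""Canonical experiment conditions.

Each preset returns an ``(AcquisitionConfig, PopulationParams)`` pair for
one of the study conditions:

* ``atp_condition`` — caged ATP present, observation at 50 °C, 10% of
  molecules rotate at the flash (the +34°/−35° mixture);
* ``no_atp_condition`` — no nucleotide: nobody rotates, only the
  zero-centered orientation jitter remains (also the responder-threshold
  calibration condition);
* ``intensity_assay`` — brightness-distribution measurement at a chosen
  temperature (no flash response of interest).

Photobleaching removes molecules throughout the movie (rate ≈ 0.05 s⁻¹),
so only the ~13% that survive one modulation half-period past the flash
yield an analyzable rotation record.  The presets therefore simulate
enough molecules that the *expected number of analyzable records* matches
the experiment's analyzed tallies — 136 molecules with caged ATP and 75
without — using the pipeline yield measured once at the defaults
(0.101 valid records per simulated molecule).
"""

from __future__ import annotations

from typing import Tuple

from .config import AcquisitionConfig, PopulationParams

#: Valid-record yield per simulated molecule at the 50 degC defaults
#: (survival past flash end + one half-period, times detection/fit losses).
PIPELINE_YIELD = 0.101

#: Analyzed-molecule tallies of the two conditions.
N_ANALYZED_ATP = 136
N_ANALYZED_NO_ATP = 75


#: Field of view of the condition presets: just large enough to hold the
#: simulated population at the simulator's non-overlap spacing.
_PRESET_SHAPE = (480, 480)


def atp_condition(seed: int = 0) -> Tuple[AcquisitionConfig, PopulationParams]:
    """Caged-ATP condition: 50 degC, flash at 30 s, 10% responders."""
    acq = AcquisitionConfig(image_shape=_PRESET_SHAPE)
    params = PopulationParams(
        n_molecules=round(N_ANALYZED_ATP / PIPELINE_YIELD),
        active_fraction=0.10,
        seed=seed,
    )
    return acq, params


def no_atp_condition(seed: int = 0) -> Tuple[AcquisitionConfig, PopulationParams]:
    """No-nucleotide condition: the flash releases nothing; only the
    zero-centered orientation jitter remains."""
    acq = AcquisitionConfig(image_shape=_PRESET_SHAPE)
    params = PopulationParams(
        n_molecules=round(N_ANALYZED_NO_ATP / PIPELINE_YIELD),
        active_fraction=0.0,
        seed=seed,
    )
    return acq, params


def intensity_assay(
    temperature: float, n_molecules: int = 500, seed: int = 0
) -> Tuple[AcquisitionConfig, PopulationParams]:
    """Brightness-distribution condition at ``temperature`` (deg C)."""
    acq = AcquisitionConfig(temperature=temperature, image_shape=_PRESET_SHAPE)
    params = PopulationParams(n_molecules=n_molecules, active_fraction=0.0, seed=seed)
    return acq, params
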