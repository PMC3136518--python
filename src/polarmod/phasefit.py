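"""Quadratic-cosine phase fitting and rotation-angle (delta-theta) analysis.

An immobile dipole under rotating excitation polarization emits

    I(t) = A * cos^2(omega*t - theta) + offset,

so the dipole orientation theta (defined modulo 180 deg) is the phase of
the second harmonic: using cos^2 u = (1 + cos 2u)/2,

    I(t) = offset + A/2 + (A/2) * cos(2*omega*t - 2*theta).

Fitting is therefore a linear least-squares problem in the basis
{1, cos 2wt, sin 2wt}; with coefficients (b0, bc, bs) the estimates are
``A = 2*hypot(bc, bs)`` and ``theta = atan2(bs, bc)/2`` mapped to
[0, 180).  When the offset is constrained to zero (background-subtracted
trajectories) the constant term must equal A/2 and the fit is refined by
bounded nonlinear least squares seeded from the linear solution.

The experiment fits theta separately before and after the ATP-releasing
UV flash.  The rotation angle ``delta = theta_post - theta_pre`` is only
defined modulo 180 (a dipole cannot distinguish alpha from alpha - 180);
the smaller-magnitude representative in (-90, +90] is adopted, positive
angles meaning counterclockwise rotation.  A molecule counts as a
*responder* when |delta| exceeds a threshold AND the orientation switch is
localized within a short latency window after the flash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import AcquisitionConfig
from .detect import Trajectory, _robust_sigma
from .simulate import intensity_model

__all__ = [
    "PhaseFit",
    "DeltaThetaRecord",
    "block_average",
    "fit_cosine",
    "compute_delta",
    "classify_responder",
    "resolve_delta",
    "analyze_trajectory",
    "analyze_trajectories",
    "records_to_frame",
    "calibrate_threshold",
]

MIN_FIT_POINTS = 6
DEFAULT_BLOCK = 5
DEFAULT_THRESHOLD = 10.0  # deg, fallback when no null calibration is available
DEFAULT_LATENCY_WINDOW = 1.0  # s


@dataclass(frozen=True)
class PhaseFit:
    """Result of one quadratic-cosine fit."""

    A: float  # modulation amplitude, a.u.
    theta: float  # dipole orientation, deg in [0, 180)
    offset: float  # additive background, a.u. (0 when not fitted)
    rss: float  # residual sum of squares, a.u.^2
    n_points: int
    modulation_depth: float  # A / (A + 2*offset), 1 when offset fixed at 0
    valid: bool


@dataclass(frozen=True)
class DeltaThetaRecord:
    """Paired pre/post-flash fits and the resolved rotation angle."""

    spot_id: int
    fit_pre: Optional[PhaseFit]
    fit_post: Optional[PhaseFit]
    delta_raw: float  # theta_post - theta_pre, deg (nan if invalid)
    delta_resolved: float  # in (-90, +90], deg (nan if invalid)
    responder: bool
    response_latency: Optional[float]  # s after flash end, None if not localized

    @property
    def valid(self) -> bool:
        return (
            self.fit_pre is not None
            and self.fit_post is not None
            and self.fit_pre.valid
            and self.fit_post.valid
        )


def block_average(traj: Trajectory, block: int = DEFAULT_BLOCK) -> Trajectory:
    """Average a trajectory over non-overlapping blocks of ``block`` frames.

    The block time stamp is the mean of the member times; a trailing
    partial block is dropped.  ``block=1`` is the identity.  Pre/post-flash
    segments must be averaged separately so no block spans the flash —
    :func:`analyze_trajectory` slices first and averages second.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    n = (len(traj.times) // block) * block
    if n == 0:
        return Trajectory(
            spot_id=traj.spot_id,
            times=np.empty(0),
            raw=np.empty(0),
            background=np.empty(0),
            corrected=np.empty(0),
        )

    def _blk(x):
        return np.asarray(x[:n], dtype=np.float64).reshape(-1, block).mean(axis=1)

    return Trajectory(
        spot_id=traj.spot_id,
        times=_blk(traj.times),
        raw=_blk(traj.raw),
        background=_blk(traj.background),
        corrected=_blk(traj.corrected),
    )


def fit_cosine(
    times,
    intensities,
    omega: float,
    fit_offset: bool = False,
    amplitude_floor: float = 0.0,
) -> PhaseFit:
    """Least-squares fit of ``A*cos^2(omega*t - theta) [+ offset]``.

    Solves the harmonic linearization exactly; with ``fit_offset=False``
    the constant term is constrained to A/2 and the solution is refined by
    bounded nonlinear least squares.  ``valid`` is False when the window is
    shorter than one modulation half-period (phase unidentifiable), has
    fewer than 6 points, or the fitted amplitude is below
    ``amplitude_floor`` (fit to pure noise).
    """
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(intensities, dtype=np.float64)
    if t.size != y.size:
        raise ValueError("times and intensities must have equal length")
    n = t.size
    window_ok = n >= MIN_FIT_POINTS and (t.max() - t.min()) >= 180.0 / omega - 1e-9
    if n < 3:
        return PhaseFit(0.0, 0.0, 0.0, float(np.sum((y - y.mean()) ** 2)) if n else 0.0,
                        n, 1.0, False)

    phi = 2.0 * np.deg2rad(omega) * t
    X = np.column_stack([np.ones(n), np.cos(phi), np.sin(phi)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, bc, bs = coef
    A = 2.0 * math.hypot(bc, bs)
    theta = math.degrees(0.5 * math.atan2(bs, bc)) % 180.0
    # validity is judged on the harmonic (modulated) amplitude: a trace
    # with no 2-omega content has no identifiable phase, whatever the
    # constrained refinement below does with the constant term
    modulated = A >= max(amplitude_floor, 1e-9 * max(1.0, float(np.abs(y).max())))

    if fit_offset:
        offset = b0 - A / 2.0
        resid = y - X @ coef
        rss = float(resid @ resid)
    else:
        offset = 0.0
        if modulated:

            def _resid(p):
                return intensity_model(t, p[0], omega, math.degrees(p[1])) - y

            theta_rad = math.radians(theta)
            sol = least_squares(
                _resid,
                x0=[max(A, 1e-12), theta_rad],
                bounds=([0.0, theta_rad - math.pi], [np.inf, theta_rad + math.pi]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
            A = float(sol.x[0])
            theta = math.degrees(sol.x[1]) % 180.0
            rss = float(sol.fun @ sol.fun)
        else:
            resid = intensity_model(t, A, omega, theta) - y
            rss = float(resid @ resid)

    depth = A / (A + 2.0 * offset) if (A + 2.0 * offset) > 0 else 1.0
    valid = bool(window_ok and modulated and A >= amplitude_floor and A > 0)
    return PhaseFit(A, theta, float(offset), rss, n, float(depth), valid)


def resolve_delta(delta_raw: float) -> float:
    """Reduce a raw orientation difference modulo 180 into (-90, +90].

    The dipole is apolar, so a rotation of alpha is indistinguishable from
    alpha - 180; the smaller-magnitude angle is adopted, with the exact
    +/-90 tie mapped to +90.
    """
    r = delta_raw % 180.0
    if r > 90.0:
        r -= 180.0
    return r


def compute_delta(
    fit_pre: Optional[PhaseFit], fit_post: Optional[PhaseFit], spot_id: int = -1
) -> DeltaThetaRecord:
    """Pair two phase fits into a rotation-angle record.

    When either fit is missing or invalid, the record carries NaN angles
    and ``responder=False``.
    """
    ok = fit_pre is not None and fit_post is not None and fit_pre.valid and fit_post.valid
    if not ok:
        return DeltaThetaRecord(
            spot_id, fit_pre, fit_post, math.nan, math.nan, False, None
        )
    raw = fit_post.theta - fit_pre.theta
    return DeltaThetaRecord(
        spot_id, fit_pre, fit_post, raw, resolve_delta(raw), False, None
    )


def _changepoint_latency(
    times: np.ndarray,
    values: np.ndarray,
    fit_pre: PhaseFit,
    fit_post: PhaseFit,
    omega: float,
    flash_end: float,
) -> Optional[float]:
    """Localize the orientation switch in the post-flash frames.

    Scans the split point of a two-model residual sum (pre-flash model up
    to the split, post-flash model after it) over the raw post-flash
    frames; the minimizing split is the change point.  Returns the latency
    from flash end, or None when there are no post-flash points.
    """
    if times.size == 0:
        return None
    rp = values - intensity_model(times, fit_pre.A, omega, fit_pre.theta, fit_pre.offset)
    rq = values - intensity_model(times, fit_post.A, omega, fit_post.theta, fit_post.offset)
    pre_cum = np.concatenate([[0.0], np.cumsum(rp**2)])
    post_tail = np.concatenate([np.cumsum(rq[::-1] ** 2)[::-1], [0.0]])
    total = pre_cum + post_tail
    # where the pre/post models cross, a few frames distinguish nothing;
    # take the earliest split statistically indistinguishable from the
    # minimum rather than letting noise push the switch later
    sigma = _robust_sigma(np.diff(values)) / math.sqrt(2.0) if values.size > 2 else 0.0
    tol = 2.0 * sigma * sigma
    split = int(np.flatnonzero(total <= total.min() + tol)[0])
    if split >= times.size:
        return None  # no switch within the trace
    return float(times[split] - flash_end)


def classify_responder(
    traj: Trajectory,
    record: DeltaThetaRecord,
    acq: AcquisitionConfig,
    threshold: float = DEFAULT_THRESHOLD,
    latency_window: float = DEFAULT_LATENCY_WINDOW,
) -> DeltaThetaRecord:
    """Flag a molecule as an ATP responder.

    A responder must both rotate by more than ``threshold`` degrees
    (|delta_resolved|) and do so within ``latency_window`` seconds of the
    end of the UV flash, as localized by a two-model change-point scan of
    the raw post-flash frames.
    """
    if not record.valid:
        return record
    t = np.asarray(traj.times, dtype=np.float64)
    x = np.asarray(traj.corrected, dtype=np.float64)
    post = t >= acq.flash_end + acq.frame_interval / 2.0
    if traj.bleach_frame is not None:
        post &= np.arange(t.size) < traj.bleach_frame
    latency = _changepoint_latency(
        t[post], x[post], record.fit_pre, record.fit_post, acq.omega, acq.flash_end
    )
    responder = bool(
        abs(record.delta_resolved) > threshold
        and latency is not None
        and 0.0 <= latency <= latency_window
    )
    return replace(record, responder=responder, response_latency=latency)


def analyze_trajectory(
    traj: Trajectory,
    acq: AcquisitionConfig,
    block: int = DEFAULT_BLOCK,
    fit_offset: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
    latency_window: float = DEFAULT_LATENCY_WINDOW,
) -> DeltaThetaRecord:
    """Full per-molecule analysis: window split, averaging, fits, delta.

    The pre window is [0, flash_time); the post window starts after the
    flash (UV-transient frames excluded) and ends at the detected bleach
    or the end of the movie.  Each segment is block-averaged separately
    (default 5 frames -> 1-s points) and fitted; windows shorter than one
    modulation half-period yield invalid fits and a non-responder record.
    """
    t = np.asarray(traj.times, dtype=np.float64)
    n = t.size
    bleach_bound = traj.bleach_frame if traj.bleach_frame is not None else n
    if bleach_bound < n:
        # guard band: the bleach localization is only good to ~window
        # frames, and dark frames leaking into the fit bias the phase far
        # more than trimming a second of signal does
        bleach_bound = max(bleach_bound - block, 0)
    alive = np.arange(n) < bleach_bound
    pre_mask = (t < acq.flash_time) & alive
    post_mask = (t >= acq.flash_end + acq.frame_interval / 2.0) & alive

    sigma_frame = _robust_sigma(np.diff(traj.corrected)) / math.sqrt(2.0)
    amplitude_floor = 3.0 * sigma_frame / math.sqrt(block)

    def _fit(mask):
        seg = Trajectory(
            spot_id=traj.spot_id,
            times=t[mask],
            raw=np.asarray(traj.raw)[mask],
            background=np.asarray(traj.background)[mask],
            corrected=np.asarray(traj.corrected)[mask],
        )
        avg = block_average(seg, block)
        if avg.times.size < MIN_FIT_POINTS:
            return None
        return fit_cosine(
            avg.times,
            avg.corrected,
            acq.omega,
            fit_offset=fit_offset,
            amplitude_floor=amplitude_floor,
        )

    record = compute_delta(_fit(pre_mask), _fit(post_mask), spot_id=traj.spot_id)
    if record.valid:
        record = classify_responder(
            traj, record, acq, threshold=threshold, latency_window=latency_window
        )
    return record


def analyze_trajectories(
    trajectories: Sequence[Trajectory],
    acq: AcquisitionConfig,
    block: int = DEFAULT_BLOCK,
    fit_offset: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
    latency_window: float = DEFAULT_LATENCY_WINDOW,
) -> List[DeltaThetaRecord]:
    return [
        analyze_trajectory(
            tr, acq, block=block, fit_offset=fit_offset,
            threshold=threshold, latency_window=latency_window,
        )
        for tr in trajectories
    ]


def calibrate_threshold(null_deltas, fallback: float = DEFAULT_THRESHOLD) -> float:
    """Responder threshold from a no-ATP calibration run: 3x the fitted sd
    of the null delta-theta distribution (robust Gaussian fit), or the
    fallback when too few calibration molecules are available."""
    d = np.asarray([v for v in null_deltas if np.isfinite(v)], dtype=np.float64)
    if d.size < 10:
        return fallback
    return 3.0 * 1.4826 * float(np.median(np.abs(d - np.median(d))))


def records_to_frame(records: Sequence[DeltaThetaRecord]) -> pd.DataFrame:
    """Tabulate records with the documented column layout."""
    rows = []
    for r in records:
        rows.append(
            {
                "spot_id": r.spot_id,
                "theta_pre_deg": r.fit_pre.theta if r.fit_pre else math.nan,
                "theta_post_deg": r.fit_post.theta if r.fit_post else math.nan,
                "A_pre": r.fit_pre.A if r.fit_pre else math.nan,
                "A_post": r.fit_post.A if r.fit_post else math.nan,
                "delta_raw_deg": r.delta_raw,
                "delta_resolved_deg": r.delta_resolved,
                "responder": r.responder,
                "latency_s": r.response_latency if r.response_latency is not None else math.nan,
                "valid_pre": bool(r.fit_pre.valid) if r.fit_pre else False,
                "valid_post": bool(r.fit_post.valid) if r.fit_post else False,
            }
        )
    return pd.DataFrame(rows)
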