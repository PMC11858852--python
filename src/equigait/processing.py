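"""Stride segmentation, time normalization and landmark extraction.

A stride is one full cycle of a designated reference limb (default: right
hind), delimited by successive stance onsets.  Each stride's displacement
curves are resampled onto a 0-100 % stride grid (101 points), level-centered,
and averaged into one mean curve per sensor.  Landmarks (the two per-stride
minima/maxima, up/down amplitudes, diffTmax, ROM) are then read off a
band-limited trigonometric interpolant of the mean curve, with each minimum
assigned to the half-stride in which the corresponding reference limb
(fore pair for head/withers, hind pair for pelvis) is in stance.

Extremum locations are refined on the trigonometric interpolant with bounded
scalar minimization, so on band-limited inputs (e.g. the two-harmonic trot
model) landmark values agree with a dense analytic scan to ~1e-12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.signal import butter, sosfiltfilt

from .simulate import GaitTrial, SENSORS

logger = logging.getLogger(__name__)

N_POINTS = 101  # percent-stride grid 0,1,...,100; odd count keeps 50% exact

#: reference limb pair (right, left) whose stance defines the half-strides
HALF_REFERENCE: dict[str, tuple[str, str]] = {
    "H": ("RF", "LF"),
    "W": ("RF", "LF"),
    "P": ("RH", "LH"),
}


class SegmentationError(ValueError):
    """Too few strides or non-periodic input."""


class LandmarkError(ValueError):
    """Mean curve does not show the expected trot extrema pattern."""


@dataclass
class StrideSeries:
    """Segmented, time-normalized strides of one trial."""

    boundaries: np.ndarray  # stride-onset times (s), length n_strides + 1
    normalized: dict[str, np.ndarray]  # sensor -> (n_strides, 101), cm
    mean_curve: dict[str, np.ndarray]  # sensor -> (101,), cm, level-centered
    stride_frequency: float  # Hz
    stance_phase: dict[str, float]  # limb -> mean stance-onset phase in [0, 1)
    reference_limb: str

    @property
    def n_strides(self) -> int:
        return len(self.boundaries) - 1


@dataclass
class StrideLandmarks:
    """Per-sensor half-stride landmarks of the mean displacement curve (cm).

    ``_R``/``_L`` refer to the half-stride in which the right/left reference
    limb is in stance.  up = local max minus preceding local min within the
    half; down = local max minus following local min; diffTmax = the half's
    local max above the curve's global minimum; ROM = global max - global min.
    """

    min_R: float
    min_L: float
    max_R: float
    max_L: float
    up_R: float
    up_L: float
    down_R: float
    down_L: float
    diffTmax_R: float
    diffTmax_L: float
    ROM: float
    reference_side: str  # "forelimb" (H, W) or "hindlimb" (P)

    def swapped(self) -> "StrideLandmarks":
        """Landmarks under the opposite left/right half assignment."""
        return replace(
            self,
            min_R=self.min_L, min_L=self.min_R,
            max_R=self.max_L, max_L=self.max_R,
            up_R=self.up_L, up_L=self.up_R,
            down_R=self.down_L, down_L=self.down_R,
            diffTmax_R=self.diffTmax_L, diffTmax_L=self.diffTmax_R,
        )


# ---------------------------------------------------------------------------
# trigonometric interpolation of a periodic curve
# ---------------------------------------------------------------------------

class TrigInterpolant:
    """Band-limited interpolant of one period of a uniformly sampled curve.

    ``samples`` are values at phases j/N for j = 0..N-1 (the closing point at
    phase 1 must not be duplicated).  ``n_harmonics`` truncates the Fourier
    series; the default keeps everything below Nyquist.
    """

    def __init__(self, samples: np.ndarray, n_harmonics: int | None = None):
        y = np.asarray(samples, dtype=float)
        if y.ndim != 1 or len(y) < 4:
            raise ValueError("need a 1-D periodic curve with >= 4 samples")
        self.n = len(y)
        coeffs = np.fft.rfft(y) / self.n
        if n_harmonics is not None:
            coeffs = coeffs[: n_harmonics + 1]
        # weights: DC once, Nyquist (if present and kept) once, others twice
        w = np.full(len(coeffs), 2.0)
        w[0] = 1.0
        if self.n % 2 == 0 and len(coeffs) == self.n // 2 + 1:
            w[-1] = 1.0
        self._a = w * coeffs.real
        self._b = w * coeffs.imag
        self._k = np.arange(len(coeffs))

    @classmethod
    def from_closed_curve(cls, curve: np.ndarray, n_harmonics: int | None = None):
        """Build from a curve sampled on [0, 1] inclusive (e.g. the 101-point
        percent-stride grid); the duplicated endpoints are averaged."""
        y = np.asarray(curve, dtype=float)[:-1].copy()
        y[0] = 0.5 * (curve[0] + curve[-1])
        return cls(y, n_harmonics=n_harmonics)

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        ang = 2 * np.pi * np.multiply.outer(u, self._k)
        vals = np.cos(ang) @ self._a - np.sin(ang) @ self._b
        return vals if u.ndim else float(vals)

    def extrema(self, n_scan: int = 2048) -> tuple[list, list]:
        """All local (minima, maxima) over one period as (phase, value) pairs,
        refined to ~1e-12 in phase."""
        ug = np.arange(n_scan) / n_scan
        vg = self(ug)
        mins, maxs = [], []
        step = 1.0 / n_scan
        for i in range(n_scan):
            prev_v, next_v = vg[i - 1], vg[(i + 1) % n_scan]
            if vg[i] < prev_v and vg[i] < next_v:
                mins.append(self._refine(ug[i], step, sign=1.0))
            elif vg[i] > prev_v and vg[i] > next_v:
                maxs.append(self._refine(ug[i], step, sign=-1.0))
        return mins, maxs

    def _refine(self, u0: float, step: float, sign: float) -> tuple[float, float]:
        res = minimize_scalar(
            lambda u: sign * self(u),
            bounds=(u0 - 1.5 * step, u0 + 1.5 * step),
            method="bounded",
            options={"xatol": 1e-13},
        )
        return float(res.x % 1.0), float(sign * res.fun)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _detect_onsets(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Descending mid-range crossings of a limb-angle series (stance onsets)."""
    x = theta - np.mean(theta)
    down = (x[:-1] > 0) & (x[1:] <= 0)
    idx = np.flatnonzero(down)
    # linear interpolation of the crossing time
    frac = x[idx] / (x[idx] - x[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _circular_mean_phase(phases: np.ndarray) -> float:
    z = np.exp(2j * np.pi * phases).mean()
    return float((np.angle(z) / (2 * np.pi)) % 1.0)


def segment_strides(
    trial: GaitTrial,
    reference_limb: str = "RH",
    min_strides: int = 3,
    periodicity_threshold: float = 0.5,
) -> StrideSeries:
    """Segment a trial into reference-limb cycles and build mean stride curves.

    Uses the trial's stance events when present, otherwise detects onsets on
    the reference limb's angle series.  Raises :class:`SegmentationError` for
    fewer than ``min_strides`` complete strides or clearly non-periodic input
    (a stride poorly correlated with the mean curve).
    """
    events = trial.stance_events.get(reference_limb)
    if events is not None and len(events) >= 2:
        onsets = np.asarray(events, dtype=float)[:, 0]
    else:
        onsets = _detect_onsets(trial.limb_angle[reference_limb], trial.time)
    if len(onsets) - 1 < min_strides:
        raise SegmentationError(
            f"trial {trial.trial_id}: only {max(len(onsets) - 1, 0)} complete "
            f"strides detected; need >= {min_strides}"
        )
    stride_frequency = (len(onsets) - 1) / (onsets[-1] - onsets[0])

    t = trial.time
    normalized: dict[str, np.ndarray] = {}
    mean_curve: dict[str, np.ndarray] = {}
    for sensor in SENSORS:
        spline = CubicSpline(t, trial.displacement[sensor])
        rows = np.empty((len(onsets) - 1, N_POINTS))
        for k in range(len(onsets) - 1):
            grid = np.linspace(onsets[k], onsets[k + 1], N_POINTS)
            row = spline(grid)
            rows[k] = row - row.mean()  # level-center: drop slow drift
        normalized[sensor] = rows
        mean_curve[sensor] = rows.mean(axis=0)

    for sensor in SENSORS:
        m = mean_curve[sensor]
        denom = np.linalg.norm(m - m.mean())
        if denom == 0:
            raise SegmentationError(f"trial {trial.trial_id}: flat {sensor} channel")
        for k, row in enumerate(normalized[sensor]):
            r = row - row.mean()
            corr = float(r @ (m - m.mean()) / (np.linalg.norm(r) * denom + 1e-300))
            if corr < periodicity_threshold:
                raise SegmentationError(
                    f"trial {trial.trial_id}: stride {k} of sensor {sensor} poorly "
                    f"correlated with the mean stride (r={corr:.2f}); input not periodic"
                )

    stance_phase: dict[str, float] = {}
    span = onsets[-1] - onsets[0]
    for limb, ev in trial.stance_events.items():
        ev = np.asarray(ev, dtype=float)
        if len(ev) == 0:
            continue
        sel = ev[(ev[:, 0] >= onsets[0]) & (ev[:, 0] < onsets[-1]), 0]
        if len(sel) == 0:
            continue
        stance_phase[limb] = _circular_mean_phase((sel - onsets[0]) * stride_frequency % 1.0)
    return StrideSeries(
        boundaries=onsets,
        normalized=normalized,
        mean_curve=mean_curve,
        stride_frequency=float(stride_frequency),
        stance_phase=stance_phase,
        reference_limb=reference_limb,
    )


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def curve_landmarks(
    mean_curve: np.ndarray,
    phase_R: float,
    phase_L: float,
    reference_side: str = "forelimb",
    n_harmonics: int | None = 10,
) -> StrideLandmarks:
    """Landmarks of one closed percent-stride curve.

    ``phase_R``/``phase_L`` are the stance-onset phases (fraction of stride)
    of the right and left reference limb; the half-stride of side X spans from
    that limb's onset to the contralateral onset.  ``n_harmonics`` truncates
    the interpolant (light denoising; exact for band-limited curves).
    """
    interp = TrigInterpolant.from_closed_curve(mean_curve, n_harmonics=n_harmonics)
    mins, maxs = interp.extrema()
    if len(mins) != 2 or len(maxs) != 2:
        raise LandmarkError(
            f"expected 2 minima and 2 maxima per stride, found "
            f"{len(mins)} minima and {len(maxs)} maxima"
        )

    half_len = (phase_L - phase_R) % 1.0
    if half_len == 0.0:
        raise LandmarkError("ambiguous half assignment: identical stance phases")

    def in_half_R(u: float) -> bool:
        return (u - phase_R) % 1.0 < half_len

    by_side_min = {"R": [m for m in mins if in_half_R(m[0])],
                   "L": [m for m in mins if not in_half_R(m[0])]}
    if len(by_side_min["R"]) != 1 or len(by_side_min["L"]) != 1:
        raise LandmarkError(
            "ambiguous half assignment: both minima fall in the same half-stride"
        )
    min_pt = {side: pts[0] for side, pts in by_side_min.items()}

    # maxima: assign by half membership, falling back to stride order
    by_side_max = {"R": [m for m in maxs if in_half_R(m[0])],
                   "L": [m for m in maxs if not in_half_R(m[0])]}
    if len(by_side_max["R"]) == 1 and len(by_side_max["L"]) == 1:
        max_pt = {side: pts[0] for side, pts in by_side_max.items()}
    else:
        max_pt = {side: _next_extremum(min_pt[side][0], maxs) for side in ("R", "L")}

    gmin = min(m[1] for m in mins)
    gmax = max(m[1] for m in maxs)
    out = {}
    for side in ("R", "L"):
        u_min, v_min = min_pt[side]
        out[f"min_{side}"] = v_min
        out[f"max_{side}"] = max_pt[side][1]
        out[f"up_{side}"] = _next_extremum(u_min, maxs)[1] - v_min
        out[f"down_{side}"] = _prev_extremum(u_min, maxs)[1] - v_min
        out[f"diffTmax_{side}"] = max_pt[side][1] - gmin
    return StrideLandmarks(ROM=gmax - gmin, reference_side=reference_side, **out)


def _next_extremum(u: float, pts: list) -> tuple[float, float]:
    """First of ``pts`` after phase ``u``, cyclically."""
    return min(pts, key=lambda p: (p[0] - u) % 1.0)


def _prev_extremum(u: float, pts: list) -> tuple[float, float]:
    return min(pts, key=lambda p: (u - p[0]) % 1.0)


def extract_landmarks(
    series: StrideSeries,
    sensor: str,
    half_assignment: dict[str, float] | None = None,
    n_harmonics: int | None = 10,
) -> StrideLandmarks:
    """Landmarks of one sensor's mean stride curve.

    Half-strides are keyed to forelimb stance for head/withers and to hindlimb
    stance for the pelvis; ``half_assignment`` ({"R": phase, "L": phase})
    overrides the stance phases measured during segmentation.
    """
    if sensor not in SENSORS:
        raise ValueError(f"unknown sensor {sensor!r}")
    right_limb, left_limb = HALF_REFERENCE[sensor]
    if half_assignment is None:
        try:
            half_assignment = {
                "R": series.stance_phase[right_limb],
                "L": series.stance_phase[left_limb],
            }
        except KeyError as exc:
            raise LandmarkError(
                f"stance events missing for limb {exc.args[0]}; cannot assign half-strides"
            ) from exc
    return curve_landmarks(
        series.mean_curve[sensor],
        phase_R=half_assignment["R"],
        phase_L=half_assignment["L"],
        reference_side="forelimb" if sensor in ("H", "W") else "hindlimb",
        n_harmonics=n_harmonics,
    )


def write_landmarks_csv(per_trial: dict[str, dict[str, StrideLandmarks]], path) -> None:
    """Long-format landmarks CSV: trial_id, sensor, field, value."""
    import pandas as pd

    rows = []
    numeric = ("min_R", "min_L", "max_R", "max_L", "up_R", "up_L",
               "down_R", "down_L", "diffTmax_R", "diffTmax_L", "ROM")
    for trial_id, by_sensor in per_trial.items():
        for sensor, lm in by_sensor.items():
            for field in numeric:
                rows.append({"trial_id": trial_id, "sensor": sensor,
                             "field": field, "value": getattr(lm, field)})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# optional plumbing: vertical displacement from acceleration
# ---------------------------------------------------------------------------

def displacement_from_acceleration(
    acc: np.ndarray, sampling_rate: float, cutoff_hz: float = 0.5
) -> np.ndarray:
    """Drift-removed double integration of vertical acceleration (m/s^2 -> cm).

    High-pass filters (2nd-order Butterworth, zero phase) are applied before
    and after each integration to reject integration drift; the cut-off must
    sit well below the stride frequency.  This is a simplified approximation
    for imported raw data and is not used by the core pipeline on synthetic
    displacement signals.
    """
    acc = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(acc)):
        raise ValueError("acceleration series contains non-finite samples")
    if np.allclose(acc, 0.0):
        return np.zeros_like(acc)
    sos = butter(2, cutoff_hz, btype="highpass", fs=sampling_rate, output="sos")
    dt = 1.0 / sampling_rate
    x = sosfiltfilt(sos, acc)
    x = sosfiltfilt(sos, cumulative_trapezoid(x, dx=dt, initial=0.0))
    x = sosfiltfilt(sos, cumulative_trapezoid(x, dx=dt, initial=0.0))
    return (x - x.mean()) * 100.0
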