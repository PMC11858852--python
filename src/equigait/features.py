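"""The 27 trial-level movement-asymmetry features.

Per upper-body sensor (head H, withers W, pelvis P): five asymmetry indices
(AsI-up, AsI-down, AsI-max, AsI-min, AsI-Tmax), the second/first harmonic
energy ratio ERz, the first-minus-second harmonic phase difference dphi, and
the range of motion ROM.  Per limb pair: the retraction-angle asymmetry at
foot lift-off.  Plus the stride frequency.  27 features in total, in a fixed
order.

Asymmetry-index dialects
------------------------
Two normalizations are supported.  The ``caption`` dialect divides each
left-minus-right numerator by the left side's own amplitude (up/down/diffTmax
as appropriate), i.e. for a curve whose halves are keyed to the right/left
reference limb:

    AsI-min  = 100 * (min_R - min_L) / up_L
    AsI-max  = 100 * (max_L - max_R) / up_L
    AsI-up   = 100 * (up_L - up_R) / up_L
    AsI-down = 100 * (down_L - down_R) / down_L
    AsI-Tmax = 100 * (diffTmax_L - diffTmax_R) / diffTmax_L

The ``rom_normalized`` dialect divides the same numerators by the stride's
range of motion, which makes every index exactly antisymmetric under a
left/right mirror.  Positive values indicate a right-side deficit in both
dialects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .processing import SENSORS, StrideLandmarks, StrideSeries, extract_landmarks, segment_strides
from .simulate import GaitTrial

logger = logging.getLogger(__name__)

DIALECTS = ("caption", "rom_normalized")

#: the 27 feature names, fixed order (matches the reference variable table)
FEATURE_NAMES: tuple[str, ...] = (
    "AsI-up_H", "AsI-up_W", "AsI-up_P",
    "AsI-down_H", "AsI-down_W", "AsI-down_P",
    "AsI-max_H", "AsI-max_W", "AsI-max_P",
    "AsI-min_H", "AsI-min_W", "AsI-min_P",
    "AsI-retraction_W", "AsI-retraction_P",
    "AsI-Tmax_H", "AsI-Tmax_W", "AsI-Tmax_P",
    "ERz_H", "ERz_W", "ERz_P",
    "dphi_H", "dphi_W", "dphi_P",
    "stride_frequency",
    "ROM_H", "ROM_W", "ROM_P",
)

ASI_KEYS = ("AsI-up", "AsI-down", "AsI-max", "AsI-min", "AsI-Tmax")


class DegenerateLandmarksError(ValueError):
    """An asymmetry-index denominator is zero."""


class FeatureExtractionError(RuntimeError):
    """A trial failed somewhere in the feature pipeline."""


def wrap_phase_deg(x: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    y = (x + 180.0) % 360.0 - 180.0
    return 180.0 if y == -180.0 else y


def asymmetry_indices(lm: StrideLandmarks, dialect: str = "caption") -> dict[str, float]:
    """The five asymmetry indices (%) of one sensor's landmarks."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    numerators = {
        "AsI-min": lm.min_R - lm.min_L,
        "AsI-max": lm.max_L - lm.max_R,
        "AsI-up": lm.up_L - lm.up_R,
        "AsI-down": lm.down_L - lm.down_R,
        "AsI-Tmax": lm.diffTmax_L - lm.diffTmax_R,
    }
    if dialect == "caption":
        denominators = {
            "AsI-min": lm.up_L,
            "AsI-max": lm.up_L,
            "AsI-up": lm.up_L,
            "AsI-down": lm.down_L,
            "AsI-Tmax": lm.diffTmax_L,
        }
    else:
        denominators = {k: lm.ROM for k in numerators}
    out = {}
    for key in ASI_KEYS:
        den = denominators[key]
        if den == 0.0:
            raise DegenerateLandmarksError(f"{key}: zero denominator ({dialect} dialect)")
        out[key] = 100.0 * numerators[key] / den
    return out


@dataclass(frozen=True)
class HarmonicFit:
    """Least-squares two-harmonic decomposition of a stride curve.

    amplitude_1/phase_1 describe the once-per-stride (asymmetric) component,
    amplitude_2/phase_2 the twice-per-stride (symmetric trot) component.
    Phases are in degrees in (-180, 180], with phase = atan2(sin-coef,
    cos-coef); a vanishing amplitude has phase 0 by convention.
    """

    amplitude_1: float
    amplitude_2: float
    phase_1: float
    phase_2: float
    residual_rms: float


def harmonic_fit(mean_curve: np.ndarray, stride_frequency: float | None = None) -> HarmonicFit:
    """Fit c0 + c1 cos(2*pi*u) + s1 sin(2*pi*u) + c2 cos(4*pi*u) + s2 sin(4*pi*u)
    over one normalized stride (the curve is assumed to span phases 0..1
    inclusive).  ``stride_frequency`` is accepted for interface symmetry but
    does not affect the normalized-phase fit."""
    y = np.asarray(mean_curve, dtype=float)
    if y.ndim != 1 or len(y) < 5:
        raise ValueError("need a 1-D stride curve with >= 5 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("stride curve contains non-finite values")
    u = np.arange(len(y)) / (len(y) - 1)
    design = np.column_stack([
        np.ones_like(u),
        np.cos(2 * np.pi * u), np.sin(2 * np.pi * u),
        np.cos(4 * np.pi * u), np.sin(4 * np.pi * u),
    ])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef

    def polar(c: float, s: float) -> tuple[float, float]:
        amp = math.hypot(c, s)
        # amplitudes at numerical-noise level carry no phase information
        phase = 0.0 if amp < 1e-12 else wrap_phase_deg(math.degrees(math.atan2(s, c)))
        return amp, phase

    a1, p1 = polar(coef[1], coef[2])
    a2, p2 = polar(coef[3], coef[4])
    return HarmonicFit(
        amplitude_1=a1, amplitude_2=a2, phase_1=p1, phase_2=p2,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


class FourierFeatures(NamedTuple):
    erz: float  # 100 * amplitude_2^2 / amplitude_1^2, capped when degenerate
    dphi: float  # phase_1 - phase_2 wrapped into (-180, 180], degrees
    degenerate: bool


def fourier_features(fit: HarmonicFit, erz_ceiling: float = 1e6) -> FourierFeatures:
    """Energy ratio (%) and phase difference of a harmonic fit.

    A symmetric signal has no first harmonic, making the ratio unbounded; the
    value is then capped at ``erz_ceiling`` and flagged degenerate.
    """
    if fit.amplitude_1 <= 0.0:
        erz, degenerate = erz_ceiling, True
    else:
        raw = 100.0 * fit.amplitude_2**2 / fit.amplitude_1**2
        degenerate = not np.isfinite(raw) or raw > erz_ceiling
        erz = erz_ceiling if degenerate else raw
    if degenerate:
        logger.debug("ERz degenerate (amplitude_1=%g); capped at %g", fit.amplitude_1, erz_ceiling)
    return FourierFeatures(erz=erz, dphi=wrap_phase_deg(fit.phase_1 - fit.phase_2), degenerate=degenerate)


def _parabolic_extremum_value(y0: float, y1: float, y2: float) -> float:
    """Value at the vertex of the parabola through three consecutive samples."""
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return y1
    delta = 0.5 * (y0 - y2) / denom
    return y1 - 0.25 * (y0 - y2) * delta


def retraction_asymmetry(trial: GaitTrial, pair: str) -> float:
    """Left-right retraction-angle asymmetry (%) of a limb pair at lift-off.

    Per limb, the retraction angle is the mean over strides of |angle| at foot
    lift-off (the retraction extremum, refined by local parabolic
    interpolation around the event); the index is
    100 * (left - right) / ((left + right) / 2), so a reduced right-limb
    retraction gives a positive index.
    """
    try:
        right_limb, left_limb = {"fore": ("RF", "LF"), "hind": ("RH", "LH")}[pair]
    except KeyError:
        raise ValueError(f"unknown pair {pair!r}; expected 'fore' or 'hind'") from None
    means = {}
    fs = trial.sampling_rate
    n = trial.n_samples
    for limb in (right_limb, left_limb):
        events = np.asarray(trial.stance_events.get(limb, ()), dtype=float).reshape(-1, 2)
        if len(events) < 3:
            raise FeatureExtractionError(
                f"trial {trial.trial_id}: fewer than 3 lift-off events for limb {limb}"
            )
        theta = trial.limb_angle[limb]
        window = max(2, int(round(0.05 * fs / max(trial.params.stride_frequency, 1e-9)))
                     ) if trial.params is not None else 5
        vals = []
        for _, liftoff in events:
            i0 = int(round(liftoff * fs))
            lo, hi = max(1, i0 - window), min(n - 1, i0 + window + 1)
            if hi <= lo:
                continue
            i = lo + int(np.argmin(theta[lo:hi]))
            i = min(max(i, 1), n - 2)
            vals.append(abs(_parabolic_extremum_value(theta[i - 1], theta[i], theta[i + 1])))
        if len(vals) < 3:
            raise FeatureExtractionError(
                f"trial {trial.trial_id}: too few usable lift-off events for limb {limb}"
            )
        means[limb] = float(np.mean(vals))
    left, right = means[left_limb], means[right_limb]
    denom = 0.5 * (left + right)
    if denom == 0.0:
        raise DegenerateLandmarksError("AsI-retraction: zero mean retraction angle")
    return 100.0 * (left - right) / denom


def build_feature_vector(
    trial: GaitTrial,
    dialect: str = "caption",
    n_harmonics: int | None = 10,
    erz_ceiling: float = 1e6,
    series: StrideSeries | None = None,
) -> dict[str, float]:
    """All 27 features of one trial, in :data:`FEATURE_NAMES` order.

    Deterministic given the trial.  A precomputed :class:`StrideSeries` may be
    passed to avoid re-segmenting.
    """
    try:
        if series is None:
            series = segment_strides(trial)
        fv: dict[str, float] = {}
        landmarks = {s: extract_landmarks(series, s, n_harmonics=n_harmonics) for s in SENSORS}
        for sensor in SENSORS:
            asi = asymmetry_indices(landmarks[sensor], dialect=dialect)
            for key in ASI_KEYS:
                fv[f"{key}_{sensor}"] = asi[key]
        fv["AsI-retraction_W"] = retraction_asymmetry(trial, "fore")
        fv["AsI-retraction_P"] = retraction_asymmetry(trial, "hind")
        for sensor in SENSORS:
            fit = harmonic_fit(series.mean_curve[sensor])
            ff = fourier_features(fit, erz_ceiling=erz_ceiling)
            fv[f"ERz_{sensor}"] = ff.erz
            fv[f"dphi_{sensor}"] = ff.dphi
            fv[f"ROM_{sensor}"] = landmarks[sensor].ROM
        fv["stride_frequency"] = series.stride_frequency
    except (ValueError, RuntimeError) as exc:
        if isinstance(exc, FeatureExtractionError):
            raise
        raise FeatureExtractionError(f"trial {trial.trial_id}: {exc}") from exc
    return {name: float(fv[name]) for name in FEATURE_NAMES}


def cohort_feature_table(
    trials: list[GaitTrial],
    dialect: str = "caption",
    n_harmonics: int | None = 10,
    erz_ceiling: float = 1e6,
) -> pd.DataFrame:
    """Feature table of a cohort: one row per trial, columns trial_id, label,
    grade and the 27 features."""
    rows = []
    for trial in trials:
        fv = build_feature_vector(
            trial, dialect=dialect, n_harmonics=n_harmonics, erz_ceiling=erz_ceiling
        )
        rows.append({"trial_id": trial.trial_id, "label": trial.label, "grade": trial.grade, **fv})
    return pd.DataFrame(rows, columns=["trial_id", "label", "grade", *FEATURE_NAMES])


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(FEATURE_NAMES) - set(table.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    return table
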