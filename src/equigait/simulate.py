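"""Seeded simulator of straight-line trot recordings with single-limb lameness.

The generator emulates what a trunk- and limb-mounted IMU system measures on a
trotting horse: vertical displacement of the head (H), withers (W) and pelvis
(P), and protraction–retraction angle of the four cannon-mounted sensors
(RF, LF, RH, LH), sampled at 200 Hz over ~15 strides.

Signal model
------------
Sound trot is left/right symmetric, so upper-body vertical displacement is
dominated by a two-per-stride oscillation (one bounce per diagonal stance).
Single-limb lameness breaks that symmetry and injects a once-per-stride
component whose amplitude scales with lameness grade and whose distribution
across sensors follows a compensation pattern (forelimb lameness dominates
head/withers, hindlimb lameness dominates pelvis, with ipsilateral carry-over).
Each displacement channel is

    y_s(t) = -A_s cos(4*pi*f*t - pi/2) + a_s sin(2*pi*f*t + psi_s) + noise,

with ``a_s = asymmetry_gain * grade * C[label, s] * A_s``.  The fixed phase
offsets place the two displacement minima at the middle of the corresponding
reference-limb stances, and the sign convention is that a *positive*
compensation weight raises the minimum of the right-limb stance half (the
lame-side bounce is damped), matching the caption-style asymmetry-index signs
downstream.

Limb angles are ``theta_l(t) = Theta_l sin(2*pi*f*t + phi_l)`` with trot
phasing (diagonal limbs in phase, contralateral limbs pi apart); the lame
limb's amplitude is reduced by ``retraction_deficit_per_grade * grade``.
Stance is entered when the angle crosses mid-range going down and ends at the
retraction extremum (most negative angle), which defines exact event times on
the sinusoid.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import CLASS_ORDER, GRADE_RANGE, REFERENCE_CLASS_COUNTS, REFERENCE_GRADE_COUNTS

logger = logging.getLogger(__name__)

SENSORS: tuple[str, ...] = ("H", "W", "P")
LIMBS: tuple[str, ...] = ("RF", "LF", "RH", "LH")

#: stride-phase offset of each limb's angle cycle (diagonal pairs in phase)
LIMB_PHASE: dict[str, float] = {"RH": 0.0, "LF": 0.0, "RF": np.pi, "LH": np.pi}

#: phase of the once-per-stride asymmetry component per sensor; chosen so a
#: positive compensation weight raises the displacement minimum of the right
#: reference limb's stance half (RF half for H/W, RH half for P)
ASYM_PHASE: dict[str, float] = {"H": np.pi / 4, "W": np.pi / 4, "P": -3 * np.pi / 4}

#: left-right mirror of labels/limbs
MIRROR_LABEL: dict[str, str] = {"RF": "LF", "LF": "RF", "RH": "LH", "LH": "RH", "SOUND": "SOUND"}

DEFAULT_CLASS_COUNTS: dict[str, int] = dict(REFERENCE_CLASS_COUNTS)

_DEFAULT_COMPENSATION: dict[str, tuple[float, float, float]] = {
    # rows: lame limb; columns: (H, W, P) signed relative asymmetry weights.
    # Signs encode side (right positive); forelimb lameness dominates
    # head/withers, hindlimb lameness dominates pelvis with ipsilateral
    # head/withers carry-over.  Modeling choice, configurable.
    "RF": (1.0, 0.6, 0.1),
    "LF": (-1.0, -0.6, -0.1),
    "RH": (0.4, 0.2, 1.0),
    "LH": (-0.4, -0.2, -1.0),
}


class SimulationError(ValueError):
    """Invalid simulation parameters or labels."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated trot recording.

    Units: stride_frequency and sampling_rate in Hz, amplitudes in cm, limb
    angles in degrees, asymmetry_gain and retraction_deficit_per_grade per
    grade unit, noise_sd in cm, angle_noise_sd in degrees.  amplitude_cv and
    stride_frequency_sd describe between-horse variability and are used by
    :func:`simulate_cohort` only.
    """

    stride_frequency: float = 1.4
    sampling_rate: float = 200.0
    n_strides: int = 15
    base_amplitude: dict[str, float] = field(
        default_factory=lambda: {"H": 3.0, "W": 2.5, "P": 3.5}
    )
    asymmetry_gain: float = 0.05
    compensation_matrix: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPENSATION)
    )
    retraction_amplitude: float = 25.0
    retraction_deficit_per_grade: float = 0.03
    noise_sd: float = 0.05
    angle_noise_sd: float = 0.2
    amplitude_cv: float = 0.10
    stride_frequency_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize container types so config round-trips compare equal
        object.__setattr__(self, "base_amplitude", dict(self.base_amplitude))
        object.__setattr__(
            self,
            "compensation_matrix",
            {k: tuple(float(x) for x in v) for k, v in self.compensation_matrix.items()},
        )

    def validate(self) -> None:
        scalars = (
            self.stride_frequency,
            self.sampling_rate,
            self.asymmetry_gain,
            self.retraction_amplitude,
            self.retraction_deficit_per_grade,
            self.noise_sd,
            self.angle_noise_sd,
            self.amplitude_cv,
            self.stride_frequency_sd,
        )
        if not all(np.isfinite(scalars)):
            raise SimulationError("all simulation parameters must be finite")
        if self.sampling_rate <= 4 * self.stride_frequency:
            raise SimulationError(
                f"sampling_rate {self.sampling_rate} Hz too low for stride "
                f"frequency {self.stride_frequency} Hz (need > 4x; aliasing guard)"
            )
        if self.n_strides < 3:
            raise SimulationError("n_strides must be >= 3")
        if set(self.base_amplitude) != set(SENSORS) or any(
            not np.isfinite(v) or v <= 0 for v in self.base_amplitude.values()
        ):
            raise SimulationError("base_amplitude must be positive and finite for H, W, P")
        if self.noise_sd < 0 or self.angle_noise_sd < 0:
            raise SimulationError("noise standard deviations must be >= 0")
        if set(self.compensation_matrix) != set(LIMBS):
            raise SimulationError("compensation_matrix must have rows RF, LF, RH, LH")


@dataclass
class GaitTrial:
    """One simulated (or imported) trot recording of a single horse.

    ``stance_events[limb]`` is an (n_events, 2) array of (stance-onset,
    lift-off) times in seconds.  All sampled series share one time base.
    """

    trial_id: str
    displacement: dict[str, np.ndarray]  # sensor -> vertical displacement, cm
    limb_angle: dict[str, np.ndarray]  # limb -> protraction(+)/retraction(-) angle, deg
    stance_events: dict[str, np.ndarray]  # limb -> (n, 2) of (onset_s, liftoff_s)
    label: str
    grade: int
    sampling_rate: float
    params: SimParams | None = None

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.displacement.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def _stance_event_times(limb: str, f: float, t_end: float) -> np.ndarray:
    """Exact stance onset/lift-off times of ``limb`` within [0, t_end]."""
    phi = LIMB_PHASE[limb]
    # onset: angle crosses zero going down -> 2*pi*f*t + phi = pi (mod 2*pi)
    # lift-off: retraction extremum       -> 2*pi*f*t + phi = 3*pi/2 (mod 2*pi)
    k0 = int(np.floor((phi - np.pi) / (2 * np.pi)))  # first k giving t >= 0
    events = []
    k = k0
    while True:
        t_on = (np.pi - phi + 2 * np.pi * k) / (2 * np.pi * f)
        t_off = t_on + 0.25 / f
        if t_on < -1e-12:
            k += 1
            continue
        if t_off > t_end + 1e-12:
            break
        events.append((t_on, t_off))
        k += 1
    return np.array(events, dtype=float).reshape(-1, 2)


def simulate_trial(
    label: str,
    grade: int,
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
    trial_id: str = "trial",
) -> GaitTrial:
    """Simulate one labeled trot recording.

    With the seed fixed the output is bit-identical across calls.  ``rng``
    overrides the generator derived from ``params.seed`` (used by
    :func:`simulate_cohort` to hand each trial its own stream).
    """
    params = params or SimParams()
    params.validate()
    if label not in CLASS_ORDER:
        raise SimulationError(f"unknown label {label!r}; expected one of {CLASS_ORDER}")
    if not 0 <= grade <= 10:
        raise SimulationError(f"grade {grade} outside the 0-10 scale")
    if label == "SOUND" and grade > 1:
        raise SimulationError("sound horses carry grade 0 or 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    f = params.stride_frequency
    fs = params.sampling_rate
    n = int(round(params.n_strides / f * fs))
    t = np.arange(n) / fs

    displacement: dict[str, np.ndarray] = {}
    for j, sensor in enumerate(SENSORS):
        amp = params.base_amplitude[sensor]
        if label == "SOUND":
            asym = 0.0
        else:
            asym = params.asymmetry_gain * grade * params.compensation_matrix[label][j] * amp
        y = -amp * np.cos(4 * np.pi * f * t - np.pi / 2)
        if asym != 0.0:
            y = y + asym * np.sin(2 * np.pi * f * t + ASYM_PHASE[sensor])
        if params.noise_sd > 0:
            y = y + rng.normal(0.0, params.noise_sd, n)
        displacement[sensor] = y

    limb_angle: dict[str, np.ndarray] = {}
    for limb in LIMBS:
        theta_amp = params.retraction_amplitude
        if limb == label:
            theta_amp *= 1.0 - params.retraction_deficit_per_grade * grade
        theta = theta_amp * np.sin(2 * np.pi * f * t + LIMB_PHASE[limb])
        if params.angle_noise_sd > 0:
            theta = theta + rng.normal(0.0, params.angle_noise_sd, n)
        limb_angle[limb] = theta

    stance_events = {limb: _stance_event_times(limb, f, t[-1]) for limb in LIMBS}
    return GaitTrial(
        trial_id=trial_id,
        displacement=displacement,
        limb_angle=limb_angle,
        stance_events=stance_events,
        label=label,
        grade=int(grade),
        sampling_rate=fs,
        params=params,
    )


def default_grade_sampler(label: str, rng: np.random.Generator) -> int:
    """Sample a lameness grade from the reference cohort's grade distribution."""
    if label == "SOUND":
        return 0
    counts = np.asarray(REFERENCE_GRADE_COUNTS[label], dtype=float)
    return int(rng.choice(GRADE_RANGE, p=counts / counts.sum()))


def simulate_cohort(
    class_counts: dict[str, int] | None = None,
    grade_sampler=None,
    params: SimParams | None = None,
) -> list[GaitTrial]:
    """Simulate a labeled cohort, one trial per horse.

    Per-trial random streams are spawned deterministically from the master
    seed, so regenerating with the same parameters reproduces every trial
    exactly.  Between-horse variability (amplitude_cv, stride_frequency_sd)
    perturbs each horse's base amplitudes and cadence.
    """
    params = params or SimParams()
    params.validate()
    class_counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    if any(c < 0 for c in class_counts.values()):
        raise SimulationError("class counts must be >= 0")
    total = sum(class_counts.values())
    if total == 0:
        raise SimulationError("empty cohort")
    unknown = set(class_counts) - set(CLASS_ORDER)
    if unknown:
        raise SimulationError(f"unknown labels in class_counts: {sorted(unknown)}")
    if grade_sampler is None:
        grade_sampler = default_grade_sampler

    labels = [lab for lab in CLASS_ORDER for _ in range(class_counts.get(lab, 0))]
    children = np.random.SeedSequence(params.seed).spawn(total)
    trials: list[GaitTrial] = []
    for i, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        f_i = params.stride_frequency
        if params.stride_frequency_sd > 0:
            f_i += float(np.clip(rng.normal(0.0, params.stride_frequency_sd),
                                 -2.5 * params.stride_frequency_sd,
                                 2.5 * params.stride_frequency_sd))
        amps = dict(params.base_amplitude)
        if params.amplitude_cv > 0:
            for s in SENSORS:
                mult = float(np.clip(rng.normal(1.0, params.amplitude_cv), 0.5, 1.5))
                amps[s] = params.base_amplitude[s] * mult
        trial_params = dataclasses.replace(
            params, stride_frequency=f_i, base_amplitude=amps, seed=trial_seed
        )
        grade = 0 if label == "SOUND" else int(grade_sampler(label, rng))
        trials.append(
            simulate_trial(label, grade, trial_params, rng=rng, trial_id=f"t{i:03d}_{label}")
        )
    return trials


def mirror_trial(trial: GaitTrial) -> GaitTrial:
    """Relabel left and right limbs (the horse seen in a mirror).

    Displacement channels are unchanged; limb-angle channels and stance
    events swap sides, and the label mirrors (RF<->LF, RH<->LH).
    """
    return GaitTrial(
        trial_id=trial.trial_id + "_mirrored",
        displacement={s: v for s, v in trial.displacement.items()},
        limb_angle={MIRROR_LABEL[l]: v for l, v in trial.limb_angle.items()},
        stance_events={MIRROR_LABEL[l]: v for l, v in trial.stance_events.items()},
        label=MIRROR_LABEL[trial.label],
        grade=trial.grade,
        sampling_rate=trial.sampling_rate,
        params=trial.params,
    )


# ---------------------------------------------------------------------------
# long-format CSV interchange
# ---------------------------------------------------------------------------

_CHANNELS = tuple(f"disp_{s}" for s in SENSORS) + tuple(f"ang_{l}" for l in LIMBS)


def write_cohort_csv(trials: list[GaitTrial], outdir: str | Path) -> dict[str, Path]:
    """Write signals, labels and events CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sig_frames = []
    labels_rows = []
    event_rows = []
    for trial in trials:
        t = trial.time
        for sensor in SENSORS:
            sig_frames.append(
                pd.DataFrame(
                    {
                        "trial_id": trial.trial_id,
                        "time_s": t,
                        "channel": f"disp_{sensor}",
                        "value": trial.displacement[sensor],
                    }
                )
            )
        for limb in LIMBS:
            sig_frames.append(
                pd.DataFrame(
                    {
                        "trial_id": trial.trial_id,
                        "time_s": t,
                        "channel": f"ang_{limb}",
                        "value": trial.limb_angle[limb],
                    }
                )
            )
            for onset, liftoff in trial.stance_events[limb]:
                event_rows.append(
                    {
                        "trial_id": trial.trial_id,
                        "limb": limb,
                        "stance_onset_s": onset,
                        "liftoff_s": liftoff,
                    }
                )
        seed = trial.params.seed if trial.params is not None else ""
        labels_rows.append(
            {"trial_id": trial.trial_id, "label": trial.label, "grade": trial.grade, "seed": seed}
        )
    paths = {
        "signals": outdir / "signals.csv",
        "labels": outdir / "labels.csv",
        "events": outdir / "events.csv",
    }
    pd.concat(sig_frames, ignore_index=True).to_csv(paths["signals"], index=False)
    pd.DataFrame(labels_rows).to_csv(paths["labels"], index=False)
    pd.DataFrame(event_rows).to_csv(paths["events"], index=False)
    return paths


def read_cohort_csv(
    signals: str | Path, labels: str | Path, events: str | Path
) -> list[GaitTrial]:
    """Reconstruct trials from the long-format CSVs written by write_cohort_csv."""
    sig = pd.read_csv(signals)
    lab = pd.read_csv(labels).set_index("trial_id")
    ev = pd.read_csv(events)
    trials = []
    for trial_id, g in sig.groupby("trial_id", sort=False):
        channels = {ch: sub.sort_values("time_s") for ch, sub in g.groupby("channel")}
        missing = set(_CHANNELS) - set(channels)
        if missing:
            raise SimulationError(f"trial {trial_id}: missing channels {sorted(missing)}")
        t = channels[_CHANNELS[0]]["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        ev_t = ev[ev.trial_id == trial_id]
        stance_events = {
            limb: ev_t[ev_t.limb == limb][["stance_onset_s", "liftoff_s"]]
            .to_numpy(dtype=float)
            .reshape(-1, 2)
            for limb in LIMBS
        }
        trials.append(
            GaitTrial(
                trial_id=str(trial_id),
                displacement={
                    s: channels[f"disp_{s}"]["value"].to_numpy(dtype=float) for s in SENSORS
                },
                limb_angle={
                    l: channels[f"ang_{l}"]["value"].to_numpy(dtype=float) for l in LIMBS
                },
                stance_events=stance_events,
                label=str(lab.loc[trial_id, "label"]),
                grade=int(lab.loc[trial_id, "grade"]),
                sampling_rate=fs,
            )
        )
    return trials
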