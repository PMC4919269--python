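"""Synthetic cohorts for dynamic renal PET with known kinetic ground truth.

This module generates everything a 90-minute dynamic small-animal PET study
of a renally excreted organic-cation tracer produces at the time-activity
curve (TAC) level: a bolus plasma input function, one-tissue-compartment
renal-cortex kinetics, frame-averaged sampling on a 33-frame schedule,
duration-scaled Gaussian measurement noise, and per-subject dosimetry
(body weight, injected dose).  Group presets encode the effect sizes of a
chronic-kidney-disease (CKD) study design: a transgenic CKD group with
reduced basolateral uptake (lower K1, higher plasma exposure), organic
cation transporter (OCT1/2) knock-outs, OCT1/2 inhibition by cimetidine,
and MATE1 inhibition by pyrimethamine.

All concentrations are decay-corrected to injection time, the standard PET
convention, so radioactive decay does not appear in the kinetics.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FrameSchedule",
    "InputFunctionModel",
    "TimeActivityCurve",
    "SubjectRecord",
    "GroupPreset",
    "CohortSubject",
    "CONTROL_INPUT",
    "DEFAULT_PRESETS",
    "REFERENCE_BODY_WEIGHT_G",
    "REFERENCE_DOSE_KBQ",
    "NOISE_FLOOR_KBQ_PER_ML",
    "make_input_function",
    "simulate_tissue_tac",
    "simulate_bladder_tac",
    "add_noise",
    "simulate_cohort",
    "write_tac",
    "read_tac",
    "export_cohort",
]

# Reference dosimetry for the cohort generator: a ~25 g mouse receiving a
# 7.7 MBq bolus.  Per-subject plasma amplitude scales with dose per
# distribution volume, i.e. with (ID / 7700 kBq) / (BW / 25 g).
REFERENCE_BODY_WEIGHT_G = 25.0
REFERENCE_DOSE_KBQ = 7700.0
#: floor used inside the duration-scaled noise model, kBq/mL
NOISE_FLOOR_KBQ_PER_ML = 0.01


class ValidationError(ValueError):
    """Raised when a domain object or operation argument is invalid."""


# --------------------------------------------------------------------------
# frame schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Temporal sampling grid of a dynamic PET acquisition.

    Frames are contiguous and non-overlapping; times are seconds from
    injection.  The default schedule has 33 frames spanning 5400 s (90 min):
    10 x 6 s, 8 x 30 s, 5 x 60 s, 4 x 300 s, 6 x 600 s.
    """

    frame_start_s: np.ndarray
    frame_duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start_s, dtype=float)
        dur = np.asarray(self.frame_duration_s, dtype=float)
        object.__setattr__(self, "frame_start_s", start)
        object.__setattr__(self, "frame_duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValidationError("frame_start_s and frame_duration_s must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValidationError("all frame durations must be > 0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @property
    def count(self) -> int:
        return int(self.frame_start_s.size)

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start_s + self.frame_duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.frame_start_s + 0.5 * self.frame_duration_s

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def span_s(self) -> float:
        return float(self.frame_end_s[-1] - self.frame_start_s[0])

    @classmethod
    def from_durations(cls, durations_s: Iterable[float], start_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(list(durations_s), dtype=float)
        starts = start_s + np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(starts, dur)

    @classmethod
    def default(cls) -> "FrameSchedule":
        return cls.from_durations([6.0] * 10 + [30.0] * 8 + [60.0] * 5 + [300.0] * 4 + [600.0] * 6)

    @classmethod
    def from_file(cls, path: str | Path) -> "FrameSchedule":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())

    def to_file(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frame_start_s": self.frame_start_s, "frame_duration_s": self.frame_duration_s}
        ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# input function
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionModel:
    """Continuous plasma input function C_p(t), a delayed tri-exponential.

    ``C_p(t) = sum_i A_i exp(-lambda_i (t - t0))`` for t >= t0, 0 before.
    Amplitudes are kBq/mL, rate constants are 1/min, the delay t0 is
    minutes.  One amplitude may be negative to give a continuous wash-in
    (the curve must remain non-negative everywhere).
    """

    amplitudes: tuple[float, float, float]
    rate_constants: tuple[float, float, float]
    delay_min: float = 0.0

    def __post_init__(self) -> None:
        amp = tuple(float(a) for a in self.amplitudes)
        lam = tuple(float(x) for x in self.rate_constants)
        object.__setattr__(self, "amplitudes", amp)
        object.__setattr__(self, "rate_constants", lam)
        if len(amp) != len(lam):
            raise ValidationError("amplitudes and rate_constants must have equal length")
        if any(x <= 0 for x in lam):
            raise ValidationError("all rate constants must be > 0")
        # non-negativity probed on a dense grid over the study span
        s = np.linspace(0.0, 180.0, 20001)
        vals = self._eval_after_delay(s)
        if np.any(vals < -1e-9 * max(abs(a) for a in amp)):
            raise ValidationError("input function must be non-negative for all t")

    def _eval_after_delay(self, s: np.ndarray) -> np.ndarray:
        out = np.zeros_like(s, dtype=float)
        for a, lam in zip(self.amplitudes, self.rate_constants):
            out += a * np.exp(-lam * s)
        return out

    def __call__(self, t_min: np.ndarray | float) -> np.ndarray:
        """Instantaneous concentration at time ``t_min`` (minutes)."""
        t = np.asarray(t_min, dtype=float)
        s = t - self.delay_min
        out = np.where(s >= 0, self._eval_after_delay(np.maximum(s, 0.0)), 0.0)
        return out

    def integral(self, t_min: np.ndarray | float) -> np.ndarray:
        """Running integral ``int_0^t C_p`` in kBq*min/mL (exact)."""
        t = np.asarray(t_min, dtype=float)
        s = np.maximum(t - self.delay_min, 0.0)
        out = np.zeros_like(s)
        for a, lam in zip(self.amplitudes, self.rate_constants):
            out += -(a / lam) * np.expm1(-lam * s)
        return out

    def auc(self, t0_min: float, t1_min: float) -> float:
        if t1_min <= t0_min:
            raise ValidationError("t1 must exceed t0")
        return float(self.integral(t1_min) - self.integral(t0_min))

    def frame_average(self, schedule: FrameSchedule) -> np.ndarray:
        """Exact frame means of C_p on the schedule (kBq/mL)."""
        a_min = schedule.frame_start_s / 60.0
        b_min = schedule.frame_end_s / 60.0
        return (self.integral(b_min) - self.integral(a_min)) / (b_min - a_min)

    def scaled(self, factor: float) -> "InputFunctionModel":
        if factor <= 0:
            raise ValidationError("scale factor must be > 0")
        return replace(self, amplitudes=tuple(a * factor for a in self.amplitudes))


#: Control (wild-type) input function.  The fast negative term is a wash-in
#: so the bolus rises continuously from zero at t0; the 0.8/min phase is
#: distribution, the 0.02/min tail is clearance-limited washout.  Absolute
#: magnitudes are chosen to give a realistic mouse total body clearance of
#: ~80 mL/min/kg at the reference dose; only group ratios are meaningful.
CONTROL_INPUT = InputFunctionModel(
    amplitudes=(-480.0, 400.0, 80.0),
    rate_constants=(8.0, 0.8, 0.02),
    delay_min=0.1,
)


# --------------------------------------------------------------------------
# subjects, TACs, presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """Dosimetry and grouping for one animal."""

    subject_id: str
    group: str
    body_weight_g: float
    injected_dose_kBq: float
    #: scalar partial-volume/spill-over factor applied to the image-derived
    #: input function; 1.0 means the heart region reads true plasma.
    idif_dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValidationError("body_weight_g must be > 0")
        if self.injected_dose_kBq <= 0:
            raise ValidationError("injected_dose_kBq must be > 0")
        if not (0 < self.idif_dilution <= 1):
            raise ValidationError("idif_dilution must lie in (0, 1]")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity concentration for one region.

    ``values`` are kBq/mL per frame in concentration mode, or dimensionless
    in SUV (standard uptake value) mode.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""
    units_mode: str = "concentration"
    subject: SubjectRecord | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.schedule.count,):
            raise ValidationError("values length must equal schedule.count")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("TAC values must be finite")
        if self.units_mode not in ("concentration", "SUV"):
            raise ValidationError("units_mode must be 'concentration' or 'SUV'")
        if self.units_mode == "SUV" and self.subject is None:
            raise ValidationError("SUV mode requires an attached SubjectRecord")


@dataclass(frozen=True)
class GroupPreset:
    """Ground-truth kinetics and exposure for one study group.

    ``plasma_scale`` multiplies the control input function; because total
    body clearance is dose divided by input AUC, a group's TBC fold-change
    versus control equals its plasma_scale by construction.
    """

    name: str
    n_default: int
    true_K1: float
    true_k2: float
    plasma_scale: float
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.true_K1 <= 0 or self.true_k2 <= 0:
            raise ValidationError("true_K1 and true_k2 must be > 0")
        if self.plasma_scale <= 0:
            raise ValidationError("plasma_scale must be > 0")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")


#: Default group presets.  Control kinetics: K1 = 0.80/min, k2 = 0.15/min.
#: The CKD transgenic (tg) group has K1 2.2-fold lower and plasma exposure
#: 1.8-fold higher; OCT1/2 knock-out and cimetidine reduce K1 and raise
#: exposure 3.0- and 2.5-fold; MATE1 inhibition (pyrimethamine) leaves renal
#: uptake intact and slightly lowers exposure (scale 1/1.1).  k2 is shared
#: across groups.
DEFAULT_PRESETS: dict[str, GroupPreset] = {
    "control": GroupPreset("control", 5, 0.80, 0.15, 1.0),
    "wt": GroupPreset("wt", 5, 0.80, 0.15, 1.0),
    "tg": GroupPreset("tg", 8, 0.80 / 2.2, 0.15, 1.8),
    "oct12_ko": GroupPreset("oct12_ko", 4, 0.80 / 3.0, 0.15, 3.0),
    "cimetidine": GroupPreset("cimetidine", 5, 0.80 / 2.5, 0.15, 2.5),
    "pyrimethamine": GroupPreset("pyrimethamine", 4, 0.80, 0.15, 1.0 / 1.1),
}


def make_input_function(
    preset: GroupPreset, control: InputFunctionModel = CONTROL_INPUT
) -> InputFunctionModel:
    """Group-level plasma input: the control curve scaled by plasma_scale."""
    return control.scaled(preset.plasma_scale)


# --------------------------------------------------------------------------
# forward kinetics (continuous input -> frame-averaged tissue TAC)
# --------------------------------------------------------------------------

def _exp_pair_integral(s: np.ndarray, lam: float, k2: float) -> np.ndarray:
    """``int_0^S (e^{-lam u} - e^{-k2 u}) / (k2 - lam) du`` elementwise.

    The convolution kernel of one input exponential with e^{-k2 t}; handles
    the k2 == lam and k2 == 0 limits.
    """
    s = np.maximum(s, 0.0)
    if k2 == 0.0:
        # kernel is (1 - e^{-lam u}) / lam
        return (s + np.expm1(-lam * s) / lam) / lam
    if abs(k2 - lam) < 1e-12 * max(k2, lam):
        # kernel is u e^{-k2 u}
        return (1.0 - (1.0 + k2 * s) * np.exp(-k2 * s)) / (k2 * k2)
    term = -np.expm1(-lam * s) / lam + np.expm1(-k2 * s) / k2
    return term / (k2 - lam)


def simulate_tissue_tac(
    input_fn: InputFunctionModel,
    K1: float,
    k2: float,
    schedule: FrameSchedule,
    region_label: str = "kidney_cortex",
) -> TimeActivityCurve:
    """Noiseless frame means of the one-tissue-compartment tissue curve.

    The tissue concentration is ``C_T(t) = K1 * int_0^t C_p(u) e^{-k2 (t-u)} du``;
    with a multi-exponential C_p both C_T and its running integral are
    analytic, so the returned frame means are exact.
    """
    if K1 < 0 or k2 < 0:
        raise ValidationError("K1 and k2 must be >= 0")
    a_min = schedule.frame_start_s / 60.0
    b_min = schedule.frame_end_s / 60.0
    sa = np.maximum(a_min - input_fn.delay_min, 0.0)
    sb = np.maximum(b_min - input_fn.delay_min, 0.0)
    means = np.zeros(schedule.count)
    for amp, lam in zip(input_fn.amplitudes, input_fn.rate_constants):
        means += amp * (_exp_pair_integral(sb, lam, k2) - _exp_pair_integral(sa, lam, k2))
    means = K1 * means / (b_min - a_min)
    return TimeActivityCurve(schedule, np.maximum(means, 0.0), region_label=region_label)


def simulate_bladder_tac(
    input_fn: InputFunctionModel,
    schedule: FrameSchedule,
    excretion_rate_per_min: float = 0.5,
    region_label: str = "bladder",
) -> TimeActivityCurve:
    """Accumulating urinary-bladder curve: a scaled running integral of C_p.

    The bladder traps excreted tracer, so its concentration is the
    cumulative renal excretion flux, monotone non-decreasing over frames.
    """
    a_min = schedule.frame_start_s / 60.0
    b_min = schedule.frame_end_s / 60.0
    sa = np.maximum(a_min - input_fn.delay_min, 0.0)
    sb = np.maximum(b_min - input_fn.delay_min, 0.0)
    means = np.zeros(schedule.count)
    # frame mean of the running integral: second antiderivative of C_p
    for amp, lam in zip(input_fn.amplitudes, input_fn.rate_constants):
        f2b = (amp / lam) * (sb - (1.0 - np.exp(-lam * sb)) / lam)
        f2a = (amp / lam) * (sa - (1.0 - np.exp(-lam * sa)) / lam)
        means += f2b - f2a
    means = excretion_rate_per_min * means / (b_min - a_min)
    return TimeActivityCurve(schedule, np.maximum(means, 0.0), region_label=region_label)


# --------------------------------------------------------------------------
# noise
# --------------------------------------------------------------------------

def add_noise(
    tac: TimeActivityCurve,
    noise_scale: float,
    seed: int | np.random.Generator,
    floor: float = NOISE_FLOOR_KBQ_PER_ML,
) -> TimeActivityCurve:
    """Duration-scaled Gaussian measurement noise, clipped at zero.

    Each frame value gets ``eps_i ~ Normal(0, sigma_i)`` with
    ``sigma_i = noise_scale * sqrt(max(value_i, floor) / duration_i)``
    (duration in seconds): longer frames and lower counts mean lower
    variance per unit activity, emulating count statistics in
    reconstructed PET frames.
    """
    if noise_scale < 0:
        raise ValidationError("noise_scale must be >= 0")
    if noise_scale == 0:
        return tac
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = noise_scale * np.sqrt(np.maximum(tac.values, floor) / tac.schedule.frame_duration_s)
    noisy = np.maximum(tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sigma, 0.0)
    return replace(tac, values=noisy)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSubject:
    """One simulated animal with its curves and retained ground truth."""

    record: SubjectRecord
    input_model: InputFunctionModel  # per-subject scaled continuous input
    idif: TimeActivityCurve
    cortex_left: TimeActivityCurve
    cortex_right: TimeActivityCurve
    true_K1: float
    true_k2: float
    plasma_scale: float
    dose_factor: float


def _subject_seed_sequence(seed: int, subject_id: str) -> np.random.SeedSequence:
    # stable per-subject substream: adding a subject never perturbs others
    return np.random.SeedSequence([int(seed), zlib.crc32(subject_id.encode("utf-8"))])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    return float(lower + abs(rng.normal(0.0, sd)))  # pragma: no cover


def simulate_cohort(
    preset: GroupPreset,
    n: int | None = None,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
    control: InputFunctionModel = CONTROL_INPUT,
    idif_dilution: float = 1.0,
    body_weight_mean_g: float = REFERENCE_BODY_WEIGHT_G,
    body_weight_sd_g: float = 2.0,
    dose_mean_kBq: float = REFERENCE_DOSE_KBQ,
    dose_sd_kBq: float = 1000.0,
) -> list[CohortSubject]:
    """Simulate ``n`` subjects of a group preset (defaults to n_default).

    Per subject: body weight ~ Normal(25 g, 2 g) truncated at 15 g and
    injected dose ~ Normal(7.7 MBq, 1 MBq) truncated at 1 MBq; the plasma
    input is the control curve scaled by ``plasma_scale`` times the dose
    factor (ID / 7.7 MBq) / (BW / 25 g); the IDIF is the frame-averaged
    input times ``idif_dilution`` plus noise; left and right renal-cortex
    TACs share the preset kinetics with independent noise.  Deterministic
    for a fixed (preset, n, seed) triple.
    """
    if n is None:
        n = preset.n_default
    if n < 0:
        raise ValidationError("n must be >= 0")
    sched = schedule or FrameSchedule.default()
    subjects: list[CohortSubject] = []
    for i in range(n):
        sid = f"{preset.name}-{i + 1:02d}"
        ss = _subject_seed_sequence(seed, sid)
        rng_subject, rng_idif, rng_cl, rng_cr = (np.random.default_rng(s) for s in ss.spawn(4))
        bw = _truncated_normal(rng_subject, body_weight_mean_g, body_weight_sd_g, 15.0)
        dose = _truncated_normal(rng_subject, dose_mean_kBq, dose_sd_kBq, 1000.0)
        record = SubjectRecord(sid, preset.name, bw, dose, idif_dilution)
        dose_factor = (dose / REFERENCE_DOSE_KBQ) / (bw / REFERENCE_BODY_WEIGHT_G)
        input_model = control.scaled(preset.plasma_scale * dose_factor)

        idif_clean = TimeActivityCurve(
            sched,
            input_model.frame_average(sched) * idif_dilution,
            region_label="idif",
            subject=record,
        )
        idif = add_noise(idif_clean, preset.noise_scale, rng_idif)
        cortices = []
        for label, rng in (("kidney_cortex_l", rng_cl), ("kidney_cortex_r", rng_cr)):
            clean = simulate_tissue_tac(input_model, preset.true_K1, preset.true_k2, sched, label)
            clean = replace(clean, subject=record)
            cortices.append(add_noise(clean, preset.noise_scale, rng))
        subjects.append(
            CohortSubject(
                record=record,
                input_model=input_model,
                idif=idif,
                cortex_left=cortices[0],
                cortex_right=cortices[1],
                true_K1=preset.true_K1,
                true_k2=preset.true_k2,
                plasma_scale=preset.plasma_scale,
                dose_factor=dose_factor,
            )
        )
    return subjects


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------

_TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "concentration_kBq_per_mL"]


def write_tac(tac: TimeActivityCurve, path: str | Path) -> None:
    """Write a TAC as delimited text (one row per frame)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TAC_COLUMNS)
        for s, d, v in zip(tac.schedule.frame_start_s, tac.schedule.frame_duration_s, tac.values):
            writer.writerow([repr(float(s)), repr(float(d)), repr(float(v))])


def read_tac(path: str | Path, region_label: str = "") -> TimeActivityCurve:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows[0] != _TAC_COLUMNS:
        raise ValidationError(f"unexpected TAC header in {path}: {rows[0]}")
    data = np.asarray([[float(x) for x in row] for row in rows[1:]], dtype=float)
    sched = FrameSchedule(data[:, 0], data[:, 1])
    return TimeActivityCurve(sched, data[:, 2], region_label=region_label or Path(path).stem)


def export_cohort(
    subjects: Sequence[CohortSubject],
    outdir: str | Path,
    seed: int,
    presets: Mapping[str, GroupPreset] | None = None,
) -> Path:
    """Write per-subject TAC files, a cohort manifest, and ground truth.

    One delimited file per subject-region (idif, kidney_cortex_l,
    kidney_cortex_r); ``manifest.csv`` lists subjects and dosimetry;
    ``ground_truth.csv`` carries the generating kinetics; the preset
    definitions are echoed to ``presets.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "body_weight_g", "injected_dose_kBq", "seed"])
        for s in subjects:
            writer.writerow(
                [s.record.subject_id, s.record.group, repr(s.record.body_weight_g),
                 repr(s.record.injected_dose_kBq), seed]
            )
    with open(out / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "K1", "k2", "plasma_scale"])
        for s in subjects:
            writer.writerow([s.record.subject_id, repr(s.true_K1), repr(s.true_k2), repr(s.plasma_scale)])
    for s in subjects:
        for tac in (s.idif, s.cortex_left, s.cortex_right):
            write_tac(tac, out / f"{s.record.subject_id}_{tac.region_label}.csv")
    echo = {
        name: {
            "name": p.name, "n_default": p.n_default, "true_K1": p.true_K1,
            "true_k2": p.true_k2, "plasma_scale": p.plasma_scale, "noise_scale": p.noise_scale,
        }
        for name, p in (presets or DEFAULT_PRESETS).items()
    }
    (out / "presets.json").write_text(json.dumps(echo, indent=2))
    return out
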