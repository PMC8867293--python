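"""Accelerometer bout detection and sensor-triggered questions.

The watch streams tri-axial acceleration at 50 Hz.  Activity intensity
is summarized as the area under the curve (AUC) of the high-pass
filtered signal over 10-second epochs:

    AUC_epoch = sum over samples, sum over 3 axes of |hp(a)| * dt

A physical-activity (PA) bout is a continuous run of at least 10 minutes
(60 epochs) with AUC above a threshold; a sedentary (SB) bout is a run
of at least 60 minutes (360 epochs) below a threshold.  A triggered
question refers back Δ minutes, where

    Δ = (now − bout end) + 0.25 × bout length

so the question lands inside the behaviour rather than at its
transition (2.5 min for a 10-minute PA bout detected at its end, 15 min
for a 60-minute SB bout).  At each scheduled prompt an eligible bout
replaces the queued question only 50% of the time, to avoid monotonous
sensor prompting during long episodes.

The high-pass filter is a first-order Butterworth at 0.25 Hz applied
forward-backward per axis — enough to strip gravity and slow posture
drift while keeping the human-movement band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .selection import QuestionSpec

SAMPLING_RATE_HZ = 50.0
EPOCH_S = 10.0
PA_WINDOW_EPOCHS = 60    # 10 minutes
SB_WINDOW_EPOCHS = 360   # 60 minutes
HIGHPASS_CUTOFF_HZ = 0.25
HIGHPASS_ORDER = 1
TRIGGER_PROB = 0.5

#: Default AUC thresholds (g*s per 10-s epoch), calibrated once as the
#: midpoint between the sedentary and active AUC distributions of the
#: bundled synthetic generator at its default intensities.
DEFAULT_PA_THRESHOLD = 2.67
DEFAULT_SB_THRESHOLD = 2.67


@dataclass(frozen=True)
class ActivityInterval:
    """One scripted segment of a synthetic trace."""

    label: str               # "active" | "sedentary" | "transition"
    duration_s: float
    intensity_g: float       # movement noise std in g


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration, in g."""

    rate_hz: float
    samples: np.ndarray                       # (n, 3)
    labels: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate_hz


@dataclass
class AucSeries:
    epoch_s: float
    values: np.ndarray       # one AUC per complete epoch

    def epoch_bounds_s(self, i: int) -> tuple[float, float]:
        return i * self.epoch_s, (i + 1) * self.epoch_s


@dataclass(frozen=True)
class BoutEvent:
    kind: str                # "PA" | "SB"
    start_s: float
    end_s: float
    delta_min: float

    @property
    def length_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


def delta_minutes(bout_start_s: float, bout_end_s: float, now_s: float) -> float:
    """Back-reference offset: gap since bout end plus 25% of bout length."""
    gap_min = (now_s - bout_end_s) / 60.0
    return gap_min + 0.25 * (bout_end_s - bout_start_s) / 60.0


DEFAULT_INTENSITIES = {"active": 0.20, "sedentary": 0.01, "transition": 0.06}


def synth_accel(script: list[ActivityInterval], rng: np.random.Generator,
                rate_hz: float = SAMPLING_RATE_HZ) -> AccelTrace:
    """Generate a labelled 50 Hz trace from an activity script.

    Each interval contributes gravity on the z axis plus white movement
    noise with the scripted intensity; active intervals also get a small
    arm-swing harmonic so their spectra are not purely flat.  Interval
    AUC distributions separate cleanly at the default intensities,
    which is what bout detection needs; the generator does not attempt
    biomechanical realism.
    """
    chunks = []
    labels = []
    t0 = 0.0
    for iv in script:
        if iv.duration_s <= 0:
            raise ValueError("interval durations must be positive")
        n = int(round(iv.duration_s * rate_hz))
        x = rng.normal(0.0, iv.intensity_g, size=(n, 3))
        x[:, 2] += 1.0  # gravity
        if iv.label == "active":
            t = np.arange(n) / rate_hz
            x[:, 0] += iv.intensity_g * np.sin(2 * np.pi * 1.8 * t)
        chunks.append(x)
        labels.append((iv.label, t0, t0 + n / rate_hz))
        t0 += n / rate_hz
    return AccelTrace(rate_hz, np.vstack(chunks), labels)


def highpass(samples: np.ndarray, rate_hz: float,
             cutoff_hz: float = HIGHPASS_CUTOFF_HZ,
             order: int = HIGHPASS_ORDER) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=rate_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, samples, axis=0)


def auc_epochs(trace: AccelTrace) -> AucSeries:
    """Per-epoch AUC of the high-passed signal, summed over axes.

    Uses a rectangle rule (|value| x sample interval); at 50 Hz the
    difference from a trapezoid is negligible.  Only complete 10-s
    epochs are scored.
    """
    n_epoch = int(round(EPOCH_S * trace.rate_hz))
    if trace.samples.shape[0] < n_epoch:
        raise ValueError("trace shorter than one epoch")
    hp = highpass(trace.samples, trace.rate_hz)
    n_full = (hp.shape[0] // n_epoch) * n_epoch
    mag = np.abs(hp[:n_full]).sum(axis=1)
    per_epoch = mag.reshape(-1, n_epoch).sum(axis=1) / trace.rate_hz
    return AucSeries(EPOCH_S, per_epoch)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_bouts(auc: AucSeries, now_s: float,
                 pa_threshold: float = DEFAULT_PA_THRESHOLD,
                 sb_threshold: float = DEFAULT_SB_THRESHOLD,
                 ) -> list[BoutEvent]:
    """Emit PA and SB bouts from an AUC series.

    ``sb_threshold`` must not exceed ``pa_threshold`` so no epoch can
    belong to both an above-PA and a below-SB run (emitted bouts never
    overlap).
    """
    if pa_threshold <= 0 or sb_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if sb_threshold > pa_threshold:
        raise ValueError("sb_threshold must be <= pa_threshold")
    events: list[BoutEvent] = []
    for kind, mask, min_epochs in (
            ("PA", auc.values > pa_threshold, PA_WINDOW_EPOCHS),
            ("SB", auc.values < sb_threshold, SB_WINDOW_EPOCHS)):
        for start, stop in _runs(mask):
            if stop - start < min_epochs:
                continue
            s, e = start * auc.epoch_s, stop * auc.epoch_s
            events.append(BoutEvent(kind, s, e, delta_minutes(s, e, now_s)))
    events.sort(key=lambda b: b.start_s)
    return events


def calibrate_thresholds(trace: AccelTrace) -> tuple[float, float]:
    """Midpoint threshold between labelled sedentary and active epochs.

    Returns identical (pa, sb) thresholds; exposed so studies with a
    different generator or real pilot data can re-derive defaults.
    """
    auc = auc_epochs(trace)
    sed, act = [], []
    for label, s, e in trace.labels:
        i0, i1 = int(s // auc.epoch_s), int(e // auc.epoch_s)
        vals = auc.values[i0:min(i1, len(auc.values))]
        if label == "sedentary":
            sed.extend(vals)
        elif label == "active":
            act.extend(vals)
    if not sed or not act:
        raise ValueError("trace needs both sedentary and active labels")
    mid = 0.5 * (float(np.mean(sed)) + float(np.mean(act)))
    return mid, mid


_SENSOR_ANSWERS = ("Yes", "Sort of", "No")


def sensor_question(bout: BoutEvent) -> QuestionSpec:
    if bout.kind == "PA":
        return QuestionSpec("sensor_pa",
                            f"Physically active {bout.delta_min:g} min ago?",
                            "sensor_pa", _SENSOR_ANSWERS, max_per_day=62)
    return QuestionSpec("sensor_sb",
                        f"Sedentary {bout.delta_min:g} min ago?",
                        "sensor_sb", _SENSOR_ANSWERS, max_per_day=62)


def maybe_trigger(bouts: list[BoutEvent], slot_question: QuestionSpec,
                  rng: np.random.Generator,
                  ) -> tuple[QuestionSpec, BoutEvent | None]:
    """Possibly replace the queued question with a sensor question.

    With at least one eligible bout the most recently *ended* bout is
    chosen (PA wins a tie) and, with probability 0.5, its question
    preempts ``slot_question``.  Returns the question to present plus
    the bout that triggered it (None when not triggered).
    """
    if not bouts:
        return slot_question, None
    # most recent end; PA outranks SB on exact ties
    best = max(bouts, key=lambda b: (b.end_s, b.kind == "PA"))
    if rng.random() < TRIGGER_PROB:
        return sensor_question(best), best
    return slot_question, None
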