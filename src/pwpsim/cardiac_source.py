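"""Periodic aortic inflow construction from HR, LVET and mean flow.

The ascending-aortic volume flow Q1(t) is the prescribed source of the
simulation (the heart is not modelled).  A template ejection shape is
time-scaled so that its systolic portion spans exactly the left
ventricular ejection time (LVET) and its diastolic portion the rest of
the cardiac period T = 60/HR, then amplitude-normalized so the period
mean equals the requested mean flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CardiacParameters",
    "FlowWaveform",
    "lvet_from_hr",
    "generate_flow",
    "periodic_extend",
    "TEMPLATES",
]


@dataclass(frozen=True)
class CardiacParameters:
    """Cardiac source parameters.

    ``hr`` beats per minute; ``lvet`` seconds (must be shorter than one
    period); ``mean_flow`` ml/s; ``fs`` sampling rate in Hz.
    """

    hr: float
    lvet: float
    mean_flow: float = 70.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise ValueError("heart rate must be positive")
        if not 0.0 < self.lvet < self.period:
            raise ValueError(
                f"LVET must lie in (0, {self.period:.4f}) s at {self.hr} bpm"
            )
        if self.mean_flow <= 0:
            raise ValueError("mean flow must be positive")
        if self.fs < 100:
            raise ValueError("sampling rate below 100 Hz is too coarse")

    @property
    def period(self) -> float:
        return 60.0 / self.hr


@dataclass(frozen=True)
class FlowWaveform:
    """One cardiac period of volume flow, uniformly sampled.

    ``samples`` in ml/s; ``period`` seconds; ``fs`` Hz.
    """

    samples: np.ndarray
    period: float
    fs: float

    def __post_init__(self) -> None:
        n = int(round(self.period * self.fs))
        if len(self.samples) != n:
            raise ValueError(
                f"expected {n} samples for period {self.period} at {self.fs} Hz"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "flow_ml_per_s": self.samples})

    @classmethod
    def from_csv(cls, path) -> "FlowWaveform":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / (t[1] - t[0])
        return cls(df["flow_ml_per_s"].to_numpy(float), len(t) / fs, fs)


def lvet_from_hr(hr: float) -> float:
    """Regression of ejection time on heart rate:
    LVET = -0.0017 * HR + 0.413 (seconds, HR in bpm)."""
    if not 30.0 <= hr <= 200.0:
        raise ValueError("heart rate outside the regression's validity range")
    return -0.0017 * hr + 0.413


def _half_sine(phase: np.ndarray) -> np.ndarray:
    """Half-sine ejection over systole, zero diastolic flow."""
    return np.where(phase < 1.0, np.sin(np.pi * np.clip(phase, 0.0, 1.0)), 0.0)


# Tabulated "typical" aortic ejection shape: rapid early-systolic
# acceleration, rounded peak in the first third of systole, gentle
# decay and a brief end-systolic backflow dip at valve closure.
# Synthetic template (drawn to resemble published aortic flow traces,
# not digitized from any figure); unit peak, systolic phase in [0, 1].
_TYPICAL_PHASE = np.linspace(0.0, 1.0, 21)
_TYPICAL_FLOW = np.array([
    0.00, 0.28, 0.62, 0.87, 0.98, 1.00, 0.96, 0.89, 0.80, 0.70,
    0.60, 0.50, 0.40, 0.31, 0.22, 0.14, 0.06, -0.04, -0.10, -0.06, 0.00,
])


def _typical(phase: np.ndarray) -> np.ndarray:
    out = np.interp(np.clip(phase, 0.0, 1.0), _TYPICAL_PHASE, _TYPICAL_FLOW)
    return np.where(phase < 1.0, out, 0.0)


TEMPLATES = {"half_sine": _half_sine, "typical": _typical}


def generate_flow(p: CardiacParameters, shape: str = "half_sine") -> FlowWaveform:
    """Build one period of aortic inflow from a template shape.

    The template's systolic portion is linearly time-scaled onto
    [0, LVET] and its diastolic portion onto [LVET, T]; the amplitude is
    then rescaled so the period mean equals ``p.mean_flow`` exactly.
    For the default half-sine shape the resulting peak flow is
    mean_flow * T * pi / (2 * LVET).
    """
    try:
        template = TEMPLATES[shape]
    except KeyError:
        raise ValueError(f"unknown template {shape!r}; have {sorted(TEMPLATES)}")
    n = int(round(p.period * p.fs))
    t = np.arange(n) / p.fs
    samples = template(t / p.lvet)
    mean = samples.mean()
    if mean <= 0:
        raise ValueError("template has non-positive mean; cannot normalize")
    samples = samples * (p.mean_flow / mean)
    return FlowWaveform(samples, p.period, p.fs)


def periodic_extend(w: FlowWaveform, n_periods: int) -> FlowWaveform:
    """Tile the one-period waveform exactly ``n_periods`` times.

    The tiled signal has spectral energy only at multiples of the
    original fundamental.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    return FlowWaveform(
        np.tile(w.samples, n_periods), w.period * n_periods, w.fs
    )
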