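"""Sine fitting, peak phases and metabolic-cycle phase assignment.

Each activity profile is summarized by the single best-fitting sinusoid of
the known cycle period,

    x_t ~= A * sin(2*pi*t/P + phi) + m,

with t = 0 at the first time point of the series.  The phase phi is found
by scanning a fine grid (default 1 degree); at each candidate phase the
amplitude A and offset m are the exact least-squares solution, so over
whole observed cycles the sequential search equals joint minimization.

Peak phases are computed differently: the three observed cycles are
averaged position-wise into one cycle, the maximum located, and its
position mapped to an angle (position 0 -> 0 degrees, one cycle -> 360).

Angles map onto the three metabolic-cycle phases: Ox (oxidative; sharp
dissolved-oxygen drop) covers [285, 345), R/B (reductive/building; oxygen
rising) covers [165, 285), and R/C (reductive/charging, the longest phase;
oxygen roughly constant) covers the wrapped arc [345, 360) + [0, 165).
Cycle phases can also be labelled per time point directly from the slope
of the oxygen trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import DataValidationError, TimeGrid

logger = logging.getLogger("tfa_cycle.phase")

OX_ARC = (285.0, 345.0)
RB_ARC = (165.0, 285.0)
# R/C is the wrapped remainder [345, 360) + [0, 165)


@dataclass
class SineFitResult:
    tf_id: str
    phase_degrees: float
    amplitude: float
    offset: float
    rss: float
    indeterminate: bool = False


@dataclass
class PeakPhaseResult:
    tf_id: str
    angle_degrees: float
    tie: bool = False
    indeterminate: bool = False


def fit_sine(profile: np.ndarray, grid: TimeGrid | None = None,
             period_samples: int | None = None,
             phase_grid_step: float = 1.0, tf_id: str = "") -> SineFitResult:
    """Best-fit sinusoid of the cycle period by phase-grid search.

    Returns phase in [0, 360) with amplitude >= 0.  A zero-variance
    profile fits amplitude 0 with an indeterminate phase flag.
    """
    x = np.asarray(profile, dtype=float)
    if np.isnan(x).any():
        raise DataValidationError("profile contains missing values")
    P = period_samples if period_samples is not None else grid.period_samples
    n = x.size
    t = np.arange(n)
    if np.allclose(x, x[0]):
        return SineFitResult(tf_id=tf_id, phase_degrees=0.0, amplitude=0.0,
                             offset=float(x[0]), rss=0.0, indeterminate=True)
    phases = np.deg2rad(np.arange(0.0, 360.0, phase_grid_step))
    omega_t = 2 * np.pi * t / P
    # regressors for every candidate phase at once: s[k, t] = sin(w t + phi_k)
    S = np.sin(omega_t[None, :] + phases[:, None])
    # per-phase exact LS of x on [s, 1]
    n_f = float(n)
    s_sum = S.sum(axis=1)
    s_sq = (S ** 2).sum(axis=1)
    sx = S @ x
    x_sum = x.sum()
    det = s_sq * n_f - s_sum ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (sx * n_f - s_sum * x_sum) / det
        m = (x_sum - a * s_sum) / n_f
    # residual sum of squares per phase
    rss = (x @ x) - 2 * a * sx - 2 * m * x_sum + a ** 2 * s_sq \
        + 2 * a * m * s_sum + n_f * m ** 2
    rss = np.where(np.isfinite(rss), rss, np.inf)
    best = int(np.argmin(rss))
    phase = float(np.rad2deg(phases[best]))
    amp = float(a[best])
    offset = float(m[best])
    if amp < 0:  # the grid covers phi+180 with the same rss; report A >= 0
        amp = -amp
        phase = (phase + 180.0) % 360.0
    return SineFitResult(tf_id=tf_id, phase_degrees=phase % 360.0,
                         amplitude=amp, offset=offset,
                         rss=float(max(rss[best], 0.0)))


def average_cycles(profile: np.ndarray, grid: TimeGrid | None = None,
                   period_samples: int | None = None) -> np.ndarray:
    """Position-wise mean across observed cycles (length = period_samples).

    A trailing remainder that does not complete a cycle is dropped with a
    warning.
    """
    x = np.asarray(profile, dtype=float)
    P = period_samples if period_samples is not None else grid.period_samples
    if P > x.size:
        raise DataValidationError("period_samples exceeds profile length")
    n_cycles = x.size // P
    if x.size % P:
        warnings.warn(
            f"profile length {x.size} not divisible by period {P}; "
            f"dropping trailing {x.size % P} samples", stacklevel=2)
    return x[: n_cycles * P].reshape(n_cycles, P).mean(axis=0)


def peak_phase(profile: np.ndarray, grid: TimeGrid | None = None,
               period_samples: int | None = None,
               tf_id: str = "") -> PeakPhaseResult:
    """Angle of the cycle-averaged maximum; ties go to the earliest position."""
    P = period_samples if period_samples is not None else grid.period_samples
    avg = average_cycles(profile, period_samples=P)
    if np.allclose(avg, avg[0]):
        return PeakPhaseResult(tf_id=tf_id, angle_degrees=0.0,
                               indeterminate=True)
    maxima = np.flatnonzero(np.isclose(avg, avg.max()))
    k = int(maxima[0])
    return PeakPhaseResult(tf_id=tf_id, angle_degrees=k * 360.0 / P,
                           tie=len(maxima) > 1)


def classify_phase(angle_degrees: float) -> str:
    """Map an angle to its metabolic-cycle phase label (Ox, R/B or R/C).

    Arcs are half-open at the lower edge; every angle receives exactly one
    label and the three arcs have lengths 60 (Ox) < 120 (R/B) < 180 (R/C).
    """
    a = float(angle_degrees) % 360.0
    if OX_ARC[0] <= a < OX_ARC[1]:
        return "Ox"
    if RB_ARC[0] <= a < RB_ARC[1]:
        return "R/B"
    return "R/C"


def trace_slopes(trace: np.ndarray) -> np.ndarray:
    """Forward-difference slopes (last point uses the backward difference).

    Forward differences keep the label of a sample aligned with the segment
    that starts at it, which is what a piecewise-linear (sawtooth-like)
    oxygen trace requires at its break points.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 2:
        raise DataValidationError("trace too short for slopes")
    s = np.empty_like(v)
    s[:-1] = np.diff(v)
    s[-1] = v[-1] - v[-2]
    return s


def classify_cycle_phases_from_oxygen(trace: np.ndarray,
                                      grid: TimeGrid | None = None,
                                      theta: float | None = None
                                      ) -> list[str]:
    """Label each time point Ox / R/B / R/C from the oxygen slope.

    Dissolved oxygen drops sharply in Ox, rises in R/B and stays roughly
    flat in R/C, so the sign of the slope against a dead band +-theta
    (default half the slope standard deviation) assigns the label.
    """
    s = trace_slopes(trace)
    if np.allclose(s, 0):
        warnings.warn("constant oxygen trace: labelling every point R/C",
                      stacklevel=2)
        return ["R/C"] * len(s)
    if theta is None:
        theta = 0.5 * float(np.std(s))
    labels = []
    for st in s:
        if st < -theta:
            labels.append("Ox")
        elif st > theta:
            labels.append("R/B")
        else:
            labels.append("R/C")
    return labels
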