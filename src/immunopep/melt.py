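"""Thermal-melt (Tm) extraction, replicate summaries and ΔTm classification.

Dye-based melt curves rise sigmoidally as the HLA-peptide complex unfolds and
then decay once the protein aggregates; the analysis truncates the trace at
its global fluorescence maximum and fits a Boltzmann sigmoid

    F(T) = B_l + (B_u - B_l) / (1 + exp((Tm - T) / s))

by least squares, with Tm — the temperature of 50% unfolding — initialised
at the maximum of the smoothed derivative.  Replicates are summarised by
mean and sample standard deviation, and Tm differences between peptide
variants are classified as stabilising (ΔTm > 1 °C), destabilising
(ΔTm < -1 °C) or negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


class NoTransitionError(ValueError):
    """Raised when a melt curve shows no detectable unfolding transition."""


class FitError(RuntimeError):
    """Raised when the sigmoid fit fails to converge."""


@dataclass
class MeltCurve:
    sample: str
    replicate: str
    temperatures: np.ndarray  # °C, strictly increasing
    fluorescence: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence vectors differ in length")
        if len(self.temperatures) < 20:
            raise ValueError("melt curve needs at least 20 points")
        if not (np.diff(self.temperatures) > 0).all():
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures[-1] - self.temperatures[0] < 20.0:
            raise ValueError("melt curve must span at least 20 °C")


@dataclass
class MeltResult:
    sample: str
    replicate: str
    tm: float                 # °C, reported to 0.1 °C
    baseline_lower: float
    baseline_upper: float
    slope: float              # transition width s (°C)
    residual_norm: float
    truncated_at: float       # temperature of the global fluorescence maximum


def boltzmann(T: np.ndarray, b_l: float, b_u: float, tm: float, s: float) -> np.ndarray:
    return b_l + (b_u - b_l) / (1.0 + np.exp((tm - T) / s))


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average used only to initialise the fit."""
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def fit_melt(curve: MeltCurve, min_slope_ratio: float = 2.0) -> MeltResult:
    """Fit the truncated Boltzmann sigmoid and report Tm to 0.1 °C.

    The trace is cut at its global fluorescence maximum to exclude the
    post-peak aggregation decay.  A transition is only accepted when the
    smoothed derivative peaks in the interior of the trace and exceeds
    ``min_slope_ratio`` times the mean slope of a straight line through the
    truncated data — a flat or purely linear trace raises
    :class:`NoTransitionError`, a non-convergent fit :class:`FitError`.
    """
    i_max = int(np.argmax(curve.fluorescence))
    T = curve.temperatures[: i_max + 1]
    F = curve.fluorescence[: i_max + 1]
    if len(T) < 10:
        raise NoTransitionError(f"{curve.sample}/{curve.replicate}: trace peaks too early to fit")
    f_smooth = _smooth(F)
    dF = np.gradient(f_smooth, T)
    span = T[-1] - T[0]
    amplitude = float(F.max() - F.min())
    if amplitude <= 0 or span <= 0:
        raise NoTransitionError(f"{curve.sample}/{curve.replicate}: flat trace")
    linear_slope = amplitude / span
    j = int(np.argmax(dF))
    if dF[j] < min_slope_ratio * linear_slope or j < 3 or j > len(T) - 4:
        raise NoTransitionError(
            f"{curve.sample}/{curve.replicate}: no sigmoidal transition detected"
        )
    p0 = [float(F.min()), float(F.max()), float(T[j]), max(span / 20.0, 0.5)]
    bounds = (
        [-np.inf, -np.inf, float(T[0]), 1e-3],
        [np.inf, np.inf, float(T[-1]), span],
    )
    try:
        popt, _ = curve_fit(boltzmann, T, F, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{curve.sample}/{curve.replicate}: sigmoid fit failed: {exc}") from exc
    b_l, b_u, tm, s = (float(v) for v in popt)
    resid = float(np.linalg.norm(F - boltzmann(T, *popt)))
    return MeltResult(
        sample=curve.sample,
        replicate=curve.replicate,
        tm=round(tm, 1),
        baseline_lower=b_l,
        baseline_upper=b_u,
        slope=s,
        residual_norm=resid,
        truncated_at=float(T[-1]),
    )


@dataclass
class ReplicateSummary:
    sample: str
    mean_tm: float
    sd_tm: float
    n: int


def summarize_replicates(results: list[MeltResult] | list[float], sample: str | None = None) -> ReplicateSummary:
    """Mean and sample standard deviation (n-1) of replicate Tm values."""
    if not results:
        raise ValueError("no replicate results")
    if isinstance(results[0], MeltResult):
        tms = [r.tm for r in results]
        sample = sample or results[0].sample
    else:
        tms = [float(v) for v in results]
        sample = sample or ""
    arr = np.asarray(tms, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return ReplicateSummary(sample=sample, mean_tm=float(arr.mean()), sd_tm=sd, n=len(arr))


@dataclass
class DeltaTm:
    variant: str
    reference: str
    delta: float  # °C, reported to 0.1 °C
    classification: str  # stabilising | destabilising | negligible


def delta_tm(variant: ReplicateSummary, reference: ReplicateSummary) -> DeltaTm:
    """ΔTm = mean(variant) - mean(reference), classified by the 1 °C rule."""
    d = round(variant.mean_tm - reference.mean_tm, 1)
    if d > 1.0:
        cls = "stabilising"
    elif d < -1.0:
        cls = "destabilising"
    else:
        cls = "negligible"
    return DeltaTm(variant.sample, reference.sample, d, cls)
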