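"""Disassembly kinetics: normalized curves, alignment, rates, persistence.

Per-frame integrated masses become :class:`MassCurve` objects; from those the
module computes the quantities reported for PCM disassembly in vivo:

* per-curve normalization (each curve divided by its own maximum);
* disassembly onset, defined as the time of the smoothed curve's maximum
  (the anaphase peak) — the natural, testable anchor;
* ensembles aligned either at NEBD or at onset, with pointwise mean and a
  normal-approximation 95% confidence band;
* disassembly rate, the least-squares slope of normalized mass versus time
  from onset until the curve first falls to half its onset value (an
  exponential log-linear fit is available as an alternative);
* percentage rate reduction of a treated condition relative to a reference;
* persistence fraction, the median normalized mass over the trailing window
  of the movie — the residue carried into the next cell cycle.

A statsmodels-style front end, :class:`PCMDisassemblyModel`, bundles these
estimators: build it from curves (or a tidy DataFrame), call ``fit()`` and
inspect the returned results' ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .quantify import FrameQuant

__all__ = [
    "MassCurve",
    "OnsetEstimate",
    "RateEstimate",
    "AlignedEnsemble",
    "normalize_curve",
    "detect_onset",
    "align_curves",
    "disassembly_rate",
    "rate_reduction",
    "persistence_fraction",
    "PCMDisassemblyModel",
    "PCMDisassemblyResults",
    "plot_ensemble",
]


@dataclass
class MassCurve:
    """Time series of PCM mass for one centrosome, anchored at NEBD."""

    times_s: np.ndarray
    raw_mass: np.ndarray
    norm_mass: np.ndarray | None = None
    centrosome: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.raw_mass = np.asarray(self.raw_mass, dtype=np.float64)
        if self.times_s.shape != self.raw_mass.shape:
            raise ValueError("times and masses must have equal length")
        if self.times_s.size and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.norm_mass is not None:
            self.norm_mass = np.asarray(self.norm_mass, dtype=np.float64)
            if self.norm_mass.shape != self.raw_mass.shape:
                raise ValueError("norm_mass length mismatch")

    @classmethod
    def from_frame_quants(
        cls, quants: Sequence[FrameQuant], centrosome: str = "", condition: str = ""
    ) -> "MassCurve":
        return cls(
            times_s=np.array([q.time_s for q in quants]),
            raw_mass=np.array([q.integrated_mass for q in quants]),
            centrosome=centrosome,
            condition=condition,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_s",
        mass_col: str = "integrated_mass",
        centrosome: str = "",
        condition: str = "",
    ) -> "MassCurve":
        return cls(
            times_s=df[time_col].to_numpy(),
            raw_mass=df[mass_col].to_numpy(),
            centrosome=centrosome,
            condition=condition,
        )

    @property
    def n(self) -> int:
        return self.times_s.size


def normalize_curve(curve: MassCurve) -> MassCurve:
    """Divide by the curve's own maximum so the peak is exactly 1."""
    peak = float(curve.raw_mass.max(initial=-np.inf))
    if not peak > 0:
        raise ValueError("cannot normalize a curve with no positive mass")
    return replace(curve, norm_mass=curve.raw_mass / peak)


def _ensure_norm(curve: MassCurve) -> MassCurve:
    return curve if curve.norm_mass is not None else normalize_curve(curve)


@dataclass(frozen=True)
class OnsetEstimate:
    """Disassembly onset: time of the smoothed curve's maximum."""

    t_onset_s: float
    index: int
    rule: str = "smoothed_argmax"


def detect_onset(curve: MassCurve, smooth_window: int = 2) -> OnsetEstimate:
    """Locate disassembly onset as the smoothed normalized curve's argmax.

    Smoothing is a centred moving average of width ``2*smooth_window + 1``
    samples (default 5); ties resolve to the earliest time.  The returned
    time is an element of the curve's own time grid.
    """
    curve = _ensure_norm(curve)
    width = 2 * smooth_window + 1
    if curve.n < width + 2:
        raise ValueError(
            f"need at least {width + 2} samples for smoothing window {width}"
        )
    smoothed = uniform_filter1d(curve.norm_mass, size=width, mode="nearest")
    idx = int(np.argmax(smoothed))  # first (earliest) maximum
    return OnsetEstimate(t_onset_s=float(curve.times_s[idx]), index=idx)


@dataclass(frozen=True)
class RateEstimate:
    """Disassembly rate from a windowed fit of normalized mass vs time."""

    rate: float  # normalized mass per second; <= 0 during disassembly
    window: tuple[float, float]
    r_squared: float
    method: str
    n_points: int

    @property
    def magnitude(self) -> float:
        return abs(self.rate)


def disassembly_rate(
    curve: MassCurve,
    onset: OnsetEstimate | None = None,
    fit_fraction: float = 0.5,
    method: str = "linear",
    smooth_window: int = 2,
) -> RateEstimate:
    """Fit the disassembly rate over [onset, first drop below half-maximum].

    The window runs from onset until the normalized mass first falls below
    ``fit_fraction`` (default 0.5) of its onset value.  ``method='linear'``
    returns the least-squares slope over that window; ``method='exponential'``
    fits ``log(mass)`` instead and returns ``-k`` of the exponential, on the
    same window.
    """
    curve = _ensure_norm(curve)
    if onset is None:
        onset = detect_onset(curve, smooth_window=smooth_window)
    norm = curve.norm_mass
    v0 = norm[onset.index]
    target = fit_fraction * v0
    below = np.nonzero(norm[onset.index + 1 :] < target)[0]
    if below.size == 0:
        raise ValueError(
            f"curve never falls below {fit_fraction:.2f} x its onset value "
            f"({target:.3g}) after t={onset.t_onset_s:.0f}s; cannot place the "
            "fit window"
        )
    end = onset.index + 1 + int(below[0])
    sl = slice(onset.index, end + 1)
    t, y = curve.times_s[sl], norm[sl]
    if t.size < 3:
        raise ValueError(
            f"fit window [{curve.times_s[onset.index]:.0f}, "
            f"{curve.times_s[end]:.0f}]s holds only {t.size} samples (need >= 3)"
        )
    if method == "linear":
        slope, intercept = np.polyfit(t, y, 1)
        fitted = slope * t + intercept
        rate = float(slope)
    elif method == "exponential":
        pos = y > 0
        if pos.sum() < 3:
            raise ValueError("too few positive samples for an exponential fit")
        k, logc = np.polyfit(t[pos], np.log(y[pos]), 1)
        fitted = np.exp(logc + k * t)
        rate = float(k)
    else:
        raise ValueError("method must be 'linear' or 'exponential'")
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RateEstimate(
        rate=rate,
        window=(float(t[0]), float(t[-1])),
        r_squared=r2,
        method=method,
        n_points=int(t.size),
    )


def rate_reduction(reference: RateEstimate, treated: RateEstimate) -> float:
    """Percent slowdown of ``treated`` relative to ``reference``:
    ``100 * (1 - |treated| / |reference|)``."""
    if reference.rate == 0:
        raise ValueError("reference rate is zero; reduction undefined")
    return 100.0 * (1.0 - abs(treated.rate) / abs(reference.rate))


def persistence_fraction(
    curve: MassCurve,
    eval_window_s: float = 60.0,
    onset: OnsetEstimate | None = None,
) -> float:
    """Median normalized mass over the trailing ``eval_window_s`` seconds.

    The median resists single-frame noise; a curve that has decayed to the
    residual plateau reports the plateau's fraction of peak mass.  If an
    onset is supplied, the curve must extend at least ``eval_window_s``
    beyond it so the window samples the plateau rather than the decay.
    """
    curve = _ensure_norm(curve)
    span = curve.times_s[-1] - curve.times_s[0]
    if span < eval_window_s:
        raise ValueError(
            f"curve spans {span:.0f}s, shorter than the {eval_window_s:.0f}s "
            "evaluation window"
        )
    if onset is not None and curve.times_s[-1] - onset.t_onset_s < eval_window_s:
        raise ValueError("curve does not extend one evaluation window past onset")
    tail = curve.times_s >= curve.times_s[-1] - eval_window_s
    return float(np.median(curve.norm_mass[tail]))


@dataclass
class AlignedEnsemble:
    """Curves on a shifted time axis plus pointwise mean and 95% CI."""

    curves: list[MassCurve]
    table: pd.DataFrame  # columns: time_s, mean, ci_lo, ci_hi, n
    anchor: str = "nebd"


def align_curves(
    curves: Iterable[MassCurve],
    anchor: str = "nebd",
    smooth_window: int = 2,
) -> AlignedEnsemble:
    """Align normalized curves at NEBD (t as given) or at disassembly onset.

    Each curve's time axis is shifted so the anchor sits at t = 0; the
    pointwise mean is reported at every sample time, with a normal
    95% confidence band (mean ± 1.96·SE) wherever at least two curves
    contribute (NaN elsewhere).
    """
    if anchor not in ("nebd", "onset"):
        raise ValueError("anchor must be 'nebd' or 'onset'")
    shifted: list[MassCurve] = []
    for c in curves:
        c = _ensure_norm(c)
        if anchor == "onset":
            t0 = detect_onset(c, smooth_window=smooth_window).t_onset_s
            c = replace(c, times_s=c.times_s - t0)
        shifted.append(c)
    if not shifted:
        raise ValueError("need at least one curve")

    buckets: dict[float, list[float]] = {}
    for c in shifted:
        for t, v in zip(np.round(c.times_s, 6), c.norm_mass):
            buckets.setdefault(float(t), []).append(float(v))
    rows = []
    for t in sorted(buckets):
        vals = np.array(buckets[t])
        n = vals.size
        mean = float(vals.mean())
        if n >= 2:
            se = float(vals.std(ddof=1)) / np.sqrt(n)
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        else:
            lo = hi = float("nan")
        rows.append({"time_s": t, "mean": mean, "ci_lo": lo, "ci_hi": hi, "n": n})
    return AlignedEnsemble(curves=shifted, table=pd.DataFrame(rows), anchor=anchor)


# ---------------------------------------------------------------------------
# Model / Results front end


class PCMDisassemblyModel:
    """Disassembly-kinetics model over an ensemble of mass curves.

    Parameters
    ----------
    curves
        One :class:`MassCurve` or an iterable of them (e.g. one per embryo).
    condition
        Optional label applied to unlabeled curves.

    ``fit()`` estimates, per curve, the disassembly onset, the windowed
    disassembly rate and the trailing-window persistence fraction, and
    builds NEBD- and onset-aligned ensemble means with 95% confidence bands.
    """

    def __init__(self, curves: MassCurve | Iterable[MassCurve], condition: str = ""):
        if isinstance(curves, MassCurve):
            curves = [curves]
        self.curves = [_ensure_norm(c) for c in curves]
        if not self.curves:
            raise ValueError("need at least one curve")
        if condition:
            self.curves = [
                replace(c, condition=c.condition or condition) for c in self.curves
            ]
        self.condition = condition or self.curves[0].condition

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time_s",
        mass_col: str = "integrated_mass",
        group_col: str | None = None,
        condition: str = "",
    ) -> "PCMDisassemblyModel":
        """Build from a tidy table; ``group_col`` separates curves."""
        if group_col is None:
            curves = [MassCurve.from_dataframe(df, time_col, mass_col)]
        else:
            curves = [
                MassCurve.from_dataframe(g, time_col, mass_col, centrosome=str(key))
                for key, g in df.groupby(group_col, sort=False)
            ]
        return cls(curves, condition=condition)

    def fit(
        self,
        smooth_window: int = 2,
        fit_fraction: float = 0.5,
        eval_window_s: float = 60.0,
        rate_method: str = "linear",
    ) -> "PCMDisassemblyResults":
        rows = []
        onsets, rates = [], []
        for i, c in enumerate(self.curves):
            onset = detect_onset(c, smooth_window=smooth_window)
            try:
                rate = disassembly_rate(
                    c, onset, fit_fraction=fit_fraction, method=rate_method
                )
                rate_val, r2 = rate.rate, rate.r_squared
            except ValueError:
                rate, rate_val, r2 = None, float("nan"), float("nan")
            try:
                persist = persistence_fraction(c, eval_window_s=eval_window_s)
            except ValueError:
                persist = float("nan")
            onsets.append(onset)
            rates.append(rate)
            rows.append(
                {
                    "curve": c.centrosome or f"curve{i}",
                    "condition": c.condition,
                    "onset_s": onset.t_onset_s,
                    "rate_per_s": rate_val,
                    "r_squared": r2,
                    "persistence": persist,
                    "n_frames": c.n,
                }
            )
        return PCMDisassemblyResults(
            model=self,
            params=pd.DataFrame(rows),
            onsets=onsets,
            rates=rates,
            smooth_window=smooth_window,
            eval_window_s=eval_window_s,
        )


@dataclass
class PCMDisassemblyResults:
    """Per-curve estimates plus ensemble summaries from a fitted model."""

    model: PCMDisassemblyModel
    params: pd.DataFrame
    onsets: list[OnsetEstimate]
    rates: list[RateEstimate | None]
    smooth_window: int = 2
    eval_window_s: float = 60.0
    _ensembles: dict[str, AlignedEnsemble] = field(default_factory=dict, repr=False)

    def ensemble(self, anchor: str = "nebd") -> AlignedEnsemble:
        if anchor not in self._ensembles:
            self._ensembles[anchor] = align_curves(
                self.model.curves, anchor=anchor, smooth_window=self.smooth_window
            )
        return self._ensembles[anchor]

    def _mean_ci(self, col: str) -> tuple[float, float]:
        vals = self.params[col].dropna().to_numpy()
        if vals.size == 0:
            return float("nan"), float("nan")
        half = (
            1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else float("nan")
        )
        return float(vals.mean()), float(half)

    @property
    def mean_rate(self) -> float:
        return self._mean_ci("rate_per_s")[0]

    @property
    def mean_persistence(self) -> float:
        return self._mean_ci("persistence")[0]

    @property
    def mean_onset_s(self) -> float:
        return self._mean_ci("onset_s")[0]

    def rate_reduction_vs(self, reference: "PCMDisassemblyResults") -> float:
        """Mean percent rate reduction of this ensemble vs a reference."""
        ref = abs(reference.mean_rate)
        if not ref > 0:
            raise ValueError("reference ensemble has zero mean rate")
        return 100.0 * (1.0 - abs(self.mean_rate) / ref)

    def summary(self) -> str:
        cond = self.model.condition or "(unlabeled)"
        lines = [
            "PCM disassembly kinetics",
            "=" * 64,
            f"condition: {cond}    curves: {len(self.model.curves)}",
            "",
            self.params.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            ),
            "",
        ]
        for col, label, unit in (
            ("onset_s", "onset", "s post-NEBD"),
            ("rate_per_s", "rate", "norm. mass/s"),
            ("persistence", "persistence", "fraction of peak"),
        ):
            mean, half = self._mean_ci(col)
            ci = f" +/- {half:.4g} (95% CI)" if np.isfinite(half) else ""
            lines.append(f"mean {label}: {mean:.4g}{ci} [{unit}]")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        onset, onset_ci = self._mean_ci("onset_s")
        rate, rate_ci = self._mean_ci("rate_per_s")
        persist, persist_ci = self._mean_ci("persistence")
        return {
            "condition": self.model.condition,
            "n_curves": len(self.model.curves),
            "mean_onset_s": onset,
            "onset_ci95_halfwidth": onset_ci,
            "mean_rate_per_s": rate,
            "rate_ci95_halfwidth": rate_ci,
            "mean_persistence": persist,
            "persistence_ci95_halfwidth": persist_ci,
        }


def plot_ensemble(ensemble: AlignedEnsemble, ax=None, label: str | None = None):
    """Mean curve with its 95% confidence band (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = ensemble.table
    ax.plot(tab["time_s"], tab["mean"], label=label)
    ax.fill_between(tab["time_s"], tab["ci_lo"], tab["ci_hi"], alpha=0.3)
    anchor = "NEBD" if ensemble.anchor == "nebd" else "disassembly onset"
    ax.set_xlabel(f"time relative to {anchor} (s)")
    ax.set_ylabel("normalized PCM mass")
    if label:
        ax.legend()
    return ax
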