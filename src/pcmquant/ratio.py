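"""Two-channel ratiometric quantification across cell-cycle stages.

Fixed embryos co-stained with a phospho-state-specific antibody (channel A,
e.g. recognizing the dephosphorylated epitope) and a general antibody for
the total scaffold protein (channel B) report the relative phosphorylation
state of the PCM.  Because the raw channel-A signal also scales with PCM
size, each centrosome is scored as the ratio A/B of integrated signals over
a single ROI segmented on the total channel, and ratios are normalized to
the interphase mean.  Stage groups are compared with Welch's unpaired
t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import (
    QuantConfig,
    compute_threshold,
    detect_seed,
    estimate_background,
    integrated_mass,
    segment_roi,
)

__all__ = [
    "STAGES",
    "RatioMeasurement",
    "RatioMeasurementError",
    "measure_ratio",
    "normalize_to_interphase",
    "compare_stages",
    "StageComparison",
    "stage_summary",
]

STAGES = ("interphase", "prophase_metaphase", "anaphase", "telophase")


class RatioMeasurementError(ValueError):
    """A centrosome that cannot yield a valid two-channel ratio."""


@dataclass(frozen=True)
class RatioMeasurement:
    """Per-centrosome two-channel integrated signals and their ratio."""

    signal_a: float
    signal_b: float
    ratio: float
    stage: str
    center: tuple[int, int] = (0, 0)
    normalized_ratio: float | None = None


def measure_ratio(
    image_a: np.ndarray,
    image_b: np.ndarray,
    center: tuple[int, int],
    cfg: QuantConfig | None = None,
    stage: str = "",
) -> RatioMeasurement:
    """Measure the A/B integrated-signal ratio for one centrosome.

    The ROI is segmented on channel B (the total-signal channel) — its own
    annulus background and ``mean + k·sigma`` threshold around the seed —
    and that same pixel set is integrated in both channels, each against its
    own channel-specific threshold.  Using one ROI for both channels
    controls for PCM size.  The seed is refined from ``center`` on the
    blurred channel-B image within the tracking search window.
    """
    cfg = cfg or QuantConfig()
    image_a = np.asarray(image_a, dtype=np.float64)
    image_b = np.asarray(image_b, dtype=np.float64)
    if image_a.shape != image_b.shape:
        raise ValueError("channels must be registered (identical shapes)")
    seed = detect_seed(image_b, cfg, prior=(int(center[0]), int(center[1])))
    bg_b = estimate_background(image_b, seed.yx, cfg)
    thr_b = compute_threshold(bg_b, cfg)
    roi = segment_roi(image_b, thr_b, seed.yx, cfg)
    if not roi.any():
        raise RatioMeasurementError(
            f"empty channel-B ROI at {seed.yx}: centrosome not resolvable"
        )
    bg_a = estimate_background(image_a, seed.yx, cfg)
    thr_a = compute_threshold(bg_a, cfg)
    signal_b = integrated_mass(image_b, roi, thr_b)
    signal_a = integrated_mass(image_a, roi, thr_a)
    if signal_b <= 0:
        raise RatioMeasurementError(
            f"non-positive channel-B signal ({signal_b:.3g}) at {seed.yx}"
        )
    return RatioMeasurement(
        signal_a=signal_a,
        signal_b=signal_b,
        ratio=signal_a / signal_b,
        stage=stage,
        center=seed.yx,
    )


def normalize_to_interphase(
    measurements: Iterable[RatioMeasurement],
) -> list[RatioMeasurement]:
    """Divide every ratio by the mean interphase ratio.

    The interphase group's mean normalized ratio is exactly 1.  Idempotent:
    normalization always restarts from the raw ratios.
    """
    measurements = list(measurements)
    inter = [m.ratio for m in measurements if m.stage == "interphase"]
    if not inter:
        raise ValueError("no interphase measurements to normalize against")
    ref = float(np.mean(inter))
    return [replace(m, normalized_ratio=m.ratio / ref) for m in measurements]


@dataclass(frozen=True)
class StageComparison:
    t_statistic: float
    p_value: float
    method: str = "welch_t"
    degenerate: bool = False


def compare_stages(
    group_a: Sequence[float], group_b: Sequence[float]
) -> StageComparison:
    """Two-sided unpaired t-test between two stage groups (Welch variant).

    Two identical zero-variance groups are degenerate: p = 1 by convention,
    flagged.  Zero-variance groups with different means are flagged with
    p = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 measurements")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        same = a.mean() == b.mean()
        return StageComparison(
            t_statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return StageComparison(t_statistic=float(t), p_value=float(p))


def stage_summary(
    measurements: Iterable[RatioMeasurement],
    stages: Sequence[str] = STAGES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-stage normalized-ratio means with 95% CIs, plus pairwise p-values.

    Measurements are interphase-normalized first (if not already).  Returns
    a per-stage table and a dict mapping ``"stageA|stageB"`` to the Welch
    p-value.
    """
    measurements = list(measurements)
    if any(m.normalized_ratio is None for m in measurements):
        measurements = normalize_to_interphase(measurements)
    groups: dict[str, np.ndarray] = {}
    for s in stages:
        vals = np.array([m.normalized_ratio for m in measurements if m.stage == s])
        if vals.size:
            groups[s] = vals
    rows = []
    for s, vals in groups.items():
        half = (
            1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        )
        rows.append(
            {
                "stage": s,
                "n": vals.size,
                "mean_normalized_ratio": float(vals.mean()),
                "ci95_halfwidth": float(half),
            }
        )
    pvals: dict[str, float] = {}
    names = list(groups)
    for i, si in enumerate(names):
        for sj in names[i + 1 :]:
            if groups[si].size >= 2 and groups[sj].size >= 2:
                pvals[f"{si}|{sj}"] = compare_stages(groups[si], groups[sj]).p_value
    return pd.DataFrame(rows), pvals
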