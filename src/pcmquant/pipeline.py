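"""High-level convenience: simulate -> ingest -> quantify in one call.

Used for parameter-recovery studies: render a condition preset, run the
exact ingestion and quantification path a real movie would take, and return
the resulting mass curve together with the simulator's ground truth.
"""

from __future__ import annotations

import pandas as pd

from .ingest import crop_post_nebd, split_hemispheres, sum_project
from .kinetics import MassCurve, normalize_curve
from .quantify import QuantConfig, quantify_movie
from .simulate import (
    ConditionPreset,
    EmbryoGeometry,
    NoiseModel,
    get_preset,
    render_movie,
)

__all__ = ["quantify_simulated"]


def quantify_simulated(
    preset: ConditionPreset | str,
    side: str = "anterior",
    rng_seed: int = 0,
    n_frames: int = 90,
    frame_interval_s: float = 10.0,
    noise: NoiseModel | None = None,
    geometry: EmbryoGeometry | None = None,
    cfg: QuantConfig | None = None,
    pre_nebd_frames: int = 0,
) -> tuple[MassCurve, pd.DataFrame]:
    """Render a preset and quantify one centrosome through the full pipeline.

    For an unresolvable (merged) preset the whole frame is quantified in
    merged mode and ``side`` selects which centrosome's ground truth to
    return (each merged measurement is already divided by two, i.e. a
    per-centrosome average).  Otherwise the projection is split at the
    midline and the requested hemisphere quantified.

    Returns the normalized :class:`MassCurve` and the ground-truth rows for
    ``side``.
    """
    if side not in ("anterior", "posterior"):
        raise ValueError("side must be 'anterior' or 'posterior'")
    if isinstance(preset, str):
        preset = get_preset(preset)
    stack, truth = render_movie(
        preset,
        noise=noise,
        geometry=geometry,
        frame_interval_s=frame_interval_s,
        n_frames=n_frames,
        rng_seed=rng_seed,
        pre_nebd_frames=pre_nebd_frames,
    )
    proj = crop_post_nebd(sum_project(stack))
    if preset.merge_centrosomes:
        cfg = cfg or QuantConfig()
        if not cfg.merged_mode:
            from dataclasses import replace

            cfg = replace(cfg, merged_mode=True)
        quants = quantify_movie(proj, cfg)
    else:
        anterior, posterior = split_hemispheres(proj)
        quants = quantify_movie(
            anterior if side == "anterior" else posterior, cfg or QuantConfig()
        )
    curve = normalize_curve(
        MassCurve.from_frame_quants(quants, centrosome=side, condition=preset.name)
    )
    truth_side = truth[
        (truth["centrosome_id"] == side) & (truth["time_s"] >= 0)
    ].reset_index(drop=True)
    return curve, truth_side
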