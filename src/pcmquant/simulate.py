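"""Ground-truthed synthetic embryo movies for exercising the quantification.

No raw microscopy accompanies the measurements this package reimplements, so
every downstream operation is validated against simulations with known
kinetics.  The simulator emulates a one-cell *C. elegans* embryo imaged by
fluorescence time-lapse after SUM projection of a z-stack:

* an ellipsoidal embryo with uniform cytoplasmic background fluorescence on
  a dark field;
* two diffraction-blurred centrosome foci (2D isotropic Gaussian spots)
  whose total above-background photon count follows a programmed
  mass-kinetics profile: logistic growth to an anaphase peak ~275 s after
  nuclear envelope breakdown (NEBD), then exponential disassembly toward a
  residual plateau;
* cortex-directed centrosome drift during disassembly (the posterior
  centrosome in particular transits toward the cortex);
* a standard camera model: Poisson photon noise, Gaussian read noise and a
  constant offset.

Four genetic-condition presets mirror the experimental conditions studied
in vivo: wild type, phosphatase-depleted (slowed disassembly), pulling-force
depleted (slower posterior disassembly only) and the double depletion
(strongly slowed disassembly, ~25% of peak mass persisting into the next
cell cycle, centrosomes too close to resolve).  Every movie is paired with a
ground-truth table of per-frame, per-centrosome positions and true masses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import MovieStack, save_movie

__all__ = [
    "KineticTruth",
    "ConditionPreset",
    "NoiseModel",
    "EmbryoGeometry",
    "PRESET_NAMES",
    "get_preset",
    "mass_profile",
    "render_movie",
    "render_two_channel_spots",
    "write_movie_bundle",
]


@dataclass(frozen=True)
class KineticTruth:
    """Programmed mass kinetics of one centrosome.

    The mass rises logistically (rate ``k_grow``), peaks at ``t_onset_s``
    seconds post-NEBD with value ``m_peak``, then decays exponentially at
    rate ``k_decay`` toward a plateau of ``f_residual * m_peak`` — the mass
    fraction persisting into the next cell cycle.  ``t_peak_s`` records the
    time of maximal mass; with these kinetics the peak coincides with
    disassembly onset.
    """

    t_peak_s: float = 275.0
    m_peak: float = 3.0e5
    k_grow: float = 0.02
    k_decay: float = 0.012
    f_residual: float = 0.0
    t_onset_s: float | None = None

    def __post_init__(self) -> None:
        if self.t_onset_s is None:
            object.__setattr__(self, "t_onset_s", self.t_peak_s)
        if not (0 <= self.f_residual < 1):
            raise ValueError("f_residual must lie in [0, 1)")
        if self.k_decay < 0 or self.k_grow < 0:
            raise ValueError("rates must be non-negative")
        if self.t_onset_s < 0:
            raise ValueError("t_onset_s must be non-negative")
        if self.m_peak <= 0:
            raise ValueError("m_peak must be positive")


def mass_profile(truth: KineticTruth, t: float | np.ndarray) -> float | np.ndarray:
    """True integrated mass at time ``t`` (seconds post-NEBD).

    Piecewise and continuous everywhere:

    * ``t < t_onset``: logistic rise, rescaled so the curve reaches
      ``m_peak`` exactly at onset (midpoint at ``t_onset / 2``);
    * ``t >= t_onset``:
      ``m_peak * (f_residual + (1 - f_residual) * exp(-k_decay * (t - t_onset)))``.

    Negative ``t`` (pre-NEBD frames) evaluates the logistic branch.
    """
    t = np.asarray(t, dtype=np.float64)
    t_on = float(truth.t_onset_s)

    def logistic(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-truth.k_grow * (x - t_on / 2.0)))

    denom = logistic(np.asarray(t_on))
    rise = truth.m_peak * logistic(t) / denom
    decay = truth.m_peak * (
        truth.f_residual
        + (1.0 - truth.f_residual) * np.exp(-truth.k_decay * np.maximum(t - t_on, 0.0))
    )
    out = np.where(t < t_on, rise, decay)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConditionPreset:
    """Kinetic and motion parameters for one genetic condition.

    Every embryo starts with exactly two centrosomes; presets differ only in
    kinetics, drift speed and whether the two foci are resolvable
    (``merge_centrosomes`` triggers the merged-mode quantification).
    """

    name: str
    anterior: KineticTruth
    posterior: KineticTruth
    motion_speed_um_per_s: float = 0.004
    merge_centrosomes: bool = False


_WT_ANT = KineticTruth(t_peak_s=275.0, m_peak=3.0e5, k_grow=0.02, k_decay=0.012)
_WT_POST = KineticTruth(t_peak_s=275.0, m_peak=3.0e5, k_grow=0.02, k_decay=0.016)

_PRESETS: dict[str, ConditionPreset] = {
    # Posterior disassembles faster than anterior; mass undetectable by
    # ~550 s post-NEBD; no persistent residue.
    "wild_type": ConditionPreset(
        name="wild_type", anterior=_WT_ANT, posterior=_WT_POST,
        motion_speed_um_per_s=0.004,
    ),
    # Phosphatase depletion slows disassembly by 54% (anterior) / 65%
    # (posterior) and leaves disassembly incomplete; peak mass slightly low.
    "phosphatase_depleted": ConditionPreset(
        name="phosphatase_depleted",
        anterior=replace(_WT_ANT, m_peak=2.5e5, k_decay=0.46 * 0.012, f_residual=0.10),
        posterior=replace(_WT_POST, m_peak=2.5e5, k_decay=0.35 * 0.016, f_residual=0.10),
        motion_speed_um_per_s=0.004,
    ),
    # Loss of cortical pulling forces slows only the posterior centrosome
    # (by 27%), removes most drift, and slightly raises anaphase mass.
    "force_depleted": ConditionPreset(
        name="force_depleted",
        anterior=replace(_WT_ANT, m_peak=3.3e5, f_residual=0.02),
        posterior=replace(_WT_POST, m_peak=3.3e5, k_decay=0.73 * 0.016, f_residual=0.02),
        motion_speed_um_per_s=0.001,
    ),
    # Double depletion: 59%/72% slower disassembly, ~25% of peak mass
    # persisting, earlier onset, unresolvable centrosome pair.
    "double_depleted": ConditionPreset(
        name="double_depleted",
        anterior=KineticTruth(
            t_peak_s=230.0, m_peak=2.8e5, k_grow=0.02,
            k_decay=0.41 * 0.012, f_residual=0.25,
        ),
        posterior=KineticTruth(
            t_peak_s=230.0, m_peak=2.8e5, k_grow=0.02,
            k_decay=0.28 * 0.016, f_residual=0.25,
        ),
        motion_speed_um_per_s=0.001,
        merge_centrosomes=True,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def get_preset(name: str) -> ConditionPreset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose one of {PRESET_NAMES}"
        ) from None


@dataclass(frozen=True)
class NoiseModel:
    """Camera model: Poisson shot noise, Gaussian read noise, offset.

    ``photon_scale`` is the counts-per-photon conversion; Poisson noise is
    applied at photon level (``photon_scale = 0`` disables shot noise).
    ``background_level`` is the cytoplasmic autofluorescence inside the
    embryo mask, in counts on the projected scale.  With ``photon_scale``
    and ``read_noise_sd`` both zero the render is deterministic.
    """

    camera_offset: float = 100.0
    read_noise_sd: float = 6.0
    photon_scale: float = 1.0
    background_level: float = 500.0

    def __post_init__(self) -> None:
        for name in ("camera_offset", "read_noise_sd", "photon_scale", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def noiseless(
        cls, background_level: float = 500.0, camera_offset: float = 100.0
    ) -> "NoiseModel":
        return cls(
            camera_offset=camera_offset,
            read_noise_sd=0.0,
            photon_scale=0.0,
            background_level=background_level,
        )


@dataclass(frozen=True)
class EmbryoGeometry:
    """Field of view and embryo layout, all in pixels.

    The long embryo axis runs along x; the anterior centrosome starts left
    of centre, the posterior right of centre (or both near the midline when
    merged).  ``border_margin_px`` is the minimum clearance every centrosome
    must keep from the frame edge so the background annulus stays inside.
    """

    shape: tuple[int, int] = (96, 160)  # (ny, nx)
    semi_axes_px: tuple[float, float] = (40.0, 72.0)  # (y, x)
    sigma_psf_px: float = 2.0
    pixel_size_um: float = 0.11
    centrosome_offset_px: float = 24.0
    merged_offset_px: float = 4.0
    border_margin_px: float = 20.0


def _embryo_mask(geom: EmbryoGeometry) -> np.ndarray:
    ny, nx = geom.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = geom.semi_axes_px
    yy, xx = np.ogrid[:ny, :nx]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _trajectories(
    preset: ConditionPreset,
    geom: EmbryoGeometry,
    times_s: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-centrosome (T, 2) float positions (y, x).

    Centrosomes sit still until disassembly onset, then drift along x toward
    the nearer cortex at ``motion_speed``.  A merged pair does not drift
    (it is held together by the collapsed spindle).
    """
    ny, nx = geom.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    off = geom.merged_offset_px if preset.merge_centrosomes else geom.centrosome_offset_px
    speed_px = (
        0.0
        if preset.merge_centrosomes
        else preset.motion_speed_um_per_s / geom.pixel_size_um
    )
    out: dict[str, np.ndarray] = {}
    for cid, truth, x0, direction in (
        ("anterior", preset.anterior, cx - off, -1.0),
        ("posterior", preset.posterior, cx + off, +1.0),
    ):
        drift = speed_px * np.maximum(times_s - truth.t_onset_s, 0.0)
        pos = np.empty((times_s.size, 2))
        pos[:, 0] = cy
        pos[:, 1] = x0 + direction * drift
        out[cid] = pos
    return out


def _stage(t: float, truth: KineticTruth) -> str:
    if t < 0:
        return "pre_nebd"
    return "assembly" if t < truth.t_onset_s else "disassembly"


def render_movie(
    preset: ConditionPreset | str,
    noise: NoiseModel | None = None,
    geometry: EmbryoGeometry | None = None,
    frame_interval_s: float = 10.0,
    n_frames: int = 90,
    rng_seed: int = 0,
    pre_nebd_frames: int = 0,
    n_z: int = 1,
    z_step_um: float = 0.5,
) -> tuple[MovieStack, pd.DataFrame]:
    """Render a condition preset into a movie plus its ground-truth table.

    Each centrosome is a 2D isotropic Gaussian spot whose total
    above-background count equals ``mass_profile(t)`` before noise.  With
    ``n_z > 1`` the spot (and background) are distributed across z slices
    with a Gaussian axial profile, producing a T×Z×Y×X stack whose SUM
    projection matches the 2D render in expectation.  Identical
    ``(preset, noise, seed)`` give bit-identical output.

    Returns the movie (``nebd_frame`` set to ``pre_nebd_frames``) and a
    table with one row per (frame, centrosome): true centre, true mass and
    stage label.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    noise = noise or NoiseModel()
    geom = geometry or EmbryoGeometry()
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if n_z < 1:
        raise ValueError("n_z must be >= 1")

    total = pre_nebd_frames + n_frames
    times = (np.arange(total) - pre_nebd_frames) * float(frame_interval_s)
    traj = _trajectories(preset, geom, times)

    ny, nx = geom.shape
    m = geom.border_margin_px
    for cid, pos in traj.items():
        if (
            pos[:, 0].min() < m
            or pos[:, 0].max() > ny - 1 - m
            or pos[:, 1].min() < m
            or pos[:, 1].max() > nx - 1 - m
        ):
            raise ValueError(
                f"{cid} trajectory leaves the {m}-px border margin of the "
                f"{geom.shape} frame; enlarge the frame or shorten the movie"
            )

    mask = _embryo_mask(geom)
    yy, xx = np.mgrid[:ny, :nx].astype(np.float64)
    two_s2 = 2.0 * geom.sigma_psf_px**2
    norm = 2.0 * np.pi * geom.sigma_psf_px**2

    if n_z > 1:
        zc = (n_z - 1) / 2.0
        sigma_z = max(n_z / 6.0, 0.8)  # axial extent within the stack
        wz = np.exp(-((np.arange(n_z) - zc) ** 2) / (2.0 * sigma_z**2))
        wz /= wz.sum()
    else:
        wz = np.ones(1)

    rng = np.random.default_rng(rng_seed)
    shape = (total, n_z, ny, nx) if n_z > 1 else (total, ny, nx)
    movie = np.empty(shape, dtype=np.float32)
    rows = []
    truths = {"anterior": preset.anterior, "posterior": preset.posterior}
    for i, t in enumerate(times):
        spots = np.zeros((ny, nx))
        for cid, truth in truths.items():
            mass_t = float(mass_profile(truth, t))
            cy, cx = traj[cid][i]
            spots += (mass_t / norm) * np.exp(
                -(((yy - cy) ** 2 + (xx - cx) ** 2) / two_s2)
            )
            rows.append(
                {
                    "frame": i,
                    "time_s": float(t),
                    "centrosome_id": cid,
                    "y": float(cy),
                    "x": float(cx),
                    "true_mass": mass_t,
                    "stage": _stage(float(t), truth),
                }
            )
        for zi in range(n_z):
            expected = (noise.background_level / n_z) * mask + wz[zi] * spots
            if noise.photon_scale > 0:
                img = noise.photon_scale * rng.poisson(
                    expected / noise.photon_scale
                ).astype(np.float64)
            else:
                img = expected
            if noise.read_noise_sd > 0:
                img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
            img = img + noise.camera_offset / n_z
            if n_z > 1:
                movie[i, zi] = img
            else:
                movie[i] = img

    stack = MovieStack(
        data=movie,
        frame_interval_s=frame_interval_s,
        pixel_size_um=geom.pixel_size_um,
        z_step_um=z_step_um if n_z > 1 else None,
        nebd_frame=pre_nebd_frames,
    )
    truth_table = pd.DataFrame(rows)
    return stack, truth_table


# default per-stage fold-change profile of the dephosphorylated-epitope /
# total-scaffold signal ratio: low in interphase, rising through mitosis,
# peaking at anaphase, partially reverting in telophase
DEFAULT_STAGE_RATIOS: dict[str, float] = {
    "interphase": 1.0,
    "prophase_metaphase": 2.0,
    "anaphase": 4.0,
    "telophase": 1.5,
}


def render_two_channel_spots(
    stage_ratios: dict[str, float] | None = None,
    n_per_stage: int | dict[str, int] = 20,
    noise: NoiseModel | None = None,
    rng_seed: int = 0,
    base_mass_b: float = 1.5e5,
    image_shape: tuple[int, int] = (64, 64),
    sigma_psf_px: float = 2.0,
    mass_jitter_sd: float = 0.15,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame]:
    """Render fixed-embryo two-channel spot pairs with known stage ratios.

    Channel B carries the total-scaffold signal (spot mass lognormal around
    ``base_mass_b``, mimicking PCM size variation across centrosomes);
    channel A carries ``stage_ratio × mass_B`` at the identical centre, so
    the true A/B ratio is the programmed per-stage value.  Returns channel-A
    images, channel-B images and a truth table (image index, stage, centre,
    true masses and ratio).
    """
    stage_ratios = dict(stage_ratios or DEFAULT_STAGE_RATIOS)
    noise = noise or NoiseModel()
    for stage, ratio in stage_ratios.items():
        if ratio <= 0:
            raise ValueError(f"stage ratio for {stage!r} must be positive")
    if base_mass_b <= 0:
        raise ValueError("base_mass_b must be positive (zero-mass spots rejected)")
    if isinstance(n_per_stage, int):
        n_per_stage = {s: n_per_stage for s in stage_ratios}
    for stage, n in n_per_stage.items():
        if n <= 0:
            raise ValueError(f"n_per_stage for {stage!r} must be positive")

    ny, nx = image_shape
    yy, xx = np.mgrid[:ny, :nx].astype(np.float64)
    two_s2 = 2.0 * sigma_psf_px**2
    norm = 2.0 * np.pi * sigma_psf_px**2
    rng = np.random.default_rng(rng_seed)

    def render(mass: float, cy: float, cx: float) -> np.ndarray:
        expected = noise.background_level + (mass / norm) * np.exp(
            -(((yy - cy) ** 2 + (xx - cx) ** 2) / two_s2)
        )
        if noise.photon_scale > 0:
            img = noise.photon_scale * rng.poisson(
                expected / noise.photon_scale
            ).astype(np.float64)
        else:
            img = expected
        if noise.read_noise_sd > 0:
            img = img + rng.normal(0.0, noise.read_noise_sd, size=img.shape)
        return img + noise.camera_offset

    images_a: list[np.ndarray] = []
    images_b: list[np.ndarray] = []
    rows = []
    idx = 0
    for stage, ratio in stage_ratios.items():
        for _ in range(n_per_stage[stage]):
            mass_b = base_mass_b * (
                float(np.exp(rng.normal(0.0, mass_jitter_sd))) if mass_jitter_sd > 0 else 1.0
            )
            cy = (ny - 1) / 2.0 + float(rng.uniform(-4, 4))
            cx = (nx - 1) / 2.0 + float(rng.uniform(-4, 4))
            images_b.append(render(mass_b, cy, cx))
            images_a.append(render(ratio * mass_b, cy, cx))
            rows.append(
                {
                    "image": idx,
                    "stage": stage,
                    "center_y": cy,
                    "center_x": cx,
                    "true_mass_b": mass_b,
                    "true_ratio": ratio,
                }
            )
            idx += 1
    return images_a, images_b, pd.DataFrame(rows)


def write_movie_bundle(
    out_dir: str | Path, stack: MovieStack, truth: pd.DataFrame, name: str = "movie"
) -> dict[str, Path]:
    """Write TIFF + calibration sidecar JSON + ground-truth CSV to a folder."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": out / f"{name}.tif",
        "meta": out / f"{name}.json",
        "truth": out / f"{name}_truth.csv",
    }
    save_movie(stack, paths["tiff"], paths["meta"])
    truth.to_csv(paths["truth"], index=False)
    return paths
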