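"""Movie ingestion: calibrated stacks, SUM projection, hemisphere split, NEBD crop.

A raw acquisition is a T×Z×Y×X (or already-projected T×Y×X) intensity stack
with physical calibration (frame interval, z step, pixel size) and a
user-annotated nuclear-envelope-breakdown (NEBD) frame that anchors the time
axis.  This module turns such a stack into the per-centrosome 2D time series
the quantifier consumes:

* z-stacks are collapsed into SUM projections (not mean or max);
* the frame is split along the long embryo axis to isolate the anterior and
  posterior centrosomes;
* frames before NEBD are discarded and times are re-expressed in seconds
  post-NEBD, with the NEBD frame itself kept as t = 0 so curves can be
  aligned at NEBD.

NEBD is always a manual annotation; no automatic detection is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "MovieStack",
    "Projection",
    "sum_project",
    "split_hemispheres",
    "crop_post_nebd",
    "load_movie",
    "save_movie",
    "save_projection",
    "load_projection",
]


@dataclass
class MovieStack:
    """A calibrated intensity movie, T×Z×Y×X or T×Y×X.

    Parameters
    ----------
    data
        Intensity array, integer or real counts.  3D arrays are treated as
        already-projected ``T×Y×X``.
    frame_interval_s
        Time between consecutive frames, seconds.
    pixel_size_um
        Lateral pixel size, micrometres.
    z_step_um
        Axial step between z slices, micrometres; ``None`` for 2D movies.
    nebd_frame
        Index of the frame at nuclear envelope breakdown (user annotation);
        ``None`` if not yet annotated.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    z_step_um: float | None = None
    nebd_frame: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected T×Z×Y×X or T×Y×X data, got {self.data.ndim} dims"
            )
        if self.data.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibration values must be positive")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive when given")
        if self.nebd_frame is not None and not (
            0 <= self.nebd_frame < self.data.shape[0]
        ):
            raise ValueError(
                f"nebd_frame {self.nebd_frame} outside [0, {self.data.shape[0] - 1}]"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 4


@dataclass
class Projection:
    """A 2D time series derived from a :class:`MovieStack`.

    ``start_frame`` is the index, in the original movie, of this projection's
    first frame; together with ``nebd_frame`` it defines the post-NEBD time
    axis.  ``origin`` is the (y, x) offset of this crop within the original
    frame, so seed coordinates can be mapped back.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float
    nebd_frame: int | None = None
    start_frame: int = 0
    origin: tuple[int, int] = (0, 0)
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Projection data must be T×Y×X")
        if self.frame_interval_s <= 0 or self.pixel_size_um <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        """Frame times in seconds; post-NEBD if ``nebd_frame`` is annotated."""
        idx = self.start_frame + np.arange(self.n_frames)
        origin = self.nebd_frame if self.nebd_frame is not None else 0
        return (idx - origin) * float(self.frame_interval_s)


def sum_project(stack: MovieStack) -> Projection:
    """Collapse z-stacks into SUM projections at each time point.

    The sum is computed in float64 so integer inputs cannot overflow.  A 3D
    (already-projected) stack passes through unchanged apart from a
    provenance note.
    """
    if stack.has_z:
        data = stack.data.astype(np.float64, copy=False).sum(axis=1)
        note = f"sum_project(z={stack.data.shape[1]})"
    else:
        data = stack.data.astype(np.float64, copy=False)
        note = "sum_project(passthrough: input had no z axis)"
    return Projection(
        data=data,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um,
        nebd_frame=stack.nebd_frame,
        provenance=(note,),
    )


def split_hemispheres(
    proj: Projection, boundary: int | None = None, axis: str = "x"
) -> tuple[Projection, Projection]:
    """Split a projection into anterior and posterior crops along ``axis``.

    The split uses half-open intervals: the anterior crop is
    ``[0, boundary)`` and the posterior crop ``[boundary, size)``, so the two
    pixel sets partition every frame.  ``boundary`` defaults to the image
    midline.  Each crop carries its ``origin`` offset so coordinates can be
    mapped back to the uncropped frame.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    size = proj.data.shape[2] if axis == "x" else proj.data.shape[1]
    if boundary is None:
        boundary = size // 2
    if not (0 < boundary < size):
        raise ValueError(f"boundary {boundary} not strictly inside [0, {size})")
    if axis == "x":
        ant_data = proj.data[:, :, :boundary]
        post_data = proj.data[:, :, boundary:]
        post_origin = (proj.origin[0], proj.origin[1] + boundary)
    else:
        ant_data = proj.data[:, :boundary, :]
        post_data = proj.data[:, boundary:, :]
        post_origin = (proj.origin[0] + boundary, proj.origin[1])
    note = f"split_hemispheres(axis={axis}, boundary={boundary})"
    anterior = replace(
        proj, data=ant_data, provenance=proj.provenance + (note + "[anterior]",)
    )
    posterior = replace(
        proj,
        data=post_data,
        origin=post_origin,
        provenance=proj.provenance + (note + "[posterior]",),
    )
    return anterior, posterior


def crop_post_nebd(proj: Projection) -> Projection:
    """Keep only frames at or after NEBD; t = 0 is the NEBD frame itself.

    Idempotent: cropping an already-cropped projection is the identity.
    """
    if proj.nebd_frame is None:
        raise ValueError(
            "nebd_frame is not annotated; supply the NEBD frame index on the "
            "movie (sidecar JSON key 'nebd_frame') before cropping"
        )
    drop = proj.nebd_frame - proj.start_frame
    if drop <= 0:
        return proj
    return replace(
        proj,
        data=proj.data[drop:],
        start_frame=proj.nebd_frame,
        provenance=proj.provenance + (f"crop_post_nebd(dropped={drop})",),
    )


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF plus a sidecar JSON with calibration and annotation.

def save_movie(stack: MovieStack, tiff_path: str | Path, meta_path: str | Path) -> None:
    tifffile.imwrite(str(tiff_path), np.asarray(stack.data), photometric="minisblack")
    meta = {
        "frame_interval_s": stack.frame_interval_s,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "nebd_frame": stack.nebd_frame,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_movie(tiff_path: str | Path, meta_path: str | Path) -> MovieStack:
    data = tifffile.imread(str(tiff_path))
    meta = json.loads(Path(meta_path).read_text())
    return MovieStack(
        data=data,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=meta.get("z_step_um"),
        nebd_frame=meta.get("nebd_frame"),
    )


def save_projection(
    proj: Projection, tiff_path: str | Path, meta_path: str | Path
) -> None:
    tifffile.imwrite(
        str(tiff_path), np.asarray(proj.data, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "frame_interval_s": proj.frame_interval_s,
        "pixel_size_um": proj.pixel_size_um,
        "nebd_frame": proj.nebd_frame,
        "start_frame": proj.start_frame,
        "origin": list(proj.origin),
        "provenance": list(proj.provenance),
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def load_projection(tiff_path: str | Path, meta_path: str | Path) -> Projection:
    data = tifffile.imread(str(tiff_path))
    meta = json.loads(Path(meta_path).read_text())
    return Projection(
        data=data,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        nebd_frame=meta.get("nebd_frame"),
        start_frame=int(meta.get("start_frame", 0)),
        origin=tuple(meta.get("origin", (0, 0))),
        provenance=tuple(meta.get("provenance", ())),
    )
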