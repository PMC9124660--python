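"""Dense optical flow between consecutive frames.

Two backends exist: a self-contained coarse-to-fine (pyramidal)
Lucas-Kanade estimator, and an import path for flow fields computed
externally (e.g. by a deep network) in either a raw-planes layout with a
JSON sidecar or the common ``.flo`` binary layout.

The flow convention follows the raster convention of :mod:`.geometry`:
a pixel at ``(x, y)`` in the source frame maps to ``(x + u, y + v)`` in
the target frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["Frame", "FlowField", "FlowFileError", "to_gray", "lk_pyramidal", "save_flow", "load_flow"]

FLO_MAGIC = 202021.25  # sanity tag of the two-channel .flo layout

# Rec. 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


class FlowFileError(IOError):
    """Malformed or inconsistent flow file."""


@dataclass
class Frame:
    """One video frame: grayscale or 3-channel pixels in [0, 1]."""

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise ValueError("frame must be 2-D grayscale or 3-channel color")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def gray(self) -> np.ndarray:
        return to_gray(self.pixels)


def to_gray(image: np.ndarray) -> np.ndarray:
    """Convert to single-channel [0, 1] float using Rec. 601 luma weights."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return img


@dataclass
class FlowField:
    """Per-pixel displacement raster between two consecutive frames.

    ``valid`` marks pixels where flow was estimable; invalid entries must
    never be consumed downstream.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.u.shape == self.v.shape == self.valid.shape):
            raise ValueError("u, v and valid must share one raster shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape


def _as_gray(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.gray
    return to_gray(frame)


def _downsample(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, sigma=1.0, mode="nearest")[::2, ::2]


def lk_pyramidal(
    src,
    tgt,
    levels: int = 3,
    window: int = 21,
    iterations: int = 5,
    eig_floor: float = 1e-4,
) -> FlowField:
    """Dense coarse-to-fine Lucas-Kanade flow from ``src`` to ``tgt``.

    At each pyramid level the brightness-constancy normal equations are
    solved per pixel over a ``window`` x ``window`` neighbourhood, warping
    the target by the running flow between iterations.  Pixels whose local
    gradient structure tensor has smallest eigenvalue below ``eig_floor``
    (the aperture problem) are marked invalid, as are pixels whose warp
    leaves the target frame.

    Parameters
    ----------
    src, tgt : Frame or ndarray
        Same-size frames; color input is converted via Rec. 601 luma.
    levels : int
        Number of pyramid levels (>= 1), factor-2 downsampling.
    window : odd int
        Side of the local integration window (>= 3).
    iterations : int
        Warp/solve iterations per level.
    eig_floor : float
        Structure-tensor eigenvalue floor on [0, 1] intensities.
    """
    a = _as_gray(src)
    b = _as_gray(tgt)
    if a.shape != b.shape:
        raise ValueError(f"frame size mismatch: {a.shape} vs {b.shape}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")

    pyr_a, pyr_b = [a], [b]
    for _ in range(levels - 1):
        if min(pyr_a[-1].shape) < 2 * window:
            break
        pyr_a.append(_downsample(pyr_a[-1]))
        pyr_b.append(_downsample(pyr_b[-1]))

    u = np.zeros(pyr_a[-1].shape)
    v = np.zeros(pyr_a[-1].shape)
    valid = np.ones(pyr_a[-1].shape, dtype=bool)

    for lvl in range(len(pyr_a) - 1, -1, -1):
        al, bl = pyr_a[lvl], pyr_b[lvl]
        if u.shape != al.shape:  # upsample flow from the coarser level
            zoom = (al.shape[0] / u.shape[0], al.shape[1] / u.shape[1])
            u = ndimage.zoom(u, zoom, order=1) * 2.0
            v = ndimage.zoom(v, zoom, order=1) * 2.0
        h, w = al.shape
        yy, xx = np.mgrid[0:h, 0:w].astype(float)

        for _ in range(iterations):
            sample_x = xx + u
            sample_y = yy + v
            inb = (
                (sample_x >= 0) & (sample_x <= w - 1) & (sample_y >= 0) & (sample_y <= h - 1)
            )
            warped = ndimage.map_coordinates(bl, [sample_y, sample_x], order=1, mode="nearest")
            gy, gx = np.gradient(warped)
            it = warped - al

            sxx = ndimage.uniform_filter(gx * gx, size=window, mode="nearest")
            sxy = ndimage.uniform_filter(gx * gy, size=window, mode="nearest")
            syy = ndimage.uniform_filter(gy * gy, size=window, mode="nearest")
            bx = ndimage.uniform_filter(gx * it, size=window, mode="nearest")
            by = ndimage.uniform_filter(gy * it, size=window, mode="nearest")

            trace = sxx + syy
            disc = np.sqrt(np.maximum((sxx - syy) ** 2 + 4.0 * sxy**2, 0.0))
            lmin = 0.5 * (trace - disc)
            det = sxx * syy - sxy * sxy
            ok = (lmin >= eig_floor) & (det > 0) & inb

            du = np.where(ok, -(syy * bx - sxy * by) / np.where(ok, det, 1.0), 0.0)
            dv = np.where(ok, -(-sxy * bx + sxx * by) / np.where(ok, det, 1.0), 0.0)
            # clamp single-iteration updates to the window radius for stability
            r = window / 2.0
            u = u + np.clip(du, -r, r)
            v = v + np.clip(dv, -r, r)
        valid = ok

    return FlowField(u=u, v=v, valid=valid)


# ---------------------------------------------------------------------------
# Flow file I/O
# ---------------------------------------------------------------------------


def save_flow(path, flow: FlowField, fmt: str | None = None) -> None:
    """Write a flow field to disk.

    ``fmt="planes"`` (default for non-``.flo`` paths) stores float32 planes
    (u, v, valid) in row-major order with a JSON sidecar ``<path>.json``
    giving height/width/planes.  ``fmt="flo"`` writes the common
    two-channel binary layout (magic tag, width, height, interleaved u, v);
    the validity channel is not representable there.
    """
    path = Path(path)
    if fmt is None:
        fmt = "flo" if path.suffix == ".flo" else "planes"
    h, w = flow.shape
    if fmt == "flo":
        with open(path, "wb") as fh:
            np.array([FLO_MAGIC], dtype=np.float32).tofile(fh)
            np.array([w, h], dtype=np.int32).tofile(fh)
            np.stack([flow.u, flow.v], axis=-1).astype(np.float32).tofile(fh)
    elif fmt == "planes":
        planes = np.stack([flow.u, flow.v, flow.valid.astype(np.float32)])
        planes.astype(np.float32).tofile(path)
        sidecar = {"height": h, "width": w, "planes": 3, "order": ["u", "v", "valid"]}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown flow format {fmt!r}")


def load_flow(path, frame_shape: tuple[int, int] | None = None) -> FlowField:
    """Read a flow field written by :func:`save_flow` or by external tools.

    Raises
    ------
    FlowFileError
        On a malformed file or a dimension mismatch against
        ``frame_shape`` when that is given.
    """
    path = Path(path)
    if not path.exists():
        raise FlowFileError(f"flow file not found: {path}")
    if path.suffix == ".flo":
        flow = _load_flo(path)
    else:
        flow = _load_planes(path)
    if frame_shape is not None and flow.shape != tuple(frame_shape):
        raise FlowFileError(
            f"flow raster {flow.shape} does not match declared frame size {tuple(frame_shape)}"
        )
    return flow


def _load_flo(path: Path) -> FlowField:
    raw = path.read_bytes()
    if len(raw) < 12:
        raise FlowFileError(f"{path}: truncated .flo header")
    magic = np.frombuffer(raw, dtype=np.float32, count=1)[0]
    if not np.isclose(magic, FLO_MAGIC):
        raise FlowFileError(f"{path}: bad .flo magic tag {magic!r}")
    w, h = np.frombuffer(raw, dtype=np.int32, count=2, offset=4)
    data = np.frombuffer(raw, dtype=np.float32, offset=12)
    if data.size != 2 * h * w:
        raise FlowFileError(f"{path}: payload size {data.size} != 2*{h}*{w}")
    uv = data.reshape(int(h), int(w), 2)
    return FlowField(u=uv[..., 0], v=uv[..., 1])


def _load_planes(path: Path) -> FlowField:
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FlowFileError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        h, w, planes = int(meta["height"]), int(meta["width"]), int(meta["planes"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FlowFileError(f"{sidecar}: invalid sidecar contents") from exc
    if planes not in (2, 3):
        raise FlowFileError(f"{path}: expected 2 or 3 planes, sidecar declares {planes}")
    data = np.fromfile(path, dtype=np.float32)
    if data.size != planes * h * w:
        raise FlowFileError(f"{path}: payload size {data.size} != {planes}*{h}*{w}")
    data = data.reshape(planes, h, w)
    valid = data[2] > 0.5 if planes == 3 else None
    return FlowField(u=data[0], v=data[1], valid=valid)
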