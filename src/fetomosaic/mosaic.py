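"""Sequential mosaicking: chain pairwise transforms to a reference frame,
warp every frame onto a common canvas, and blend seam-free.

The reference frame (by default the middle of the sequence, which tends
to sit near the center of the mosaic) defines the mosaic plane.  With
pairwise transforms ``A_k`` mapping frame ``k+1`` into frame ``k``,
frames after the reference chain by left multiplication and frames
before it by left multiplication of inverses.

Blending offers a feathered (distance-weighted) average and a
self-contained multi-resolution spline blender in the Burt-Adelson
style (Laplacian-pyramid level-wise combination).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .correspondence import CircularMask
from .geometry import AffineTransform
from .registration import PairwiseRegistration

__all__ = [
    "TrajectorySolution",
    "MosaicCanvas",
    "CanvasBounds",
    "ChainBreakError",
    "chain_to_reference",
    "compute_canvas",
    "warp_frame",
    "blend",
    "build_mosaic",
    "incremental_preview",
]


class ChainBreakError(RuntimeError):
    """A failed pairwise registration splits the transform chain."""

    def __init__(self, break_index: int):
        self.break_index = break_index
        super().__init__(f"transform chain broken at pair {break_index}")


@dataclass
class TrajectorySolution:
    """Absolute transforms mapping each frame into the reference frame."""

    reference_index: int
    absolute: list[AffineTransform]

    def __post_init__(self) -> None:
        if not 0 <= self.reference_index < len(self.absolute):
            raise ValueError("reference index outside trajectory")


@dataclass
class CanvasBounds:
    x_min: float
    y_min: float
    width: int
    height: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass
class MosaicCanvas:
    """Blended mosaic image + accumulated weight raster.

    ``origin_offset`` is the (x, y) translation from canvas coordinates to
    reference-frame coordinates.
    """

    image: np.ndarray
    weight: np.ndarray
    origin_offset: tuple[float, float]


def _as_transform(p) -> AffineTransform:
    return p.transform if isinstance(p, PairwiseRegistration) else p


def chain_to_reference(pairwise, reference_index: int | None = None) -> TrajectorySolution:
    """Compose pairwise transforms outward from the reference frame.

    ``pairwise[k]`` maps frame k+1 coordinates into frame k; a ``None``
    entry marks a failed registration and raises :class:`ChainBreakError`
    with the break index.  Default reference is the middle frame.
    """
    n_frames = len(pairwise) + 1
    if reference_index is None:
        reference_index = n_frames // 2
    if not 0 <= reference_index < n_frames:
        raise ValueError(f"reference index {reference_index} outside 0..{n_frames - 1}")
    for k, p in enumerate(pairwise):
        if p is None:
            raise ChainBreakError(k)
    transforms = [_as_transform(p) for p in pairwise]

    absolute: list[AffineTransform | None] = [None] * n_frames
    absolute[reference_index] = AffineTransform.identity()
    for f in range(reference_index + 1, n_frames):
        absolute[f] = absolute[f - 1] @ transforms[f - 1]
    for f in range(reference_index - 1, -1, -1):
        absolute[f] = absolute[f + 1] @ transforms[f].invert()
    return TrajectorySolution(reference_index=reference_index, absolute=absolute)


def compute_canvas(
    traj: TrajectorySolution,
    frame_shape: tuple[int, int],
    mask: CircularMask | None = None,
    margin: int = 2,
) -> CanvasBounds:
    """Bounds covering every transformed field-of-view bounding box."""
    h, w = frame_shape
    if mask is None:
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
    else:
        r = mask.radius
        corners = np.array(
            [
                [mask.cx - r, mask.cy - r],
                [mask.cx + r, mask.cy - r],
                [mask.cx - r, mask.cy + r],
                [mask.cx + r, mask.cy + r],
            ]
        )
    pts = np.vstack([A.apply(corners) for A in traj.absolute])
    x_min = float(np.floor(pts[:, 0].min())) - margin
    y_min = float(np.floor(pts[:, 1].min())) - margin
    x_max = float(np.ceil(pts[:, 0].max())) + margin
    y_max = float(np.ceil(pts[:, 1].max())) + margin
    return CanvasBounds(
        x_min=x_min, y_min=y_min, width=int(x_max - x_min) + 1, height=int(y_max - y_min) + 1
    )


def warp_frame(
    frame: np.ndarray,
    A_to_reference: AffineTransform,
    mask: CircularMask | np.ndarray | None,
    canvas: CanvasBounds,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-warp one frame onto the canvas with bilinear interpolation.

    Returns the warped image and a Boolean validity raster (the warped
    field-of-view footprint); pixels outside the source mask contribute
    nothing.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape[:2]
    inv = A_to_reference.invert()
    yy, xx = np.mgrid[0 : canvas.height, 0 : canvas.width].astype(float)
    ref = np.stack([xx + canvas.x_min, yy + canvas.y_min], axis=-1)
    src = ref @ inv.linear.T + inv.translation_part
    coords = [src[..., 1], src[..., 0]]  # row, col order

    if mask is None:
        mask_raster = np.ones((h, w), dtype=float)
    elif isinstance(mask, CircularMask):
        mask_raster = mask.raster((h, w)).astype(float)
    else:
        mask_raster = np.asarray(mask, dtype=float)
    validity = ndimage.map_coordinates(mask_raster, coords, order=1, cval=0.0) > 0.999

    if frame.ndim == 2:
        warped = ndimage.map_coordinates(frame, coords, order=1, cval=0.0)
        warped[~validity] = 0.0
    else:
        warped = np.stack(
            [ndimage.map_coordinates(frame[..., c], coords, order=1, cval=0.0) for c in range(frame.shape[2])],
            axis=-1,
        )
        warped[~validity] = 0.0
    return warped, validity


# ---------------------------------------------------------------------------
# Blending
# ---------------------------------------------------------------------------


def _feather_weights(validity: np.ndarray) -> np.ndarray:
    # distance to the footprint boundary; >= 1 inside so lone frames keep weight
    return ndimage.distance_transform_edt(validity).astype(float)


def _pyr_down(img: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(img, sigma=(1.0, 1.0) + (0.0,) * (img.ndim - 2), mode="nearest")
    return sm[::2, ::2]


def _pyr_up(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    zoom = (shape[0] / img.shape[0], shape[1] / img.shape[1]) + (1.0,) * (img.ndim - 2)
    return ndimage.zoom(img, zoom, order=1, mode="nearest", grid_mode=True)


def blend(warped, validities, mode: str = "feather", levels: int = 4) -> np.ndarray:
    """Blend warped frames sharing one canvas into a single image.

    ``mode="feather"``: distance-transform-weighted average (default,
    deterministic and exact for constant overlap).  ``mode="multiband"``:
    Laplacian-pyramid blending with validity-weighted level-wise
    combination, a self-contained stand-in for an external multi-resolution
    spline blender.  Uncovered pixels are zero with zero weight.
    """
    warped = [np.asarray(f, dtype=float) for f in warped]
    validities = [np.asarray(v, dtype=bool) for v in validities]
    weights = [_feather_weights(v) for v in validities]
    wsum = np.sum(weights, axis=0)

    if mode == "feather":
        if warped[0].ndim == 3:
            num = np.sum([f * w[..., None] for f, w in zip(warped, weights)], axis=0)
            denom = np.where(wsum > 1e-12, wsum, 1.0)[..., None]
        else:
            num = np.sum([f * w for f, w in zip(warped, weights)], axis=0)
            denom = np.where(wsum > 1e-12, wsum, 1.0)
        image = num / denom
    elif mode == "multiband":
        image = _multiband_combine(warped, weights, levels)
    else:
        raise ValueError(f"unknown blend mode {mode!r}")
    image[wsum <= 1e-12] = 0.0
    return image


def _multiband_combine(images, weights, levels: int) -> np.ndarray:
    """Laplacian-pyramid blend: normalized weights smoothed per level."""
    shapes = [images[0].shape[:2]]
    for _ in range(levels - 1):
        h, w = shapes[-1]
        if min(h, w) < 8:
            break
        shapes.append((-(-h // 2), -(-w // 2)))
    n_levels = len(shapes)

    wsum = np.sum(weights, axis=0)
    norm = [w / np.where(wsum > 1e-12, wsum, 1.0) for w in weights]
    # fill each image outside its footprint with the nearest valid value so
    # the zero background does not bleed into boundary Laplacian coefficients
    filled = []
    for img, wt in zip(images, weights):
        inside = wt > 0
        if inside.all():
            filled.append(img)
            continue
        _, (iy, ix) = ndimage.distance_transform_edt(~inside, return_indices=True)
        filled.append(img[iy, ix])
    images = filled

    acc = [np.zeros(s + images[0].shape[2:], dtype=float) for s in shapes]
    wacc = [np.zeros(s, dtype=float) for s in shapes]
    for img, wt in zip(images, norm):
        gauss, gw = [img], [wt]
        for lvl in range(1, n_levels):
            gauss.append(_pyr_down(gauss[-1]))
            gw.append(_pyr_down(gw[-1]))
        for lvl in range(n_levels):
            if lvl < n_levels - 1:
                lap = gauss[lvl] - _pyr_up(gauss[lvl + 1], shapes[lvl])
            else:
                lap = gauss[lvl]
            wl = gw[lvl][..., None] if img.ndim == 3 else gw[lvl]
            acc[lvl] += lap * wl
            wacc[lvl] += gw[lvl]
    # renormalize: smoothed weight sums drift below 1 near coverage edges
    for lvl in range(n_levels):
        denom = np.where(wacc[lvl] > 1e-12, wacc[lvl], 1.0)
        acc[lvl] = acc[lvl] / (denom[..., None] if acc[lvl].ndim == 3 else denom)
    out = acc[-1]
    for lvl in range(n_levels - 2, -1, -1):
        out = acc[lvl] + _pyr_up(out, shapes[lvl])
    return out


def build_mosaic(
    frames,
    traj: TrajectorySolution,
    mask: CircularMask | np.ndarray | None = None,
    mode: str = "feather",
    levels: int = 4,
) -> MosaicCanvas:
    """Warp every frame into the reference plane and blend."""
    frame_arrays = [np.asarray(getattr(f, "pixels", f), dtype=float) for f in frames]
    canvas = compute_canvas(traj, frame_arrays[0].shape[:2], mask if isinstance(mask, CircularMask) else None)
    warped, valid = [], []
    for f, A in zip(frame_arrays, traj.absolute):
        wimg, v = warp_frame(f, A, mask, canvas)
        warped.append(wimg)
        valid.append(v)
    image = blend(warped, valid, mode=mode, levels=levels)
    weight = np.sum([_feather_weights(v) for v in valid], axis=0)
    return MosaicCanvas(image=image, weight=weight, origin_offset=(canvas.x_min, canvas.y_min))


def incremental_preview(
    frames,
    traj: TrajectorySolution,
    mask: CircularMask | np.ndarray | None = None,
    every_k: int = 10,
    mode: str = "feather",
) -> list[tuple[int, MosaicCanvas]]:
    """Intermediate mosaics after every ``k`` frames (always including the
    final complete mosaic); supports supplementary-video style output."""
    frame_arrays = [np.asarray(getattr(f, "pixels", f), dtype=float) for f in frames]
    n = len(frame_arrays)
    canvas = compute_canvas(traj, frame_arrays[0].shape[:2], mask if isinstance(mask, CircularMask) else None)
    warped, valid = [], []
    for f, A in zip(frame_arrays, traj.absolute):
        wimg, v = warp_frame(f, A, mask, canvas)
        warped.append(wimg)
        valid.append(v)
    checkpoints = sorted(set(list(range(every_k - 1, n, every_k)) + [n - 1]))
    out = []
    for cp in checkpoints:
        image = blend(warped[: cp + 1], valid[: cp + 1], mode=mode)
        weight = np.sum([_feather_weights(v) for v in valid[: cp + 1]], axis=0)
        out.append((cp, MosaicCanvas(image=image, weight=weight, origin_offset=(canvas.x_min, canvas.y_min))))
    return out
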