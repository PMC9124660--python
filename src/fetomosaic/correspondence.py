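"""Pairwise point correspondences from a flow field, restricted to the
circular fetoscope field of view.

A fetoscope produces a bright circular image surrounded by black; only
pixels inside that circle carry scene content.  Each valid flow pixel
``(x, y)`` inside the mask yields the pair ``src=(x, y)``,
``dst=(x+u, y+v)``; masked-out or invalid pixels are excluded entirely
(destination points may leave the field of view - robust estimation
downstream copes with that).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .flow import Frame, FlowField, to_gray

__all__ = ["CircularMask", "CorrespondenceSet", "flow_to_correspondences", "estimate_mask"]


@dataclass(frozen=True)
class CircularMask:
    """Circular Boolean field-of-view mask.

    ``raster(shape)`` is true exactly where (x-cx)^2 + (y-cy)^2 <= r^2.
    """

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("mask radius must be positive")

    def raster(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts[:, 0] - self.cx) ** 2 + (pts[:, 1] - self.cy) ** 2 <= self.radius**2

    @classmethod
    def inscribed(cls, shape: tuple[int, int], shrink: float = 1.0) -> "CircularMask":
        """Largest centred circle inscribed in ``shape``, optionally shrunk."""
        h, w = shape
        return cls(cx=(w - 1) / 2.0, cy=(h - 1) / 2.0, radius=shrink * min(h, w) / 2.0)


@dataclass
class CorrespondenceSet:
    """Paired point lists: ``src`` in frame i, ``dst`` in frame i+1."""

    src: np.ndarray
    dst: np.ndarray

    def __post_init__(self) -> None:
        self.src = np.asarray(self.src, dtype=float).reshape(-1, 2)
        self.dst = np.asarray(self.dst, dtype=float).reshape(-1, 2)
        if len(self.src) != len(self.dst):
            raise ValueError("src and dst must have equal length")

    def __len__(self) -> int:
        return len(self.src)

    def subset(self, index) -> "CorrespondenceSet":
        return CorrespondenceSet(self.src[index], self.dst[index])

    def swapped(self) -> "CorrespondenceSet":
        """Exchange the roles of the two frames (plumbing for direction choice)."""
        return CorrespondenceSet(self.dst, self.src)


def flow_to_correspondences(
    flow: FlowField, mask: CircularMask | np.ndarray, stride: int = 2
) -> CorrespondenceSet:
    """Convert a flow field into explicit point pairs under the mask.

    Pixels are sampled on a ``stride`` x ``stride`` grid; a pixel is
    emitted only if it is flow-valid and inside the circular mask.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    h, w = flow.shape
    raster = mask.raster((h, w)) if isinstance(mask, CircularMask) else np.asarray(mask, dtype=bool)
    if raster.shape != (h, w):
        raise ValueError(f"mask raster {raster.shape} does not match flow raster {(h, w)}")
    keep = np.zeros((h, w), dtype=bool)
    keep[::stride, ::stride] = True
    keep &= raster & flow.valid
    ys, xs = np.nonzero(keep)
    src = np.column_stack([xs, ys]).astype(float)
    dst = src + np.column_stack([flow.u[ys, xs], flow.v[ys, xs]])
    return CorrespondenceSet(src, dst)


def estimate_mask(
    frame,
    threshold: float | None = None,
    min_area_fraction: float = 0.02,
    fallback: CircularMask | None = None,
) -> CircularMask:
    """Fit the circular field-of-view boundary of a fetoscopic frame.

    The bright region is thresholded (Otsu by default), the largest
    connected component taken, and a circle recovered from its centroid
    and equivalent radius.  When detection confidence is low (component
    too small, or clearly non-circular) a fallback circle is returned:
    ``fallback`` if given, else the full inscribed circle.
    """
    from skimage.filters import threshold_otsu

    img = frame.gray if isinstance(frame, Frame) else to_gray(frame)
    h, w = img.shape
    default = fallback if fallback is not None else CircularMask.inscribed((h, w))

    finite = img[np.isfinite(img)]
    if finite.size == 0 or float(finite.max() - finite.min()) < 1e-3:
        return default  # flat frame: nothing to segment
    if threshold is None:
        try:
            threshold = float(threshold_otsu(img))
        except ValueError:
            return default
    fg = img > threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        return default
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    area = float(sizes[biggest - 1])
    if area < min_area_fraction * h * w:
        return default
    comp = labels == biggest
    cy, cx = ndimage.center_of_mass(comp)
    radius = float(np.sqrt(area / np.pi))
    # confidence: the component should fill most of its fitted circle
    yy, xx = np.mgrid[0:h, 0:w]
    circ = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    overlap = float(np.sum(comp & circ)) / max(float(np.sum(circ)), 1.0)
    if overlap < 0.8:
        return default
    return CircularMask(cx=float(cx), cy=float(cy), radius=radius)
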