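"""2-D affine algebra shared by every pipeline stage.

Coordinate convention: 0-based, ``x`` is the column index increasing
rightward, ``y`` the row index increasing downward, pixel centers at
integer coordinates.  A transform is the 6-parameter planar motion model

    [x']   [a11 a12] [x]   [b1]
    [y'] = [a21 a22] [y] + [b2]

stored as a 2x3 matrix; the homogeneous 3x3 form is used internally for
composition and inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AffineTransform", "DegenerateTransformError", "identity", "translation", "similarity"]


class DegenerateTransformError(ValueError):
    """Raised when a transform with (near-)singular linear part is inverted."""


@dataclass(frozen=True)
class AffineTransform:
    """A planar affine motion model (scale, shear, rotation, translation).

    Parameters
    ----------
    matrix : (2, 3) ndarray
        ``[[a11, a12, b1], [a21, a22, b2]]`` with the linear part
        dimensionless and the translation in pixels.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2, 3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("affine matrix entries must be finite")
        object.__setattr__(self, "matrix", m)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(2, 3))

    @classmethod
    def from_params(cls, a11, a12, b1, a21, a22, b2) -> "AffineTransform":
        return cls(np.array([[a11, a12, b1], [a21, a22, b2]], dtype=float))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform":
        return cls.from_params(1.0, 0.0, tx, 0.0, 1.0, ty)

    @classmethod
    def similarity(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        tx: float = 0.0,
        ty: float = 0.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Rotation (degrees, about ``center``) + isotropic scale + translation."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        lin = scale * np.array([[c, -s], [s, c]])
        ctr = np.asarray(center, dtype=float)
        trans = ctr - lin @ ctr + np.array([tx, ty], dtype=float)
        return cls(np.column_stack([lin, trans]))

    @classmethod
    def from_list(cls, values) -> "AffineTransform":
        """Build from the flat JSON layout ``[a11, a12, b1, a21, a22, b2]``."""
        v = list(values)
        if len(v) != 6:
            raise ValueError("expected 6 entries [a11,a12,b1,a21,a22,b2]")
        return cls(np.asarray(v, dtype=float).reshape(2, 3))

    # -- accessors ---------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        """The 2x2 linear part."""
        return self.matrix[:, :2]

    @property
    def translation_part(self) -> np.ndarray:
        return self.matrix[:, 2]

    def to_list(self) -> list[float]:
        """Flat JSON layout ``[a11, a12, b1, a21, a22, b2]``."""
        return [float(v) for v in self.matrix.ravel()]

    def as_matrix3(self) -> np.ndarray:
        """Homogeneous 3x3 form."""
        out = np.eye(3)
        out[:2, :] = self.matrix
        return out

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))

    # -- operations --------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` points (x, y) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation_part

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """``self @ other``: apply ``other`` first, then ``self``."""
        m = self.as_matrix3() @ other.as_matrix3()
        return AffineTransform(m[:2, :])

    def invert(self) -> "AffineTransform":
        det = self.determinant
        if abs(det) < 1e-12:
            raise DegenerateTransformError(
                f"linear part is singular (|det| = {abs(det):.3e}); transform not invertible"
            )
        lin_inv = np.linalg.inv(self.linear)
        return AffineTransform(np.column_stack([lin_inv, -lin_inv @ self.translation_part]))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def almost_equal(self, other: "AffineTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol, rtol=0.0))


def identity() -> AffineTransform:
    return AffineTransform.identity()


def translation(tx: float, ty: float) -> AffineTransform:
    return AffineTransform.translation(tx, ty)


def similarity(rotation_deg=0.0, scale=1.0, tx=0.0, ty=0.0, center=(0.0, 0.0)) -> AffineTransform:
    return AffineTransform.similarity(rotation_deg, scale, tx, ty, center)
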