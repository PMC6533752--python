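"""2-D affine transforms between H&E and SHG pixel coordinates.

Points are ``(x, y)`` with ``x`` the column index and ``y`` the row index,
origin at the top-left pixel corner. A transform maps source coordinates to
target coordinates through a 3x3 homogeneous matrix acting on ``(x, y, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skimage.transform import AffineTransform as _SkAffine

MODELS = ("translation", "rigid", "similarity", "affine")


class SingularTransformError(ValueError):
    """Raised when a transform with a non-invertible linear part is inverted."""


@dataclass(frozen=True)
class AffineTransform2D:
    """Affine map between two pixel coordinate systems.

    Parameters
    ----------
    matrix
        3x3 homogeneous matrix; the last row must be ``(0, 0, 1)``.
    model
        One of ``translation``, ``rigid``, ``similarity``, ``affine`` —
        records which family the matrix was estimated in.
    meta
        Free-form diagnostics (registration metric, landmark residual, ...).
        Excluded from equality.
    """

    matrix: np.ndarray
    model: str = "affine"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains non-finite entries")
        if not np.allclose(m[2], (0.0, 0.0, 1.0), atol=1e-12):
            raise ValueError("last row of an affine matrix must be (0, 0, 1)")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        object.__setattr__(self, "matrix", m)

    # -- constructors -----------------------------------------------------

    @classmethod
    def identity(cls, model: str = "affine") -> "AffineTransform2D":
        return cls(np.eye(3), model=model)

    @classmethod
    def translation(cls, tx: float, ty: float) -> "AffineTransform2D":
        m = np.eye(3)
        m[0, 2] = tx
        m[1, 2] = ty
        return cls(m, model="translation")

    @classmethod
    def scaling(cls, sx: float, sy: float | None = None) -> "AffineTransform2D":
        sy = sx if sy is None else sy
        m = np.diag([float(sx), float(sy), 1.0])
        return cls(m, model="affine")

    @classmethod
    def similarity(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Rotation+scale about ``center`` followed by a translation."""
        th = np.deg2rad(rotation_deg)
        c, s = np.cos(th), np.sin(th)
        lin = scale * np.array([[c, -s], [s, c]])
        cx, cy = center
        t = np.array([cx, cy]) - lin @ np.array([cx, cy]) + np.asarray(translation, float)
        m = np.eye(3)
        m[:2, :2] = lin
        m[:2, 2] = t
        return cls(m, model="similarity")

    @classmethod
    def from_skimage(cls, t: _SkAffine, model: str = "affine") -> "AffineTransform2D":
        return cls(np.asarray(t.params, float), model=model)

    # -- algebra ----------------------------------------------------------

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:2, 2]

    @property
    def is_invertible(self) -> bool:
        return abs(float(np.linalg.det(self.linear))) > 1e-12

    @property
    def scale(self) -> float:
        """Isotropic scale factor, ``sqrt(|det|)`` of the linear part."""
        return float(np.sqrt(abs(np.linalg.det(self.linear))))

    @property
    def rotation_deg(self) -> float:
        """Rotation angle of the linear part (meaningful for rigid/similarity)."""
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def __matmul__(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Composition: ``(a @ b)(p) == a(b(p))``."""
        model = self.model if self.model == other.model else "affine"
        return AffineTransform2D(self.matrix @ other.matrix, model=model)

    def inverse(self) -> "AffineTransform2D":
        if not self.is_invertible:
            raise SingularTransformError("transform has a singular linear part")
        return AffineTransform2D(np.linalg.inv(self.matrix), model=self.model)

    def apply(self, points: Iterable) -> np.ndarray:
        """Map an ``(n, 2)`` array of ``(x, y)`` points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.offset
        return out

    def to_skimage(self) -> _SkAffine:
        return _SkAffine(matrix=self.matrix)

    def almost_equal(self, other: "AffineTransform2D", atol: float = 1e-8) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))
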