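"""Rigid (translation + rotation) transforms about a fixed pivot.

All transforms in this package belong to the family

    T(p) = R(theta) (p - c) + c + t

where ``p = (x, y)`` is a pixel coordinate (x rightward, y downward,
0-based, pixel centers at integers), ``c`` is the pivot (by convention the
geometric center of the untransformed image) and ``t = (dx, dy)`` is a
translation in pixels.  The family is closed under composition and
inversion for a shared pivot, which keeps the pairwise-consensus algebra
in :mod:`gazefuse.registration` linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class RigidTransform:
    """Translation (px) plus rotation (deg) about a pivot supplied at use."""

    dx_px: float
    dy_px: float
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.dx_px, self.dy_px, self.theta_deg])):
            raise ValueError("transform parameters must be finite")
        if abs(self.theta_deg) >= 45.0:
            raise ValueError(
                f"|theta| = {abs(self.theta_deg):.1f} deg exceeds the 45 deg "
                "sanity bound for fixational rotation"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(0.0, 0.0, 0.0)

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dx_px, self.dy_px], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        cs, sn = np.cos(th), np.sin(th)
        return np.array([[cs, -sn], [sn, cs]])

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` xy points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(center, dtype=float)
        out = (pts - c) @ self.rotation_matrix().T + c + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "RigidTransform":
        ti = -self.rotation_matrix().T @ self.translation
        return RigidTransform(ti[0], ti[1], -self.theta_deg)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), same pivot."""
        t = self.rotation_matrix() @ other.translation + self.translation
        return RigidTransform(t[0], t[1], self.theta_deg + other.theta_deg)

    def relative_to(self, anchor: "RigidTransform") -> "RigidTransform":
        """Express this transform in the frame of ``anchor`` (anchor^-1 ∘ self)."""
        return anchor.inverse().compose(self)


def image_center(shape: tuple[int, int]) -> np.ndarray:
    """Geometric center of an ``(H, W)`` image in xy coordinates."""
    h, w = shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def warp_rigid(
    image: np.ndarray,
    transform: RigidTransform,
    out_shape: tuple[int, int] | None = None,
    out_origin: tuple[float, float] = (0.0, 0.0),
    order: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``image`` onto a canvas where it sits at ``transform``.

    Output pixel ``(r, col)`` corresponds to canvas coordinate
    ``q = out_origin + (col, r)``; its value is sampled from the source at
    ``transform⁻¹(q)`` with spline interpolation of the given order
    (default bilinear).  Returns ``(values, defined_mask)`` where pixels
    whose full interpolation support falls outside the source are NaN and
    masked out — conservative masking so downstream statistics never draw
    on fabricated intensities.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if out_shape is None:
        out_shape = image.shape
    oh, ow = out_shape
    c = image_center(image.shape)
    inv = transform.inverse()

    qx, qy = np.meshgrid(
        np.arange(ow, dtype=float) + out_origin[0],
        np.arange(oh, dtype=float) + out_origin[1],
    )
    rmat = inv.rotation_matrix()
    px = rmat[0, 0] * (qx - c[0]) + rmat[0, 1] * (qy - c[1]) + c[0] + inv.dx_px
    py = rmat[1, 0] * (qx - c[0]) + rmat[1, 1] * (qy - c[1]) + c[1] + inv.dy_px

    eps = 1e-9
    mask = (px >= -eps) & (px <= w - 1 + eps) & (py >= -eps) & (py <= h - 1 + eps)
    values = ndimage.map_coordinates(
        image, [py, px], order=order, mode="constant", cval=0.0
    )
    values[~mask] = np.nan
    return values, mask
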