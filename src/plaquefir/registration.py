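"""Landmark-based affine registration of the immunostain image onto the
spectral cube, and paired ROI cutouts.

The spectral cube is always the reference frame: the transform maps
immunostain (IHC) pixel coordinates (row, col) into cube coordinates and
the IHC image is warped (inverse-mapped, bilinear) onto the cube grid.
Stain images acquired at higher magnification are downsampled by the
affine itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectra_core import HyperCube, InputError, PipelineError, RangeError

__all__ = [
    "EstimationError",
    "AffineTransform2D",
    "PlaqueROI",
    "estimate_affine",
    "warp_image",
    "cutout_roi",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

_DET_MIN = 1e-12


class EstimationError(PipelineError):
    """The affine transform cannot be estimated from the given landmarks."""


@dataclass(frozen=True)
class AffineTransform2D:
    """2x3 affine matrix mapping IHC (row, col) -> cube (row, col)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise InputError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) <= _DET_MIN:
            raise InputError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_components(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        th = np.deg2rad(rotation_deg)
        rot = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(np.column_stack([rot, np.asarray(translation, float)]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points (row, col) through the transform."""
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform2D":
        a_inv = np.linalg.inv(self.linear)
        return AffineTransform2D(
            np.column_stack([a_inv, -a_inv @ self.translation])
        )

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps({"matrix": self.matrix.tolist()})
        if path is not None:
            with open(path, "w") as f:
                f.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "AffineTransform2D":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as f:
                payload = json.load(f)
        return cls(np.asarray(payload["matrix"], dtype=np.float64))


def estimate_affine(
    points_ihc: np.ndarray, points_cube: np.ndarray
) -> tuple[AffineTransform2D, float]:
    """Least-squares affine minimising sum ||T(p_ihc) - p_cube||^2.

    Returns the transform and the RMS residual over the landmarks.
    Requires at least 3 non-collinear source points.
    """
    src = np.atleast_2d(np.asarray(points_ihc, float))
    dst = np.atleast_2d(np.asarray(points_cube, float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise InputError("landmark arrays must both be (N, 2)")
    if src.shape[0] < 3:
        raise InputError("at least 3 landmark pairs are required")
    g = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(g, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise EstimationError("source landmarks are collinear or degenerate")
    coef, _, _, _ = np.linalg.lstsq(g, dst, rcond=None)
    matrix = np.column_stack([coef[:2].T, coef[2]])
    try:
        transform = AffineTransform2D(matrix)
    except InputError as exc:
        raise EstimationError(str(exc)) from exc
    resid = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


def warp_image(
    image: np.ndarray,
    transform: AffineTransform2D,
    out_shape: tuple[int, int],
    background: float = 0.0,
) -> np.ndarray:
    """Warp an IHC image onto the cube grid.

    For each output (cube) pixel q the value is sampled at T^-1(q) in the
    input image by bilinear interpolation; out-of-bounds positions take
    the background value.  Deterministic.
    """
    inv = transform.inverse()
    return ndimage.affine_transform(
        np.asarray(image, dtype=np.float64),
        inv.linear,
        offset=inv.translation,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=background,
    )


@dataclass
class PlaqueROI:
    """One plaque's paired cutouts in cube coordinates.

    ``offset`` is the (row, col) of the cutout origin in the parent cube,
    kept for provenance.  Masks are filled by the masking stage.
    """

    cube: HyperCube
    ihc: np.ndarray
    offset: tuple[int, int]
    label: str | None = None
    plaque_mask: np.ndarray | None = None
    ring_mask: np.ndarray | None = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (*self.offset, self.cube.rows, self.cube.cols)


def cutout_roi(
    cube: HyperCube,
    warped_ihc: np.ndarray,
    bbox: tuple[int, int, int, int],
    label: str | None = None,
) -> PlaqueROI:
    """Cut a paired spectral sub-cube and IHC cutout over an identical
    pixel extent.  ``bbox`` is (row0, col0, height, width).  The cutouts
    are independent copies."""
    r0, c0, h, w = bbox
    if warped_ihc.shape != (cube.rows, cube.cols):
        raise InputError("warped IHC shape does not match the cube")
    if h <= 0 or w <= 0:
        raise RangeError("bbox height and width must be positive")
    if r0 < 0 or c0 < 0 or r0 + h > cube.rows or c0 + w > cube.cols:
        raise RangeError(f"bbox {bbox} outside cube {cube.rows}x{cube.cols}")
    sub = HyperCube(
        cube.data[r0 : r0 + h, c0 : c0 + w].copy(), cube.axis, cube.pixel_size_um
    )
    return PlaqueROI(
        cube=sub,
        ihc=np.asarray(warped_ihc[r0 : r0 + h, c0 : c0 + w], float).copy(),
        offset=(r0, c0),
        label=label,
    )


def read_landmarks_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Landmark CSV with columns src_row, src_col, dst_row, dst_col."""
    df = pd.read_csv(path)
    needed = ["src_row", "src_col", "dst_row", "dst_col"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing landmark columns {missing}")
    return df[needed[:2]].to_numpy(float), df[needed[2:]].to_numpy(float)


def write_landmarks_csv(
    path: str, points_ihc: np.ndarray, points_cube: np.ndarray
) -> None:
    df = pd.DataFrame(
        np.column_stack([points_ihc, points_cube]),
        columns=["src_row", "src_col", "dst_row", "dst_col"],
    )
    df.to_csv(path, index=False)
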