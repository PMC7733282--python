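"""Plaque, ring and mean-spectrum extraction.

The amyloid-positive plaque mask is thresholded from the warped
immunostain cutout with Otsu's method (dark = stain-positive).  The
*surrounding* compartment is a ring of configurable radial thickness
(default 100 um) measured by Euclidean distance transform from the
plaque mask boundary, with amyloid-positive pixels excluded.  Mean
spectra are arithmetic means over QC-valid pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .qc_correction import QCResult
from .spectra_core import HyperCube, PipelineError, PixelMask, Spectrum

__all__ = [
    "MaskError",
    "GroupSpectra",
    "otsu_mask",
    "ring_mask",
    "mean_masked_spectrum",
    "compute_group_spectra",
]

RING_THICKNESS_UM_DEFAULT = 100.0


class MaskError(PipelineError):
    """A mask cannot be built or selects no usable pixels."""


@dataclass
class GroupSpectra:
    """Mean plaque / surrounding (and optionally core) spectra of one
    plaque, with the pixel counts that entered each mean."""

    plaque_spectrum: Spectrum
    surrounding_spectrum: Spectrum
    n_plaque: int
    n_surrounding: int
    core_spectrum: Spectrum | None = None
    n_core: int = 0
    label: str | None = None


def otsu_mask(ihc_cutout: np.ndarray, invert: bool = False) -> PixelMask:
    """Binary stain mask from a grayscale immunostain cutout.

    Threshold maximizes between-class variance over a 256-bin histogram;
    the positive class is the lower-intensity (dark, DAB-stained) side.
    ``invert`` selects the complementary class instead.
    """
    img = np.asarray(ihc_cutout, dtype=np.float64)
    if img.ndim != 2:
        raise MaskError("cutout must be a 2-D grayscale image")
    if np.nanmin(img) == np.nanmax(img):
        raise MaskError("constant image has no Otsu threshold")
    threshold = threshold_otsu(img, nbins=256)
    mask = img > threshold if invert else img < threshold
    return PixelMask(mask)


def ring_mask(
    plaque_mask: PixelMask | np.ndarray,
    thickness_um: float = RING_THICKNESS_UM_DEFAULT,
    pixel_size_um: float = 1.1,
    abeta_positive_mask: PixelMask | np.ndarray | None = None,
) -> PixelMask:
    """Ring of radial thickness ``thickness_um`` surrounding the plaque.

    ring = { p : 0 < dist(p, plaque) * pixel_size <= thickness } minus
    the amyloid-positive mask, with dist the Euclidean distance
    transform to the nearest plaque pixel; clipped at the image borders.
    """
    pm = plaque_mask.mask if isinstance(plaque_mask, PixelMask) else np.asarray(
        plaque_mask, bool
    )
    if not pm.any():
        raise MaskError("empty plaque mask")
    dist = ndimage.distance_transform_edt(~pm) * float(pixel_size_um)
    ring = (dist > 0) & (dist <= thickness_um)
    if abeta_positive_mask is not None:
        am = (
            abeta_positive_mask.mask
            if isinstance(abeta_positive_mask, PixelMask)
            else np.asarray(abeta_positive_mask, bool)
        )
        ring &= ~am
    return PixelMask(ring)


def mean_masked_spectrum(
    cube: HyperCube,
    mask: PixelMask | np.ndarray,
    qc: QCResult | np.ndarray | None = None,
) -> tuple[Spectrum, int]:
    """Channel-wise arithmetic mean over masked, QC-valid pixels.

    Returns the mean spectrum and the number of pixels used; raises
    :class:`MaskError` if the selection is empty.  Permutation-invariant
    in pixel order by construction.
    """
    m = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask, bool)
    if m.shape != (cube.rows, cube.cols):
        raise MaskError("mask shape does not match the cube")
    if qc is not None:
        valid = qc.valid if isinstance(qc, QCResult) else np.asarray(qc, bool)
        m = m & valid
    n = int(m.sum())
    if n == 0:
        raise MaskError("mask selects no QC-valid pixels")
    mean = cube.data[m].astype(np.float64).mean(axis=0)
    return Spectrum(cube.axis, mean), n


def compute_group_spectra(
    cube: HyperCube,
    plaque_mask: PixelMask | np.ndarray,
    ring: PixelMask | np.ndarray,
    qc: QCResult | np.ndarray | None = None,
    core_mask: PixelMask | np.ndarray | None = None,
    label: str | None = None,
) -> GroupSpectra:
    """Assemble the plaque / surrounding (and optional core) mean
    spectra of one plaque."""
    plaque_spec, n_p = mean_masked_spectrum(cube, plaque_mask, qc)
    surround_spec, n_s = mean_masked_spectrum(cube, ring, qc)
    core_spec, n_c = (None, 0)
    if core_mask is not None:
        cm = core_mask.mask if isinstance(core_mask, PixelMask) else core_mask
        if np.asarray(cm).any():
            core_spec, n_c = mean_masked_spectrum(cube, core_mask, qc)
    return GroupSpectra(
        plaque_spectrum=plaque_spec,
        surrounding_spectrum=surround_spec,
        n_plaque=n_p,
        n_surrounding=n_s,
        core_spectrum=core_spec,
        n_core=n_c,
        label=label,
    )
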