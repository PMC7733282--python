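"""Spectrum quality control and EMSC-based Mie scattering correction.

Two per-pixel quality rules are applied before any averaging:

* noise: SNR >= 100, with SNR defined as the Amide I maximum
  (1700-1600 cm^-1) divided by the standard deviation of the linearly
  detrended absorbance in part of the silent region (2000-1800 cm^-1);
* scattering: the mean apparent absorbance over the silent region
  (2300-1800 cm^-1) must not exceed half the absorbance at 1655 cm^-1.

Pixels failing either rule are dropped from all downstream means, never
imputed.  Remaining spectra are corrected by extended multiplicative
signal correction (EMSC) with a scattering basis built from the first
principal components of a sampled family of van de Hulst extinction
curves, the classical thin-sphere approximation for Mie-type baseline
ripple in tissue microspectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .spectra_core import (
    HyperCube,
    PipelineError,
    Spectrum,
    WavenumberAxis,
    channel_slice,
    index_of,
)

__all__ = [
    "ModelError",
    "QCResult",
    "EMSCModel",
    "compute_qc",
    "van_de_hulst_curve",
    "mie_curve_family",
    "build_emsc_model",
    "correct_spectrum",
    "correct_cube",
    "save_emsc_model",
    "load_emsc_model",
]

SNR_MIN_DEFAULT = 100.0
SILENT_REGION = (1800.0, 2300.0)
SILENT_NOISE_REGION = (1800.0, 2000.0)
AMIDE_I_REGION = (1600.0, 1700.0)


class ModelError(PipelineError):
    """The EMSC model cannot be built or applied."""


@dataclass
class QCResult:
    """Per-pixel quality metrics and the resulting validity mask."""

    snr: np.ndarray
    silent_mean: np.ndarray
    a1655: np.ndarray
    valid: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def compute_qc(cube: HyperCube, snr_min: float = SNR_MIN_DEFAULT) -> QCResult:
    """Apply the noise and scattering rules to every pixel of a cube.

    valid <=> (snr >= snr_min) and (silent_mean <= a1655 / 2)
    """
    axis = cube.axis
    lo, hi = axis.span
    for needed in (SILENT_REGION[0], SILENT_REGION[1], AMIDE_I_REGION[1], 1655.0):
        if not (lo <= needed <= hi):
            raise PipelineError(
                f"axis [{lo}, {hi}] does not cover required wavenumber {needed}"
            )
    flat = cube.flat().astype(np.float64)

    sl_amide = channel_slice(axis, *AMIDE_I_REGION)
    sl_silent = channel_slice(axis, *SILENT_REGION)
    sl_noise = channel_slice(axis, *SILENT_NOISE_REGION)

    amide_max = flat[:, sl_amide].max(axis=1)
    silent_mean = flat[:, sl_silent].mean(axis=1)
    a1655 = flat[:, index_of(axis, 1655.0)]

    # std of the linearly detrended noise window, via the projection
    # residual of a per-pixel straight-line fit
    x = axis.values[sl_noise]
    g = np.column_stack([x, np.ones_like(x)])
    proj = g @ np.linalg.pinv(g)  # symmetric hat matrix
    y = flat[:, sl_noise]
    resid = y - y @ proj.T
    noise_std = resid.std(axis=1)

    snr = np.where(noise_std > 0, amide_max / np.maximum(noise_std, 1e-300), 0.0)
    snr = np.where((noise_std == 0) & (amide_max > 0), np.inf, snr)

    valid = (snr >= snr_min) & (silent_mean <= a1655 / 2.0)
    shape = (cube.rows, cube.cols)
    return QCResult(
        snr=snr.reshape(shape),
        silent_mean=silent_mean.reshape(shape),
        a1655=a1655.reshape(shape),
        valid=valid.reshape(shape),
    )


# ---------------------------------------------------------------------------
# Mie scattering basis (van de Hulst thin-sphere extinction)
# ---------------------------------------------------------------------------

def van_de_hulst_curve(
    wavenumbers: np.ndarray, radius_um: float, dn: float
) -> np.ndarray:
    """Extinction efficiency Q of a homogeneous sphere in the van de Hulst
    (anomalous diffraction) approximation.

    Q(x) = 2 - (4/x) sin x + (4/x^2)(1 - cos x),  x = 4*pi*a*(n-1)*nu

    with sphere radius ``a`` (here in um, converted to cm) and relative
    refractive-index excess ``dn`` = n - 1, evaluated per wavenumber ``nu``
    in cm^-1.  The curve is smooth and oscillatory, the canonical shape of
    Mie-type baseline distortion in IR microspectra of tissue.
    """
    x = 4.0 * np.pi * (radius_um * 1e-4) * dn * np.asarray(wavenumbers, float)
    x = np.maximum(x, 1e-12)
    return 2.0 - (4.0 / x) * np.sin(x) + (4.0 / x**2) * (1.0 - np.cos(x))


def mie_curve_family(
    axis: WavenumberAxis,
    radii_um: np.ndarray | None = None,
    dns: np.ndarray | None = None,
) -> np.ndarray:
    """Matrix of max-normalised van de Hulst curves (one row per
    (radius, dn) pair) sampled over the axis."""
    if radii_um is None:
        radii_um = np.linspace(2.0, 12.0, 15)
    if dns is None:
        dns = np.linspace(0.1, 0.5, 8)
    curves = np.array(
        [
            van_de_hulst_curve(axis.values, a, d)
            for a in np.atleast_1d(radii_um)
            for d in np.atleast_1d(dns)
        ]
    )
    return curves / curves.max(axis=1, keepdims=True)


@dataclass
class EMSCModel:
    """EMSC decomposition basis: reference + polynomial + Mie components.

    The reference spectrum is normalised to unit maximum in the Amide I
    region, so corrected spectra share the reference's intensity scale
    (the multiplicative coefficient absorbs per-pixel optical density);
    downstream metrics are therefore band ratios, which are unaffected.
    """

    axis: WavenumberAxis
    reference: np.ndarray
    poly_basis: np.ndarray  # (order+1, n_channels)
    mie_basis: np.ndarray  # (n_mie, n_channels), orthonormal rows
    order: int
    n_mie: int
    coefficients: np.ndarray | None = field(default=None, repr=False)
    flags: dict = field(default_factory=dict)

    @property
    def design(self) -> np.ndarray:
        """(n_channels, 1 + order + 1 + n_mie) design matrix."""
        return np.vstack([self.reference[None, :], self.poly_basis, self.mie_basis]).T


def build_emsc_model(
    cube: HyperCube,
    qc: QCResult | None = None,
    order: int = 2,
    n_mie: int = 7,
    reference: Spectrum | None = None,
) -> EMSCModel:
    """Build the EMSC basis from a cube.

    The reference defaults to the median spectrum over QC-valid pixels;
    the Mie basis holds the first ``n_mie`` principal components (SVD) of
    the sampled van de Hulst family.  The model is fitted over the full
    axis with no excluded sub-regions.
    """
    axis = cube.axis
    if reference is not None:
        if reference.axis != axis:
            raise ModelError("reference spectrum is not on the cube axis")
        ref = reference.absorbance.astype(np.float64).copy()
    else:
        valid = qc.valid if qc is not None else np.ones(
            (cube.rows, cube.cols), dtype=bool
        )
        n_valid = int(valid.sum())
        if n_valid < 10:
            raise ModelError(f"only {n_valid} valid pixels; need at least 10")
        ref = np.median(cube.flat()[valid.ravel()], axis=0).astype(np.float64)
    sl_amide = channel_slice(axis, *AMIDE_I_REGION)
    peak = np.max(np.abs(ref[sl_amide]))
    if peak <= 0:
        raise ModelError("reference has no Amide I intensity")
    ref = ref / peak

    # Legendre polynomial baseline terms on the scaled axis
    x = np.linspace(-1.0, 1.0, axis.n_channels)
    poly = np.array([np.polynomial.legendre.Legendre.basis(i)(x) for i in range(order + 1)])

    if n_mie > 0:
        family = mie_curve_family(axis)
        _, _, vt = np.linalg.svd(family, full_matrices=False)
        mie = vt[:n_mie]
    else:
        mie = np.zeros((0, axis.n_channels))
    return EMSCModel(
        axis=axis, reference=ref, poly_basis=poly, mie_basis=mie,
        order=order, n_mie=n_mie,
    )


_C_FLOOR = 1e-6


def _fit_coefficients(y: np.ndarray, model: EMSCModel) -> tuple[np.ndarray, dict]:
    """Least-squares EMSC coefficients for spectra in the rows of ``y``."""
    d = model.design
    flags: dict = {}
    coef, _, rank, _ = np.linalg.lstsq(d, y.T, rcond=None)
    if rank < d.shape[1]:
        # singular design: fall back to plain EMSC without Mie terms
        flags["mie_dropped"] = True
        d0 = d[:, : 1 + model.poly_basis.shape[0]]
        coef0, _, _, _ = np.linalg.lstsq(d0, y.T, rcond=None)
        coef = np.zeros((d.shape[1], y.shape[0]))
        coef[: coef0.shape[0]] = coef0
    return coef.T, flags  # (n_pixels, n_terms)


def _apply_correction(
    y: np.ndarray, coef: np.ndarray, model: EMSCModel
) -> tuple[np.ndarray, dict]:
    npoly = model.poly_basis.shape[0]
    c = coef[:, 0]
    flags: dict = {}
    small = np.abs(c) < _C_FLOOR
    if np.any(small):
        flags["c_clamped"] = int(small.sum())
        c = np.where(small, np.where(c < 0, -_C_FLOOR, _C_FLOOR), c)
    background = coef[:, 1 : 1 + npoly] @ model.poly_basis
    if model.n_mie > 0:
        background = background + coef[:, 1 + npoly :] @ model.mie_basis
    return (y - background) / c[:, None], flags


def correct_spectrum(spectrum: Spectrum, model: EMSCModel) -> Spectrum:
    """EMSC-correct a single spectrum:
    corrected = (y - polynomial - Mie) / c."""
    if spectrum.axis != model.axis:
        raise ModelError("spectrum is not on the model axis")
    y = spectrum.absorbance[None, :].astype(np.float64)
    coef, f1 = _fit_coefficients(y, model)
    corrected, f2 = _apply_correction(y, coef, model)
    return Spectrum(spectrum.axis, corrected[0])


def correct_cube(cube: HyperCube, model: EMSCModel) -> HyperCube:
    """EMSC-correct every pixel of a cube.  The fitted per-pixel
    coefficients are stored on ``model.coefficients`` (multiplicative c
    first, then polynomial, then Mie terms)."""
    if cube.axis != model.axis:
        raise ModelError("cube is not on the model axis")
    y = cube.flat().astype(np.float64)
    coef, f1 = _fit_coefficients(y, model)
    corrected, f2 = _apply_correction(y, coef, model)
    model.coefficients = coef
    model.flags = {**f1, **f2}
    return HyperCube(
        corrected.reshape(cube.data.shape).astype(np.float32),
        cube.axis,
        cube.pixel_size_um,
    )


def save_emsc_model(model: EMSCModel, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("wavenumbers", data=model.axis.values)
        f.create_dataset("reference", data=model.reference)
        f.create_dataset("poly_basis", data=model.poly_basis)
        f.create_dataset("mie_basis", data=model.mie_basis)
        f.attrs["order"] = model.order
        f.attrs["n_mie"] = model.n_mie
        if model.coefficients is not None:
            f.create_dataset("coefficients", data=model.coefficients)


def load_emsc_model(path: str) -> EMSCModel:
    with h5py.File(path, "r") as f:
        model = EMSCModel(
            axis=WavenumberAxis(f["wavenumbers"][()]),
            reference=f["reference"][()],
            poly_basis=f["poly_basis"][()],
            mie_basis=f["mie_basis"][()],
            order=int(f.attrs["order"]),
            n_mie=int(f.attrs["n_mie"]),
        )
        if "coefficients" in f:
            model.coefficients = f["coefficients"][()]
    return model
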