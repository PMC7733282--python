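"""Amide-region spectral mathematics.

Linear baselines, area normalization, difference spectra,
Savitzky-Golay second derivatives, band-position picking with parabolic
sub-grid refinement, and the two spectroscopic ratios used throughout:

* protein ratio  A1545 / A_CH — Amide II peak height over the mean
  absorbance of the CH-stretch region (3000-2800 cm^-1), a proxy for
  protein accumulation relative to total lipid+protein content;
* beta-sheet ratio  A1630 / A1655 — height of the main beta-sheet band
  over the non-beta Amide I band, both read from the 1800-1480 cm^-1
  linearly baselined segment.

Band heights are local extrema within +-5 cm^-1 of the nominal position
rather than fixed-channel lookups, because the sampling grid does not
contain the nominal positions exactly; band positions are refined by
parabolic interpolation through the extremum and its two neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_core import (
    HyperCube,
    InputError,
    RangeError,
    Spectrum,
    WavenumberAxis,
    channel_slice,
)
from .qc_correction import QCResult

__all__ = [
    "NormalizationError",
    "BandTable",
    "BandPick",
    "RatioSet",
    "subtract_linear_baseline",
    "area_normalize",
    "difference_spectrum",
    "second_derivative",
    "pick_band",
    "compute_ratios",
    "ratio_maps",
    "spline_resample",
]

_DENOM_FLOOR = 1e-6


class NormalizationError(RangeError):
    """Area normalization over a non-positive integral."""


@dataclass(frozen=True)
class BandTable:
    """Named band positions (cm^-1) and analysis windows."""

    amide_ii: float = 1545.0
    non_beta: float = 1655.0
    beta_main: float = 1630.0
    fibril: float = 1628.0
    fibril_shoulder: float = 1620.0
    turn: float = 1682.0
    antiparallel: float = 1693.0
    turn_minor: float = 1657.0
    minor: float = 1639.0
    ester: float = 1738.0
    pick_half_window: float = 5.0
    ch_region: tuple[float, float] = (2800.0, 3000.0)
    silent_region: tuple[float, float] = (1800.0, 2300.0)
    amide_window: tuple[float, float] = (1480.0, 1800.0)
    beta_window: tuple[float, float] = (1610.0, 1690.0)


@dataclass(frozen=True)
class BandPick:
    """A picked band: refined position, (unrefined) extremum height and
    whether an interior extremum was actually resolved."""

    position_cm1: float
    height: float
    resolved: bool


@dataclass(frozen=True)
class RatioSet:
    """The spectroscopic metrics of one spectrum.

    ``d2_height_diff`` is the second-derivative value at the 1628 pick
    minus the value at the 1693 pick (it is not scale-free and becomes
    more negative as the parallel beta-sheet band dominates).
    """

    protein_ratio: float
    beta_ratio: float
    d2_height_diff: float
    beta_position_cm1: float = float("nan")
    flags: tuple[str, ...] = ()


def subtract_linear_baseline(
    spectrum: Spectrum, lo_cm1: float, hi_cm1: float
) -> Spectrum:
    """Restrict to [lo, hi] and subtract the straight line through the
    endpoint values (the channels nearest lo and hi map to zero)."""
    sl = channel_slice(spectrum.axis, lo_cm1, hi_cm1)
    wn = spectrum.axis.values[sl]
    y = spectrum.absorbance[sl].astype(np.float64)
    line = y[0] + (y[-1] - y[0]) * (wn - wn[0]) / (wn[-1] - wn[0])
    return Spectrum(WavenumberAxis(wn), y - line)


def area_normalize(
    spectrum: Spectrum, lo_cm1: float = 1610.0, hi_cm1: float = 1690.0
) -> Spectrum:
    """Divide all values by the rectangle-rule integral
    sum(|A|) * step over [lo, hi]; the normalized integral is 1."""
    lo_cm1, hi_cm1 = sorted((lo_cm1, hi_cm1))
    sl = channel_slice(spectrum.axis, lo_cm1, hi_cm1)
    area = float(np.sum(np.abs(spectrum.absorbance[sl])) * spectrum.axis.step_cm1)
    if area <= 0:
        raise NormalizationError(
            f"non-positive area {area} over [{lo_cm1}, {hi_cm1}]"
        )
    return Spectrum(spectrum.axis, spectrum.absorbance / area)


def difference_spectrum(a: Spectrum, b: Spectrum, mode: str = "amide") -> Spectrum:
    """Difference between two spectra (a - b) after the mode's pretreatment.

    mode "amide": linear baseline over 1800-1480 cm^-1 on each, subtract.
    mode "beta": linear baseline over 1690-1610 cm^-1, area-normalize
    each over that window, subtract — isolates Amide I band-shape
    differences independent of amount.
    """
    if a.axis != b.axis:
        raise InputError("spectra are on different axes")
    table = BandTable()
    if mode == "amide":
        lo, hi = table.amide_window
        sa = subtract_linear_baseline(a, lo, hi)
        sb = subtract_linear_baseline(b, lo, hi)
    elif mode == "beta":
        lo, hi = table.beta_window
        sa = area_normalize(subtract_linear_baseline(a, lo, hi), lo, hi)
        sb = area_normalize(subtract_linear_baseline(b, lo, hi), lo, hi)
    else:
        raise InputError(f"unknown difference mode {mode!r}")
    return Spectrum(sa.axis, sa.absorbance - sb.absorbance)


def spline_resample(spectrum: Spectrum, factor: int = 5) -> Spectrum:
    """Cubic-spline interpolation onto a denser grid, for display only."""
    from scipy.interpolate import CubicSpline

    wn = spectrum.axis.values[::-1]  # ascending for the spline
    cs = CubicSpline(wn, spectrum.absorbance[::-1])
    dense = np.linspace(wn[0], wn[-1], (len(wn) - 1) * factor + 1)
    return Spectrum(WavenumberAxis(dense[::-1]), cs(dense)[::-1])


def second_derivative(spectrum: Spectrum) -> Spectrum:
    """Savitzky-Golay second derivative (polynomial order 3, window 5),
    expressed per (cm^-1)^2.  The first and last two channels, where the
    window would be truncated, are marked invalid (NaN)."""
    n = spectrum.axis.n_channels
    if n < 5:
        raise InputError("second derivative needs at least 5 channels")
    d2 = savgol_filter(
        spectrum.absorbance, window_length=5, polyorder=3, deriv=2,
        delta=spectrum.axis.step_cm1,
    )
    d2[:2] = np.nan
    d2[-2:] = np.nan
    return Spectrum(spectrum.axis, d2)


def pick_band(
    spectrum: Spectrum,
    nominal_cm1: float,
    half_window_cm1: float = 5.0,
    sense: str = "max",
) -> BandPick:
    """Locate a band extremum within nominal +- half_window.

    sense "max" picks the absorbance maximum (band height), sense "min"
    the second-derivative minimum.  The position is refined by parabolic
    interpolation through the extremum and its two neighbours; the
    height is the unrefined extremum value.  If the extremum sits on the
    window boundary (no interior extremum), the pick is flagged
    unresolved.
    """
    if sense not in ("max", "min"):
        raise InputError(f"unknown pick sense {sense!r}")
    sl = channel_slice(spectrum.axis, nominal_cm1 - half_window_cm1,
                       nominal_cm1 + half_window_cm1)
    idx = np.arange(sl.start, sl.stop)
    if idx.size < 3:
        raise RangeError("pick window narrower than 3 channels")
    vals = spectrum.absorbance[sl]
    if np.all(np.isnan(vals)):
        raise RangeError("pick window contains no finite values")
    pos_in = int(np.nanargmax(vals) if sense == "max" else np.nanargmin(vals))
    j = int(idx[pos_in])
    height = float(spectrum.absorbance[j])
    position = float(spectrum.axis.values[j])
    flat = bool(np.nanmax(vals) == np.nanmin(vals))
    if flat or pos_in == 0 or pos_in == len(idx) - 1:
        return BandPick(position, height, resolved=False)
    y0, y1, y2 = spectrum.absorbance[j - 1], height, spectrum.absorbance[j + 1]
    denom = y0 - 2 * y1 + y2
    if np.isfinite(denom) and denom != 0:
        offset = 0.5 * (y0 - y2) / denom
        step = spectrum.axis.values[j] - spectrum.axis.values[j - 1]  # negative
        position = float(spectrum.axis.values[j] + offset * step)
    return BandPick(position, height, resolved=True)


def compute_ratios(spectrum: Spectrum, table: BandTable = BandTable()) -> RatioSet:
    """Spectroscopic ratios of a (corrected, non-baselined) spectrum.

    The Amide II height and the CH-region mean are read from the raw
    spectrum; the beta-sheet ratio from the 1800-1480 baselined segment;
    the second-derivative height difference from the same segment.
    Denominators are floored at 1e-6 with a flag.
    """
    flags: list[str] = []
    ch = spectrum.absorbance[channel_slice(spectrum.axis, *table.ch_region)]
    a_ch = float(np.mean(ch))
    amide_ii = pick_band(spectrum, table.amide_ii, table.pick_half_window, "max")

    seg = subtract_linear_baseline(spectrum, *table.amide_window)
    beta = pick_band(seg, table.beta_main, table.pick_half_window, "max")
    non_beta = pick_band(seg, table.non_beta, table.pick_half_window, "max")

    d2 = second_derivative(seg)
    d2_beta = pick_band(d2, table.fibril, table.pick_half_window, "min")
    d2_anti = pick_band(d2, table.antiparallel, table.pick_half_window, "min")

    if a_ch < _DENOM_FLOOR:
        a_ch = _DENOM_FLOOR
        flags.append("ch_floored")
    h_nonbeta = non_beta.height
    if h_nonbeta < _DENOM_FLOOR:
        h_nonbeta = _DENOM_FLOOR
        flags.append("non_beta_floored")
    return RatioSet(
        protein_ratio=amide_ii.height / a_ch,
        beta_ratio=beta.height / h_nonbeta,
        d2_height_diff=d2_beta.height - d2_anti.height,
        beta_position_cm1=d2_beta.position_cm1,
        flags=tuple(flags),
    )


def ratio_maps(
    cube: HyperCube, qc: QCResult | None = None, table: BandTable = BandTable()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel protein-ratio and beta-ratio images.

    Vectorized band heights: window maxima without sub-grid refinement
    (maps report heights, not positions).  The protein ratio uses the
    raw spectrum, the beta ratio the per-pixel 1800-1480 baselined
    segment, mirroring the treatment of plaque mean spectra.  QC-invalid
    pixels are NaN.
    """
    axis = cube.axis
    flat = cube.flat().astype(np.float64)

    sl_ch = channel_slice(axis, *table.ch_region)
    a_ch = np.maximum(flat[:, sl_ch].mean(axis=1), _DENOM_FLOOR)
    half = table.pick_half_window
    sl_1545 = channel_slice(axis, table.amide_ii - half, table.amide_ii + half)
    protein = flat[:, sl_1545].max(axis=1) / a_ch

    sl_seg = channel_slice(axis, *table.amide_window)
    wn = axis.values[sl_seg]
    seg = flat[:, sl_seg]
    w = (wn - wn[0]) / (wn[-1] - wn[0])
    baseline = seg[:, [0]] * (1 - w)[None, :] + seg[:, [-1]] * w[None, :]
    seg = seg - baseline
    sub_axis = WavenumberAxis(wn)
    sl_beta = channel_slice(sub_axis, table.beta_main - half, table.beta_main + half)
    sl_nonb = channel_slice(sub_axis, table.non_beta - half, table.non_beta + half)
    beta = seg[:, sl_beta].max(axis=1) / np.maximum(
        seg[:, sl_nonb].max(axis=1), _DENOM_FLOOR
    )

    shape = (cube.rows, cube.cols)
    protein = protein.reshape(shape)
    beta = beta.reshape(shape)
    if qc is not None:
        protein = np.where(qc.valid, protein, np.nan)
        beta = np.where(qc.valid, beta, np.nan)
    return protein, beta
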