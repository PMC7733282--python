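"""Synthetic FTIR hyperspectral scenes with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in cortical gray matter carrying amyloid-beta deposits:

* a gray-matter base spectrum built from Gaussian bands — a composite
  Amide I (main non-beta band at 1655 cm^-1 plus minor sub-bands at
  1693, 1682, 1657 and 1639 cm^-1, so second derivatives of control
  tissue resolve the same sub-band set as plaques), Amide II at 1545,
  the lipid ester band at 1738, CH-stretch bands in 3000-2800 and a
  broad N-H/O-H band near 3300;
* amyloid deposits as a density-weighted mixture of an *oligomer* band
  model (main beta-sheet band at 1630, antiparallel marker at 1693 held
  at a fixed minor fraction of the main band, weak turn band at 1682)
  and a *fibril* model (main band at 1628 with a low-wavenumber shoulder
  raising absorbance around 1620, turn band at 1683, no 1693 component);
* three plaque morphologies: diffuse (low density, oligomer-dominated,
  blob-like scatter), compact (intermediate, centralized or homogeneous)
  and classic cored (corona plus a dense, fibril-dominated core in which
  the ester band is reduced but strictly positive);
* smooth van de Hulst Mie baselines with per-pixel random sphere size
  and amplitude, i.i.d. Gaussian noise, and an optional fraction of
  deliberately low-SNR pixels (the QC ground truth);
* a matched pseudo-immunostain (DAB-like, dark = amyloid-positive)
  image rendered at higher magnification under a known misalignment
  affine.

The silent region (2300-1800 cm^-1) carries no band absorbance by
construction; apparent absorbance there comes only from the Mie term.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
from scipy import ndimage

from .registration import AffineTransform2D
from .spectra_core import (
    HyperCube,
    PipelineError,
    PixelMask,
    WavenumberAxis,
    default_axis,
)

__all__ = [
    "ConfigError",
    "SamplingError",
    "GaussianBand",
    "BandModel",
    "GRAY_MATTER_BANDS",
    "ESTER_BAND",
    "OLIGOMER_BANDS",
    "FIBRIL_BANDS",
    "PlaqueSpec",
    "SceneConfig",
    "SceneTruth",
    "simulate_scene",
    "render_ihc",
    "true_landmarks",
    "sample_control_patches",
    "single_plaque_config",
    "cohort_scene_config",
    "write_scene",
]

PLAQUE_TYPES = ("diffuse", "compact", "classic_cored")


class ConfigError(PipelineError):
    """Invalid scene configuration."""


class SamplingError(PipelineError):
    """Control-patch sampling could not satisfy its constraints."""


@dataclass(frozen=True)
class GaussianBand:
    center_cm1: float
    width_cm1: float  # Gaussian sigma
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_cm1 <= 0:
            raise ConfigError("band width must be positive")
        if self.amplitude < 0:
            raise ConfigError("band amplitude must be non-negative")


@dataclass(frozen=True)
class BandModel:
    """Sum-of-Gaussians spectral component."""

    bands: tuple[GaussianBand, ...]

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        wn = axis.values
        out = np.zeros_like(wn)
        for b in self.bands:
            out += b.amplitude * np.exp(-0.5 * ((wn - b.center_cm1) / b.width_cm1) ** 2)
        return out


def _bm(triples) -> BandModel:
    return BandModel(tuple(GaussianBand(*t) for t in triples))


# Gray matter base, split into a protein group (Amide I composite +
# Amide II), a lipid CH-stretch group, and a broad N-H/O-H band; the
# ester band is kept separate because it is scaled per pixel (reduced
# in plaque cores).  Amplitudes in absorbance units for a 20 um
# section; widths are Gaussian sigmas in cm^-1.
GRAY_PROTEIN_BANDS = _bm([
    (1655.0, 13.0, 0.40),   # main non-beta Amide I
    (1693.0, 5.5, 0.075),   # antiparallel/turn sub-band of tissue proteins
    (1682.0, 5.5, 0.045),   # turn sub-band
    (1657.0, 5.0, 0.030),   # helical sub-band
    (1639.0, 8.0, 0.050),   # unordered sub-band
    (1545.0, 15.0, 0.25),   # Amide II
])
GRAY_LIPID_BANDS = _bm([
    (2852.0, 11.0, 0.10),   # CH2 sym stretch
    (2872.0, 9.0, 0.05),    # CH3 sym stretch
    (2925.0, 13.0, 0.16),   # CH2 asym stretch
    (2958.0, 9.0, 0.09),    # CH3 asym stretch
])
GRAY_NH_BAND = _bm([(3290.0, 75.0, 0.30)])  # broad N-H / O-H

ESTER_BAND = _bm([(1738.0, 9.0, 0.10)])  # lipid ester C=O stretch

# combined model (heterogeneity fields at their mean of 1)
GRAY_MATTER_BANDS = BandModel(
    GRAY_PROTEIN_BANDS.bands + GRAY_LIPID_BANDS.bands + GRAY_NH_BAND.bands
)

# Amyloid-beta oligomer component (per unit density).  The antiparallel
# 1693 marker is fixed at a small constant fraction of the 1630 band.
# Oligomers/protofibrils carry less beta-sheet per protein than mature
# fibrils, so the main band is weaker than the fibril model's.
OLIGOMER_BANDS = _bm([
    (1630.0, 6.0, 0.65),
    (1693.0, 5.5, 0.052),
    (1682.0, 5.5, 0.039),
    (1655.0, 13.0, 0.30),
    (1545.0, 15.0, 0.45),
    (2925.0, 13.0, 0.06),
    (2852.0, 11.0, 0.03),
])

# Amyloid-beta fibril component: main band at 1628 with a shoulder
# raising absorbance around 1620, turn band at 1683, no 1693 marker.
FIBRIL_BANDS = _bm([
    (1628.0, 7.0, 1.00),
    (1618.0, 6.0, 0.15),
    (1683.0, 5.5, 0.25),
    (1655.0, 13.0, 0.08),
    (1545.0, 15.0, 0.45),
    (2925.0, 13.0, 0.06),
    (2852.0, 11.0, 0.03),
])

# Per-type priors for the per-plaque (density scale, fibril fraction)
# draw: mean and standard deviation of each marginal.
TYPE_PRIORS = {
    "diffuse": {"density": (0.35, 0.15), "fibril": (0.08, 0.05)},
    "compact": {"density": (0.80, 0.35), "fibril": (0.50, 0.25)},
    "classic_cored": {"density": (0.50, 0.20), "fibril": (0.25, 0.12)},
}
CORE_PRIORS = {"density": (2.0, 0.60), "fibril": (0.92, 0.04)}
# per-plaque spread of the deposit's Amide II content relative to its
# beta-sheet bands (non-amyloid protein admixture varies between
# plaques); multiplies the amyloid models' 1545 cm^-1 band
AMIDE2_ADMIX_SD = 0.19
_AMIDE2_BAND = _bm([(1545.0, 15.0, 0.45)])
CORE_ESTER_SCALE = 0.35  # reduced but strictly positive lipid content

# Packaged default coupling between per-plaque density and fibril
# fraction (Gaussian copula correlation).  Calibrated once during
# development so the full pipeline's measured Pearson correlation
# between the protein and beta-sheet ratios on the default cohort
# matches the R = 0.73 reported for human AD plaque cohorts (see
# docs/methods.md).
DEFAULT_COUPLING_RHO = 0.6


@dataclass
class PlaqueSpec:
    """One plaque to place in the scene.

    ``density_scale`` and ``fibril_fraction`` may be left as None to be
    drawn from the per-type priors under the configured coupling.
    """

    type: str
    center: tuple[float, float]
    radius_um: float
    density_scale: float | None = None
    fibril_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.type not in PLAQUE_TYPES:
            raise ConfigError(f"unknown plaque type {self.type!r}")
        if self.radius_um <= 0:
            raise ConfigError("plaque radius must be positive")


@dataclass
class SceneConfig:
    rows: int = 64
    cols: int = 64
    pixel_size_um: float = 1.1
    plaques: list[PlaqueSpec] = field(default_factory=list)
    coupling_rho: float = DEFAULT_COUPLING_RHO
    # Mie baseline distortion
    mie_enabled: bool = True
    mie_amplitude: tuple[float, float] = (0.005, 0.05)
    mie_radius_um: tuple[float, float] = (2.0, 12.0)
    mie_dn: tuple[float, float] = (0.1, 0.5)
    # noise
    noise_sigma: float = 0.001
    low_snr_fraction: float = 0.02
    low_snr_sigma: float = 0.02
    # pseudo-IHC rendering and misalignment
    ihc_magnification: float = 2.0
    ihc_rotation_deg: float = 3.0
    ihc_translation: tuple[float, float] = (2.5, -1.8)
    ihc_background: float = 0.9
    ihc_contrast: float = 0.75
    ihc_saturation: float = 0.08
    ihc_glial_gaps: int = 0
    ihc_hollow_cores: bool = False
    # gray-matter composition heterogeneity (smooth multiplicative
    # fields; control tissue protein/lipid content is not homogeneous)
    protein_heterogeneity: float = 0.25
    lipid_heterogeneity: float = 0.35
    heterogeneity_scale_px: float = 12.0
    # morphology
    compact_profile: str = "centralized"  # or "homogeneous"
    core_radius_frac: float = 0.35
    edge_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ConfigError("coupling_rho must lie in [-1, 1]")
        if self.compact_profile not in ("centralized", "homogeneous"):
            raise ConfigError("compact_profile must be centralized|homogeneous")

    def axis(self) -> WavenumberAxis:
        return default_axis()

    def misalignment(self) -> AffineTransform2D:
        return AffineTransform2D.from_components(
            rotation_deg=self.ihc_rotation_deg,
            scale=1.0 / self.ihc_magnification,
            translation=self.ihc_translation,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SceneTruth:
    """Ground truth of a simulated scene."""

    density: np.ndarray
    fibril_fraction: np.ndarray
    ester_scale: np.ndarray
    plaque_masks: list[np.ndarray]
    core_masks: list[np.ndarray]
    labels: list[str]
    plaque_params: list[dict]
    affine: AffineTransform2D
    qc_valid: np.ndarray
    pixel_size_um: float


def _disk_profile(rows, cols, center, radius_px, edge_px):
    rr, cc = np.mgrid[0:rows, 0:cols]
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip((radius_px - d) / max(edge_px, 1e-9), 0.0, 1.0), d


def _draw_plaque_params(spec: PlaqueSpec, rho: float, rng) -> dict:
    """Per-plaque (density, fibril fraction) draw under the configured
    bivariate-Gaussian copula; values set explicitly on the PlaqueSpec win."""
    z1 = rng.standard_normal()
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
    amide2 = float(np.clip(1.0 + AMIDE2_ADMIX_SD * rng.standard_normal(), 0.3, 1.9))
    pr = TYPE_PRIORS[spec.type]
    d = spec.density_scale
    f = spec.fibril_fraction
    if d is None:
        mu, sd = pr["density"]
        d = max(0.05, mu + sd * z1)
    if f is None:
        mu, sd = pr["fibril"]
        f = float(np.clip(mu + sd * z2, 0.01, 0.99))
    out = {"density": float(d), "fibril": float(f), "amide2": amide2}
    if spec.type == "classic_cored":
        mu, sd = CORE_PRIORS["density"]
        out["core_density"] = max(0.5, mu + sd * z1)
        mu, sd = CORE_PRIORS["fibril"]
        out["core_fibril"] = float(np.clip(mu + sd * z2, 0.5, 0.99))
    return out


def simulate_scene(config: SceneConfig) -> tuple[HyperCube, SceneTruth]:
    """Generate a hyperspectral scene and its ground truth.

    Per-pixel spectrum = gray-matter base (ester band scaled per pixel)
    + density x [(1-f) oligomer + f fibril] + Mie baseline + noise.
    Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis()
    rows, cols = config.rows, config.cols
    px = config.pixel_size_um

    density = np.zeros((rows, cols))
    fibril = np.zeros((rows, cols))
    amide2_excess = np.zeros((rows, cols))  # density x (amide2 - 1)
    ester = np.ones((rows, cols))
    plaque_masks: list[np.ndarray] = []
    core_masks: list[np.ndarray] = []
    labels: list[str] = []
    params_list: list[dict] = []

    for spec in config.plaques:
        r_px = spec.radius_um / px
        r0, c0 = spec.center
        if not (0 <= r0 - r_px and r0 + r_px < rows and 0 <= c0 - r_px and c0 + r_px < cols):
            raise ConfigError(
                f"plaque at {spec.center} radius {spec.radius_um} um exceeds "
                f"cube bounds {rows}x{cols}"
            )
        params = _draw_plaque_params(spec, config.coupling_rho, rng)
        profile, dist = _disk_profile(rows, cols, spec.center, r_px, config.edge_px)
        if spec.type == "diffuse":
            # blob-like scatter: smooth random field modulating the disk
            blob = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 3.0)
            blob = (blob - blob.min()) / max(np.ptp(blob), 1e-12)
            dprof = profile * (0.35 + 0.65 * blob)
        elif spec.type == "compact" and config.compact_profile == "centralized":
            dprof = profile * (0.45 + 0.55 * np.exp(-(dist**2) / (2 * (0.55 * r_px) ** 2)))
        else:
            dprof = profile
        pmask = profile >= 0.5
        inside = dprof > 0
        density[inside] += params["density"] * dprof[inside]
        fibril[inside] = params["fibril"]
        amide2_excess[inside] += (
            (params["amide2"] - 1.0) * params["density"] * dprof[inside]
        )
        cmask = np.zeros((rows, cols), dtype=bool)
        if spec.type == "classic_cored":
            core_r = config.core_radius_frac * r_px
            cprof, _ = _disk_profile(rows, cols, spec.center, core_r, 1.0)
            cmask = cprof >= 0.5
            cin = cprof > 0
            amide2_excess[cin] = (1 - cprof[cin]) * amide2_excess[cin] + cprof[
                cin
            ] * (params["amide2"] - 1.0) * params["core_density"]
            density[cin] = (1 - cprof[cin]) * density[cin] + cprof[cin] * params["core_density"]
            fibril[cin] = (1 - cprof[cin]) * fibril[cin] + cprof[cin] * params["core_fibril"]
            ester[cin] = (1 - cprof[cin]) + cprof[cin] * CORE_ESTER_SCALE
        plaque_masks.append(pmask | cmask)
        core_masks.append(cmask)
        labels.append(spec.type)
        params_list.append(params)

    # smooth multiplicative gray-matter heterogeneity fields (mean 1)
    def _smooth_field(sd: float) -> np.ndarray:
        if sd <= 0:
            return np.ones((rows, cols))
        raw = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), config.heterogeneity_scale_px
        )
        raw = raw / max(raw.std(), 1e-12)
        return np.clip(1.0 + sd * raw, 0.2, None)

    protein_field = _smooth_field(config.protein_heterogeneity)
    lipid_field = _smooth_field(config.lipid_heterogeneity)

    # spectral assembly (float32 cube to bound memory)
    gray_protein = GRAY_PROTEIN_BANDS.evaluate(axis).astype(np.float32)
    gray_lipid = GRAY_LIPID_BANDS.evaluate(axis).astype(np.float32)
    gray_nh = GRAY_NH_BAND.evaluate(axis).astype(np.float32)
    ester_spec = ESTER_BAND.evaluate(axis).astype(np.float32)
    olig = OLIGOMER_BANDS.evaluate(axis).astype(np.float32)
    fib = FIBRIL_BANDS.evaluate(axis).astype(np.float32)

    n = axis.n_channels
    cube = np.empty((rows, cols, n), dtype=np.float32)
    cube[:] = gray_nh
    cube += protein_field.astype(np.float32)[:, :, None] * gray_protein
    cube += lipid_field.astype(np.float32)[:, :, None] * gray_lipid
    cube += (ester * lipid_field).astype(np.float32)[:, :, None] * ester_spec
    d_olig = (density * (1.0 - fibril)).astype(np.float32)
    d_fib = (density * fibril).astype(np.float32)
    cube += d_olig[:, :, None] * olig
    cube += d_fib[:, :, None] * fib
    amide2_spec = _AMIDE2_BAND.evaluate(axis).astype(np.float32)
    cube += amide2_excess.astype(np.float32)[:, :, None] * amide2_spec

    if config.mie_enabled:
        npix = rows * cols
        amp = rng.uniform(*config.mie_amplitude, size=npix).astype(np.float32)
        radius = rng.uniform(*config.mie_radius_um, size=npix)
        dn = rng.uniform(*config.mie_dn, size=npix)
        flat = cube.reshape(npix, n)
        chunk = 4096
        for i in range(0, npix, chunk):
            j = min(i + chunk, npix)
            x = (
                4.0 * np.pi * (radius[i:j, None] * 1e-4) * dn[i:j, None] * axis.values[None, :]
            )
            q = 2.0 - (4.0 / x) * np.sin(x) + (4.0 / x**2) * (1.0 - np.cos(x))
            q /= q.max(axis=1, keepdims=True)
            flat[i:j] += (amp[i:j, None] * q).astype(np.float32)

    qc_valid = np.ones((rows, cols), dtype=bool)
    if config.noise_sigma > 0 or config.low_snr_fraction > 0:
        sigma = np.full((rows, cols), config.noise_sigma, dtype=np.float32)
        if config.low_snr_fraction > 0:
            n_low = int(round(config.low_snr_fraction * rows * cols))
            idx = rng.choice(rows * cols, size=n_low, replace=False)
            sigma.ravel()[idx] = config.low_snr_sigma
            qc_valid.ravel()[idx] = False
        noise = rng.standard_normal((rows, cols, n)).astype(np.float32)
        cube += sigma[:, :, None] * noise

    truth = SceneTruth(
        density=density,
        fibril_fraction=fibril,
        ester_scale=ester,
        plaque_masks=plaque_masks,
        core_masks=core_masks,
        labels=labels,
        plaque_params=params_list,
        affine=config.misalignment(),
        qc_valid=qc_valid,
        pixel_size_um=px,
    )
    return HyperCube(cube, axis, px), truth


# ---------------------------------------------------------------------------
# pseudo-IHC rendering
# ---------------------------------------------------------------------------

def render_ihc(truth: SceneTruth, config: SceneConfig) -> np.ndarray:
    """Render the DAB-like grayscale immunostain image.

    Stain uptake saturates with amyloid density (Hill-type), intensity is
    monotonically decreasing in density (dark = amyloid-positive).  The
    image is produced in the misaligned IHC frame: pixel p of the output
    samples the cube-frame stain field at T(p), where T is the true
    IHC -> cube affine, at the configured magnification.
    """
    rng = np.random.default_rng(config.seed + 104729)  # decoupled sub-stream
    d = truth.density
    stain = d / (d + config.ihc_saturation)
    if config.ihc_glial_gaps > 0:
        rows, cols = d.shape
        candidates = np.argwhere(d > 0.05)
        if len(candidates):
            for _ in range(config.ihc_glial_gaps):
                r0, c0 = candidates[rng.integers(len(candidates))]
                gap, _ = _disk_profile(rows, cols, (r0, c0), 2.5, 1.0)
                stain = stain * (1.0 - 0.8 * gap)
    if config.ihc_hollow_cores:
        for cmask in truth.core_masks:
            if not cmask.any():
                continue
            rr, cc = np.nonzero(cmask)
            centroid = (rr.mean(), cc.mean())
            radius = max(1.0, np.sqrt(cmask.sum() / np.pi))
            hollow, _ = _disk_profile(*d.shape, centroid, 0.6 * radius, 1.0)
            stain = stain * (1.0 - 0.7 * hollow)
    intensity = config.ihc_background - config.ihc_contrast * stain

    t = truth.affine
    # output frame large enough to cover the cube footprint under T^-1
    corners = np.array(
        [[0, 0], [0, d.shape[1]], [d.shape[0], 0], [d.shape[0], d.shape[1]]], float
    )
    src = t.inverse().apply(corners)
    out_shape = (
        int(np.ceil(src[:, 0].max())) + 4,
        int(np.ceil(src[:, 1].max())) + 4,
    )
    return ndimage.affine_transform(
        intensity,
        t.linear,
        offset=t.translation,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=config.ihc_background,
    )


def true_landmarks(
    truth: SceneTruth, n_per_side: int = 3, margin: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact landmark pairs derived from the true misalignment affine:
    a grid of cube-frame points and their IHC-frame preimages."""
    rows, cols = truth.density.shape
    rs = np.linspace(margin, rows - 1 - margin, n_per_side)
    cs = np.linspace(margin, cols - 1 - margin, n_per_side)
    dst = np.array([(r, c) for r in rs for c in cs])
    src = truth.affine.inverse().apply(dst)
    return src, dst


def sample_control_patches(
    truth: SceneTruth,
    n: int,
    patch_um: float = 100.0,
    seed: int = 0,
    max_tries_per_patch: int = 500,
) -> list[PixelMask]:
    """Randomly place ``n`` non-overlapping square patches of side
    ``patch_um`` whose pixels are all amyloid-negative in the truth."""
    rng = np.random.default_rng(seed)
    rows, cols = truth.density.shape
    side = int(round(patch_um / truth.pixel_size_um))
    if side < 1 or side > min(rows, cols):
        raise SamplingError(f"patch side {side} px does not fit the scene")
    negative = truth.density <= 0.0
    occupied = np.zeros((rows, cols), dtype=bool)
    patches: list[PixelMask] = []
    for _ in range(n):
        for _try in range(max_tries_per_patch):
            r0 = int(rng.integers(0, rows - side + 1))
            c0 = int(rng.integers(0, cols - side + 1))
            window = np.s_[r0 : r0 + side, c0 : c0 + side]
            if negative[window].all() and not occupied[window].any():
                m = np.zeros((rows, cols), dtype=bool)
                m[window] = True
                occupied[window] = True
                patches.append(PixelMask(m))
                break
        else:
            raise SamplingError(
                f"could not place patch {len(patches) + 1} of {n} after "
                f"{max_tries_per_patch} tries"
            )
    return patches


# ---------------------------------------------------------------------------
# convenience scene builders
# ---------------------------------------------------------------------------

def single_plaque_config(
    plaque_type: str,
    rows: int = 64,
    cols: int = 64,
    radius_um: float = 18.0,
    seed: int = 0,
    **overrides,
) -> SceneConfig:
    """A scene holding one centered plaque of the requested type."""
    spec = PlaqueSpec(plaque_type, (rows / 2.0, cols / 2.0), radius_um)
    return SceneConfig(rows=rows, cols=cols, plaques=[spec], seed=seed, **overrides)


def cohort_scene_config(
    n_diffuse: int = 3,
    n_compact: int = 3,
    n_cored: int = 3,
    rows: int = 150,
    cols: int = 150,
    seed: int = 0,
    **overrides,
) -> SceneConfig:
    """Several plaques of mixed types on a jittered grid."""
    rng = np.random.default_rng(seed)
    types = (
        ["diffuse"] * n_diffuse + ["compact"] * n_compact + ["classic_cored"] * n_cored
    )
    rng.shuffle(types)
    n = len(types)
    grid = int(np.ceil(np.sqrt(n)))
    cell_r, cell_c = rows / grid, cols / grid
    plaques = []
    for i, t in enumerate(types):
        gr, gc = divmod(i, grid)
        radius_um = float(rng.uniform(10.0, 15.0))
        margin = radius_um / 1.1 + 3.0
        r0 = np.clip(
            (gr + 0.5) * cell_r + rng.uniform(-4, 4), margin, rows - 1 - margin
        )
        c0 = np.clip(
            (gc + 0.5) * cell_c + rng.uniform(-4, 4), margin, cols - 1 - margin
        )
        plaques.append(PlaqueSpec(t, (float(r0), float(c0)), radius_um))
    return SceneConfig(rows=rows, cols=cols, plaques=plaques, seed=seed, **overrides)


def write_scene(cube: HyperCube, truth: SceneTruth, path: str) -> None:
    """Scene container: the HDF5 cube plus a /truth group."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=cube.data.astype(np.float32))
        f.create_dataset("wavenumbers", data=cube.axis.values)
        f.attrs["pixel_size_um"] = cube.pixel_size_um
        g = f.create_group("truth")
        g.create_dataset("density", data=truth.density)
        g.create_dataset("fibril_fraction", data=truth.fibril_fraction)
        g.create_dataset("ester_scale", data=truth.ester_scale)
        g.create_dataset("qc_valid", data=truth.qc_valid)
        g.create_dataset("affine", data=truth.affine.matrix)
        if truth.plaque_masks:
            g.create_dataset("plaque_masks", data=np.array(truth.plaque_masks))
            g.create_dataset("core_masks", data=np.array(truth.core_masks))
            g.create_dataset(
                "labels", data=np.array(truth.labels, dtype=h5py.string_dtype())
            )
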