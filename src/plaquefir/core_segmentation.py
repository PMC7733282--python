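"""Hierarchical-clustering segmentation of classic cored plaque cutouts.

QC-valid pixel spectra of a plaque cutout, restricted to the
fingerprint region (1800-1000 cm^-1) and vector-normalized, are grouped
by agglomerative hierarchical cluster analysis (Ward linkage, Euclidean
metric) into k = 10 subgroups.  Core selection is an automated stand-in
for expert visual merging: clusters are ranked by the beta-sheet ratio
of their mean spectrum, and those exceeding the surrounding-tissue
cluster's ratio by a margin — and spatially overlapping the plaque
mask — are merged into the core.  An empty core is a legal outcome
(small or poorly resolved cores are discarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

from .amide_analysis import BandTable, compute_ratios
from .qc_correction import QCResult
from .spectra_core import HyperCube, PipelineError, PixelMask, Spectrum, channel_slice

__all__ = ["SegmentationError", "SegmentationResult", "hca_segment", "select_core"]

FINGERPRINT_REGION = (1000.0, 1800.0)
HCA_K_DEFAULT = 10
SUBSAMPLE_LIMIT_DEFAULT = 20000
CORE_MARGIN_DEFAULT = 1.0
MIN_CORE_PIXELS_DEFAULT = 5
_TIE_TOL = 1e-9


class SegmentationError(PipelineError):
    """Segmentation preconditions violated."""


@dataclass
class SegmentationResult:
    """HCA labels (1..k on QC-valid pixels, 0 elsewhere) and, after
    :func:`select_core`, the merged core/corona cluster sets."""

    labels: np.ndarray
    cluster_means: dict[int, Spectrum]
    cluster_sizes: dict[int, int]
    core_clusters: frozenset[int] = frozenset()
    corona_clusters: frozenset[int] = frozenset()
    core_mask: np.ndarray | None = None
    core_spectrum: Spectrum | None = None
    ranking: list[dict] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.cluster_means)


def hca_segment(
    roi_cube: HyperCube,
    qc: QCResult | np.ndarray | None = None,
    k: int = HCA_K_DEFAULT,
    subsample_limit: int = SUBSAMPLE_LIMIT_DEFAULT,
) -> SegmentationResult:
    """Ward/Euclidean agglomerative clustering of the cutout's QC-valid
    spectra into ``k`` subgroups.

    Spectra are restricted to 1800-1000 cm^-1 and L2 vector-normalized
    before clustering.  Above ``subsample_limit`` pixels a deterministic
    subsample is clustered and the remaining pixels take the label of
    the nearest cluster centroid.  Deterministic given the input.
    """
    if qc is None:
        valid = np.ones((roi_cube.rows, roi_cube.cols), dtype=bool)
    else:
        valid = qc.valid if isinstance(qc, QCResult) else np.asarray(qc, bool)
    idx = np.flatnonzero(valid.ravel())
    if idx.size < k:
        raise SegmentationError(f"{idx.size} valid pixels < k = {k}")

    sl = channel_slice(roi_cube.axis, *FINGERPRINT_REGION)
    x = roi_cube.flat()[idx][:, sl].astype(np.float64)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    x = x / np.maximum(norms, 1e-300)

    if idx.size > subsample_limit:
        # deterministic subsample; labels propagate by nearest centroid
        sub = np.random.default_rng(0).choice(idx.size, subsample_limit, replace=False)
        sub.sort()
        z = linkage(x[sub], method="ward", metric="euclidean")
        sub_labels = fcluster(z, t=k, criterion="maxclust")
        centroids = np.array([x[sub][sub_labels == c].mean(axis=0) for c in range(1, k + 1)])
        d = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        flat_labels = d.argmin(axis=1) + 1
    else:
        z = linkage(x, method="ward", metric="euclidean")
        flat_labels = fcluster(z, t=k, criterion="maxclust")

    labels = np.zeros(roi_cube.rows * roi_cube.cols, dtype=np.int32)
    labels[idx] = flat_labels
    labels = labels.reshape(roi_cube.rows, roi_cube.cols)

    means: dict[int, Spectrum] = {}
    sizes: dict[int, int] = {}
    full = roi_cube.flat().astype(np.float64)
    for c in range(1, k + 1):
        sel = idx[flat_labels == c]
        sizes[c] = int(sel.size)
        means[c] = Spectrum(roi_cube.axis, full[sel].mean(axis=0))
    return SegmentationResult(labels=labels, cluster_means=means, cluster_sizes=sizes)


def select_core(
    seg: SegmentationResult,
    roi_cube: HyperCube,
    plaque_mask: PixelMask | np.ndarray,
    margin: float = CORE_MARGIN_DEFAULT,
    min_core_pixels: int = MIN_CORE_PIXELS_DEFAULT,
    manual_core_clusters: list[int] | None = None,
    table: BandTable = BandTable(),
) -> SegmentationResult:
    """Complete a segmentation by merging core clusters.

    Clusters are ranked by the beta-sheet ratio of their mean spectrum.
    The reference is the surrounding-tissue cluster (the one with the
    most pixels outside the plaque mask); core clusters must exceed its
    ratio by ``margin`` (ties within numerical tolerance are merged
    inclusively) and overlap the plaque mask.  The merged core keeps
    only connected components of at least ``min_core_pixels``; the
    remaining plaque-overlapping clusters form the corona.  Passing
    ``manual_core_clusters`` reproduces expert manual selection.
    """
    pm = plaque_mask.mask if isinstance(plaque_mask, PixelMask) else np.asarray(
        plaque_mask, bool
    )
    if pm.shape != seg.labels.shape:
        raise SegmentationError("plaque mask shape does not match the labels")

    ratios = {c: compute_ratios(m, table).beta_ratio for c, m in seg.cluster_means.items()}
    outside_counts = {
        c: int(((seg.labels == c) & ~pm).sum()) for c in seg.cluster_means
    }
    ref_cluster = max(outside_counts, key=lambda c: (outside_counts[c], -c))
    ref_ratio = ratios[ref_cluster]

    if manual_core_clusters is not None:
        core_set = frozenset(manual_core_clusters)
    else:
        core_set = frozenset(
            c
            for c in seg.cluster_means
            if c != ref_cluster
            and ratios[c] >= ref_ratio + margin - _TIE_TOL
            and bool(((seg.labels == c) & pm).any())
        )

    core_mask = np.isin(seg.labels, list(core_set)) & pm
    if core_mask.any():
        comp_labels, n_comp = ndimage.label(core_mask)
        keep = np.zeros_like(core_mask)
        for comp in range(1, n_comp + 1):
            comp_mask = comp_labels == comp
            if comp_mask.sum() >= min_core_pixels:
                keep |= comp_mask
        core_mask = keep
    if not core_mask.any():
        core_set = frozenset()
        core_mask = np.zeros_like(pm)

    corona_set = frozenset(
        c
        for c in seg.cluster_means
        if c not in core_set and bool(((seg.labels == c) & pm).any())
    )
    core_spectrum = None
    if core_mask.any():
        sel = core_mask.ravel()
        core_spectrum = Spectrum(
            roi_cube.axis, roi_cube.flat()[sel].astype(np.float64).mean(axis=0)
        )
    ranking = [
        {
            "cluster": c,
            "beta_ratio": ratios[c],
            "size": seg.cluster_sizes[c],
            "outside_pixels": outside_counts[c],
            "is_reference": c == ref_cluster,
            "in_core": c in core_set,
        }
        for c in sorted(ratios, key=ratios.get, reverse=True)
    ]
    return SegmentationResult(
        labels=seg.labels,
        cluster_means=seg.cluster_means,
        cluster_sizes=seg.cluster_sizes,
        core_clusters=core_set,
        corona_clusters=corona_set,
        core_mask=core_mask,
        core_spectrum=core_spectrum,
        ranking=ranking,
    )
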