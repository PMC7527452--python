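"""Anisotropy-aware multi-scale Laplacian-of-Gaussian blob detection.

Scales are expressed as an *isotropic physical* sigma (um); each filter pass
divides by the per-axis voxel size so the operator is the physical-space
scale-normalized LoG, which is what anisotropic confocal voxels
(e.g. 0.3 um z-steps over 0.13 um pixels) require.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: diameter = 2 * sqrt(3) * sigma for a solid sphere's optimal LoG scale
DIAMETER_PER_SIGMA = 2.0 * np.sqrt(3.0)


def log_scales(min_diameter: float, max_diameter: float, n_scales: int = 5) -> np.ndarray:
    """Log-spaced physical sigmas covering [min_diameter, max_diameter]."""
    return np.geomspace(
        min_diameter / DIAMETER_PER_SIGMA, max_diameter / DIAMETER_PER_SIGMA, n_scales
    )


def scale_normalized_log(
    image: np.ndarray, sigma_um: float, voxel_size: np.ndarray
) -> np.ndarray:
    """-sigma^2 * Laplacian(G_sigma * I) evaluated in physical coordinates."""
    voxel_size = np.asarray(voxel_size, float)
    sigma_vox = sigma_um / voxel_size
    out = np.zeros_like(image, dtype=np.float32)
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 2
        out -= (
            ndimage.gaussian_filter(image, sigma=sigma_vox, order=tuple(order))
            / voxel_size[axis] ** 2
        ).astype(np.float32)
    return sigma_um**2 * out


def robust_zscore(image: np.ndarray) -> np.ndarray:
    """(I - median) / (1.4826 * MAD): intensities in background-noise units."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    sd = 1.4826 * mad
    if sd <= 0:
        sd = float(image.std()) or 1.0
    return (image - med) / sd


def detect_blobs(
    image: np.ndarray,
    voxel_size,
    min_diameter: float,
    max_diameter: float,
    threshold: float,
    n_scales: int = 5,
    merge_distance: float | None = None,
    mask: np.ndarray | None = None,
) -> list[dict]:
    """Multi-scale LoG maxima of a (z, y, x) volume.

    Parameters
    ----------
    image
        Intensity volume, already normalized to whatever units ``threshold``
        is expressed in (typically background-noise units).
    threshold
        Minimum scale-normalized LoG response for a detection.
    merge_distance
        Physical distance (um) under which the weaker of two detections is
        dropped; defaults to ``min_diameter / 2``.
    mask
        Optional boolean volume; peaks outside it are discarded.

    Returns
    -------
    list of dict with keys ``center`` ((z, y, x) um, voxel-center convention),
    ``sigma`` (physical um), ``diameter`` (um), ``response``.
    """
    voxel_size = np.asarray(voxel_size, float)
    sigmas = log_scales(min_diameter, max_diameter, n_scales)
    responses = np.stack(
        [scale_normalized_log(image, s, voxel_size) for s in sigmas]
    )  # (s, z, y, x)
    best = responses.max(axis=0)
    best_idx = responses.argmax(axis=0)

    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = (best == ndimage.maximum_filter(best, footprint=footprint)) & (
        best >= threshold
    )
    if mask is not None:
        local_max &= mask
    coords = np.argwhere(local_max)
    if len(coords) == 0:
        return []
    resp = best[tuple(coords.T)]
    sig = sigmas[best_idx[tuple(coords.T)]]
    centers = (coords + 0.5) * voxel_size

    # greedy non-maximum suppression by physical distance, strongest first
    if merge_distance is None:
        merge_distance = min_diameter / 2.0
    order = np.argsort(-resp)
    centers, resp, sig = centers[order], resp[order], sig[order]
    tree = cKDTree(centers)
    keep = np.ones(len(centers), dtype=bool)
    for i in range(len(centers)):
        if not keep[i]:
            continue
        for j in tree.query_ball_point(centers[i], merge_distance):
            if j > i:
                keep[j] = False
    return [
        dict(
            center=tuple(c),
            sigma=float(s),
            diameter=float(DIAMETER_PER_SIGMA * s),
            response=float(r),
        )
        for c, r, s in zip(centers[keep], resp[keep], sig[keep])
    ]


def refine_center(
    image: np.ndarray,
    voxel_size,
    center_um,
    radius_um: float,
) -> tuple[float, float, float]:
    """Sub-voxel center: intensity-weighted centroid in an ellipsoid window.

    Weights are the image values minus the window minimum, so a constant
    offset does not bias the centroid.
    """
    voxel_size = np.asarray(voxel_size, float)
    center_um = np.asarray(center_um, float)
    shape = np.asarray(image.shape)
    lo = np.maximum(np.floor((center_um - radius_um) / voxel_size - 0.5).astype(int), 0)
    hi = np.minimum(np.ceil((center_um + radius_um) / voxel_size - 0.5).astype(int) + 1, shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    window = image[sl].astype(float)
    axes = [
        (np.arange(s.start, s.stop) + 0.5) * v for s, v in zip(sl, voxel_size)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    inside = (
        ((zz - center_um[0]) ** 2 + (yy - center_um[1]) ** 2 + (xx - center_um[2]) ** 2)
        <= radius_um**2
    )
    w = np.where(inside, window - window[inside].min(), 0.0)
    total = w.sum()
    if total <= 0:
        return tuple(center_um)
    return (
        float((w * zz).sum() / total),
        float((w * yy).sum() / total),
        float((w * xx).sum() / total),
    )
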