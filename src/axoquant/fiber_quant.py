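"""Axon segmentation, volume density, filament skeletons, varicosity detection.

The transporter channel (SERT/NET, or YFP in reporter animals) labels
unmyelinated monoaminergic fibers ~0.5-0.6 um across. The segmentation is a
standard open pipeline — background subtraction, Gaussian smoothing, global
threshold, small-object removal — whose accuracy is judged by recovery of
simulated ground truth, not by matching any particular commercial renderer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from ._blobs import detect_blobs, refine_center, robust_zscore
from .image_io import ImageStack

__all__ = [
    "SegmentationParams",
    "Branch",
    "FiberModel",
    "VaricosityList",
    "segment_fibers",
    "fiber_volume_density",
    "skeletonize_fibers",
    "detect_varicosities",
]

#: Filament diameter range (um) of the thin monoaminergic fibers this
#: pipeline targets; also the floor for keeping isolated skeleton fragments.
FILAMENT_DIAMETER_RANGE = (0.5, 0.6)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the fiber segmentation pipeline (all lengths in um)."""

    background_radius: float = 2.0  # top-hat structuring size
    smooth_sigma: float = 0.1  # Gaussian smoothing, matched to the lateral PSF width
    threshold: str | float = "halfmax"  # "halfmax", "otsu", absolute, or "qXX" quantile
    min_object_volume: float = 0.05  # um^3; connected components below are dropped


@dataclass
class Branch:
    """One skeleton branch: an ordered polyline of physical points."""

    points: np.ndarray  # (N, 3) zyx um
    length: float  # um
    trunk_radius: float  # um
    is_leaf: bool = False


@dataclass
class FiberModel:
    """Binary fiber mask plus volumes and (optionally) a branch skeleton."""

    mask: np.ndarray  # (z, y, x) bool
    voxel_size: tuple[float, float, float]
    tissue_volume: float  # um^3 (ROI volume)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    skeleton: list[Branch] = field(default_factory=list)
    filament_diameter_range: tuple[float, float] = FILAMENT_DIAMETER_RANGE

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def fiber_volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume


def _resolve_threshold(image: np.ndarray, spec: str | float) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if spec == "halfmax":
        # half of the robust signal plateau: the mean of the brightest 0.02 %
        # of voxels (at least 100). Under a symmetric PSF the half-maximum
        # surface tracks the true object boundary, so the measured fiber
        # volume scales linearly with the true volume without an additive
        # noise-floor offset.
        k = max(20, int(2e-4 * image.size))
        top = np.partition(image.ravel(), image.size - k)[-k:]
        return 0.5 * float(top.mean())
    if spec == "otsu":
        return float(threshold_otsu(image))
    if isinstance(spec, str) and spec.startswith("q"):
        return float(np.quantile(image, float(spec[1:]) / 100.0))
    raise ValueError(
        f"unknown threshold spec {spec!r}; use 'halfmax', 'otsu', a number, or 'q<percent>'"
    )


def segment_fibers(
    stack: ImageStack,
    channel: str,
    params: SegmentationParams | None = None,
) -> FiberModel:
    """Segment the fiber channel into a binary mask.

    Pipeline: rectangular top-hat background subtraction (physical radius
    ``background_radius``) -> Gaussian smoothing (``smooth_sigma``) -> global
    threshold (Otsu by default) -> removal of connected components below
    ``min_object_volume``.
    """
    params = params or SegmentationParams()
    image = stack.channel(channel).astype(np.float32)
    voxel = np.asarray(stack.voxel_size, float)

    if image.max() == image.min():
        # a constant channel carries no structure; an absolute threshold still
        # applies (e.g. already-binary masks), otherwise warn and return empty
        if isinstance(params.threshold, (int, float)):
            mask = image > params.threshold
        else:
            warnings.warn(
                f"channel {channel!r} is constant (all background); returning empty mask",
                stacklevel=2,
            )
            mask = np.zeros(image.shape, dtype=bool)
        return FiberModel(
            mask=mask,
            voxel_size=stack.voxel_size,
            tissue_volume=stack.tissue_volume,
            origin=stack.origin,
        )

    size = tuple(int(2 * round(params.background_radius / v) + 1) for v in voxel)
    image = ndimage.white_tophat(image, size=size)
    if params.smooth_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=params.smooth_sigma / voxel)
    thr = _resolve_threshold(image, params.threshold)
    mask = image > thr

    min_voxels = int(np.ceil(params.min_object_volume / np.prod(voxel)))
    if min_voxels > 1 and mask.any():
        labels, n = ndimage.label(mask)
        if n:
            counts = np.bincount(labels.ravel())
            small = np.flatnonzero(counts < min_voxels)
            mask &= ~np.isin(labels, small[small > 0])

    if not mask.any():
        warnings.warn(f"channel {channel!r}: segmentation found no fibers", stacklevel=2)
    return FiberModel(
        mask=mask,
        voxel_size=stack.voxel_size,
        tissue_volume=stack.tissue_volume,
        origin=stack.origin,
    )


def fiber_volume_density(model: FiberModel) -> float:
    """Segmented fiber volume normalized to tissue (ROI) volume."""
    if model.tissue_volume <= 0:
        raise ValueError("tissue_volume must be positive")
    return model.fiber_volume / model.tissue_volume


# ---------------------------------------------------------------------------
# Skeletonization
# ---------------------------------------------------------------------------

def _skeleton_branches(skel: np.ndarray, voxel: np.ndarray) -> list[list[tuple]]:
    """Split a skeleton voxel set into branches between junctions/endpoints."""
    coords = [tuple(c) for c in np.argwhere(skel)]
    if not coords:
        return []
    coord_set = set(coords)
    g = nx.Graph()
    g.add_nodes_from(coords)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for c in coords:
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            if nb in coord_set:
                g.add_edge(c, nb)

    branches: list[list[tuple]] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = [n for n in sub if sub.degree(n) != 2]
        if not nodes:  # pure cycle or isolated voxel
            cycle = list(comp)
            if len(cycle) > 1:
                branches.append(cycle)
            continue
        visited_edges: set[frozenset] = set()
        for start in nodes:
            for nb in sub.neighbors(start):
                e = frozenset((start, nb))
                if e in visited_edges:
                    continue
                path = [start, nb]
                visited_edges.add(e)
                prev, cur = start, nb
                while sub.degree(cur) == 2:
                    nxt = next(n for n in sub.neighbors(cur) if n != prev)
                    visited_edges.add(frozenset((cur, nxt)))
                    path.append(nxt)
                    prev, cur = cur, nxt
                branches.append(path)
    return branches


def _smooth_polyline(pts: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing (endpoints fixed): discrete voxel paths zigzag
    on anisotropic grids, which inflates arc length."""
    if len(pts) <= 2 or window < 3:
        return pts
    out = pts.astype(float).copy()
    half = window // 2
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _branch_length(path_vox: np.ndarray, voxel: np.ndarray) -> float:
    pts = _smooth_polyline((path_vox + 0.5) * voxel)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def skeletonize_fibers(model: FiberModel, min_ratio: float = 2.0) -> FiberModel:
    """Medial-axis skeleton with branch filtering; populates ``model.skeleton``.

    Branches are polylines between junctions and endpoints. The trunk radius
    of a leaf branch is the median Euclidean-distance-transform value along
    the longest other branch at its junction (the parent trunk); leaf branches
    with length / trunk-radius below ``min_ratio`` are removed as background
    spurs, and isolated fragments shorter than the filament diameter are
    dropped. ``min_ratio`` is meaningful in [1.5, 2.5]; values outside only
    warn.
    """
    if not 1.5 <= min_ratio <= 2.5:
        warnings.warn(
            f"min_ratio {min_ratio} is outside the usual [1.5, 2.5] branch-length/"
            "trunk-radius range",
            stacklevel=2,
        )
    voxel = np.asarray(model.voxel_size, float)
    if not model.mask.any():
        model.skeleton = []
        return model

    skel = skeletonize(model.mask)
    edt = ndimage.distance_transform_edt(model.mask, sampling=voxel)
    raw = _skeleton_branches(skel, voxel)

    # index branches by their endpoint voxels to find junction partners
    lengths = [ _branch_length(np.asarray(b), voxel) for b in raw ]
    by_endpoint: dict[tuple, list[int]] = {}
    for i, b in enumerate(raw):
        for end in (b[0], b[-1]):
            by_endpoint.setdefault(end, []).append(i)

    def median_radius(idx: int) -> float:
        path = np.asarray(raw[idx])
        return float(np.median(edt[tuple(path.T)]))

    branches: list[Branch] = []
    for i, b in enumerate(raw):
        path = np.asarray(b)
        n_junctions = sum(len(by_endpoint[end]) > 1 for end in (b[0], b[-1]))
        is_leaf = n_junctions <= 1
        # parent trunk: longest *other* branch sharing a junction; fall back to self
        parent = None
        for end in (b[0], b[-1]):
            for j in by_endpoint[end]:
                if j != i and (parent is None or lengths[j] > lengths[parent]):
                    parent = j
        trunk_r = median_radius(parent if parent is not None else i)
        branch = Branch(
            points=(path + 0.5) * voxel,
            length=lengths[i],
            trunk_radius=max(trunk_r, 1e-6),
            is_leaf=is_leaf,
        )
        if branch.is_leaf and branch.length / branch.trunk_radius < min_ratio:
            continue  # spur
        branches.append(branch)

    # drop isolated fragments shorter than the filament diameter
    min_frag = model.filament_diameter_range[1]
    kept: list[Branch] = []
    for br in branches:
        attached = any(
            other is not br
            and (
                np.min(np.linalg.norm(other.points - br.points[0], axis=1)) < 1e-6
                or np.min(np.linalg.norm(other.points - br.points[-1], axis=1)) < 1e-6
            )
            for other in branches
        )
        if not attached and br.length < min_frag:
            continue
        kept.append(br)
    model.skeleton = kept
    return model


# ---------------------------------------------------------------------------
# Varicosities
# ---------------------------------------------------------------------------

@dataclass
class VaricosityList:
    """Detected varicosities and their density per tissue volume."""

    points: list[dict]  # center (zyx um), diameter um, intensity
    tissue_volume: float

    @property
    def density(self) -> float:
        return len(self.points) / self.tissue_volume

    def coordinates(self) -> np.ndarray:
        if not self.points:
            return np.empty((0, 3))
        return np.array([p["center"] for p in self.points])


def detect_varicosities(
    stack: ImageStack,
    model: FiberModel,
    channel: str,
    min_diameter: float = 0.6,
    max_diameter_factor: float = 3.0,
    threshold: float = 6.0,
    tube_suppress_factor: float = 1.5,
) -> VaricosityList:
    """Detect varicosities as bright swellings of the fiber channel.

    The fiber channel is normalized to background-noise units, the thin tube
    signal is suppressed with a grey-scale ellipsoid opening (ball diameter
    ``tube_suppress_factor`` x the filament diameter: structures thinner than
    a varicosity cannot contain the ball and erode away), and anisotropy-aware
    multi-scale LoG detection runs on the result, restricted to the fiber mask
    dilated by one voxel. Per-blob diameter is ``2 * sigma * sqrt(3)`` at the
    best scale. ``threshold`` is the minimum scale-normalized LoG response in
    background-noise units; the default separates sphere-like swellings from
    residual tube ridge responses at detection signal-to-noise >= 5.
    """
    z_step = stack.voxel_size[0]
    if min_diameter < z_step:
        warnings.warn(
            f"min_diameter {min_diameter} um is below the z-step {z_step} um: such "
            "spots may appear in fewer than two optical slices",
            stacklevel=2,
        )
    voxel = np.asarray(stack.voxel_size, float)
    z = robust_zscore(stack.channel(channel).astype(np.float32))

    # ellipsoid opening: removes structures that cannot contain the ball.
    # Semi-axes round *down* in voxels so anisotropic (coarse-z) grids never
    # inflate the ball beyond the varicosity scale.
    ball_r = tube_suppress_factor * model.filament_diameter_range[1] / 2.0
    semi = np.maximum(np.floor(ball_r / voxel).astype(int), 1)
    grids = np.meshgrid(*[np.arange(-s, s + 1) / max(s, 1) for s in semi], indexing="ij")
    footprint = sum(g**2 for g in grids) <= 1.0001
    opened = ndimage.grey_opening(z, footprint=footprint)

    dilated = ndimage.binary_dilation(model.mask, iterations=1)
    blobs = detect_blobs(
        opened,
        voxel,
        min_diameter=min_diameter,
        max_diameter=max_diameter_factor * min_diameter,
        threshold=threshold,
        mask=dilated,
    )
    points = []
    for b in blobs:
        center = refine_center(z, voxel, b["center"], b["diameter"] / 2.0)
        idx = tuple(
            np.clip((np.asarray(center) / voxel).astype(int), 0, np.asarray(z.shape) - 1)
        )
        if not dilated[idx]:
            continue
        points.append(
            dict(center=center, diameter=b["diameter"], intensity=float(z[idx]))
        )
    return VaricosityList(points=points, tissue_volume=stack.tissue_volume)
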