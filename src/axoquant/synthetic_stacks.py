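"""Synthetic multi-channel confocal stacks with known ground truth.

The simulator emulates the imaging study this package quantifies: thin
unmyelinated monoaminergic axons (persistence random walks, drawn as tubes),
varicosities (spherical swellings along the axons), synaptophysin puncta
split into in-fiber boutons and outside-fiber puncta, postsynaptic scaffold
puncta (gephyrin or PSD95), constructed synapse pairs and triads at the
0.6 um pairing distance, and a confocal forward model (anisotropic Gaussian
PSF, Poisson shot noise, Gaussian read noise). Every emitted object is
recorded in a :class:`GroundTruth` so downstream detection and statistics
can be validated by recovery rather than by eye.

Coordinates are (z, y, x) micrometers; the voxel grid follows
:mod:`axoquant.image_io` conventions (voxel centers at
``(index + 0.5) * voxel_size``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .image_io import ImageStack

__all__ = [
    "PAIRING_DISTANCE_UM",
    "SimulationConfig",
    "GroundTruth",
    "simulate_axons",
    "place_puncta",
    "render_stack",
    "simulate_stack",
    "generate_cohort",
]

#: Pairing distance (um) shared by the simulator's constructed arrangements and
#: the analysis threshold: two puncta centers within this distance form a pair.
PAIRING_DISTANCE_UM = 0.6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic stack.

    Defaults describe a scaled-down field of view (256 x 256 x 30 voxels at
    0.13 / 0.13 / 0.3 um) with innervation dense enough that per-stack synapse
    counts are in the hundreds, comparable to confocal ROIs in monoaminergic
    innervation studies.
    """

    box_size: tuple[float, float, float] = (9.0, 33.28, 33.28)  # um (z, y, x)
    voxel_size: tuple[float, float, float] = (0.3, 0.13, 0.13)  # um (z, y, x)
    n_axons: int = 40
    axon_radius: float = 0.3  # um
    axon_length: float = 50.0  # um of path per axon
    step_length: float = 1.0  # um per random-walk step
    persistence: float = 0.9  # direction correlation in [0, 1]
    varicosity_rate: float = 0.1  # varicosities per um of axon (~one per 10 um)
    varicosity_radius_factor: float = 2.0  # varicosity radius / axon radius
    bouton_fraction: float = 0.7  # varicosities carrying a synaptophysin punctum
    outside_syn_density: float = 0.25  # synaptophysin puncta per um^3 outside fibers
    postsyn_density: float = 0.3  # gephyrin/PSD95 puncta per um^3
    paired_fraction: float = 0.3  # outside-syn puncta constructed next to a postsyn punctum
    sero_paired_fraction: float = 0.4  # boutons with a postsyn punctum apposed
    triad_fraction: float = 0.2  # boutons with a constructed nearby pair
    pairing_distance: float = PAIRING_DISTANCE_UM
    punctum_radius: float = 0.3  # rendered radius of syn/postsyn puncta (0.6 um spots)
    post_channel: str = "gephyrin"  # or "psd95"
    fiber_marker: str = "SERT"  # or "NET" / "YFP"
    psf_sigma: tuple[float, float, float] = (0.2, 0.1, 0.1)  # um (z, y, x)
    photon_scale: float = 50.0  # expected photons at full intensity
    background: float = 5.0  # photons
    read_noise_sd: float = 1.0  # photons
    yfp_omit_fraction: float | None = None  # add a YFP channel missing this axon fraction
    seed: int = 0

    def __post_init__(self) -> None:
        box = np.asarray(self.box_size, float)
        voxel = np.asarray(self.voxel_size, float)
        if np.any(voxel <= 0):
            raise ValueError(f"voxel_size must be strictly positive; got {self.voxel_size}")
        if np.any(box <= 0):
            raise ValueError(f"box_size must be strictly positive; got {self.box_size}")
        ratio = box / voxel
        if np.any(np.abs(ratio - np.round(ratio)) > 1e-6):
            raise ValueError(
                f"box_size {self.box_size} must be an integer multiple of voxel_size "
                f"{self.voxel_size} per axis"
            )
        for name in ("varicosity_rate", "outside_syn_density", "postsyn_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bouton_fraction", "paired_fraction", "sero_paired_fraction",
                     "triad_fraction", "persistence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.yfp_omit_fraction is not None and not 0.0 <= self.yfp_omit_fraction <= 1.0:
            raise ValueError("yfp_omit_fraction must lie in [0, 1]")
        if self.n_axons < 0:
            raise ValueError("n_axons must be >= 0")
        if self.varicosity_radius_factor < 1.0:
            raise ValueError("varicosity_radius_factor must be >= 1")
        if self.axon_radius <= 0 or self.step_length <= 0 or self.axon_length <= 0:
            raise ValueError("axon_radius, step_length and axon_length must be positive")
        if self.pairing_distance <= 0:
            raise ValueError("pairing_distance must be positive")
        if self.post_channel not in ("gephyrin", "psd95"):
            raise ValueError(f"post_channel must be 'gephyrin' or 'psd95'; got {self.post_channel!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        box = np.asarray(self.box_size, float)
        voxel = np.asarray(self.voxel_size, float)
        return tuple(int(round(v)) for v in box / voxel)

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_size))

    @property
    def post_kind(self) -> str:
        """Synapse polarity class of the postsynaptic channel."""
        return "inhibitory" if self.post_channel == "gephyrin" else "excitatory"


@dataclass
class GroundTruth:
    """Everything the simulator knows about one stack."""

    config: SimulationConfig
    axon_centerlines: list[np.ndarray] = field(default_factory=list)  # each (N, 3) zyx um
    true_volume_fraction: float = 0.0
    puncta: pd.DataFrame | None = None  # columns: z_um, y_um, x_um, channel, role, radius_um, axon_id
    true_pair_counts: dict[str, int] = field(default_factory=dict)
    true_triad_counts: dict[str, int] = field(default_factory=dict)
    group_effects: dict[str, float] = field(default_factory=dict)
    yfp_kept_axons: list[int] | None = None

    def puncta_of(self, channel: str, role: str | None = None) -> np.ndarray:
        """(N, 3) zyx coordinates of puncta of one channel (optionally one role)."""
        if self.puncta is None or len(self.puncta) == 0:
            return np.empty((0, 3))
        df = self.puncta[self.puncta["channel"] == channel]
        if role is not None:
            df = df[df["role"] == role]
        return df[["z_um", "y_um", "x_um"]].to_numpy(float)

    @property
    def total_axon_length(self) -> float:
        return float(
            sum(np.linalg.norm(np.diff(c, axis=0), axis=1).sum() for c in self.axon_centerlines)
        )


# ---------------------------------------------------------------------------
# Axon geometry
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _reflect_into_box(p: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Mirror-fold a point into [0, box] per axis (billiard reflection)."""
    q = np.mod(p, 2.0 * box)
    over = q > box
    q[over] = 2.0 * box[over] - q[over]
    return q


def _walk_axon(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """One persistence-correlated random walk, reflected at the box faces."""
    box = np.asarray(cfg.box_size, float)
    n_steps = max(1, int(round(cfg.axon_length / cfg.step_length)))
    pts = np.empty((n_steps + 1, 3))
    pos = rng.uniform(0.0, box)
    direction = _random_unit(rng)[0]
    pts[0] = pos
    for i in range(n_steps):
        proposal = cfg.persistence * direction + (1.0 - cfg.persistence) * _random_unit(rng)[0]
        norm = np.linalg.norm(proposal)
        if norm < 1e-12:
            proposal, norm = _random_unit(rng)[0], 1.0
        direction = proposal / norm
        nxt = pos + cfg.step_length * direction
        folded = _reflect_into_box(nxt.copy(), box)
        # a reflection flips the corresponding direction component
        direction = direction * np.where(np.isclose(folded, nxt), 1.0, -1.0)
        pos = folded
        pts[i + 1] = pos
    return pts


def _segment_mask_window(
    p0: np.ndarray,
    p1: np.ndarray,
    radius: float,
    spacing: np.ndarray,
    shape: tuple[int, int, int],
):
    """Voxel-index window (slices) covering a capsule of given radius around a segment."""
    lo = np.minimum(p0, p1) - radius - spacing
    hi = np.maximum(p0, p1) + radius + spacing
    i0 = np.maximum(np.floor(lo / spacing - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing - 0.5).astype(int) + 1, np.asarray(shape))
    if np.any(i1 <= i0):
        return None
    return tuple(slice(int(a), int(b)) for a, b in zip(i0, i1))


def _window_coords(sl, spacing: np.ndarray) -> list[np.ndarray]:
    return [
        (np.arange(s.start, s.stop) + 0.5) * sp for s, sp in zip(sl, spacing)
    ]


def _dist_to_segment(zz, yy, xx, p0, p1) -> np.ndarray:
    d = p1 - p0
    len2 = float(d @ d)
    rz, ry, rx = zz - p0[0], yy - p0[1], xx - p0[2]
    if len2 < 1e-18:
        return np.sqrt(rz * rz + ry * ry + rx * rx)
    t = np.clip((rz * d[0] + ry * d[1] + rx * d[2]) / len2, 0.0, 1.0)
    cz, cy, cx = rz - t * d[0], ry - t * d[1], rx - t * d[2]
    return np.sqrt(cz * cz + cy * cy + cx * cx)


def _paint_tubes(
    out: np.ndarray,
    centerlines: Sequence[np.ndarray],
    radius: float,
    spacing: np.ndarray,
    soft_edge: float | None,
) -> None:
    """Accumulate tube intensity (max-composited) into ``out`` on a grid with
    the given spacing. ``soft_edge`` gives anti-aliased edges; ``None`` paints
    a hard boolean-like 0/1 indicator (used for volume-fraction union)."""
    shape = out.shape
    for line in centerlines:
        for p0, p1 in zip(line[:-1], line[1:]):
            sl = _segment_mask_window(p0, p1, radius, spacing, shape)
            if sl is None:
                continue
            z, y, x = _window_coords(sl, spacing)
            zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
            dist = _dist_to_segment(zz, yy, xx, p0, p1)
            if soft_edge is None:
                out[sl] |= dist <= radius
            else:
                val = np.clip((radius - dist) / soft_edge + 0.5, 0.0, 1.0)
                np.maximum(out[sl], val.astype(out.dtype), out=out[sl])


def _paint_spheres(
    out: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    spacing: np.ndarray,
    soft_edge: float,
) -> None:
    shape = out.shape
    for c, r in zip(centers, radii):
        sl = _segment_mask_window(c, c, float(r), spacing, shape)
        if sl is None:
            continue
        z, y, x = _window_coords(sl, spacing)
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
        dist = _dist_to_segment(zz, yy, xx, c, c)
        val = np.clip((float(r) - dist) / soft_edge + 0.5, 0.0, 1.0)
        np.maximum(out[sl], val.astype(out.dtype), out=out[sl])


def _union_volume_fraction(
    centerlines: Sequence[np.ndarray], cfg: SimulationConfig, max_spacing_factor: float = 0.25
) -> float:
    """Tube-union volume / box volume by voxel counting on a fine sub-grid.

    The sub-grid spacing per axis is the voxel size divided by the smallest
    integer factor that brings it to <= ``max_spacing_factor * axon_radius``
    (default radius/4), which keeps straight-tube unions within ~1-2 % of the
    closed-form cylinder volume.
    """
    if not centerlines:
        return 0.0
    voxel = np.asarray(cfg.voxel_size, float)
    target = max_spacing_factor * cfg.axon_radius
    factors = np.maximum(1, np.ceil(voxel / target)).astype(int)
    spacing = voxel / factors
    shape = tuple(int(g * f) for g, f in zip(cfg.grid_shape, factors))
    union = np.zeros(shape, dtype=bool)
    _paint_tubes(union, centerlines, cfg.axon_radius, spacing, soft_edge=None)
    return float(union.mean())


def simulate_axons(config: SimulationConfig, compute_volume_fraction: bool = True) -> GroundTruth:
    """Generate axon centerlines and their true tube-union volume fraction.

    Axons are fixed-step persistence random walks reflected at the box faces,
    emulating tortuous-but-smooth unmyelinated monoaminergic fibers. The true
    volume fraction is the voxel-union of all tubes on a fine sub-grid, so
    overlap between axons is not double-counted.
    """
    if config.axon_radius >= min(config.box_size) / 2.0:
        raise ValueError(
            f"axon_radius {config.axon_radius} um must be smaller than half the "
            f"smallest box dimension ({min(config.box_size) / 2.0} um)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    centerlines = [_walk_axon(rng, config) for _ in range(config.n_axons)]
    vf = _union_volume_fraction(centerlines, config) if compute_volume_fraction else float("nan")
    if config.n_axons == 0:
        vf = 0.0
    return GroundTruth(config=config, axon_centerlines=centerlines, true_volume_fraction=vf)


# ---------------------------------------------------------------------------
# Puncta placement
# ---------------------------------------------------------------------------

def _arc_interpolate(line: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Points at arc-lengths ``s`` along a polyline."""
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.clip(s, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    t = (s - cum[idx]) / np.maximum(seg[idx], 1e-12)
    return line[idx] + t[:, None] * (line[idx + 1] - line[idx])


class _FiberDistance:
    """Fast approximate distance-to-fiber queries via a densified centerline cloud.

    ``clearance`` extends the exclusion radius: outside puncta are whole
    objects, so their centers must clear the tube surface by their own
    radius rather than merely falling off the centerline tube.
    """

    def __init__(self, centerlines: Sequence[np.ndarray], radius: float, clearance: float = 0.0):
        pts = []
        spacing = max(radius / 2.0, 0.05)
        for line in centerlines:
            seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
            total = seg.sum()
            if total <= 0:
                pts.append(line[:1])
                continue
            n = max(2, int(np.ceil(total / spacing)) + 1)
            pts.append(_arc_interpolate(line, np.linspace(0.0, total, n)))
        self.tree = cKDTree(np.concatenate(pts)) if pts else None
        self.radius = radius + clearance
        self.margin = spacing**2 / (8.0 * max(radius, 1e-6))  # chord sagitta bound
        self.clearance = clearance
        self.sphere_tree: cKDTree | None = None
        self.sphere_exclusion = 0.0

    def add_spheres(self, centers: np.ndarray, radius: float) -> None:
        """Also exclude balls (e.g. varicosity swellings) of a common radius."""
        if len(centers):
            self.sphere_tree = cKDTree(centers)
            self.sphere_exclusion = radius + self.clearance

    def outside(self, points: np.ndarray) -> np.ndarray:
        if len(points) == 0:
            return np.ones(0, dtype=bool)
        ok = np.ones(len(points), dtype=bool)
        if self.tree is not None:
            d, _ = self.tree.query(points, k=1)
            ok &= d > self.radius + self.margin
        if self.sphere_tree is not None:
            d, _ = self.sphere_tree.query(points, k=1)
            ok &= d > self.sphere_exclusion
        return ok


def _sample_outside(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    fibers: _FiberDistance,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform samples in the fiber-free part of the box (rejection sampling)."""
    out: list[np.ndarray] = []
    need = n
    tries = 0
    while need > 0 and tries < max_tries:
        cand = rng.uniform(0.0, box, size=(max(need * 2, 16), 3))
        keep = cand[fibers.outside(cand)][:need]
        out.append(keep)
        need -= len(keep)
        tries += 1
    if need > 0:
        raise RuntimeError(
            f"could not place {n} puncta outside fibers ({need} short after {tries} rounds); "
            "the fiber volume fraction is too high for the requested density"
        )
    return np.concatenate(out) if out else np.empty((0, 3))


def _place_near(
    rng: np.random.Generator,
    anchor: np.ndarray,
    r_lo: float,
    r_hi: float,
    box: np.ndarray,
    fibers: _FiberDistance | None,
    max_tries: int = 200,
) -> np.ndarray | None:
    """A point at distance U(r_lo, r_hi) from ``anchor``, inside the box and
    (if ``fibers`` given) outside the fiber tubes; None if infeasible."""
    for _ in range(max_tries):
        p = anchor + rng.uniform(r_lo, r_hi) * _random_unit(rng)[0]
        if np.any(p < 0.0) or np.any(p >= box):
            continue
        if fibers is not None and not bool(fibers.outside(p[None])[0]):
            continue
        return p
    return None


def _greedy_unique_pairs_bruteforce(
    a: np.ndarray, b: np.ndarray, d: float
) -> list[tuple[int, int, float]]:
    """Exhaustive O(n^2) greedy shortest-distance-first unique matching.

    This is the simulator's own recount of its emitted coordinates; the
    analysis module implements the same matching independently with a spatial
    index, and tests require the two to agree exactly.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    dist = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    ii, jj = np.nonzero(dist <= d)
    dd = dist[ii, jj]
    order = np.lexsort((jj, ii, dd))  # distance first, then a index, then b index
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    pairs = []
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((int(i), int(j), float(dd[k])))
    return pairs


def _recount_truth(truth: GroundTruth) -> tuple[dict[str, int], dict[str, int]]:
    """Brute-force recount of synapse pairs and triads over emitted coordinates."""
    cfg = truth.config
    d = cfg.pairing_distance
    kind = cfg.post_kind
    boutons = truth.puncta_of("synaptophysin", role="bouton")
    syn_out = truth.puncta[
        (truth.puncta["channel"] == "synaptophysin") & (truth.puncta["role"] != "bouton")
    ][["z_um", "y_um", "x_um"]].to_numpy(float)
    post = truth.puncta_of(cfg.post_channel)

    sero = _greedy_unique_pairs_bruteforce(boutons, post, d)
    other = _greedy_unique_pairs_bruteforce(syn_out, post, d)
    pair_counts = {f"serotonergic_{kind}": len(sero), f"other_{kind}": len(other)}

    triad_counts = {f"{kind}_presynaptic": 0, f"{kind}_postsynaptic": 0}
    if other and len(boutons):
        refs = np.array([(syn_out[i] + post[j]) / 2.0 for i, j, _ in other])
        dist = np.linalg.norm(boutons[:, None, :] - refs[None, :, :], axis=2)
        for bi in range(len(boutons)):
            qual = np.nonzero(dist[bi] <= d)[0]
            if len(qual) == 0:
                continue
            pj = qual[np.argmin(dist[bi, qual])]
            i, j, _ = other[pj]
            d_syn = np.linalg.norm(boutons[bi] - syn_out[i])
            d_post = np.linalg.norm(boutons[bi] - post[j])
            polarity = "presynaptic" if d_syn <= d_post else "postsynaptic"
            triad_counts[f"{kind}_{polarity}"] += 1
    return pair_counts, triad_counts


def place_puncta(config: SimulationConfig, truth: GroundTruth) -> GroundTruth:
    """Place varicosities, boutons, outside puncta and constructed arrangements.

    Completes ``truth`` in place-like fashion (returns the same object) with a
    ``puncta`` table and the brute-force recounted true pair/triad counts.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    box = np.asarray(cfg.box_size, float)
    # outside puncta may abut and partly interdigitate with the fiber surface,
    # but their centers must clear the tube by half their radius so the
    # center-voxel compartment rule can separate them from true boutons
    fibers = _FiberDistance(
        truth.axon_centerlines, cfg.axon_radius, clearance=0.5 * cfg.punctum_radius
    )

    rows: list[dict] = []
    vari_radius = cfg.varicosity_radius_factor * cfg.axon_radius

    # varicosities along each centerline (Poisson process in arc length);
    # a bouton's synaptophysin punctum sits offset from the varicosity center
    # toward the surface, where the vesicle cluster apposes the membrane
    bouton_coords: list[np.ndarray] = []
    bouton_axons: list[int] = []
    vari_centers: list[np.ndarray] = []
    bouton_offset = 0.5 * vari_radius
    for axon_id, line in enumerate(truth.axon_centerlines):
        length = float(np.linalg.norm(np.diff(line, axis=0), axis=1).sum())
        # quasi-deterministic count at the requested linear rate: animals are
        # meant to differ by their group effect and geometry, not by Poisson
        # scatter in the generator itself
        expected = cfg.varicosity_rate * length
        n_var = int(expected) + int(rng.random() < (expected - int(expected)))
        if n_var == 0:
            continue
        pts = _arc_interpolate(line, rng.uniform(0.0, length, size=n_var))
        is_bouton = np.zeros(n_var, dtype=bool)
        n_bouton = int(round(cfg.bouton_fraction * n_var))
        is_bouton[rng.permutation(n_var)[:n_bouton]] = True
        for p, b in zip(pts, is_bouton):
            rows.append(
                dict(
                    z_um=p[0], y_um=p[1], x_um=p[2], channel=cfg.fiber_marker,
                    role="varicosity", radius_um=vari_radius, axon_id=axon_id,
                )
            )
            vari_centers.append(p)
            if b:
                bc = None
                for _ in range(50):
                    cand = p + bouton_offset * _random_unit(rng)[0]
                    if np.all(cand >= 0.0) and np.all(cand < box):
                        bc = cand
                        break
                bouton_coords.append(bc if bc is not None else p)
                bouton_axons.append(axon_id)
    fibers.add_spheres(np.asarray(vari_centers).reshape(-1, 3), vari_radius)

    # triad construction relocates pairs next to boutons, so build the bouton
    # list first, then outside populations
    free_volume = cfg.box_volume * (1.0 - min(truth.true_volume_fraction, 0.95))
    n_syn_out = rng.poisson(cfg.outside_syn_density * free_volume)
    n_post = rng.poisson(cfg.postsyn_density * free_volume)
    syn_out = _sample_outside(rng, n_syn_out, box, fibers)
    post_list: list[np.ndarray] = []
    post_roles: list[str] = []
    shortfall = 0

    # constructed serotonergic synapses: a postsyn punctum apposed to a
    # fraction of the boutons, just outside the fiber on the bouton's side
    def outward_of(b: np.ndarray) -> np.ndarray:
        if fibers.tree is None:
            return _random_unit(rng)[0]
        _, ni = fibers.tree.query(b)
        v = b - fibers.tree.data[ni]
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 1e-9 else _random_unit(rng)[0]

    n_sero = int(round(cfg.sero_paired_fraction * len(bouton_coords)))
    placed_sero = 0
    for bi in rng.permutation(len(bouton_coords)):
        if placed_sero >= n_sero:
            break
        b = bouton_coords[bi]
        out_dir = outward_of(b)
        for _ in range(300):
            u = out_dir + 0.35 * _random_unit(rng)[0]
            u /= np.linalg.norm(u)
            p = b + rng.uniform(0.3, cfg.pairing_distance * 0.95) * u
            if np.any(p < 0.0) or np.any(p >= box):
                continue
            if not bool(fibers.outside(p[None])[0]):
                continue
            post_list.append(p)
            post_roles.append("post_sero")
            placed_sero += 1
            break
    shortfall += n_sero - placed_sero

    # constructed synapse pairs: place a postsyn punctum within pairing
    # distance of a fraction of the outside-synaptophysin puncta
    n_paired = int(round(cfg.paired_fraction * len(syn_out)))
    placed_pairs = 0
    for i in rng.permutation(len(syn_out)):
        if placed_pairs >= n_paired:
            break
        p = _place_near(rng, syn_out[i], 0.05, cfg.pairing_distance * 0.95, box, fibers)
        if p is not None:
            post_list.append(p)
            post_roles.append("post_paired")
            placed_pairs += 1
    shortfall += n_paired - placed_pairs

    # remaining postsynaptic puncta are background
    n_bg = max(0, n_post - len(post_list))
    for p in _sample_outside(rng, n_bg, box, fibers):
        post_list.append(p)
        post_roles.append("post")

    # constructed triads: a (syn_out, postsyn) pair whose midpoint lies within
    # the pairing distance of a fraction of the boutons
    n_triad = int(round(cfg.triad_fraction * len(bouton_coords)))
    syn_out_extra: list[np.ndarray] = []
    placed_triads = 0
    for bi in rng.permutation(len(bouton_coords)):
        if placed_triads >= n_triad:
            break
        b = bouton_coords[bi]
        outward = outward_of(b)  # away from the local fiber axis
        placed = False
        for _ in range(300):
            # midpoint outward of the bouton, within the pairing distance;
            # the pair axis lies tangent (perpendicular to outward) so both
            # members keep the midpoint's clearance from the fiber
            u = outward + 0.35 * _random_unit(rng)[0]
            u /= np.linalg.norm(u)
            mid = b + rng.uniform(0.3, cfg.pairing_distance * 0.9) * u
            if np.any(mid < 0.0) or np.any(mid >= box):
                continue
            axis = np.cross(u, _random_unit(rng)[0])
            nrm = np.linalg.norm(axis)
            if nrm < 1e-9:
                continue
            axis /= nrm
            sep = rng.uniform(0.3, cfg.pairing_distance * 0.95)
            m_syn = mid + 0.5 * sep * axis
            m_post = mid - 0.5 * sep * axis
            members = np.stack([m_syn, m_post])
            if np.any(members < 0.0) or np.any(members >= box):
                continue
            if not np.all(fibers.outside(members)):
                continue
            syn_out_extra.append(m_syn)
            post_list.append(m_post)
            post_roles.append("post_triad")
            placed = True
            break
        if placed:
            placed_triads += 1
    shortfall += n_triad - placed_triads
    if shortfall:
        raise RuntimeError(
            f"{shortfall} requested paired/triad arrangements could not be placed in the "
            "remaining fiber-free volume; lower paired_fraction/triad_fraction or densities"
        )

    for p in syn_out:
        rows.append(
            dict(z_um=p[0], y_um=p[1], x_um=p[2], channel="synaptophysin",
                 role="syn_out", radius_um=cfg.punctum_radius, axon_id=-1)
        )
    for p in syn_out_extra:
        rows.append(
            dict(z_um=p[0], y_um=p[1], x_um=p[2], channel="synaptophysin",
                 role="syn_out_triad", radius_um=cfg.punctum_radius, axon_id=-1)
        )
    for p, role in zip(post_list, post_roles):
        rows.append(
            dict(z_um=p[0], y_um=p[1], x_um=p[2], channel=cfg.post_channel,
                 role=role, radius_um=cfg.punctum_radius, axon_id=-1)
        )
    for p, axon_id in zip(bouton_coords, bouton_axons):
        rows.append(
            dict(z_um=p[0], y_um=p[1], x_um=p[2], channel="synaptophysin",
                 role="bouton", radius_um=cfg.punctum_radius, axon_id=axon_id)
        )

    truth.puncta = pd.DataFrame(
        rows, columns=["z_um", "y_um", "x_um", "channel", "role", "radius_um", "axon_id"]
    )
    truth.true_pair_counts, truth.true_triad_counts = _recount_truth(truth)
    return truth


# ---------------------------------------------------------------------------
# Forward optical model
# ---------------------------------------------------------------------------

def _apply_noise(
    ideal: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    expected = ideal * cfg.photon_scale + cfg.background
    noisy = rng.poisson(expected).astype(np.float32)
    if cfg.read_noise_sd > 0:
        noisy += rng.normal(0.0, cfg.read_noise_sd, size=noisy.shape).astype(np.float32)
    return np.maximum(noisy, 0.0)


def render_stack(config: SimulationConfig, truth: GroundTruth) -> ImageStack:
    """Render the ground truth into a noisy multi-channel stack.

    Per channel: objects are drawn as anti-aliased ideal intensity in [0, 1],
    convolved with the anisotropic Gaussian PSF, scaled to expected photons,
    then Poisson shot noise and Gaussian read noise are applied.
    """
    cfg = config
    voxel = np.asarray(cfg.voxel_size, float)
    psf = np.asarray(cfg.psf_sigma, float)
    if np.any(psf < voxel / 4.0):
        warnings.warn(
            f"psf_sigma {cfg.psf_sigma} is under a quarter voxel {cfg.voxel_size} on some "
            "axis: the PSF is undersampled",
            stacklevel=2,
        )
    shape = cfg.grid_shape
    soft = float(np.min(voxel))
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    puncta = truth.puncta if truth.puncta is not None else pd.DataFrame(
        columns=["z_um", "y_um", "x_um", "channel", "role", "radius_um", "axon_id"]
    )

    def sphere_layer(df: pd.DataFrame) -> np.ndarray:
        layer = np.zeros(shape, dtype=np.float32)
        if len(df):
            _paint_spheres(
                layer,
                df[["z_um", "y_um", "x_um"]].to_numpy(float),
                df["radius_um"].to_numpy(float),
                voxel,
                soft,
            )
        return layer

    def fiber_layer(axon_ids: set[int] | None) -> np.ndarray:
        layer = np.zeros(shape, dtype=np.float32)
        lines = truth.axon_centerlines
        if axon_ids is not None:
            lines = [l for i, l in enumerate(lines) if i in axon_ids]
        _paint_tubes(layer, lines, cfg.axon_radius, voxel, soft_edge=soft)
        vari = puncta[puncta["role"] == "varicosity"]
        if axon_ids is not None:
            vari = vari[vari["axon_id"].isin(list(axon_ids))]
        if len(vari):
            _paint_spheres(
                layer,
                vari[["z_um", "y_um", "x_um"]].to_numpy(float),
                vari["radius_um"].to_numpy(float),
                voxel,
                soft,
            )
        return layer

    channels = [cfg.fiber_marker, "synaptophysin", cfg.post_channel]
    layers = [
        fiber_layer(None),
        sphere_layer(puncta[puncta["channel"] == "synaptophysin"]),
        sphere_layer(puncta[puncta["channel"] == cfg.post_channel]),
    ]
    if cfg.yfp_omit_fraction is not None:
        n = len(truth.axon_centerlines)
        n_omit = int(round(cfg.yfp_omit_fraction * n))
        omit = set(rng.choice(n, size=n_omit, replace=False).tolist()) if n_omit else set()
        kept = set(range(n)) - omit
        truth.yfp_kept_axons = sorted(kept)
        channels.append("YFP")
        layers.append(fiber_layer(kept))

    sigma_vox = psf / voxel
    data = np.stack(
        [_apply_noise(gaussian_filter(layer, sigma=sigma_vox), cfg, rng) for layer in layers]
    )
    return ImageStack(data=data, voxel_size=tuple(voxel), channel_names=channels)


def simulate_stack(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Convenience wrapper: axons -> puncta -> rendered stack."""
    truth = simulate_axons(config)
    truth = place_puncta(config, truth)
    return render_stack(config, truth), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    groups: Sequence[tuple[str, float]],
    n_per_group: int,
    render: bool = True,
) -> list[dict]:
    """Simulate a multi-group cohort of independent animals.

    Each animal receives a deterministic seed derived from ``config.seed``.
    The group effect multiplier scales the number of axons, so all axon-borne
    quantities (fiber volume, varicosities, boutons, serotonergic synapses)
    scale with it while the outside punctum populations stay fixed —
    emulating a lesion that removes innervating fibers, not tissue.

    Returns a list of records with keys ``group``, ``multiplier``, ``animal``,
    ``config``, ``truth`` and (if ``render``) ``stack``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for name, mult in groups:
        if mult <= 0:
            raise ValueError(f"group {name!r}: effect multiplier must be > 0; got {mult}")
    seeds = np.random.SeedSequence(int(config.seed)).generate_state(
        len(groups) * n_per_group
    ) % (2**31)
    records = []
    k = 0
    for name, mult in groups:
        for a in range(n_per_group):
            animal_cfg = replace(
                config,
                n_axons=int(round(config.n_axons * mult)),
                seed=int(seeds[k]),
            )
            k += 1
            truth = simulate_axons(animal_cfg)
            truth = place_puncta(animal_cfg, truth)
            truth.group_effects = {name: mult}
            rec = dict(
                group=name, multiplier=mult, animal=f"{name}_{a + 1}",
                config=animal_cfg, truth=truth,
            )
            if render:
                rec["stack"] = render_stack(animal_cfg, truth)
            records.append(rec)
    return records
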