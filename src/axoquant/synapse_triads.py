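"""Proximity-defined synapse and triad calling, colocalization, density tables.

A putative synapse is a synaptophysin punctum whose center lies within the
pairing distance (0.6 um) of a postsynaptic scaffold punctum — gephyrin for
inhibitory sites, PSD95 for excitatory sites. Serotonergic (or, with NET,
noradrenergic) synapses use the in-fiber synaptophysin boutons; all other
synapses use outside-fiber synaptophysin. A triad is an in-fiber bouton
within the pairing distance of a non-serotonergic synapse pair, classified
pre- or post-synaptic by which pair member the bouton is nearer.

All distances are center-to-center Euclidean distances in physical
micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .fiber_quant import FiberModel, VaricosityList, fiber_volume_density
from .puncta_detection import Punctum, puncta_coordinates

__all__ = [
    "PAIRING_DISTANCE_UM",
    "SynapseCall",
    "TriadCall",
    "DensityRecord",
    "pair_within",
    "call_synapses",
    "call_triads",
    "colocalization_ratio",
    "tabulate_densities",
]

PAIRING_DISTANCE_UM = 0.6

SYNAPSE_CLASSES = (
    "serotonergic_inhibitory",
    "serotonergic_excitatory",
    "other_inhibitory",
    "other_excitatory",
)


@dataclass
class SynapseCall:
    """A (presynaptic synaptophysin, postsynaptic scaffold) punctum pair."""

    id: int
    pre: int  # synaptophysin punctum id
    post: int  # gephyrin / PSD95 punctum id
    distance: float  # um, center-to-center
    cls: str  # one of SYNAPSE_CLASSES
    pre_center: tuple[float, float, float]
    post_center: tuple[float, float, float]

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.pre_center) + np.asarray(self.post_center)) / 2.0


@dataclass
class TriadCall:
    """An in-fiber bouton adjacent to a non-serotonergic synapse pair."""

    bouton: int  # Punctum id of the in-fiber synaptophysin bouton
    synapse: int  # SynapseCall id of the other_* pair
    distance: float  # um, bouton to the pair's reference point
    polarity: str  # "presynaptic" | "postsynaptic"
    cls: str  # "inhibitory" | "excitatory"


@dataclass
class DensityRecord:
    animal: str
    group: str
    region: str
    measure: str
    value: float
    tissue_volume: float

    def __post_init__(self) -> None:
        if self.value < 0 and not np.isnan(self.value):
            raise ValueError(f"density {self.measure} must be >= 0; got {self.value}")


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_within(
    set_a: np.ndarray | list,
    set_b: np.ndarray | list,
    d: float,
    mode: str = "unique",
) -> list[tuple[int, int, float]]:
    """All or uniquely-matched (a, b) index pairs with centers within ``d`` um.

    ``mode="unique"`` (default) performs greedy globally-shortest-first
    matching — candidate pairs are sorted by (distance, a index, b index) and
    accepted while both members are unused, so each punctum joins at most one
    pair, which avoids double-counting in crowded neuropil. ``mode="all"``
    returns every qualifying pair. Uses a KD-tree; an exhaustive quadratic
    enumeration must give identical results.
    """
    if d <= 0:
        raise ValueError("pairing distance d must be positive")
    if mode not in ("unique", "all"):
        raise ValueError(f"unknown mode {mode!r}; use 'unique' or 'all'")
    a = np.asarray(set_a, float).reshape(-1, 3)
    b = np.asarray(set_b, float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return []
    neighbors = cKDTree(a).query_ball_tree(cKDTree(b), d)
    counts = [len(nb) for nb in neighbors]
    if sum(counts) == 0:
        return []
    ii = np.repeat(np.arange(len(a)), counts)
    jj = np.concatenate([nb for nb in neighbors if nb]).astype(int)
    dd = np.sqrt(((a[ii] - b[jj]) ** 2).sum(axis=1))
    order = np.lexsort((jj, ii, dd))  # distance first, then a index, then b index
    if mode == "all":
        return [(int(ii[k]), int(jj[k]), float(dd[k])) for k in order]
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    out = []
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        out.append((int(i), int(j), float(dd[k])))
    return out


def call_synapses(
    syn: list[Punctum],
    post: list[Punctum],
    post_kind: str,
    d: float = PAIRING_DISTANCE_UM,
    mode: str = "unique",
) -> list[SynapseCall]:
    """Call synapses between synaptophysin and one postsynaptic channel.

    In-fiber synaptophysin x postsynaptic puncta gives the serotonergic
    class; outside-fiber synaptophysin x postsynaptic puncta gives the
    non-serotonergic ("other") class. The two matchings are independent:
    a postsynaptic punctum may appear once in each.
    """
    if post_kind not in ("inhibitory", "excitatory"):
        raise ValueError(f"post_kind must be 'inhibitory' or 'excitatory'; got {post_kind!r}")
    unpartitioned = [p for p in syn if p.compartment is None]
    if unpartitioned:
        raise ValueError(
            f"{len(unpartitioned)} synaptophysin puncta have no compartment; run "
            "partition_by_compartment first"
        )
    calls: list[SynapseCall] = []
    next_id = 0
    post_xyz = puncta_coordinates(post)
    for compartment, prefix in (("in_fiber", "serotonergic"), ("out_fiber", "other")):
        subset = [p for p in syn if p.compartment == compartment]
        for i, j, dd in pair_within(puncta_coordinates(subset), post_xyz, d, mode=mode):
            calls.append(
                SynapseCall(
                    id=next_id,
                    pre=subset[i].id,
                    post=post[j].id,
                    distance=dd,
                    cls=f"{prefix}_{post_kind}",
                    pre_center=subset[i].center,
                    post_center=post[j].center,
                )
            )
            next_id += 1
    return calls


def call_triads(
    boutons: list[Punctum],
    other_synapses: list[SynapseCall],
    d: float = PAIRING_DISTANCE_UM,
    reference: str = "midpoint",
) -> list[TriadCall]:
    """Call triads: in-fiber boutons within ``d`` of a non-serotonergic pair.

    The bouton-to-pair distance uses the chosen ``reference``: the pair
    midpoint (default), the nearest member, or both members (the farther
    member must still lie within ``d``). Each bouton joins at most one triad
    (nearest reference wins); polarity is presynaptic when the bouton is
    nearer the pair's synaptophysin member, postsynaptic when nearer the
    scaffold member, with exact ties resolved as presynaptic.
    """
    if reference not in ("midpoint", "nearest-member", "both-members"):
        raise ValueError(
            f"unknown reference {reference!r}; use 'midpoint', 'nearest-member' or "
            "'both-members'"
        )
    pairs = [s for s in other_synapses if s.cls.startswith("other_")]
    in_fiber = [p for p in boutons if p.compartment == "in_fiber"]
    if not pairs or not in_fiber:
        return []
    b_xyz = np.array([p.center for p in in_fiber])
    pre_xyz = np.array([s.pre_center for s in pairs])
    post_xyz = np.array([s.post_center for s in pairs])
    d_pre = np.linalg.norm(b_xyz[:, None, :] - pre_xyz[None, :, :], axis=2)
    d_post = np.linalg.norm(b_xyz[:, None, :] - post_xyz[None, :, :], axis=2)
    if reference == "midpoint":
        mid = (pre_xyz + post_xyz) / 2.0
        ref = np.linalg.norm(b_xyz[:, None, :] - mid[None, :, :], axis=2)
    elif reference == "nearest-member":
        ref = np.minimum(d_pre, d_post)
    else:  # both-members: the farther member must still be within d
        ref = np.maximum(d_pre, d_post)

    triads: list[TriadCall] = []
    for bi, p in enumerate(in_fiber):
        qualifying = np.nonzero(ref[bi] <= d)[0]
        if len(qualifying) == 0:
            continue
        pj = int(qualifying[np.argmin(ref[bi, qualifying])])
        s = pairs[pj]
        polarity = "presynaptic" if d_pre[bi, pj] <= d_post[bi, pj] else "postsynaptic"
        triads.append(
            TriadCall(
                bouton=p.id,
                synapse=s.id,
                distance=float(ref[bi, pj]),
                polarity=polarity,
                cls=s.cls.removeprefix("other_"),
            )
        )
    return triads


# ---------------------------------------------------------------------------
# Colocalization and density tables
# ---------------------------------------------------------------------------

def colocalization_ratio(
    fiber_a: FiberModel, fiber_b: FiberModel, tolerance_voxels: int = 1
) -> float:
    """Fraction of fiber volume a that colocalizes with fiber volume b.

    By convention a is the transporter (SERT) channel and b the second marker
    (YFP). ``tolerance_voxels`` dilates b before intersecting: independent
    photon noise jitters the two segmentation boundaries by about a voxel, so
    a strict voxel-wise intersection (``tolerance_voxels=0``) systematically
    undercounts colocalized volume at the fiber surface. Returns NaN when a
    is empty (undefined ratio).
    """
    if fiber_a.mask.shape != fiber_b.mask.shape or not np.allclose(
        fiber_a.voxel_size, fiber_b.voxel_size
    ):
        raise ValueError("fiber masks must live on the same voxel grid")
    vol_a = int(fiber_a.mask.sum())
    if vol_a == 0:
        return float("nan")
    mask_b = fiber_b.mask
    if tolerance_voxels > 0:
        from scipy.ndimage import binary_dilation

        mask_b = binary_dilation(mask_b, iterations=tolerance_voxels)
    return float(np.logical_and(fiber_a.mask, mask_b).sum() / vol_a)


TRIAD_CLASSES = tuple(
    f"triad_{cls}_{pol}" for cls in ("inhibitory", "excitatory")
    for pol in ("presynaptic", "postsynaptic")
)


def tabulate_densities(
    animal: str,
    group: str,
    region: str,
    fiber: FiberModel,
    varicosities: VaricosityList | None = None,
    puncta: list[Punctum] | None = None,
    synapses: list[SynapseCall] | None = None,
    triads: list[TriadCall] | None = None,
    coloc: float | None = None,
    existing: list[DensityRecord] | None = None,
) -> list[DensityRecord]:
    """One density record per measure for one (animal, region) stack.

    Measures: fiber volume density (unitless), varicosity density, in/out
    synaptophysin bouton densities, the four synapse-class densities, the
    four triad-class densities (all counts per um^3 of tissue) and, when
    available, the SERT/YFP colocalization ratio. Absent inputs yield
    zero-valued records (an empty stack is a measurement, not missing data).
    Appending a duplicate (animal, region, measure) to ``existing`` raises.
    """
    tv = fiber.tissue_volume
    values: dict[str, float] = {"fiber_volume_density": fiber_volume_density(fiber)}
    values["varicosity_density"] = varicosities.density if varicosities is not None else 0.0
    n_in = n_out = 0
    for p in puncta or []:
        if p.channel == "synaptophysin":
            if p.compartment == "in_fiber":
                n_in += 1
            elif p.compartment == "out_fiber":
                n_out += 1
    values["bouton_density"] = n_in / tv
    values["syn_out_density"] = n_out / tv
    for cls in SYNAPSE_CLASSES:
        values[f"synapse_{cls}"] = sum(
            1 for s in synapses or [] if s.cls == cls
        ) / tv
    for key in TRIAD_CLASSES:
        _, cls, pol = key.split("_")
        values[key] = sum(
            1 for t in triads or [] if t.cls == cls and t.polarity == pol
        ) / tv
    if coloc is not None:
        values["colocalization_ratio"] = coloc

    records = list(existing) if existing is not None else []
    seen = {(r.animal, r.region, r.measure) for r in records}
    for measure, value in values.items():
        key = (animal, region, measure)
        if key in seen:
            raise ValueError(f"duplicate density record {key}")
        records.append(
            DensityRecord(
                animal=animal, group=group, region=region,
                measure=measure, value=float(value), tissue_volume=tv,
            )
        )
    return records


def densities_to_frame(records: list[DensityRecord]) -> pd.DataFrame:
    """Long-format table: animal, group, region, measure, value, tissue_volume."""
    return pd.DataFrame(
        [
            dict(
                animal=r.animal, group=r.group, region=r.region,
                measure=r.measure, value=r.value, tissue_volume=r.tissue_volume,
            )
            for r in records
        ]
    )
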