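"""Stack I/O with physical metadata, ROI cropping, and acquisition-geometry arithmetic.

All volumes are kept internally in ``(channel, z, y, x)`` axis order with
0-based voxel indices. The physical coordinate of a voxel is its *center*:
``origin + (index + 0.5) * voxel_size``; physical intervals are half-open
``[lo, hi)``. Coordinate 3-vectors are ordered ``(z, y, x)`` in micrometers
to match array axes.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "AcquisitionGeometry",
    "read_stack",
    "write_stack",
    "crop_roi",
    "abbe_resolution",
    "lateral_pixel_size",
    "slices_spanned",
    "mass_to_molar",
]


@dataclass
class ImageStack:
    """A multi-channel 3-D volume with physical voxel sizes.

    Parameters
    ----------
    data
        Intensity array in ``(channel, z, y, x)`` order.
    voxel_size
        Physical voxel edge lengths ``(z, y, x)`` in micrometers.
    channel_names
        One name per channel, e.g. ``["SERT", "synaptophysin", "gephyrin"]``.
    origin
        Physical coordinate (um, ``(z, y, x)``) of the lower corner of voxel
        ``(0, 0, 0)``; voxel centers sit half a voxel further in.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (c, z, y, x); got ndim={self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 strictly positive values; got {self.voxel_size}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (um) of the volume along (z, y, x)."""
        return tuple(s * v for s, v in zip(self.shape_zyx, self.voxel_size))

    @property
    def tissue_volume(self) -> float:
        """Total physical volume (um^3) of the stack — the tissue/ROI volume."""
        return float(np.prod(self.shape_zyx) * np.prod(self.voxel_size))

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None
        return self.data[idx]

    def same_grid(self, other: "ImageStack", atol: float = 1e-6) -> bool:
        return (
            self.shape_zyx == other.shape_zyx
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class AcquisitionGeometry:
    """Confocal acquisition geometry: ROI extent, frame size, z-step, optics."""

    roi_extent: tuple[float, float, float] = (15.6, 134.95, 134.95)  # (z, y, x) um
    frame_pixels: tuple[int, int] = (1024, 1024)
    z_step: float = 0.3  # um
    na: float = 1.4
    wavelengths: list[float] = field(default_factory=lambda: [405.0, 488.0, 561.0, 639.0])

    def __post_init__(self) -> None:
        vals = (*self.roi_extent, *self.frame_pixels, self.z_step, self.na, *self.wavelengths)
        if any(v <= 0 for v in vals):
            raise ValueError("all acquisition-geometry quantities must be positive")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an OME-TIFF with channel axis, channel names and physical voxel sizes."""
    path = Path(path)
    vz, vy, vx = stack.voxel_size
    tifffile.imwrite(
        path,
        np.ascontiguousarray(stack.data),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": stack.channel_names},
        },
    )
    return path


def _parse_ome(xml_text: str) -> tuple[tuple[float, float, float] | None, list[str] | None]:
    """Extract (z, y, x) voxel size and channel names from OME-XML, if present."""
    root = ET.fromstring(xml_text)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None, None
    try:
        voxel = (
            float(pixels.attrib["PhysicalSizeZ"]),
            float(pixels.attrib["PhysicalSizeY"]),
            float(pixels.attrib["PhysicalSizeX"]),
        )
    except KeyError:
        voxel = None
    names = [ch.attrib.get("Name", f"ch{i}") for i, ch in enumerate(pixels.findall(f"{ns}Channel"))]
    return voxel, names or None


def read_stack(
    path: str | Path,
    voxel_override: tuple[float, float, float] | None = None,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF into a ``(c, z, y, x)`` :class:`ImageStack`.

    Voxel sizes come from OME metadata unless ``voxel_override`` (z, y, x um)
    is given; a plain TIFF without metadata *requires* the override.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper().replace("S", "C")
        if "Z" not in axes and data.ndim >= 3:
            # plain TIFF page stacks come back with an anonymous axis (Q/I):
            # interpret it as z
            for anon in ("Q", "I"):
                if anon in axes:
                    axes = axes.replace(anon, "Z", 1)
                    break
        ome_voxel = ome_names = None
        if tf.ome_metadata:
            ome_voxel, ome_names = _parse_ome(tf.ome_metadata)

    if "Z" not in axes:
        if data.ndim == 2:
            raise ValueError("2-D image: a stack must have a z axis")
        raise ValueError(f"cannot identify a z axis in TIFF axes {axes!r}")
    if data.ndim == 3 and "C" not in axes:
        data = data[None]
        axes = "C" + axes
    if data.ndim != 4 or set(axes) != {"C", "Z", "Y", "X"}:
        raise ValueError(
            f"ambiguous axis layout {axes!r} (shape {data.shape}); expected CZYX-compatible"
        )
    data = np.moveaxis(data, [axes.index(a) for a in "CZYX"], [0, 1, 2, 3])

    voxel = voxel_override if voxel_override is not None else ome_voxel
    if voxel is None:
        raise ValueError(f"{path}: no voxel-size metadata and no voxel_override given")
    names = channel_names or ome_names or [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data=data, voxel_size=tuple(voxel), channel_names=names)


def crop_roi(
    stack: ImageStack,
    lo: tuple[float, float, float],
    hi: tuple[float, float, float],
) -> ImageStack:
    """Crop the half-open physical box ``[lo, hi)`` (um, (z, y, x)).

    Voxel boundaries are snapped *outward* so the returned stack fully covers
    the requested box; the returned ``origin`` is updated accordingly.
    """
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    if np.any(lo >= hi):
        raise ValueError(f"empty crop: lo {tuple(lo)} must be < hi {tuple(hi)} per axis")
    origin = np.asarray(stack.origin)
    voxel = np.asarray(stack.voxel_size)
    shape = np.asarray(stack.shape_zyx)
    eps = 1e-9
    lo_idx = np.floor((lo - origin) / voxel + eps).astype(int)
    hi_idx = np.ceil((hi - origin) / voxel - eps).astype(int)
    if np.any(lo_idx < 0) or np.any(hi_idx > shape):
        raise ValueError(
            f"crop box [{tuple(lo)}, {tuple(hi)}) exceeds stack extent {stack.extent}"
        )
    if np.any(hi_idx <= lo_idx):
        raise ValueError("crop box intersects no voxels")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
    return ImageStack(
        data=stack.data[(slice(None),) + sl],
        voxel_size=stack.voxel_size,
        channel_names=list(stack.channel_names),
        origin=tuple(origin + lo_idx * voxel),
    )


# ---------------------------------------------------------------------------
# Acquisition-geometry arithmetic
# ---------------------------------------------------------------------------

def abbe_resolution(wavelength_nm: float, na: float) -> int:
    """Abbe diffraction limit λ/(2·NA), rounded to the nearest nanometer."""
    if wavelength_nm <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    return int(round(wavelength_nm / (2.0 * na)))


def lateral_pixel_size(extent_um: float, pixels: int, rounded: bool = True) -> float:
    """Pixel size extent/pixels (um); reported at 2 decimals by default."""
    if pixels < 1:
        raise ValueError("pixels must be >= 1")
    value = extent_um / pixels
    return round(value, 2) if rounded else value


def slices_spanned(diameter_um: float, z_step_um: float, n_offsets: int = 2001) -> int:
    """Minimum number of optical z-planes a sphere of given diameter intersects.

    The minimum is taken over all axial placements of the sphere center
    relative to the plane grid (spacing ``z_step_um``); a plane at axial
    position p intersects the sphere when ``|p - c| <= diameter/2``. A sphere
    must span >= 2 planes to be distinguishable from a single-slice artifact,
    which is what motivates a 0.6 um detection floor at 0.3 um z-steps.
    """
    if diameter_um <= 0 or z_step_um <= 0:
        raise ValueError("diameter and z_step must be positive")
    r = diameter_um / 2.0
    best = math.inf
    tol = 1e-9
    for offset in np.linspace(0.0, z_step_um, n_offsets, endpoint=False):
        # planes at k*z_step; sphere center at offset
        k_lo = math.ceil((offset - r - tol) / z_step_um)
        k_hi = math.floor((offset + r + tol) / z_step_um)
        count = sum(
            1 for k in range(k_lo, k_hi + 1) if abs(k * z_step_um - offset) <= r + tol
        )
        best = min(best, count)
    return int(best)


def _round_sig(value: float, sig: int) -> float:
    if value == 0:
        return 0.0
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))


def mass_to_molar(mass_conc_ug_per_ul: float, mw_da: float, sig: int = 2) -> float:
    """Convert a mass concentration (ug/uL) to pmol/uL given molecular weight (Da).

    1 ug/uL at 1 kDa is 1 nmol/uL = 1000 pmol/uL. Reported at 2 significant
    figures, matching the precision such concentrations are quoted at.
    """
    if mass_conc_ug_per_ul < 0 or mw_da <= 0:
        raise ValueError("mass concentration must be >= 0 and MW > 0")
    pmol_per_ul = mass_conc_ug_per_ul / mw_da * 1e6
    return _round_sig(pmol_per_ul, sig)
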