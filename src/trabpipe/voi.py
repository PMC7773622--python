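"""Standardized volume-of-interest (VOI) extraction from aligned CT slice stacks.

Clinical abdominopelvic CT arrives with heterogeneous pixel spacing and slice
thickness.  To make trabecular texture and density features comparable across
subjects, each anatomical region is reduced to a fixed physical volume of
16 mm x 16 mm x 24 mm and resampled onto a common 0.8 x 0.8 x 3 mm voxel grid,
i.e. a 20 x 20 x 8 voxel VOI of 8-bit gray values.  The processing chain is

    HU windowing -> slice selection -> in-plane ROI crop -> resampling.

Hounsfield units are windowed to [-150, 600] HU and linearly rescaled to
[0, 255]; this window targets trabecular bone on uncalibrated clinical CT.

Conventions (fixed and documented here because they matter for reproducing
voxel-exact output): arrays are indexed (row, col, slice), 0-based; the
physical position of a voxel center is (index + 0.5) * spacing; all mm<->voxel
conversions use voxel centers.  HU->8-bit rounding is half-away-from-zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SliceStack",
    "ROISpec",
    "VOIGrid",
    "window_hu",
    "select_slices",
    "crop_roi",
    "resample_voi",
    "extract_voi",
    "read_png_stack",
    "read_nifti_stack",
    "read_voi_nifti",
    "write_voi_nifti",
    "VOI_SHAPE",
    "VOI_SPACING",
    "HU_WINDOW",
    "ROI_SIZE_MM",
    "VOI_DEPTH_MM",
]

VOI_SHAPE = (20, 20, 8)
VOI_SPACING = (0.8, 0.8, 3.0)
HU_WINDOW = (-150.0, 600.0)
ROI_SIZE_MM = 16.0
VOI_DEPTH_MM = 24.0


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class SliceStack:
    """An axial CT slice stack, (row, col, slice), with isotropic in-plane spacing.

    ``is_hu`` flags whether ``values`` are calibrated Hounsfield units (floats)
    or already-windowed 8-bit gray values.
    """

    values: np.ndarray
    pixel_spacing: float
    slice_thickness: float
    is_hu: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("SliceStack expects a 3D (row, col, slice) array")
        if not self.pixel_spacing > 0:
            raise ValueError("pixel_spacing must be positive")
        if not self.slice_thickness > 0:
            raise ValueError("slice_thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]


@dataclass
class ROISpec:
    """In-plane rectangular ROI placed on a center slice.

    ``center`` is (row, col); ``center_unit`` selects whether it is given in mm
    (voxel-center convention) or in voxel indices on the slice.
    """

    center: tuple[float, float]
    center_slice_index: int
    size_mm: float = ROI_SIZE_MM
    depth_mm: float = VOI_DEPTH_MM
    center_unit: str = "mm"

    def __post_init__(self) -> None:
        if self.center_unit not in ("mm", "voxel"):
            raise ValueError("center_unit must be 'mm' or 'voxel'")
        if not (self.size_mm > 0 and self.depth_mm > 0):
            raise ValueError("ROI size and depth must be positive")


@dataclass
class VOIGrid:
    """A standardized VOI: 8-bit gray values on the common voxel grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = VOI_SPACING
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("VOIGrid expects a 3D array")
        if self.values.min() < 0 or self.values.max() > 255:
            raise ValueError("VOI gray values must lie in [0, 255]")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def window_hu(values_hu: np.ndarray, low: float = HU_WINDOW[0], high: float = HU_WINDOW[1]) -> np.ndarray:
    """Window HU values to ``[low, high]`` and linearly rescale to 8-bit gray.

    Values at or below ``low`` map to 0, at or above ``high`` to 255; the map
    is linear in between and monotone overall.
    """
    if not low < high:
        raise ValueError("HU window requires low < high")
    arr = np.asarray(values_hu, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite HU value at voxel index {idx}")
    scaled = (arr - low) * (255.0 / (high - low))
    out = _round_half_away(np.clip(scaled, 0.0, 255.0))
    return out.astype(np.uint8)


def select_slices(
    n_available: int,
    center_index: int,
    slice_thickness: float,
    depth: float = VOI_DEPTH_MM,
) -> list[int]:
    """Indices of the contiguous slice window covering ``depth`` mm around a center.

    The slice count is round(depth / thickness).  For even counts the window
    takes one extra slice below the center (floor(n/2) below, n-1-floor(n/2)
    above), a fixed deterministic convention.
    """
    if not slice_thickness > 0:
        raise ValueError("slice_thickness must be positive")
    ratio = depth / slice_thickness
    n = max(1, int(round(ratio)))
    if abs(ratio - round(ratio)) > 0.25:
        warnings.warn(
            f"depth/thickness ratio {ratio:.3f} is far from integer; using {n} slices",
            stacklevel=2,
        )
    below = n // 2
    above = n - 1 - below
    lo, hi = center_index - below, center_index + above
    if lo < 0 or hi >= n_available:
        raise ValueError(
            f"slice window [{lo}, {hi}] needs {n} slices around index "
            f"{center_index} but only {n_available} are available"
        )
    return list(range(lo, hi + 1))


def _center_to_voxel(center: float, spacing: float) -> float:
    # voxel-center convention: physical x sits at fractional index x/spacing - 0.5
    return center / spacing - 0.5


def crop_roi(stack: SliceStack, roi: ROISpec) -> SliceStack:
    """Crop the ROI patch from every selected slice, at a fixed in-plane position.

    The patch side is round(size_mm / pixel_spacing) pixels; the same rows and
    columns are used on every slice of the depth window.
    """
    side = int(round(roi.size_mm / stack.pixel_spacing))
    if side < 1:
        raise ValueError("ROI smaller than one pixel")
    if roi.center_unit == "mm":
        cr = _center_to_voxel(roi.center[0], stack.pixel_spacing)
        cc = _center_to_voxel(roi.center[1], stack.pixel_spacing)
    else:
        cr, cc = float(roi.center[0]), float(roi.center[1])
    r0 = int(round(cr - side / 2 + 0.5))
    c0 = int(round(cc - side / 2 + 0.5))
    r1, c1 = r0 + side, c0 + side
    nr, nc = stack.values.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
        clipped = (max(r0, 0), min(r1, nr), max(c0, 0), min(c1, nc))
        raise ValueError(
            f"ROI rows [{r0}, {r1}) cols [{c0}, {c1}) exceeds slice bounds "
            f"({nr}, {nc}); in-bounds extent would be rows [{clipped[0]}, {clipped[1]}) "
            f"cols [{clipped[2]}, {clipped[3]})"
        )
    idx = select_slices(stack.n_slices, roi.center_slice_index, stack.slice_thickness, roi.depth_mm)
    patch = stack.values[r0:r1, c0:c1, idx[0] : idx[-1] + 1]
    return SliceStack(patch, stack.pixel_spacing, stack.slice_thickness, is_hu=stack.is_hu)


def resample_voi(
    cropped: np.ndarray | SliceStack,
    in_spacing: tuple[float, float, float] | None = None,
    out_spacing: tuple[float, float, float] = VOI_SPACING,
    through_plane_order: int = 1,
) -> VOIGrid:
    """Resample a cropped ROI stack onto the common voxel grid.

    In-plane interpolation is bicubic (cubic spline); the through-plane axis is
    interpolated linearly by default because the axial direction carries at
    most 8 samples, too few for useful cubic support (``through_plane_order=3``
    switches it).  Resampling is alignment-preserving in the voxel-center
    convention and the output is clamped to [0, 255].
    """
    if isinstance(cropped, SliceStack):
        values = cropped.values
        in_spacing = (cropped.pixel_spacing, cropped.pixel_spacing, cropped.slice_thickness)
    else:
        values = np.asarray(cropped)
        if in_spacing is None:
            raise ValueError("in_spacing is required for a bare array")
    extent = np.array(values.shape, dtype=float) * np.array(in_spacing, dtype=float)
    target_extent = (ROI_SIZE_MM, ROI_SIZE_MM, VOI_DEPTH_MM)
    out_shape = []
    for ax in range(3):
        n_out = int(round(extent[ax] / out_spacing[ax]))
        if abs(extent[ax] - target_extent[ax]) > out_spacing[ax] / 2:
            raise ValueError(
                f"axis {ax}: physical extent {extent[ax]:.2f} mm deviates from "
                f"{target_extent[ax]:.2f} mm by more than half an output voxel"
            )
        out_shape.append(n_out)

    vol = values.astype(float)
    # fractional input index for each output voxel center, per axis
    coords = [
        ((np.arange(out_shape[ax]) + 0.5) * out_spacing[ax]) / in_spacing[ax] - 0.5
        for ax in range(3)
    ]
    # stage 1: bicubic in-plane at the original slice positions
    rr, cc, ss = np.meshgrid(coords[0], coords[1], np.arange(values.shape[2], dtype=float), indexing="ij")
    stage1 = ndimage.map_coordinates(vol, [rr, cc, ss], order=3, mode="nearest")
    # stage 2: through-plane interpolation of the in-plane-resampled stack
    rr2, cc2, ss2 = np.meshgrid(
        np.arange(out_shape[0], dtype=float),
        np.arange(out_shape[1], dtype=float),
        coords[2],
        indexing="ij",
    )
    out = ndimage.map_coordinates(stage1, [rr2, cc2, ss2], order=through_plane_order, mode="nearest")
    out = _round_half_away(np.clip(out, 0.0, 255.0)).astype(np.uint8)
    return VOIGrid(out, tuple(out_spacing))


def extract_voi(
    stack: SliceStack,
    roi: ROISpec,
    hu_window: tuple[float, float] = HU_WINDOW,
    out_spacing: tuple[float, float, float] = VOI_SPACING,
) -> VOIGrid:
    """Full chain: (window if HU) -> slice selection + crop -> resample."""
    if stack.is_hu:
        stack = SliceStack(
            window_hu(stack.values, *hu_window),
            stack.pixel_spacing,
            stack.slice_thickness,
            is_hu=False,
        )
    cropped = crop_roi(stack, roi)
    voi = resample_voi(cropped, out_spacing=out_spacing)
    voi.meta.update(
        {
            "roi_center": list(roi.center),
            "roi_center_unit": roi.center_unit,
            "center_slice_index": roi.center_slice_index,
            "hu_window": list(hu_window) if stack.is_hu else None,
        }
    )
    return voi


# ---------------------------------------------------------------------------
# I/O


def read_png_stack(directory: str | Path, pixel_spacing: float, slice_thickness: float) -> SliceStack:
    """Read a directory of equally-sized 8-bit PNG slices ordered by filename."""
    import imageio.v3 as iio

    paths = sorted(Path(directory).glob("*.png"))
    if not paths:
        raise FileNotFoundError(f"no PNG slices in {directory}")
    slices = [np.asarray(iio.imread(p)) for p in paths]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"PNG slices differ in shape: {sorted(shapes)}")
    vol = np.stack(slices, axis=2)
    if vol.ndim != 3:
        raise ValueError("PNG slices must be single-channel grayscale")
    return SliceStack(vol, pixel_spacing, slice_thickness, is_hu=False)


def read_nifti_stack(path: str | Path, is_hu: bool | None = None) -> SliceStack:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if abs(zooms[0] - zooms[1]) > 1e-6:
        raise ValueError("anisotropic in-plane spacing is not supported")
    if is_hu is None:
        is_hu = vol.min() < 0 or vol.max() > 255
    return SliceStack(vol, float(zooms[0]), float(zooms[2]), is_hu=bool(is_hu))


def write_voi_nifti(voi: VOIGrid, path: str | Path) -> None:
    """Write a VOI as NIfTI plus a JSON sidecar with spacing and provenance."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(voi.spacing) + [1.0])
    nib.save(nib.Nifti1Image(voi.values, affine), str(path))
    sidecar = {"spacing_mm": list(voi.spacing), **voi.meta}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_voi_nifti(path: str | Path) -> VOIGrid:
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {}
    sidecar = Path(path).with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        meta.pop("spacing_mm", None)
    return VOIGrid(vol, zooms, meta)
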