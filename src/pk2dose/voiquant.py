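"""Partial-method image quantification.

Instead of contouring whole organs, a handful of small cubic volumes of
interest (VOIs, default five of 1 mm³ per organ, three for bone) are placed
inside each organ mask — non-overlapping and separated by a minimum gap —
and the organ concentration is the mean over all voxels of all VOIs. The
module also provides the whole-organ reference statistics, the remainder-body
activity and the tumour-to-lung signal-to-noise ratio used to pick the best
imaging time point.

Boxes are axis-aligned and snapped to the voxel grid (a 1 mm cube at 251 μm
voxels rasterises to 4 voxels per edge); the inter-box distance is the
Euclidean gap between nearest faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import InvalidInputError


class InfeasibleVOIError(RuntimeError):
    """Raised when the requested number of spaced VOIs cannot be placed."""


@dataclass
class VoxelVolume:
    """3-D activity-concentration grid (kBq/mL) with its voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError("volume must be 3-D")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise InvalidInputError("voxels must be finite and >= 0")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidInputError("voxel size must be three positive lengths")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def voxel_volume_mL(self) -> float:
        dx, dy, dz = self.voxel_size_mm
        return dx * dy * dz / 1000.0  # mm³ -> mL


@dataclass
class LabelMask:
    """Integer label grid aligned with a VoxelVolume; 0 is background."""

    labels: np.ndarray
    region_names: dict  # label -> region

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidInputError("mask must be 3-D")
        if np.any(self.labels < 0):
            raise InvalidInputError("labels must be >= 0")

    def label_of(self, region: str) -> int:
        for lab, name in self.region_names.items():
            if name == region:
                return int(lab)
        raise InvalidInputError(f"region {region!r} not in mask")


@dataclass(frozen=True)
class VOIBox:
    """Axis-aligned cubic VOI, grid-snapped.

    ``index0`` is the low corner in voxel indices, ``shape_vox`` the box edge
    lengths in voxels.
    """

    region: str
    index0: tuple
    shape_vox: tuple
    voxel_size_mm: tuple

    @property
    def slices(self) -> tuple:
        return tuple(
            slice(i, i + n) for i, n in zip(self.index0, self.shape_vox)
        )

    @property
    def center_mm(self) -> tuple:
        return tuple(
            (i + n / 2.0) * v
            for i, n, v in zip(self.index0, self.shape_vox, self.voxel_size_mm)
        )

    def face_gap_mm(self, other: "VOIBox") -> float:
        """Euclidean distance between nearest faces (0 if touching/overlapping)."""
        gaps = []
        for i1, n1, i2, n2, v in zip(
            self.index0, self.shape_vox, other.index0, other.shape_vox, self.voxel_size_mm
        ):
            lo1, hi1 = i1 * v, (i1 + n1) * v
            lo2, hi2 = i2 * v, (i2 + n2) * v
            gaps.append(max(lo2 - hi1, lo1 - hi2, 0.0))
        return float(np.sqrt(sum(g * g for g in gaps)))

    def overlaps(self, other: "VOIBox") -> bool:
        return all(
            i1 < i2 + n2 and i2 < i1 + n1
            for i1, n1, i2, n2 in zip(
                self.index0, self.shape_vox, other.index0, other.shape_vox
            )
        )


def _edge_voxels(edge_mm: float, voxel_size_mm) -> tuple:
    return tuple(max(1, round(edge_mm / v)) for v in voxel_size_mm)


def sample_partial_vois(
    mask: LabelMask,
    region: str,
    k: int = 5,
    edge_mm: float = 1.0,
    min_gap_mm: float = 1.0,
    seed: int = 0,
    voxel_size_mm=(0.251, 0.251, 0.251),
    max_attempts: int = 20000,
) -> list:
    """Place ``k`` disjoint, spaced cubic VOIs fully inside a region mask.

    Rejection sampling over candidate low corners, deterministic under the
    seed; raises :class:`InfeasibleVOIError` when the attempt budget runs out
    (region too small for the requested layout).
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    label = mask.label_of(region)
    inside = mask.labels == label
    if not inside.any():
        raise InvalidInputError(f"region {region!r} empty in mask")
    shape_vox = _edge_voxels(edge_mm, voxel_size_mm)
    # valid low corners: every voxel of the box carries the region label
    valid = inside.copy()
    for axis, n in enumerate(shape_vox):
        sl = [slice(None)] * 3
        acc = np.ones_like(valid)
        for off in range(n):
            shifted = np.zeros_like(valid)
            idx = [slice(None)] * 3
            src = [slice(None)] * 3
            idx[axis] = slice(0, valid.shape[axis] - off)
            src[axis] = slice(off, valid.shape[axis])
            shifted[tuple(idx)] = valid[tuple(src)]
            acc &= shifted
        valid = acc
        del sl
    corners = np.argwhere(valid)
    if corners.shape[0] == 0:
        raise InfeasibleVOIError(
            f"region {region!r} cannot contain a single {edge_mm} mm box"
        )
    rng = np.random.default_rng(seed)
    boxes: list = []
    attempts = 0
    while len(boxes) < k:
        if attempts >= max_attempts:
            raise InfeasibleVOIError(
                f"could not place {k} spaced {edge_mm} mm boxes in {region!r} "
                f"after {max_attempts} attempts (placed {len(boxes)})"
            )
        attempts += 1
        corner = corners[rng.integers(corners.shape[0])]
        cand = VOIBox(
            region=region,
            index0=tuple(int(x) for x in corner),
            shape_vox=shape_vox,
            voxel_size_mm=tuple(voxel_size_mm),
        )
        ok = all(
            (not cand.overlaps(b)) and cand.face_gap_mm(b) >= min_gap_mm
            for b in boxes
        )
        if ok:
            boxes.append(cand)
    return boxes


def _collect_voxels(vol: VoxelVolume, vois) -> np.ndarray:
    vois = list(vois)
    if not vois:
        raise InvalidInputError("need at least one VOI")
    chunks = []
    for b in vois:
        for i, n, dim in zip(b.index0, b.shape_vox, vol.data.shape):
            if i < 0 or i + n > dim:
                raise InvalidInputError(f"VOI at {b.index0} outside the grid")
        chunks.append(vol.data[b.slices].ravel())
    return np.concatenate(chunks)


def voi_stats(vol: VoxelVolume, vois) -> tuple:
    """(mean kBq/mL, CV %) over all voxels of all VOIs."""
    vox = _collect_voxels(vol, vois)
    mean = float(np.mean(vox))
    cv = 100.0 * float(np.std(vox, ddof=1)) / mean if vox.size > 1 and mean != 0 else 0.0
    return mean, cv


def whole_organ_stats(vol: VoxelVolume, mask: LabelMask, region: str) -> tuple:
    """(mean, CV %) over every voxel of the full organ contour."""
    if vol.data.shape != mask.labels.shape:
        raise InvalidInputError("volume and mask shapes differ")
    vox = vol.data[mask.labels == mask.label_of(region)]
    if vox.size == 0:
        raise InvalidInputError(f"region {region!r} empty in mask")
    mean = float(np.mean(vox))
    cv = 100.0 * float(np.std(vox, ddof=1)) / mean if vox.size > 1 and mean != 0 else 0.0
    return mean, cv


def region_activity_kBq(vol: VoxelVolume, mask: LabelMask, region: str) -> float:
    """Total activity in a region: Σ concentration · voxel volume."""
    mean, _ = whole_organ_stats(vol, mask, region)
    n = int(np.sum(mask.labels == mask.label_of(region)))
    return mean * n * vol.voxel_volume_mL


def remainder_body_activity(total_body_kBq: float, organ_kBq) -> float:
    """Total-body activity minus the explicitly quantified organs."""
    if total_body_kBq < 0:
        raise InvalidInputError("total_body_kBq must be >= 0")
    organ_sum = float(sum(organ_kBq))
    remainder = total_body_kBq - organ_sum
    if remainder < 0:
        raise InvalidInputError(
            f"organ activities exceed total body by {-remainder:.6g} kBq"
        )
    return remainder


def snr(tumour_conc: float, lung_conc: float) -> float:
    """Tumour-to-lung concentration ratio (image signal-to-noise)."""
    if lung_conc <= 0:
        raise InvalidInputError("lung concentration must be > 0")
    return tumour_conc / lung_conc


# ---------------------------------------------------------------------------
# Volume I/O: raw float32 + JSON sidecar (NIfTI optional, when nibabel is
# importable)
# ---------------------------------------------------------------------------


def write_volume(vol: VoxelVolume, data_path, sidecar_path) -> None:
    np.asarray(vol.data, dtype=np.float32).tofile(data_path)
    with open(sidecar_path, "w") as fh:
        json.dump(
            {"shape": list(vol.data.shape), "voxel_size_mm": list(vol.voxel_size_mm)},
            fh,
        )


def read_volume(data_path, sidecar_path) -> VoxelVolume:
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    data = np.fromfile(data_path, dtype=np.float32).reshape(meta["shape"])
    return VoxelVolume(data=data.astype(float), voxel_size_mm=tuple(meta["voxel_size_mm"]))


def write_nifti(vol: VoxelVolume, path) -> None:
    """Write the volume as NIfTI (requires nibabel)."""
    import nibabel as nib

    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_nifti(path) -> VoxelVolume:
    """Read a NIfTI volume (requires nibabel); voxel size from the affine."""
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VoxelVolume(
        data=np.asarray(img.get_fdata(), dtype=float),
        voxel_size_mm=tuple(float(z) for z in zooms),
    )
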