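"""Volume I/O, lesion bookkeeping, ROI extraction and gray-level quantization.

The analysis operates on a lesion-centred sub-volume of 21 x 21 x 3 voxels
(in-plane window of 21 x 21 on three consecutive axial slices), uniformly
quantized to ``Ng`` = 32 gray levels before any texture matrix is built.
Quantization bins are equal-width over the patch's own intensity range, which
makes every downstream texture feature invariant to affine intensity
rescaling of the scanner output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: in-plane half-width, in-plane half-width, through-plane half-width
ROI_SHAPE = (21, 21, 3)
DEFAULT_NG = 32

# Gleason score string -> (three-group label, five-tier grade group)
_GS_TABLE = {
    "2": (1, 1),
    "3": (1, 1),
    "4": (1, 1),
    "5": (1, 1),
    "6": (1, 1),
    "3+3": (1, 1),
    "3+4": (2, 2),
    "4+3": (3, 3),
    "8": (3, 4),
    "3+5": (3, 4),
    "5+3": (3, 4),
    "4+4": (3, 4),
    "9": (3, 5),
    "4+5": (3, 5),
    "5+4": (3, 5),
    "10": (3, 5),
    "5+5": (3, 5),
}


def gleason_to_group(gleason_score: str, scheme: str = "three") -> int:
    """Map a Gleason score string to a group label.

    The three-group scheme pools the five Gleason grade groups into
    G1 (GS <= 6), G2 (GS = 3+4) and G3 (primary pattern 4 or higher:
    4+3, 8, 9 or 10).  The five-group scheme returns the grade group
    itself (1: <=6, 2: 3+4, 3: 4+3, 4: 8, 5: 9-10).

    Parameters
    ----------
    gleason_score : str
        e.g. ``"6"``, ``"3+4"``, ``"4+3"``, ``"8"``, ``"9"``, ``"10"``.
    scheme : {"three", "five"}
    """
    key = str(gleason_score).strip().replace(" ", "")
    if key not in _GS_TABLE:
        raise ValueError(f"unrecognized Gleason score string: {gleason_score!r}")
    three, five = _GS_TABLE[key]
    if scheme == "three":
        return three
    if scheme == "five":
        return five
    raise ValueError(f"unknown grouping scheme: {scheme!r}")


@dataclass
class MRIVolume:
    """A single modality's 3D intensity volume in (x, y, z) array order."""

    voxels: np.ndarray
    modality: str = "T2"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got rank {self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LesionRecord:
    """One lesion: centroid voxel coordinate and its pathology grade."""

    patient_id: str
    centroid: tuple[int, int, int]
    gleason_score: str
    group: int = field(default=0)

    def __post_init__(self) -> None:
        self.centroid = tuple(int(c) for c in self.centroid)
        derived = gleason_to_group(self.gleason_score)
        if self.group == 0:
            self.group = derived
        elif self.group != derived:
            raise ValueError(
                f"group {self.group} inconsistent with Gleason score "
                f"{self.gleason_score!r} (expected {derived})"
            )


@dataclass
class ROIPatch:
    """Lesion-centred 21 x 21 x 3 real-valued sub-volume."""

    voxels: np.ndarray
    modality: str = "T2"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.shape != ROI_SHAPE:
            raise ValueError(
                f"ROI patch must have shape {ROI_SHAPE}, got {self.voxels.shape}"
            )


@dataclass
class QuantizedPatch:
    """Integer patch with gray levels in 1..Ng."""

    levels: np.ndarray
    ng: int = DEFAULT_NG

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        if self.levels.size == 0:
            raise ValueError("empty patch")
        if self.levels.min() < 1 or self.levels.max() > self.ng:
            raise ValueError(
                f"levels must lie in 1..{self.ng}, got range "
                f"[{self.levels.min()}, {self.levels.max()}]"
            )


def read_volume(path, modality: str = "T2") -> MRIVolume:
    """Read a NIfTI volume into (x, y, z) array order with header spacing."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise FileNotFoundError(f"volume file not found: {path}")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume at {path}, got rank {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MRIVolume(voxels=data, modality=modality, spacing=spacing)


def write_volume(volume: MRIVolume, path) -> None:
    """Write a volume as NIfTI with a diagonal affine from its spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def normalize_volume(volume: MRIVolume, method: str = "minmax") -> MRIVolume:
    """Rescale the whole volume's intensities to reduce inter-scan variation.

    ``minmax`` maps the volume linearly onto [0, 1]; a constant volume maps
    to all zeros.  ``zscore`` subtracts the mean and divides by the SD.
    """
    v = volume.voxels
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize non-finite intensities")
    if method == "minmax":
        lo, hi = float(v.min()), float(v.max())
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    elif method == "zscore":
        sd = float(v.std())
        out = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return MRIVolume(voxels=out, modality=volume.modality, spacing=volume.spacing)


def extract_roi(volume: MRIVolume, centroid, patient_id: str = "") -> ROIPatch:
    """Extract the 21 x 21 x 3 window centred on the lesion centroid.

    The window spans centroid +/- 10 in x and y and centroid +/- 1 in z.  A
    window that would cross a volume boundary is shifted minimally to fit
    (and a warning is logged) rather than padded: padding would inject
    artificial homogeneous zones into the size-zone statistics.
    """
    shape = volume.shape
    if any(s < r for s, r in zip(shape, ROI_SHAPE)):
        raise ValueError(
            f"volume shape {shape} smaller than ROI window {ROI_SHAPE}"
        )
    half = tuple(r // 2 for r in ROI_SHAPE)
    starts = []
    shifted = False
    for axis, (c, h, r, s) in enumerate(zip(centroid, half, ROI_SHAPE, shape)):
        start = int(c) - h
        clipped = min(max(start, 0), s - r)
        if clipped != start:
            shifted = True
        starts.append(clipped)
    if shifted:
        logger.warning(
            "ROI window for centroid %s shifted to fit volume of shape %s "
            "(patient %s)", tuple(centroid), shape, patient_id or "<unknown>",
        )
    sl = tuple(slice(st, st + r) for st, r in zip(starts, ROI_SHAPE))
    return ROIPatch(
        voxels=volume.voxels[sl].copy(),
        modality=volume.modality,
        patient_id=patient_id,
    )


def quantize(patch: ROIPatch | np.ndarray, ng: int = DEFAULT_NG) -> QuantizedPatch:
    """Uniformly quantize a patch to ``ng`` gray levels over its own range.

    level = min(ng, floor((v - min) / (max - min) * ng) + 1); a constant
    patch maps to all level 1.  The map is monotone in intensity and
    invariant to positive affine transforms of the patch.
    """
    if ng < 2:
        raise ValueError(f"need at least 2 gray levels, got {ng}")
    v = patch.voxels if isinstance(patch, ROIPatch) else np.asarray(patch, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        levels = np.ones(v.shape, dtype=np.int64)
    else:
        levels = np.floor((v - lo) / (hi - lo) * ng).astype(np.int64) + 1
        np.minimum(levels, ng, out=levels)
    return QuantizedPatch(levels=levels, ng=ng)
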