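"""Synthetic mpMRI cohort generator with group-dependent zone-size texture.

The generator's purpose is to produce cohorts in which the three
Gleason-score groups differ in the *spatial zone-size structure* of the
lesion, the property the size-zone (GLSZM) features measure: group 1
lesions are built from a few large homogeneous blobs, group 3 lesions from
many small fragmented ones.  Consequently large-zone-size emphasis
decreases, and zone-size percentage increases, with group index — the sign
pattern the screening stage is expected to recover.

Lesion texture model: homogeneous spherical blobs of group-dependent mean
diameter are stamped in random order over a mid-gray background (later
blobs overwrite earlier ones), then i.i.d. Gaussian noise is added and the
result clipped to [0, 1].  Blob count scales with patch volume / blob
volume so coverage is dense at every scale.  Everything is a pure function
of the cohort spec, including its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import LesionRecord, MRIVolume, ROI_SHAPE, write_volume

logger = logging.getLogger(__name__)

_ROI_MARGIN = tuple(r // 2 for r in ROI_SHAPE)  # (10, 10, 1)

# Gleason score strings available per three-group label; group 3 spans the
# full "primary pattern >= 4" range so the five-tier grade-group reanalysis
# has patients in bins 3, 4 and 5.
_GS_CHOICES = {1: ("6",), 2: ("3+4",), 3: ("4+3", "8", "9", "10")}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic three-group cohort.

    blob_scale_per_group is the mean homogeneous-blob diameter in voxels
    for groups 1..3 and must be strictly decreasing: fragmentation grows
    with grade.  Setting all three equal is the supported "null" mode used
    for calibration experiments (groups become exchangeable).
    """

    n_per_group: int = 30
    volume_shape: tuple[int, int, int] = (64, 64, 19)
    lesion_radius: int = 12
    blob_scale_per_group: tuple[float, float, float] = (9.0, 5.0, 2.0)
    noise_sd: float = 0.05
    background_level: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if any(v < r for v, r in zip(self.volume_shape, ROI_SHAPE)):
            raise ValueError(
                f"volume shape {self.volume_shape} cannot contain a "
                f"{ROI_SHAPE} ROI"
            )
        if any(b <= 0 for b in self.blob_scale_per_group):
            raise ValueError("blob scales must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def is_null(self) -> bool:
        return len(set(self.blob_scale_per_group)) == 1


@dataclass
class SyntheticPatient:
    patient_id: str
    t2_volume: MRIVolume
    adc_volume: MRIVolume
    lesion: LesionRecord
    true_group: int


def generate_lesion_texture(
    group: int,
    patch_shape: tuple[int, int, int],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One lesion texture patch with the group's blob-size distribution.

    Returns intensities in [0, 1].  Deterministic given the generator
    state.  Blob diameters are jittered by +/-30% around the group's mean
    scale; blob intensities are uniform in [0, 1].
    """
    if group not in (1, 2, 3):
        raise ValueError(f"invalid group index: {group!r}")
    if any(p < r for p, r in zip(patch_shape, ROI_SHAPE)):
        raise ValueError(
            f"patch shape {patch_shape} smaller than ROI {ROI_SHAPE}"
        )
    scale = spec.blob_scale_per_group[group - 1]
    patch = np.full(patch_shape, 0.5, dtype=float)
    volume = float(np.prod(patch_shape))
    blob_volume = (np.pi / 6.0) * scale**3
    n_blobs = max(1, int(np.ceil(2.0 * volume / blob_volume)))
    grid = np.indices(patch_shape).astype(float)
    for _ in range(n_blobs):
        centre = rng.uniform(0, 1, size=3) * (np.array(patch_shape) - 1)
        radius = 0.5 * scale * rng.uniform(0.7, 1.3)
        intensity = rng.uniform(0.0, 1.0)
        d2 = sum((grid[a] - centre[a]) ** 2 for a in range(3))
        patch[d2 <= radius**2] = intensity
    if spec.noise_sd > 0:
        patch = patch + rng.normal(0.0, spec.noise_sd, size=patch_shape)
    return np.clip(patch, 0.0, 1.0)


def _patient_volume(
    group: int,
    spec: CohortSpec,
    centroid: tuple[int, int, int],
    modality: str,
    rng: np.random.Generator,
) -> MRIVolume:
    """Quiet noisy background with the lesion texture stamped at the centroid."""
    shape = spec.volume_shape
    vox = spec.background_level + rng.normal(0.0, 0.02, size=shape)
    lesion_shape = ROI_SHAPE
    texture = generate_lesion_texture(group, lesion_shape, spec, rng)
    sl = tuple(
        slice(c - m, c - m + r)
        for c, m, r in zip(centroid, _ROI_MARGIN, lesion_shape)
    )
    vox[sl] = texture
    vox = np.clip(vox, 0.0, 1.0)
    # arbitrary scanner-like output scales; downstream quantization is
    # affine-invariant so these only exercise the normalization path
    if modality == "T2":
        vox = vox * 800.0 + 200.0
        spacing = (0.5, 0.5, 3.6)
    else:
        vox = vox * 2000.0 + 500.0
        spacing = (2.0, 2.0, 3.6)
    return MRIVolume(voxels=vox, modality=modality, spacing=spacing)


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate 3 x n_per_group patients, pure function of the spec."""
    patients: list[SyntheticPatient] = []
    idx = 0
    shape = np.array(spec.volume_shape)
    margin = np.array(_ROI_MARGIN)
    for group in (1, 2, 3):
        for _ in range(spec.n_per_group):
            idx += 1
            rng = np.random.default_rng([spec.seed, idx])
            centroid = tuple(
                int(rng.integers(m, s - m)) for m, s in zip(margin, shape)
            )
            gs = str(rng.choice(_GS_CHOICES[group]))
            t2 = _patient_volume(group, spec, centroid, "T2", rng)
            adc = _patient_volume(group, spec, centroid, "ADC", rng)
            lesion = LesionRecord(
                patient_id=f"SYN-{idx:03d}",
                centroid=centroid,
                gleason_score=gs,
            )
            patients.append(
                SyntheticPatient(
                    patient_id=lesion.patient_id,
                    t2_volume=t2,
                    adc_volume=adc,
                    lesion=lesion,
                    true_group=group,
                )
            )
    return patients


def null_spec(spec: CohortSpec, blob_scale: float | None = None) -> CohortSpec:
    """Spec with equal blob scales: groups exchangeable (calibration mode)."""
    b = blob_scale if blob_scale is not None else spec.blob_scale_per_group[1]
    return replace(spec, blob_scale_per_group=(b, b, b))


CSV_COMMENT = "# centroid columns x,y,z are 0-based voxel indices in (x, y, z) array order"


def write_cohort(
    patients: list[SyntheticPatient],
    out_dir,
    overwrite: bool = False,
) -> Path:
    """Write NIfTI volumes, the lesion CSV and a JSON manifest.

    Returns the manifest path.  Refuses to clobber existing files unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume_paths: dict[str, dict[str, str]] = {}
    planned = []
    for p in patients:
        planned.append((p, "T2", out / f"{p.patient_id}_t2.nii.gz"))
        planned.append((p, "ADC", out / f"{p.patient_id}_adc.nii.gz"))
    csv_path = out / "lesions.csv"
    manifest_path = out / "manifest.json"
    if not overwrite:
        clashes = [
            str(path)
            for path in [csv_path, manifest_path] + [pl[2] for pl in planned]
            if path.exists()
        ]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite existing files (pass overwrite=True): "
                f"{clashes[:3]}..."
            )
    for p, modality, path in planned:
        vol = p.t2_volume if modality == "T2" else p.adc_volume
        write_volume(vol, path)
        volume_paths.setdefault(p.patient_id, {})[modality] = path.name
    rows = [
        {
            "patient_id": p.patient_id,
            "x": p.lesion.centroid[0],
            "y": p.lesion.centroid[1],
            "z": p.lesion.centroid[2],
            "gleason_score": p.lesion.gleason_score,
            "group": p.lesion.group,
        }
        for p in patients
    ]
    with open(csv_path, "w") as fh:
        fh.write(CSV_COMMENT + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    manifest = {
        "n_patients": len(patients),
        "lesion_table": csv_path.name,
        "volumes": volume_paths,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2))
    logger.info("wrote %d patients to %s", len(patients), out)
    return manifest_path


def read_lesion_table(csv_path) -> list[LesionRecord]:
    """Read the lesion CSV (same dialect write_cohort emits)."""
    frame = pd.read_csv(csv_path, comment="#")
    records = []
    for _, row in frame.iterrows():
        records.append(
            LesionRecord(
                patient_id=str(row["patient_id"]),
                centroid=(int(row["x"]), int(row["y"]), int(row["z"])),
                gleason_score=str(row["gleason_score"]),
            )
        )
    return records
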