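"""Volume and table I/O, coordinate conversion, and seed time-series extraction.

Volumes are NIfTI-1 (``.nii``/``.nii.gz``) on a spatially normalized grid
(typically 3 mm isotropic MNI).  Tabular inputs are TSV with a header row:
ROI tables carry ``label, x_mm, y_mm, z_mm``; motion tables are six columns
(three translations in mm, three rotations in radians, one row per volume);
cohort tables are long-format clinical records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("TSZ", "DSZ", "HC")
TIMEPOINTS = ("t1", "t2")

#: columns of a long-format cohort table
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "timepoint",
    "age_years",
    "sex",
    "education_years",
    "illness_duration_months",
    "cpz_equiv_mg_per_day",
    "panss_positive",
    "panss_negative",
    "panss_general",
    "panss_total",
]


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as the expected format."""


class DimensionError(ValueError):
    """Raised when an image has the wrong number of dimensions."""


class SeedError(ValueError):
    """Raised when a seed coordinate falls outside the brain mask."""


@dataclass
class BoldVolumeSeries:
    """A 4D BOLD image with its voxel-to-MNI affine, TR, and brain mask.

    ``data`` is ``[X, Y, Z, T]``; ``brain_mask`` marks voxels that enter any
    analysis (default: voxels with nonzero temporal variance).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    brain_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DimensionError(f"expected a 4D array, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 volumes")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.brain_mask is None:
            self.brain_mask = self.data.std(axis=3) > 0
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal spatial shape")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SeedDefinition:
    """A labeled seed given by its MNI coordinate in millimetres."""

    label: str
    mni_mm: tuple[float, float, float]


@dataclass
class RoiTimeSeries:
    """Per-region BOLD time courses: ``values`` is ``[T, R]``."""

    values: np.ndarray
    labels: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a [T x R] matrix")
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("label count must match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate region labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def read_bold(path: str | Path, tr_seconds: float | None = None) -> BoldVolumeSeries:
    """Read a 4D NIfTI-1 BOLD image.

    TR is taken from the header (``pixdim[4]``) unless overridden.  The
    default brain mask keeps voxels with nonzero temporal variance.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI image at {path}: {exc}") from exc
    if img.ndim != 4:
        raise DimensionError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
        if tr_seconds <= 0:
            raise FormatError(f"{path}: header TR is {tr_seconds}; pass tr_seconds explicitly")
    return BoldVolumeSeries(data=data, affine=np.asarray(img.affine), tr_seconds=tr_seconds)


def write_bold(vol: BoldVolumeSeries, path: str | Path) -> None:
    """Write a BOLD series as NIfTI-1 float32 with TR in the header."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_seconds
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; MNI->voxel convention here is half away
    # from zero so that e.g. -0.5 -> -1 deterministically.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mni_to_voxel(
    mni_mm: tuple[float, float, float],
    affine: np.ndarray,
    shape: tuple[int, int, int] | None = None,
) -> tuple[int, int, int]:
    """Convert an MNI mm coordinate to the nearest voxel index.

    Applies the inverse affine and rounds half away from zero.  If ``shape``
    is given, an index outside the image raises ``IndexError``.
    """
    affine = np.asarray(affine, dtype=np.float64)
    inv = np.linalg.inv(affine)
    hom = np.append(np.asarray(mni_mm, dtype=np.float64), 1.0)
    ijk = _round_half_away(inv @ hom)[:3].astype(int)
    if shape is not None:
        if np.any(ijk < 0) or np.any(ijk >= np.asarray(shape[:3])):
            raise IndexError(f"MNI {tuple(mni_mm)} maps to voxel {tuple(ijk)} outside shape {shape[:3]}")
    return tuple(int(v) for v in ijk)


def voxel_to_mni(ijk: tuple[int, int, int], affine: np.ndarray) -> tuple[float, float, float]:
    """Map a voxel index to its MNI mm coordinate."""
    hom = np.append(np.asarray(ijk, dtype=np.float64), 1.0)
    xyz = np.asarray(affine, dtype=np.float64) @ hom
    return tuple(float(v) for v in xyz[:3])


#: the six face-adjacent offsets on a 3D grid
_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def seed_neighborhood(
    vol: BoldVolumeSeries, seed: SeedDefinition
) -> list[tuple[int, int, int]]:
    """In-bounds, in-mask voxel indices of the seed plus its six face neighbors.

    The seed voxel itself must be inside the brain mask; out-of-bounds or
    out-of-mask neighbors are dropped (with a logged warning), never
    zero-filled, so seeds at the cortical edge stay unbiased.
    """
    shape = vol.data.shape[:3]
    try:
        center = mni_to_voxel(seed.mni_mm, vol.affine, shape)
    except IndexError as exc:
        raise SeedError(f"seed '{seed.label}': {exc}") from exc
    if not vol.brain_mask[center]:
        raise SeedError(f"seed '{seed.label}' voxel {center} is outside the brain mask")
    kept = [center]
    dropped = 0
    for off in _FACE_NEIGHBORS:
        idx = tuple(int(v) for v in (np.asarray(center) + off))
        if any(i < 0 or i >= s for i, s in zip(idx, shape)):
            dropped += 1
            continue
        if not vol.brain_mask[idx]:
            dropped += 1
            continue
        kept.append(idx)
    if dropped:
        logger.warning(
            "seed '%s': dropped %d of 6 face neighbors (out of bounds or mask)",
            seed.label,
            dropped,
        )
    return kept


def extract_seed_series(vol: BoldVolumeSeries, seed: SeedDefinition) -> np.ndarray:
    """Mean time course over the seed voxel and its retained face neighbors.

    At most seven voxels contribute (the seed plus six face-adjacent voxels);
    neighbors outside the image or brain mask are dropped.
    """
    voxels = seed_neighborhood(vol, seed)
    series = np.stack([vol.data[idx] for idx in voxels], axis=0)
    return series.mean(axis=0)


def extract_roi_series(
    vol: BoldVolumeSeries, seeds: list[SeedDefinition]
) -> RoiTimeSeries:
    """Extract one averaged seed-neighborhood time course per ROI, in order."""
    if not seeds:
        raise ValueError("seed list is empty")
    labels = [s.label for s in seeds]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate seed labels")
    cols = [extract_seed_series(vol, s) for s in seeds]
    return RoiTimeSeries(
        values=np.column_stack(cols), labels=labels, tr_seconds=vol.tr_seconds
    )


# ---------------------------------------------------------------------------
# tabular I/O


def read_roi_table(path: str | Path) -> list[SeedDefinition]:
    """Read a TSV ROI table with columns ``label, x_mm, y_mm, z_mm``."""
    df = pd.read_csv(path, sep="\t")
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: ROI table needs columns {sorted(required)}")
    return [
        SeedDefinition(str(row.label), (float(row.x_mm), float(row.y_mm), float(row.z_mm)))
        for row in df.itertuples()
    ]


def read_motion(path: str | Path) -> np.ndarray:
    """Read a 6-column motion-parameter table (whitespace or tab separated)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise FormatError(f"{path}: motion table must have 6 columns, got {arr.shape[1]}")
    return arr


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort TSV."""
    df = pd.read_csv(path, sep="\t")
    return validate_cohort_table(df)


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check cohort-table invariants and return the frame.

    Invariants: known columns present; (subject_id, timepoint) unique; group
    and timepoint levels valid; healthy controls appear only at baseline and
    carry no symptom scores.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise FormatError(f"unknown group labels: {sorted(bad_groups)}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"unknown timepoints: {sorted(bad_tp)}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        raise FormatError("duplicate (subject_id, timepoint) records")
    hc = df[df["group"] == "HC"]
    if (hc["timepoint"] != "t1").any():
        raise FormatError("HC records must appear only at t1")
    panss_cols = ["panss_positive", "panss_negative", "panss_general", "panss_total"]
    if not hc.empty and hc[panss_cols].notna().to_numpy().any():
        raise FormatError("HC records must not carry PANSS scores")
    return df


def write_roi_series(rois: RoiTimeSeries, path: str | Path) -> None:
    """Write an ROI time-series matrix as labeled TSV (rows = volumes)."""
    pd.DataFrame(rois.values, columns=rois.labels).to_csv(path, sep="\t", index=False)


def read_roi_series(path: str | Path, tr_seconds: float) -> RoiTimeSeries:
    """Read a labeled TSV time-series matrix written by :func:`write_roi_series`."""
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        values=df.to_numpy(dtype=np.float64),
        labels=[str(c) for c in df.columns],
        tr_seconds=tr_seconds,
    )
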