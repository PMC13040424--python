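"""Label-volume I/O and coordinate conventions.

The toolkit consumes 3D multi-label segmentations of the late-gestation
uterocervix.  Voxel values follow a fixed tissue code:

====  =======================
code  tissue
====  =======================
0     background
1     outer cervical stroma
2     inner cervical stroma
3     cervical canal
4     canal cyst (optional)
5     lower-uterine-segment reference region (optional)
====  =======================

All geometry downstream is computed in world millimetres through the NIfTI
affine (voxel-centre convention: the world position of voxel index ``i`` is
``affine @ [i, 1]``), so anisotropic or oblique volumes are handled
uniformly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_OUTER_STROMA",
    "LABEL_INNER_STROMA",
    "LABEL_CANAL",
    "LABEL_CYST",
    "LABEL_UTERUS",
    "ALLOWED_LABELS",
    "LabelVolume",
    "UterineAxis",
    "QualityRecord",
    "read_label_volume",
    "write_label_volume",
    "load_uterine_axis",
    "read_quality_records",
]

LABEL_BACKGROUND = 0
LABEL_OUTER_STROMA = 1
LABEL_INNER_STROMA = 2
LABEL_CANAL = 3
LABEL_CYST = 4
LABEL_UTERUS = 5

ALLOWED_LABELS = frozenset(
    {LABEL_BACKGROUND, LABEL_OUTER_STROMA, LABEL_INNER_STROMA,
     LABEL_CANAL, LABEL_CYST, LABEL_UTERUS}
)


class LabelValidationError(ValueError):
    """Raised when voxel data violates the label scheme."""


@dataclass
class LabelVolume:
    """A 3D integer label map with physical geometry.

    Parameters
    ----------
    voxels
        3D integer array of tissue codes.
    affine
        4x4 voxel-to-world map in mm (voxel-centre convention).
    """

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise LabelValidationError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            flo = np.asarray(self.voxels, dtype=float)
            rounded = np.rint(flo)
            if np.max(np.abs(flo - rounded)) > 1e-6:
                raise LabelValidationError(
                    "voxel data is not integer-valued (off grid by >1e-6)")
            self.voxels = rounded.astype(np.int16)
        if self.affine.shape != (4, 4):
            raise LabelValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise LabelValidationError("affine is singular")
        bad = set(np.unique(self.voxels)) - ALLOWED_LABELS
        if bad:
            raise LabelValidationError(
                f"disallowed label values {sorted(bad)}; "
                f"allowed set is {sorted(ALLOWED_LABELS)}")
        if np.any(self.spacing <= 0):
            raise LabelValidationError("voxel spacing must be strictly positive")
        self._check_adjacency()

    def _check_adjacency(self) -> None:
        # Canal/cyst should touch inner stroma under 6-connectivity;
        # violation is anatomically suspicious but not fatal.
        inner = self.voxels == LABEL_INNER_STROMA
        if not inner.any():
            return
        dilated = ndimage.binary_dilation(
            inner, structure=ndimage.generate_binary_structure(3, 1))
        for code, name in ((LABEL_CANAL, "canal"), (LABEL_CYST, "cyst")):
            mask = self.voxels == code
            if mask.any() and not (mask & dilated).any():
                warnings.warn(
                    f"{name} voxels are not 6-adjacent to inner stroma",
                    stacklevel=3)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def labels_present(self) -> set[int]:
        return {int(v) for v in np.unique(self.voxels)}

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World-mm positions of voxel indices (n, 3) -> (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.voxels, labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (np.array_equal(self.voxels, other.voxels)
                and np.allclose(self.affine, other.affine, atol=1e-6))


@dataclass(frozen=True)
class UterineAxis:
    """Reference line through the lower uterine segment.

    ``point_a`` is the end nearer the cervix (internal os side) and
    ``point_b`` the end pointing into the uterine body; the direction
    a->b is therefore "away from the cervix", the orientation the
    utero-cervical angle is measured against.
    """

    point_a: np.ndarray
    point_b: np.ndarray
    source: str  # "sidecar" or "label5-fit"

    def __post_init__(self) -> None:
        a = np.asarray(self.point_a, dtype=float)
        b = np.asarray(self.point_b, dtype=float)
        object.__setattr__(self, "point_a", a)
        object.__setattr__(self, "point_b", b)
        if a.shape != (3,) or b.shape != (3,):
            raise ValueError("axis points must be 3-vectors")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValueError("axis points must be finite")
        if np.allclose(a, b):
            raise ValueError("axis points must be distinct")

    @property
    def direction(self) -> np.ndarray:
        d = self.point_b - self.point_a
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class QualityRecord:
    """Visual quality grades for one scan.

    Reconstruction grade: 1=failed, 2=poor, 3=acceptable, 4=good.
    Segmentation grade:   1=poor, 2=moderate, 3=good, 4=excellent.
    Grade 1 on either scale marks the scan for exclusion from analysis.
    """

    scan_id: str
    reconstruction_grade: int
    segmentation_grade: int

    def __post_init__(self) -> None:
        for g, name in ((self.reconstruction_grade, "reconstruction"),
                        (self.segmentation_grade, "segmentation")):
            if not (isinstance(g, (int, np.integer)) and 1 <= g <= 4):
                raise ValueError(f"{name} grade must be an integer in 1..4, got {g!r}")

    @property
    def excluded(self) -> bool:
        return self.reconstruction_grade == 1 or self.segmentation_grade == 1


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1/2 label map and validate it against the label scheme."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return LabelVolume(voxels=data, affine=np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a LabelVolume as NIfTI; read(write(v)) == v voxel-for-voxel."""
    img = nib.Nifti1Image(vol.voxels.astype(np.int16), vol.affine)
    nib.save(img, str(path))


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit first principal axis of a point cloud (covariance eigendecomposition)."""
    centred = points - points.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def load_uterine_axis(vol: LabelVolume,
                      sidecar: str | Path | None = None) -> UterineAxis:
    """Obtain the lower-uterine-segment reference line.

    A JSON sidecar with two explicit world-mm points takes precedence.
    Otherwise the line is fitted as the first principal axis of the
    label-5 (uterine reference) voxel cloud, oriented so that ``point_a``
    is the end nearer the cervical canal.
    """
    if sidecar is not None:
        with open(sidecar) as fh:
            payload = json.load(fh)
        ax = payload["uterine_axis"]
        return UterineAxis(point_a=np.asarray(ax["a"], dtype=float),
                           point_b=np.asarray(ax["b"], dtype=float),
                           source="sidecar")

    mask = vol.voxels == LABEL_UTERUS
    if not mask.any():
        raise ValueError(
            "no uterine reference available: provide a JSON sidecar with "
            '{"uterine_axis": {"a": [...], "b": [...]}} or segment a '
            f"label-{LABEL_UTERUS} lower-uterine-segment region")
    pts = vol.world_coords(np.argwhere(mask))
    centre = pts.mean(axis=0)
    axis = _principal_axis(pts)
    t = (pts - centre) @ axis
    end_lo, end_hi = centre + t.min() * axis, centre + t.max() * axis

    canal = vol.voxels == LABEL_CANAL
    if canal.any():
        canal_centre = vol.world_coords(np.argwhere(canal)).mean(axis=0)
    else:
        canal_centre = centre  # degenerate; orientation arbitrary but defined
    if np.linalg.norm(end_lo - canal_centre) <= np.linalg.norm(end_hi - canal_centre):
        a, b = end_lo, end_hi
    else:
        a, b = end_hi, end_lo
    return UterineAxis(point_a=a, point_b=b, source="label5-fit")


def read_quality_records(path: str | Path) -> list[QualityRecord]:
    """Read quality grades from CSV with columns scan_id, recon_grade, seg_grade."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"scan_id", "recon_grade", "seg_grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"quality CSV missing columns: {sorted(missing)}")
    return [
        QualityRecord(scan_id=str(r.scan_id),
                      reconstruction_grade=int(r.recon_grade),
                      segmentation_grade=int(r.seg_grade))
        for r in df.itertuples()
    ]
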