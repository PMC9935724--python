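"""Reading and writing the imaging and tabular formats used by the pipeline.

Images travel as NIfTI-1 (``.nii``/``.nii.gz``) via nibabel; diffusion
gradient tables use the FSL bval/bvec text dialect (one whitespace-delimited
row of b-values, three rows of x/y/z direction components); cohort tables are
plain CSV handled by pandas elsewhere. This module contains no science — it
only validates and moves data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError

#: b-values below this (s/mm^2) are classified as b = 0; vendor "b0" volumes
#: often carry a small residual diffusion weighting.
B0_THRESHOLD = 50.0

#: Default rotator-cuff label convention for muscle masks.
DEFAULT_LABEL_MAP = {0: "background", 1: "SSP", 2: "ISP", 3: "SSC"}


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Directions for diffusion-weighted volumes are renormalized to unit norm at
    construction; the direction stored for b = 0 volumes is irrelevant and
    kept as given.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValidationError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"bval/bvec length mismatch: {len(bvals)} b-values vs "
                f"{len(bvecs)} directions"
            )
        if not np.all(np.isfinite(bvals)) or not np.all(np.isfinite(bvecs)):
            raise ValidationError("non-finite values in gradient table")
        if np.any(bvals < 0):
            raise ValidationError("negative b-values are not physical")
        dw = bvals >= B0_THRESHOLD
        if not np.any(~dw):
            raise ValidationError("scheme contains no b = 0 volume")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(norms <= 0):
            raise ValidationError("zero-norm direction on a diffusion-weighted volume")
        bvecs = bvecs.copy()
        bvecs[dw] /= norms[:, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def effective_bvals(self) -> np.ndarray:
        """b-values with sub-threshold values mapped to exactly 0."""
        out = self.bvals.copy()
        out[out < B0_THRESHOLD] = 0.0
        return out

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def shells(self) -> np.ndarray:
        """Unique nonzero b-values, ascending."""
        eb = self.effective_bvals
        return np.unique(eb[eb > 0])

    def shell_mask(self, b: float) -> np.ndarray:
        return np.isclose(self.effective_bvals, b)


@dataclass
class DWIStack:
    """4D diffusion-weighted magnitude image plus its acquisition scheme."""

    data: np.ndarray
    voxel_size: np.ndarray
    scheme: AcquisitionScheme

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValidationError(f"DWI data must be 4D, got {data.ndim}D")
        if data.shape[3] != len(self.scheme):
            raise FormatError(
                f"volume-count mismatch: image has {data.shape[3]} volumes but "
                f"gradient table has {len(self.scheme)} entries"
            )
        if not np.all(np.isfinite(data)):
            raise ValidationError("non-finite intensities in DWI stack")
        if np.any(data < 0):
            raise ValidationError("negative intensities in DWI stack")
        vs = np.asarray(self.voxel_size, dtype=float).ravel()
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValidationError(f"voxel_size must be 3 positive floats, got {vs}")
        self.data = data
        self.voxel_size = vs

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ScalarMap:
    """3D scalar map (a fraction, FF, or sigma map) with voxel geometry.

    NaN marks invalid/background voxels; all other values must be finite.
    """

    data: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValidationError(f"scalar map must be 3D, got {data.ndim}D")
        if np.any(np.isinf(data)):
            raise ValidationError("infinite values in scalar map")
        vs = np.asarray(self.voxel_size, dtype=float).ravel()
        if vs.shape != (3,) or np.any(vs <= 0):
            raise ValidationError(f"voxel_size must be 3 positive floats, got {vs}")
        self.data = data
        self.voxel_size = vs


@dataclass
class MuscleMask:
    """Integer-labeled muscle segmentation on the image grid."""

    labels: np.ndarray
    label_map: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValidationError(f"mask must be 3D, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValidationError("mask labels must be integers")
            labels = labels.astype(np.int16)
        declared = set(self.label_map)
        present = set(np.unique(labels).tolist())
        if not present <= declared:
            raise ValidationError(
                f"mask contains undeclared labels {sorted(present - declared)}"
            )
        self.labels = labels

    def voxel_count(self, label: int) -> int:
        return int(np.sum(self.labels == label))

    def muscles(self) -> dict:
        """Non-background labels present in the mask, as {label: name}."""
        return {
            lab: name
            for lab, name in self.label_map.items()
            if lab != 0 and self.voxel_count(lab) > 0
        }


def _affine(voxel_size: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_bval_bvec(bval_path, bvec_path) -> AcquisitionScheme:
    """Parse FSL-dialect bval/bvec text files into a scheme."""
    bvals = np.loadtxt(bval_path, ndmin=1, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is rows = components
        bvecs = bvecs.T
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise FormatError(f"bvec file must have 3 rows (x/y/z), parsed {bvecs.shape}")
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_bval_bvec(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_dwi(image_path, bval_path, bvec_path) -> DWIStack:
    """Load a 4D DWI NIfTI with its FSL gradient table."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D volume at {image_path}, got {data.ndim}D")
    scheme = read_bval_bvec(bval_path, bvec_path)
    if data.shape[3] != len(scheme):
        raise FormatError(
            f"volume-count mismatch: image has {data.shape[3]} volumes but "
            f"gradient table has {len(scheme)} entries"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIStack(data=data, voxel_size=voxel_size, scheme=scheme)


def write_dwi(stack: DWIStack, image_path, bval_path=None, bvec_path=None) -> None:
    img = nib.Nifti1Image(stack.data.astype(np.float32), _affine(stack.voxel_size))
    img.header.set_zooms((*stack.voxel_size, 1.0))
    nib.save(img, str(image_path))
    if bval_path is not None and bvec_path is not None:
        write_bval_bvec(stack.scheme, bval_path, bvec_path)


def read_scalar_map(path, expect_voxel_size=None) -> ScalarMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D map at {path}, got {data.ndim}D")
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if expect_voxel_size is not None and not np.allclose(
        voxel_size, expect_voxel_size, atol=1e-4
    ):
        raise ValidationError(
            f"grid mismatch: file voxel size {voxel_size} vs expected "
            f"{np.asarray(expect_voxel_size, dtype=float)}"
        )
    return ScalarMap(data=data, voxel_size=voxel_size)


def write_scalar_map(smap: ScalarMap, path) -> None:
    """Store a scalar map as float32 NIfTI (sufficient for fractions/FF)."""
    img = nib.Nifti1Image(smap.data.astype(np.float32), _affine(smap.voxel_size))
    img.header.set_zooms(tuple(smap.voxel_size))
    nib.save(img, str(path))


def read_mask(path, label_map=None) -> MuscleMask:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    return MuscleMask(
        labels=np.round(labels).astype(np.int16),
        label_map=dict(label_map) if label_map else dict(DEFAULT_LABEL_MAP),
    )


def write_mask(mask: MuscleMask, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    vs = np.asarray(voxel_size, dtype=float)
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(vs))
    img.header.set_zooms(tuple(vs))
    nib.save(img, str(path))


__all__ = [
    "AcquisitionScheme",
    "DWIStack",
    "ScalarMap",
    "MuscleMask",
    "B0_THRESHOLD",
    "DEFAULT_LABEL_MAP",
    "read_bval_bvec",
    "write_bval_bvec",
    "read_dwi",
    "write_dwi",
    "read_scalar_map",
    "write_scalar_map",
    "read_mask",
    "write_mask",
]
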