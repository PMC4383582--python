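"""Volume I/O and preprocessing: NIfTI reading/writing, Gaussian smoothing,
brain-mask construction, TIV, masked vectorisation, and covariate removal
via a residual-forming projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GMVolumeSet",
    "BrainMask",
    "FeatureMatrix",
    "Residualizer",
    "read_volumes",
    "write_volume",
    "smooth_volumes",
    "build_mask",
    "compute_tiv",
    "tiv_ml",
    "vectorize",
    "unvectorize",
    "residualize",
    "FWHM_TO_SIGMA",
]

# FWHM = sigma * 2 sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GMVolumeSet:
    """Per-subject 3-D gray-matter volumes on one shared grid.

    ``data`` is stacked (n_subjects, nx, ny, nz); ``affine`` maps voxel to
    world coordinates and encodes the voxel size on its diagonal.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D: (subjects, x, y, z)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        self.subject_ids = list(self.subject_ids)
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("one subject id per volume required")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class BrainMask:
    """Boolean analysis mask on the volume grid."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels_in(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureMatrix:
    """Subjects-by-masked-voxels feature matrix.

    Column order is the mask's linear (C-order) voxel order, so the mapping
    back to the 3-D grid is invertible.
    """

    X: np.ndarray
    subject_ids: list
    mask: BrainMask

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.subject_ids):
            raise ValueError("one row per subject required")
        if self.X.shape[1] != self.mask.n_voxels_in:
            raise ValueError("one column per masked voxel required")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# I/O

def read_volumes(paths: Sequence, subject_ids: Sequence | None = None) -> GMVolumeSet:
    """Load NIfTI volumes onto one verified-identical grid.

    A shape or affine mismatch is an error naming the offending file —
    never a silent resample.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no volume paths given")
    if subject_ids is None:
        subject_ids = [p.name.split(".")[0] for p in paths]
    vols = []
    ref_shape = ref_affine = None
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"volume file not found: {p}")
        img = nib.load(str(p))
        arr = np.asarray(img.get_fdata(), dtype=np.float64)
        if ref_shape is None:
            ref_shape, ref_affine = arr.shape, img.affine
        else:
            if arr.shape != ref_shape:
                raise ValueError(
                    f"grid shape mismatch for {p}: {arr.shape} vs {ref_shape}"
                )
            if not np.allclose(img.affine, ref_affine, atol=1e-4):
                raise ValueError(f"affine mismatch for {p}")
        vols.append(arr)
    return GMVolumeSet(np.stack(vols), ref_affine, list(subject_ids))


def write_volume(volume: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write one 3-D volume as NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"failed to write volume to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# preprocessing

def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    return fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)


def smooth_volumes(
    volset: GMVolumeSet, fwhm_mm: float, boundary: str = "constant"
) -> GMVolumeSet:
    """Isotropic Gaussian smoothing at the given FWHM (mm).

    sigma per axis is ``fwhm / (voxel_size * 2 sqrt(2 ln 2))`` voxels.
    ``boundary`` is "constant" (zero padding, default) or "nearest".
    fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if boundary not in ("constant", "nearest"):
        raise ValueError("boundary must be 'constant' or 'nearest'")
    if fwhm_mm == 0:
        return GMVolumeSet(volset.data.copy(), volset.affine, volset.subject_ids)
    sigma = _fwhm_to_sigma_vox(fwhm_mm, volset.voxel_size_mm)
    out = np.empty_like(volset.data)
    for i in range(volset.n_subjects):
        out[i] = ndimage.gaussian_filter(
            volset.data[i], sigma=sigma, mode=boundary, cval=0.0
        )
    return GMVolumeSet(out, volset.affine, volset.subject_ids)


def smooth_array(volume: np.ndarray, fwhm_mm: float, voxel_size_mm, boundary="constant"):
    """Smooth a single 3-D array (helper shared with the cohort generator)."""
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=np.float64).copy()
    sigma = _fwhm_to_sigma_vox(fwhm_mm, voxel_size_mm)
    return ndimage.gaussian_filter(
        np.asarray(volume, dtype=np.float64), sigma=sigma, mode=boundary, cval=0.0
    )


def build_mask(volset: GMVolumeSet, mean_threshold: float = 0.1) -> BrainMask:
    """Voxels whose across-subject mean exceeds ``mean_threshold``."""
    if mean_threshold < 0:
        raise ValueError("mean_threshold must be >= 0")
    mean = volset.data.mean(axis=0)
    m = mean > mean_threshold
    if not m.any():
        raise ValueError(
            f"mask is empty at mean_threshold={mean_threshold}; "
            "lower the threshold"
        )
    return BrainMask(m)


def compute_tiv(volume: np.ndarray, voxel_size_mm) -> float:
    """Total tissue volume in ml: sum of voxel values x voxel volume (mm^3) / 1000.

    In the synthetic world the gray-matter map is the only tissue segment,
    so this doubles as the total-intracranial-volume (TIV) surrogate.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if np.any(volume < 0):
        raise ValueError("volume must be nonnegative")
    vox_mm3 = float(np.prod(np.asarray(voxel_size_mm, dtype=float)))
    return float(volume.sum() * vox_mm3 / 1000.0)


def tiv_ml(volset: GMVolumeSet) -> np.ndarray:
    """Per-subject TIV (ml) for a volume set."""
    return np.array(
        [compute_tiv(volset.data[i], volset.voxel_size_mm) for i in range(volset.n_subjects)]
    )


def vectorize(volset: GMVolumeSet, mask: BrainMask) -> FeatureMatrix:
    """Stack each subject's masked voxels (C-order) into a feature row."""
    if mask.mask.shape != volset.grid_shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} does not match volume grid "
            f"{volset.grid_shape}"
        )
    X = volset.data[:, mask.mask]
    return FeatureMatrix(X, volset.subject_ids, mask)


def unvectorize(values: np.ndarray, mask: BrainMask) -> np.ndarray:
    """Place a masked-voxel vector back onto the 3-D grid (zeros outside)."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mask.n_voxels_in,):
        raise ValueError(
            f"expected {mask.n_voxels_in} values, got {values.shape}"
        )
    out = np.zeros(mask.mask.shape, dtype=np.float64)
    out[mask.mask] = values
    return out


# ---------------------------------------------------------------------------
# covariate removal

class Residualizer:
    """Removes covariate effects via the residual-forming projection
    R = I - X (X'X)^- X' of a covariate design X (intercept included).

    Fitted on a chosen subset of rows (e.g. the training rows of a
    cross-validation fold) and applied to any rows, which avoids test-set
    leakage: ``transform`` subtracts ``C_rows @ beta_`` where ``beta_`` was
    estimated from the fit rows only.

    Follows the scikit-learn transformer conventions (``fit`` returning
    ``self``, fitted attributes with trailing underscores) with the covariate
    design passed alongside the data, since out-of-sample rows carry their
    own covariates.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def get_params(self, deep: bool = True) -> dict:
        return {"add_intercept": self.add_intercept}

    def set_params(self, **params) -> "Residualizer":
        for k, v in params.items():
            if k != "add_intercept":
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _design(self, covariates) -> np.ndarray:
        C = np.asarray(covariates, dtype=np.float64)
        if C.ndim == 1:
            C = C[:, None]
        if self.add_intercept:
            C = np.column_stack([np.ones(C.shape[0]), C])
        return C

    def fit(self, covariates, data) -> "Residualizer":
        """Estimate covariate coefficients ``beta_`` from these rows."""
        C = self._design(covariates)
        data = np.asarray(data, dtype=np.float64)
        if data.ndim == 1:
            data = data[:, None]
        if C.shape[0] != data.shape[0]:
            raise ValueError("covariates and data must have the same rows")
        rank = np.linalg.matrix_rank(C)
        if rank < C.shape[1]:
            warnings.warn(
                "covariate design is rank-deficient; using the pseudo-inverse",
                RuntimeWarning,
                stacklevel=2,
            )
        pinv = np.linalg.pinv(C)
        self.beta_ = pinv @ data
        self.design_ = C
        self.rank_ = int(rank)
        # residual-forming matrix for the fitted rows
        self.R_ = np.eye(C.shape[0]) - C @ pinv
        return self

    def transform(self, covariates, data) -> np.ndarray:
        if not hasattr(self, "beta_"):
            raise RuntimeError("Residualizer is not fitted")
        C = self._design(covariates)
        data = np.asarray(data, dtype=np.float64)
        squeeze = data.ndim == 1
        if squeeze:
            data = data[:, None]
        out = data - C @ self.beta_
        return out[:, 0] if squeeze else out

    def fit_transform(self, covariates, data) -> np.ndarray:
        return self.fit(covariates, data).transform(covariates, data)

    @property
    def n_covariate_columns(self) -> int:
        """Non-intercept covariate columns (for degree-of-freedom bookkeeping)."""
        return self.design_.shape[1] - (1 if self.add_intercept else 0)


def residualize(
    features: FeatureMatrix | np.ndarray,
    covariates,
    fit_rows=None,
    add_intercept: bool = True,
):
    """Project features onto the orthogonal complement of the covariates.

    ``fit_rows`` selects the rows used to estimate the projection (all rows
    when None), supporting fold-wise fitting inside cross-validation; the
    projection is then applied to every row.  Returns the residualised
    features (same container type as the input) and the fitted
    :class:`Residualizer`.
    """
    is_fm = isinstance(features, FeatureMatrix)
    X = features.X if is_fm else np.asarray(features, dtype=np.float64)
    C = np.asarray(covariates, dtype=np.float64)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != X.shape[0]:
        raise ValueError("covariates must have one row per subject")
    if fit_rows is None:
        fit_rows = np.arange(X.shape[0])
    fit_rows = np.asarray(fit_rows)
    res = Residualizer(add_intercept=add_intercept).fit(C[fit_rows], X[fit_rows])
    Xr = res.transform(C, X)
    if is_fm:
        return FeatureMatrix(Xr, features.subject_ids, features.mask), res
    return Xr, res
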