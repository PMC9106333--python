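"""Minimal per-voxel BOLD cleaning steps for seed-based connectivity.

Implements the cleaning stages a resting-state pipeline applies between
acquisition and correlation: removal of the constant offset and linear trend,
grand-mean intensity scaling, temporal band-pass filtering, nuisance
regression, and mask-aware Gaussian spatial smoothing. Upstream steps
(motion correction, registration, segmentation) are out of scope; volumes
are assumed to already live on a common grid.

All steps operate only on in-mask voxels; out-of-mask voxels pass through
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import linalg as sla
from scipy import ndimage, signal

__all__ = [
    "VolumeImage",
    "detrend_and_normalize",
    "bandpass",
    "nuisance_regress",
    "spatial_smooth",
    "load_nifti",
    "save_nifti",
]

#: FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class VolumeImage:
    """A 3D or 4D voxel grid with a world affine and a brain mask.

    ``data`` is (x, y, z) or (x, y, z, t); ``affine`` maps voxel indices to
    world millimetres (RAS+); ``brain_mask`` matches the spatial shape;
    ``tr_seconds`` is required for 4D images.
    """

    data: np.ndarray
    affine: np.ndarray
    brain_mask: np.ndarray | None = None
    tr_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3D or 4D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.brain_mask is not None and self.brain_mask.shape != self.spatial_shape:
            raise ValueError(
                f"mask shape {self.brain_mask.shape} != spatial shape {self.spatial_shape}"
            )
        if self.data.ndim == 4 and (self.tr_seconds is None or self.tr_seconds <= 0):
            raise ValueError("4D images require tr_seconds > 0")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3] if self.data.ndim == 4 else 1

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask_array(self) -> np.ndarray:
        if self.brain_mask is None:
            return np.ones(self.spatial_shape, dtype=bool)
        return self.brain_mask.astype(bool)

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*spatial, 3)."""
        idx = np.indices(self.spatial_shape).reshape(3, -1)
        ijk1 = np.vstack([idx, np.ones(idx.shape[1])])
        xyz = (self.affine @ ijk1)[:3].T
        return xyz.reshape(*self.spatial_shape, 3)


def load_nifti(path: str | Path, mask_path: str | Path | None = None,
               tr_seconds: float | None = None) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if tr_seconds is None and data.ndim == 4:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return VolumeImage(data, np.asarray(img.affine, dtype=float), mask, tr_seconds)


def save_nifti(img: VolumeImage, path: str | Path) -> None:
    out = nib.Nifti1Image(np.asarray(img.data, dtype=np.float32), img.affine)
    if img.data.ndim == 4 and img.tr_seconds:
        zooms = list(out.header.get_zooms())
        zooms[3] = img.tr_seconds
        out.header.set_zooms(zooms)
    nib.save(out, str(path))


def _require_4d(img: VolumeImage, min_t: int = 3) -> None:
    if img.data.ndim != 4:
        raise ValueError("operation requires a 4D image")
    if img.data.shape[3] < min_t:
        raise ValueError(f"need at least {min_t} time points, got {img.data.shape[3]}")


def detrend_and_normalize(
    img: VolumeImage, target: float = 100.0, normalize: bool = True
) -> VolumeImage:
    """Remove per-voxel constant offset and linear trend; grand-mean scale.

    Detrending is the least-squares projection of each voxel series off the
    [intercept, linear-ramp] design (so constants and pure ramps map to zero).
    Grand-mean scaling multiplies the detrended data by ``target / g`` where
    ``g`` is the within-mask mean of the *original* intensities; if the input
    has (near-)zero mean intensity, scaling is skipped.
    """
    _require_4d(img)
    mask = img.mask_array()
    data = img.data.copy()
    series = data[mask]  # (n_voxels, t)
    g = float(np.abs(series).mean()) if series.size else 0.0
    detrended = signal.detrend(series, axis=-1, type="linear")
    if normalize and g > 1e-12:
        detrended = detrended * (target / g)
    data[mask] = detrended
    return replace(img, data=data)


def bandpass(
    img: VolumeImage,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    method: str = "butter",
    order: int = 2,
) -> VolumeImage:
    """Zero-phase temporal band-pass of every in-mask voxel series.

    ``method='butter'`` (default) applies a Butterworth filter of the given
    order forward and backward (filtfilt; zero phase, squared magnitude
    response). ``method='fft'`` applies an ideal frequency mask. The DC
    component is removed in either case.
    """
    _require_4d(img)
    fs = 1.0 / img.tr_seconds
    nyq = fs / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz must satisfy 0 <= low < high < "
            f"Nyquist ({nyq:.4g} Hz at TR={img.tr_seconds}s)"
        )
    mask = img.mask_array()
    series = img.data[mask] - img.data[mask].mean(axis=-1, keepdims=True)
    if method == "fft":
        t = img.data.shape[3]
        freqs = np.fft.rfftfreq(t, d=img.tr_seconds)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec = np.fft.rfft(series, axis=-1)
        spec[:, ~keep] = 0.0
        filtered = np.fft.irfft(spec, n=t, axis=-1)
    elif method == "butter":
        if low_hz <= 0:
            sos = signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
        else:
            sos = signal.butter(
                order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
            )
        filtered = signal.sosfiltfilt(sos, series, axis=-1)
        filtered = filtered - filtered.mean(axis=-1, keepdims=True)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    data = img.data.copy()
    data[mask] = filtered
    return replace(img, data=data)


def nuisance_regress(img: VolumeImage, regressors: np.ndarray) -> VolumeImage:
    """OLS residuals of every in-mask voxel series on regressors + intercept.

    ``regressors`` is (t, k). The design is checked for full column rank; a
    rank-deficient design raises an error naming the collinear columns.
    """
    _require_4d(img)
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    t = img.data.shape[3]
    if X.shape[0] != t:
        raise ValueError(f"regressors have {X.shape[0]} rows but image has {t} time points")
    if X.shape[1] < 1:
        raise ValueError("need at least one regressor")
    design = np.column_stack([np.ones(t), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via pivoted QR on the scaled design
        scaled = design / np.maximum(np.linalg.norm(design, axis=0), 1e-300)
        _, _, piv = sla.qr(scaled, mode="economic", pivoting=True)
        dropped = sorted(piv[rank:])
        names = ["intercept"] + [f"regressor {j}" for j in range(X.shape[1])]
        bad = [names[j] for j in dropped]
        raise ValueError(f"rank-deficient nuisance design; collinear column(s): {bad}")
    mask = img.mask_array()
    Y = img.data[mask].T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    data = img.data.copy()
    data[mask] = resid.T
    return replace(img, data=data)


def spatial_smooth(img: VolumeImage, fwhm_mm: float) -> VolumeImage:
    """Mask-normalized Gaussian smoothing with a kernel given in millimetres.

    Per-axis sigma is fwhm / (2*sqrt(2*ln 2)) converted to voxel units using
    the voxel sizes read from the affine (anisotropic grids supported).
    Smoothing is restricted to in-mask voxels: the data and the mask are
    convolved separately and their ratio taken, so no signal bleeds in from
    outside the brain and a constant image stays constant.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / img.voxel_sizes_mm
    mask = img.mask_array().astype(float)
    denom = ndimage.gaussian_filter(mask, sigma=sigma_vox, mode="constant")
    data = img.data.copy()
    maskb = mask > 0

    def _smooth3(vol: np.ndarray) -> np.ndarray:
        num = ndimage.gaussian_filter(vol * mask, sigma=sigma_vox, mode="constant")
        out = vol.copy()
        out[maskb] = num[maskb] / denom[maskb]
        return out

    if img.data.ndim == 3:
        data = _smooth3(data)
    else:
        for ti in range(img.data.shape[3]):
            data[..., ti] = _smooth3(img.data[..., ti])
    return replace(img, data=data)
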