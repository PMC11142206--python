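"""Preprocessing of BOLD timecourses: nuisance regression, normalization,
band-pass filtering, spatial smoothing, and ROI extraction.

All timecourse operations accept either a :class:`ParcellatedScan` or a
:class:`VoxelScan` and return the same type with new values; the canonical
order of application is regression → normalization → band-pass →
smoothing → ROI extraction.

Filtering is zero-phase (forward–backward Butterworth, order 2 per pass by
default) so that event timing used downstream by the sliding-template
detector is not shifted. Normalization uses the sample (n−1) standard
deviation.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .core import InvalidConfigError, ParcellatedScan, VoxelScan

logger = logging.getLogger(__name__)


@dataclass
class NuisanceSet:
    """Time × k matrix of nuisance regressors.

    Columns are a constant, linear and quadratic trend, plus optional
    motion traces. Trends are built on a [-1, 1] time axis for conditioning.
    """

    regressors: np.ndarray

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] < 1:
            raise InvalidConfigError("need at least one regressor column")
        # forbid duplicated constant columns (exactly collinear intercepts)
        const = [
            j
            for j in range(self.regressors.shape[1])
            if np.ptp(self.regressors[:, j]) == 0 and np.any(self.regressors[:, j])
        ]
        if len(const) > 1:
            raise InvalidConfigError("duplicated constant column in nuisance set")

    @classmethod
    def trends(cls, n_frames: int, motion: np.ndarray | None = None) -> "NuisanceSet":
        """Constant + linear + quadratic trend, plus optional motion columns.

        Motion defaults to absent (synthetic data simulates none); the slot
        exists so that real-data motion traces can be slotted in.
        """
        t = np.linspace(-1.0, 1.0, n_frames)
        cols = [np.ones(n_frames), t, t**2]
        if motion is not None:
            motion = np.asarray(motion, dtype=float)
            if motion.shape[0] != n_frames:
                raise InvalidConfigError("motion rows must equal n_frames")
            cols.extend(motion.T)
        return cls(np.column_stack(cols))

    @property
    def n_frames(self) -> int:
        return self.regressors.shape[0]


def _timecourse_matrix(scan) -> tuple[np.ndarray, bool]:
    """Return (n_series × n_frames) view of the scan and whether it is voxel data."""
    if isinstance(scan, ParcellatedScan):
        return scan.values, False
    if isinstance(scan, VoxelScan):
        return scan.data[scan.brain_mask], True
    raise TypeError(f"unsupported scan type {type(scan).__name__}")


def _rebuild(scan, mat: np.ndarray):
    if isinstance(scan, ParcellatedScan):
        return scan.with_values(mat)
    data = scan.data.copy()
    data[scan.brain_mask] = mat
    return scan.with_data(data)


def regress_nuisance(scan, nuisance: NuisanceSet):
    """Replace each timecourse by its least-squares residual against the
    nuisance columns. Rank-deficient designs fall back to the pseudoinverse
    (minimum-norm solution) with a warning."""
    mat, _ = _timecourse_matrix(scan)
    X = nuisance.regressors
    if X.shape[0] != mat.shape[1]:
        raise InvalidConfigError(
            f"nuisance has {X.shape[0]} rows for {mat.shape[1]} frames"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient nuisance matrix; using pseudoinverse")
        beta = np.linalg.pinv(X) @ mat.T
    else:
        beta, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    resid = mat.T - X @ beta
    return _rebuild(scan, resid.T)


def bandpass(scan, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 2):
    """Zero-phase Butterworth band-pass, applied per timecourse."""
    mat, _ = _timecourse_matrix(scan)
    nyq = 0.5 / scan.tr_seconds
    if not (0 < low_hz < high_hz):
        raise InvalidConfigError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise InvalidConfigError(f"high_hz must be below Nyquist ({nyq:g} Hz)")
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass",
                     fs=1.0 / scan.tr_seconds, output="sos")
    default_pad = 3 * (2 * len(sos) + 1)
    return _rebuild(scan, sps.sosfiltfilt(
        sos, mat, axis=-1, padlen=min(default_pad, mat.shape[-1] - 1)))


def zscore_timecourses(scan):
    """Center each timecourse and scale to unit sample SD.

    Zero-variance timecourses are left at zeros, with a warning and a log
    of how many were flagged.
    """
    mat, _ = _timecourse_matrix(scan)
    mean = mat.mean(axis=-1, keepdims=True)
    sd = mat.std(axis=-1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance timecourse(s) set to zero")
        logger.info("zscore: %d zero-variance timecourses flagged", int(flat.sum()))
    sd = np.where(sd == 0, 1.0, sd)
    return _rebuild(scan, (mat - mean) / sd)


def smooth_spatial(vol: VoxelScan, fwhm_mm: float = 0.5,
                   voxel_mm: float | None = None) -> VoxelScan:
    """Per-frame Gaussian smoothing restricted to the brain mask.

    Uses mask-normalized convolution (smooth the masked data and the mask,
    then divide) so out-of-mask voxels never bleed in. σ = FWHM / (2√(2 ln 2))
    in voxel units; ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise InvalidConfigError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    voxel_mm = vol.voxel_mm if voxel_mm is None else voxel_mm
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_mm
    mask = vol.brain_mask.astype(float)
    weight = ndimage.gaussian_filter(mask, sigma)
    out = vol.data.copy()
    for t in range(vol.n_frames):
        frame = vol.data[..., t] * mask
        sm = ndimage.gaussian_filter(frame, sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(weight > 0, sm / weight, 0.0)
        out[..., t] = np.where(vol.brain_mask, sm, vol.data[..., t])
    return vol.with_data(out)


def extract_rois(vol: VoxelScan, region_names: dict[int, str] | None = None
                 ) -> ParcellatedScan:
    """Label-wise voxel averaging: region ``r``'s timecourse is the mean over
    voxels with label ``r`` at each frame; regions are ordered by ascending
    label. Labels present in ``region_names`` but absent from the volume are
    dropped with a warning."""
    labels = vol.labels
    present = np.unique(labels[labels > 0])
    if present.size == 0:
        raise InvalidConfigError("no labelled voxels in volume")
    if region_names:
        missing = sorted(set(region_names) - set(int(x) for x in present))
        if missing:
            warnings.warn(f"labels {missing} have no voxels; regions dropped")
    series = []
    names = []
    lab_flat = labels.ravel()
    flat = vol.data.reshape(-1, vol.n_frames)
    for lab in present:
        idx = np.flatnonzero(lab_flat == lab)
        series.append(flat[idx].mean(axis=0))
        name = (region_names or {}).get(int(lab), f"Region {int(lab) - 1:02d}")
        names.append(name)
    return ParcellatedScan(
        values=np.asarray(series),
        region_names=names,
        tr_seconds=vol.tr_seconds,
    )
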