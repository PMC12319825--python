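"""Run-level time-series cleaning for resting-state fMRI.

The cleaning chain operates on masked voxel-by-frame matrices and is
applied in a fixed order:

    scrub (frame censoring by framewise displacement)
      -> band-pass filter (zero-phase Butterworth, on kept frames)
      -> nuisance regression (white-matter / ventricle traces)

Spatial smoothing is a separate operation on volume maps (or,
optionally, frame-wise on the 4D series); see :func:`smooth`.

Censored frames are dropped from every downstream computation, never
interpolated: filtered/regressed outputs keep the full frame count but
censored rows are zeroed and flagged in ``censor``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: minimum number of frames for a stable band-pass filter
MIN_FRAMES = 64

#: minimum number of kept frames for a usable run
MAX_CENSOR_FRACTION = 0.5


class RunExcludedError(RuntimeError):
    """Raised when a run fails quality control (e.g. > 50% frames censored)."""


@dataclass
class RunTimeSeries:
    """One run's masked voxel signal plus nuisance bookkeeping.

    Attributes
    ----------
    data : ndarray, shape (frames, voxels)
        BOLD signal for in-mask voxels, in the fixed voxel ordering of
        the accompanying :class:`~vipgradient.phantom.VolumeGeometry`.
    tr_seconds : float
        Repetition time.
    subject_id, run_id : str
        Identifiers used in logs and output names.
    nuisance : dict
        Per-frame traces, at least ``{"wm": ..., "csf": ...}``.
    fd : ndarray, shape (frames,)
        Framewise displacement in mm.
    censor : ndarray of bool, shape (frames,)
        True = frame kept.  All-true before scrubbing.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str
    run_id: str
    nuisance: dict = field(default_factory=dict)
    fd: np.ndarray | None = None
    censor: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a frames x voxels matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in run data")
        n = self.n_frames
        if self.censor is None:
            self.censor = np.ones(n, dtype=bool)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.fd is not None:
            self.fd = np.asarray(self.fd, dtype=float)
            if self.fd.shape != (n,):
                raise ValueError("fd trace length does not match frame count")
        for name, trace in self.nuisance.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != (n,):
                raise ValueError(f"nuisance trace {name!r} length mismatch")
            self.nuisance[name] = trace
        if self.censor.shape != (n,):
            raise ValueError("censor length does not match frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_kept(self) -> int:
        return int(self.censor.sum())

    def kept_data(self) -> np.ndarray:
        """Signal restricted to kept frames (cached per instance)."""
        cache = getattr(self, "_kept_cache", None)
        if cache is None:
            cache = self.data if self.censor.all() else self.data[self.censor]
            self._kept_cache = cache
        return cache


@dataclass
class FilterSettings:
    """Cleaning parameters.

    band_hz
        Band-pass edges in Hz; default 0.01-0.1, the conventional
        resting-state band.  An alternative low band (0.0025-0.05) is
        valid for long-TR acquisitions.
    order
        Butterworth order (applied forward-backward, so the effective
        order doubles).
    fwhm_mm
        Gaussian smoothing kernel full width at half maximum; 0 disables.
    voxel_mm
        Isotropic voxel edge length.
    fd_threshold_mm
        Frames with framewise displacement above this are censored.
    """

    band_hz: tuple[float, float] = (0.01, 0.1)
    order: int = 4
    fwhm_mm: float = 1.5
    voxel_mm: float = 1.25
    fd_threshold_mm: float = 0.5

    def __post_init__(self):
        low, high = self.band_hz
        if not (0 < low < high):
            raise ValueError("band_hz must satisfy 0 < low < high")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.fd_threshold_mm <= 0:
            raise ValueError("fd_threshold_mm must be > 0")

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyquist = 0.5 / tr_seconds
        if self.band_hz[1] >= nyquist:
            raise ValueError(
                f"band upper edge {self.band_hz[1]} Hz is not below the "
                f"Nyquist frequency {nyquist} Hz for TR {tr_seconds} s"
            )


def scrub(run: RunTimeSeries, settings: FilterSettings) -> RunTimeSeries:
    """Censor frames whose framewise displacement exceeds the threshold.

    Returns a new run with ``censor`` updated (logical AND with any
    prior censoring).  Raises :class:`RunExcludedError` when more than
    half of the frames would be censored.
    """
    if run.fd is None:
        raise ValueError("run has no framewise-displacement trace")
    keep = run.fd <= settings.fd_threshold_mm
    censor = run.censor & keep
    n_censored = int((~censor).sum())
    if n_censored > MAX_CENSOR_FRACTION * run.n_frames:
        logger.warning(
            "run %s/%s excluded: %d of %d frames censored",
            run.subject_id, run.run_id, n_censored, run.n_frames,
        )
        raise RunExcludedError(
            f"run {run.subject_id}/{run.run_id}: {n_censored}/{run.n_frames} "
            "frames censored (> 50%)"
        )
    if n_censored:
        logger.info(
            "run %s/%s: censored %d frames (fd > %.3g mm)",
            run.subject_id, run.run_id, n_censored, settings.fd_threshold_mm,
        )
    return replace(run, censor=censor)


def _bandpass_sos(settings: FilterSettings, tr_seconds: float):
    nyquist = 0.5 / tr_seconds
    low, high = settings.band_hz
    return signal.butter(
        settings.order, [low / nyquist, high / nyquist], btype="band", output="sos"
    )


def bandpass_array(
    x: np.ndarray, tr_seconds: float, settings: FilterSettings
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0.

    The series is demeaned before and after filtering: the filter's DC
    gain is zero in steady state, but finite-length padding leaks a
    small residual offset, and downstream correlation/regression steps
    assume strictly zero-mean columns.
    """
    sos = _bandpass_sos(settings, tr_seconds)
    x = np.asarray(x, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if x.ndim == 2 and x.shape[1] > x.shape[0]:
        # filtering along the last axis of the transpose is much faster
        # for wide frame-by-voxel matrices (memory layout)
        y = signal.sosfiltfilt(sos, x.T, axis=1).T
    else:
        y = signal.sosfiltfilt(sos, x, axis=0)
    return y - y.mean(axis=0, keepdims=True)


def bandpass(run: RunTimeSeries, settings: FilterSettings) -> RunTimeSeries:
    """Band-pass filter the kept frames of a run (zero-phase).

    The kept frames are concatenated and filtered as one contiguous
    series; censored rows of the output are zeroed.  Nuisance traces
    are filtered identically so that later regression operates on
    commensurate signals.
    """
    settings.validate_for_tr(run.tr_seconds)
    if run.n_kept < MIN_FRAMES:
        raise ValueError(
            f"band-pass requires >= {MIN_FRAMES} kept frames, got {run.n_kept}"
        )
    out = np.zeros_like(run.data)
    out[run.censor] = bandpass_array(run.kept_data(), run.tr_seconds, settings)
    nuisance = {}
    for name, trace in run.nuisance.items():
        filt = np.zeros_like(trace)
        filt[run.censor] = bandpass_array(
            trace[run.censor], run.tr_seconds, settings
        )
        nuisance[name] = filt
    return replace(run, data=out, nuisance=nuisance)


def regress_out(y: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Residual of column-wise least squares of ``y`` on [1 | regressors].

    Rank-deficient designs are handled by the pseudo-inverse (equivalent
    to dropping collinear columns); a warning is logged when the design
    is not full rank.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if regressors is None or regressors.size == 0:
        return y - y.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(n), np.asarray(regressors, dtype=float)])
    if X.shape[1] >= n:
        raise ValueError("more regressors than frames")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s.max() * 1e-10
    if int(keep.sum()) < X.shape[1]:
        logger.warning(
            "rank-deficient nuisance design (%d of %d columns independent); "
            "collinear columns dropped", int(keep.sum()), X.shape[1],
        )
    q = u[:, keep]
    return y - q @ (q.T @ y)


def nuisance_regress(
    run: RunTimeSeries, regressors: np.ndarray | None = None
) -> RunTimeSeries:
    """Regress nuisance traces out of every voxel's kept-frame series.

    ``regressors`` is a (kept-or-all frames) x k matrix; when omitted,
    the run's white-matter and ventricle traces are used.  An intercept
    is always included, so the output is also demeaned.
    """
    keep = run.censor
    if regressors is None:
        cols = [run.nuisance[k] for k in ("wm", "csf") if k in run.nuisance]
        regressors = np.column_stack(cols) if cols else np.empty((run.n_frames, 0))
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] == run.n_frames:
        regressors = regressors[keep]
    elif regressors.shape[0] != int(keep.sum()):
        raise ValueError("regressor rows match neither total nor kept frames")
    if not np.all(np.isfinite(regressors)):
        raise ValueError("non-finite values in nuisance regressors")
    out = np.zeros_like(run.data)
    out[keep] = regress_out(run.data[keep], regressors)
    return replace(run, data=out)


def preprocess_run(
    run: RunTimeSeries, settings: FilterSettings
) -> RunTimeSeries:
    """Full cleaning chain: scrub -> band-pass -> nuisance regression."""
    run = scrub(run, settings)
    run = bandpass(run, settings)
    run = nuisance_regress(run)
    return run


def smooth(
    values: np.ndarray,
    geometry,
    settings: FilterSettings,
) -> np.ndarray:
    """Mask-normalized Gaussian smoothing of a per-voxel volume map.

    ``values`` is defined on the geometry's in-mask voxel ordering; NaN
    entries (e.g. contralateral voxels of an ipsilateral map) carry no
    weight and remain NaN in the output.  The kernel is renormalized
    over in-mask, non-missing neighbors so constant maps are preserved
    exactly, including at mask edges.
    """
    values = np.asarray(values, dtype=float)
    if settings.fwhm_mm == 0:
        return values.copy()
    sigma_vox = settings.fwhm_mm * FWHM_TO_SIGMA / settings.voxel_mm
    vol = np.zeros(geometry.shape, dtype=float)
    wgt = np.zeros(geometry.shape, dtype=float)
    finite = np.isfinite(values)
    coords = geometry.coords[finite]
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values[finite]
    wgt[coords[:, 0], coords[:, 1], coords[:, 2]] = 1.0
    num = ndimage.gaussian_filter(vol, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(wgt, sigma_vox, mode="constant", cval=0.0)
    out = np.full_like(values, np.nan)
    c = geometry.coords[finite]
    out[finite] = num[c[:, 0], c[:, 1], c[:, 2]] / den[c[:, 0], c[:, 1], c[:, 2]]
    return out
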