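"""ROI-level time-series cleaning.

The cleaning contract, applied in this fixed order:

1. discard the initial volumes (scanner equilibration),
2. regress out a 36-parameter nuisance design (6 motion + white-matter +
   CSF + global signal, their temporal derivatives, and the squares of all
   18; 32 parameters when the global signal is withheld),
3. zero-phase band-pass filter the residuals (0.01-0.1 Hz by default),
4. scrub high-motion volumes: every volume with framewise displacement
   (FD) above threshold is removed together with 1 volume before and
   2 after; a subject with fewer than 140 surviving volumes is excluded.

Scrubbed volumes are removed, never interpolated. FD uses the Power
formulation: the sum of absolute translation differences plus the
rotation differences expressed as arc length on a 50 mm sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import SubjectTimeSeries

__all__ = [
    "PreprocessConfig",
    "MinimumVolumesError",
    "compute_fd",
    "flag_and_censor",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "Preprocessor",
]


class MinimumVolumesError(RuntimeError):
    """Raised when scrubbing leaves fewer volumes than the exclusion guard allows."""

    def __init__(self, n_kept: int, min_volumes: int, subject: str = ""):
        self.n_kept = n_kept
        self.min_volumes = min_volumes
        self.subject = subject
        msg = f"only {n_kept} volumes survive scrubbing (< {min_volumes})"
        if subject:
            msg = f"{subject}: {msg}"
        super().__init__(msg)


@dataclass
class PreprocessConfig:
    """Cleaning thresholds; defaults are the study's stated values."""

    fd_threshold_mm: float = 0.5
    censor_before: int = 1
    censor_after: int = 2
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    min_volumes: int = 140
    use_global_signal: bool = True
    rotation_sphere_radius_mm: float = 50.0
    n_discard_initial: int = 10

    def __post_init__(self) -> None:
        if self.fd_threshold_mm <= 0:
            raise ValueError("fd_threshold_mm must be positive")
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("need 0 < band_low_hz < band_high_hz")
        if self.censor_before < 0 or self.censor_after < 0:
            raise ValueError("censor window sizes must be non-negative")

    def validate_tr(self, tr: float) -> None:
        nyquist = 0.5 / tr
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} >= Nyquist {nyquist} for TR={tr}")


def compute_fd(motion: np.ndarray, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement per volume (Power formulation).

    FD(t) = sum |delta translations| + radius x sum |delta rotations|,
    with FD of the first volume defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be (n_volumes, 6)")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion trace contains non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.zeros(motion.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return fd


def flag_and_censor(fd: np.ndarray, config: PreprocessConfig | None = None,
                    subject: str = "") -> np.ndarray:
    """Surviving volume indices after motion scrubbing.

    Every volume with FD above threshold is removed along with
    ``censor_before`` preceding and ``censor_after`` following volumes
    (windows may overlap and are clipped at the series ends). Raises
    :class:`MinimumVolumesError` if fewer than ``min_volumes`` survive.
    """
    config = config or PreprocessConfig()
    fd = np.asarray(fd, dtype=float)
    n = fd.shape[0]
    bad = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(fd > config.fd_threshold_mm):
        lo = max(0, t - config.censor_before)
        hi = min(n, t + config.censor_after + 1)
        bad[lo:hi] = True
    kept = np.flatnonzero(~bad)
    if kept.size < config.min_volumes:
        raise MinimumVolumesError(int(kept.size), config.min_volumes, subject)
    return kept


def build_nuisance_design(
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    global_signal: np.ndarray | None = None,
    use_global: bool = True,
) -> np.ndarray:
    """The 36-parameter nuisance design (32 without the global signal).

    Columns: 9 base signals (6 motion + WM + CSF + global), their backward
    temporal differences (0 at the first volume), and the element-wise
    squares of those 18.
    """
    motion = np.asarray(motion, dtype=float)
    cols = [motion[:, i] for i in range(6)]
    cols += [np.asarray(wm, dtype=float), np.asarray(csf, dtype=float)]
    if use_global:
        if global_signal is None:
            raise ValueError("use_global=True but no global signal supplied")
        cols.append(np.asarray(global_signal, dtype=float))
    n = cols[0].shape[0]
    for c in cols:
        if c.shape != (n,):
            raise ValueError("all nuisance signals must have the same length")
    base = np.column_stack(cols)
    deriv = np.zeros_like(base)
    deriv[1:] = np.diff(base, axis=0)
    first18 = np.column_stack([base, deriv])
    design = np.column_stack([first18, first18 ** 2])
    return design


def regress_nuisance(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residualize each node series against the design (intercept always included).

    A rank-deficient design is handled by the least-norm solution with a
    warning; residuals are orthogonal to every design column either way.
    """
    data = np.asarray(data, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.shape[0] != data.shape[0]:
        raise ValueError("design and data must have the same number of volumes")
    X = np.column_stack([np.ones(design.shape[0]), design])
    beta, _, rank, _ = np.linalg.lstsq(X, data, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient (rank {rank} < {X.shape[1]}); "
            "using least-norm solution", stacklevel=2)
    return data - X @ beta


def bandpass(data: np.ndarray, tr: float, low_hz: float = 0.01,
             high_hz: float = 0.1, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 30:
        raise ValueError("need at least 30 volumes to band-pass filter")
    nyquist = 0.5 / tr
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz incompatible with TR={tr}s "
            f"(Nyquist {nyquist} Hz)")
    sos = sp_signal.butter(order, [low_hz, high_hz], btype="bandpass",
                           fs=1.0 / tr, output="sos")
    return sp_signal.sosfiltfilt(sos, data, axis=0)


class Preprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the full cleaning pipeline per subject.

    ``transform`` maps a sequence of :class:`SubjectTimeSeries` to cleaned
    copies whose ``data`` contains only surviving volumes and whose
    ``kept_volumes`` records their indices (relative to the series after
    initial-volume discard). Subjects failing the minimum-volume guard
    raise :class:`MinimumVolumesError`; batch callers that need to skip
    them should catch it per subject (the pipeline runner does).
    """

    def __init__(self, fd_threshold_mm: float = 0.5, censor_before: int = 1,
                 censor_after: int = 2, band_low_hz: float = 0.01,
                 band_high_hz: float = 0.1, min_volumes: int = 140,
                 use_global_signal: bool = True,
                 rotation_sphere_radius_mm: float = 50.0,
                 n_discard_initial: int = 10):
        self.fd_threshold_mm = fd_threshold_mm
        self.censor_before = censor_before
        self.censor_after = censor_after
        self.band_low_hz = band_low_hz
        self.band_high_hz = band_high_hz
        self.min_volumes = min_volumes
        self.use_global_signal = use_global_signal
        self.rotation_sphere_radius_mm = rotation_sphere_radius_mm
        self.n_discard_initial = n_discard_initial

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            fd_threshold_mm=self.fd_threshold_mm,
            censor_before=self.censor_before,
            censor_after=self.censor_after,
            band_low_hz=self.band_low_hz,
            band_high_hz=self.band_high_hz,
            min_volumes=self.min_volumes,
            use_global_signal=self.use_global_signal,
            rotation_sphere_radius_mm=self.rotation_sphere_radius_mm,
            n_discard_initial=self.n_discard_initial,
        )

    def fit(self, X=None, y=None):
        self._config()  # validate parameters
        return self

    def clean(self, ts: SubjectTimeSeries) -> SubjectTimeSeries:
        """Clean one subject: discard -> regress -> band-pass -> scrub."""
        cfg = self._config()
        cfg.validate_tr(ts.tr)
        if ts.motion is None:
            raise ValueError(f"{ts.subject_id}: motion trace required for cleaning")
        if ts.wm is None or ts.csf is None:
            raise ValueError(f"{ts.subject_id}: WM and CSF nuisance signals required")
        k = cfg.n_discard_initial
        if ts.n_volumes <= k:
            raise ValueError(f"{ts.subject_id}: fewer volumes than the initial discard")
        data = ts.data[k:]
        motion = ts.motion[k:]
        wm = np.asarray(ts.wm)[k:]
        csf = np.asarray(ts.csf)[k:]
        gs = ts.get_global_signal()[k:]

        design = build_nuisance_design(motion, wm, csf, gs,
                                       use_global=cfg.use_global_signal)
        resid = regress_nuisance(data, design)
        filtered = bandpass(resid, ts.tr, cfg.band_low_hz, cfg.band_high_hz)

        fd = compute_fd(motion, cfg.rotation_sphere_radius_mm)
        kept = flag_and_censor(fd, cfg, subject=ts.subject_id)
        return SubjectTimeSeries(
            data=filtered[kept], node_ids=list(ts.node_ids), tr=ts.tr,
            motion=motion[kept], wm=wm[kept], csf=csf[kept],
            subject_id=ts.subject_id, timepoint=ts.timepoint, kept_volumes=kept)

    def transform(self, X):
        if isinstance(X, SubjectTimeSeries):
            return self.clean(X)
        return [self.clean(ts) for ts in X]
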