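"""Temporal denoising of ROI BOLD time series.

Implements the preprocessing chain applied to each subject after rigid-body
realignment: deletion of initial dummy volumes, framewise-displacement (FD)
computation from the six realignment parameters, subject-level motion
exclusion, 36-parameter nuisance regression (6 motion + white matter + CSF +
global signal, their temporal derivatives, and the squares of all 18),
zero-phase band-pass filtering, FD-based volume censoring, and a minimum
retained-duration gate.

The default chain order is: drop initial volumes -> FD -> subject motion gate
-> nuisance regression (full series) -> band-pass (full series) -> censor ->
duration gate.  Regression and filtering operate on the full, regularly
sampled series because filtering an irregularly censored series is
ill-defined; censoring only flips the retained mask and never alters sample
values.  Censoring before regression/filtering is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MotionRecord",
    "RoiTimeSeriesMatrix",
    "NuisanceDesign",
    "GateResult",
    "RankDeficiencyWarning",
    "compute_fd",
    "drop_initial_volumes",
    "censor_volumes",
    "subject_motion_gate",
    "build_36p_design",
    "nuisance_regress",
    "bandpass",
    "duration_gate",
    "denoise_subject",
    "DenoiseResult",
]

#: column order of the 6 rigid-body parameters (documented file format)
MOTION_COLUMNS = ("rot_x_rad", "rot_y_rad", "rot_z_rad",
                  "trans_x_mm", "trans_y_mm", "trans_z_mm")


class RankDeficiencyWarning(UserWarning):
    """A nuisance design is rank deficient (e.g. an all-zero base column)."""


@dataclass
class MotionRecord:
    """Six rigid-body realignment parameters per volume.

    ``params`` is (n_volumes, 6): three rotations in radians followed by
    three translations in mm (see :data:`MOTION_COLUMNS`).
    ``mean_rel_displacement`` is the realignment tool's mean relative
    displacement in mm when available; when ``None`` the subject motion gate
    falls back to mean FD as a proxy.
    """

    params: np.ndarray
    mean_rel_displacement: float | None = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be (n_volumes, 6), got {self.params.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class RoiTimeSeriesMatrix:
    """One subject's region-by-volume BOLD signal.

    ``values`` is (n_regions, n_volumes); ``retained_mask`` marks volumes
    that survive censoring; ``region_ids`` are 1-based parcellation indices.
    """

    values: np.ndarray
    tr_seconds: float
    retained_mask: np.ndarray = None  # type: ignore[assignment]
    region_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_regions, n_volumes)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.retained_mask is None:
            self.retained_mask = np.ones(self.n_volumes, dtype=bool)
        self.retained_mask = np.asarray(self.retained_mask, dtype=bool)
        if self.retained_mask.shape != (self.n_volumes,):
            raise ValueError("retained_mask length must equal n_volumes")
        if self.region_ids is None:
            self.region_ids = np.arange(1, self.n_regions + 1)
        self.region_ids = np.asarray(self.region_ids, dtype=int)
        if self.region_ids.shape != (self.n_regions,):
            raise ValueError("region_ids length must equal n_regions")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def retained_seconds(self) -> float:
        return float(self.retained_mask.sum()) * self.tr_seconds

    def retained_values(self) -> np.ndarray:
        """Signal restricted to retained volumes (regions x retained)."""
        return self.values[:, self.retained_mask]


@dataclass(frozen=True)
class GateResult:
    """Outcome of a subject-level exclusion gate."""

    passed: bool
    reason: str | None = None
    value: float | None = None

    def __bool__(self) -> bool:
        return self.passed


def compute_fd(motion: MotionRecord | np.ndarray,
               head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement per volume, in mm.

    FD[t] = sum of absolute backward differences of the three translations
    plus ``head_radius_mm`` times the sum of absolute backward differences of
    the three rotations; FD[0] is defined as 0.  This is the scrubbing
    convention in which rotations are converted to arc length on a 50 mm
    sphere.
    """
    params = motion.params if isinstance(motion, MotionRecord) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be (n_volumes, 6)")
    if params.shape[0] < 2:
        raise ValueError("FD requires at least 2 volumes")
    d = np.abs(np.diff(params, axis=0))
    fd = np.empty(params.shape[0])
    fd[0] = 0.0
    fd[1:] = head_radius_mm * d[:, :3].sum(axis=1) + d[:, 3:].sum(axis=1)
    return fd


def drop_initial_volumes(series: RoiTimeSeriesMatrix,
                         motion: MotionRecord | None = None,
                         n_drop: int = 15):
    """Delete the first ``n_drop`` volumes (magnetization stabilisation).

    Removes the volumes from the signal, the retained mask and, when given,
    the paired motion record.  Raises ``ValueError`` when no volumes would
    remain (the subject is invalid).
    """
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if series.n_volumes <= n_drop:
        raise ValueError(
            f"cannot drop {n_drop} of {series.n_volumes} volumes: none would remain"
        )
    out = RoiTimeSeriesMatrix(
        values=series.values[:, n_drop:].copy(),
        tr_seconds=series.tr_seconds,
        retained_mask=series.retained_mask[n_drop:].copy(),
        region_ids=series.region_ids.copy(),
    )
    if motion is None:
        return out
    if motion.n_volumes != series.n_volumes:
        raise ValueError("motion record length must match the series")
    trimmed = MotionRecord(motion.params[n_drop:].copy(),
                           mean_rel_displacement=motion.mean_rel_displacement)
    return out, trimmed


def censor_volumes(series: RoiTimeSeriesMatrix, fd: np.ndarray,
                   threshold_mm: float = 0.2) -> RoiTimeSeriesMatrix:
    """Mark volumes whose FD *exceeds* the threshold as not retained.

    The inequality is strict: a volume at exactly the threshold is kept.
    Values are never modified, only the mask.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (series.n_volumes,):
        raise ValueError("fd length must equal n_volumes")
    mask = series.retained_mask & ~(fd > threshold_mm)
    return replace(series, values=series.values, retained_mask=mask)


def subject_motion_gate(motion: MotionRecord | None,
                        threshold_mm: float = 0.2,
                        fd: np.ndarray | None = None) -> GateResult:
    """Exclude a subject whose mean relative displacement is > threshold.

    When the realignment tool's mean relative displacement is unavailable,
    mean FD over the record is used as a documented proxy.  A missing motion
    record fails with a distinct reason code.
    """
    if motion is None:
        return GateResult(False, reason="missing_motion")
    if motion.mean_rel_displacement is not None:
        value = float(motion.mean_rel_displacement)
    else:
        if fd is None:
            fd = compute_fd(motion)
        value = float(np.mean(fd))
    if value > threshold_mm:
        return GateResult(False, reason="motion", value=value)
    return GateResult(True, value=value)


@dataclass
class NuisanceDesign:
    """36-column confound design: 9 base signals, 9 derivatives, 18 squares."""

    columns: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 36:
            raise ValueError("design must have exactly 36 columns")
        if len(self.column_names) != 36:
            raise ValueError("need 36 column names")

    @property
    def n_volumes(self) -> int:
        return self.columns.shape[0]


def build_36p_design(motion: MotionRecord, wm: np.ndarray, csf: np.ndarray,
                     global_sig: np.ndarray) -> NuisanceDesign:
    """Assemble the 36-parameter nuisance design.

    9 base regressors (6 rigid-body parameters + white matter + CSF + global
    signal), their backward-difference temporal derivatives (first element 0),
    and the elementwise squares of those 18.
    """
    wm = np.asarray(wm, float)
    csf = np.asarray(csf, float)
    global_sig = np.asarray(global_sig, float)
    n = motion.n_volumes
    for name, sig in (("wm", wm), ("csf", csf), ("global", global_sig)):
        if sig.shape != (n,):
            raise ValueError(f"{name} signal length {sig.shape} != n_volumes {n}")
    base = np.column_stack([motion.params, wm, csf, global_sig])
    base_names = list(MOTION_COLUMNS) + ["wm", "csf", "global"]
    if np.any(np.all(base == 0.0, axis=0)):
        dead = [base_names[j] for j in range(9) if np.all(base[:, j] == 0.0)]
        warnings.warn(
            f"all-zero base regressor(s) {dead}: design will be rank deficient",
            RankDeficiencyWarning,
        )
    deriv = np.vstack([np.zeros((1, 9)), np.diff(base, axis=0)])
    eighteen = np.hstack([base, deriv])
    cols = np.hstack([eighteen, eighteen**2])
    names = (base_names
             + [f"{s}_d" for s in base_names]
             + [f"{s}_sq" for s in base_names]
             + [f"{s}_d_sq" for s in base_names])
    return NuisanceDesign(cols, tuple(names))


def nuisance_regress(series: RoiTimeSeriesMatrix,
                     design: NuisanceDesign) -> RoiTimeSeriesMatrix:
    """Replace each region's series by its least-squares residual.

    An intercept is appended internally, so residuals are demeaned and
    orthogonal to every design column.  A rank-deficient design is handled by
    the SVD-based least squares (minimum-norm solution) with a warning.
    """
    if design.n_volumes != series.n_volumes:
        raise ValueError("design rows must equal n_volumes")
    X = np.column_stack([np.ones(design.n_volumes), design.columns])
    Y = series.values.T  # volumes x regions
    Q, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    if d.min() < d.max() * max(X.shape) * np.finfo(float).eps:
        warnings.warn(
            "nuisance design is rank deficient: using pseudoinverse",
            RankDeficiencyWarning,
        )
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    else:
        # residual = projection onto the orthogonal complement of span(X)
        resid = Y - Q @ (Q.T @ Y)
    return replace(series, values=resid.T)


def _butter_sos(order: int, low_hz: float, high_hz: float, fs: float):
    return _signal.butter(order, [low_hz, high_hz], btype="bandpass",
                          fs=fs, output="sos")


_SOS_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, int]] = {}


def _zero_phase_sosfilt(sos: np.ndarray, zi: np.ndarray, edge: int,
                        x: np.ndarray) -> np.ndarray:
    """Forward-backward second-order-section filtering along the last axis.

    Odd-extension padding of ``edge`` samples on both ends and step-response
    initial conditions (``zi`` from ``sosfilt_zi``), matching the standard
    zero-phase (filtfilt) construction; ``zi`` is precomputed once per
    filter, which matters when thousands of subjects are filtered.
    """
    if x.shape[-1] <= edge:
        raise ValueError(f"series too short to band-pass (need > {edge} samples)")
    left = 2 * x[..., :1] - x[..., edge:0:-1]
    right = 2 * x[..., -1:] - x[..., -2:-edge - 2:-1]
    ext = np.concatenate([left, x, right], axis=-1)
    zi_shaped = zi.reshape(zi.shape[0], *([1] * (x.ndim - 1)), 2)
    y, _ = _signal.sosfilt(sos, ext, axis=-1, zi=zi_shaped * ext[..., :1])
    y = y[..., ::-1]
    y, _ = _signal.sosfilt(sos, y, axis=-1, zi=zi_shaped * y[..., :1])
    return y[..., ::-1][..., edge:-edge]


def bandpass(series: RoiTimeSeriesMatrix, low_hz: float = 0.01,
             high_hz: float = 0.08, order: int = 2) -> RoiTimeSeriesMatrix:
    """Zero-phase Butterworth band-pass along time.

    Applied forward and backward (``sosfiltfilt``), so the effective
    magnitude response is the squared Butterworth response and the phase is
    zero.  The band must satisfy 0 < low < high < Nyquist = 1/(2 TR).
    """
    fs = 1.0 / series.tr_seconds
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside (0, {nyq}) Hz"
        )
    key = (order, low_hz, high_hz, fs)
    cached = _SOS_CACHE.get(key)
    if cached is None:
        sos = _butter_sos(order, low_hz, high_hz, fs)
        zi = _signal.sosfilt_zi(sos)
        ntaps = 2 * sos.shape[0] + 1
        ntaps -= min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
        cached = (sos, zi, 3 * int(ntaps))
        _SOS_CACHE[key] = cached
    sos, zi, edge = cached
    filtered = _zero_phase_sosfilt(sos, zi, edge, series.values)
    return replace(series, values=filtered)


def duration_gate(series: RoiTimeSeriesMatrix,
                  min_seconds: float = 240.0) -> GateResult:
    """Fail when the retained duration is strictly less than ``min_seconds``."""
    secs = series.retained_seconds
    if secs < min_seconds:
        return GateResult(False, reason="duration", value=secs)
    return GateResult(True, value=secs)


@dataclass
class DenoiseResult:
    """Denoised series plus a QC report; ``passed`` is False when a gate failed."""

    series: RoiTimeSeriesMatrix | None
    passed: bool
    reason: str | None
    qc: dict = field(default_factory=dict)


def denoise_subject(series: RoiTimeSeriesMatrix,
                    motion: MotionRecord,
                    wm: np.ndarray,
                    csf: np.ndarray,
                    global_sig: np.ndarray,
                    *,
                    n_drop: int = 15,
                    fd_threshold_mm: float = 0.2,
                    gate_threshold_mm: float = 0.2,
                    min_seconds: float = 240.0,
                    low_hz: float = 0.01,
                    high_hz: float = 0.08,
                    censor_before_filter: bool = False) -> DenoiseResult:
    """Run the full per-subject denoising chain with exclusion gates.

    Order: drop initial volumes -> FD -> subject motion gate -> 36-parameter
    regression -> band-pass -> censor -> duration gate (censoring may be
    moved before regression/filtering with ``censor_before_filter``).
    """
    if series.n_volumes <= n_drop:
        return DenoiseResult(None, False, "too_few_volumes",
                             {"n_volumes": series.n_volumes})
    # FD is computed on the full motion trace *before* the dummy volumes are
    # discarded, then trimmed: the first retained volume keeps its transition
    # (a movement landing exactly on the boundary would otherwise be lost)
    fd_full = compute_fd(motion)
    series, motion = drop_initial_volumes(series, motion, n_drop=n_drop)
    wm = np.asarray(wm, float)[n_drop:]
    csf = np.asarray(csf, float)[n_drop:]
    global_sig = np.asarray(global_sig, float)[n_drop:]
    fd = fd_full[n_drop:]
    gate = subject_motion_gate(motion, gate_threshold_mm, fd=fd)
    qc = {"mean_displacement_mm": gate.value, "n_volumes": series.n_volumes}
    if not gate:
        return DenoiseResult(None, False, gate.reason, qc)

    design = build_36p_design(motion, wm, csf, global_sig)
    if censor_before_filter:
        series = censor_volumes(series, fd, fd_threshold_mm)
    series = nuisance_regress(series, design)
    series = bandpass(series, low_hz=low_hz, high_hz=high_hz)
    if not censor_before_filter:
        series = censor_volumes(series, fd, fd_threshold_mm)

    qc["n_censored"] = int((~series.retained_mask).sum())
    qc["retained_seconds"] = series.retained_seconds
    dgate = duration_gate(series, min_seconds)
    if not dgate:
        return DenoiseResult(None, False, dgate.reason, qc)
    return DenoiseResult(series, True, None, qc)
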