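"""Synthetic resting-state cohort: covariates, BOLD ROI series, motion.

Generates seeded synthetic subjects so the whole pipeline is testable
without any imaging data.  Three pieces per subject:

* covariates drawn to match the demographic marginals of an elderly
  (65+) surgical cohort — age, premorbid IQ, MMSE, depression, alcohol
  misuse, Barthel index, TIA/stroke history, ASA physical status, centre
  and gender;
* region-by-volume BOLD series drawn from a zero-mean multivariate normal
  with a block-structured ("modular") correlation matrix, optionally with
  a planted covariate effect on global coupling, plus shared low-frequency
  tissue confounds (WM / CSF / global) added to every region;
* six-parameter rigid-body motion traces: smooth low-amplitude drift plus
  step-like spikes whose framewise displacement exceeds the 0.2 mm
  scrubbing threshold by construction.

Planted effect.  Each subject's correlation matrix is
``C_i = m_i * C + (1 - m_i) * I`` (off-diagonals of the base matrix C
scaled by a coupling multiplier ``m_i``).  The multiplier is

    m_i = 1 + s * (gamma * z_i + sqrt(1 - gamma^2) * eta_i)

where ``z_i`` is the standardized planted covariate, ``eta_i ~ N(0,1)`` is
subject-level coupling noise and ``s`` (``coupling_sd``) sets the
between-subject spread of global coupling.  By construction
``corr(z_i, m_i) = gamma``, so ``gamma`` is the *standardized* slope of the
covariate on connectivity scaling, and the downstream standardized
regression coefficient of the covariate on mean spanning-tree edge weight
recovers ``gamma`` up to attenuation by sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import sqrt

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .denoise import MotionRecord, RoiTimeSeriesMatrix

__all__ = [
    "CovariateModel",
    "SimulationConfig",
    "COHORT_COLUMNS",
    "gen_covariates",
    "gen_base_correlation",
    "nearest_psd_correlation",
    "coupling_multiplier",
    "subject_correlation_target",
    "gen_subject_timeseries",
    "gen_tissue_signals",
    "gen_motion_trace",
    "SubjectData",
    "simulate_subject",
    "simulate_cohort_subjects",
]

#: cohort table column order (binary columns coded 0/1; center 1 = Berlin,
#: gender 1 = male)
COHORT_COLUMNS = ("id", "center", "gender", "age", "iq", "alcohol_misuse",
                  "mmse", "depression", "barthel", "tia_stroke",
                  "asa_unhealthy")


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of the cohort covariates.

    Defaults reproduce the included-sample demographics of the study cohort
    the generator emulates: mean age 71.2 (SD 4.9, truncated at 65), IQ
    105 +/- 12.2, MMSE 28.7 +/- 1.4 (floor 24: lower scores are an exclusion
    criterion), Barthel 98.4 +/- 4.8, and prevalences — male 63%, Berlin
    centre 30%, alcohol misuse 5%, depression 5%, TIA/stroke 24%,
    ASA-unhealthy 86%.
    """

    p_berlin: float = 0.30
    p_male: float = 0.63
    age_mean: float = 71.2
    age_sd: float = 4.9
    age_min: float = 65.0
    iq_mean: float = 105.0
    iq_sd: float = 12.2
    p_alcohol: float = 0.05
    mmse_mean: float = 28.7
    mmse_sd: float = 1.4
    mmse_min: int = 24
    mmse_max: int = 30
    p_depression: float = 0.05
    barthel_mean: float = 98.4
    barthel_sd: float = 4.8
    p_tia_stroke: float = 0.24
    p_asa_unhealthy: float = 0.86


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    ``n_modules`` splits the regions into (as equal as possible, non-empty)
    blocks with correlation ``within_block_r`` inside a block and
    ``between_block_r`` across blocks.  ``planted_covariate`` /
    ``planted_gamma`` plant a standardized effect of that covariate on
    global coupling (see module docstring); ``coupling_sd`` is the
    between-subject SD of the coupling multiplier.  ``motion_spike_prob``
    is the per-transition probability of a motion spike.
    """

    n_subjects: int
    n_regions: int = 264
    n_volumes: int = 238
    tr_seconds: float = 2.0
    n_modules: int = 8
    within_block_r: float = 0.4
    between_block_r: float = 0.1
    planted_covariate: str | None = "age"
    planted_gamma: float = 0.18
    coupling_sd: float = 0.2
    motion_spike_prob: float = 0.05
    confound_gain: float = 0.5
    seed: int = 0
    covariates: CovariateModel = field(default_factory=CovariateModel)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not (1 <= self.n_modules <= self.n_regions):
            raise ValueError("n_modules must divide regions into non-empty blocks")
        if not (0.0 <= self.between_block_r <= self.within_block_r < 1.0):
            raise ValueError("need 0 <= between_block_r <= within_block_r < 1")
        if not (0.0 <= self.motion_spike_prob <= 1.0):
            raise ValueError("motion_spike_prob must be a probability")
        if not (-1.0 <= self.planted_gamma <= 1.0):
            raise ValueError("planted_gamma must lie in [-1, 1]")
        if self.coupling_sd < 0:
            raise ValueError("coupling_sd must be >= 0")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    """Independent deterministic stream keyed on (seed, stream ids)."""
    return np.random.default_rng([config.seed, *stream])


# ---------------------------------------------------------------------------
# covariates


@lru_cache(maxsize=64)
def _truncnorm_with_mean(target_mean: float, sd: float, lo: float,
                         hi: float = np.inf):
    """Truncated normal on [lo, hi] whose *truncated* mean equals the target.

    Truncation shifts the mean of a normal (e.g. truncating N(71.2, 4.9) at
    65 inflates the mean to ~72.2), so the location parameter is solved
    numerically to keep the configured marginal mean honest.
    """
    if not (lo < target_mean < hi):
        raise ValueError(
            f"impossible truncation: target mean {target_mean} outside ({lo}, {hi})"
        )

    def dist_for(scale):
        def gap(loc):
            a = (lo - loc) / scale
            b = (hi - loc) / scale if np.isfinite(hi) else np.inf
            return truncnorm.mean(a, b, loc=loc, scale=scale) - target_mean

        # expand the location bracket until it straddles the root (a large
        # scale can require a location tens of scales below the target)
        span = max(8 * scale, 8 * sd)
        left, right = target_mean - span, target_mean + span
        for _ in range(40):
            if gap(left) < 0 < gap(right):
                break
            if gap(left) >= 0:
                left -= span
            if gap(right) <= 0:
                right += span
        loc = brentq(gap, left, right, xtol=1e-10)
        a = (lo - loc) / scale
        b = (hi - loc) / scale if np.isfinite(hi) else np.inf
        return truncnorm(a, b, loc=loc, scale=scale)

    # also try to match the target SD by searching over the scale; near a
    # bound (e.g. a score ceiling) the printed SD may be unattainable for a
    # truncated normal, in which case only the mean is matched
    def sd_gap(scale):
        return dist_for(scale).std() - sd

    lo_s, hi_s = 0.2 * sd, 25 * sd
    try:
        if sd_gap(lo_s) < 0 < sd_gap(hi_s):
            scale = brentq(sd_gap, lo_s, hi_s, xtol=1e-8)
            return dist_for(scale)
    except ValueError:
        pass
    return dist_for(sd)


def gen_covariates(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the cohort covariate table (one row per subject).

    Age is a truncated normal (lower bound ``age_min``); MMSE is a rounded
    truncated normal on [mmse_min, mmse_max]; Barthel is a rounded clipped
    normal on [0, 100]; binary factors are Bernoulli with the configured
    prevalences.
    """
    cm = config.covariates
    n = config.n_subjects
    if rng is None:
        rng = _rng(config, 0)

    if cm.age_sd < 0:
        raise ValueError("age_sd must be >= 0")
    if cm.age_sd == 0:
        if cm.age_mean < cm.age_min:
            raise ValueError("degenerate age distribution below truncation bound")
        age = np.full(n, float(cm.age_mean))
    else:
        age = _truncnorm_with_mean(cm.age_mean, cm.age_sd,
                                   cm.age_min).rvs(n, random_state=rng)

    if cm.mmse_sd == 0:
        mmse = np.full(n, round(cm.mmse_mean))
    else:
        dist = _truncnorm_with_mean(cm.mmse_mean, cm.mmse_sd,
                                    cm.mmse_min - 0.49, cm.mmse_max + 0.49)
        mmse = np.clip(np.rint(dist.rvs(n, random_state=rng)),
                       cm.mmse_min, cm.mmse_max)

    bdist = _truncnorm_with_mean(cm.barthel_mean, cm.barthel_sd, -0.49, 100.49)
    barthel = np.clip(np.rint(bdist.rvs(n, random_state=rng)), 0, 100)
    iq = np.rint(rng.normal(cm.iq_mean, cm.iq_sd, n))

    df = pd.DataFrame({
        "id": [f"sub-{i + 1:04d}" for i in range(n)],
        "center": (rng.random(n) < cm.p_berlin).astype(int),
        "gender": (rng.random(n) < cm.p_male).astype(int),
        "age": age,
        "iq": iq,
        "alcohol_misuse": (rng.random(n) < cm.p_alcohol).astype(int),
        "mmse": mmse.astype(int),
        "depression": (rng.random(n) < cm.p_depression).astype(int),
        "barthel": barthel.astype(int),
        "tia_stroke": (rng.random(n) < cm.p_tia_stroke).astype(int),
        "asa_unhealthy": (rng.random(n) < cm.p_asa_unhealthy).astype(int),
    })
    return df[list(COHORT_COLUMNS)]


# ---------------------------------------------------------------------------
# base correlation structure


def _block_sizes(n_regions: int, n_modules: int) -> list[int]:
    base, rem = divmod(n_regions, n_modules)
    return [base + 1] * rem + [base] * (n_modules - rem)


def gen_base_correlation(config: SimulationConfig) -> np.ndarray:
    """Block-structured base correlation matrix (symmetric, unit diagonal).

    With within-block correlation w and between-block correlation b,
    0 <= b <= w < 1, the matrix is b*J + (w-b)*blockdiag(J) + (1-w)*I which
    is positive semidefinite by construction; a PSD check (and repair via
    eigenvalue clipping) still runs as a guard.
    """
    n = config.n_regions
    C = np.full((n, n), config.between_block_r)
    start = 0
    for size in _block_sizes(n, config.n_modules):
        C[start:start + size, start:start + size] = config.within_block_r
        start += size
    np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() < -1e-8:
        C = nearest_psd_correlation(C)
    return C


def nearest_psd_correlation(C: np.ndarray,
                            irreparable_min_eig: float = -0.1) -> np.ndarray:
    """Repair a nearly-PSD correlation matrix.

    Clips negative eigenvalues at zero and rescales to unit diagonal.
    A matrix whose smallest eigenvalue is below ``irreparable_min_eig`` is
    considered too indefinite to repair meaningfully and raises.
    """
    w, V = np.linalg.eigh(np.asarray(C, float))
    if w.min() < irreparable_min_eig:
        raise ValueError(
            f"correlation matrix is irreparably non-PSD (min eig {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    if np.any(d <= 0):
        raise ValueError("repair collapsed a diagonal entry to zero")
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A


# ---------------------------------------------------------------------------
# per-subject time series


def coupling_multiplier(z_cov: float, config: SimulationConfig,
                        eta: float | None = None,
                        rng: np.random.Generator | None = None) -> float:
    """Subject coupling multiplier m = 1 + s*(gamma*z + sqrt(1-gamma^2)*eta).

    Pass ``eta=0`` for the deterministic expected multiplier (used by
    construction oracles); otherwise eta is drawn from ``rng``.
    """
    g = config.planted_gamma if config.planted_covariate is not None else 0.0
    if eta is None:
        if rng is None:
            raise ValueError("need rng when eta is not supplied")
        eta = float(rng.standard_normal())
    # the standardized deviate is truncated at +/-3.5 so the multiplier is
    # always positive at the default coupling_sd (negligible distortion)
    dev = float(np.clip(g * z_cov + sqrt(max(0.0, 1.0 - g * g)) * eta, -3.5, 3.5))
    m = 1.0 + config.coupling_sd * dev
    if m <= 0:
        raise ValueError(f"coupling multiplier {m:.3g} is non-positive")
    return m


def subject_correlation_target(base: np.ndarray, m: float) -> np.ndarray:
    """Target correlation with off-diagonals of ``base`` scaled by ``m``.

    Equals ``m*base + (1-m)*I``; raises when scaling pushes any |r| >= 1.
    """
    base = np.asarray(base, float)
    n = base.shape[0]
    off = base[~np.eye(n, dtype=bool)]
    if off.size and np.max(np.abs(off)) * m >= 1.0:
        raise ValueError("coupling multiplier pushes an off-diagonal |r| >= 1")
    C = m * base + (1.0 - m) * np.eye(n)
    return nearest_psd_correlation(C) if m > 1.0 else C


def _sample_factor(base: np.ndarray, m: float,
                   eig: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """A matrix A with A @ A.T equal to the subject's target correlation.

    Uses the eigendecomposition of the base matrix: the target
    m*C + (1-m)*I has the same eigenvectors with eigenvalues m*w + (1-m),
    clipped at 0 (the PSD re-repair).
    """
    if eig is None:
        w, V = np.linalg.eigh(base)
    else:
        w, V = eig
    wi = np.clip(m * w + (1.0 - m), 0.0, None)
    return V * np.sqrt(wi)


def gen_subject_timeseries(base: np.ndarray,
                           z_cov: float,
                           config: SimulationConfig,
                           rng: np.random.Generator,
                           *,
                           eig: tuple[np.ndarray, np.ndarray] | None = None,
                           confound: np.ndarray | None = None,
                           m: float | None = None) -> RoiTimeSeriesMatrix:
    """Sample one subject's region-by-volume BOLD series.

    Draws ``n_volumes`` iid samples from N(0, C_i) where C_i is the base
    correlation with off-diagonals scaled by the subject's coupling
    multiplier, then adds the shared ``confound`` signal (one value per
    volume) to every region when given.
    """
    if m is None:
        m = coupling_multiplier(z_cov, config, rng=rng)
    base = np.asarray(base, float)
    n = base.shape[0]
    cmax = float(np.max(np.abs(base - np.eye(n)))) if n > 1 else 0.0
    if cmax * m >= 1.0:
        raise ValueError("coupling multiplier pushes an off-diagonal |r| >= 1")
    A = _sample_factor(base, m, eig=eig)
    X = rng.standard_normal((config.n_volumes, n)) @ A.T  # volumes x regions
    values = X.T
    if confound is not None:
        values = values + np.asarray(confound, float)[None, :]
    return RoiTimeSeriesMatrix(values=values, tr_seconds=config.tr_seconds)


def gen_tissue_signals(config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WM, CSF and global tissue signals: smooth low-frequency confounds.

    Each is a sum of three sinusoids with frequencies in 0.005-0.03 Hz and
    random phases, standardized to zero mean and unit variance.
    """
    t = np.arange(config.n_volumes) * config.tr_seconds

    def one() -> np.ndarray:
        f = rng.uniform(0.005, 0.03, 3)
        phi = rng.uniform(0, 2 * np.pi, 3)
        amp = rng.uniform(0.5, 1.0, 3)
        s = (amp[:, None] * np.sin(2 * np.pi * f[:, None] * t + phi[:, None])).sum(0)
        s = s - s.mean()
        sd = s.std()
        return s / sd if sd > 0 else s

    return one(), one(), one()


# ---------------------------------------------------------------------------
# motion


#: drift amplitudes keep the worst-case drift FD well below the 0.2 mm
#: scrubbing threshold: sinusoid bound 6 * amp * 2*pi*f_max*TR ~ 0.076 mm
#: plus clipped random-walk bound 6 * 3 * step_sd (x50 for rotations)
#: ~ 0.072 mm, total < 0.15 mm < 0.2 mm
_DRIFT_TRANS_AMP = (0.01, 0.04)   # mm
_DRIFT_ROT_AMP = (0.0002, 0.0008)  # rad  (x50 mm -> 0.01-0.04 mm arc)
_DRIFT_FREQ = (0.005, 0.02)       # Hz
_WALK_TRANS_SD = 0.004            # mm per step, clipped at 3 sd
_WALK_ROT_SD = 0.00008            # rad per step, clipped at 3 sd
_SPIKE_STEP = (0.3, 0.8)          # mm translation step at a spike


def gen_motion_trace(config: SimulationConfig,
                     rng: np.random.Generator,
                     threshold_mm: float = 0.2) -> tuple[MotionRecord, np.ndarray]:
    """Six-parameter motion trace: smooth drift plus step-like spikes.

    Returns the record and the boolean spike mask (per volume; volume 0 is
    never a spike).  By construction spike volumes have FD > ``threshold_mm``
    and non-spike volumes FD <= ``threshold_mm``: spikes are persistent
    position steps, so only the transition into the spike volume exceeds the
    threshold.
    """
    T = config.n_volumes
    t = np.arange(T) * config.tr_seconds
    params = np.zeros((T, 6))
    for c in range(6):
        lo, hi = _DRIFT_ROT_AMP if c < 3 else _DRIFT_TRANS_AMP
        amp = rng.uniform(lo, hi)
        f = rng.uniform(*_DRIFT_FREQ)
        phi = rng.uniform(0, 2 * np.pi)
        # sinusoid + clipped random walk: the walk breaks the algebraic
        # dependence a pure sinusoid would induce among the 36 regressors
        # (sin^2 and its derivative-square are collinear with the intercept)
        sd = _WALK_ROT_SD if c < 3 else _WALK_TRANS_SD
        steps = np.clip(rng.normal(0.0, sd, T), -3 * sd, 3 * sd)
        steps[0] = 0.0
        params[:, c] = amp * np.sin(2 * np.pi * f * t + phi) + np.cumsum(steps)

    spikes = np.zeros(T, dtype=bool)
    spikes[1:] = rng.random(T - 1) < config.motion_spike_prob
    for v in np.flatnonzero(spikes):
        ch = int(rng.integers(3, 6))
        delta = float(rng.choice([-1.0, 1.0]) * rng.uniform(*_SPIKE_STEP))
        params[v:, ch] += delta
    return MotionRecord(params), spikes


# ---------------------------------------------------------------------------
# whole subjects / cohorts


@dataclass
class SubjectData:
    """Everything the pipeline needs for one synthetic subject."""

    subject_id: str
    series: RoiTimeSeriesMatrix
    motion: MotionRecord
    spikes: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    global_sig: np.ndarray


def simulate_subject(config: SimulationConfig,
                     base: np.ndarray,
                     subject_index: int,
                     z_cov: float,
                     subject_id: str | None = None,
                     eig: tuple[np.ndarray, np.ndarray] | None = None) -> SubjectData:
    """Simulate one subject (deterministic given config.seed and index)."""
    rng = _rng(config, 2, subject_index)
    wm, csf, gs = gen_tissue_signals(config, rng)
    gains = rng.uniform(0.3, 0.9, 3) * config.confound_gain
    confound = gains[0] * wm + gains[1] * csf + gains[2] * gs
    series = gen_subject_timeseries(base, z_cov, config, rng, eig=eig,
                                    confound=confound)
    motion, spikes = gen_motion_trace(config, rng)
    return SubjectData(
        subject_id=subject_id or f"sub-{subject_index + 1:04d}",
        series=series, motion=motion, spikes=spikes,
        wm=wm, csf=csf, global_sig=gs,
    )


def simulate_cohort_subjects(config: SimulationConfig):
    """Yield (covariates row, SubjectData) for every subject.

    Standardizes the planted covariate within the cohort; subjects are
    generated from per-subject streams, so any subset is reproducible.
    """
    cov = gen_covariates(config)
    base = gen_base_correlation(config)
    eig = np.linalg.eigh(base)
    eig = (eig[0], eig[1])
    if config.planted_covariate is not None:
        x = cov[config.planted_covariate].to_numpy(float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    else:
        z = np.zeros(config.n_subjects)
    for i in range(config.n_subjects):
        yield cov.iloc[i], simulate_subject(config, base, i, float(z[i]),
                                            subject_id=cov["id"].iloc[i],
                                            eig=eig)
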