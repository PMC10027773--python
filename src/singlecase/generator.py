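"""Autocorrelated time-series generation with initial-instability screening.

Single-case (n-of-1) AB designs start treatment only after a baseline
phase.  To study what "waiting for baseline stability" buys, we need
series that are *initially unstable*: a lag-1 autoregressive process

    y_t = x_t + 10,        x_t = a * x_{t-1} + eps_t,   x_0 = 0

with standard-normal innovations (trend experiment) or Uniform(-3, 3)
innovations (variability experiment), kept by rejection sampling only
when the first ``min_a`` baseline points look unstable: a fitted trend
steeper than a maximum allowable angle (trend experiment), or a sample
standard deviation of the last three baseline points above a maximum
allowable SD (variability experiment).

Every retained series has exactly 30 points; phases are carved out of it
downstream (:mod:`singlecase.phases`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

TREND = "trend"
VARIABILITY = "variability"
EXPERIMENTS = (TREND, VARIABILITY)

#: Length of every simulated latent series.
SERIES_LENGTH = 30

#: Constant added to the AR(1) process so series stay positive.
BASELINE_OFFSET = 10.0

#: Uniform(-3, 3) innovations have SD sqrt(3) ~= 1.73; injected effects in the
#: variability experiment are scaled by this factor so standardized mean
#: differences remain comparable across experiments.
UNIFORM_SMD_SCALE = 1.73

#: Rejection-sampling safety cap (attempts per requested series).
MAX_REJECTION_ATTEMPTS = 1_000_000

_MIN_A_VALUES = (3, 5)
_N_B_VALUES = (5, 10)
_AUTOCORR_VALUES = (0.0, 0.4)
_TREND_THRESHOLDS = (15.0, 30.0)
_SD_THRESHOLDS = (1.0, 1.5)
_SMD_VALUES = tuple(range(6))


class ScreeningError(RuntimeError):
    """Rejection sampling exhausted its attempt budget for a condition."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the factorial simulation design.

    Parameters
    ----------
    experiment:
        ``"trend"`` (normal innovations, trend-angle stability criterion)
        or ``"variability"`` (uniform innovations, last-three-point SD
        criterion).
    min_a:
        Minimum number of baseline (phase A) sessions, 3 or 5.  Fixed
        graphs use exactly this many.
    n_b:
        Number of treatment (phase B) sessions, 5 or 10.
    autocorr:
        Lag-1 autocorrelation ``a`` of the generating process, 0.0 or 0.4.
    stability_threshold:
        Maximum allowable trend in degrees (15 or 30) for the trend
        experiment; maximum allowable SD (1.0 or 1.5) for the variability
        experiment.
    smd:
        Standardized mean difference injected into phase B, integer 0-5.
        0 means a null (no-effect) series.
    """

    experiment: str
    min_a: int
    n_b: int
    autocorr: float
    stability_threshold: float
    smd: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.min_a not in _MIN_A_VALUES:
            raise ValueError(f"min_a must be one of {_MIN_A_VALUES}, got {self.min_a}")
        if self.n_b not in _N_B_VALUES:
            raise ValueError(f"n_b must be one of {_N_B_VALUES}, got {self.n_b}")
        if self.autocorr not in _AUTOCORR_VALUES:
            raise ValueError(
                f"autocorr must be one of {_AUTOCORR_VALUES}, got {self.autocorr}"
            )
        thresholds = _TREND_THRESHOLDS if self.experiment == TREND else _SD_THRESHOLDS
        if float(self.stability_threshold) not in thresholds:
            raise ValueError(
                f"stability_threshold must be one of {thresholds} for the "
                f"{self.experiment} experiment, got {self.stability_threshold}"
            )
        if self.smd not in _SMD_VALUES:
            raise ValueError(f"smd must be an integer in 0..5, got {self.smd}")

    @property
    def noise(self) -> str:
        """Innovation family implied by the experiment."""
        return "normal" if self.experiment == TREND else "uniform"

    @property
    def max_a(self) -> int:
        """Largest phase-A length leaving room for phase B."""
        return SERIES_LENGTH - self.n_b

    @property
    def effect_delta(self) -> float:
        """Constant added to every phase-B point (SMD, scaled for uniform noise)."""
        scale = UNIFORM_SMD_SCALE if self.experiment == VARIABILITY else 1.0
        return self.smd * scale


def _draw_innovations(
    rng: np.random.Generator, noise: str, size: int | tuple[int, ...]
) -> np.ndarray:
    if noise == "normal":
        return rng.standard_normal(size)
    if noise == "uniform":
        return rng.uniform(-3.0, 3.0, size)
    raise ValueError(f"noise must be 'normal' or 'uniform', got {noise!r}")


def generate_raw_series(
    autocorr: float,
    n_points: int,
    noise: str = "normal",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one AR(1) series ``y_t = x_t + 10`` of length ``n_points``.

    The recursion ``x_t = autocorr * x_{t-1} + eps_t`` starts from
    ``x_0 = 0`` (no burn-in), so the first point is ``eps_1 + 10``.
    """
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    if not 0.0 <= autocorr < 1.0:
        raise ValueError(f"autocorr must be in [0, 1), got {autocorr}")
    rng = np.random.default_rng() if rng is None else rng
    eps = _draw_innovations(rng, noise, n_points)
    x = signal.lfilter([1.0], [1.0, -autocorr], eps)
    return x + BASELINE_OFFSET


def generate_raw_batch(
    autocorr: float,
    n_series: int,
    n_points: int,
    noise: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised ``generate_raw_series``: returns ``(n_series, n_points)``."""
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    if not 0.0 <= autocorr < 1.0:
        raise ValueError(f"autocorr must be in [0, 1), got {autocorr}")
    eps = _draw_innovations(rng, noise, (n_series, n_points))
    x = signal.lfilter([1.0], [1.0, -autocorr], eps, axis=1)
    return x + BASELINE_OFFSET


def ols_slopes(values: np.ndarray) -> np.ndarray:
    """OLS slope of each row against session indices 0, 1, 2, ...

    Closed-form normal equations; accepts a 1-D series or a 2-D stack.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    m = values.shape[1]
    if m < 2:
        raise ValueError("need at least 2 values to fit a trend")
    idx = np.arange(m, dtype=float)
    xc = idx - idx.mean()
    return values @ xc / (xc @ xc)


def trend_angle(values: np.ndarray) -> float:
    """Angle (degrees) of the OLS trend of ``values`` over unit-spaced sessions.

    ``arctan(slope) * 180 / pi`` with sessions indexed 0, 1, 2, ...  The axes
    are commensurate because innovations have unit SD.
    """
    slope = ols_slopes(np.asarray(values, dtype=float).ravel())[0]
    return float(np.degrees(np.arctan(slope)))


def trend_angles(values: np.ndarray) -> np.ndarray:
    """Row-wise :func:`trend_angle` for a 2-D stack of series."""
    return np.degrees(np.arctan(ols_slopes(values)))


def last3_sd(values: np.ndarray, end: int) -> np.ndarray:
    """Sample SD (n-1 denominator) of columns ``end-3 .. end-1`` per row."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if end < 3:
        raise ValueError("need at least 3 points for the SD criterion")
    return values[:, end - 3 : end].std(axis=1, ddof=1)


def _screening_stat(values: np.ndarray, spec: ConditionSpec, end: int) -> np.ndarray:
    """Instability statistic over the first ``end`` points, per row."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if spec.experiment == TREND:
        return np.abs(trend_angles(values[:, :end]))
    return last3_sd(values, end)


def is_initially_unstable(values: np.ndarray, spec: ConditionSpec) -> bool:
    """Does the series fail the stability criterion at its first ``min_a`` points?

    Trend experiment: absolute trend angle over the first ``min_a`` points
    exceeds the maximum allowable trend.  Variability experiment: sample SD
    of the last three of the first ``min_a`` points exceeds the maximum
    allowable SD.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) < spec.min_a:
        raise ValueError(f"need at least min_a={spec.min_a} values")
    stat = _screening_stat(values[None, :], spec, spec.min_a)[0]
    return bool(stat > spec.stability_threshold)


def sample_screened_series(
    spec: ConditionSpec,
    rng: np.random.Generator,
    max_attempts: int = MAX_REJECTION_ATTEMPTS,
) -> np.ndarray:
    """Rejection-sample one 30-point series that is initially unstable."""
    for _ in range(max_attempts):
        series = generate_raw_series(spec.autocorr, SERIES_LENGTH, spec.noise, rng)
        if is_initially_unstable(series, spec):
            return series
    raise ScreeningError(
        f"no initially unstable series found in {max_attempts} attempts for {spec}"
    )


def sample_screened_batch(
    spec: ConditionSpec,
    n_series: int,
    rng: np.random.Generator,
    max_attempts: int = MAX_REJECTION_ATTEMPTS,
) -> np.ndarray:
    """Rejection-sample ``n_series`` screened series at once.

    Functionally equivalent to repeated :func:`sample_screened_series`
    (each retained row is initially unstable) but draws candidate series
    in vectorised chunks, so the random stream differs from the scalar
    loop for the same generator state.
    """
    out = np.empty((n_series, SERIES_LENGTH))
    filled = 0
    attempts = 0
    budget = max_attempts * max(n_series, 1)
    while filled < n_series:
        chunk = min(max(1024, 2 * (n_series - filled)), budget - attempts)
        if chunk <= 0:
            raise ScreeningError(
                f"no initially unstable series found within the attempt budget "
                f"for {spec}"
            )
        attempts += chunk
        cand = generate_raw_batch(spec.autocorr, chunk, SERIES_LENGTH, spec.noise, rng)
        stat = _screening_stat(cand, spec, spec.min_a)
        keep = cand[stat > spec.stability_threshold]
        take = min(len(keep), n_series - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out
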