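"""Breath-by-breath metabolic cost estimation.

Indirect calorimetry gives oxygen uptake and carbon-dioxide production per
breath; the Brockway equation converts these to metabolic power.  Because
the respiratory response lags mechanical demand with a time constant of
roughly 42 s, the *instantaneous* energetic cost driving the response is
recovered by inverting a first-order dynamic model of the breath-level
response

    r_i = (1 - h_i/tau) * r_{i-1} + (h_i/tau) * c_i,

where ``r_i`` is the measured metabolic power at breath ``i`` and ``h_i``
the elapsed time since the previous breath.  The inverted samples ``c_i``
are then summarised either by a constant fit (zero-order model, used by
Bayesian optimization) or by a linear-in-step-frequency fit (used by
gradient descent to obtain the cost slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BROCKWAY_O2_J_PER_ML",
    "BROCKWAY_CO2_J_PER_ML",
    "DEFAULT_TAU_S",
    "BreathRecord",
    "BreathSeries",
    "CostModel",
    "brockway_power",
    "invert_dynamics",
    "estimate_cost_zero_order",
    "estimate_cost_linear",
    "forward_response",
    "estimate_step_frequency",
]

# Energy equivalents of respiratory gas exchange (J per mL of gas).
# Overridable where a different calorimetric convention is needed.
BROCKWAY_O2_J_PER_ML = 16.58
BROCKWAY_CO2_J_PER_ML = 4.51

#: Respiratory time constant used throughout (seconds).
DEFAULT_TAU_S = 42.0


def brockway_power(
    vo2: float | np.ndarray,
    vco2: float | np.ndarray,
    *,
    o2_coef: float = BROCKWAY_O2_J_PER_ML,
    co2_coef: float = BROCKWAY_CO2_J_PER_ML,
) -> float | np.ndarray:
    """Metabolic power (W) from gas-exchange rates (mL/min).

    Parameters
    ----------
    vo2, vco2
        Oxygen uptake and carbon-dioxide production rates in mL/min.
        Scalars or arrays; must be non-negative.

    Returns
    -------
    Metabolic power in watts: ``(o2_coef*vo2 + co2_coef*vco2) / 60``.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas-exchange rates must be non-negative")
    power = (o2_coef * vo2 + co2_coef * vco2) / 60.0
    return float(power) if power.ndim == 0 else power


@dataclass(frozen=True)
class BreathRecord:
    """A single breath: time, interval, gas exchange, derived power."""

    t: float                    # time since bout start (s)
    h: float                    # elapsed time since previous breath (s)
    vo2: float | None = None    # mL/min
    vco2: float | None = None   # mL/min
    power: float | None = None  # metabolic power (W); derived if None
    x_meas: float | None = None  # measured step frequency (Hz)

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError(f"breath interval h must be > 0, got {self.h}")
        if self.power is None:
            if self.vo2 is None or self.vco2 is None:
                raise ValueError("need either power or (vo2, vco2)")
            object.__setattr__(self, "power", brockway_power(self.vo2, self.vco2))


@dataclass
class BreathSeries:
    """Ordered breath-by-breath record of one walking or standing bout.

    Stored column-wise as numpy arrays.  ``power`` is in watts; ``x_meas``
    (measured step frequency, Hz) is optional and NaN where unknown.
    """

    t: np.ndarray
    h: np.ndarray
    power: np.ndarray
    vo2: np.ndarray | None = None
    vco2: np.ndarray | None = None
    x_meas: np.ndarray | None = None
    mass: float | None = None  # body mass (kg), for W/kg normalisation

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.t) != len(self.h) or len(self.t) != len(self.power):
            raise ValueError("t, h, power must have equal length")
        if np.any(self.h <= 0):
            raise ValueError("all breath intervals must be positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("breath timestamps must be strictly increasing")
        for name in ("vo2", "vco2", "x_meas"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.t):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_records(cls, records: Sequence[BreathRecord],
                     mass: float | None = None) -> "BreathSeries":
        if not records:
            raise ValueError("empty record list")
        has_gas = all(r.vo2 is not None for r in records)
        has_x = all(r.x_meas is not None for r in records)
        return cls(
            t=np.array([r.t for r in records]),
            h=np.array([r.h for r in records]),
            power=np.array([r.power for r in records]),
            vo2=np.array([r.vo2 for r in records]) if has_gas else None,
            vco2=np.array([r.vco2 for r in records]) if has_gas else None,
            x_meas=np.array([r.x_meas for r in records]) if has_x else None,
            mass=mass,
        )

    @property
    def records(self) -> list[BreathRecord]:
        out = []
        for i in range(len(self)):
            out.append(BreathRecord(
                t=float(self.t[i]), h=float(self.h[i]),
                vo2=None if self.vo2 is None else float(self.vo2[i]),
                vco2=None if self.vco2 is None else float(self.vco2[i]),
                power=float(self.power[i]),
                x_meas=None if self.x_meas is None else float(self.x_meas[i]),
            ))
        return out

    @property
    def duration(self) -> float:
        """Total bout duration in seconds (sum of breath intervals)."""
        return float(np.sum(self.h))


@dataclass(frozen=True)
class CostModel:
    """Linear instantaneous-cost model ``c(x) = lambda1 * x + lambda0``."""

    lambda1: float            # cost slope (cost-units per Hz)
    lambda0: float            # cost intercept (cost-units)
    tau: float = DEFAULT_TAU_S  # respiratory time constant (s)

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.lambda1 * x + self.lambda0


def invert_dynamics(series: BreathSeries, tau: float = DEFAULT_TAU_S
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Recover instantaneous cost samples by inverting the breath dynamics.

    The first breath seeds the dynamic state; for every later breath

        c_i = r_{i-1} + (tau / h_i) * (r_i - r_{i-1}).

    Returns
    -------
    (c, x) where ``c`` has length ``len(series) - 1`` and ``x`` are the
    paired measured step frequencies (``None`` if the series carries none).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(series) < 2:
        raise ValueError("need at least two breaths to invert the dynamics")
    r = series.power
    h = series.h[1:]
    c = r[:-1] + (tau / h) * np.diff(r)
    x = None if series.x_meas is None else series.x_meas[1:]
    return c, x


def estimate_cost_zero_order(series: BreathSeries, tau: float = DEFAULT_TAU_S,
                             *, trim_sd: float | None = None) -> float:
    """Zero-order (constant) instantaneous cost: mean of the inverted samples.

    ``trim_sd`` optionally discards inverted samples more than that many
    sample standard deviations from the mean before averaging (off by
    default: no outlier rejection).
    """
    c, _ = invert_dynamics(series, tau)
    if trim_sd is not None:
        sd = np.std(c)
        if sd > 0:
            keep = np.abs(c - np.mean(c)) <= trim_sd * sd
            if keep.any():
                c = c[keep]
    return float(np.mean(c))


def estimate_cost_linear(series: BreathSeries, tau: float = DEFAULT_TAU_S,
                         *, method: str = "ols") -> CostModel:
    """Fit the linear cost model c(x) = lambda1*x + lambda0.

    ``method="ols"`` (default) regresses the inverted instantaneous-cost
    samples on the paired measured step frequencies.  ``method="forward"``
    instead fits (lambda1, lambda0) by least squares on the *measured*
    response: the model response is propagated through the first-order
    dynamics from the observed initial breath, which is linear in the
    coefficients.  Both agree exactly on noiseless data.
    """
    if series.x_meas is None:
        raise ValueError("linear fit requires measured step frequencies")
    if len(series) < 2:
        raise ValueError("need at least two breaths")
    x_all = series.x_meas
    if np.ptp(x_all) == 0:
        raise ValueError("all measured step frequencies identical: "
                         "cost slope is unidentifiable")
    if method == "ols":
        c, x = invert_dynamics(series, tau)
        A = np.column_stack([x, np.ones_like(x)])
        (lam1, lam0), *_ = np.linalg.lstsq(A, c, rcond=None)
    elif method == "forward":
        # r_hat_i = base_i + lam1*bx_i + lam0*b0_i by linearity of the
        # recursion; seed with the observed first breath.
        r = series.power
        h = series.h
        n = len(series)
        base = np.empty(n)
        bx = np.zeros(n)
        b0 = np.zeros(n)
        base[0] = r[0]
        for i in range(1, n):
            a = 1.0 - h[i] / tau
            b = h[i] / tau
            base[i] = a * base[i - 1]
            bx[i] = a * bx[i - 1] + b * x_all[i]
            b0[i] = a * b0[i - 1] + b
        A = np.column_stack([bx[1:], b0[1:]])
        (lam1, lam0), *_ = np.linalg.lstsq(A, r[1:] - base[1:], rcond=None)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CostModel(lambda1=float(lam1), lambda0=float(lam0), tau=tau)


def forward_response(
    cost: float | Sequence[float] | Callable[[float], float],
    tau: float,
    breath_times: Sequence[float],
    r0: float,
) -> np.ndarray:
    """Propagate the first-order respiratory dynamics forward.

    Parameters
    ----------
    cost
        Instantaneous cost driving the response: a constant, a per-breath
        sequence (one value per breath after the first), or a callable of
        breath time.
    tau
        Respiratory time constant (s).
    breath_times
        Strictly increasing breath timestamps; the first seeds ``r0``.
    r0
        Response at the first breath.

    Returns
    -------
    Array of responses ``r_i``, same length as ``breath_times``.
    """
    t = np.asarray(breath_times, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("breath times must be strictly increasing")
    n = len(t)
    if callable(cost):
        c = np.array([cost(ti) for ti in t[1:]])
    elif np.ndim(cost) == 0:
        c = np.full(n - 1, float(cost))
    else:
        c = np.asarray(cost, dtype=float)
        if len(c) == n:          # per-breath including the seeded first
            c = c[1:]
        elif len(c) != n - 1:
            raise ValueError("cost sequence length must be n or n-1")
    r = np.empty(n)
    r[0] = r0
    h = np.diff(t)
    for i in range(1, n):
        b = h[i - 1] / tau
        r[i] = (1.0 - b) * r[i - 1] + b * c[i - 1]
    return r


def estimate_step_frequency(
    angle: np.ndarray,
    fs: float,
    *,
    n_steps: int = 4,
    refractory_s: float = 0.3,
    min_prominence_frac: float = 0.10,
    smooth_s: float = 0.15,
) -> float:
    """Step frequency (Hz) from a thigh flexion-angle signal.

    Stride time is the interval between consecutive thigh-angle maxima;
    step frequency doubles stride frequency (left/right symmetry).  The
    returned value averages over the most recent ``n_steps`` steps, i.e.
    the last ``n_steps/2`` strides.

    The signal is smoothed with a centred moving average of ``smooth_s``
    seconds (0 disables) before peak finding; maxima closer than
    ``refractory_s`` or with prominence below ``min_prominence_frac`` of
    the signal range are rejected.
    """
    angle = np.asarray(angle, dtype=float)
    if fs <= 0:
        raise ValueError("sample rate must be positive")
    w = int(round(smooth_s * fs))
    if w > 1:
        angle = np.convolve(angle, np.ones(w) / w, mode="same")
    rng_ = np.ptp(angle)
    if rng_ == 0:
        raise ValueError("flat signal: no maxima")
    peaks, _ = find_peaks(
        angle,
        distance=max(1, int(round(refractory_s * fs))),
        prominence=min_prominence_frac * rng_,
    )
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 thigh-angle maxima, found {len(peaks)}")
    stride_times = np.diff(peaks) / fs
    n_strides = max(1, n_steps // 2)
    recent = stride_times[-n_strides:]
    # n_steps steps span sum(recent) seconds
    return float(2 * len(recent) / np.sum(recent))
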