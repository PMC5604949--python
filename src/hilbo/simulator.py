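"""Synthetic walking subject for end-to-end protocol simulation.

A simulated subject has a smooth single-minimum net metabolic landscape
over step frequency (quadratic in relative deviation from the optimum,
optionally skewed), a first-order respiratory lag with time constant tau,
irregular breath timing in the physiologic 0.2-0.3 breaths/s range,
additive Gaussian breath noise, and imperfect metronome tracking.  It is
the ground-truth generator behind every protocol-level test: the true
optimum is known, so optimizer output can be scored exactly.

What it does *not* emulate: cardiovascular drift, adaptation/learning,
fatigue, or respiratory-exchange-ratio dynamics — gas volumes are backed
out of simulated power at a fixed RER.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .respiratory import (
    BROCKWAY_CO2_J_PER_ML,
    BROCKWAY_O2_J_PER_ML,
    BreathSeries,
)

__all__ = [
    "SubjectProfile",
    "DEFAULT_RER",
    "ml_o2_per_min_per_watt",
    "true_cost",
    "simulate_bout",
    "simulate_standing",
    "carry_through_rest",
    "simulate_thigh_angle",
    "make_cohort",
]

#: Respiratory exchange ratio used to back gas volumes out of power.
DEFAULT_RER = 0.85


def ml_o2_per_min_per_watt(rer: float = DEFAULT_RER) -> float:
    """mL O2/min equivalent of one watt of metabolic power at a fixed RER."""
    return 60.0 / (BROCKWAY_O2_J_PER_ML + BROCKWAY_CO2_J_PER_ML * rer)


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth for one simulated subject.

    The net (standing-subtracted, mass-normalised) cost landscape is

        c_net(x) = c_min + curvature * d^2 + skew * d^3,  d = (x - x_opt)/x_pref

    in W/kg.  Defaults: a 3.0 W/kg minimum at the preferred frequency with
    curvature 16 W/kg (so walking 25% off-frequency costs +1.0 W/kg) over a
    1.5 W/kg standing baseline — magnitudes typical of treadmill walking.
    ``breath_noise_sd`` (W/kg per breath) is calibrated so a 40-breath
    zero-order net-cost estimate has a standard deviation near 0.2 W/kg.
    """

    x_pref: float = 1.8            # preferred step frequency (Hz)
    mass: float = 65.8             # body mass (kg)
    x_opt: float | None = None     # landscape argmin (Hz); default x_pref
    c_min: float = 3.0             # net cost at the optimum (W/kg)
    curvature: float = 16.0        # W/kg per squared relative deviation
    skew: float = 0.0              # optional cubic asymmetry (W/kg)
    standing_cost: float = 1.5     # W/kg
    tau: float = 42.0              # respiratory time constant (s)
    breath_rate_mean: float = 0.25  # breaths/s
    breath_rate_sd: float = 0.05    # breaths/s (spread of instantaneous rate)
    breath_noise_sd: float = 0.27   # W/kg additive noise per breath
    tracking_sd: float = 0.01       # fractional metronome-tracking error
    rer: float = DEFAULT_RER
    seed: int = 0

    def __post_init__(self):
        if self.x_opt is None:
            object.__setattr__(self, "x_opt", self.x_pref)
        if not (0.2 <= self.breath_rate_mean <= 0.3):
            raise ValueError("breath_rate_mean outside physiologic 0.2-0.3 /s")
        if not (0.75 * self.x_pref <= self.x_opt <= 1.25 * self.x_pref):
            raise ValueError("x_opt must lie within [0.75, 1.25] x_pref")
        for name in ("x_pref", "mass", "tau", "breath_rate_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.breath_noise_sd < 0 or self.tracking_sd < 0:
            raise ValueError("noise levels must be non-negative")

    def noiseless(self) -> "SubjectProfile":
        """Copy with breath noise and tracking error switched off."""
        return replace(self, breath_noise_sd=0.0, tracking_sd=0.0)

    def gross_power_w(self, x: float | np.ndarray) -> float | np.ndarray:
        """Total metabolic power (W) while walking at x: net + standing."""
        return (true_cost(self, x) + self.standing_cost) * self.mass

    @property
    def standing_power_w(self) -> float:
        return self.standing_cost * self.mass


def true_cost(subj: SubjectProfile, x: float | np.ndarray) -> float | np.ndarray:
    """Ground-truth net metabolic cost (W/kg) at step frequency x (Hz)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("step frequency must be positive")
    d = (x - subj.x_opt) / subj.x_pref
    c = subj.c_min + subj.curvature * d**2 + subj.skew * d**3
    return float(c) if c.ndim == 0 else c


def _breath_intervals(subj: SubjectProfile, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Irregular breath intervals: normal around 1/rate, truncated at 1 s."""
    mean_h = 1.0 / subj.breath_rate_mean
    sd_h = subj.breath_rate_sd / subj.breath_rate_mean**2
    return np.maximum(rng.normal(mean_h, sd_h, size=n), 1.0)


def _series_from_power(subj: SubjectProfile, t, h, power, x_meas) -> BreathSeries:
    # Back out gas volumes at fixed RER so the Brockway conversion
    # round-trips; noisy power is floored at 0 for the gas columns.
    p = np.maximum(power, 0.0)
    vo2 = p * 60.0 / (BROCKWAY_O2_J_PER_ML + BROCKWAY_CO2_J_PER_ML * subj.rer)
    return BreathSeries(t=t, h=h, power=power, vo2=vo2, vco2=subj.rer * vo2,
                        x_meas=x_meas, mass=subj.mass)


def simulate_bout(
    subj: SubjectProfile,
    x_cmd: float,
    n_breaths: int,
    rng: np.random.Generator,
    r0: float | None = None,
    t0: float = 0.0,
) -> tuple[BreathSeries, float]:
    """Simulate one walking bout at a commanded step frequency.

    Per breath: an irregular interval, a measured frequency
    ``x_cmd * (1 + N(0, tracking_sd^2))``, a latent respiratory response
    following the first-order dynamics driven by the gross power at the
    measured frequency, and an observed power with additive Gaussian noise.

    ``r0`` is the latent respiratory level (W) carried in from preceding
    activity; ``None`` starts at steady state for the first breath's
    demand (as after a warm-up at a similar intensity).

    Returns the breath series and the final latent level for carry-over.
    """
    if n_breaths < 2:
        raise ValueError("a bout needs at least 2 breaths")
    h = _breath_intervals(subj, n_breaths, rng)
    t = t0 + np.cumsum(h)
    x_meas = x_cmd * (1.0 + rng.normal(0.0, subj.tracking_sd, size=n_breaths)) \
        if subj.tracking_sd > 0 else np.full(n_breaths, float(x_cmd))
    demand = subj.gross_power_w(x_meas)
    r = np.empty(n_breaths)
    prev = demand[0] if r0 is None else float(r0)
    for i in range(n_breaths):
        b = h[i] / subj.tau
        prev = (1.0 - b) * prev + b * demand[i]
        r[i] = prev
    noise = rng.normal(0.0, subj.breath_noise_sd * subj.mass, size=n_breaths) \
        if subj.breath_noise_sd > 0 else 0.0
    series = _series_from_power(subj, t, h, r + noise, x_meas)
    return series, float(r[-1])


def simulate_standing(
    subj: SubjectProfile,
    n_breaths: int,
    rng: np.random.Generator,
    r0: float | None = None,
    t0: float = 0.0,
) -> tuple[BreathSeries, float]:
    """Simulate a quiet-standing bout (constant standing demand)."""
    if n_breaths < 2:
        raise ValueError("a bout needs at least 2 breaths")
    h = _breath_intervals(subj, n_breaths, rng)
    t = t0 + np.cumsum(h)
    demand = subj.standing_power_w
    r = np.empty(n_breaths)
    prev = demand if r0 is None else float(r0)
    for i in range(n_breaths):
        b = h[i] / subj.tau
        prev = (1.0 - b) * prev + b * demand
        r[i] = prev
    noise = rng.normal(0.0, subj.breath_noise_sd * subj.mass, size=n_breaths) \
        if subj.breath_noise_sd > 0 else 0.0
    series = _series_from_power(subj, t, h, r + noise, x_meas=None)
    return series, float(r[-1])


def carry_through_rest(subj: SubjectProfile, r0: float, duration_s: float) -> float:
    """Latent respiratory level after resting (standing) for a given time.

    Continuous-limit exponential decay toward the standing demand; used to
    carry state across rest periods between walking bouts.
    """
    target = subj.standing_power_w
    return target + (r0 - target) * float(np.exp(-duration_s / subj.tau))


def simulate_thigh_angle(
    subj: SubjectProfile,
    x: float,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    *,
    amplitude_deg: float = 25.0,
    phase_jitter: float = 0.005,
    noise_sd_deg: float = 0.0,
) -> np.ndarray:
    """Thigh flexion-angle signal while stepping at frequency x (Hz).

    A sinusoid at the stride frequency x/2 (one thigh swing per stride)
    with random-walk phase jitter and optional additive noise.
    """
    n = int(round(duration_s * fs))
    if n < 3 * fs / (x / 2):
        raise ValueError("duration too short: need at least 3 strides")
    stride_f = x / 2.0
    dphi = 2 * np.pi * stride_f / fs + rng.normal(0, phase_jitter, size=n)
    phase = np.cumsum(dphi)
    angle = amplitude_deg * np.sin(phase)
    if noise_sd_deg > 0:
        angle = angle + rng.normal(0, noise_sd_deg, size=n)
    return angle


def make_cohort(n: int, seed: int | np.random.SeedSequence = 0
                ) -> list[SubjectProfile]:
    """Generate a cohort of simulated subjects.

    Preferred frequency ~ U(1.7, 2.0) Hz; mass ~ N(65.8, 9.7^2) kg
    truncated positive; the landscape optimum sits at the preferred
    frequency.  Per-subject seeds are derived deterministically from the
    cohort seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    children = ss.spawn(n)
    cohort = []
    for i in range(n):
        x_pref = rng.uniform(1.7, 2.0)
        mass = rng.normal(65.8, 9.7)
        while mass <= 0:  # truncation; astronomically rare
            mass = rng.normal(65.8, 9.7)
        cohort.append(SubjectProfile(
            x_pref=float(x_pref), mass=float(mass),
            seed=int(children[i].generate_state(1)[0] % 2**31)))
    return cohort
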