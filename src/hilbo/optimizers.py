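"""Human-in-the-loop search strategies over step frequency.

Two optimizers drive an abstract evaluator (a simulated subject or a
replayed dataset):

* **Bayesian optimization** — a Gaussian-process surrogate over step
  frequency, refit after every evaluation, with the next command chosen
  by maximising expected improvement (EI) over the search domain from
  multi-restart local search.  Evaluations are zero-order instantaneous
  cost estimates from 40-breath windows.

* **Gradient descent** — the classic comparator: per iteration the subject
  walks at +/- delta around the current command, a linear instantaneous
  cost model is fitted to the 2 x 30 breaths, and the command moves
  against the fitted slope with a decaying step-size schedule
  alpha_n = A0*alpha0 / (A0 + n*gamma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .gp import GPDataset, GPHyperparameters, fit_hyperparameters, posterior
from .respiratory import CostModel

__all__ = [
    "BOConfig",
    "GDConfig",
    "TrajectoryStep",
    "Trajectory",
    "EvalResult",
    "GradientEvalResult",
    "expected_improvement",
    "mu_best",
    "propose_next",
    "initial_design",
    "run_bayes_opt",
    "gd_step_size",
    "run_gradient_descent",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BOConfig:
    """Bayesian-optimization protocol constants.

    Defaults follow the study protocol: a 3-point random initial design
    over thirds of the 75-125% domain, 40-breath zero-order cost
    estimates, and 10 random restarts for both the hyperparameter fit and
    the EI maximisation.  ``n_iterations`` counts EI-driven evaluations
    after the initial design (17 for a 20-evaluation budget).
    """

    n_init: int = 3
    n_iterations: int = 17
    breaths_per_eval: int = 40
    domain_frac: tuple[float, float] = (0.75, 1.25)
    ei_restarts: int = 10
    hp_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.domain_frac[0] >= self.domain_frac[1]:
            raise ValueError("domain lower bound must be below upper bound")
        if self.breaths_per_eval < 2:
            raise ValueError("breaths_per_eval must be >= 2")

    def domain(self, x_pref: float) -> tuple[float, float]:
        return (self.domain_frac[0] * x_pref, self.domain_frac[1] * x_pref)


@dataclass(frozen=True)
class GDConfig:
    """Gradient-descent protocol constants.

    ``alpha0`` is in Hz per (mL/min)/Hz of cost slope, so costs are
    expressed in mL O2/min equivalents by default; set
    ``cost_units="watt"`` to step directly against a W/Hz slope.
    """

    A0: float = 3.0
    alpha0: float = 4e-4
    gamma: float = 1.0
    delta_frac: float = 0.05
    n_iterations: int = 15
    breaths_per_side: int = 30
    init_offset: float = 0.20
    domain_frac: tuple[float, float] = (0.75, 1.25)
    cost_units: str = "ml_o2_per_min"
    seed: int = 0

    def __post_init__(self):
        if self.alpha0 <= 0 or self.delta_frac <= 0:
            raise ValueError("alpha0 and delta_frac must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def domain(self, x_pref: float) -> tuple[float, float]:
        return (self.domain_frac[0] * x_pref, self.domain_frac[1] * x_pref)


@dataclass
class EvalResult:
    """One zero-order cost evaluation at a commanded frequency."""

    cost: float           # zero-order instantaneous cost estimate
    x_meas: float         # mean measured step frequency (Hz)
    duration_s: float     # walking time spent on the evaluation
    cost_units: str = "W/kg"


@dataclass
class GradientEvalResult:
    """One paired +/-delta evaluation returning a fitted linear cost model."""

    model: CostModel      # c(x) = lambda1*x + lambda0 in `cost_units`
    x_meas: float         # mean measured step frequency (Hz)
    duration_s: float
    cost_units: str = "ml_o2_per_min"


class ZeroOrderEvaluator(Protocol):
    def evaluate(self, x_cmd: float, rng: np.random.Generator) -> EvalResult: ...


class GradientEvaluator(Protocol):
    def evaluate_gradient(self, x_cmd: float, delta: float,
                          rng: np.random.Generator) -> GradientEvalResult: ...


@dataclass
class TrajectoryStep:
    iter: int
    method: str           # "bo" | "gd" | "grid"
    phase: str            # "init" | "ei" | "gd" | "grid"
    x_cmd: float
    x_meas: float
    cost: float
    cost_units: str
    duration_s: float
    hp: GPHyperparameters | None = None


@dataclass
class Trajectory:
    """Ordered per-iteration record of one optimization run."""

    steps: list[TrajectoryStep] = field(default_factory=list)
    method: str = ""
    x_pref: float | None = None
    status: str = "ok"

    def __len__(self) -> int:
        return len(self.steps)

    def append(self, step: TrajectoryStep) -> None:
        if self.steps and step.iter != self.steps[-1].iter + 1:
            raise ValueError("iteration indices must be contiguous")
        if step.duration_s <= 0:
            raise ValueError("durations must be positive")
        self.steps.append(step)

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.steps])

    @property
    def x_cmd(self) -> np.ndarray:
        return self.column("x_cmd")

    @property
    def costs(self) -> np.ndarray:
        return self.column("cost")

    @property
    def durations(self) -> np.ndarray:
        return self.column("duration_s")

    @property
    def phases(self) -> list[str]:
        return [s.phase for s in self.steps]

    def post_init_steps(self) -> list[TrajectoryStep]:
        """Steps after any initial design (all steps for GD/grid runs)."""
        return [s for s in self.steps if s.phase != "init"]

    def to_frame(self):
        import pandas as pd

        rows = []
        for s in self.steps:
            rows.append({
                "iter": s.iter, "method": s.method, "phase": s.phase,
                "x_cmd_hz": s.x_cmd, "x_meas_hz": s.x_meas,
                "cost": s.cost, "cost_units": s.cost_units,
                "duration_s": s.duration_s,
                "hyp_sigma2": np.nan if s.hp is None else s.hp.sigma2,
                "hyp_l": np.nan if s.hp is None else s.hp.length_scale,
                "hyp_noise2": np.nan if s.hp is None else s.hp.noise2,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Expected improvement
# ---------------------------------------------------------------------------

def expected_improvement(mean, sd, mu_best):
    """Closed-form expected improvement for minimisation.

    EI = sd * (u*Phi(u) + phi(u)) with u = (mu_best - mean)/sd, and 0
    wherever sd = 0.  Accepts scalars or arrays; always >= 0.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be non-negative")
    scalar = mean.ndim == 0 and sd.ndim == 0
    mean, sd = np.atleast_1d(mean), np.atleast_1d(sd)
    mean, sd = np.broadcast_arrays(mean, sd)
    ei = np.zeros(mean.shape)
    pos = sd > 0
    u = (mu_best - mean[pos]) / sd[pos]
    ei[pos] = sd[pos] * (u * norm.cdf(u) + norm.pdf(u))
    ei = np.maximum(ei, 0.0)
    return float(ei[0]) if scalar else ei


def mu_best(data: GPDataset, hp: GPHyperparameters) -> float:
    """Incumbent: minimum posterior *mean* over the evaluated frequencies."""
    post = posterior(data, hp)
    return float(np.min(post.mean(data.X)))


def propose_next(
    data: GPDataset,
    hp: GPHyperparameters,
    domain: tuple[float, float],
    restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    *,
    grid_size: int = 257,
) -> float:
    """Next commanded frequency: argmax of EI over the closed domain.

    Candidate starts are the domain endpoints, the best points of a coarse
    scan, and ``restarts`` uniform random draws, each refined by a
    bound-constrained local search.  Exact ties break toward the lowest
    frequency.  If EI vanishes everywhere (degenerate posterior) the
    maximum-variance point is returned instead.
    """
    rng = np.random.default_rng(rng)
    lo, hi = domain
    post = posterior(data, hp)
    incumbent = float(np.min(post.mean(data.X)))

    def ei_at(x):
        x = np.atleast_1d(x)
        return expected_improvement(post.mean(x), post.sd(x), incumbent)

    grid = np.linspace(lo, hi, grid_size)
    ei_grid = ei_at(grid)
    order = np.argsort(ei_grid)[::-1]
    starts = np.concatenate([
        [lo, hi],
        grid[order[:3]],
        rng.uniform(lo, hi, size=restarts),
    ])

    candidates: list[tuple[float, float]] = [(float(ei_grid[i]), float(grid[i]))
                                             for i in order[:3]]
    for x0 in starts:
        res = minimize(lambda z: -ei_at(z)[0], x0=[x0], method="L-BFGS-B",
                       bounds=[(lo, hi)])
        if np.isfinite(res.fun):
            candidates.append((float(-res.fun), float(res.x[0])))

    best_ei = max(c[0] for c in candidates)
    if best_ei <= 0.0:
        log.info("EI degenerate (max EI = 0); falling back to max variance")
        var_grid = post.var(grid)
        return float(grid[int(np.argmax(var_grid))])
    tol = 1e-9 * best_ei
    tied = [x for e, x in candidates if e >= best_ei - tol]
    return float(min(tied))


def initial_design(x_pref: float, rng: np.random.Generator | int | None = None,
                   domain_frac: tuple[float, float] = (0.75, 1.25),
                   n: int = 3) -> np.ndarray:
    """Random initial design: one uniform draw per equal third (by default)
    of the search domain, presented in randomised order."""
    if x_pref <= 0:
        raise ValueError("preferred frequency must be positive")
    rng = np.random.default_rng(rng)
    edges = np.linspace(domain_frac[0], domain_frac[1], n + 1) * x_pref
    draws = np.array([rng.uniform(edges[i], edges[i + 1]) for i in range(n)])
    rng.shuffle(draws)
    return draws


def run_bayes_opt(evaluator, config: BOConfig,
                  x_pref: float | None = None) -> Trajectory:
    """Run the full Bayesian-optimization protocol against an evaluator.

    Executes the random initial design, then ``config.n_iterations`` EI
    steps, refitting the GP hyperparameters after every evaluation (first
    fit once two observations exist).  The evaluator must provide
    ``evaluate(x_cmd, rng) -> EvalResult`` (a 40-breath zero-order cost
    estimate in the simulated protocol).
    """
    if x_pref is None:
        x_pref = evaluator.x_pref
    rng = np.random.default_rng(config.seed)
    domain = config.domain(x_pref)
    traj = Trajectory(method="bo", x_pref=x_pref)

    design = initial_design(x_pref, rng, config.domain_frac, config.n_init)
    X: list[float] = []
    y: list[float] = []
    hp: GPHyperparameters | None = None

    def observe(i, phase, x_cmd):
        nonlocal hp
        try:
            res = evaluator.evaluate(float(x_cmd), rng)
        except Exception as e:
            log.warning("evaluator failed at iter %d: %s", i, e)
            traj.status = f"truncated: {e}"
            return False
        X.append(res.x_meas)
        y.append(res.cost)
        if len(X) >= 2:
            hp = fit_hyperparameters(
                GPDataset(np.array(X), np.array(y)),
                n_restarts=config.hp_restarts, rng=rng, domain=domain)
        traj.append(TrajectoryStep(
            iter=i, method="bo", phase=phase, x_cmd=float(x_cmd),
            x_meas=res.x_meas, cost=res.cost, cost_units=res.cost_units,
            duration_s=res.duration_s, hp=hp))
        return True

    i = 0
    for x_cmd in design:
        if not observe(i, "init", x_cmd):
            return traj
        i += 1
    for _ in range(config.n_iterations):
        x_cmd = propose_next(GPDataset(np.array(X), np.array(y)), hp, domain,
                             restarts=config.ei_restarts, rng=rng)
        x_cmd = float(np.clip(x_cmd, *domain))
        if not observe(i, "ei", x_cmd):
            return traj
        i += 1
    return traj


def gd_step_size(n: int, cfg: GDConfig) -> float:
    """Decaying step size alpha_n = A0*alpha0 / (A0 + n*gamma)."""
    if n < 0:
        raise ValueError("iteration index must be >= 0")
    return cfg.A0 * cfg.alpha0 / (cfg.A0 + n * cfg.gamma)


def run_gradient_descent(evaluator, config: GDConfig,
                         x_pref: float | None = None) -> Trajectory:
    """Run the gradient-descent protocol against an evaluator.

    Starts 20% above or below the preferred frequency (sign by seeded coin
    flip); each iteration fits a linear cost model from paired +/-delta
    walking bouts and updates x_{n+1} = clip(x_n - alpha_n * lambda1).
    The evaluator must provide
    ``evaluate_gradient(x_cmd, delta, rng) -> GradientEvalResult``.
    """
    if x_pref is None:
        x_pref = evaluator.x_pref
    rng = np.random.default_rng(config.seed)
    domain = config.domain(x_pref)
    delta = config.delta_frac * x_pref
    sign = 1.0 if rng.random() < 0.5 else -1.0
    x = float(np.clip((1.0 + sign * config.init_offset) * x_pref, *domain))
    traj = Trajectory(method="gd", x_pref=x_pref)
    for n in range(config.n_iterations):
        try:
            res = evaluator.evaluate_gradient(x, delta, rng)
        except Exception as e:
            log.warning("evaluator failed at iter %d: %s", n, e)
            traj.status = f"truncated: {e}"
            return traj
        traj.append(TrajectoryStep(
            iter=n, method="gd", phase="gd", x_cmd=x, x_meas=res.x_meas,
            cost=float(res.model(x)), cost_units=res.cost_units,
            duration_s=res.duration_s))
        J = res.model.lambda1
        x = float(np.clip(x - gd_step_size(n, config) * J, *domain))
    return traj
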