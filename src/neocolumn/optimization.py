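"""Stepwise evoked-response parameter optimization.

Evoked inputs are Gaussian-timed, so input k's likelihood of having
occurred by time t is the Normal CDF with that input's start-time mean and
standard deviation.  Early in the response only the earliest input can have
shaped the waveform; later inputs progressively dilute its unique
contribution.  The optimizer exploits this by fitting one input at a time,
each within a time window where that input dominates, using a weighted RMSE
whose weight function is built from the CDFs:

- UCI (unique contribution index):
  ``max(0, CDF_k(t) - sum_{i>k} CDF_i(t))`` — strictly the window where no
  later input has begun.
- ECI (extended contribution index): each subtracted CDF is attenuated by
  ``A**(-(mu_i - mu_k)/T)`` (A = 1.6, T = simulation length), which delays
  the weight's return to zero and keeps some pressure on the fit beyond the
  unique window.  ECI >= UCI everywhere, and ECI of the last input equals
  its plain CDF.

Each per-input step minimizes wRMSE over that input's free parameters with
COBYLA under box constraints, evaluated only where ECI exceeds a 0.01
threshold; a final step polishes all free parameters jointly under plain
RMSE.  Budgets are expressed in simulations per step (0 skips a step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "InputTiming",
    "ParameterSpec",
    "OptimizationConfig",
    "OptimizationResult",
    "input_cdf",
    "uci",
    "eci",
    "wrmse",
    "optimization_window",
    "stepwise_optimize",
]

ECI_DECAY_A = 1.6
WINDOW_THRESHOLD = 0.01


@dataclass(frozen=True)
class InputTiming:
    """Start-time distribution of one evoked input."""

    name: str
    mean: float   # ms
    stdev: float  # ms

    def __post_init__(self):
        if self.stdev < 0:
            raise ValueError("stdev must be >= 0")


def input_cdf(timing: InputTiming, t: np.ndarray | float) -> np.ndarray | float:
    """Normal CDF of an input's start time (unit step if stdev = 0)."""
    t = np.asarray(t, dtype=float)
    if timing.stdev == 0:
        out = (t >= timing.mean).astype(float)
    else:
        out = norm.cdf(t, loc=timing.mean, scale=timing.stdev)
    return out if out.ndim else float(out)


def _ordered(inputs: list[InputTiming]) -> list[InputTiming]:
    return sorted(inputs, key=lambda k: k.mean)


def uci(
    k: int, t: np.ndarray, inputs: list[InputTiming]
) -> np.ndarray:
    """Unique contribution index of the k-th input (0-based, mean-ordered).

    CDF_k minus the summed CDFs of all later inputs, clamped at zero.
    """
    inputs = _ordered(inputs)
    t = np.asarray(t, dtype=float)
    w = np.asarray(input_cdf(inputs[k], t), dtype=float).copy()
    for later in inputs[k + 1:]:
        w -= input_cdf(later, t)
    return np.maximum(w, 0.0)


def eci(
    k: int,
    t: np.ndarray,
    inputs: list[InputTiming],
    T: float,
    A: float = ECI_DECAY_A,
) -> np.ndarray:
    """Extended contribution index of the k-th input.

    Subtracted CDFs are attenuated by A**(-(mu_i - mu_k)/T), so the weight
    decays back to zero later than the UCI; for the last input the sum is
    empty and ECI equals the plain CDF.  ECI >= UCI pointwise for A > 1.
    """
    if A <= 1:
        raise ValueError("decay constant A must exceed 1")
    if T <= 0:
        raise ValueError("simulation length T must be positive")
    inputs = _ordered(inputs)
    t = np.asarray(t, dtype=float)
    w = np.asarray(input_cdf(inputs[k], t), dtype=float).copy()
    mu_k = inputs[k].mean
    for later in inputs[k + 1:]:
        atten = A ** (-(later.mean - mu_k) / T)
        w -= atten * np.asarray(input_cdf(later, t))
    return np.maximum(w, 0.0)


def wrmse(
    sim: np.ndarray, data: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted RMSE: sqrt(sum w (x1 - x2)^2 / sum w).

    Uniform weights reduce this to the plain RMSE.
    """
    sim = np.asarray(sim, dtype=float)
    data = np.asarray(data, dtype=float)
    w = np.asarray(weights, dtype=float)
    if sim.shape != data.shape or sim.shape != w.shape:
        raise ValueError("sim, data and weights must share one grid")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    return float(np.sqrt(np.sum(w * (sim - data) ** 2) / total))


def optimization_window(
    times: np.ndarray,
    eci_values: np.ndarray,
    threshold: float = WINDOW_THRESHOLD,
) -> tuple[float, float]:
    """[t_start, t_end] where the ECI exceeds ``threshold``.

    t_start is the first rise above the threshold and t_end the last fall
    below it (the end of the grid if the ECI never falls back, as for the
    last input).  Raises if the ECI never exceeds the threshold.
    """
    times = np.asarray(times, dtype=float)
    w = np.asarray(eci_values, dtype=float)
    above = w > threshold
    if not above.any():
        raise ValueError(
            f"ECI never exceeds the window threshold {threshold}"
        )
    i0 = int(np.argmax(above))
    i1 = len(above) - 1 - int(np.argmax(above[::-1]))
    return float(times[i0]), float(times[i1])


@dataclass
class ParameterSpec:
    """One free parameter of one evoked input."""

    input_name: str
    key: str            # e.g. 'start_time_mean' or 'weight:L5_pyramidal:ampa'
    value: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"{self.input_name}.{self.key}: initial value {self.value} "
                f"outside bounds [{self.lower}, {self.upper}]"
            )


def timing_bounds(mean: float, stdev: float, n_stdev: float = 3.0):
    """Start-time bounds: plus or minus a number of standard deviations."""
    return mean - n_stdev * stdev, mean + n_stdev * stdev


def weight_bounds(value: float, percent: float = 500.0, zero_max: float = 1.0):
    """Weight bounds: +/- a percentage of the initial value; parameters with
    an initial value of zero get [0, zero_max] instead."""
    if value == 0:
        return 0.0, zero_max
    lo = value * max(0.0, 1.0 - percent / 100.0)
    hi = value * (1.0 + percent / 100.0)
    return lo, hi


@dataclass
class OptimizationConfig:
    """Free parameters, bounds and budgets for the stepwise procedure."""

    inputs: list[InputTiming]
    parameters: list[ParameterSpec]
    sims_per_step: dict[str, int] = field(default_factory=dict)  # name -> budget
    final_step_sims: int = 30
    eci_decay: float = ECI_DECAY_A
    window_threshold: float = WINDOW_THRESHOLD
    horizon: float = 170.0  # simulation length T, ms

    def step_budget(self, input_name: str) -> int:
        return self.sims_per_step.get(input_name, 30)


@dataclass
class OptimizationResult:
    """Optimized parameters plus the per-step fit history."""

    parameters: dict[tuple[str, str], float]
    initial_rmse: float
    final_rmse: float
    step_history: list[dict]
    n_evaluations: int

    def summary(self) -> str:
        lines = [
            "Stepwise evoked-response optimization",
            f"  initial RMSE: {self.initial_rmse:.4f}",
            f"  final RMSE:   {self.final_rmse:.4f}",
            f"  simulations:  {self.n_evaluations}",
        ]
        for h in self.step_history:
            lines.append(
                f"  step {h['step']:<10} objective {h['objective']:.4f} "
                f"({h['n_evals']} sims, window {h['window'][0]:.1f}-"
                f"{h['window'][1]:.1f} ms)"
            )
        return "\n".join(lines)


def _clip_to_bounds(x, lo, hi):
    return np.minimum(np.maximum(x, lo), hi)


def _cobyla(objective, x0, lo, hi, budget):
    """Bound-constrained derivative-free minimization with COBYLA.

    Parameters are rescaled to the unit box so the initial simplex step
    (rhobeg) is meaningful regardless of units; every evaluated point is
    clipped to the box, so no candidate ever leaves its bounds.
    """
    x0 = np.asarray(x0, dtype=float)
    if budget <= 0:
        return x0, 0
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = np.where(hi > lo, hi - lo, 1.0)
    z0 = (x0 - lo) / span
    n_evals = 0
    best = (np.inf, z0)

    def counted(z):
        nonlocal n_evals, best
        z = np.clip(z, 0.0, 1.0)
        n_evals += 1
        val = objective(lo + z * span)
        if val < best[0]:
            best = (val, z.copy())
        return val

    rhobeg = 0.25
    zstart = z0
    remaining = budget
    if len(x0) == 1 and budget >= 6:
        # 1-D objectives over spiking networks are rugged; bracket the
        # basin with a coarse scan before the local COBYLA refinement
        k = min(9, budget // 2)
        for z in np.linspace(0.02, 0.98, k):
            counted(np.array([z]))
        zstart = best[1]
        rhobeg = 1.0 / (k + 1)
        remaining = budget - k
    cons = []
    for i in range(len(x0)):
        cons.append({"type": "ineq", "fun": lambda z, i=i: z[i]})
        cons.append({"type": "ineq", "fun": lambda z, i=i: 1.0 - z[i]})
    if remaining > 0:
        minimize(
            counted,
            zstart,
            method="COBYLA",
            constraints=cons,
            options={"maxiter": remaining, "rhobeg": rhobeg, "tol": 1e-6},
        )
    z = np.clip(best[1], 0.0, 1.0)
    return lo + z * span, n_evals


def stepwise_optimize(
    forward,
    times: np.ndarray,
    data: np.ndarray,
    config: OptimizationConfig,
    analysis_start: float = 0.0,
) -> OptimizationResult:
    """Fit evoked-input parameters to a target dipole trace.

    ``forward(params_dict) -> dipole`` maps a {(input_name, key): value}
    mapping to a mean dipole on ``times``.  For each input in order of
    start-time mean, that input's free parameters are fitted by COBYLA
    under wRMSE with the input's ECI weight restricted to its threshold
    window; a final step fits all free parameters under plain RMSE.
    ``analysis_start`` excludes the settling window from every objective.
    Re-running with the result as the new starting point is supported (the
    returned parameters are a valid input configuration).
    """
    times = np.asarray(times, dtype=float)
    data = np.asarray(data, dtype=float)
    if times.shape != data.shape:
        raise ValueError("times and data must share one grid")

    current = {(p.input_name, p.key): p.value for p in config.parameters}
    by_input: dict[str, list[ParameterSpec]] = {}
    for p in config.parameters:
        by_input.setdefault(p.input_name, []).append(p)

    post = times >= analysis_start
    n_evals = 0

    def run(params):
        nonlocal n_evals
        n_evals += 1
        return np.asarray(forward(params), dtype=float)

    def plain_rmse(sim):
        return wrmse(sim[post], data[post], np.ones(post.sum()))

    sim0 = run(current)
    initial_rmse = plain_rmse(sim0)

    history: list[dict] = []
    ordered = _ordered(config.inputs)

    def live_timings():
        """Input timings reflecting the current parameter values."""
        out = []
        for k in config.inputs:
            mean = current.get((k.name, "start_time_mean"), k.mean)
            stdev = current.get((k.name, "start_time_stdev"), k.stdev)
            out.append(InputTiming(k.name, mean, stdev))
        return out

    for k, timing in enumerate(ordered):
        specs = by_input.get(timing.name, [])
        budget = config.step_budget(timing.name)
        if not specs or budget <= 0:
            continue
        timings = _ordered(live_timings())
        kk = [x.name for x in timings].index(timing.name)
        w_full = eci(kk, times, timings, T=config.horizon, A=config.eci_decay)
        t0, t1 = optimization_window(
            times, w_full, threshold=config.window_threshold
        )
        in_win = (times >= max(t0, analysis_start)) & (times <= t1)
        w = w_full[in_win]
        d = data[in_win]

        keys = [(s.input_name, s.key) for s in specs]
        x0 = np.array([current[key] for key in keys])
        lo = np.array([s.lower for s in specs])
        hi = np.array([s.upper for s in specs])

        def objective(x):
            trial = dict(current)
            for key, val in zip(keys, x):
                trial[key] = float(val)
            sim = run(trial)
            return wrmse(sim[in_win], d, w)

        xbest, used = _cobyla(objective, x0, lo, hi, budget)
        obj = objective(xbest)
        for key, val in zip(keys, xbest):
            current[key] = float(val)
        history.append(
            {
                "step": timing.name,
                "objective": obj,
                "n_evals": used + 1,
                "window": (t0, t1),
            }
        )

    # final polish: all free parameters, plain RMSE
    if config.final_step_sims > 0 and config.parameters:
        keys = [(p.input_name, p.key) for p in config.parameters]
        x0 = np.array([current[key] for key in keys])
        lo = np.array([p.lower for p in config.parameters])
        hi = np.array([p.upper for p in config.parameters])

        def objective_all(x):
            trial = dict(current)
            for key, val in zip(keys, x):
                trial[key] = float(val)
            return plain_rmse(run(trial))

        xbest, used = _cobyla(objective_all, x0, lo, hi, config.final_step_sims)
        final_candidate = objective_all(xbest)
        if final_candidate <= plain_rmse(run(current)):
            for key, val in zip(keys, xbest):
                current[key] = float(val)
        history.append(
            {
                "step": "final",
                "objective": plain_rmse(run(current)),
                "n_evals": used + 2,
                "window": (float(times[post][0]), float(times[-1])),
            }
        )

    final_rmse = plain_rmse(run(current))
    return OptimizationResult(
        parameters=current,
        initial_rmse=initial_rmse,
        final_rmse=final_rmse,
        step_history=history,
        n_evaluations=n_evals,
    )
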