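"""Perturbation and recovery analysis around macroecological baselines.

A disturbance is applied to a simulated assemblage, the baseline
distribution (truncated-Pareto size spectrum or beta abundance
distribution) is refitted through time, and the deviation from the
pre-disturbance baseline is tracked.  Three canonical disturbance
scenarios:

* a pulse removing small individuals (shallower fitted exponent, recovery
  by recruitment);
* a pulse removing the largest individuals (reduced maximum size, recovery
  as survivors grow); and
* a press shift in demographic rates (the assemblage equilibrates to a new,
  different baseline — no recovery).

Recovery time is the first time the baseline deviation stays below a
calibrated tolerance for a required number of consecutive samples; the
tolerance defaults to the 95th percentile of the deviation fluctuation of
an unperturbed (null) run panel.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats

from ._rng import stream
from .distributions import (
    TruncatedParetoSizeDist,
    fit_trunc_pareto,
    trunc_pareto_cdf,
    trunc_pareto_pdf,
)
from .size_structure import IbmForest

__all__ = [
    "PerturbationSpec",
    "BaselineSummary",
    "RecoveryTrajectory",
    "apply_perturbation",
    "track_recovery",
    "baseline_deviation",
    "recovery_time",
    "bray_curtis",
    "calibrate_tolerance",
]

Kind = Literal["remove_small", "remove_large", "proportional_thinning", "rate_shift"]


@dataclass(frozen=True)
class PerturbationSpec:
    """A disturbance: what it hits, how hard, and when.

    ``intensity`` is the removal probability for the pulse kinds (in
    [0, 1]) or the rate multiplier for ``rate_shift``; ``threshold`` is the
    size cutoff for size-selective kinds; ``press_interval`` bounds a press
    disturbance in time (None = permanent).
    """

    kind: Kind
    intensity: float
    threshold: float | None = None
    press_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind != "rate_shift" and not (0.0 <= self.intensity <= 1.0):
            raise ValueError("removal intensity must lie in [0, 1]")
        if self.kind in ("remove_small", "remove_large") and self.threshold is None:
            raise ValueError(f"{self.kind} requires a size threshold")


@dataclass(frozen=True)
class BaselineSummary:
    """A fitted baseline distribution: family name plus parameters."""

    family: Literal["trunc_pareto", "beta"]
    params: dict
    meta: dict = field(default_factory=dict)

    def dist(self) -> TruncatedParetoSizeDist:
        if self.family != "trunc_pareto":
            raise ValueError("only the size-spectrum family has a dist() helper")
        return TruncatedParetoSizeDist(
            self.params["lambda"], self.params["m0"], self.params["mmax"]
        )


@dataclass
class RecoveryTrajectory:
    """Fitted baseline parameters and baseline deviations through time."""

    times: np.ndarray
    params_series: list[BaselineSummary]
    deviation_series: np.ndarray
    t_perturb: float = 0.0
    metric: str = "ks"
    sizes_series: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.deviation_series = np.asarray(self.deviation_series, dtype=float)
        if self.times.size != self.deviation_series.size or self.times.size != len(
            self.params_series
        ):
            raise ValueError("trajectory series must align")
        if np.any(self.deviation_series < 0):
            raise ValueError("deviations must be non-negative")


# ---------------------------------------------------------------------------
# perturbation operators
# ---------------------------------------------------------------------------

def apply_perturbation(population, spec: PerturbationSpec, seed: int):
    """Apply a disturbance.

    For the pulse kinds, ``population`` is an array of individual sizes and
    a reduced array is returned: each individual below (``remove_small``) or
    above (``remove_large``) the threshold, or any individual
    (``proportional_thinning``), is removed independently with probability
    ``intensity``.  For ``rate_shift``, ``population`` is a mortality
    function and a modified function (multiplied by ``intensity`` below the
    threshold, or everywhere if no threshold) is returned.

    Raises if a pulse would remove the entire population — total mortality
    is outside the framework's scope.
    """
    if spec.kind == "rate_shift":
        base = population
        thr = spec.threshold

        def shifted(D):
            D = np.asarray(D, dtype=float)
            m = np.asarray(base(D), dtype=float)
            if thr is None:
                return m * spec.intensity
            return np.where(D < thr, m * spec.intensity, m)

        return shifted

    sizes = np.asarray(population, dtype=float)
    if sizes.size == 0:
        raise ValueError("population is empty")
    rng = stream(seed, "perturbation")
    u = rng.random(sizes.size)
    if spec.kind == "remove_small":
        hit = sizes < spec.threshold
    elif spec.kind == "remove_large":
        hit = sizes > spec.threshold
    elif spec.kind == "proportional_thinning":
        hit = np.ones(sizes.size, dtype=bool)
    else:
        raise ValueError(f"unknown perturbation kind {spec.kind!r}")
    removed = hit & (u < spec.intensity)
    out = sizes[~removed]
    if out.size == 0:
        raise ValueError(
            "perturbation removed the whole population; total mortality is not "
            "a recoverable disturbance"
        )
    return out


# ---------------------------------------------------------------------------
# deviation metrics
# ---------------------------------------------------------------------------

def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity between two relative-abundance vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.abs(p - q).sum() / (p.sum() + q.sum()))


def baseline_deviation(
    current,
    baseline: BaselineSummary,
    metric: Literal["ks", "hellinger", "param_distance"] = "ks",
    *,
    param_scale: dict | None = None,
) -> float:
    """Distance between the current state and the baseline distribution.

    ``current`` is an array of individual sizes for ``ks`` (empirical cdf vs
    baseline cdf) and ``hellinger`` (both densities on a shared grid), or a
    fitted :class:`BaselineSummary` for ``param_distance`` (Euclidean
    distance on parameters standardized by ``param_scale``, default 1).
    """
    if metric == "param_distance":
        if not isinstance(current, BaselineSummary) or current.family != baseline.family:
            raise ValueError("param_distance needs two summaries of the same family")
        keys = sorted(set(baseline.params) & set(current.params))
        scale = param_scale or {}
        d2 = sum(
            ((current.params[k] - baseline.params[k]) / scale.get(k, 1.0)) ** 2
            for k in keys
        )
        return float(np.sqrt(d2))

    dist = baseline.dist()
    sizes = np.asarray(current, dtype=float)
    if metric == "ks":
        return float(stats.kstest(sizes, lambda m: trunc_pareto_cdf(m, dist)).statistic)
    if metric == "hellinger":
        lo = min(sizes.min(), dist.m0)
        hi = max(sizes.max(), dist.mmax)
        grid = np.geomspace(lo, hi, 201)
        # empirical density via refitted truncated Pareto of the sample
        cur_fit = fit_trunc_pareto(sizes)
        f = trunc_pareto_pdf(grid, cur_fit)
        g = trunc_pareto_pdf(grid, dist)
        h2 = 0.5 * np.trapezoid((np.sqrt(f) - np.sqrt(g)) ** 2, grid)
        return float(np.sqrt(max(h2, 0.0)))
    raise ValueError(f"unknown metric {metric!r}")


def hellinger_between(d1: TruncatedParetoSizeDist, d2: TruncatedParetoSizeDist) -> float:
    """Hellinger distance between two truncated-Pareto densities."""
    grid = np.geomspace(min(d1.m0, d2.m0), max(d1.mmax, d2.mmax), 401)
    h2 = 0.5 * np.trapezoid(
        (np.sqrt(trunc_pareto_pdf(grid, d1)) - np.sqrt(trunc_pareto_pdf(grid, d2))) ** 2,
        grid,
    )
    return float(np.sqrt(max(h2, 0.0)))


# ---------------------------------------------------------------------------
# recovery tracking
# ---------------------------------------------------------------------------

def _fit_summary(sizes: np.ndarray) -> BaselineSummary:
    fit = fit_trunc_pareto(sizes)
    return BaselineSummary("trunc_pareto", fit.to_dict(), meta={"loglik": fit.loglik})


def track_recovery(
    forest: IbmForest,
    baseline: BaselineSummary,
    spec: PerturbationSpec,
    *,
    horizon: float,
    sampling_interval: float,
    seed: int,
    metric: Literal["ks", "hellinger", "param_distance"] = "ks",
    keep_sizes: bool = False,
) -> RecoveryTrajectory:
    """Perturb a steady-state forest and track its return to baseline.

    The forest must already be at its demographic steady state (the
    baseline).  Pulse perturbations remove individuals instantaneously at
    t_perturb = current forest time; a press ``rate_shift`` multiplies the
    mortality schedule for its ``press_interval`` (default: the whole
    horizon).  At each sampling time the truncated-Pareto baseline family is
    refitted and the deviation from ``baseline`` recorded.
    """
    if horizon < sampling_interval:
        raise ValueError("horizon shorter than one sampling interval")
    t0 = forest.t
    base_mortality = forest.mortality

    if spec.kind == "rate_shift":
        shifted = apply_perturbation(base_mortality, spec, seed)
        press = spec.press_interval or (t0, t0 + horizon)
    else:
        n_before = forest.diameters.size
        forest.diameters = apply_perturbation(forest.diameters, spec, seed)
        if forest.recruitment == "zero-sum":
            # zero-sum space filling: the space a pulse frees is recolonized
            # immediately by recruits at the minimum size
            n_freed = n_before - forest.diameters.size
            forest.diameters = np.concatenate(
                [forest.diameters, np.full(n_freed, forest.D_min)]
            )
        press = None

    times, summaries, devs = [], [], []
    sizes: list[np.ndarray] | None = [] if keep_sizes else None
    n_steps = int(round(horizon / sampling_interval))
    for k in range(1, n_steps + 1):
        if press is not None:
            in_press = press[0] <= forest.t < press[1]
            forest.mortality = shifted if in_press else base_mortality
        forest.run(sampling_interval, seed + 1000 + k)
        times.append(forest.t)
        summ = _fit_summary(forest.diameters)
        summaries.append(summ)
        devs.append(baseline_deviation(
            summ if metric == "param_distance" else forest.diameters,
            baseline,
            metric,
        ))
        if sizes is not None:
            sizes.append(forest.diameters.copy())
    forest.mortality = base_mortality
    return RecoveryTrajectory(
        np.asarray(times), summaries, np.asarray(devs),
        t_perturb=t0, metric=metric, sizes_series=sizes,
    )


def calibrate_tolerance(
    forest_factory: Callable[[int], IbmForest],
    baseline: BaselineSummary,
    *,
    seeds: Sequence[int],
    horizon: float,
    sampling_interval: float,
    metric: Literal["ks", "hellinger", "param_distance"] = "ks",
    quantile: float = 95.0,
) -> float:
    """Null-calibrated recovery tolerance.

    Runs unperturbed forests (one per seed), pools their baseline
    deviations, and returns the requested percentile — the band of
    fluctuation the steady state itself produces.
    """
    null = PerturbationSpec("proportional_thinning", 0.0)
    devs = []
    for s in seeds:
        f = forest_factory(int(s))
        traj = track_recovery(
            f, baseline, null,
            horizon=horizon, sampling_interval=sampling_interval,
            seed=int(s), metric=metric,
        )
        devs.append(traj.deviation_series)
    return float(np.percentile(np.concatenate(devs), quantile))


def recovery_time(
    traj: RecoveryTrajectory, tolerance: float, persistence: int = 3
) -> float | None:
    """First post-perturbation time at which the deviation stays below
    ``tolerance`` for ``persistence`` consecutive samples; None if the
    trajectory never recovers."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if persistence < 1:
        raise ValueError("persistence must be at least 1")
    below = traj.deviation_series < tolerance
    run = 0
    for i, ok in enumerate(below):
        run = run + 1 if ok else 0
        if run >= persistence:
            return float(traj.times[i - persistence + 1])
    return None
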