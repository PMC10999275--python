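"""Stochastic community dynamics.

Birth-death-immigration Markov chains for species abundances: an exact
(Gillespie) event-driven simulator for a single-species chain with arbitrary
state-dependent rates, a truncated master-equation integrator for the
pure-birth (Yule) process, a zero-sum neutral local community with
immigration from a fixed metacommunity, the diffusion-limit rescaling check
b_J(xJ) -> b(x), and a goodness-of-fit comparison of simulated
quasi-stationary proportional abundances against the beta baseline.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import expm_multiply

from ._rng import stream
from .distributions import BetaSAD

__all__ = [
    "CommunityState",
    "RateFunctions",
    "MasterEquationState",
    "gillespie_simulate",
    "solve_master_equation",
    "diffusion_limit_check",
    "NeutralCommunity",
    "simulate_neutral_community",
    "stationary_abundance_test",
    "rank_abundance",
]


@dataclass
class CommunityState:
    """Per-species counts in a focal community at elapsed model time t."""

    counts: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def J(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        return self.counts / self.J


@dataclass
class RateFunctions:
    """State-dependent birth/death rates B_J(n), D_J(n) for one species,
    with optional rescaled diffusion-limit rates b(x), d(x) on [0, 1] and an
    interaction/migration scale c_J (free; read from config when present)."""

    birth: Callable[[int], float]
    death: Callable[[int], float]
    c_J: float = 0.0
    rescaled_birth: Callable[[float], float] | None = None
    rescaled_death: Callable[[float], float] | None = None


# ---------------------------------------------------------------------------
# Gillespie
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Event-time trajectory of a single-species chain."""

    times: np.ndarray
    counts: np.ndarray
    absorbed: bool = False

    def final(self) -> int:
        return int(self.counts[-1])


def gillespie_simulate(
    rates: RateFunctions,
    init: int,
    t_max: float,
    seed: int,
    *,
    max_events: int = 10_000_000,
) -> Trajectory:
    """Statistically exact simulation of the birth-death chain.

    For small h the chain moves n -> n+1 with probability B(n) h and
    n -> n-1 with probability D(n) h; waiting times are exponential with
    rate B(n) + D(n).  Every event is recorded.  If the total rate hits 0
    before ``t_max`` the trajectory ends early and is flagged absorbed.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = stream(seed, "gillespie")
    t, n = 0.0, int(init)
    times, counts = [0.0], [n]
    absorbed = False
    for _ in range(max_events):
        b, d = rates.birth(n), rates.death(n)
        if b < 0 or d < 0:
            raise ValueError(f"negative rate at n={n}")
        total = b + d
        if total == 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        n = n + 1 if rng.random() < b / total else n - 1
        times.append(t)
        counts.append(n)
    times.append(t_max)
    counts.append(n)
    return Trajectory(np.asarray(times), np.asarray(counts), absorbed)


# ---------------------------------------------------------------------------
# master equation
# ---------------------------------------------------------------------------

@dataclass
class MasterEquationState:
    """Probability vector p_n(t) over n = 0..n_max for the pure-birth chain
    with per-capita rate beta (p'_n = (n-1) beta p_{n-1} - n beta p_n)."""

    probs: np.ndarray
    birth_rate: float
    t: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must be a probability vector (sum 1, >=0)")

    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)


def solve_master_equation(
    init: MasterEquationState, t: float, *, tail_tol: float = 1e-6
) -> MasterEquationState:
    """Integrate the pure-birth master equation to time t.

    Uses the exact matrix exponential of the (sparse, bidiagonal) truncated
    generator; the top state's outflow is suppressed so probability is
    conserved exactly, and the resulting mass near the truncation boundary
    is checked against ``tail_tol``.
    """
    p0 = init.probs
    beta = init.birth_rate
    nmax = p0.size - 1
    n = np.arange(nmax + 1, dtype=float)
    out = n * beta
    out[-1] = 0.0  # reflecting top: conserves mass, leak checked below
    gen = diags([-out, out[:-1]], [0, -1], format="csr")
    p = expm_multiply(gen * t, p0)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    # mass in the top 1% of states must be negligible for the truncation
    k = max(1, nmax // 100)
    if p[-k:].sum() > tail_tol:
        raise ValueError(
            f"probability mass {p[-k:].sum():.2e} near truncation n_max={nmax}; "
            "increase n_max"
        )
    return MasterEquationState(p, beta, t=init.t + t)


def yule_pmf(n: np.ndarray | int, beta: float, t: float, n0: int = 1) -> np.ndarray:
    """Closed-form Yule law for n0 = 1: geometric with success e^{-beta t}."""
    if n0 != 1:
        raise NotImplementedError("closed form implemented for n0 = 1")
    n = np.asarray(n)
    q = np.exp(-beta * t)
    return np.where(n >= 1, q * (1.0 - q) ** (n - 1), 0.0)


# ---------------------------------------------------------------------------
# diffusion-limit rescaling
# ---------------------------------------------------------------------------

def diffusion_limit_check(
    rate_family: Callable[[int], RateFunctions],
    J_values: Sequence[int],
    *,
    n_grid: int = 101,
):
    """Sup-norm gap between rescaled finite-J rates and their diffusion
    limits b(x), d(x), per community size J.

    ``rate_family(J)`` must return a :class:`RateFunctions` whose
    ``rescaled_birth``/``rescaled_death`` hold the limits; the finite-J
    rescaling evaluated is b_J(n) at n = round(xJ) on a fixed x-grid.
    Returns a list of dict rows ``{"J", "gap_birth", "gap_death"}``.
    """
    import pandas as pd

    xs = np.linspace(0.0, 1.0, n_grid)
    rows = []
    for J in J_values:
        rf = rate_family(int(J))
        if rf.rescaled_birth is None or rf.rescaled_death is None:
            raise ValueError("rate family must supply rescaled limits b(x), d(x)")
        ns = np.rint(xs * J).astype(int)
        gb = max(abs(rf.birth(int(n)) - rf.rescaled_birth(x)) for n, x in zip(ns, xs))
        gd = max(abs(rf.death(int(n)) - rf.rescaled_death(x)) for n, x in zip(ns, xs))
        rows.append({"J": int(J), "gap_birth": gb, "gap_death": gd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# zero-sum neutral local community with immigration
# ---------------------------------------------------------------------------

@dataclass
class NeutralCommunity:
    """Zero-sum neutral local community of J individuals.

    Per event, one individual chosen uniformly dies and is immediately
    replaced: with probability m by an immigrant drawn from the fixed
    metacommunity relative abundances, otherwise by the offspring of another
    local individual chosen uniformly.  Each individual carries an
    independent unit-rate death clock, so events occur at total rate J and
    J is conserved exactly.
    """

    J: int = 500
    m: float = 0.1
    meta_abundance: np.ndarray | None = None
    S_meta: int = 25

    def __post_init__(self) -> None:
        if self.meta_abundance is None:
            self.meta_abundance = np.full(self.S_meta, 1.0 / self.S_meta)
        else:
            self.meta_abundance = np.asarray(self.meta_abundance, dtype=float)
            self.meta_abundance /= self.meta_abundance.sum()
            self.S_meta = self.meta_abundance.size
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("immigration probability m must lie in [0, 1]")


def simulate_neutral_community(
    model: NeutralCommunity,
    n_events: int,
    seed: int,
    *,
    burn_in: int | None = None,
    thin: int | None = None,
    init: np.ndarray | None = None,
):
    """Run the neutral community and return thinned count snapshots.

    Parameters
    ----------
    model, n_events, seed
        Model, number of post-burn-in events, and run seed.
    burn_in
        Events discarded before sampling; default 20 J.
    thin
        Events between retained snapshots; default 10 J (roughly the 1/m
        immigration relaxation time in generations for the default m).
    init
        Optional initial per-species counts (summing to J); default draws
        every individual independently from the metacommunity.

    Returns
    -------
    (times, snapshots)
        Event times of the snapshots and an array of per-species counts,
        shape (n_snapshots, S_meta).
    """
    rng = stream(seed, "neutral-community")
    J, m, p = model.J, model.m, model.meta_abundance
    S = p.size
    burn_in = 20 * J if burn_in is None else int(burn_in)
    thin = 10 * J if thin is None else int(thin)

    if init is None:
        community = rng.choice(S, size=J, p=p)
    else:
        init = np.asarray(init, dtype=np.int64)
        if init.sum() != J or init.size != S:
            raise ValueError("init counts must sum to J over S_meta species")
        community = np.repeat(np.arange(S), init)
    counts = np.bincount(community, minlength=S).astype(np.int64)

    total = burn_in + n_events
    cum_p = np.cumsum(p)
    # exponential event clock at total rate J
    t = 0.0
    times, snaps = [], []
    # pre-draw randomness in blocks for speed
    block = 65536
    u_death = u_mode = u_repl = None
    idx = block
    for e in range(total):
        if idx >= block:
            u_death = rng.integers(0, J, size=block)
            u_mode = rng.random(block)
            u_repl = rng.random(block)
            wait = rng.exponential(1.0 / J, size=block)
            idx = 0
        t += wait[idx]
        die = u_death[idx]
        dead_sp = community[die]
        if u_mode[idx] < m:
            new_sp = int(np.searchsorted(cum_p, u_repl[idx]))
        else:
            # parent uniform among the J-1 survivors
            j = int(u_repl[idx] * (J - 1))
            if j >= die:
                j += 1
            new_sp = community[j]
        community[die] = new_sp
        counts[dead_sp] -= 1
        counts[new_sp] += 1
        idx += 1
        if e >= burn_in and (e - burn_in) % thin == thin - 1:
            times.append(t)
            snaps.append(counts.copy())
    if burn_in >= total:
        raise ValueError("burn-in consumed the whole trajectory")
    return np.asarray(times), np.asarray(snaps)


# ---------------------------------------------------------------------------
# goodness of fit against the beta baseline
# ---------------------------------------------------------------------------

def stationary_abundance_test(
    snapshots: np.ndarray,
    J: int,
    baseline: BetaSAD,
    *,
    seed: int,
    n_boot: int = 200,
) -> dict:
    """Kolmogorov-Smirnov comparison of simulated proportional abundances
    with a beta baseline.

    Pools x = n/J over species and snapshots, dropping zeros (species
    absent from the local community); requires at least 200 observations.
    The p-value and the 95% critical distance come from a parametric
    bootstrap: ``n_boot`` samples of equal size drawn from the baseline.
    """
    from scipy import stats as st

    x = (np.asarray(snapshots, dtype=float) / J).ravel()
    x = x[(x > 0) & (x < 1)]
    if x.size < 200:
        raise ValueError("need at least 200 proportional-abundance observations")
    ks = float(st.kstest(x, lambda v: st.beta.cdf(v, baseline.alpha, baseline.beta_shape)).statistic)

    if n_boot < 1:
        # distance only, no calibrated critical value
        return {"ks": ks, "crit_95": None, "p_value": None, "n_obs": int(x.size)}

    rng = stream(seed, "sad-ks-bootstrap")
    null = np.empty(n_boot)
    for b in range(n_boot):
        sim = rng.beta(baseline.alpha, baseline.beta_shape, size=x.size)
        null[b] = st.kstest(
            sim, lambda v: st.beta.cdf(v, baseline.alpha, baseline.beta_shape)
        ).statistic
    crit = float(np.percentile(null, 95))
    pval = float((np.sum(null >= ks) + 1) / (n_boot + 1))
    return {"ks": ks, "crit_95": crit, "p_value": pval, "n_obs": int(x.size)}


def rank_abundance(counts, labels: Sequence[str] | None = None):
    """Descending relative-abundance curve.

    Zero-count species are dropped; ties are broken by species label
    (lexicographic) so the curve is deterministic.  Returns a DataFrame
    with columns ``rank`` (1-based) and ``relative_abundance`` (sums to 1).
    """
    import pandas as pd

    c = np.asarray(counts, dtype=float)
    if labels is None:
        labels = [f"sp{i:04d}" for i in range(c.size)]
    keep = c > 0
    if not keep.any():
        raise ValueError("all counts are zero")
    c, labels = c[keep], np.asarray(labels)[keep]
    order = np.lexsort((labels, -c))
    rel = c[order] / c.sum()
    return pd.DataFrame(
        {"rank": np.arange(1, rel.size + 1), "species": labels[order], "relative_abundance": rel}
    )
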