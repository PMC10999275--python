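"""Random community-matrix stability.

Classic random-matrix analysis of large ecological networks: S species,
each ordered pair interacting independently with connectance probability C,
interaction strengths drawn from a zero-mean normal with standard deviation
alpha, and self-regulation on the diagonal.  Such a community rests at a
locally stable equilibrium (all eigenvalues of the community matrix have
negative real part) with high probability iff the complexity parameter
alpha * sqrt(S C) is below 1, and the transition sharpens as S grows.  A
corollary: if networks are sparse, with C proportional to 1/S, complexity
is independent of S and stability is unaffected by network size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream

__all__ = [
    "CommunityMatrixSpec",
    "random_community_matrix",
    "is_stable",
    "stability_probability",
    "sparse_scaling_scan",
]


@dataclass(frozen=True)
class CommunityMatrixSpec:
    """Ensemble parameters for random community matrices."""

    S: int
    C: float
    alpha_strength: float
    self_regulation: float = -1.0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need at least 2 species")
        if not 0 < self.C <= 1:
            raise ValueError("connectance must lie in (0, 1]")
        if self.alpha_strength < 0:
            raise ValueError("interaction-strength sd must be non-negative")

    @property
    def complexity(self) -> float:
        """May complexity parameter alpha * sqrt(S C)."""
        return self.alpha_strength * np.sqrt(self.S * self.C)


def random_community_matrix(spec: CommunityMatrixSpec, seed: int) -> np.ndarray:
    """Draw one community matrix from the ensemble."""
    rng = stream(seed, "community-matrix")
    S = spec.S
    A = rng.normal(0.0, spec.alpha_strength or 1.0, size=(S, S))
    if spec.alpha_strength == 0:
        A = np.zeros((S, S))
    mask = rng.random((S, S)) < spec.C
    A = np.where(mask, A, 0.0)
    np.fill_diagonal(A, spec.self_regulation)
    return A


def is_stable(matrix: np.ndarray) -> bool:
    """True iff every eigenvalue has strictly negative real part."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("community matrix must be square")
    return bool(np.max(np.linalg.eigvals(matrix).real) < 0)


def stability_probability(
    spec: CommunityMatrixSpec, reps: int, seed: int, *, ci_level: float = 0.95
) -> dict:
    """Monte-Carlo probability that a random community is stable.

    Returns the fraction of stable draws over ``reps`` matrices with a
    Wilson binomial confidence interval.
    """
    if reps < 50:
        raise ValueError("need at least 50 replicates")
    n_stable = sum(
        is_stable(random_community_matrix(spec, seed * 100_003 + r)) for r in range(reps)
    )
    lo, hi = _wilson_ci(n_stable, reps, ci_level)
    return {
        "frac_stable": n_stable / reps,
        "ci_lo": lo,
        "ci_hi": hi,
        "reps": reps,
        "complexity": spec.complexity,
    }


def _wilson_ci(k: int, n: int, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return float(max(centre - half, 0.0)), float(min(centre + half, 1.0))


def sparse_scaling_scan(
    S_values,
    alpha_strength: float,
    c0: float,
    reps: int,
    seed: int,
    *,
    dense_C: float | None = None,
) -> pd.DataFrame:
    """Stability fractions across network sizes under sparse connectance.

    For each S the connectance is C = c0 / S (complexity alpha*sqrt(c0),
    independent of S), or the fixed ``dense_C`` when given (the contrast
    case, where complexity grows with sqrt(S)).  Sizes whose implied C
    exceeds 1 are skipped with a warning row omitted.
    """
    import warnings

    rows = []
    for i, S in enumerate(S_values):
        C = dense_C if dense_C is not None else c0 / S
        if not 0 < C <= 1:
            warnings.warn(f"S={S}: connectance {C:.3g} infeasible; row skipped")
            continue
        spec = CommunityMatrixSpec(int(S), float(C), alpha_strength)
        res = stability_probability(spec, reps, seed + 17 * i)
        rows.append(
            {
                "S": int(S),
                "C": float(C),
                "alpha": alpha_strength,
                "complexity": spec.complexity,
                "frac_stable": res["frac_stable"],
                "ci_lo": res["ci_lo"],
                "ci_hi": res["ci_hi"],
            }
        )
    return pd.DataFrame(rows)
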