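"""Closed-form macroecological baseline distributions.

Three baselines recur throughout macroecology and anchor this package:

* the **beta** stationary species proportional-abundance distribution,
  rho(x) = Gamma(a+b)/(Gamma(a)Gamma(b)) x^(a-1) (1-x)^(b-1), the invariant
  density of symmetric (neutral) birth-death-immigration community dynamics;
* the **Pareto / truncated Pareto** individual size spectrum,
  f(m) = (lam+1)/(mmax^(lam+1) - m0^(lam+1)) m^lam, the inverse-J size
  distribution of assemblages at demographic steady state (density exponent
  lam close to -2 for tree diameters); and
* the **density-mass scaling** rule N = a M^(-b) linking population density
  to body mass across species (energetic equivalence).

The lambda sign convention is the density-exponent one (lam is the log-log
slope of the pdf, so lam is about -2 at steady state), not the positive
"slope magnitude"; :func:`slope_magnitude` converts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "BetaSAD",
    "ParetoSizeDist",
    "TruncatedParetoSizeDist",
    "DensityMassScaling",
    "beta_sad_pdf",
    "fit_beta_sad",
    "trunc_pareto_pdf",
    "trunc_pareto_cdf",
    "sample_trunc_pareto",
    "fit_trunc_pareto",
    "fit_density_mass_scaling",
    "slope_magnitude",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaSAD:
    """Beta stationary proportional-abundance distribution.

    ``alpha`` reflects the strength of immigration, ``beta_shape`` that of
    local extinction / speciation turnover, each relative to demographic
    stochasticity; both must be positive.
    """

    alpha: float
    beta_shape: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta_shape > 0):
            raise ValueError("beta shape parameters must be positive")

    # fitted-model metadata, populated by fit_beta_sad
    se_alpha: float | None = None
    se_beta: float | None = None
    loglik: float | None = None

    def pdf(self, x):
        return beta_sad_pdf(x, self)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta_shape, size=n)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta_shape}


@dataclass(frozen=True)
class ParetoSizeDist:
    """Pareto size spectrum f(m) = -(lam+1) m0^-(lam+1) m^lam on [m0, inf).

    Normalizable only for ``lam < -1``; size units (mass or diameter) are
    declared by the caller and carried through unchanged.
    """

    lam: float
    m0: float

    def __post_init__(self) -> None:
        if not self.lam < -1:
            raise ValueError("Pareto exponent lam must be < -1 to normalize")
        if not self.m0 > 0:
            raise ValueError("m0 must be positive")

    def pdf(self, m):
        m = np.asarray(m, dtype=float)
        out = np.where(
            m >= self.m0,
            -(self.lam + 1.0) * self.m0 ** -(self.lam + 1.0) * m**self.lam,
            0.0,
        )
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "m0": self.m0}


@dataclass(frozen=True)
class TruncatedParetoSizeDist:
    """Truncated Pareto size spectrum on [m0, mmax].

    f(m) = (lam+1)/(mmax^(lam+1) - m0^(lam+1)) m^lam, with the logarithmic
    limit 1/(m ln(mmax/m0)) at lam = -1.  Any real exponent is admissible
    because the finite upper bound keeps the density normalizable.
    """

    lam: float
    m0: float
    mmax: float

    # fit metadata
    ci_lam: tuple[float, float] | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.m0 < self.mmax):
            raise ValueError("need 0 < m0 < mmax")

    def pdf(self, m):
        return trunc_pareto_pdf(m, self)

    def cdf(self, m):
        return trunc_pareto_cdf(m, self)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return sample_trunc_pareto(self, n, rng)

    def to_dict(self) -> dict:
        return {"lambda": self.lam, "m0": self.m0, "mmax": self.mmax}


@dataclass(frozen=True)
class DensityMassScaling:
    """Density-mass scaling N = a M^(-b); b is the positive exponent of the
    inverse relationship."""

    a: float
    b: float
    r_squared: float | None = None
    se_b: float | None = None

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("normalization a must be positive")

    def predict(self, mass):
        return self.a * np.asarray(mass, dtype=float) ** (-self.b)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}


# ---------------------------------------------------------------------------
# beta SAD
# ---------------------------------------------------------------------------

def beta_sad_pdf(x, sad: BetaSAD):
    """Beta density of proportional abundance x in (0, 1).

    Evaluates Gamma(a+b)/(Gamma(a)Gamma(b)) x^(a-1)(1-x)^(b-1).  Raises on
    arguments outside the open unit interval (the abundance of a present
    species is strictly between 0 and 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError("proportional abundance must lie strictly in (0, 1)")
    out = stats.beta.pdf(x, sad.alpha, sad.beta_shape)
    return out if out.ndim else float(out)


def fit_beta_sad(proportions, *, nudge_total: int | None = None) -> BetaSAD:
    """Maximum-likelihood beta fit to species proportional abundances.

    Parameters
    ----------
    proportions
        At least 10 values strictly inside (0, 1).  Exact 0/1 values are
        rejected; pass ``nudge_total=J`` (total community size) to replace
        them by the standard boundary nudge 1/(2J), resp. 1 - 1/(2J).
    nudge_total
        Community size J used for the boundary nudge; ``None`` disables it.

    Returns
    -------
    BetaSAD
        With MLE shapes, closed-form Fisher standard errors and the
        maximized log-likelihood attached.  Estimates are invariant to the
        input order.
    """
    x = np.asarray(proportions, dtype=float).copy()
    if nudge_total is not None:
        eps = 1.0 / (2.0 * nudge_total)
        x[x <= 0] = eps
        x[x >= 1] = 1.0 - eps
    if np.any((x <= 0) | (x >= 1)):
        raise ValueError(
            "proportions at exactly 0 or 1: pass nudge_total=J to apply the "
            "1/(2J) boundary nudge"
        )
    if x.size < 10:
        raise ValueError("need at least 10 proportional abundances")

    a_hat, b_hat, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    n = x.size
    ll = float(np.sum(stats.beta.logpdf(x, a_hat, b_hat)))

    # Fisher information of the beta family in closed form
    tri = special.polygamma(1, [a_hat, b_hat, a_hat + b_hat])
    info = n * np.array(
        [[tri[0] - tri[2], -tri[2]], [-tri[2], tri[1] - tri[2]]]
    )
    cov = np.linalg.inv(info)
    se_a, se_b = np.sqrt(np.diag(cov))
    return BetaSAD(a_hat, b_hat, se_alpha=float(se_a), se_beta=float(se_b), loglik=ll)


# ---------------------------------------------------------------------------
# truncated Pareto
# ---------------------------------------------------------------------------

def _tp_lognorm(lam: float, m0: float, mmax: float) -> float:
    """log of the normalization integral of m^lam on [m0, mmax]."""
    if abs(lam + 1.0) < 1e-12:
        return float(np.log(np.log(mmax / m0)))
    lp1 = lam + 1.0
    return float(np.log(abs(mmax**lp1 - m0**lp1) / abs(lp1)))


def trunc_pareto_pdf(m, dist: TruncatedParetoSizeDist):
    """Truncated-Pareto density; 0 outside [m0, mmax] by convention."""
    m = np.asarray(m, dtype=float)
    inside = (m >= dist.m0) & (m <= dist.mmax)
    logc = _tp_lognorm(dist.lam, dist.m0, dist.mmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.exp(dist.lam * np.log(np.where(inside, m, 1.0)) - logc)
    out = np.where(inside, dens, 0.0)
    return out if out.ndim else float(out)


def trunc_pareto_cdf(m, dist: TruncatedParetoSizeDist):
    """Truncated-Pareto cumulative distribution (clipped to [0, 1])."""
    m = np.asarray(m, dtype=float)
    mc = np.clip(m, dist.m0, dist.mmax)
    lam, m0, mmax = dist.lam, dist.m0, dist.mmax
    if abs(lam + 1.0) < 1e-12:
        out = np.log(mc / m0) / np.log(mmax / m0)
    else:
        lp1 = lam + 1.0
        out = (mc**lp1 - m0**lp1) / (mmax**lp1 - m0**lp1)
    out = np.where(m < dist.m0, 0.0, np.where(m > dist.mmax, 1.0, out))
    return out if out.ndim else float(out)


def sample_trunc_pareto(
    dist: TruncatedParetoSizeDist, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-cdf sampler for the truncated Pareto."""
    u = rng.random(n)
    lam, m0, mmax = dist.lam, dist.m0, dist.mmax
    if abs(lam + 1.0) < 1e-12:
        return m0 * (mmax / m0) ** u
    lp1 = lam + 1.0
    return (m0**lp1 + u * (mmax**lp1 - m0**lp1)) ** (1.0 / lp1)


def _tp_negloglik(lam: float, logs: np.ndarray, m0: float, mmax: float) -> float:
    return len(logs) * _tp_lognorm(lam, m0, mmax) - lam * float(logs.sum())


def fit_trunc_pareto(
    sizes,
    *,
    n_boot: int = 200,
    seed: int | None = None,
    lam_bounds: tuple[float, float] = (-6.0, 2.0),
) -> TruncatedParetoSizeDist:
    """Fit a truncated Pareto to individual sizes by maximum likelihood.

    Endpoints use the plug-in convention m0 = min(sizes), mmax = max(sizes);
    the exponent is estimated by bounded one-dimensional likelihood
    maximization.  A percentile bootstrap confidence interval on lambda is
    attached when a seed is given (``n_boot`` replicates, 95% level).
    """
    m = np.asarray(sizes, dtype=float)
    if m.size < 30:
        raise ValueError("need at least 30 sizes to fit a size spectrum")
    if np.any(m <= 0):
        raise ValueError("sizes must be positive")
    m0, mmax = float(m.min()), float(m.max())
    if m0 == mmax:
        raise ValueError("degenerate sample: all sizes identical")

    logs = np.log(m)

    def fit_one(lg: np.ndarray, lo: float, hi: float) -> float:
        res = optimize.minimize_scalar(
            _tp_negloglik,
            bounds=lam_bounds,
            args=(lg, lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)

    lam_hat = fit_one(logs, m0, mmax)
    ll = -_tp_negloglik(lam_hat, logs, m0, mmax)

    ci = None
    if seed is not None and n_boot > 0:
        from ._rng import stream

        rng = stream(seed, "trunc-pareto-bootstrap")
        boots = np.empty(n_boot)
        for b in range(n_boot):
            res = m[rng.integers(0, m.size, m.size)]
            boots[b] = fit_one(np.log(res), float(res.min()), float(res.max()))
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return TruncatedParetoSizeDist(lam_hat, m0, mmax, ci_lam=ci, loglik=ll)


# ---------------------------------------------------------------------------
# density-mass scaling
# ---------------------------------------------------------------------------

def fit_density_mass_scaling(masses, abundances) -> DensityMassScaling:
    """OLS of log N on log M; returns N = a M^(-b) with b the positive
    exponent of the inverse relationship, plus R-squared and SE(b)."""
    M = np.asarray(masses, dtype=float)
    N = np.asarray(abundances, dtype=float)
    if M.shape != N.shape or M.size < 3:
        raise ValueError("need equal-length vectors of at least 3 species")
    if np.any(M <= 0) or np.any(N <= 0):
        raise ValueError("masses and abundances must be positive")
    res = stats.linregress(np.log(M), np.log(N))
    return DensityMassScaling(
        a=float(np.exp(res.intercept)),
        b=float(-res.slope),
        r_squared=float(res.rvalue**2),
        se_b=float(res.stderr),
    )


def slope_magnitude(lam: float) -> float:
    """Convert a density exponent (lam, about -2 at steady state) to the
    positive slope-magnitude convention."""
    return -lam
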