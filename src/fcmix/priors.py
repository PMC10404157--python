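"""Prior construction for the binding-screen inference.

Affinity priors are log-normal, parameterized so that the distribution's
*mode* equals the documented association constant and its *interquartile
range* equals the documented standard error.  Documented non-binders (zero
or missing affinity) are handled by clipping: the mode is floored at
1e4 M^-1 and the IQR at 1e5 M^-1, which keeps nominally non-binding
interactions estimable rather than pinned at zero.

Receptor-expression priors are log-normal fits (maximum likelihood on the
log scale) to replicate abundance measurements of each cell line, with a
floor on the log-scale spread to guard degenerate replicate sets.

The effective-valency and crosslinking priors are fixed:
``f4 ~ logN(log 4, 0.2)``, ``f33 ~ logN(log 33, 0.2)``,
``Kx* ~ logN(log 6.31e-13, 2.0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fcmix.binding import DEFAULT_KX_STAR

__all__ = [
    "KA_MODE_CLIP",
    "KA_IQR_CLIP",
    "EXPRESSION_SIGMA_FLOOR",
    "LogNormalPrior",
    "AffinityPrior",
    "ExpressionPrior",
    "PriorSet",
    "lognormal_from_mode_iqr",
    "expression_prior_mle",
    "build_priors",
]

KA_MODE_CLIP = 1e4  # M^-1; floor for documented affinity modes
KA_IQR_CLIP = 1e5  # M^-1; floor for documented standard errors as IQRs
EXPRESSION_SIGMA_FLOOR = 0.01  # log-scale spread floor for expression priors

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal with density parameters (mu, sigma) on the natural log."""

    mu: float
    sigma: float

    def logpdf_log(self, log_x: float | np.ndarray) -> float | np.ndarray:
        """Normal log-density of log(x); the inference works on log scale."""
        z = (log_x - self.mu) / self.sigma
        return -0.5 * z * z - math.log(self.sigma) - 0.5 * math.log(2.0 * math.pi)

    @property
    def mode(self) -> float:
        return math.exp(self.mu - self.sigma**2)

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def iqr(self) -> float:
        return math.exp(self.mu + _Z75 * self.sigma) - math.exp(self.mu - _Z75 * self.sigma)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=size))


@dataclass(frozen=True)
class AffinityPrior(LogNormalPrior):
    """Affinity prior tied to its documented value and standard error."""

    documented_ka: float = float("nan")
    documented_se: float = float("nan")


@dataclass(frozen=True)
class ExpressionPrior(LogNormalPrior):
    """Receptor-abundance prior for one cell line."""

    label: str = ""


def lognormal_from_mode_iqr(mode: float, iqr: float) -> tuple[float, float]:
    """Solve (mu, sigma) of a log-normal from its mode and interquartile range.

    The mode is ``exp(mu - sigma^2)`` and the IQR is
    ``exp(mu + z sigma) - exp(mu - z sigma)`` with ``z = Phi^-1(0.75)``.
    Substituting ``mu = log(mode) + sigma^2`` leaves a single strictly
    increasing function of sigma, ``mode * exp(sigma^2) * 2 sinh(z sigma)``,
    whose root is bracketed and solved with Brent's method to 1e-10.
    """
    if not (mode > 0 and iqr > 0):
        raise ValueError("mode and iqr must be positive")

    log_mode = math.log(mode)

    def iqr_of_sigma(sig: float) -> float:
        return math.exp(log_mode + sig * sig) * 2.0 * math.sinh(_Z75 * sig)

    lo, hi = 1e-12, 1.0
    while iqr_of_sigma(hi) < iqr:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError("no positive-sigma solution in numeric range")
    if iqr_of_sigma(lo) > iqr:
        raise ValueError("iqr too small relative to mode for a positive sigma")
    sigma = optimize.brentq(
        lambda s: iqr_of_sigma(s) - iqr, lo, hi, xtol=1e-14, rtol=1e-14, maxiter=200
    )
    mu = log_mode + sigma * sigma
    return mu, sigma


def expression_prior_mle(label: str, replicates: np.ndarray) -> ExpressionPrior:
    """Log-normal MLE fit to positive abundance replicates.

    The MLE on the log scale is the sample mean and (biased, 1/n) standard
    deviation of log replicates; the spread is floored to keep the prior
    proper when replicates coincide.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError(f"need >= 2 expression replicates for {label!r}")
    if np.any(reps <= 0):
        raise ValueError("expression replicates must be positive")
    logs = np.log(reps)
    mu = float(np.mean(logs))
    sigma = max(float(np.std(logs)), EXPRESSION_SIGMA_FLOOR)
    return ExpressionPrior(mu=mu, sigma=sigma, label=label)


@dataclass(frozen=True)
class PriorSet:
    """Complete prior specification for a binding-screen fit."""

    affinity: dict[tuple[str, str], AffinityPrior]  # (ligand, receptor) -> prior
    expression: dict[str, ExpressionPrior]  # receptor line -> prior
    f4: LogNormalPrior
    f33: LogNormalPrior
    kx_star: LogNormalPrior
    # Nuisance priors (likelihood-side; see docs/methods.md for rationale)
    batch_scale: LogNormalPrior
    noise_sigma: LogNormalPrior

    @property
    def ligand_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[0] for k in self.affinity))

    @property
    def receptor_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(k[1] for k in self.affinity))


def build_priors(
    documented_affinities: pd.DataFrame,
    expression_replicates: pd.DataFrame,
    f_valencies: tuple[float, float] = (4.0, 33.0),
) -> PriorSet:
    """Assemble the full prior set for a screen.

    Parameters
    ----------
    documented_affinities
        Columns ``ligand``, ``receptor``, ``ka`` (M^-1), ``ka_se``; zero or
        missing entries are clipped to the non-binder floors.
    expression_replicates
        Columns ``receptor`` (cell-line label) and ``rtot`` with >= 2 rows
        per line.
    f_valencies
        Nominal valencies of the two complex preparations; the effective
        valency priors are centered on them with log-sd 0.2.
    """
    required = {"ligand", "receptor", "ka", "ka_se"}
    if not required.issubset(documented_affinities.columns):
        raise ValueError(f"affinity table needs columns {sorted(required)}")

    affinity: dict[tuple[str, str], AffinityPrior] = {}
    for row in documented_affinities.itertuples(index=False):
        ka = float(row.ka) if np.isfinite(row.ka) else 0.0
        se = float(row.ka_se) if np.isfinite(row.ka_se) else 0.0
        mode = max(ka, KA_MODE_CLIP)
        iqr = max(se, KA_IQR_CLIP)
        mu, sigma = lognormal_from_mode_iqr(mode, iqr)
        affinity[(str(row.ligand), str(row.receptor))] = AffinityPrior(
            mu=mu, sigma=sigma, documented_ka=ka, documented_se=se
        )

    expression = {
        str(label): expression_prior_mle(str(label), grp["rtot"].to_numpy())
        for label, grp in expression_replicates.groupby("receptor", sort=False)
    }

    f_lo, f_hi = f_valencies
    return PriorSet(
        affinity=affinity,
        expression=expression,
        f4=LogNormalPrior(mu=math.log(f_lo), sigma=0.2),
        f33=LogNormalPrior(mu=math.log(f_hi), sigma=0.2),
        kx_star=LogNormalPrior(mu=math.log(DEFAULT_KX_STAR), sigma=2.0),
        batch_scale=LogNormalPrior(mu=0.0, sigma=10.0),
        noise_sigma=LogNormalPrior(mu=math.log(0.2), sigma=1.0),
    )
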