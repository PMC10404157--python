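"""Bayesian refinement of Fc-FcγR affinities from multivalent binding screens.

The forward model is the closed-form equilibrium of :mod:`fcmix.binding`:
each CHO line displays a single receptor type, so a measurement row
(receptor line, valency, subclass pair, composition) maps to a bound-complex
prediction ``Lbound``.  A free positive scale factor per assay day links
model units to day-normalized RFU, and measurement noise is multiplicative
log-normal with one shared spread:

    log RFU ~ Normal(log scale_day + log Lbound, sigma)

This likelihood is a modeling choice: the data are geometric-mean
normalized per day, for which multiplicative error and a per-day scale are
the natural closure.

Three fitting regimes mirror the analysis ladder of a binding screen:

``fixed_all``
    Every parameter pinned at its prior mode (documented affinities,
    measured expression, nominal valencies, default Kx*); no sampling —
    prediction is deterministic.
``fit_nonaffinity``
    Affinities stay at their documented values; receptor abundances,
    effective valencies, Kx*, day scales and noise are sampled.
``fit_affinity``
    Affinities are sampled too, but the likelihood sees only the
    pure-composition (single-subclass) rows; mixture rows are held out for
    validation through the posterior predictive.

All parameters are sampled on the log scale (they are strictly positive and
span decades).  Sampling is ensemble MCMC (emcee) initialized from a
L-BFGS-B MAP estimate; split-chain R-hat is computed across independently
seeded ensembles with arviz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fcmix.priors import PriorSet

__all__ = [
    "REGIMES",
    "FitConfig",
    "BindingScreenModel",
    "PosteriorSamples",
    "model_log_posterior",
    "map_estimate",
    "sample_posterior",
    "posterior_predictive",
    "validate_with_fixed_affinities",
]

REGIMES = ("fixed_all", "fit_nonaffinity", "fit_affinity")

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FitConfig:
    """Sampler and regime settings for one screen fit.

    ``draws`` counts retained posterior draws per chain; each chain is one
    emcee ensemble whose post-warmup walker states are flattened, so the
    total retained draw count is ``chains * draws``.  ``warmup`` counts
    ensemble steps discarded before retention.
    """

    regime: str = "fit_affinity"
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    walkers: int | None = None  # default max(2*ndim + 2, 48)
    map_maxiter: int = 2000
    map_tol: float = 1e-10
    l0: float = 1e-9  # molar IC concentration of the screen
    f_valencies: tuple[float, float] = (4.0, 33.0)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if min(self.chains, self.draws, self.warmup) < 1:
            raise ValueError("chains, draws and warmup must be positive")


def _is_pure(frac1: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    return (frac1 <= eps) | (frac1 >= 1.0 - eps)


class BindingScreenModel:
    """Posterior density of a binding screen under one fitting regime.

    Parameters
    ----------
    table
        Measurement rows with columns ``day``, ``receptor``, ``valency``,
        ``subclass1``, ``subclass2``, ``frac1``, ``replicate``, ``rfu``.
        May be empty (prior-only model).
    priors
        Complete :class:`~fcmix.priors.PriorSet` covering every (ligand,
        receptor) pair and receptor line the table references.
    config
        Regime and sampler settings.
    fixed_ka
        Optional override of the pinned affinity values (natural scale,
        ``{(ligand, receptor): ka}``) used when affinities are not free;
        defaults to the prior modes (clipped documented values).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        priors: PriorSet,
        config: FitConfig,
        fixed_ka: dict[tuple[str, str], float] | None = None,
    ) -> None:
        self.priors = priors
        self.config = config
        self.ligands = priors.ligand_ids
        self.receptors = priors.receptor_ids
        self.lig_index = {l: i for i, l in enumerate(self.ligands)}
        self.rec_index = {r: j for j, r in enumerate(self.receptors)}

        table = table.reset_index(drop=True)
        if len(table):
            unknown_r = set(table["receptor"]) - set(self.receptors)
            unknown_l = (set(table["subclass1"]) | set(table["subclass2"])) - set(self.ligands)
            if unknown_r or unknown_l:
                raise ValueError(f"unknown labels in table: {unknown_r | unknown_l}")
        if config.regime == "fit_affinity" and len(table):
            fit_table = table[_is_pure(table["frac1"].to_numpy(float))].reset_index(drop=True)
        else:
            fit_table = table
        self.table = table
        self.fit_table = fit_table
        self.days = tuple(dict.fromkeys(fit_table["day"])) if len(fit_table) else ()
        self.day_index = {d: k for k, d in enumerate(self.days)}

        # Row-aligned arrays for the likelihood
        t = fit_table
        n = len(t)
        self._rec = np.array([self.rec_index[r] for r in t["receptor"]], dtype=int)
        self._s1 = np.array([self.lig_index[l] for l in t["subclass1"]], dtype=int)
        self._s2 = np.array([self.lig_index[l] for l in t["subclass2"]], dtype=int)
        self._frac1 = t["frac1"].to_numpy(float) if n else np.empty(0)
        f_lo, f_hi = config.f_valencies
        val = t["valency"].to_numpy(float) if n else np.empty(0)
        if n and not np.all(np.isin(val, [f_lo, f_hi])):
            raise ValueError(f"valency labels must be in {{{f_lo}, {f_hi}}}")
        self._is_hi = val == f_hi
        self._day = np.array([self.day_index[d] for d in t["day"]], dtype=int)
        self._log_rfu = np.log(t["rfu"].to_numpy(float)) if n else np.empty(0)

        # Free-parameter layout
        self.pair_keys = tuple(priors.affinity)
        names: list[str] = []
        if config.regime == "fit_affinity":
            names += [f"logka:{l}:{r}" for l, r in self.pair_keys]
        if config.regime != "fixed_all":
            names += [f"logrtot:{r}" for r in self.receptors]
            names += ["logf_lo", "logf_hi", "logkx"]
            names += [f"logscale:{d}" for d in self.days]
            names += ["logsigma"]
        self.names = tuple(names)
        self.ndim = len(names)

        # Pinned values (log scale).  Affinities pin at the documented
        # (clipped) value, which is the natural-scale mode of their prior by
        # construction; every other positive parameter pins at its prior mu,
        # the mode of the Normal prior on the log scale (e.g. the nominal
        # valency and the default Kx*).
        ka_pin = np.empty((len(self.ligands), len(self.receptors)))
        for (l, r), prior in priors.affinity.items():
            ka_pin[self.lig_index[l], self.rec_index[r]] = prior.mode
        if fixed_ka is not None:
            for (l, r), v in fixed_ka.items():
                ka_pin[self.lig_index[l], self.rec_index[r]] = v
        self._log_ka_pin = np.log(ka_pin)
        self._log_rtot_pin = np.array([priors.expression[r].mu for r in self.receptors])
        self._log_f_pin = np.array([priors.f4.mu, priors.f33.mu])
        self._log_kx_pin = priors.kx_star.mu
        self._affinity_free = config.regime == "fit_affinity"
        self._n_pairs = len(self.pair_keys)
        self._pair_li = np.array([self.lig_index[l] for l, _ in self.pair_keys], dtype=int)
        self._pair_ri = np.array([self.rec_index[r] for _, r in self.pair_keys], dtype=int)

    # -- parameter packing ------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray | float]:
        """Full parameter dictionary (log scale) implied by a free vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.ndim,):
            raise ValueError(f"theta must have length {self.ndim}")
        pos = 0
        log_ka = self._log_ka_pin.copy()
        if self._affinity_free:
            log_ka[self._pair_li, self._pair_ri] = theta[pos : pos + self._n_pairs]
            pos += self._n_pairs
        if self.config.regime == "fixed_all":
            return {
                "log_ka": log_ka,
                "log_rtot": self._log_rtot_pin.copy(),
                "log_f": self._log_f_pin.copy(),
                "log_kx": self._log_kx_pin,
                "log_scale": np.zeros(len(self.days)),
                "log_sigma": self.priors.noise_sigma.mu,
            }
        nr = len(self.receptors)
        log_rtot = theta[pos : pos + nr]
        pos += nr
        log_f = theta[pos : pos + 2]
        pos += 2
        log_kx = theta[pos]
        pos += 1
        log_scale = theta[pos : pos + len(self.days)]
        pos += len(self.days)
        log_sigma = theta[pos]
        return {
            "log_ka": log_ka,
            "log_rtot": log_rtot,
            "log_f": log_f,
            "log_kx": log_kx,
            "log_scale": log_scale,
            "log_sigma": log_sigma,
        }

    def pinned_theta(self) -> np.ndarray:
        """Free vector with every parameter at its prior mode (log scale)."""
        parts: list[np.ndarray] = []
        if self._affinity_free:
            parts.append(self._log_ka_pin[self._pair_li, self._pair_ri])
        if self.config.regime != "fixed_all":
            parts.append(self._log_rtot_pin)
            parts.append(self._log_f_pin)
            parts.append(np.array([self._log_kx_pin]))
            parts.append(np.zeros(len(self.days)))
            parts.append(np.array([self.priors.noise_sigma.mu]))
        return np.concatenate(parts) if parts else np.empty(0)

    # -- density ----------------------------------------------------------

    def _predict_log_lbound(
        self,
        params: dict,
        rec: np.ndarray,
        s1: np.ndarray,
        s2: np.ndarray,
        frac1: np.ndarray,
        is_hi: np.ndarray,
    ) -> np.ndarray:
        from fcmix.binding import solve_lbound_1r

        ka = np.exp(params["log_ka"])
        rtot = np.exp(params["log_rtot"])
        f_pair = np.exp(params["log_f"])
        kx = math.exp(min(params["log_kx"], 500.0))
        ka_eff = frac1 * ka[s1, rec] + (1.0 - frac1) * ka[s2, rec]
        f_row = np.where(is_hi, f_pair[1], f_pair[0])
        lbound = solve_lbound_1r(rtot[rec], ka_eff, self.config.l0, f_row, kx)
        return np.log(np.maximum(lbound, 1e-300))

    def log_likelihood(self, theta: np.ndarray) -> float:
        if len(self.fit_table) == 0:
            return 0.0
        params = self.unpack(theta)
        mu = (
            params["log_scale"][self._day]
            + self._predict_log_lbound(
                params, self._rec, self._s1, self._s2, self._frac1, self._is_hi
            )
        )
        sigma = math.exp(params["log_sigma"])
        z = (self._log_rfu - mu) / sigma
        return float(-0.5 * np.sum(z * z) - len(z) * (math.log(sigma) + 0.5 * _LOG2PI))

    def log_prior(self, theta: np.ndarray) -> float:
        params = self.unpack(theta)
        lp = 0.0
        if self._affinity_free:
            for (key, li, ri) in zip(self.pair_keys, self._pair_li, self._pair_ri):
                lp += self.priors.affinity[key].logpdf_log(params["log_ka"][li, ri])
        if self.config.regime != "fixed_all":
            for j, r in enumerate(self.receptors):
                lp += self.priors.expression[r].logpdf_log(params["log_rtot"][j])
            lp += self.priors.f4.logpdf_log(params["log_f"][0])
            lp += self.priors.f33.logpdf_log(params["log_f"][1])
            lp += self.priors.kx_star.logpdf_log(params["log_kx"])
            for k in range(len(self.days)):
                lp += self.priors.batch_scale.logpdf_log(params["log_scale"][k])
            lp += self.priors.noise_sigma.logpdf_log(params["log_sigma"])
        return float(lp)

    def log_posterior(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        # hard support box (±50 log units around the pins) keeps optimizer
        # line searches and walkers out of overflow territory
        if not hasattr(self, "_pin_box"):
            self._pin_box = self.pinned_theta()
        if theta.size and np.any(np.abs(theta - self._pin_box) > 50.0):
            return -np.inf
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.log_likelihood(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    # -- prediction -------------------------------------------------------

    def predict_rfu(self, conditions: pd.DataFrame, theta: np.ndarray) -> np.ndarray:
        """Scaled RFU prediction for arbitrary conditions at one parameter point.

        Conditions carry ``receptor``, ``valency``, ``subclass1``,
        ``subclass2``, ``frac1`` and optionally ``day``; without a day the
        geometric mean of the fitted day scales is applied.
        """
        params = self.unpack(np.asarray(theta, dtype=float))
        rec = np.array([self.rec_index[r] for r in conditions["receptor"]], dtype=int)
        s1 = np.array([self.lig_index[l] for l in conditions["subclass1"]], dtype=int)
        s2 = np.array([self.lig_index[l] for l in conditions["subclass2"]], dtype=int)
        frac1 = conditions["frac1"].to_numpy(float)
        f_lo, f_hi = self.config.f_valencies
        is_hi = conditions["valency"].to_numpy(float) == f_hi
        log_lb = self._predict_log_lbound(params, rec, s1, s2, frac1, is_hi)
        if "day" in conditions.columns and len(self.days):
            log_scale = np.array(
                [
                    params["log_scale"][self.day_index[d]]
                    if d in self.day_index
                    else float(np.mean(params["log_scale"]))
                    for d in conditions["day"]
                ]
            )
        else:
            log_scale = float(np.mean(params["log_scale"])) if len(self.days) else 0.0
        return np.exp(log_scale + log_lb)


@dataclass(frozen=True)
class PosteriorSamples:
    """Retained MCMC draws (log scale) with diagnostics.

    ``chains`` has shape (n_chains, draws, ndim) aligned with ``names``.
    """

    names: tuple[str, ...]
    chains: np.ndarray
    rhat: dict[str, float]
    acceptance_fraction: float
    map_theta: np.ndarray
    model: BindingScreenModel = field(repr=False, compare=False, default=None)

    @property
    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[-1])

    def draws_of(self, name: str) -> np.ndarray:
        """Natural-scale draws of one parameter."""
        return np.exp(self.flat[:, self.names.index(name)])

    def log_draws_of(self, name: str) -> np.ndarray:
        return self.flat[:, self.names.index(name)]

    def summary(self) -> pd.DataFrame:
        """Per-parameter natural-scale median, quartiles and R-hat."""
        flat = np.exp(self.flat)
        q = np.percentile(flat, [50, 25, 75], axis=0)
        return pd.DataFrame(
            {
                "parameter": list(self.names),
                "median": q[0],
                "q25": q[1],
                "q75": q[2],
                "r_hat": [self.rhat[n] for n in self.names],
            }
        )

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


def model_log_posterior(
    params: np.ndarray,
    table: pd.DataFrame,
    priors: PriorSet,
    regime: str,
    config: FitConfig | None = None,
) -> float:
    """Log posterior of a free-parameter vector under the given regime."""
    config = replace(config or FitConfig(), regime=regime)
    return BindingScreenModel(table, priors, config).log_posterior(np.asarray(params))


def map_estimate(
    table: pd.DataFrame,
    priors: PriorSet,
    config: FitConfig,
    model: BindingScreenModel | None = None,
) -> tuple[np.ndarray, BindingScreenModel]:
    """Maximum a posteriori point by L-BFGS-B on the log-scale free vector.

    Day-scale entries are warm-started from the residual between measured
    RFU and the prior-mode prediction; everything else starts at its prior
    mode.  Deterministic: no randomness enters the optimization.
    """
    from scipy import optimize

    model = model or BindingScreenModel(table, priors, config)
    x0 = model.pinned_theta()
    if model.ndim == 0:
        return x0, model
    # Warm-start day scales from prior-mode residuals
    if len(model.fit_table):
        params0 = model.unpack(x0)
        log_lb = model._predict_log_lbound(
            params0, model._rec, model._s1, model._s2, model._frac1, model._is_hi
        )
        resid = model._log_rfu - log_lb
        for d, k in model.day_index.items():
            x0[model.names.index(f"logscale:{d}")] = float(np.mean(resid[model._day == k]))

    res = optimize.minimize(
        lambda th: -model.log_posterior(th),
        x0,
        method="L-BFGS-B",
        options={"maxiter": config.map_maxiter, "ftol": config.map_tol, "gtol": 1e-8},
    )
    if not res.success:
        warnings.warn(f"MAP optimizer stopped early: {res.message}", RuntimeWarning)
    return np.asarray(res.x), model


def sample_posterior(
    table: pd.DataFrame,
    priors: PriorSet,
    config: FitConfig,
    fixed_ka: dict[tuple[str, str], float] | None = None,
) -> PosteriorSamples:
    """Ensemble MCMC over the regime's free parameters.

    Each requested chain is an independently seeded emcee ensemble started
    from a tight Gaussian ball around the MAP point.  After ``warmup``
    ensemble steps, walker states are flattened until ``draws`` samples per
    chain are retained.  R-hat is computed across chains with arviz; values
    above 1.05 raise a warning (flagged, not fatal).
    """
    import emcee

    model = BindingScreenModel(table, priors, config, fixed_ka=fixed_ka)
    if model.ndim == 0:
        raise ValueError("regime fixed_all has no free parameters to sample")
    map_theta, _ = map_estimate(table, priors, config, model=model)
    nwalkers = config.walkers or max(2 * model.ndim + 2, 48)
    keep_steps = -(-config.draws // nwalkers)  # ceil

    all_chains = []
    acc = []
    for c in range(config.chains):
        rs = np.random.RandomState((config.seed + 7919 * (c + 1)) % (2**31))
        p0 = map_theta[None, :] + 1e-3 * rs.randn(nwalkers, model.ndim)
        sampler = emcee.EnsembleSampler(nwalkers, model.ndim, model.log_posterior)
        sampler._random = rs
        sampler.run_mcmc(p0, config.warmup + keep_steps, progress=False)
        chain = sampler.get_chain(discard=config.warmup)  # (keep_steps, walkers, ndim)
        flat = chain.reshape(-1, model.ndim)[: config.draws]
        all_chains.append(flat)
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    chains = np.stack(all_chains)  # (chains, draws, ndim)
    rhat = _rhat(chains, model.names)
    bad = {n: v for n, v in rhat.items() if v > 1.05}
    if bad:
        worst = max(bad.values())
        warnings.warn(
            f"{len(bad)} parameter(s) with split R-hat > 1.05 (worst {worst:.3f})",
            RuntimeWarning,
        )
    return PosteriorSamples(
        names=model.names,
        chains=chains,
        rhat=rhat,
        acceptance_fraction=float(np.mean(acc)),
        map_theta=map_theta,
        model=model,
    )


def _rhat(chains: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = az.rhat(az.convert_to_dataset(chains))["x"].values
    return {n: float(r[i]) for i, n in enumerate(names)}


def posterior_predictive(
    samples: PosteriorSamples,
    conditions: pd.DataFrame,
    n_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictive median and interquartile range of RFU per condition.

    Mixture conditions are predicted from the same posterior as pure ones;
    when the posterior was trained on pure rows only this realizes the
    train-on-singles / predict-mixtures protocol.
    """
    model = samples.model
    unknown = set(conditions["receptor"]) - set(model.receptors)
    unknown |= (set(conditions["subclass1"]) | set(conditions["subclass2"])) - set(model.ligands)
    if unknown:
        raise KeyError(f"unknown labels in conditions: {unknown}")
    flat = samples.flat
    rng = np.random.default_rng(seed)
    idx = (
        rng.choice(len(flat), size=n_draws, replace=False)
        if n_draws < len(flat)
        else np.arange(len(flat))
    )
    preds = np.stack([model.predict_rfu(conditions, flat[i]) for i in idx])
    out = conditions.copy().reset_index(drop=True)
    out["pred_median"] = np.median(preds, axis=0)
    out["pred_q25"] = np.percentile(preds, 25, axis=0)
    out["pred_q75"] = np.percentile(preds, 75, axis=0)
    return out


def validate_with_fixed_affinities(
    table: pd.DataFrame,
    affinity_set: pd.DataFrame,
    priors: PriorSet,
    config: FitConfig,
) -> dict:
    """Fit non-affinity parameters under a fully specified affinity set.

    Used to score competing affinity sets (documented vs refined) on an
    external dataset: affinities are pinned to ``affinity_set`` (columns
    ``ligand``, ``receptor``, ``ka``), the remaining parameters are
    sampled, and concordance is the Pearson correlation between log
    predictive medians and log measurements.
    """
    fixed = {
        (str(r.ligand), str(r.receptor)): float(r.ka)
        for r in affinity_set.itertuples(index=False)
    }
    missing = set(priors.affinity) - set(fixed)
    if missing:
        raise ValueError(f"affinity_set must cover all modeled pairs; missing {missing}")
    cfg = replace(config, regime="fit_nonaffinity")
    samples = sample_posterior(table, priors, cfg, fixed_ka=fixed)
    pred = posterior_predictive(samples, table, seed=cfg.seed)
    log_p = np.log(pred["pred_median"].to_numpy())
    log_m = np.log(table["rfu"].to_numpy(float))
    r = float(np.corrcoef(log_p, log_m)[0, 1])
    rmse = float(np.sqrt(np.mean((log_p - log_m) ** 2)))
    map_lp = samples.model.log_posterior(samples.map_theta)
    return {
        "samples": samples,
        "concordance_r": r,
        "log_rmse": rmse,
        "map_log_posterior": float(map_lp),
        "predictions": pred,
    }
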