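"""Synthetic binding screens, expression replicates, and depletion studies.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes, so every stage is testable end to end
without external downloads.  Each generated dataset is parameterized by an
explicit :class:`GroundTruth` that is returned (and serializable) alongside
it, supporting parameter-recovery tests.

The default ground truth mirrors the study system: six CHO lines each
expressing one human FcγR variant, immune complexes of human IgG1-4
assembled at nominal valencies 4 and 33 and 1 nM concentration, a full
factorial over the six subclass pairs and a six-level composition series,
3 technical replicates with ~20% multiplicative noise, measurements spread
over 3 assay days, raw fluorescence in the low-thousands before each day is
normalized to geometric mean 1.  Default affinities are documented
literature-scale association constants (with non-binder clipping), so
synthetic screens reproduce the qualitative signatures of real ones:
binding tracks affinity, the high-valency arm always binds at least as
much, and the intervalency ratio anti-correlates with affinity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fcmix.binding import (
    DEFAULT_KX_STAR,
    AffinityMatrix,
    ComplexMixture,
    ReceptorPool,
    solve_equilibrium,
)
from fcmix.depletion import DepletionConfig, ReceptorWeights, compute_activities, predict_depletion
from fcmix.priors import KA_IQR_CLIP, KA_MODE_CLIP

__all__ = [
    "SUBCLASSES",
    "CHO_RECEPTORS",
    "EFFECTOR_RECEPTORS",
    "COMPOSITION_SERIES",
    "GroundTruth",
    "documented_affinity_table",
    "default_truth",
    "default_cell_profiles",
    "default_cell_weights",
    "generate_design",
    "simulate_binding_screen",
    "simulate_expression_replicates",
    "simulate_depletion_study",
    "normalize_per_day",
]

SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")
CHO_RECEPTORS = (
    "FcgRI",
    "FcgRIIA-131H",
    "FcgRIIA-131R",
    "FcgRIIB-232I",
    "FcgRIIIA-158F",
    "FcgRIIIA-158V",
)
#: Receptor subset displayed on the modeled effector cell types.
EFFECTOR_RECEPTORS = ("FcgRI", "FcgRIIA-131H", "FcgRIIB-232I", "FcgRIIIA-158F")

#: Composition fractions of the first pair member, pure endpoints included.
COMPOSITION_SERIES = (1.0, 0.9, 2.0 / 3.0, 1.0 / 3.0, 0.1, 0.0)

# Documented monovalent association constants (M^-1) of human IgG subclasses
# for FcγR variants, with standard errors; 0 marks reported non-binders.
_DOCUMENTED_KA: dict[str, dict[str, float]] = {
    "FcgRI": {"IgG1": 6.5e7, "IgG2": 0.0, "IgG3": 6.1e7, "IgG4": 3.4e7},
    "FcgRIIA-131H": {"IgG1": 5.2e6, "IgG2": 4.5e5, "IgG3": 8.9e5, "IgG4": 1.7e5},
    "FcgRIIA-131R": {"IgG1": 3.5e6, "IgG2": 1.0e5, "IgG3": 9.1e5, "IgG4": 2.1e5},
    "FcgRIIB-232I": {"IgG1": 1.2e5, "IgG2": 2.0e4, "IgG3": 1.7e5, "IgG4": 2.0e5},
    "FcgRIIIA-158F": {"IgG1": 1.2e6, "IgG2": 7.0e4, "IgG3": 7.7e6, "IgG4": 2.0e5},
    "FcgRIIIA-158V": {"IgG1": 2.0e6, "IgG2": 3.2e5, "IgG3": 9.8e6, "IgG4": 2.5e5},
}

# True receptor display of the synthetic CHO lines (receptors/cell).
_CHO_EXPRESSION = {
    "FcgRI": 4.0e5,
    "FcgRIIA-131H": 6.0e5,
    "FcgRIIA-131R": 5.0e5,
    "FcgRIIB-232I": 3.0e5,
    "FcgRIIIA-158F": 2.0e5,
    "FcgRIIIA-158V": 2.5e5,
}

# Synthetic effector-cell receptor profiles (receptors/cell, geometric-mean
# scale): classical monocytes, non-classical monocytes, neutrophils.  Each
# type is dominated by a different receptor (cMO: FcγRI, ncMO: FcγRIIIA,
# Neu: FcγRIIA) so its clearance weight is identifiable from the treatment
# panel rather than confounded with the others.
_EFFECTOR_PROFILES = {
    "cMO": {"FcgRI": 8.0e3, "FcgRIIA-131H": 1.0e4, "FcgRIIB-232I": 5.0e3, "FcgRIIIA-158F": 1.0e3},
    "ncMO": {"FcgRI": 3.0e2, "FcgRIIA-131H": 5.0e3, "FcgRIIB-232I": 5.0e3, "FcgRIIIA-158F": 1.2e5},
    "Neu": {"FcgRI": 1.0e2, "FcgRIIA-131H": 2.0e5, "FcgRIIB-232I": 1.0e3, "FcgRIIIA-158F": 5.0e2},
}

# True cell-type clearance weights for the synthetic depletion study:
# classical monocytes dominant, then non-classical, then neutrophils.
_TRUE_CELL_WEIGHTS = {"cMO": 2.0e-4, "ncMO": 5.0e-5, "Neu": 1.0e-5}


def documented_affinity_table(clip: bool = False) -> pd.DataFrame:
    """Documented affinities with standard errors, tidy long format.

    Standard errors default to 15% of the documented value; reported
    non-binders carry zero affinity and error.  With ``clip=True`` the
    non-binder floors (mode 1e4 M^-1, IQR 1e5 M^-1) are applied in place.
    """
    rows = []
    for rec in CHO_RECEPTORS:
        for sub in SUBCLASSES:
            ka = _DOCUMENTED_KA[rec][sub]
            se = 0.15 * ka
            if clip:
                ka, se = max(ka, KA_MODE_CLIP), max(se, KA_IQR_CLIP)
            rows.append({"ligand": sub, "receptor": rec, "ka": ka, "ka_se": se})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters recorded alongside every synthetic dataset."""

    affinities: AffinityMatrix
    expression: dict[str, float]
    f4: float = 4.0
    f33: float = 33.0
    kx_star: float = DEFAULT_KX_STAR
    l0: float = 1e-9
    batch_scales: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 0.2
    seed: int = 0

    def to_manifest(self) -> dict:
        """JSON-serializable record of the generating parameters."""
        return {
            "ligands": list(self.affinities.ligand_ids),
            "receptors": list(self.affinities.receptor_ids),
            "ka": self.affinities.ka.tolist(),
            "expression": dict(self.expression),
            "f4": self.f4,
            "f33": self.f33,
            "kx_star": self.kx_star,
            "l0": self.l0,
            "batch_scales": dict(self.batch_scales),
            "noise_cv": self.noise_cv,
            "seed": self.seed,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=2)


def default_truth(seed: int = 0, noise_cv: float = 0.2, n_days: int = 3) -> GroundTruth:
    """Default synthetic ground truth for the factorial CHO screen.

    Affinities are the documented values after non-binder clipping (so
    every interaction is estimable); per-day raw-fluorescence scales are
    log-normal around 0.5 RFU per bound complex, which puts raw signals in
    the low-thousands for typical bound-complex amounts.
    """
    doc = documented_affinity_table(clip=True)
    ka = doc.pivot(index="ligand", columns="receptor", values="ka")
    ka = ka.loc[list(SUBCLASSES), list(CHO_RECEPTORS)]
    rng = np.random.default_rng(seed)
    scales = {
        f"day{d + 1}": float(0.5 * np.exp(rng.normal(0.0, 0.2))) for d in range(n_days)
    }
    return GroundTruth(
        affinities=AffinityMatrix(SUBCLASSES, CHO_RECEPTORS, ka.to_numpy()),
        expression=dict(_CHO_EXPRESSION),
        batch_scales=scales,
        noise_cv=noise_cv,
        seed=seed,
    )


def default_cell_profiles() -> dict[str, ReceptorPool]:
    """Synthetic effector-cell receptor pools in :data:`EFFECTOR_RECEPTORS` order."""
    return {
        cell: ReceptorPool(cell, np.array([prof[r] for r in EFFECTOR_RECEPTORS]))
        for cell, prof in _EFFECTOR_PROFILES.items()
    }


def default_cell_weights() -> dict[str, float]:
    """True cell-type weights of the synthetic depletion study."""
    return dict(_TRUE_CELL_WEIGHTS)


def generate_design(
    receptors: tuple[str, ...] = CHO_RECEPTORS,
    subclasses: tuple[str, ...] = SUBCLASSES,
    valencies: tuple[float, float] = (4.0, 33.0),
    composition_series: tuple[float, ...] = COMPOSITION_SERIES,
) -> pd.DataFrame:
    """Full factorial design: receptors x valencies x subclass pairs x compositions.

    Subclass pairs are the unordered pairs of distinct subclasses; pure
    endpoints are counted per pair (not deduplicated), giving
    6 x 2 x 6 x 6 = 432 rows for the defaults.
    """
    pairs = [
        (subclasses[i], subclasses[j])
        for i in range(len(subclasses))
        for j in range(i + 1, len(subclasses))
    ]
    rows = [
        {"receptor": rec, "valency": val, "subclass1": s1, "subclass2": s2, "frac1": frac}
        for rec in receptors
        for val in valencies
        for (s1, s2) in pairs
        for frac in composition_series
    ]
    return pd.DataFrame(rows)


def normalize_per_day(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each day's RFU by that day's geometric mean (making it 1.0)."""
    out = table.copy()
    gm = out.groupby("day")["rfu"].transform(lambda v: np.exp(np.mean(np.log(v))))
    out["rfu"] = out["rfu"] / gm
    return out


def _noiseless_lbound(truth: GroundTruth, design: pd.DataFrame) -> np.ndarray:
    """Model-predicted bound complexes for every design row."""
    aff = truth.affinities
    out = np.empty(len(design))
    cache: dict[tuple, float] = {}
    for i, row in enumerate(design.itertuples(index=False)):
        key = (row.receptor, row.valency, row.subclass1, row.subclass2, round(row.frac1, 12))
        if key not in cache:
            ri = aff.receptor_ids.index(row.receptor)
            if row.subclass1 == row.subclass2:
                li = aff.ligand_ids.index(row.subclass1)
                sub = AffinityMatrix((row.subclass1,), (row.receptor,), aff.ka[[li]][:, [ri]])
                comp = np.array([1.0])
            else:
                li1 = aff.ligand_ids.index(row.subclass1)
                li2 = aff.ligand_ids.index(row.subclass2)
                sub = AffinityMatrix(
                    (row.subclass1, row.subclass2),
                    (row.receptor,),
                    aff.ka[[li1, li2]][:, [ri]],
                )
                comp = np.array([row.frac1, 1.0 - row.frac1])
            f = truth.f33 if row.valency == 33.0 else truth.f4
            mixture = ComplexMixture(l0=truth.l0, f=f, composition=comp, kx_star=truth.kx_star)
            pool = ReceptorPool(row.receptor, np.array([truth.expression[row.receptor]]))
            cache[key] = solve_equilibrium(pool, mixture, sub).lbound
        out[i] = cache[key]
    return out


def simulate_binding_screen(
    truth: GroundTruth,
    design: pd.DataFrame | None = None,
    replicates: int = 3,
    noise_cv: float | None = None,
    seed: int | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Forward-simulated measurement table for a design.

    Conditions are assigned to assay days at random (fixed by the seed),
    each condition receives ``replicates`` technical replicates with raw
    signal ``batch_scale * Lbound * exp(eps)``, ``eps ~ N(0, sigma)`` with
    ``sigma = sqrt(log(1 + cv^2))``, and each day is geometric-mean
    normalized to 1.0 unless ``normalize=False``.
    """
    design = design if design is not None else generate_design()
    noise_cv = truth.noise_cv if noise_cv is None else noise_cv
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    days = list(truth.batch_scales) or ["day1"]
    scales = truth.batch_scales or {"day1": 1.0}
    day_of_condition = rng.choice(days, size=len(design))
    lbound = _noiseless_lbound(truth, design)

    sigma = math.sqrt(math.log1p(noise_cv**2))
    rows = []
    for i, row in enumerate(design.itertuples(index=False)):
        day = day_of_condition[i]
        for rep in range(replicates):
            eps = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append(
                {
                    "day": day,
                    "receptor": row.receptor,
                    "valency": row.valency,
                    "subclass1": row.subclass1,
                    "subclass2": row.subclass2,
                    "frac1": row.frac1,
                    "replicate": rep + 1,
                    "rfu": scales[day] * lbound[i] * math.exp(eps),
                }
            )
    table = pd.DataFrame(rows)
    return normalize_per_day(table) if normalize else table


def simulate_expression_replicates(
    truth: GroundTruth, n: int = 4, seed: int | None = None, log_sd: float = 0.1
) -> pd.DataFrame:
    """Log-normal abundance replicates around the true per-line expression."""
    if n < 2:
        raise ValueError("need at least 2 replicates per line")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    rows = [
        {"receptor": rec, "replicate": rep + 1, "rtot": float(rt * np.exp(rng.normal(0, log_sd)))}
        for rec, rt in truth.expression.items()
        for rep in range(n)
    ]
    return pd.DataFrame(rows)


def simulate_depletion_study(
    truth_weights: dict[str, float],
    profiles: dict[str, ReceptorPool] | None = None,
    affinities: AffinityMatrix | None = None,
    subclasses: tuple[str, ...] = SUBCLASSES,
    n_mice: int = 6,
    noise: float = 40.0,
    seed: int = 0,
    config: DepletionConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse depletion records around the link-model prediction.

    Observed fractions are beta-distributed with mean ``ŷ`` and
    concentration ``noise``; larger ``noise`` concentrates mice around the
    model prediction (the default emulates sizable donor-to-donor spread).
    Returns (records, per-treatment truth table with activities and ŷ).
    """
    if any(w < 0 for w in truth_weights.values()):
        raise ValueError("cell weights must be nonnegative")
    profiles = profiles or default_cell_profiles()
    if affinities is None:
        truth = default_truth()
        affinities = truth.affinities.select(list(subclasses), list(EFFECTOR_RECEPTORS))
    signs = ReceptorWeights.from_inhibitory(affinities.receptor_ids)
    config = config or DepletionConfig()
    activity = compute_activities(profiles, affinities, signs, subclasses, config)
    piv = activity.pivot(index="treatment", columns="cell", values="activity")
    cells = list(truth_weights)
    w = np.array([truth_weights[c] for c in cells])

    rng = np.random.default_rng(seed)
    records, truth_rows = [], []
    for tr in subclasses:
        x = piv.loc[tr, cells].to_numpy(float)
        yhat = predict_depletion(x, w)
        mu = min(max(yhat, 1e-4), 1.0 - 1e-4)
        ys = rng.beta(mu * noise, (1.0 - mu) * noise, size=n_mice)
        for m, y in enumerate(ys):
            records.append({"treatment": tr, "experiment": f"mouse{m + 1}", "y": float(y)})
        truth_rows.append({"treatment": tr, "yhat": yhat, **dict(zip(cells, x))})
    return pd.DataFrame(records), pd.DataFrame(truth_rows)
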