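"""Closed-form equilibrium model of multivalent immune-complex binding.

An immune complex (IC) carries ``f`` IgG Fc units drawn at random from a
mixture of ``NL`` monomer species (e.g. IgG subclasses), with species ``i``
present at proportion ``C_i``.  The complex binds a cell displaying ``NR``
Fcγ-receptor types with monovalent association constants ``Ka[i, j]``
(M^-1); every bond after the first forms with constant ``Kx* · Ka[i, j]``,
where the crosslinking constant ``Kx*`` converts solution affinity into the
propensity of an already-tethered complex to engage further receptors.

Writing ``phi[i, j] = Req_j · Ka[i, j] · Kx* · C_i`` (dimensionless) for the
bound slots and ``phi[i, 0] = C_i`` for the unbound slot, the relative
abundance of a binding configuration ``q`` (a table of per-(species,
receptor) bond counts plus unbound counts, summing to ``f``) is multinomial:

    v_q = multinom(f; q) · (L0 / Kx*) · prod(phi ** q)

Summing this distribution in closed form gives the macroscopic observables

    Lbound    = (L0 / Kx*) · (Φ^f − 1)
    Rbound_n  = (L0 · f / Kx*) · φ_n · Φ^(f−1)
    Rmulti_n  = (L0 · f / Kx*) · φ_n · (Φ^(f−1) − 1)

with ``Φ = Σ_{i,j} phi[i, j]`` and ``φ_n = Σ_i phi[i, n]``.  ``Rmulti_n`` —
receptor ``n`` engaged by complexes holding at least two bonds — is the
model's proxy for activation-competent, crosslinked receptor.

Free receptor ``Req`` is fixed by conservation of mass,
``Rtot_n = Req_n + Rbound_n(Req)``; :func:`solve_equilibrium` reduces this
NR-dimensional system to a single scalar root in ``Φ`` (see the function's
notes) and solves it with Brent's method.

:func:`enumerate_configurations` provides an exhaustive integer-valency
enumeration of the configuration distribution, used as an independent oracle
against the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DEFAULT_KX_STAR",
    "AffinityMatrix",
    "ComplexMixture",
    "ReceptorPool",
    "PhiMatrix",
    "EquilibriumState",
    "Configuration",
    "compute_phi",
    "lbound_closed_form",
    "rbound_closed_form",
    "rmulti_closed_form",
    "solve_equilibrium",
    "enumerate_configurations",
    "oracle_macroscopics",
    "solve_lbound_1r",
    "solve_rmulti_1l",
]

#: Default crosslinking constant (printed unit "cell·M"), treated as an
#: opaque scale; absolute units cancel into the fitted batch scale.
DEFAULT_KX_STAR = 6.31e-13

_ENUM_GUARD = 1_000_000


@dataclass(frozen=True)
class AffinityMatrix:
    """Monovalent association constants Ka (M^-1) per (Fc species, receptor)."""

    ligand_ids: tuple[str, ...]
    receptor_ids: tuple[str, ...]
    ka: np.ndarray

    def __post_init__(self) -> None:
        ka = np.asarray(self.ka, dtype=float)
        object.__setattr__(self, "ka", ka)
        object.__setattr__(self, "ligand_ids", tuple(self.ligand_ids))
        object.__setattr__(self, "receptor_ids", tuple(self.receptor_ids))
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise ValueError("duplicate ligand labels")
        if len(set(self.receptor_ids)) != len(self.receptor_ids):
            raise ValueError("duplicate receptor labels")
        if ka.shape != (len(self.ligand_ids), len(self.receptor_ids)):
            raise ValueError(
                f"ka shape {ka.shape} inconsistent with "
                f"{len(self.ligand_ids)} ligands x {len(self.receptor_ids)} receptors"
            )
        if ka.size == 0:
            raise ValueError("affinity matrix must be non-empty")
        if not np.all(np.isfinite(ka)) or np.any(ka < 0):
            raise ValueError("affinities must be finite and nonnegative")

    @property
    def n_ligands(self) -> int:
        return len(self.ligand_ids)

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_ids)

    def select(self, ligands: Sequence[str], receptors: Sequence[str]) -> "AffinityMatrix":
        """Submatrix for the given label subsets (order preserved)."""
        li = [self.ligand_ids.index(l) for l in ligands]
        ri = [self.receptor_ids.index(r) for r in receptors]
        return AffinityMatrix(tuple(ligands), tuple(receptors), self.ka[np.ix_(li, ri)])


@dataclass(frozen=True)
class ComplexMixture:
    """An immune-complex preparation.

    Parameters
    ----------
    l0
        Molar concentration of complexes.
    f
        Effective valency (positive real; non-integer values arise from the
        fitted effective-valency parameters).
    composition
        Length-NL simplex of monomer proportions ``C_i``.
    kx_star
        Crosslinking constant (unit "cell·M", opaque scale).
    """

    l0: float
    f: float
    composition: np.ndarray
    kx_star: float = DEFAULT_KX_STAR

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        object.__setattr__(self, "composition", comp)
        if self.l0 < 0:
            raise ValueError("l0 must be nonnegative")
        if not self.f > 0:
            raise ValueError("valency f must be positive")
        if not self.kx_star > 0:
            raise ValueError("kx_star must be positive")
        if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-12:
            raise ValueError("composition must be a simplex summing to 1")


@dataclass(frozen=True)
class ReceptorPool:
    """Total receptor display of one cell type (receptors/cell)."""

    cell_label: str
    rtot: np.ndarray

    def __post_init__(self) -> None:
        rtot = np.asarray(self.rtot, dtype=float)
        object.__setattr__(self, "rtot", rtot)
        if np.any(rtot < 0):
            raise ValueError("receptor abundances must be nonnegative")


@dataclass(frozen=True)
class PhiMatrix:
    """Dimensionless per-slot binding propensities; column 0 is the unbound slot."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        if phi.ndim != 2 or phi.shape[1] < 1:
            raise ValueError("phi must be NL x (NR + 1)")
        if np.any(phi < 0):
            raise ValueError("phi entries must be nonnegative")

    @property
    def total(self) -> float:
        """Φ, the sum over every slot including unbound."""
        return float(self.phi.sum())

    def receptor_sum(self, n: int) -> float:
        """φ_n = Σ_i phi[i, n+1] for receptor index ``n`` (0-based)."""
        nr = self.phi.shape[1] - 1
        if not 0 <= n < nr:
            raise IndexError(f"receptor index {n} outside 0..{nr - 1}")
        return float(self.phi[:, n + 1].sum())


@dataclass(frozen=True)
class EquilibriumState:
    """Solved per-cell state at binding equilibrium."""

    req: np.ndarray
    rbound: np.ndarray
    lbound: float
    rmulti: np.ndarray


@dataclass(frozen=True)
class Configuration:
    """One integer binding configuration and its equilibrium weight."""

    q: tuple[int, ...]  # flattened NL x (NR+1), slot 0 of each row unbound
    weight: float

    def bonds(self, n_ligands: int) -> int:
        """Total receptor bonds (excludes unbound slots)."""
        q = np.asarray(self.q).reshape(n_ligands, -1)
        return int(q[:, 1:].sum())

    def receptor_bonds(self, n_ligands: int, n: int) -> int:
        """Bonds to receptor ``n`` (0-based) summed over ligand species."""
        q = np.asarray(self.q).reshape(n_ligands, -1)
        return int(q[:, n + 1].sum())


def compute_phi(
    req: np.ndarray,
    affinities: AffinityMatrix,
    kx_star: float,
    composition: np.ndarray,
) -> PhiMatrix:
    """Binding propensity matrix at given free-receptor levels.

    ``phi[i, j+1] = req[j] * Ka[i, j] * kx_star * C[i]`` and
    ``phi[i, 0] = C[i]``.
    """
    req = np.asarray(req, dtype=float)
    comp = np.asarray(composition, dtype=float)
    if req.shape != (affinities.n_receptors,):
        raise ValueError("req length must equal the number of receptors")
    if comp.shape != (affinities.n_ligands,):
        raise ValueError("composition length must equal the number of ligands")
    if np.any(req < 0) or np.any(comp < 0) or kx_star < 0:
        raise ValueError("inputs must be nonnegative")
    phi = np.empty((affinities.n_ligands, affinities.n_receptors + 1))
    phi[:, 0] = comp
    phi[:, 1:] = req[None, :] * affinities.ka * kx_star * comp[:, None]
    return PhiMatrix(phi)


def lbound_closed_form(phi: PhiMatrix, l0: float, f: float, kx_star: float) -> float:
    """Bound complexes: ``(L0/Kx*) · (Φ^f − 1)``.

    Continuous in real-valued ``f``; zero when no slot has affinity (Φ = 1).
    """
    if not kx_star > 0:
        raise ValueError("kx_star must be positive")
    return l0 / kx_star * (phi.total**f - 1.0)


def rbound_closed_form(
    phi: PhiMatrix, l0: float, f: float, kx_star: float, n: int
) -> float:
    """Bound receptor ``n``: ``(L0·f/Kx*) · φ_n · Φ^(f−1)``."""
    if not kx_star > 0:
        raise ValueError("kx_star must be positive")
    return l0 * f / kx_star * phi.receptor_sum(n) * phi.total ** (f - 1.0)


def rmulti_closed_form(
    phi: PhiMatrix, l0: float, f: float, kx_star: float, n: int
) -> float:
    """Multimerized receptor ``n``: ``(L0·f/Kx*) · φ_n · (Φ^(f−1) − 1)``.

    Receptor engaged by complexes with two or more bonds, i.e. ``rbound``
    minus the receptors held in singly bound complexes; identically zero at
    ``f = 1``.
    """
    if not kx_star > 0:
        raise ValueError("kx_star must be positive")
    return l0 * f / kx_star * phi.receptor_sum(n) * (phi.total ** (f - 1.0) - 1.0)


def _phi_from_s(
    pool: ReceptorPool, mixture: ComplexMixture, affinities: AffinityMatrix, s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Free receptors and per-receptor coupling ``a_j`` implied by Φ = s."""
    a = mixture.kx_star * (mixture.composition @ affinities.ka)  # length NR
    c = mixture.l0 * mixture.f / mixture.kx_star
    req = pool.rtot / (1.0 + c * a * s ** (mixture.f - 1.0))
    return req, a


def solve_equilibrium(
    pool: ReceptorPool, mixture: ComplexMixture, affinities: AffinityMatrix
) -> EquilibriumState:
    """Solve the mass-balance ``Rtot = Req + Rbound(Req)`` for all receptors.

    Notes
    -----
    With ``a_j = Kx* Σ_i C_i Ka[i, j]`` the slot sum is
    ``Φ = 1 + Σ_j a_j Req_j`` and the mass balance is separable given Φ:
    ``Req_j = Rtot_j / (1 + (L0 f / Kx*) a_j Φ^(f−1))``.  Substituting back
    gives one scalar equation ``h(Φ) = Φ − 1 − Σ_j a_j Req_j(Φ) = 0`` whose
    right-hand side is strictly decreasing in Φ, so the root on
    ``[1, 1 + Σ a_j Rtot_j]`` is unique and bracketed; Brent's method finds
    it to near machine precision.  This avoids the poor conditioning of a
    direct NR-dimensional solve over free-receptor counts spanning decades.
    """
    rtot = pool.rtot
    if rtot.shape != (affinities.n_receptors,):
        raise ValueError("pool size inconsistent with affinity matrix")
    if mixture.composition.shape != (affinities.n_ligands,):
        raise ValueError("mixture composition inconsistent with affinity matrix")

    nr = affinities.n_receptors
    if mixture.l0 == 0.0:
        return EquilibriumState(rtot.copy(), np.zeros(nr), 0.0, np.zeros(nr))

    a = mixture.kx_star * (mixture.composition @ affinities.ka)
    hi = 1.0 + float(a @ rtot)
    if hi == 1.0:  # no binding possible
        return EquilibriumState(rtot.copy(), np.zeros(nr), 0.0, np.zeros(nr))

    def h(s: float) -> float:
        req, _ = _phi_from_s(pool, mixture, affinities, s)
        return s - 1.0 - float(a @ req)

    try:
        s = optimize.brentq(h, 1.0, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError) as err:  # pragma: no cover - defensive
        raise RuntimeError(
            f"equilibrium solve failed on [1, {hi:g}]: {err}; residual at "
            f"bracket ends {h(1.0):g}, {h(hi):g}"
        ) from err

    req, _ = _phi_from_s(pool, mixture, affinities, s)
    phi = compute_phi(req, affinities, mixture.kx_star, mixture.composition)
    rbound = np.array(
        [rbound_closed_form(phi, mixture.l0, mixture.f, mixture.kx_star, n) for n in range(nr)]
    )
    rmulti = np.array(
        [rmulti_closed_form(phi, mixture.l0, mixture.f, mixture.kx_star, n) for n in range(nr)]
    )
    lb = lbound_closed_form(phi, mixture.l0, mixture.f, mixture.kx_star)

    resid = np.abs(req + rbound - rtot)
    scale = np.maximum(rtot, 1.0)
    if np.any(resid / scale > 1e-8):
        raise RuntimeError(
            f"equilibrium solver did not converge: max relative residual "
            f"{np.max(resid / scale):.3e}"
        )
    return EquilibriumState(req, rbound, lb, rmulti)


def _compositions(total: int, cells: int) -> Iterator[tuple[int, ...]]:
    """Weak compositions of ``total`` into ``cells`` nonnegative parts."""
    if cells == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, cells - 1):
            yield (first,) + rest


def enumerate_configurations(
    f_int: int, phi: PhiMatrix, l0: float, kx_star: float
) -> list[Configuration]:
    """Exhaustive configuration distribution for integer valency.

    Every nonnegative integer table ``q`` over the NL x (NR+1) slots with
    ``Σ q = f`` receives weight ``multinom(f; q) (L0/Kx*) Π phi^q``.  Used
    as an independent oracle for the closed-form macroscopic quantities;
    guarded against combinatorial blow-up.
    """
    if f_int < 1 or f_int != int(f_int):
        raise ValueError("valency must be a positive integer for enumeration")
    nl, nr1 = phi.phi.shape
    n_cells = nl * nr1
    n_conf = math.comb(f_int + n_cells - 1, n_cells - 1)
    if n_conf > _ENUM_GUARD:
        raise ValueError(f"{n_conf} configurations exceeds enumeration guard")
    flat_phi = phi.phi.ravel()
    f_fact = math.factorial(f_int)
    out = []
    for q in _compositions(f_int, n_cells):
        coef = f_fact
        for qi in q:
            coef //= math.factorial(qi)
        w = coef * (l0 / kx_star) * float(np.prod(flat_phi**np.asarray(q)))
        out.append(Configuration(q, w))
    return out


def oracle_macroscopics(
    f_int: int, phi: PhiMatrix, l0: float, kx_star: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """(lbound, rbound, rmulti) summed from the exhaustive enumeration."""
    nl, nr1 = phi.phi.shape
    nr = nr1 - 1
    confs = enumerate_configurations(f_int, phi, l0, kx_star)
    lb = 0.0
    rb = np.zeros(nr)
    rm = np.zeros(nr)
    for conf in confs:
        b = conf.bonds(nl)
        if b >= 1:
            lb += conf.weight
        for n in range(nr):
            qn = conf.receptor_bonds(nl, n)
            rb[n] += qn * conf.weight
            if b >= 2:
                rm[n] += qn * conf.weight
    return lb, rb, rm


def solve_lbound_1r(
    rtot: np.ndarray,
    ka_eff: np.ndarray,
    l0: np.ndarray,
    f: np.ndarray,
    kx_star: np.ndarray,
    n_iter: int = 90,
) -> np.ndarray:
    """Vectorized bound-complex prediction for single-receptor cells.

    Each element describes one condition: a cell line displaying one
    receptor type at ``rtot`` copies, exposed to complexes of valency ``f``
    at concentration ``l0`` whose composition-weighted affinity is
    ``ka_eff = Σ_i C_i Ka[i]``.  The scalar slot-sum equation (see
    :func:`solve_equilibrium`) is solved by bisection, which is branch-free
    and vectorizes across conditions; 90 halvings brings the bracket below
    machine epsilon relative width.
    """
    rtot, ka_eff, l0, f, kx_star = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (rtot, ka_eff, l0, f, kx_star))
    )
    a = kx_star * ka_eff
    c = l0 * f / kx_star
    lo = np.ones_like(a)
    hi = 1.0 + a * rtot
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        req = rtot / (1.0 + c * a * mid ** (f - 1.0))
        h = mid - 1.0 - a * req
        take_hi = h > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    s = 0.5 * (lo + hi)
    return l0 / kx_star * (s**f - 1.0)


def solve_rmulti_1l(
    pool: ReceptorPool, affinities: AffinityMatrix, ligand: str, l0: float, f: float,
    kx_star: float = DEFAULT_KX_STAR,
) -> np.ndarray:
    """Per-receptor multimerization for a pure single-ligand complex.

    Convenience wrapper used by the effector-cell activity calculation.
    """
    li = affinities.ligand_ids.index(ligand)
    sub = AffinityMatrix((ligand,), affinities.receptor_ids, affinities.ka[li : li + 1, :])
    mixture = ComplexMixture(l0=l0, f=f, composition=np.array([1.0]), kx_star=kx_star)
    return solve_equilibrium(pool, mixture, sub).rmulti
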