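"""Descriptive analyses of binding screens.

PCA variance explained is defined through reconstruction error in the
Frobenius norm, ``1 − ‖X − X̂_k‖²_F / ‖X‖²_F`` for the rank-k
reconstruction of the (column-centered) condition matrix.  The ANOVA
variance partition is the classical one-way between-condition fraction of
total sum of squares.  Intervalency ratios compare median binding of the
high- and low-valency arms of the same condition, and Spearman correlations
are tested with the t-statistic under the null of zero rank correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "condition_matrix",
    "pca_variance_explained",
    "pca_scores_loadings",
    "anova_between_fraction",
    "intervalency_ratio",
    "spearman_test",
]


def condition_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Median binding per condition (rows) by receptor (columns).

    A condition is a (valency, subclass pair, composition) cell of the
    design; the matrix must be complete and strictly positive.
    """
    piv = table.pivot_table(
        index=["valency", "subclass1", "subclass2", "frac1"],
        columns="receptor",
        values="rfu",
        aggfunc="median",
    )
    if piv.isna().any().any():
        missing = int(piv.isna().sum().sum())
        raise ValueError(f"condition matrix incomplete: {missing} missing cells")
    if (piv.to_numpy() <= 0).any():
        raise ValueError("condition medians must be positive")
    return piv


def _center(x: np.ndarray, center: bool) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True) if center else x


def pca_variance_explained(matrix: np.ndarray, k: int, center: bool = True) -> float:
    """Fraction of Frobenius variance captured by a rank-k reconstruction.

    Equals the cumulative squared-singular-value fraction of the centered
    matrix; nondecreasing in k and exactly 1.0 at full rank.
    """
    x = np.asarray(matrix, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    if not 0 <= k <= min(x.shape):
        raise ValueError(f"k must be in 0..{min(x.shape)}")
    xc = _center(x, center)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    xk = (u[:, :k] * s[:k]) @ vt[:k]
    denom = float(np.sum(xc * xc))
    if denom == 0.0:
        return 1.0
    return 1.0 - float(np.sum((xc - xk) ** 2)) / denom


def pca_scores_loadings(
    matrix: pd.DataFrame, k: int = 2, center: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Scores, loadings and per-component variance fractions."""
    x = matrix.to_numpy(dtype=float)
    xc = _center(x, center)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((u[:, :k] * s[:k]), index=matrix.index, columns=cols)
    loadings = pd.DataFrame(vt[:k].T, index=matrix.columns, columns=cols)
    return scores, loadings, frac[:k]


def anova_between_fraction(table: pd.DataFrame, condition_cols: list[str] | None = None) -> float:
    """Between-condition sum of squares over total sum of squares.

    One-way layout over condition labels; 1.0 when replicates agree exactly
    within every condition, defined as 0 for a totally constant table.
    """
    condition_cols = condition_cols or ["receptor", "valency", "subclass1", "subclass2", "frac1"]
    y = table["rfu"].to_numpy(float)
    if len(y) < 2:
        raise ValueError("need at least two measurements")
    groups = table.groupby(condition_cols, sort=False)["rfu"]
    if groups.ngroups < 2 and len(y) == groups.ngroups:
        raise ValueError("a single condition with a single replicate has no partition")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0.0:
        return 0.0
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups))
    return ss_between / ss_total


def intervalency_ratio(
    table: pd.DataFrame, valencies: tuple[float, float] = (4.0, 33.0)
) -> pd.DataFrame:
    """High- over low-valency median binding per (receptor, subclass).

    Pure compositions only.  Low-affinity interactions gain more from
    avidity, so under the binding model this ratio anti-correlates with the
    interaction affinity.
    """
    lo, hi = valencies
    pure = table[np.isclose(table["frac1"], 1.0) | np.isclose(table["frac1"], 0.0)].copy()
    pure["subclass"] = np.where(
        np.isclose(pure["frac1"], 1.0), pure["subclass1"], pure["subclass2"]
    )
    med = pure.groupby(["receptor", "subclass", "valency"], sort=False)["rfu"].median()
    rows = []
    for (rec, sub), grp in med.groupby(level=["receptor", "subclass"], sort=False):
        vals = grp.droplevel(["receptor", "subclass"])
        if lo not in vals.index or hi not in vals.index:
            raise ValueError(f"missing valency arm for ({rec}, {sub})")
        rows.append({"receptor": rec, "subclass": sub, "ratio": vals[hi] / vals[lo]})
    return pd.DataFrame(rows)


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value from the t approximation.

    ``t = rho * sqrt((n − 2) / (1 − rho²))`` with n − 2 degrees of freedom;
    ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, p
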