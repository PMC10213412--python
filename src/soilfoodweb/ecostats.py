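"""Statistical procedures linking soil properties, communities and C fluxes.

One-way ANOVA with Tukey HSD compact letter displays, Spearman rank
correlation matrices, adjusted-R2 variance partitioning between two
explanatory tables, and permutation-based fitting of environmental
vectors onto ordination coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD compact letters
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    p: float
    means: dict = field(default_factory=dict)
    letters: dict = field(default_factory=dict)
    tukey_p: pd.DataFrame | None = None


def compact_letters(
    groups: list, significant: set[frozenset]
) -> dict:
    """Compact letter display by insert-and-absorb.

    ``significant`` holds the pairs judged different.  Two groups share a
    letter iff their pair is not in ``significant``.  Letters are assigned
    walking ``groups`` in the given order, so the first group gets 'a'.
    """
    # Start with one letter set covering everything; split on each
    # significant pair, then drop sets contained in another (absorption).
    sets: list[set] = [set(groups)]
    for pair in significant:
        g1, g2 = tuple(pair)
        for s in list(sets):
            if g1 in s and g2 in s:
                sets.remove(s)
                sets.append(s - {g1})
                sets.append(s - {g2})
        # absorb duplicates/subsets
        sets = [
            s
            for i, s in enumerate(sets)
            if s and not any(s < t or (s == t and i > j)
                             for j, t in enumerate(sets) if i != j)
        ]
    # Order letter sets by first appearance in `groups`
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for k, s in enumerate(sets):
        for g in groups:
            if g in s:
                letters[g] += alphabet[k % len(alphabet)]
    return letters


def anova_tukey_letters(
    values, labels, alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc compact letter display.

    Groups sharing no letter differ at level ``alpha`` by the studentized
    range test; letters walk groups in order of first appearance.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(labels)
    if y.shape != g.shape:
        raise ValueError("values and labels must be the same length")
    names = list(pd.unique(g))
    samples = [y[g == name] for name in names]
    if len(names) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 observations each")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")

    F, p = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pmat = pd.DataFrame(hsd.pvalue, index=names, columns=names)

    means = {name: float(np.mean(s)) for name, s in zip(names, samples)}
    significant = {
        frozenset((a, b))
        for i, a in enumerate(names)
        for b in names[i + 1:]
        if pmat.at[a, b] < alpha
    }
    letters = compact_letters(names, significant)
    return AnovaResult(float(F), float(p), means, letters, pmat)


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

def spearman_matrix(
    X: pd.DataFrame, Y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p between every X and Y column.

    Missing values are handled pairwise; ties take average ranks and p
    comes from the t approximation on n-2 df (approximate below n ~ 10).
    Constant columns give NaN with a warning.
    """
    rho = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    pval = rho.copy()
    for xc in X.columns:
        for yc in Y.columns:
            pair = pd.concat([X[xc], Y[yc]], axis=1).dropna()
            if len(pair) < 4:
                raise ValueError(
                    f"fewer than 4 paired observations for ({xc}, {yc})"
                )
            a, b = pair.iloc[:, 0], pair.iloc[:, 1]
            if a.nunique() < 2 or b.nunique() < 2:
                warnings.warn(
                    f"constant variable in pair ({xc}, {yc}); rho undefined"
                )
                continue
            r, p = sps.spearmanr(a, b)
            rho.at[xc, yc] = r
            pval.at[xc, yc] = p
    return rho, pval


def bh_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of a p-value matrix (NaNs kept)."""
    flat = p.to_numpy(dtype=float).ravel()
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = sps.false_discovery_control(flat[ok], method="bh")
    return pd.DataFrame(
        adj.reshape(p.shape), index=p.index, columns=p.columns
    )


# ---------------------------------------------------------------------------
# Variance partitioning (adjusted-R2, two predictor tables)
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    """Adjusted-R2 variance partition of Y between X1 and X2.

    Fractions: ``a`` unique to X1, ``c`` unique to X2, ``b`` shared,
    ``d`` residual; a+b+c+d = 1.  ``r2``/``adj_r2`` hold the redundancy
    statistics for X1, X2 and the combined model.
    """

    a: float
    b: float
    c: float
    d: float
    r2: dict = field(default_factory=dict)
    adj_r2: dict = field(default_factory=dict)


def _as_matrix(T) -> np.ndarray:
    arr = np.asarray(T, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _redundancy_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Fraction of total variance of column-centred Y explained by X.

    Returns ``(R2, rank)`` where rank is the number of independent
    predictor dimensions (degrees of freedom for the adjustment; aliased
    columns do not inflate it, as in redundancy analysis).
    """
    n = Y.shape[0]
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    fitted = Xc @ beta
    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc**2).sum()
    ss_fit = ((fitted - fitted.mean(axis=0)) ** 2).sum()
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    return float(ss_fit / ss_tot), rank


def _adjusted(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1-R2)(n-1)/(n-m-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def variance_partition(Y, X1, X2) -> PartitionResult:
    """Partition the variation of Y between predictor tables X1 and X2.

    Unconstrained-redundancy R2 on column-centred Y, adjusted by the
    Ezekiel formula with rank-based degrees of freedom; negative adjusted
    fractions are reported as-is.  A set that is internally collinear
    (rank below its column count) is rejected naming the columns;
    redundancy *between* the two sets is legitimate and shows up in the
    shared fraction b.
    """
    Ym, X1m, X2m = _as_matrix(Y), _as_matrix(X1), _as_matrix(X2)
    n = Ym.shape[0]
    if not (X1m.shape[0] == n and X2m.shape[0] == n):
        raise ValueError("Y, X1, X2 must have equal row counts")
    m1, m2 = X1m.shape[1], X2m.shape[1]
    if n <= m1 + m2 + 1:
        raise ValueError("need n > total predictors + 1")
    for tag, T, arr, m in (("X1", X1, X1m, m1), ("X2", X2, X2m, m2)):
        if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < m:
            cols = _collinear_columns(tag, T, arr)
            raise ValueError(
                f"predictor set {tag} rank-deficient (collinear columns): "
                f"{cols}"
            )
    Xb = np.column_stack([X1m, X2m])

    r2_1, rk1 = _redundancy_r2(Ym, X1m)
    r2_2, rk2 = _redundancy_r2(Ym, X2m)
    r2_b, rkb = _redundancy_r2(Ym, Xb)
    a1 = _adjusted(r2_1, n, rk1)
    a2 = _adjusted(r2_2, n, rk2)
    ab = _adjusted(r2_b, n, rkb)
    a = ab - a2
    c = ab - a1
    b = a1 + a2 - ab
    d = 1.0 - ab
    return PartitionResult(
        a, b, c, d,
        r2={"X1": r2_1, "X2": r2_2, "X1X2": r2_b},
        adj_r2={"X1": a1, "X2": a2, "X1X2": ab},
    )


def _collinear_columns(tag: str, T, arr: np.ndarray) -> list:
    """Name columns involved in a within-set rank deficiency (via QR)."""
    names = (
        list(T.columns)
        if isinstance(T, pd.DataFrame)
        else [f"{tag}[{j}]" for j in range(arr.shape[1])]
    )
    X = np.column_stack([np.ones(arr.shape[0]), arr - arr.mean(axis=0)])
    _, Rm = np.linalg.qr(X)
    diag = np.abs(np.diag(Rm))
    tol = diag.max() * 1e-10 if diag.size else 0.0
    bad = [i - 1 for i in np.where(diag <= tol)[0] if i >= 1]
    return [names[i] for i in bad] or names


# ---------------------------------------------------------------------------
# envfit: permutation test of environmental vectors on ordination scores
# ---------------------------------------------------------------------------

def envfit_permutation(
    scores: pd.DataFrame,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each variable onto ordination axes; permutation significance.

    For each variable, r2 is the squared multiple correlation from
    least-squares regression of the variable on the axis scores; p is
    (1 + #{permuted r2 >= observed}) / (n_perm + 1), permuting the
    variable's rows.  Constant variables give NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    S = np.asarray(scores, dtype=float)
    if S.shape[0] != variables.shape[0]:
        raise ValueError("scores and variables must be row-aligned")
    n = S.shape[0]
    X = np.column_stack([np.ones(n), S])
    # Hat matrix of the axis regression; r2 of y is then a quadratic form.
    H = X @ np.linalg.pinv(X)
    rng = np.random.default_rng(seed)

    out = {}
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.ptp(y[np.isfinite(y)]) == 0:
            warnings.warn(f"constant variable {name!r}; r2 undefined")
            out[name] = (np.nan, np.nan)
            continue

        def r2_of(v: np.ndarray) -> float:
            vc = v - v.mean()
            fit = H @ v
            fitc = fit - fit.mean()
            return float((fitc @ fitc) / (vc @ vc))

        obs = r2_of(y)
        perms = np.array(
            [r2_of(rng.permutation(y)) for _ in range(n_perm)]
        )
        p = (1 + np.sum(perms >= obs)) / (n_perm + 1)
        out[name] = (obs, p)
    return pd.DataFrame(out, index=["r2", "p"]).T
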