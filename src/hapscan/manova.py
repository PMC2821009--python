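"""One-way MANOVA for genotype classes: Wilk's lambda and partial Wilk's tests.

For a branch of the haplotype tree, individuals fall into genotype classes
(AA/AB/BB) and the adjusted phenotypes form the response matrix Y. The joint
association is measured by Wilk's lambda

    Lambda = det(E) / det(E + H),

with E and H the within- and between-class sums-of-squares-and-cross-products
matrices. The unique contribution of one phenotype y_g in the presence of the
others is the partial (conditional) Wilk's statistic, the ratio of the
full-model lambda to the lambda of the reduced model that drops y_g:

    Lambda(y_g | others) = Lambda_p / Lambda_{p-1},

which has an exact transformation to a partial F statistic with degrees of
freedom (v_H, v_E - p + 1), where v_H = k - 1, v_E = N - k:

    F = ((1 - Lambda) / Lambda) * ((v_E - p + 1) / v_H).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Condition-number guard for the determinant computations; beyond this the
#: within-class SSCP is treated as numerically singular and reported.
CONDITION_LIMIT = 1e12


@dataclass
class ManovaStats:
    """Full one-way MANOVA summary for one branch/genotype factor."""

    p: int
    N: int
    k: int
    v_E: int
    v_H: int
    E: np.ndarray
    H: np.ndarray
    lambda_full: float
    F: float
    df: tuple[float, float]
    p_value: float
    phenotypes: tuple[str, ...]
    lambda_reduced: dict[str, float] = field(default_factory=dict)
    partial_lambda: dict[str, float] = field(default_factory=dict)
    partial_F: dict[str, float] = field(default_factory=dict)
    partial_p: dict[str, float] = field(default_factory=dict)
    univariate_F: dict[str, float] = field(default_factory=dict)
    univariate_p: dict[str, float] = field(default_factory=dict)


def _sscp(Y: np.ndarray, classes: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Within (E) and between (H) SSCP matrices for a one-way layout."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    classes = np.asarray(classes)
    levels, inv = np.unique(classes, return_inverse=True)
    k = len(levels)
    n, p = Y.shape
    if k < 2:
        raise ValueError("need at least 2 factor levels")
    if n <= k:
        raise ValueError(f"need n > k (got n={n}, k={k})")
    grand = Y.mean(axis=0)
    Yc = Y - grand
    T = Yc.T @ Yc
    H = np.zeros((p, p))
    for j in range(k):
        grp = Y[inv == j]
        d = grp.mean(axis=0) - grand
        H += len(grp) * np.outer(d, d)
    E = T - H
    return E, H, k


def _safe_det_ratio(E: np.ndarray, H: np.ndarray) -> float:
    """det(E)/det(E+H) via triangular factorization, with conditioning guard."""
    EH = E + H
    if np.linalg.cond(EH) > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            "within+between SSCP numerically singular (degenerate phenotypes); "
            f"condition number exceeds {CONDITION_LIMIT:.0e}"
        )
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(EH)
    if sign_e <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "SSCP determinant non-positive (degenerate phenotypes)"
        )
    return float(np.exp(logdet_e - logdet_t))


def wilks_lambda(
    Y: np.ndarray, classes: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Wilk's Lambda = det(E)/det(E+H) with its E and H matrices."""
    E, H, _ = _sscp(Y, classes)
    return _safe_det_ratio(E, H), E, H


def wilks_full_model_p(
    lambda_: float, p: int, v_H: int, v_E: int
) -> tuple[float, tuple[float, float], float]:
    """Rao's F approximation for Wilk's Lambda (exact when p <= 2 or v_H <= 2).

    Returns (F, (df1, df2), p_value).
    """
    if v_E < p:
        raise ValueError(f"insufficient error df: v_E={v_E} < p={p}")
    denom = p * p + v_H * v_H - 5
    t = np.sqrt((p * p * v_H * v_H - 4) / denom) if denom > 0 else 1.0
    w = v_E + v_H - (p + v_H + 1) / 2.0
    df1 = p * v_H
    df2 = w * t - (p * v_H - 2) / 2.0
    if df2 <= 0:
        raise ValueError(f"insufficient df for Rao's F (df2={df2:.2f})")
    lam_t = lambda_ ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    p_value = float(stats.f.sf(F, df1, df2)) if F > 0 else 1.0
    return float(F), (float(df1), float(df2)), p_value


def partial_wilks(Y: np.ndarray, classes: np.ndarray, g: int) -> float:
    """Partial Wilk's statistic for phenotype column g: Lambda_p / Lambda_{p-1}."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("partial Wilk's needs at least two phenotypes")
    lam_full, _, _ = wilks_lambda(Y, classes)
    reduced = np.delete(Y, g, axis=1)
    lam_red, _, _ = wilks_lambda(reduced, classes)
    return float(lam_full / lam_red)


def partial_F(
    lambda_partial: float, p: int, v_H: int, v_E: int
) -> tuple[float, tuple[int, int], float]:
    """Exact partial-F transform of the conditional Wilk's statistic."""
    df2 = v_E - p + 1
    if df2 < 1:
        raise ValueError(f"nonpositive partial-F df: v_E - p + 1 = {df2}")
    if not (0 < lambda_partial <= 1):
        raise ValueError(f"partial lambda must be in (0, 1], got {lambda_partial}")
    F = (1.0 - lambda_partial) / lambda_partial * df2 / v_H
    p_value = float(stats.f.sf(F, v_H, df2)) if F > 0 else 1.0
    return float(F), (v_H, df2), p_value


def univariate_followups(
    Y: np.ndarray, classes: np.ndarray, names: tuple[str, ...] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-phenotype one-way ANOVA F and parametric p; constant columns skipped."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    names = names or tuple(f"y{j}" for j in range(Y.shape[1]))
    out = {}
    for j, name in enumerate(names):
        y = Y[:, j]
        if np.ptp(y) == 0:
            import warnings

            warnings.warn(f"phenotype {name!r} is constant; excluded from follow-ups")
            continue
        E, H, k = _sscp(y, classes)
        ssw, ssb = float(E[0, 0]), float(H[0, 0])
        dfb, dfw = k - 1, len(y) - k
        if ssw == 0:
            F = 0.0 if ssb == 0 else np.inf
        else:
            F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw)) if np.isfinite(F) else 0.0
        out[name] = (float(F), p)
    return out


def manova_summary(
    Y: np.ndarray,
    classes: np.ndarray,
    phenotypes: tuple[str, ...] | None = None,
) -> ManovaStats:
    """Full model test plus per-phenotype partial Wilk's and univariate F tests."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    phenotypes = tuple(phenotypes) if phenotypes else tuple(f"y{j}" for j in range(p))
    lam, E, H = wilks_lambda(Y, classes)
    k = len(np.unique(classes))
    v_E, v_H = n - k, k - 1
    F, dfs, p_value = wilks_full_model_p(lam, p, v_H, v_E)
    res = ManovaStats(
        p=p, N=n, k=k, v_E=v_E, v_H=v_H, E=E, H=H,
        lambda_full=lam, F=F, df=dfs, p_value=p_value, phenotypes=phenotypes,
    )
    if p >= 2 and v_E - p + 1 >= 1:
        for g, name in enumerate(phenotypes):
            lam_red, _, _ = wilks_lambda(np.delete(Y, g, axis=1), classes)
            lam_part = lam / lam_red
            Fg, _, pg = partial_F(min(lam_part, 1.0), p, v_H, v_E)
            res.lambda_reduced[name] = float(lam_red)
            res.partial_lambda[name] = float(lam_part)
            res.partial_F[name] = Fg
            res.partial_p[name] = pg
    for name, (Fu, pu) in univariate_followups(Y, classes, phenotypes).items():
        res.univariate_F[name] = Fu
        res.univariate_p[name] = pu
    return res
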