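"""Branch-by-branch genotype/phenotype association scanning.

Every branch of the loop-resolved haplotype network bipartitions the
haplotypes; an individual's two haplotypes then place it in one of three
genotype classes (AA/AB/BB = 0/1/2 copies of the derived-side allele). After
the phenotypes are adjusted for covariates by ordinary least squares, each
testable branch (all retained genotype classes holding at least
``min_class_count`` individuals, and at least two such classes) is tested by a
one-way ANOVA F whose significance comes from permutations of phenotype rows.
A single permutation stream is shared across branches so that the step-down
max-T correction (the permutation analog of sequential step-down Bonferroni)
respects the correlation between branch tests. The multivariate variant uses
the Rao-F transform of Wilk's lambda as the branch statistic, permuting whole
phenotype vectors.

The second-round conditional scan re-tests every branch with the first-round
branch's genotype held as a blocking factor: permutations are restricted to
within-stratum shuffles and the statistic is the partial F for the target
branch after the conditioning factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manova import ManovaStats, manova_summary
from .network import BranchPartition
from ._util import rng_for

CLASS_LABELS = {0: "AA", 1: "AB", 2: "BB"}


@dataclass
class ScanConfig:
    phenotypes: tuple[str, ...]
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    min_class_count: int = 5
    n_permutations: int = 10_000
    seed: int = 0
    multivariate: bool = True
    alpha: float = 0.05

    def __post_init__(self):
        if not self.phenotypes:
            raise ValueError("at least one phenotype is required")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.phenotypes = tuple(self.phenotypes)
        self.covariates = tuple(self.covariates)


@dataclass
class GenotypeClassing:
    """Genotype classes for one branch over the analysed individuals."""

    branch_id: str
    copies: np.ndarray  # 0/1/2 derived-allele copies for every individual
    class_counts: dict[str, int]  # all classes, before filtering
    included_classes: tuple[str, ...]
    mask: np.ndarray  # rows entering this branch's test
    classes: np.ndarray  # 0..k-1 codes for the masked rows

    @property
    def testable(self) -> bool:
        return len(self.included_classes) >= 2

    @property
    def k(self) -> int:
        return len(self.included_classes)


@dataclass
class ScanResult:
    table: pd.DataFrame  # branch x phenotype univariate results
    multivariate: pd.DataFrame | None
    manova: dict[str, ManovaStats]
    dropped: list[tuple[str, str]]
    classings: dict[str, GenotypeClassing]
    config: ScanConfig

    def top_branch(self, multivariate: bool | None = None) -> str:
        """Branch with the largest observed statistic (smallest corrected p)."""
        use_mv = self.multivariate is not None if multivariate is None else multivariate
        if use_mv:
            t = self.multivariate
            return t.loc[t["F"].idxmax(), "branch"]
        t = self.table
        return t.loc[t["F"].idxmax(), "branch"]


def adjust_phenotypes(
    df: pd.DataFrame,
    phenotypes: tuple[str, ...],
    covariates: tuple[str, ...],
) -> pd.DataFrame:
    """Replace each phenotype by its OLS residual on the covariates + intercept.

    Constant covariates carry no information beyond the intercept and are
    dropped (covariates-all-constant therefore mean-centers the phenotypes);
    genuinely collinear covariate sets are rejected.
    """
    cols = [
        df[c].to_numpy(dtype=float)
        for c in covariates
        if np.ptp(df[c].to_numpy(dtype=float)) > 0
    ]
    X = np.column_stack([np.ones(len(df))] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear covariate matrix: rank {rank} < {X.shape[1]} "
            f"(covariates {covariates})"
        )
    Y = df.loc[:, list(phenotypes)].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = df.copy()
    out.loc[:, list(phenotypes)] = resid
    return out


def genotype_classes(
    diplotypes: pd.DataFrame,
    partition: BranchPartition,
    min_count: int = 5,
) -> GenotypeClassing:
    """Class individuals by derived-allele copies; drop small classes."""
    known = partition.side_a | partition.side_b
    for col in ("hap_a", "hap_b"):
        unknown = set(diplotypes[col]) - known
        if unknown:
            raise ValueError(
                f"diplotype haplotypes {sorted(unknown)} missing from the partition"
            )
    a = diplotypes["hap_a"].isin(partition.side_b).to_numpy(dtype=int)
    b = diplotypes["hap_b"].isin(partition.side_b).to_numpy(dtype=int)
    copies = a + b
    counts = {CLASS_LABELS[c]: int((copies == c).sum()) for c in (0, 1, 2)}
    included = tuple(
        CLASS_LABELS[c] for c in (0, 1, 2) if counts[CLASS_LABELS[c]] >= min_count
    )
    inc_codes = [c for c in (0, 1, 2) if CLASS_LABELS[c] in included]
    mask = np.isin(copies, inc_codes)
    remap = {c: i for i, c in enumerate(inc_codes)}
    classes = np.array([remap[c] for c in copies[mask]], dtype=int)
    return GenotypeClassing(
        branch_id=partition.branch_id,
        copies=copies,
        class_counts=counts,
        included_classes=included,
        mask=mask,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# vectorized permutation statistics


def _group_indicator(classes: np.ndarray, k: int) -> np.ndarray:
    G = np.zeros((len(classes), k))
    G[np.arange(len(classes)), classes] = 1.0
    return G


def _anova_f_many(Yp: np.ndarray, G: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each row of Yp (C, n_b) given indicator G (n_b, k)."""
    n_b, k = G.shape
    S = Yp @ G  # (C, k) group sums
    tot = Yp.sum(axis=1)
    correction = tot * tot / n_b
    ssb = (S * S / counts).sum(axis=1) - correction
    sst = (Yp * Yp).sum(axis=1) - correction
    ssw = sst - ssb
    dfb, dfw = k - 1, n_b - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw <= 1e-300, np.where(ssb <= 1e-300, 0.0, np.inf), F)
    return F


def _wilks_f_many(Yp: np.ndarray, G: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Rao-F of Wilk's lambda for each permutation slab Yp (C, n_b, p)."""
    C, n_b, p = Yp.shape
    k = G.shape[1]
    S = np.einsum("cnp,nk->ckp", Yp, G)
    tot = Yp.sum(axis=1)  # (C, p)
    outer_tot = np.einsum("cp,cq->cpq", tot, tot) / n_b
    H = np.einsum("ckp,ckq,k->cpq", S, S, 1.0 / counts) - outer_tot
    T = np.einsum("cnp,cnq->cpq", Yp, Yp) - outer_tot
    E = T - H
    det_e = np.linalg.det(E)
    det_t = np.linalg.det(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = det_e / det_t
    lam = np.clip(lam, 1e-300, 1.0)
    v_E, v_H = n_b - k, k - 1
    denom = p * p + v_H * v_H - 5
    t = np.sqrt((p * p * v_H * v_H - 4) / denom) if denom > 0 else 1.0
    w = v_E + v_H - (p + v_H + 1) / 2.0
    df1 = p * v_H
    df2 = w * t - (p * v_H - 2) / 2.0
    lam_t = lam ** (1.0 / t)
    return (1.0 - lam_t) / lam_t * df2 / df1


def step_down_maxt(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down max-T corrected p-values.

    ``obs``: observed statistics per branch (larger = more extreme);
    ``perm``: (B, n_branch) statistics from the shared permutation stream.
    Corrected p of the branch ranked r uses, per permutation, the maximum
    statistic over branches ranked r..last; monotonicity is enforced down the
    sorted list.
    """
    obs = np.asarray(obs, dtype=float)
    order = np.argsort(-obs, kind="stable")
    perm_ord = perm[:, order]
    suffix_max = np.maximum.accumulate(perm_ord[:, ::-1], axis=1)[:, ::-1]
    B = perm.shape[0]
    counts = (suffix_max >= obs[order][None, :]).sum(axis=0)
    p_sorted = (1.0 + counts) / (1.0 + B)
    p_sorted = np.maximum.accumulate(p_sorted)
    out = np.empty_like(p_sorted)
    out[order] = p_sorted
    return out


def _permutation_chunks(
    rng: np.random.Generator, n: int, B: int, chunk: int = 250
):
    """Yield (C, n) row-permutation index arrays totalling B permutations."""
    base = np.arange(n)
    done = 0
    while done < B:
        C = min(chunk, B - done)
        idx = rng.permuted(np.tile(base, (C, 1)), axis=1)
        yield idx
        done += C


def univariate_branch_test(
    y: np.ndarray,
    classing: GenotypeClassing,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way permutation ANOVA for a single branch and phenotype.

    Returns (F, nominal p) with the add-one permutation estimator
    (1 + #{F_perm >= F_obs}) / (1 + B).
    """
    if not classing.testable:
        raise ValueError(f"branch {classing.branch_id} is untestable (<2 classes)")
    y = np.asarray(y, dtype=float)
    G = _group_indicator(classing.classes, classing.k)
    counts = G.sum(axis=0)
    obs = float(_anova_f_many(y[classing.mask][None, :], G, counts)[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for idx in _permutation_chunks(rng, len(y), n_perm):
        Yp = y[idx][:, classing.mask]
        exceed += int((_anova_f_many(Yp, G, counts) >= obs).sum())
    return obs, (1.0 + exceed) / (1.0 + n_perm)


def scan(
    partitions: list[BranchPartition],
    cohort: pd.DataFrame,
    config: ScanConfig,
    adjusted: bool = False,
) -> ScanResult:
    """Scan every branch against the (covariate-adjusted) phenotypes.

    ``cohort`` must carry hap_a/hap_b plus the phenotype and covariate
    columns. Rows with any missing phenotype or covariate are dropped before
    adjustment. Returns per-branch univariate results, and when
    ``config.multivariate`` also a Wilk's-lambda branch table with full MANOVA
    summaries (partial Wilk's tests included) per testable branch.
    """
    needed = list(config.phenotypes) + [
        c for c in config.covariates if c in cohort.columns
    ]
    data = cohort.dropna(subset=needed).reset_index(drop=True)
    if not adjusted:
        covs = tuple(c for c in config.covariates if c in data.columns)
        if covs:
            data = adjust_phenotypes(data, config.phenotypes, covs)
    Z = data.loc[:, list(config.phenotypes)].to_numpy(dtype=float)
    n = len(data)

    classings: dict[str, GenotypeClassing] = {}
    dropped: list[tuple[str, str]] = []
    testable: list[tuple[BranchPartition, GenotypeClassing]] = []
    for part in partitions:
        cl = genotype_classes(data, part, config.min_class_count)
        classings[part.branch_id] = cl
        if cl.testable:
            testable.append((part, cl))
        else:
            dropped.append(
                (part.branch_id, f"<2 classes with count >= {config.min_class_count}")
            )
    if not testable:
        raise ValueError("no testable branches")

    nb = len(testable)
    nph = len(config.phenotypes)
    B = config.n_permutations

    Gs, counts_list = [], []
    for _, cl in testable:
        G = _group_indicator(cl.classes, cl.k)
        Gs.append(G)
        counts_list.append(G.sum(axis=0))

    obs_uni = np.zeros((nb, nph))
    obs_mv = np.zeros(nb)
    for i, (part, cl) in enumerate(testable):
        Zi = Z[cl.mask]
        for j in range(nph):
            obs_uni[i, j] = _anova_f_many(Zi[:, j][None, :], Gs[i], counts_list[i])[0]
        if config.multivariate:
            obs_mv[i] = _wilks_f_many(Zi[None, :, :], Gs[i], counts_list[i])[0]

    perm_uni = np.zeros((B, nb, nph))
    perm_mv = np.zeros((B, nb)) if config.multivariate else None
    rng = np.random.default_rng(config.seed)
    row = 0
    for idx in _permutation_chunks(rng, n, B):
        C = idx.shape[0]
        Zp = Z[idx]  # (C, n, nph) whole phenotype vectors move together
        for i, (_, cl) in enumerate(testable):
            slab = Zp[:, cl.mask, :]
            for j in range(nph):
                perm_uni[row : row + C, i, j] = _anova_f_many(
                    slab[:, :, j], Gs[i], counts_list[i]
                )
            if config.multivariate:
                perm_mv[row : row + C, i] = _wilks_f_many(
                    slab, Gs[i], counts_list[i]
                )
        row += C

    rows = []
    for j, ph in enumerate(config.phenotypes):
        p_nom = (1.0 + (perm_uni[:, :, j] >= obs_uni[:, j][None, :]).sum(axis=0)) / (
            1.0 + B
        )
        p_corr = step_down_maxt(obs_uni[:, j], perm_uni[:, :, j])
        for i, (part, cl) in enumerate(testable):
            rows.append(
                {
                    "branch": part.branch_id,
                    "label": part.label,
                    "phenotype": ph,
                    "k": cl.k,
                    "n": int(cl.mask.sum()),
                    "class_counts": "/".join(
                        str(cl.class_counts[c]) for c in cl.included_classes
                    ),
                    "F": obs_uni[i, j],
                    "p_nominal": p_nom[i],
                    "p_corrected": p_corr[i],
                }
            )
    table = pd.DataFrame(rows)

    mv_table = None
    manova: dict[str, ManovaStats] = {}
    if config.multivariate:
        p_nom_mv = (1.0 + (perm_mv >= obs_mv[None, :]).sum(axis=0)) / (1.0 + B)
        p_corr_mv = step_down_maxt(obs_mv, perm_mv)
        mv_rows = []
        for i, (part, cl) in enumerate(testable):
            try:
                ms = manova_summary(
                    Z[cl.mask], cl.classes, phenotypes=config.phenotypes
                )
                manova[part.branch_id] = ms
                lam, p_param = ms.lambda_full, ms.p_value
            except (ValueError, np.linalg.LinAlgError) as exc:
                warnings.warn(f"MANOVA failed for {part.branch_id}: {exc}")
                lam, p_param = np.nan, np.nan
            mv_rows.append(
                {
                    "branch": part.branch_id,
                    "label": part.label,
                    "k": cl.k,
                    "n": int(cl.mask.sum()),
                    "wilks_lambda": lam,
                    "F": obs_mv[i],
                    "p_parametric": p_param,
                    "p_nominal": p_nom_mv[i],
                    "p_corrected": p_corr_mv[i],
                }
            )
        mv_table = pd.DataFrame(mv_rows)

    return ScanResult(
        table=table,
        multivariate=mv_table,
        manova=manova,
        dropped=dropped,
        classings=classings,
        config=config,
    )


# ---------------------------------------------------------------------------
# second-round conditional scan


def _partial_f_projected(
    Yp: np.ndarray, Q_red: np.ndarray, Q_full: np.ndarray, df1: int, df_res: int
) -> np.ndarray:
    """Partial F for adding the branch factor, per permutation row of Yp."""
    yy = (Yp * Yp).sum(axis=1)
    rss_red = yy - ((Yp @ Q_red) ** 2).sum(axis=1)
    rss_full = yy - ((Yp @ Q_full) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df1) / (rss_full / df_res)
    return np.where(rss_full <= 1e-300, 0.0, np.maximum(F, 0.0))


def _orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    return U[:, :rank]


def conditional_scan(
    partitions: list[BranchPartition],
    cohort: pd.DataFrame,
    config: ScanConfig,
    condition_branch: str,
    phenotype: str | None = None,
) -> ScanResult:
    """Re-scan with the conditioning branch's genotype as a blocking factor.

    Individuals outside the conditioning branch's retained classes are
    excluded; permutations shuffle phenotype rows only within conditioning
    strata; the branch statistic is the partial F of the branch factor in the
    additive two-factor layout. Strata contributing fewer than two branch
    classes simply add no information to that branch's F.
    """
    phenos = (phenotype,) if phenotype else config.phenotypes
    needed = list(phenos) + [c for c in config.covariates if c in cohort.columns]
    data = cohort.dropna(subset=needed).reset_index(drop=True)
    covs = tuple(c for c in config.covariates if c in data.columns)
    if covs:
        data = adjust_phenotypes(data, phenos, covs)

    by_id = {p.branch_id: p for p in partitions}
    if condition_branch not in by_id:
        raise KeyError(f"unknown conditioning branch {condition_branch!r}")
    cond = genotype_classes(data, by_id[condition_branch], config.min_class_count)
    if not cond.testable:
        raise ValueError(f"conditioning branch {condition_branch} is untestable")

    data = data.loc[cond.mask].reset_index(drop=True)
    strata = cond.classes
    Z = data.loc[:, list(phenos)].to_numpy(dtype=float)
    n = len(data)
    S = _group_indicator(strata, cond.k)

    prepared = []
    dropped: list[tuple[str, str]] = []
    classings: dict[str, GenotypeClassing] = {}
    for part in partitions:
        cl = genotype_classes(data, part, config.min_class_count)
        classings[part.branch_id] = cl
        if not cl.testable:
            dropped.append(
                (part.branch_id, f"<2 classes with count >= {config.min_class_count}")
            )
            continue
        mask = cl.mask
        Gb = _group_indicator(cl.classes, cl.k)
        X_red = S[mask]
        X_full = np.hstack([X_red, Gb])
        Q_red = _orth_basis(X_red)
        Q_full = _orth_basis(X_full)
        df1 = Q_full.shape[1] - Q_red.shape[1]
        df_res = int(mask.sum()) - Q_full.shape[1]
        if df_res < 1:
            dropped.append((part.branch_id, "insufficient residual df"))
            continue
        prepared.append((part, cl, mask, Q_red, Q_full, df1, df_res))
    if not prepared:
        raise ValueError("no testable branches under conditioning")

    B = config.n_permutations
    nb = len(prepared)
    obs = np.zeros((nb, len(phenos)))
    for i, (_, _, mask, Q_red, Q_full, df1, df_res) in enumerate(prepared):
        for j in range(len(phenos)):
            if df1 == 0:
                obs[i, j] = 0.0
            else:
                obs[i, j] = _partial_f_projected(
                    Z[mask, j][None, :], Q_red, Q_full, df1, df_res
                )[0]

    # stratified permutation indices: shuffle positions within each stratum
    rng = np.random.default_rng(config.seed)
    stratum_pos = [np.where(strata == s)[0] for s in range(cond.k)]
    perm_stats = np.zeros((B, nb, len(phenos)))
    done = 0
    while done < B:
        C = min(250, B - done)
        idx = np.tile(np.arange(n), (C, 1))
        for pos in stratum_pos:
            idx[:, pos] = pos[rng.permuted(np.tile(np.arange(len(pos)), (C, 1)), axis=1)]
        Zp = Z[idx]  # (C, n, nph)
        for i, (_, _, mask, Q_red, Q_full, df1, df_res) in enumerate(prepared):
            for j in range(len(phenos)):
                if df1 == 0:
                    continue
                perm_stats[done : done + C, i, j] = _partial_f_projected(
                    Zp[:, mask, j], Q_red, Q_full, df1, df_res
                )
        done += C

    rows = []
    for j, ph in enumerate(phenos):
        p_nom = (1.0 + (perm_stats[:, :, j] >= obs[:, j][None, :]).sum(axis=0)) / (
            1.0 + B
        )
        p_corr = step_down_maxt(obs[:, j], perm_stats[:, :, j])
        for i, (part, cl, mask, *_rest) in enumerate(prepared):
            rows.append(
                {
                    "branch": part.branch_id,
                    "label": part.label,
                    "phenotype": ph,
                    "k": cl.k,
                    "n": int(mask.sum()),
                    "class_counts": "/".join(
                        str(cl.class_counts[c]) for c in cl.included_classes
                    ),
                    "F": obs[i, j],
                    "p_nominal": p_nom[i],
                    "p_corrected": p_corr[i],
                }
            )
    return ScanResult(
        table=pd.DataFrame(rows),
        multivariate=None,
        manova={},
        dropped=dropped,
        classings=classings,
        config=config,
    )
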