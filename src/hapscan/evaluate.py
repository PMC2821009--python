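"""Evaluating site-prediction criteria against "known" functional variants.

The packaged fixture annotates 27 missense variants of ANGPTL4 with: where
their carriers fell in the triglyceride distribution (or whether the variant
was scan-significant), the biological-assay outcome, the PolyPhen score and
prediction, and the radical-substitution category from the physicochemical
analysis. Eight variants count as "known" functional-or-significant (six
low-tail variants with assay-confirmed effects plus two scan-significant
common variants); the two high-tail variants that assayed as non-functional
are kept out of the 2x2 table and reported alongside; the remaining 17 form
the middle-or-not-significant column.

Each prediction criterion yields a 2x2 table (predicted-significant x known
status), a two-tailed Fisher exact p-value, the conditional maximum-likelihood
odds ratio with its exact tail-inversion confidence interval, and
sensitivity/specificity with their complements alpha and beta.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio

FUNCTIONAL_CLASSES = frozenset({"Low", "Significant"})
HIGH_TAIL = "High"
MIDDLE_CLASSES = frozenset({"Middle", "NonSig"})


@dataclass
class VariantAnnotation:
    """One fixture row: a missense variant with its predictions and status."""

    variant: str
    distribution: str  # High / Middle / Low / Significant / NonSig
    assay: str
    polyphen_score: float | None
    polyphen_prediction: str  # benign / possibly damaging / probably damaging
    treesaap_category: int  # 0 = unflagged, 6 = category 6-7, 8 = category 8

    @property
    def functional(self) -> bool:
        return self.distribution in FUNCTIONAL_CLASSES

    @property
    def high_tail(self) -> bool:
        return self.distribution == HIGH_TAIL


#: Predicates defining each significance criterion over a variant annotation.
CRITERIA = {
    "PolyPhen": lambda v: v.polyphen_prediction != "benign",
    "Strict PolyPhen": lambda v: v.polyphen_prediction == "probably damaging",
    "TreeSAAP": lambda v: v.treesaap_category >= 6,
    "Strict TreeSAAP": lambda v: v.treesaap_category == 8,
    "PolyPhen AND TreeSAAP": lambda v: v.polyphen_prediction != "benign"
    and v.treesaap_category >= 6,
    "Strict AND Strict": lambda v: v.polyphen_prediction == "probably damaging"
    and v.treesaap_category == 8,
    "Strict OR Strict": lambda v: v.polyphen_prediction == "probably damaging"
    or v.treesaap_category == 8,
}


@dataclass
class ContingencyTable:
    """2x2 counts plus the separately-reported high-tail variants."""

    a: int  # functional & predicted significant
    b: int  # middle/notsig & predicted significant
    c: int  # functional & predicted not significant
    d: int  # middle/notsig & predicted not significant
    high_tail_flagged: int
    high_tail_total: int

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class EvalResult:
    criterion: str
    counts: ContingencyTable
    fisher_p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float

    @property
    def alpha(self) -> float:
        return 1.0 - self.specificity

    @property
    def beta(self) -> float:
        return 1.0 - self.sensitivity


def load_annotations(path: str | None = None) -> list[VariantAnnotation]:
    """Load the packaged known-variant fixture, or a CSV with the same schema."""
    if path is None:
        with resources.files("hapscan.data").joinpath(
            "angptl4_known_variants.csv"
        ).open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        cat8 = isinstance(row.treesaap_cat8_properties, str) and row.treesaap_cat8_properties
        cat67 = isinstance(row.treesaap_cat67_properties, str) and row.treesaap_cat67_properties
        out.append(
            VariantAnnotation(
                variant=row.variant,
                distribution=row.distribution,
                assay=row.assay,
                polyphen_score=None if pd.isna(row.polyphen_score) else float(row.polyphen_score),
                polyphen_prediction=row.polyphen_prediction,
                treesaap_category=8 if cat8 else (6 if cat67 else 0),
            )
        )
    return out


def classify_variants(
    annotations: list[VariantAnnotation], criterion: str
) -> dict[str, bool]:
    """Apply one named criterion; returns per-variant predicted-significant flags."""
    if criterion not in CRITERIA:
        raise KeyError(
            f"unknown criterion {criterion!r}; known: {sorted(CRITERIA)}"
        )
    pred = CRITERIA[criterion]
    return {v.variant: bool(pred(v)) for v in annotations}


def build_2x2(
    flags: dict[str, bool], annotations: list[VariantAnnotation]
) -> ContingencyTable:
    """Cross the predicted flags with known status; high-tail rows set aside."""
    missing = {v.variant for v in annotations} - set(flags)
    if missing:
        raise ValueError(f"flags missing for variants {sorted(missing)}")
    a = b = c = d = ht_flag = ht_tot = 0
    for v in annotations:
        f = flags[v.variant]
        if v.high_tail:
            ht_tot += 1
            ht_flag += f
        elif v.functional:
            a += f
            c += not f
        else:
            b += f
            d += not f
    return ContingencyTable(a, b, c, d, ht_flag, ht_tot)


def fisher_exact_two_tailed(table: list[list[int]] | np.ndarray) -> float:
    """Two-tailed Fisher exact p (point-probability rule over fixed margins)."""
    table = np.asarray(table, dtype=int)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        import warnings

        warnings.warn("all-zero 2x2 table; p = 1")
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def conditional_odds_ratio(
    table: list[list[int]] | np.ndarray, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Conditional-MLE odds ratio with exact tail-inversion confidence interval.

    The estimate maximizes the noncentral hypergeometric likelihood of the
    table with margins fixed; it is the convention whose point estimates
    differ from the sample cross-product ratio. Degenerate margins (a zero
    row or column total) have no information about the odds ratio and raise.
    """
    table = np.asarray(table, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: odds ratio undefined")
    res = odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence)
    return float(res.statistic), (float(ci.low), float(ci.high))


def evaluate_criterion(
    annotations: list[VariantAnnotation], criterion: str
) -> EvalResult:
    flags = classify_variants(annotations, criterion)
    counts = build_2x2(flags, annotations)
    p = fisher_exact_two_tailed(counts.table)
    try:
        or_, (lo, hi) = conditional_odds_ratio(counts.table)
    except ValueError:
        or_, lo, hi = float("nan"), float("nan"), float("nan")
    n_func = counts.a + counts.c
    n_mid = counts.b + counts.d
    return EvalResult(
        criterion=criterion,
        counts=counts,
        fisher_p=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        sensitivity=counts.a / n_func if n_func else float("nan"),
        specificity=counts.d / n_mid if n_mid else float("nan"),
    )


def evaluate_all(
    annotations: list[VariantAnnotation] | None = None,
) -> pd.DataFrame:
    """All criteria evaluated against the known variants, one row per criterion."""
    annotations = annotations or load_annotations()
    rows = []
    for crit in CRITERIA:
        r = evaluate_criterion(annotations, crit)
        rows.append(
            {
                "criterion": crit,
                "func_sig": r.counts.a,
                "high_tail_sig": r.counts.high_tail_flagged,
                "mid_notsig_sig": r.counts.b,
                "func_notsig": r.counts.c,
                "mid_notsig_notsig": r.counts.d,
                "fisher_p": r.fisher_p,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "alpha": r.alpha,
                "beta": r.beta,
            }
        )
    return pd.DataFrame(rows)
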