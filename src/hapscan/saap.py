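"""Radical amino-acid substitution scoring on a haplotype tree.

Ancestral coding sequences are reconstructed by parsimony (Hartigan's
algorithm, exact also on multifurcating trees) and substitution events read
off each branch. For each physicochemical property, the magnitude of change
of every nonsynonymous event is binned into 8 equal-width categories spanning
the range of changes achievable by a single nucleotide substitution under the
standard genetic code. The observed category counts are compared with the
distribution expected under completely random single-nucleotide amino-acid
replacement by one-sided z-tests; events in significantly enriched categories
flag their amino-acid site, and categories 6-8 mark the substitution as
radical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Phylo.BaseTree import Clade, Tree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_CATEGORIES = 8
RADICAL_CATEGORIES = (6, 7, 8)


@dataclass
class SubstitutionEvent:
    branch_id: str
    codon_position: int  # 1-based amino-acid site
    from_aa: str
    to_aa: str
    synonymous: bool

    def __post_init__(self):
        if not self.synonymous and self.from_aa == self.to_aa:
            raise ValueError("nonsynonymous event with identical residues")


@dataclass
class PropertyCategoryResult:
    property: str
    category: int
    observed: int
    expected: float
    z: float | None
    significant: bool


@dataclass
class SiteFlag:
    site: int
    max_category: int
    properties: tuple[str, ...]
    radical: bool


@dataclass
class AminoAcidPropertyTable:
    """Named physicochemical scales, one numeric value per standard residue."""

    values: dict[str, dict[str, float]]

    @classmethod
    def packaged(cls) -> "AminoAcidPropertyTable":
        with resources.files("hapscan.data").joinpath("aa_properties.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AminoAcidPropertyTable":
        values: dict[str, dict[str, float]] = {}
        for prop, grp in df.groupby("property"):
            table = dict(zip(grp["amino_acid"], grp["value"].astype(float)))
            missing = set(AMINO_ACIDS) - set(table)
            if missing:
                raise ValueError(f"property {prop!r} missing residues {sorted(missing)}")
            if not all(np.isfinite(list(table.values()))):
                raise ValueError(f"property {prop!r} has non-finite values")
            values[prop] = table
        return cls(values)

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.values)


def property_change_magnitude(
    from_aa: str, to_aa: str, prop: dict[str, float]
) -> float:
    """|value(to) - value(from)|; symmetric; rejects nonstandard residues."""
    for aa in (from_aa, to_aa):
        if aa not in prop:
            raise KeyError(f"nonstandard residue {aa!r}")
    return abs(prop[to_aa] - prop[from_aa])


# ---------------------------------------------------------------------------
# ancestral reconstruction (Hartigan parsimony)


def reconstruct_ancestors(
    tree: Tree, tip_sequences: dict[str, str]
) -> dict[Clade, str]:
    """Minimum-mutation ancestral sequences for every node of a rooted tree.

    Hartigan's two-pass algorithm, per site. Tie-break on the downward pass:
    keep the parent's state when it is optimal, otherwise take the
    alphabetically first optimal state. Returns a mapping from every clade
    (tips included) to its sequence.
    """
    tips = tree.get_terminals()
    lengths = {len(tip_sequences[t.name]) for t in tips}
    if len(lengths) != 1:
        raise ValueError(f"tip sequences are not aligned: lengths {sorted(lengths)}")
    L = lengths.pop()

    postorder = list(tree.find_clades(order="postorder"))
    seqs: dict[Clade, list[str]] = {c: [] for c in postorder}

    for site in range(L):
        upper: dict[Clade, set[str]] = {}
        for clade in postorder:
            if clade.is_terminal():
                upper[clade] = {tip_sequences[clade.name][site].upper()}
            else:
                counts: dict[str, int] = {}
                for child in clade.clades:
                    for s in upper[child]:
                        counts[s] = counts.get(s, 0) + 1
                best = max(counts.values())
                upper[clade] = {s for s, c in counts.items() if c == best}
        # downward pass
        assign: dict[Clade, str] = {}
        for clade in tree.find_clades(order="preorder"):
            if clade.is_terminal():
                assign[clade] = tip_sequences[clade.name][site].upper()
                continue
            parent_state = assign.get(_parent_of(tree, clade))
            if parent_state is not None and parent_state in upper[clade]:
                assign[clade] = parent_state
            else:
                assign[clade] = min(upper[clade])
        for clade in postorder:
            seqs[clade].append(assign[clade])

    return {c: "".join(s) for c, s in seqs.items()}


def _parent_of(tree: Tree, clade: Clade) -> Clade | None:
    # Bio.Phylo clades do not track parents; cache the map on the tree object.
    if not hasattr(tree, "_hapscan_parents"):
        parents = {}
        for c in tree.find_clades():
            for child in c.clades:
                parents[child] = c
        tree._hapscan_parents = parents
    return tree._hapscan_parents.get(clade)


def substitutions_from_tree(
    tree: Tree, tip_sequences: dict[str, str]
) -> list[SubstitutionEvent]:
    """Read substitution events off every branch after ancestral reconstruction.

    Sequences are treated as in-frame coding sequences; each differing codon
    yields one event, synonymous or not, at its 1-based amino-acid position.
    """
    anc = reconstruct_ancestors(tree, tip_sequences)
    code = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        code[stop] = "*"

    events = []
    counter = 0
    for clade in tree.find_clades():
        parent = _parent_of(tree, clade)
        if parent is None:
            continue
        pseq, cseq = anc[parent], anc[clade]
        counter += 1
        bid = clade.name or f"branch{counter}"
        for i in range(0, len(pseq) - len(pseq) % 3, 3):
            if pseq[i : i + 3] == cseq[i : i + 3]:
                continue
            aa_from = code.get(pseq[i : i + 3])
            aa_to = code.get(cseq[i : i + 3])
            if aa_from is None or aa_to is None:
                continue
            events.append(
                SubstitutionEvent(
                    branch_id=bid,
                    codon_position=i // 3 + 1,
                    from_aa=aa_from,
                    to_aa=aa_to,
                    synonymous=aa_from == aa_to,
                )
            )
    return events


# ---------------------------------------------------------------------------
# expected distribution and scoring


def _single_step_pairs() -> list[tuple[str, str]]:
    """All nonsynonymous (from, to) residue pairs reachable by one nucleotide
    change between sense codons, with multiplicity (one entry per codon path)."""
    code = standard_dna_table.forward_table
    pairs = []
    for codon, aa in code.items():
        for pos, alt in product(range(3), "ACGT"):
            if alt == codon[pos]:
                continue
            neighbor = codon[:pos] + alt + codon[pos + 1 :]
            aa2 = code.get(neighbor)
            if aa2 is None or aa2 == aa:
                continue
            pairs.append((aa, aa2))
    return pairs


def category_edges(prop: dict[str, float]) -> np.ndarray:
    """8 equal-width magnitude bins over [0, max single-step change]."""
    mags = [property_change_magnitude(a, b, prop) for a, b in _single_step_pairs()]
    top = max(mags)
    if top == 0:  # constant property: single degenerate bin boundary set
        top = 1.0
    return np.linspace(0.0, top, N_CATEGORIES + 1)


def magnitude_category(magnitude: float, edges: np.ndarray) -> int:
    """1-based category of a change magnitude; the top edge closes category 8."""
    cat = int(np.searchsorted(edges, magnitude, side="right"))
    return min(max(cat, 1), N_CATEGORIES)


def expected_distribution(prop: dict[str, float]) -> np.ndarray:
    """Per-category expected proportions under random single-step replacement.

    Every nonsynonymous single-nucleotide codon change under the standard
    genetic code is weighted uniformly; proportions sum to 1.
    """
    edges = category_edges(prop)
    counts = np.zeros(N_CATEGORIES)
    for a, b in _single_step_pairs():
        counts[magnitude_category(property_change_magnitude(a, b, prop), edges) - 1] += 1
    return counts / counts.sum()


def score_events(
    events: list[SubstitutionEvent],
    table: AminoAcidPropertyTable | None = None,
    z_threshold: float = 1.645,
) -> tuple[list[PropertyCategoryResult], list[SiteFlag]]:
    """Observed-vs-expected category tests and per-site radical flags.

    For each property, z = (obs - n q) / sqrt(n q (1 - q)) per category, tested
    one-sided for excess at |z| >= z_threshold (default 1.645, alpha = 0.05).
    A site is flagged when one of its events falls in a significant category;
    the flag is radical iff that category is 6, 7 or 8.
    """
    table = table or AminoAcidPropertyTable.packaged()
    nonsyn = [e for e in events if not e.synonymous]
    if not nonsyn:
        raise ValueError("no nonsynonymous events to score")

    cat_results: list[PropertyCategoryResult] = []
    site_hits: dict[int, list[tuple[int, str]]] = {}

    for prop_name, prop in table.values.items():
        edges = category_edges(prop)
        q = expected_distribution(prop)
        cats = np.array(
            [
                magnitude_category(
                    property_change_magnitude(e.from_aa, e.to_aa, prop), edges
                )
                for e in nonsyn
            ]
        )
        n = len(nonsyn)
        obs = np.bincount(cats, minlength=N_CATEGORIES + 1)[1:]
        significant = np.zeros(N_CATEGORIES, dtype=bool)
        for c in range(N_CATEGORIES):
            if q[c] == 0.0:
                z = None
                sig = obs[c] > 0
                if sig:
                    warnings.warn(
                        f"{prop_name}: {obs[c]} events in category {c + 1} with zero "
                        "expected proportion (infinite surprise)"
                    )
            elif q[c] >= 1.0:  # degenerate: the category is certain
                z = 0.0
                sig = False
            else:
                z = float((obs[c] - n * q[c]) / np.sqrt(n * q[c] * (1 - q[c])))
                sig = z >= z_threshold
            significant[c] = sig
            cat_results.append(
                PropertyCategoryResult(
                    property=prop_name,
                    category=c + 1,
                    observed=int(obs[c]),
                    expected=float(n * q[c]),
                    z=z,
                    significant=bool(sig),
                )
            )
        for e, c in zip(nonsyn, cats):
            if significant[c - 1]:
                site_hits.setdefault(e.codon_position, []).append((int(c), prop_name))

    flags = []
    for site in sorted(site_hits):
        hits = site_hits[site]
        max_cat = max(c for c, _ in hits)
        props = tuple(sorted({p for _, p in hits}))
        flags.append(
            SiteFlag(
                site=site,
                max_category=max_cat,
                properties=props,
                radical=max_cat in RADICAL_CATEGORIES,
            )
        )
    return cat_results, flags


def category_table(results: list[PropertyCategoryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "property": r.property,
                "category": r.category,
                "observed": r.observed,
                "expected": r.expected,
                "z": r.z,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def site_table(flags: list[SiteFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": f.site,
                "max_category": f.max_category,
                "radical": f.radical,
                "properties": ",".join(f.properties),
            }
            for f in flags
        ]
    )
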