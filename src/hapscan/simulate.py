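"""Synthetic cohorts with the statistical structure the scan assumes.

The generator emulates a resequenced single-gene region in a large population
sample: a set of haplotypes dominated by two common ones, every derived
haplotype one mutational step from its parent (a star-like single-step
genealogy), Hardy-Weinberg pairing of haplotypes into diplotypes across a few
populations, and correlated lipid phenotypes (triglycerides, HDL, VLDL, LDL,
and a total-cholesterol composite) driven by age/sex/BMI covariates plus an
optional additive genetic effect linked to one branch of the haplotype tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import check_positive_definite, rng_for

PHENOTYPES = ("tg", "hdl", "vldl", "ldl", "chol")
#: Phenotypes entering the multivariate model; total cholesterol is excluded
#: because it is a composite of the others.
CORE_PHENOTYPES = ("tg", "hdl", "vldl", "ldl")
COVARIATES = ("age", "sex", "bmi")

#: Default correlation of the multivariate phenotype noise (tg, hdl, vldl, ldl).
#: VLDL tracks triglycerides closely (VLDL-c is commonly estimated as TG/5),
#: HDL is moderately anticorrelated with both, LDL only weakly related.
DEFAULT_PHENOTYPE_CORR = np.array(
    [
        [1.00, -0.40, 0.90, 0.20],
        [-0.40, 1.00, -0.40, 0.10],
        [0.90, -0.40, 1.00, 0.20],
        [0.20, 0.10, 0.20, 1.00],
    ]
)

#: Covariate coefficients on the standardized phenotype scale. Only the
#: residual structure after adjustment matters downstream; these give the
#: covariates a visible but not dominant share of variance.
DEFAULT_COVARIATE_EFFECTS = {"age": 0.01, "sex": 0.20, "bmi": 0.03}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the resequencing study the pipeline is built around:
    three populations of 1830/601/1045 individuals, 45 haplotypes over a
    ~1.2 kb coding region, and the two dominant haplotypes at frequencies
    0.512 and 0.260.
    """

    n_individuals: tuple[int, ...] = (1830, 601, 1045)
    populations: tuple[str, ...] = ("AA", "MA", "EA")
    n_haplotypes: int = 45
    seq_length: int = 1218
    two_common_freq: tuple[float, float] = (0.512, 0.260)
    effect_branch: tuple[str, str] | None = None
    effect_sizes: dict[str, float] = field(default_factory=dict)
    phenotype_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_PHENOTYPE_CORR.copy()
    )
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    rare_freq_concentration: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_individuals, int):
            self.n_individuals = (self.n_individuals,)
            if len(self.populations) != 1:
                self.populations = ("P1",)
        if len(self.n_individuals) != len(self.populations):
            raise ValueError("n_individuals and populations must align")
        if self.n_haplotypes > self.seq_length:
            raise ValueError(
                f"infeasible: {self.n_haplotypes} haplotypes need "
                f"{self.n_haplotypes - 1} distinct mutated sites but only "
                f"{self.seq_length} sites are available"
            )
        f1, f2 = self.two_common_freq
        if not (0 < f2 <= f1 and f1 + f2 < 1):
            raise ValueError("two_common_freq must satisfy 0 < f2 <= f1, f1+f2 < 1")
        self.phenotype_corr = np.asarray(self.phenotype_corr, dtype=float)
        check_positive_definite(self.phenotype_corr, "phenotype_corr")
        if self.phenotype_corr.shape[0] != len(CORE_PHENOTYPES):
            raise ValueError("phenotype_corr must be 4x4 (tg, hdl, vldl, ldl)")


@dataclass
class SimulatedCohort:
    haplotypes: dict[str, str]
    frequencies: pd.Series
    parents: dict[str, str]  # child haplotype -> parent haplotype
    mutated_site: dict[str, int]  # child haplotype -> 0-based site of its step
    table: pd.DataFrame  # per-individual diplotype + covariates + phenotypes
    config: SimulationConfig

    def derived_carriers(self, branch: tuple[str, str]) -> np.ndarray:
        """Copies (0/1/2) of the derived-side allele of a genealogy branch."""
        derived = descendant_set(self.parents, branch)
        a = self.table["hap_a"].isin(derived).to_numpy(dtype=int)
        b = self.table["hap_b"].isin(derived).to_numpy(dtype=int)
        return a + b


def descendant_set(parents: dict[str, str], branch: tuple[str, str]) -> set[str]:
    """Haplotypes on the derived (child) side of a parent->child branch."""
    parent, child = branch
    if parents.get(child) != parent:
        raise KeyError(f"branch {parent}->{child} not in the genealogy")
    children: dict[str, list[str]] = {}
    for c, p in parents.items():
        children.setdefault(p, []).append(c)
    out, stack = set(), [child]
    while stack:
        node = stack.pop()
        out.add(node)
        stack.extend(children.get(node, []))
    return out


def _random_coding_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random nucleotide sequence; in-frame stop codons avoided when length % 3 == 0."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    if length % 3 == 0:
        for i in range(0, length, 3):
            while "".join(seq[i : i + 3]) in _STOPS:
                seq[i : i + 3] = rng.choice(bases, size=3)
    return seq


def _mutate_one_site(
    seq: np.ndarray, site: int, rng: np.random.Generator
) -> np.ndarray:
    bases = [b for b in "ACGT" if b != seq[site]]
    out = seq.copy()
    for b in rng.permutation(bases):
        out[site] = b
        if len(seq) % 3 == 0:
            codon_start = 3 * (site // 3)
            if "".join(out[codon_start : codon_start + 3]) in _STOPS:
                continue
        return out
    out[site] = bases[0]  # all alternatives are stops: accept the first
    return out


def simulate_haplotype_set(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.Series, dict[str, str], dict[str, int]]:
    """Generate haplotype sequences, frequencies and their single-step genealogy.

    h1 is the ancestral common haplotype, h2 the second common one (one step
    away). Each further haplotype mutates one previously untouched site off an
    existing haplotype chosen with probability proportional to its frequency,
    which reproduces the star-like, all-single-step topology of a low-diversity
    intragenic network. Returns (sequences, frequencies, parents, mutated_site).
    """
    rng = rng_for(config.seed, "haplotypes")
    H, L = config.n_haplotypes, config.seq_length
    f1, f2 = config.two_common_freq

    ancestral = _random_coding_sequence(L, rng)
    seqs: dict[str, np.ndarray] = {"h1": ancestral}
    parents: dict[str, str] = {}
    mutated_site: dict[str, int] = {}
    free_sites = list(rng.permutation(L))

    # frequencies: two common haplotypes, remainder spread over rare ones
    if H > 2:
        rest = rng.dirichlet(np.full(H - 2, config.rare_freq_concentration))
        rest = np.sort(rest)[::-1] * (1.0 - f1 - f2)
        freqs = np.concatenate([[f1, f2], rest])
    else:
        freqs = np.array([f1, f2]) / (f1 + f2) if H == 2 else np.array([1.0])
    ids = [f"h{i + 1}" for i in range(H)]

    for i in range(1, H):
        hid = ids[i]
        if i == 1:
            parent = "h1"
        else:
            cur = np.array(freqs[:i])
            parent = ids[rng.choice(i, p=cur / cur.sum())]
        site = int(free_sites.pop())
        seqs[hid] = _mutate_one_site(seqs[parent], site, rng)
        parents[hid] = parent
        mutated_site[hid] = site

    sequences = {k: "".join(v) for k, v in seqs.items()}
    frequencies = pd.Series(freqs[:H], index=ids, name="frequency")
    return sequences, frequencies, parents, mutated_site


def assign_diplotypes(frequencies: pd.Series, config: SimulationConfig) -> pd.DataFrame:
    """Hardy-Weinberg random union of haplotypes within each population."""
    rng = rng_for(config.seed, "diplotypes")
    ids = frequencies.index.to_numpy()
    p = frequencies.to_numpy()
    p = p / p.sum()
    rows = []
    counter = 0
    for pop, n in zip(config.populations, config.n_individuals):
        hap_a = rng.choice(ids, size=n, p=p)
        hap_b = rng.choice(ids, size=n, p=p)
        for a, b in zip(hap_a, hap_b):
            counter += 1
            rows.append((f"ind{counter:05d}", pop, a, b))
    return pd.DataFrame(rows, columns=["id", "population", "hap_a", "hap_b"])


def simulate_phenotypes(
    cohort: SimulatedCohort, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Covariates plus phenotypes on the standardized (SD-unit) scale.

    phenotype = covariate term + branch-genotype effect + correlated MVN noise;
    total cholesterol is the deterministic composite ldl + hdl + tg/5 plus a
    small independent noise term.
    """
    config = config or cohort.config
    rng = rng_for(config.seed, "phenotypes")
    df = cohort.table.copy()
    n = len(df)

    df["age"] = rng.uniform(18, 65, size=n).round(1)
    df["sex"] = rng.integers(0, 2, size=n)
    df["bmi"] = rng.normal(28, 5, size=n).round(2)

    cov_term = (
        config.covariate_effects.get("age", 0.0) * (df["age"] - df["age"].mean())
        + config.covariate_effects.get("sex", 0.0) * df["sex"]
        + config.covariate_effects.get("bmi", 0.0) * (df["bmi"] - df["bmi"].mean())
    ).to_numpy()

    chol_fac = np.linalg.cholesky(config.phenotype_corr)
    noise = rng.standard_normal((n, len(CORE_PHENOTYPES))) @ chol_fac.T

    genetic = np.zeros((n, len(CORE_PHENOTYPES)))
    if config.effect_branch is not None and config.effect_sizes:
        copies = cohort.derived_carriers(tuple(config.effect_branch))
        for j, ph in enumerate(CORE_PHENOTYPES):
            genetic[:, j] = config.effect_sizes.get(ph, 0.0) * copies

    for j, ph in enumerate(CORE_PHENOTYPES):
        df[ph] = cov_term + genetic[:, j] + noise[:, j]
    df["chol"] = df["ldl"] + df["hdl"] + df["tg"] / 5.0 + 0.05 * rng.standard_normal(n)
    return df


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full generator: haplotypes -> diplotypes -> covariates and phenotypes."""
    sequences, frequencies, parents, mutated_site = simulate_haplotype_set(config)
    table = assign_diplotypes(frequencies, config)
    cohort = SimulatedCohort(
        haplotypes=sequences,
        frequencies=frequencies,
        parents=parents,
        mutated_site=mutated_site,
        table=table,
        config=config,
    )
    cohort.table = simulate_phenotypes(cohort, config)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA (haplotypes), TSV (individuals) and a JSON config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "haplotypes.fasta"
    with open(fasta, "w") as fh:
        for hid, seq in cohort.haplotypes.items():
            fh.write(f">{hid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    tsv = outdir / "cohort.tsv"
    out = cohort.table.copy()
    for ph in PHENOTYPES:
        out[ph] = out[ph].map(lambda v: f"{v:.10g}")
    out.to_csv(tsv, sep="\t", index=False)
    sidecar = outdir / "simulation.json"
    cfg = cohort.config
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "seed": cfg.seed,
                "n_individuals": list(cfg.n_individuals),
                "populations": list(cfg.populations),
                "n_haplotypes": cfg.n_haplotypes,
                "seq_length": cfg.seq_length,
                "two_common_freq": list(cfg.two_common_freq),
                "effect_branch": list(cfg.effect_branch) if cfg.effect_branch else None,
                "effect_sizes": cfg.effect_sizes,
                "covariate_effects": cfg.covariate_effects,
                "phenotype_corr": cfg.phenotype_corr.tolist(),
                "haplotype_frequencies": {
                    k: float(v) for k, v in cohort.frequencies.items()
                },
                "genealogy": cohort.parents,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return {"fasta": fasta, "cohort": tsv, "sidecar": sidecar}
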