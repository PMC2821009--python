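"""Readers, writers and run configuration.

Canonical tabular dialect: tab-separated, header row, UTF-8, '.' decimal.
FASTA wraps at 60 columns. Every pipeline run writes a JSON manifest echoing
the resolved configuration and seed so outputs regenerate bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .network import HaplotypeNetwork
from .scan import ScanConfig, ScanResult

REQUIRED_COHORT_COLUMNS = ("id", "population", "hap_a", "hap_b")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run; JSON round-trippable."""

    fasta: str
    cohort: str
    phenotypes: tuple[str, ...] = ("tg", "hdl", "vldl", "ldl")
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    population: str | None = None
    min_class_count: int = 5
    n_permutations: int = 10_000
    multivariate: bool = True
    alpha: float = 0.05
    conditional: bool = True
    loop_breaks: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    outdir: str = "hapscan_out"

    def to_json(self) -> str:
        d = asdict(self)
        d["phenotypes"] = list(self.phenotypes)
        d["covariates"] = list(self.covariates)
        d["loop_breaks"] = [list(e) for e in self.loop_breaks]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["phenotypes"] = tuple(d["phenotypes"])
        d["covariates"] = tuple(d["covariates"])
        d["loop_breaks"] = [tuple(e) for e in d.get("loop_breaks", [])]
        return cls(**d)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            phenotypes=self.phenotypes,
            covariates=self.covariates,
            min_class_count=self.min_class_count,
            n_permutations=self.n_permutations,
            seed=self.seed,
            multivariate=self.multivariate,
            alpha=self.alpha,
        )


def read_haplotypes(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def read_cohort(
    path: str | Path, haplotype_ids: set[str] | None = None
) -> pd.DataFrame:
    """Cohort TSV: one row per individual with diplotype, covariates, phenotypes.

    Validates required columns, duplicate ids and (when ``haplotype_ids`` is
    given) that every referenced haplotype exists, naming offenders.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing required columns {missing}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated individual ids: {sorted(set(dup))}")
    if haplotype_ids is not None:
        refs = set(df["hap_a"]) | set(df["hap_b"])
        unknown = refs - set(haplotype_ids)
        if unknown:
            raise ValueError(
                f"cohort references haplotypes absent from FASTA: {sorted(unknown)}"
            )
    return df


def write_network(net: HaplotypeNetwork, path: str | Path) -> None:
    """Edge list TSV: node_a, node_b, length, site, change, aa_change."""
    rows = []
    for a, b, data in sorted(net.graph.edges(data=True)):
        changes = data.get("changes", ())
        if changes:
            for ch in changes:
                rows.append(
                    {
                        "node_a": a,
                        "node_b": b,
                        "length": data.get("length", len(changes)),
                        "site": ch.site + 1,
                        "change": f"{ch.from_base}>{ch.to_base}",
                        "aa_change": ch.aa_change or "",
                    }
                )
        else:
            rows.append(
                {
                    "node_a": a,
                    "node_b": b,
                    "length": data.get("length", ""),
                    "site": "",
                    "change": "",
                    "aa_change": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_scan_results(result: ScanResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    uni = outdir / "scan_univariate.tsv"
    t = result.table.copy()
    for col in ("F", "p_nominal", "p_corrected"):
        t[col] = t[col].map(lambda v: f"{v:.10g}")
    t.to_csv(uni, sep="\t", index=False)
    paths["univariate"] = uni

    if result.multivariate is not None:
        mv = outdir / "scan_multivariate.tsv"
        m = result.multivariate.copy()
        for col in ("wilks_lambda", "F", "p_parametric", "p_nominal", "p_corrected"):
            m[col] = m[col].map(lambda v: f"{v:.10g}")
        m.to_csv(mv, sep="\t", index=False)
        paths["multivariate"] = mv
    return paths


def write_manifest(
    config: RunConfig, result: ScanResult, outdir: str | Path, extra: dict | None = None
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    payload = {
        "config": json.loads(config.to_json()),
        "seed": config.seed,
        "n_branches_tested": int(result.table["branch"].nunique()),
        "dropped_branches": [list(d) for d in result.dropped],
        "n_permutations": result.config.n_permutations,
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
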