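"""End-to-end orchestration: network -> scan -> MANOVA follow-ups -> conditional scan."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import (
    RunConfig,
    read_cohort,
    read_haplotypes,
    write_manifest,
    write_network,
    write_scan_results,
)
from .network import HaplotypeNetwork, enumerate_branches, network_from_genealogy
from .scan import ScanResult, conditional_scan, scan

log = logging.getLogger("hapscan")


@dataclass
class PipelineResult:
    network: HaplotypeNetwork
    scan: ScanResult
    conditional: ScanResult | None
    significant_branches: list[str]
    outputs: dict[str, Path]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write all outputs plus a manifest.

    Stages: read inputs, build and loop-resolve the haplotype network,
    enumerate branch partitions, run the permutation scan (univariate and,
    when configured, multivariate with per-branch MANOVA summaries including
    partial Wilk's tests), and — when a branch is corrected-significant —
    a second-round scan conditioning on the top branch.
    """
    sequences = _stage("read_fasta", read_haplotypes, config.fasta)
    cohort = _stage("read_cohort", read_cohort, config.cohort, set(sequences))
    if config.population is not None:
        cohort = cohort[cohort["population"] == config.population].reset_index(
            drop=True
        )
        if cohort.empty:
            raise ValueError(f"no individuals in population {config.population!r}")

    counts = pd.concat([cohort["hap_a"], cohort["hap_b"]]).value_counts()
    frequencies = (counts / counts.sum()).to_dict()
    for hid in sequences:
        frequencies.setdefault(hid, 0.0)

    net = _stage(
        "network",
        network_from_genealogy,
        sequences,
        frequencies,
        forced_breaks=config.loop_breaks or None,
    )
    branches = enumerate_branches(net)
    log.info(
        "haplotypes=%d branches=%d individuals=%d",
        len(sequences),
        len(branches),
        len(cohort),
    )

    result = _stage("scan", scan, branches, cohort, config.scan_config())
    testable = result.table["branch"].nunique()
    log.info(
        "testable_branches=%d dropped=%d permutations=%d",
        testable,
        len(result.dropped),
        config.n_permutations,
    )

    sig_table = result.multivariate if result.multivariate is not None else result.table
    sig = sig_table.loc[sig_table["p_corrected"] < config.alpha, "branch"]
    significant = sorted(set(sig))

    cond = None
    if config.conditional and significant:
        top = result.top_branch()
        cond = _stage(
            "conditional_scan",
            conditional_scan,
            branches,
            cohort,
            config.scan_config(),
            top,
        )

    outdir = Path(config.outdir)
    outputs = {}
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(net, outdir / "network.tsv")
    outputs["network"] = outdir / "network.tsv"
    outputs.update(write_scan_results(result, outdir))
    if cond is not None:
        c = cond.table.copy()
        for col in ("F", "p_nominal", "p_corrected"):
            c[col] = c[col].map(lambda v: f"{v:.10g}")
        c.to_csv(outdir / "scan_conditional.tsv", sep="\t", index=False)
        outputs["conditional"] = outdir / "scan_conditional.tsv"
    outputs["manifest"] = write_manifest(
        config,
        result,
        outdir,
        extra={
            "significant_branches": significant,
            "loop_breaks_applied": [list(e) for e in net.removed_edges],
        },
    )
    return PipelineResult(
        network=net,
        scan=result,
        conditional=cond,
        significant_branches=significant,
        outputs=outputs,
    )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
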