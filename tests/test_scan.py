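"""Genotype classing, permutation ANOVA, max-T correction, conditional scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapscan.network import BranchPartition, enumerate_branches, network_from_genealogy
from hapscan.scan import (
    ScanConfig,
    adjust_phenotypes,
    conditional_scan,
    genotype_classes,
    scan,
    step_down_maxt,
    univariate_branch_test,
)
from hapscan.simulate import SimulationConfig, simulate_cohort

from conftest import make_diplotypes


def _partition(side_a, side_b, edge=None):
    side_a, side_b = frozenset(side_a), frozenset(side_b)
    edge = edge or (sorted(side_a)[0], sorted(side_b)[0])
    return BranchPartition(edge=edge, side_a=side_a, side_b=side_b)


class TestAdjustPhenotypes:
    def test_constant_covariates_mean_center(self, rng):
        df = pd.DataFrame({"y": rng.standard_normal(20), "c": np.ones(20)})
        out = adjust_phenotypes(df, ("y",), ("c",))
        assert np.allclose(out["y"], df["y"] - df["y"].mean())

    def test_residuals_orthogonal_to_covariate(self, rng):
        age = rng.uniform(18, 65, 500)
        df = pd.DataFrame({"y": 2.0 * age + rng.standard_normal(500), "age": age})
        out = adjust_phenotypes(df, ("y",), ("age",))
        assert abs(np.corrcoef(out["y"], age)[0, 1]) < 1e-10

    def test_matches_normal_equations_oracle(self):
        # 6-row example solved explicitly via (X'X)^-1 X'y
        y = np.array([1.0, 2.0, 0.5, 3.0, 2.5, 1.5])
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({"y": y, "x": x})
        X = np.column_stack([np.ones(6), x])
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        expected = y - X @ beta
        out = adjust_phenotypes(df, ("y",), ("x",))
        assert np.allclose(out["y"], expected, atol=1e-12)

    def test_collinear_covariates_reported(self, rng):
        x = rng.standard_normal(30)
        df = pd.DataFrame({"y": rng.standard_normal(30), "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            adjust_phenotypes(df, ("y",), ("a", "b"))


class TestGenotypeClasses:
    def test_all_ancestral_untestable(self):
        d = make_diplotypes({("h1", "h1"): 30})
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}))
        assert not cl.testable and cl.included_classes == ("AA",)

    def test_large_rare_homozygote_class_retained(self):
        # class counts 1263/156/7 all pass the >=5 filter
        d = make_diplotypes(
            {("h1", "h1"): 1263, ("h1", "h2"): 156, ("h2", "h2"): 7}
        )
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}), min_count=5)
        assert cl.class_counts == {"AA": 1263, "AB": 156, "BB": 7}
        assert cl.included_classes == ("AA", "AB", "BB")
        assert cl.mask.all()

    def test_small_class_filter_forces_skip(self):
        d = make_diplotypes({("h1", "h1"): 100, ("h1", "h2"): 4})
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}), min_count=5)
        assert cl.included_classes == ("AA",)
        assert not cl.testable
        assert int(cl.mask.sum()) == 100  # the 4 AB individuals are dropped

    def test_unknown_haplotype_rejected(self):
        d = make_diplotypes({("h1", "hX"): 5})
        with pytest.raises(ValueError, match="hX"):
            genotype_classes(d, _partition({"h1"}, {"h2"}))


class TestUnivariateBranchTest:
    def test_matches_hand_anova_oracle(self, rng):
        # 12 rows, 3 classes: explicit SS_between / SS_within
        d = make_diplotypes(
            {("h1", "h1"): 4, ("h1", "h2"): 4, ("h2", "h2"): 4}
        )
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}), min_count=4)
        y = np.array([3.1, 2.2, 1.4, 2.8, 4.5, 5.1, 3.9, 4.2, 6.0, 7.1, 6.4, 5.8])
        F, p = univariate_branch_test(y, cl, n_perm=500, seed=9)
        groups = [y[cl.classes == g] for g in range(3)]
        grand = y.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        assert F == pytest.approx((ssb / 2) / (ssw / 9), rel=1e-12)
        assert F == pytest.approx(stats.f_oneway(*groups)[0], rel=1e-10)

    def test_perfect_separation_smallest_achievable_p(self):
        d = make_diplotypes({("h1", "h1"): 3, ("h2", "h2"): 3})
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}), min_count=3)
        y = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
        F, p = univariate_branch_test(y, cl, n_perm=2000, seed=1)
        assert np.isinf(F)  # zero within-class variance, unequal means
        # only the 2 perfectly-separating assignments of C(6,3)=20 reach F=inf
        assert p == pytest.approx(0.1, abs=0.03)

    def test_null_p_not_small_on_null_fixture(self, rng):
        d = make_diplotypes({("h1", "h1"): 40, ("h1", "h2"): 40})
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}))
        y = rng.standard_normal(80)
        _, p = univariate_branch_test(y, cl, n_perm=1000, seed=4)
        assert p > 0.05

    def test_untestable_branch_rejected(self):
        d = make_diplotypes({("h1", "h1"): 30})
        cl = genotype_classes(d, _partition({"h1"}, {"h2"}))
        with pytest.raises(ValueError, match="untestable"):
            univariate_branch_test(np.zeros(30), cl, 10, 0)


class TestStepDownMaxT:
    def test_single_branch_corrected_equals_nominal(self, rng):
        obs = np.array([2.5])
        perm = rng.standard_normal((500, 1)) ** 2
        p_corr = step_down_maxt(obs, perm)
        p_nom = (1 + (perm[:, 0] >= 2.5).sum()) / 501
        assert p_corr[0] == pytest.approx(p_nom)

    def test_identical_branches_effectively_one_test(self, rng):
        stats_col = rng.standard_normal(800) ** 2
        perm = np.column_stack([stats_col, stats_col, stats_col])
        obs = np.array([4.0, 4.0, 4.0])
        p_corr = step_down_maxt(obs, perm)
        p_nom = (1 + (stats_col >= 4.0).sum()) / 801
        assert np.allclose(p_corr, p_nom)

    def test_monotone_and_at_least_nominal(self, rng):
        obs = rng.standard_normal(6) ** 2
        perm = rng.standard_normal((400, 6)) ** 2
        p_corr = step_down_maxt(obs, perm)
        p_nom = (1 + (perm >= obs[None, :]).sum(axis=0)) / 401
        assert (p_corr >= p_nom - 1e-12).all()
        order = np.argsort(-obs)
        assert (np.diff(p_corr[order]) >= -1e-12).all()


def _scan_setup(seed=3, n=400, effect=0.0):
    cfg = SimulationConfig(
        n_individuals=(n,),
        populations=("P1",),
        n_haplotypes=8,
        seq_length=60,
        effect_branch=("h1", "h2") if effect else None,
        effect_sizes={"hdl": effect} if effect else {},
        seed=seed,
    )
    coh = simulate_cohort(cfg)
    net = network_from_genealogy(coh.haplotypes, coh.frequencies.to_dict())
    return coh, enumerate_branches(net)


class TestScan:
    def test_effect_branch_detected_and_invariants_hold(self):
        coh, branches = _scan_setup(seed=5, n=800, effect=0.6)
        cfg = ScanConfig(
            phenotypes=("tg", "hdl", "vldl", "ldl"), n_permutations=500, seed=2
        )
        res = scan(branches, coh.table, cfg)
        assert (res.table["p_corrected"] >= res.table["p_nominal"] - 1e-12).all()
        assert res.table["p_nominal"].between(0, 1).all()
        hdl = res.table[res.table["phenotype"] == "hdl"]
        assert hdl.loc[hdl["F"].idxmax(), "branch"] == "h1|h2"
        assert hdl.loc[hdl["branch"] == "h1|h2", "p_corrected"].iloc[0] < 0.05
        assert res.top_branch() == "h1|h2"
        ms = res.manova["h1|h2"]
        assert min(ms.partial_lambda, key=ms.partial_lambda.get) == "hdl"

    def test_two_identical_partitions_corrected_close_to_nominal(self):
        coh, _ = _scan_setup(seed=7, n=300)
        part = _partition({"h1"}, set(coh.frequencies.index) - {"h1"}, edge=("h1", "h2"))
        twin = BranchPartition(("h1", "h3"), part.side_a, part.side_b)
        cfg = ScanConfig(
            phenotypes=("hdl",), n_permutations=800, seed=11, multivariate=False
        )
        res = scan([part, twin], coh.table, cfg)
        t = res.table
        assert np.allclose(t["p_corrected"], t["p_nominal"], atol=1e-12)

    def test_corrected_matches_bruteforce_oracle(self):
        """Step-down corrected p equals an independently coded max-T enumeration
        on the same permutation stream (3 branches, 50 individuals, 200 perms)."""
        coh, branches = _scan_setup(seed=13, n=50)
        branches = [b for b in branches][:6]
        cfg = ScanConfig(
            phenotypes=("hdl",),
            covariates=(),
            n_permutations=200,
            seed=21,
            multivariate=False,
            min_class_count=2,
        )
        res = scan(branches, coh.table, cfg)
        tested = list(res.table["branch"])
        assert len(tested) >= 3

        # oracle: same stream convention (default_rng(seed), rng.permuted in
        # chunks of 250), statistics and step-down logic recoded from scratch
        data = coh.table.dropna(subset=["hdl"]).reset_index(drop=True)
        y = data["hdl"].to_numpy()
        cls = {
            b.branch_id: genotype_classes(data, b, 2)
            for b in branches
            if genotype_classes(data, b, 2).testable
        }

        def f_stat(values, cl):
            groups = [values[cl.mask][cl.classes == g] for g in range(cl.k)]
            if all(len(set(g)) <= 1 for g in groups):
                means = [g.mean() for g in groups]
                return 0.0 if len(set(means)) == 1 else np.inf
            return stats.f_oneway(*groups)[0]

        obs = {b: f_stat(y, cl) for b, cl in cls.items()}
        rng = np.random.default_rng(21)
        idx = rng.permuted(np.tile(np.arange(len(y)), (200, 1)), axis=1)
        perm = {b: np.array([f_stat(y[i], cl) for i in idx]) for b, cl in cls.items()}

        names = sorted(obs, key=lambda b: -obs[b])
        p_corr_oracle = {}
        prev = 0.0
        for r, b in enumerate(names):
            maxima = np.max([perm[bb] for bb in names[r:]], axis=0)
            p = (1 + (maxima >= obs[b]).sum()) / 201
            prev = max(prev, p)
            p_corr_oracle[b] = prev

        for b in tested:
            got = res.table.loc[res.table["branch"] == b, "p_corrected"].iloc[0]
            assert got == pytest.approx(p_corr_oracle[b], abs=1e-12), b

    def test_no_testable_branches_raises(self):
        coh, branches = _scan_setup(seed=3, n=20)
        cfg = ScanConfig(phenotypes=("hdl",), n_permutations=10, min_class_count=1000)
        with pytest.raises(ValueError, match="testable"):
            scan(branches, coh.table, cfg)


class TestPhasingInvariance:
    def _cohort(self, phasing: str):
        """One individual heterozygous at a singleton site on an h1/h2
        background; the two phasings attach the singleton to h1 or to h2."""
        seqs = {"h1": "AAAAAA", "h2": "TAAAAA"}
        if phasing == "a":
            seqs["hs"] = "AAAATA"  # singleton on the h1 background
            pair = ("hs", "h2")
        else:
            seqs["hs"] = "TAAATA"  # singleton on the h2 background
            pair = ("h1", "hs")
        d = make_diplotypes(
            {("h1", "h1"): 40, ("h1", "h2"): 30, ("h2", "h2"): 12, pair: 1}
        )
        rng = np.random.default_rng(55)
        d["hdl"] = rng.standard_normal(len(d))
        return seqs, d

    def test_singleton_heterozygote_always_AB(self):
        for phasing in ("a", "b"):
            seqs, d = self._cohort(phasing)
            counts = pd.concat([d["hap_a"], d["hap_b"]]).value_counts()
            net = network_from_genealogy(seqs, (counts / counts.sum()).to_dict())
            parts = {p.branch_id: p for p in enumerate_branches(net)}
            singleton = [p for p in parts.values() if "hs" in p.edge]
            assert len(singleton) == 1
            cl = genotype_classes(d, singleton[0], min_count=1)
            carrier = d.index[(d["hap_a"] == "hs") | (d["hap_b"] == "hs")][0]
            assert cl.copies[carrier] == 1  # AB under either phasing

    def test_scan_output_identical_under_both_phasings(self):
        results = {}
        for phasing in ("a", "b"):
            seqs, d = self._cohort(phasing)
            counts = pd.concat([d["hap_a"], d["hap_b"]]).value_counts()
            net = network_from_genealogy(seqs, (counts / counts.sum()).to_dict())
            parts = enumerate_branches(net)
            cfg = ScanConfig(
                phenotypes=("hdl",),
                covariates=(),
                n_permutations=300,
                seed=6,
                multivariate=False,
                min_class_count=1,
            )
            res = scan(parts, d, cfg).table
            # key branches by the mutated site so ids match across phasings
            res["key"] = res["label"].str.extract(r"[ACGT](\d+)[ACGT]")
            results[phasing] = res.set_index("key")[
                ["F", "p_nominal", "p_corrected"]
            ].sort_index()
        pd.testing.assert_frame_equal(results["a"], results["b"])


class TestSingletonExclusion:
    def test_dropping_singletons_leaves_other_branches_unchanged(self):
        """Relabeling a pendant singleton haplotype to its parent (= excluding
        the singleton) does not move any individual across other branches'
        partitions, so their tests are unchanged."""
        seqs = {"h1": "AAAAAA", "h2": "TAAAAA", "h3": "TCAAAA", "hs": "AAAAAT"}
        d = make_diplotypes(
            {
                ("h1", "h1"): 30,
                ("h1", "h2"): 25,
                ("h2", "h2"): 10,
                ("h2", "h3"): 8,
                ("h1", "hs"): 2,  # singleton carriers: AB class of hs branch, <5
            }
        )
        rng = np.random.default_rng(17)
        d["hdl"] = rng.standard_normal(len(d))
        cfg = ScanConfig(
            phenotypes=("hdl",), covariates=(), n_permutations=300, seed=8,
            multivariate=False,
        )

        counts = pd.concat([d["hap_a"], d["hap_b"]]).value_counts()
        net = network_from_genealogy(seqs, (counts / counts.sum()).to_dict())
        res_full = scan(enumerate_branches(net), d, cfg).table

        d2 = d.replace({"hap_a": {"hs": "h1"}, "hap_b": {"hs": "h1"}})
        seqs2 = {k: v for k, v in seqs.items() if k != "hs"}
        counts2 = pd.concat([d2["hap_a"], d2["hap_b"]]).value_counts()
        net2 = network_from_genealogy(seqs2, (counts2 / counts2.sum()).to_dict())
        res_drop = scan(enumerate_branches(net2), d2, cfg).table

        merged = res_full.merge(res_drop, on="label", suffixes=("_full", "_drop"))
        assert len(merged) == len(res_drop)
        for col in ("F", "p_nominal", "p_corrected"):
            assert np.allclose(merged[f"{col}_full"], merged[f"{col}_drop"])


class TestConditionalScan:
    def test_self_conditioning_null(self):
        coh, branches = _scan_setup(seed=5, n=800, effect=0.6)
        cfg = ScanConfig(
            phenotypes=("hdl",), n_permutations=300, seed=2, multivariate=False
        )
        res = conditional_scan(branches, coh.table, cfg, condition_branch="h1|h2")
        row = res.table[res.table["branch"] == "h1|h2"].iloc[0]
        assert row["F"] == 0.0 and row["p_nominal"] > 0.99

    def test_irrelevant_conditioning_preserves_p(self):
        coh, branches = _scan_setup(seed=19, n=1000, effect=0.5)
        cfg = ScanConfig(
            phenotypes=("hdl",), n_permutations=400, seed=3, multivariate=False
        )
        uncond = scan(branches, coh.table, cfg).table
        other = [
            b for b in uncond["branch"] if b != "h1|h2"
        ][0]  # a testable branch unrelated to the effect
        cond = conditional_scan(branches, coh.table, cfg, condition_branch=other).table
        p_u = uncond.loc[uncond["branch"] == "h1|h2", "p_nominal"].iloc[0]
        p_c = cond.loc[cond["branch"] == "h1|h2", "p_nominal"].iloc[0]
        # strong effect stays highly significant under unrelated conditioning
        assert p_u < 0.01 and p_c < 0.01

    def test_unknown_condition_branch(self):
        coh, branches = _scan_setup()
        cfg = ScanConfig(phenotypes=("hdl",), n_permutations=10)
        with pytest.raises(KeyError):
            conditional_scan(branches, coh.table, cfg, condition_branch="nope")
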