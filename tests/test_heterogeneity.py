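"""Purity estimation, presence partitioning, prevalence clustering, trees."""

import numpy as np
import pytest

from ecpdx.core import SampleProfile, SomaticVariant
from ecpdx.heterogeneity import (
    CloneCluster,
    build_panel,
    cellular_prevalence,
    cluster_prevalences,
    estimate_purity,
    euler_regions,
    infer_clone_tree,
)
from ecpdx.simulate import CloneTreeSpec, pdx58_like_spec, simulate_lineage_panel


def snv(vaf, pos=None, depth=100, vid=None):
    return SomaticVariant("1", pos or 100, "C", "T", "SNP", vaf, depth,
                          context3="ACA", id=vid)


class TestEstimatePurity:
    def test_vafs_at_half_give_pure_tumor(self):
        vs = [snv(0.5, pos=i + 1) for i in range(100)]
        assert estimate_purity(vs) == 1.0

    def test_recovers_planted_purity(self):
        rng = np.random.default_rng(1)
        alts = rng.binomial(100, 0.415, size=500)  # purity 0.83, diploid
        vs = [snv(a / 100, pos=i + 1) for i, a in enumerate(alts)]
        assert estimate_purity(vs) == pytest.approx(0.83, abs=0.05)

    def test_mode_picks_the_clonal_majority_peak(self):
        # clonal majority at VAF 0.4, subclone at 0.1 -> purity 2 x 0.4
        vs = ([snv(0.4, pos=i + 1) for i in range(300)]
              + [snv(0.1, pos=1000 + i) for i in range(150)])
        assert estimate_purity(vs) == pytest.approx(0.8, abs=0.01)

    def test_too_few_variants_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            estimate_purity([snv(0.5)] * 10)

    def test_low_depth_variants_filtered(self):
        vs = [snv(0.5, pos=i + 1) for i in range(60)]
        shallow = [snv(0.1, pos=1000 + i, depth=10) for i in range(100)]
        assert estimate_purity(vs + shallow) == 1.0


def _profile(sid, vids, vaf=0.5):
    return SampleProfile(
        sid, role="pdx", callable_mb=30,
        variants=[snv(vaf, pos=i + 1, vid=v) for i, v in enumerate(vids)])


class TestPanelAndEuler:
    def test_two_sample_set_arithmetic(self):
        p = build_panel([_profile("primary", ["A", "B", "C"]),
                         _profile("pdx", ["A", "D"])])
        regions = euler_regions(p)
        assert regions[("primary", "pdx")] == 1
        assert regions[("primary",)] == 2
        assert regions[("pdx",)] == 1

    def test_identical_samples_share_everything(self):
        p = build_panel([_profile("s1", ["A", "B"]), _profile("s2", ["A", "B"])])
        assert euler_regions(p) == {("s1", "s2"): 2}

    def test_counts_conserve_the_universe(self):
        samples, _ = simulate_lineage_panel(pdx58_like_spec(), seed=3)
        p = build_panel(samples)
        assert sum(euler_regions(p).values()) == len(p.mutation_universe)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            build_panel([_profile("s1", ["A"])])

    def test_detection_thresholds_applied(self):
        low = _profile("low", ["A"], vaf=0.01)
        high = _profile("high", ["A"], vaf=0.5)
        p = build_panel([low, high], detect_vaf=0.05)
        assert euler_regions(p) == {("high",): 1}

    def test_divergent_lineage_shares_a_third_with_primary(self):
        fracs = []
        for seed in range(1, 6):
            samples, _ = simulate_lineage_panel(pdx58_like_spec(), seed=seed)
            regions = euler_regions(build_panel(samples))
            shared = sum(n for pat, n in regions.items()
                         if "primary" in pat and "PDX-A" in pat)
            total_a = sum(n for pat, n in regions.items() if "PDX-A" in pat)
            fracs.append(shared / total_a)
        assert np.mean(fracs) == pytest.approx(1 / 3, abs=0.05)


class TestCellularPrevalence:
    @pytest.mark.parametrize("vaf,purity,cn,expected", [
        (0.5, 1.0, 2, 1.0),
        (0.25, 1.0, 2, 0.5),
        (0.415, 0.83, 2, 1.0),  # 0.415*2/0.83 = 1.0 exactly, clamped
    ])
    def test_closed_form(self, vaf, purity, cn, expected):
        assert cellular_prevalence(vaf, purity, cn) == pytest.approx(expected)

    def test_equals_twice_vaf_in_pure_diploid(self):
        for vaf in (0.0, 0.1, 0.2, 0.35):
            assert cellular_prevalence(vaf, 1.0, 2) == pytest.approx(2 * vaf)

    def test_monotone_in_vaf(self):
        cps = [cellular_prevalence(v, 0.7, 2) for v in np.linspace(0, 0.4, 20)]
        assert all(b >= a for a, b in zip(cps, cps[1:]))

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            cellular_prevalence(0.3, 0.0, 2)


class TestClustering:
    def test_single_clone_panel_gives_one_cluster(self):
        spec = CloneTreeSpec(
            clones=({"id": "t", "parent_id": None, "n_private_mutations": 100},),
            prevalence={"primary": {"t": 1.0}, "PDX-A": {"t": 1.0}})
        # deep sequencing keeps prevalence noise under the variance floor
        samples, _ = simulate_lineage_panel(spec, seed=1, depth=2000)
        panel = build_panel(samples)
        clusters = cluster_prevalences(panel, {s.sample_id: 1.0 for s in samples},
                                       seed=1)
        assert len(clusters) == 1
        assert clusters[0].fraction_of_substitutions == 1.0

    def test_three_planted_clones_recovered(self):
        hits = 0
        for seed in range(1, 11):
            samples, _ = simulate_lineage_panel(pdx58_like_spec(), seed=seed)
            panel = build_panel(samples)
            clusters = cluster_prevalences(
                panel, {s.sample_id: 1.0 for s in samples}, seed=seed)
            if len([c for c in clusters if not c.minor]) == 3:
                hits += 1
        assert hits >= 9

    def test_five_planted_clones_recovered(self):
        # a PDX03-like panel: five clusters all holding >=5% of mutations
        spec = CloneTreeSpec(
            clones=(
                {"id": "t", "parent_id": None, "n_private_mutations": 200},
                {"id": "a", "parent_id": "t", "n_private_mutations": 150},
                {"id": "b", "parent_id": "t", "n_private_mutations": 150},
                {"id": "c", "parent_id": "a", "n_private_mutations": 120},
                {"id": "d", "parent_id": "b", "n_private_mutations": 120},
            ),
            prevalence={
                "primary": {"t": 1.0, "a": 0.5, "b": 0.4, "c": 0.1, "d": 0.05},
                "PDX-A": {"t": 1.0, "a": 1.0, "b": 0.0, "c": 0.6, "d": 0.0},
                "PDX-B": {"t": 1.0, "a": 0.0, "b": 1.0, "c": 0.0, "d": 0.55},
            })
        samples, _ = simulate_lineage_panel(spec, seed=5)
        panel = build_panel(samples)
        clusters = cluster_prevalences(panel, {s.sample_id: 1.0 for s in samples},
                                       seed=5)
        assert len([c for c in clusters if not c.minor]) == 5

    def test_too_few_mutations_rejected(self):
        p = build_panel([_profile("a", ["x", "y"]), _profile("b", ["x"])])
        with pytest.raises(ValueError, match="too few"):
            cluster_prevalences(p, {"a": 1.0, "b": 1.0})


def _cluster(cid, prev, n=100, universe=400):
    return CloneCluster(cluster_id=cid, members=tuple(f"m{cid}-{i}" for i in range(n)),
                        prevalence=prev, fraction_of_substitutions=n / universe)


class TestCloneTree:
    def test_two_clusters_give_single_chain(self):
        root = _cluster(0, {"s": 1.0})
        child = _cluster(1, {"s": 0.4})
        (tree,) = infer_clone_tree([root, child])
        assert tree.root == 0 and tree.edges == ((0, 1),)

    def test_overbudget_branching_rejected_linear_chain_kept(self):
        root = _cluster(0, {"s": 1.0})
        a = _cluster(1, {"s": 0.7})
        b = _cluster(2, {"s": 0.6})
        trees = infer_clone_tree([root, a, b])
        # 0.7 + 0.6 > 1.0: both children cannot hang off the root
        assert all(t.children(0) != [1, 2] for t in trees)
        assert any(t.edges == ((0, 1), (1, 2)) for t in trees)

    def test_planted_topology_recovered_and_sum_rule_revalidates(self):
        samples, truth = simulate_lineage_panel(pdx58_like_spec(), seed=2)
        panel = build_panel(samples)
        clusters = cluster_prevalences(panel, {s.sample_id: 1.0 for s in samples},
                                       seed=2)
        top = [c for c in clusters if not c.minor]
        trees = infer_clone_tree(top)
        # identify clusters by size: truncal=150, A=300, B=150 mutations
        by_size = sorted(top, key=lambda c: -len(c.members))
        trunk = max(top, key=lambda c: min(c.prevalence.values()))
        star = tuple(sorted((trunk.cluster_id, c.cluster_id)
                            for c in top if c is not trunk))
        assert any(t.edges == star for t in trees)
        for t in trees:
            for parent in t.nodes:
                kids = t.children(parent)
                if not kids:
                    continue
                pc = next(c for c in top if c.cluster_id == parent)
                for sid in pc.prevalence:
                    child_sum = sum(
                        next(c for c in top if c.cluster_id == k).prevalence[sid]
                        for k in kids)
                    assert child_sum <= pc.prevalence[sid] + 0.05 + 1e-9

    def test_no_dominating_cluster_is_an_error(self):
        a = _cluster(0, {"s1": 1.0, "s2": 0.2})
        b = _cluster(1, {"s1": 0.2, "s2": 1.0})
        with pytest.raises(ValueError, match="no valid root"):
            infer_clone_tree([a, b])
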