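"""Variant calling, homozygous filtering, TN93, NJ, bootstrap, concordance."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest
from skbio.tree import TreeNode

from calcstrain import phylogeny as ph, strain, synthdata as sd
from conftest import pileup_from_counts


class TestCallsAndFilters:
    def test_depth_below_minimum_yields_no_call(self):
        p = pileup_from_counts({0: {"A": 4}, 1: {"A": 5}}, 2)
        calls = ph.call_variants(p, np.zeros(2, dtype=np.uint8), min_cov=5)
        assert calls["position"].tolist() == [1]

    def test_major_allele_and_frequency_arithmetic(self):
        p = pileup_from_counts({0: {"A": 19, "G": 1}, 1: {"A": 9, "G": 1}}, 2)
        calls = ph.call_variants(p, np.zeros(2, dtype=np.uint8), min_cov=5)
        assert calls.iloc[0]["major"] == "A"
        assert calls.iloc[0]["major_freq"] == pytest.approx(0.95)
        assert calls.iloc[1]["major_freq"] == pytest.approx(0.9)

    def test_homozygous_filter_is_strict_and_idempotent(self):
        calls = pd.DataFrame({
            "position": [0, 1, 2],
            "ref": ["A", "A", "A"],
            "major": ["G", "G", "G"],
            "major_freq": [0.95, 0.9, 1.0],
            "depth": [20, 10, 10],
        })
        kept = ph.filter_homozygous(calls, 0.9)
        assert kept["major_freq"].tolist() == [0.95, 1.0]  # 0.9 removed: strict >
        again = ph.filter_homozygous(kept, 0.9)
        pd.testing.assert_frame_equal(kept, again)

    def test_heterozygous_fraction(self):
        calls = pd.DataFrame({"major_freq": [0.95, 0.9, 0.85, 1.0]})
        assert ph.heterozygous_fraction(calls, 0.9) == pytest.approx(0.5)

    def test_sample_qc_boundaries(self):
        stats = pd.DataFrame({
            "n_snps": [999, 1000, 1000, 1500],
            "mean_coverage": [10.0, 1.9, 5.0, 2.0],
        }, index=["low_snps", "low_cov", "ok5", "ok2"])
        qc5 = ph.sample_qc(stats, min_snps=1000, min_mean_cov=5.0)
        assert not qc5.loc["low_snps", "included"]
        assert "n_snps" in qc5.loc["low_snps", "reason"]
        assert not qc5.loc["low_cov", "included"]
        assert qc5.loc["ok5", "included"]  # both thresholds inclusive
        qc2 = ph.sample_qc(stats, min_snps=1000, min_mean_cov=2.0)
        assert qc2.loc["ok2", "included"]


class TestSnpAlignment:
    def test_disjoint_snps_fill_with_confident_reference(self):
        ref = np.zeros(10, dtype=np.uint8)  # all A
        s1 = pd.DataFrame({"position": [2, 7], "ref": ["A", "A"],
                           "major": ["G", "A"], "major_freq": [1.0, 1.0],
                           "depth": [10, 10]})
        s2 = pd.DataFrame({"position": [2, 7], "ref": ["A", "A"],
                           "major": ["A", "T"], "major_freq": [1.0, 1.0],
                           "depth": [10, 10]})
        aln = ph.build_snp_alignment({"s1": s1, "s2": s2}, ref)
        assert aln.positions.tolist() == [2, 7]
        assert "".join(aln.matrix[0]) == "GA"
        assert "".join(aln.matrix[1]) == "AT"

    def test_uncovered_column_is_n(self):
        ref = np.zeros(10, dtype=np.uint8)
        s1 = pd.DataFrame({"position": [2], "ref": ["A"], "major": ["G"],
                           "major_freq": [1.0], "depth": [10]})
        s2 = pd.DataFrame({"position": [5], "ref": ["A"], "major": ["C"],
                           "major_freq": [1.0], "depth": [10]})
        aln = ph.build_snp_alignment({"s1": s1, "s2": s2}, ref)
        assert "".join(aln.matrix[1]) == "NC"  # s2 has no call at position 2

    def test_no_snps_gives_empty_alignment_and_tree_refused(self):
        ref = np.zeros(5, dtype=np.uint8)
        calls = pd.DataFrame({"position": [1], "ref": ["A"], "major": ["A"],
                              "major_freq": [1.0], "depth": [10]})
        aln = ph.build_snp_alignment({"s1": calls, "s2": calls, "s3": calls}, ref)
        assert aln.n_columns == 0
        dm, _ = ph.tn93_distance(aln)
        with pytest.raises(ValueError):
            ph.nj_tree(dm)


def snp_aln(rows: dict[str, str]) -> ph.SnpAlignment:
    ids = list(rows)
    mat = np.array([list(s) for s in rows.values()], dtype="U1")
    return ph.SnpAlignment(ids, np.arange(mat.shape[1]), mat)


class TestTN93:
    def test_identical_sequences_have_zero_distance(self):
        aln = snp_aln({"a": "ACGTACGT", "b": "ACGTACGT"})
        dm, reasons = ph.tn93_distance(aln)
        assert dm.loc["a", "b"] == 0.0 and not reasons

    def test_reduces_to_jukes_cantor_in_symmetric_limit(self):
        # equal base composition, all six difference pair types equally
        # represented and balanced in direction -> JC closed form
        n = 600
        x = np.array(list("ACGT" * (n // 4)))
        y = x.copy()
        free = {b: [i for i in range(n) if x[i] == b] for b in "ACGT"}
        for a, b in [("A", "G"), ("C", "T"), ("A", "C"),
                     ("A", "T"), ("C", "G"), ("G", "T")]:
            for _ in range(2):
                y[free[a].pop()] = b
                y[free[b].pop()] = a
        aln = ph.SnpAlignment(["x", "y"], np.arange(n), np.array([x, y]))
        dm, _ = ph.tn93_distance(aln)
        p = 24 / n
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert abs(dm.loc["x", "y"] - jc) < 1e-10

    def test_pure_transition_case_matches_direct_evaluation(self):
        # 100 columns, 10 A<->G differences; evaluate the closed form from
        # the counted proportions independently
        x = list("AG" * 25 + "CT" * 25)
        y = x.copy()
        for i in range(0, 20, 2):
            y[i] = "G" if x[i] == "A" else "A"
        # 10 sites change A->G (indices 0..18 even): recount composition
        aln = snp_aln({"x": "".join(x), "y": "".join(y)})
        dm, _ = ph.tn93_distance(aln)
        xv = np.array(x)
        yv = np.array(y)
        freqs = {b: (np.sum(xv == b) + np.sum(yv == b)) / 200 for b in "ACGT"}
        pi_r = freqs["A"] + freqs["G"]
        pi_y = freqs["C"] + freqs["T"]
        p1, q = 0.10, 0.0
        k1 = 2 * freqs["A"] * freqs["G"] / pi_r
        k3 = 2 * (pi_r * pi_y - freqs["A"] * freqs["G"] * pi_y / pi_r
                  - freqs["C"] * freqs["T"] * pi_r / pi_y)
        expected = -k1 * np.log(1 - p1 / k1 - q / (2 * pi_r))
        assert dm.loc["x", "y"] == pytest.approx(expected, abs=1e-12)

    def test_columns_with_n_are_excluded_pairwise(self):
        aln = snp_aln({"a": "ACGTNNNN", "b": "ACGANNNN"})
        dm, reasons = ph.tn93_distance(aln)
        assert not reasons
        assert dm.loc["a", "b"] > 0  # computed over the 4 shared columns

    def test_saturated_pair_is_undefined_with_reason(self):
        aln = snp_aln({"a": "A" * 40, "b": "C" * 40})
        dm, reasons = ph.tn93_distance(aln)
        assert np.isnan(dm.loc["a", "b"])
        assert ("a", "b") in reasons


class TestTrees:
    def test_three_taxon_branch_lengths_exact(self):
        d = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = ph.nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_nj_recovers_random_additive_trees_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        ids = [f"t{i}" for i in range(n)]
        # random bifurcating tree with positive branch lengths
        nodes = [TreeNode(name=i) for i in ids]
        while len(nodes) > 1:
            a = nodes.pop(int(rng.integers(len(nodes))))
            b = nodes.pop(int(rng.integers(len(nodes))))
            a.length = float(rng.uniform(0.1, 2.0))
            b.length = float(rng.uniform(0.1, 2.0))
            nodes.append(TreeNode(children=[a, b]))
        true_tree = nodes[0]
        dm = true_tree.tip_tip_distances()
        d = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
        recovered = ph.nj_tree(d)
        rec = recovered.tip_tip_distances().filter(list(dm.ids))
        assert np.allclose(rec.data, dm.data, atol=1e-9)

    def test_midpoint_root_is_equidistant_on_two_tip_tree(self):
        tree = ph.midpoint_root(TreeNode.read(StringIO("(A:1,B:3);")))
        dists = {t.name: tree.distance(t) for t in tree.tips()}
        assert dists["A"] == pytest.approx(2.0)
        assert dists["B"] == pytest.approx(2.0)

    def test_nan_distances_refused(self):
        d = pd.DataFrame([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]],
                         index=list("ABC"), columns=list("ABC"))
        with pytest.raises(ValueError):
            ph.nj_tree(d)


class TestBootstrap:
    def test_congruent_columns_give_full_support(self):
        # shared background columns plus three mutually compatible signal
        # blocks, one per internal edge of a six-taxon ladder; every
        # informative column agrees with the same tree
        rng = np.random.default_rng(1)
        background = rng.choice(list("ACGT"), size=60)
        mat = np.tile(background, (6, 1))
        pairs = [("A", "G"), ("C", "T"), ("A", "C"),
                 ("G", "T"), ("A", "T"), ("C", "G")]
        blocks = []
        for members in ([0, 1, 2], [0, 1], [3, 4]):
            block = []
            for x, y in pairs:
                col = [y] * 6
                for m in members:
                    col[m] = x
                block.append(col)
            blocks.append(np.array(block).T)
        mat = np.hstack([mat] + blocks)
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        aln = ph.SnpAlignment(ids, np.arange(mat.shape[1]), mat.astype("U1"))
        tree, effective = ph.bootstrap_support(aln, replicates=50, seed=1)
        assert effective == 50
        supports = [n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_supports_reproducible_and_bounded(self):
        rng = np.random.default_rng(3)
        base = rng.choice(list("ACGT"), size=40)
        mat = np.tile(base, (5, 1))
        flips = rng.random(mat.shape) < 0.15  # sparse noise keeps TN93 defined
        mat[flips] = rng.choice(list("ACGT"), size=int(flips.sum()))
        aln = ph.SnpAlignment([f"s{i}" for i in range(5)], np.arange(40), mat)
        t1, _ = ph.bootstrap_support(aln, replicates=30, seed=7)
        t2, _ = ph.bootstrap_support(aln, replicates=30, seed=7)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_conflicting_column_classes_split_support(self):
        # two equally common column classes supporting rival splits of four
        # samples; bootstrap support behaves like a binomial over resampled
        # class counts, so the winning split hovers around 50%
        background = np.tile(np.array(list("ACGT" * 25)), (4, 1))
        class1 = np.tile(np.array(list("AAGG")), (20, 1)).T  # {s0,s1}|{s2,s3}
        class2 = np.tile(np.array(list("CTCT")), (20, 1)).T  # {s0,s2}|{s1,s3}
        mat = np.hstack([background, class1, class2])
        aln = ph.SnpAlignment(["s0", "s1", "s2", "s3"],
                              np.arange(mat.shape[1]), mat.astype("U1"))
        tree, effective = ph.bootstrap_support(aln, replicates=200, seed=11)
        assert effective == 200
        supports = {n.support for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")}
        assert len(supports) == 1  # one internal bipartition on 4 taxa
        assert 25.0 <= supports.pop() <= 75.0

    def test_unseeded_call_rejected(self):
        aln = snp_aln({"a": "AC", "b": "AG", "c": "CC"})
        with pytest.raises(ValueError):
            ph.bootstrap_support(aln, replicates=5)


class TestConcordance:
    def test_identical_trees_have_w_one(self):
        t1 = TreeNode.read(StringIO("((A:1,B:2):1.5,(C:0.7,D:2.2):0.4);"))
        t2 = TreeNode.read(StringIO("((A:1,B:2):1.5,(C:0.7,D:2.2):0.4);"))
        r = ph.concordance([t1, t2], permutations=99, seed=4)
        assert r.w == pytest.approx(1.0)

    def test_reversed_rankings_give_w_zero(self):
        m1 = pd.DataFrame([[0, 1, 2], [1, 0, 3], [2, 3, 0]],
                          index=list("ABC"), columns=list("ABC"), dtype=float)
        m2 = pd.DataFrame([[0, 3, 2], [3, 0, 1], [2, 1, 0]],
                          index=list("ABC"), columns=list("ABC"), dtype=float)
        r = ph.concordance([m1, m2], permutations=99, seed=4)
        assert r.w == pytest.approx(0.0, abs=1e-12)

    def test_minimum_p_value_attained_at_99_permutations(self):
        rng = np.random.default_rng(12)
        m = rng.random((8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ids = [f"s{i}" for i in range(8)]
        d = pd.DataFrame(m, index=ids, columns=ids)
        r = ph.concordance([d, d.copy()], permutations=99, seed=5)
        assert r.p_value == pytest.approx(1 / 100)

    def test_mismatched_tip_sets_rejected(self):
        t1 = TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        t2 = TreeNode.read(StringIO("((A:1,B:1):1,(C:1,E:1):1);"))
        with pytest.raises(Exception):
            ph.concordance([t1, t2], permutations=9, seed=1)


class TestIslandRecovery:
    def test_two_island_simulation_clusters_by_island(self):
        """Samples simulated from two island-specific strain pools, pushed
        through calling, homozygous filtering, SNP alignment, TN93 and NJ,
        split into two clades that match the islands (divergences chosen to
        keep between-island distances below TN93 saturation; see methods)."""
        rng = np.random.default_rng(10)
        L = 60_000
        base, _, _ = sd.generate_genome_pair(L, 0.5, 0.0, seed=int(rng.integers(2 ** 31)))
        islands = {}
        for name in ("A", "B"):
            islands[name], _ = sd.mutate_genome(base, 0.001,
                                                int(rng.integers(2 ** 31)), name)
        calls = {}
        for name, anc in islands.items():
            for k in range(4):
                g, _ = sd.mutate_genome(anc, 0.0004, int(rng.integers(2 ** 31)),
                                        f"{name}{k}")
                reads = sd.simulate_reads(
                    g, sd.SimulationConfig(seed=int(rng.integers(2 ** 31)),
                                           n_pairs=4000, read_length=75,
                                           damage=sd.DAMAGE_UDG_HALF),
                    sample_id=f"{name}{k}")
                reads = strain.mask_reads(reads, 1)
                for r in reads:
                    r.reference_id = base.id
                pileup = strain.build_pileup(reads, 30, 12, reference_length=L,
                                             sample_id=f"{name}{k}")
                c = ph.call_variants(pileup, base.codes, min_cov=5)
                calls[f"{name}{k}"] = ph.filter_homozygous(c, 0.9)
        aln = ph.build_snp_alignment(calls, base.codes)
        dm, reasons = ph.tn93_distance(aln)
        assert not reasons
        tree = ph.midpoint_root(ph.nj_tree(dm))
        clades = [frozenset(t.name for t in child.tips()) if not child.is_tip()
                  else frozenset([child.name]) for child in tree.children]
        expected = {frozenset(f"A{k}" for k in range(4)),
                    frozenset(f"B{k}" for k in range(4))}
        assert set(clades) == expected

    def test_bootstrap_perturbed_trees_stay_concordant(self):
        # resampled replicates of one signal-rich alignment give trees whose
        # cophenetic distances agree strongly (W near 1)
        rng = np.random.default_rng(6)
        base = rng.choice(list("ACGT"), size=60)
        mat = np.tile(base, (8, 1))
        flips = rng.random(mat.shape) < 0.05
        mat[flips] = rng.choice(list("ACGT"), size=int(flips.sum()))
        # group signal spread over substitution classes so no single TN93
        # term can saturate in a resample
        sig_pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T")] * 2
        signal = np.array([[x] * 4 + [y] * 4 for x, y in sig_pairs]).T
        mat = np.hstack([mat, signal])
        aln = ph.SnpAlignment([f"s{i}" for i in range(8)],
                              np.arange(mat.shape[1]), mat.astype("U1"))
        dm, reasons = ph.tn93_distance(aln)
        assert not reasons
        trees = []
        for seed in (1, 2, 3):
            cols = np.random.default_rng(seed).integers(0, aln.n_columns,
                                                        aln.n_columns)
            rep = ph.SnpAlignment(aln.sample_ids, aln.positions[cols],
                                  aln.matrix[:, cols])
            rep_dm, rep_reasons = ph.tn93_distance(rep)
            assert not rep_reasons
            trees.append(ph.nj_tree(rep_dm))
        r = ph.concordance(trees, permutations=99, seed=8)
        assert r.w > 0.8
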