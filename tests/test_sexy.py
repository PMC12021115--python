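"""Sex assignment from depth tables, MSY filtering attrition, haplotype
counting, p-distance, NJ tree recovery on additive matrices, and relative
depth scoring."""

import numpy as np
import pandas as pd
import pytest

from ponypop.sexy import (
    SexThresholds,
    call_sex,
    count_haplotypes,
    msy_filter,
    nj_tree,
    p_distance_matrix,
    relative_depth,
    sex_indices,
)
from ponypop.simulate import simulate_depth_cohort
from tests.conftest import make_gm


def depth_row(chrom, sample, reads, cov, length):
    return {
        "chrom": chrom,
        "sample": sample,
        "total_reads": reads,
        "covered_bp": cov,
        "chrom_len": length,
    }


def manual_depth(sample, auto_rate, x_rate, y_rate, y_cov_frac):
    lens = {"1": 2_000_000, "2": 2_000_000, "X": 1_200_000, "Y": 120_000}
    rows = [
        depth_row("1", sample, int(auto_rate * lens["1"]), lens["1"], lens["1"]),
        depth_row("2", sample, int(auto_rate * lens["2"]), lens["2"], lens["2"]),
        depth_row("X", sample, int(x_rate * lens["X"]), lens["X"], lens["X"]),
        depth_row(
            "Y", sample, int(y_rate * lens["Y"]), int(y_cov_frac * lens["Y"]), lens["Y"]
        ),
    ]
    return pd.DataFrame(rows)


class TestSexIndices:
    def test_female_zero_residual(self):
        idx = sex_indices(manual_depth("F0", 10, 10, 0.0, 0.0)).iloc[0]
        assert idx["ry"] == 0.0
        assert idx["cov_y"] == 0.0
        assert idx["rx"] == pytest.approx(1.0, abs=0.01)

    def test_male_profile_ranges(self):
        idx = sex_indices(manual_depth("M0", 10, 5, 5, 0.99)).iloc[0]
        assert 0.4 < idx["x_over_chr1"] < 0.6
        assert 0.4 < idx["rx"] < 0.6
        assert idx["ry"] > 0.05

    def test_scale_invariance(self):
        t = manual_depth("S", 10, 5, 5, 0.99)
        t10 = t.copy()
        t10["total_reads"] *= 10
        a = sex_indices(t).iloc[0]
        b = sex_indices(t10).iloc[0]
        for col in ("x_over_chr1", "y_over_chr1", "rx", "ry", "cov_y"):
            assert a[col] == pytest.approx(b[col])

    def test_missing_chromosome_is_error(self):
        t = manual_depth("S", 10, 5, 5, 0.99)
        with pytest.raises(ValueError):
            sex_indices(t[t.chrom != "Y"])

    def test_zero_autosomal_reads_is_error(self):
        t = manual_depth("S", 10, 5, 5, 0.99)
        t.loc[t.chrom.isin(["1", "2"]), "total_reads"] = 0
        with pytest.raises(ValueError):
            sex_indices(t)


class TestCallSex:
    def make_indices(self, cov_y, ry, rx):
        return pd.DataFrame(
            [{"sample": "S", "cov_y": cov_y, "x_over_chr1": rx, "y_over_chr1": ry,
              "rx": rx, "ry": ry}]
        )

    def test_consistent_male(self):
        calls = call_sex(self.make_indices(0.99, 0.2, 0.51))
        assert calls["call"].iloc[0] == "male"

    def test_consistent_female(self):
        calls = call_sex(self.make_indices(0.01, 0.001, 0.98))
        assert calls["call"].iloc[0] == "female"

    def test_conflict_is_ambiguous_with_both_rules_named(self):
        calls = call_sex(self.make_indices(0.99, 0.001, 0.98))
        assert calls["call"].iloc[0] == "ambiguous"
        why = calls["rationale"].iloc[0]
        assert "covY" in why and "Ry" in why

    def test_recorded_sex_mismatch_reported(self):
        calls = call_sex(
            self.make_indices(0.99, 0.2, 0.51), recorded_sex={"S": "female"}
        )
        assert bool(calls["mismatch"].iloc[0])

    def test_simulated_cohort_fully_correct_at_10x(self):
        depth, truth = simulate_depth_cohort(50, 50, 10.0, seed=42)
        calls = call_sex(sex_indices(depth)).merge(truth, on="sample")
        assert (calls["call"] == calls["sex"]).all()

    def test_low_depth_degrades_to_ambiguous_never_wrong(self):
        depth, truth = simulate_depth_cohort(20, 20, 0.5, seed=43)
        calls = call_sex(sex_indices(depth)).merge(truth, on="sample")
        decided = calls[calls["call"] != "ambiguous"]
        assert (decided["call"] == decided["sex"]).all()


class TestMSYFilter:
    def test_clean_hemizygous_matrix_is_identity(self):
        d = np.array([[0, 2, 0], [2, 0, 0], [0, 2, 2]], dtype=np.int8)
        gm = make_gm(d, samples=["m1", "m2", "m3"])
        out, rep = msy_filter(gm, ["m1", "m2", "m3"], max_sample_missing=1.0)
        assert out.n_sites == 3
        assert rep["n_sites_complete_case"] == 3

    def test_heterozygous_site_dropped(self):
        d = np.array([[0, 1], [2, 0]], dtype=np.int8)
        gm = make_gm(d, samples=["m1", "m2"])
        out, rep = msy_filter(gm, ["m1", "m2"], max_sample_missing=1.0)
        assert rep["n_sites_after_het_drop"] == 1
        assert out.n_sites == 1

    def test_planned_attrition_stage_by_stage(self):
        # 10 sites, 4 males: 3 sites het (10->7), 1 site with a missing call
        # (7->6), 1 monomorphic site (6->5), complete-case 5->5
        d = np.zeros((4, 10), dtype=np.int8)
        d[:, [0, 3]] = 2  # polymorphic? no -- fixed alt = monomorphic
        d[:2, 1] = 2  # site 1 polymorphic 2/2
        d[0, 2] = 1  # het -> dropped
        d[1, 4] = 1  # het -> dropped
        d[3, 5] = 1  # het -> dropped
        d[2, 6] = -1  # missing (25% > 2%) -> dropped at missingness stage
        d[:2, 7] = 2
        d[:1, 8] = 2
        d[:3, 9] = 2
        # monomorphic sites 0,3: MAF 0 -> dropped at MAF stage (2 sites!) --
        # keep exactly one monomorphic site for the planned 6->5
        d[:2, 0] = 0
        d[0, 0] = 2  # site 0 now polymorphic 1/4
        gm = make_gm(d, samples=["m1", "m2", "m3", "m4"])
        out, rep = msy_filter(gm, ["m1", "m2", "m3", "m4"], max_sample_missing=1.0)
        assert rep["n_sites_in"] == 10
        assert rep["n_sites_after_het_drop"] == 7
        assert rep["n_sites_after_missingness"] == 6
        assert rep["n_sites_after_maf"] == 5
        assert rep["n_sites_complete_case"] == 5
        assert out.n_sites == 5

    def test_everything_filtered_is_error(self):
        d = np.ones((2, 2), dtype=np.int8)  # all het
        gm = make_gm(d, samples=["m1", "m2"])
        with pytest.raises(ValueError):
            msy_filter(gm, ["m1", "m2"])


class TestCountHaplotypes:
    def test_all_identical_is_one(self):
        count, _ = count_haplotypes(np.zeros((5, 4), dtype=np.int8))
        assert count == 1

    def test_hand_count(self):
        m = np.array([[0, 0], [0, 0], [0, 2], [2, 0], [0, 2]], dtype=np.int8)
        count, membership = count_haplotypes(m, ["a", "b", "c", "d", "e"])
        assert count == 3
        assert membership["a"] == membership["b"]
        assert membership["c"] == membership["e"]

    def test_duplicate_sample_never_changes_count(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 3, (6, 8)).astype(np.int8)
        c1, _ = count_haplotypes(m)
        c2, _ = count_haplotypes(np.vstack([m, m[2:3]]))
        assert c1 == c2

    def test_order_invariant(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 3, (7, 5)).astype(np.int8)
        c1, _ = count_haplotypes(m)
        c2, _ = count_haplotypes(m[::-1])
        assert c1 == c2

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            count_haplotypes(np.array([[0, -1]], dtype=np.int8))


class TestPDistance:
    def test_identical_samples_zero(self):
        d = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (2, 1))
        m = p_distance_matrix(make_gm(d))
        assert m.iloc[0, 1] == 0.0

    def test_hand_example(self):
        d = np.array([[0, 0, 2, 1], [0, 2, 2, 1]], dtype=np.int8)
        m = p_distance_matrix(make_gm(d))
        assert m.iloc[0, 1] == pytest.approx(0.25)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (6, 20)).astype(np.int8)
        m = p_distance_matrix(make_gm(d)).to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)


def random_additive_matrix(rng, n_leaves):
    """Random binary tree with positive branch lengths -> path-sum matrix."""
    import itertools

    nodes = {i: None for i in range(n_leaves)}
    adj = {}
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        adj.setdefault(nxt, {})[a] = adj.setdefault(a, {})[nxt] = float(
            rng.uniform(0.5, 3.0)
        )
        adj[nxt][b] = adj.setdefault(b, {})[nxt] = float(rng.uniform(0.5, 3.0))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    def path_len(u, v):
        stack = [(u, None, 0.0)]
        while stack:
            node, par, dist = stack.pop()
            if node == v:
                return dist
            for k, l in adj.get(node, {}).items():
                if k != par:
                    stack.append((k, node, dist + l))
        raise RuntimeError

    taxa = [f"T{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for u, v in itertools.combinations(range(n_leaves), 2):
        D[u, v] = D[v, u] = path_len(u, v)
    return pd.DataFrame(D, index=taxa, columns=taxa)


def patristic(newick):
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    tax = {x.label: x for x in t.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(tax[a], tax[b])


class TestNJTree:
    def test_three_taxon_exact_fit(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC")
        )
        dist = patristic(nj_tree(D, "C"))
        assert dist("A", "B") == pytest.approx(3)
        assert dist("A", "C") == pytest.approx(4)
        assert dist("B", "C") == pytest.approx(5)

    def test_four_taxon_additive_recovery(self):
        taxa = list("ABCD")
        D = pd.DataFrame(
            [[0, 3, 5.5, 6.5], [3, 0, 6.5, 7.5], [5.5, 6.5, 0, 7], [6.5, 7.5, 7, 0]],
            index=taxa,
            columns=taxa,
        )
        dist = patristic(nj_tree(D, "D"))
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                assert dist(a, b) == pytest.approx(D.loc[a, b], abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_additive_battery_recovered_exactly(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for rep in range(4):
            D = random_additive_matrix(rng, n_leaves)
            dist = patristic(nj_tree(D, D.index[0]))
            for i, a in enumerate(D.index):
                for b in D.index[i + 1 :]:
                    assert dist(a, b) == pytest.approx(D.loc[a, b], abs=1e-8)

    def test_outgroup_pendant_split_at_midpoint(self):
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC")
        )
        nwk = nj_tree(D, "C")
        assert nwk.startswith("(C:")

    def test_missing_outgroup_is_error(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError):
            nj_tree(D, "Z")


class TestRelativeDepth:
    TABLE = pd.DataFrame(
        {
            "gene": ["or1", "or2", "sc1", "sc2"],
            "total_reads": [500, 0, 1000, 1000],
            "length_bp": [1000, 1000, 1000, 1000],
        }
    )

    def test_single_copy_average_scores_one(self):
        out = relative_depth(self.TABLE, ["sc1", "sc2"]).set_index("gene")
        assert out.loc["sc1", "relative_depth"] == pytest.approx(1.0)

    def test_absent_gene_scores_zero(self):
        out = relative_depth(self.TABLE, ["sc1", "sc2"]).set_index("gene")
        assert out.loc["or2", "relative_depth"] == 0.0

    def test_half_depth_gene(self):
        out = relative_depth(self.TABLE, ["sc1", "sc2"]).set_index("gene")
        assert out.loc["or1", "relative_depth"] == pytest.approx(0.5)

    def test_no_single_copy_is_error(self):
        with pytest.raises(ValueError):
            relative_depth(self.TABLE, ["nope"])
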