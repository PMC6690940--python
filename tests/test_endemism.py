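"""PE / PEalt / RPE: hand oracles, brute-force equivalence, invariants."""

import numpy as np
import pytest

from islandpe import (
    DatedTree,
    GenusAnnotations,
    IncidenceMatrix,
    OccurrenceRecord,
    branch_ranges,
    build_incidence,
    compute_scores,
    pe,
    pe_alt,
    restrict_islands,
    rpe,
)
from islandpe.io_formats import ConfigurationError, ValidationError

from conftest import random_world


def brute_force_scores(tree, incidence, annotations=None, variant="expanded", n_max=None):
    """Independent oracle: per island, rebuild the tip-to-root path set C
    from scratch, recount every branch's island set by direct enumeration,
    and sum l_c / R_c. No shared code with the production path beyond the
    tree arrays themselves."""
    n_max = n_max if n_max is not None else incidence.n_islands
    genus_rows = {
        g: {incidence.island_ids[k] for k in np.flatnonzero(incidence.matrix[:, j])}
        for j, g in enumerate(incidence.genus_names)
    }
    # island set per branch: union over descendant genera present in the matrix
    branch_islands = {}
    for b in range(tree.n_branches):
        s = set()
        for j, g in enumerate(incidence.genus_names):
            if tree.desc[b, tree.tip_index[g]]:
                s |= genus_rows[g]
        branch_islands[b] = s
    cont = (
        annotations.continental_vector(incidence.genus_names)
        if annotations is not None
        else np.zeros(incidence.n_genera, dtype=bool)
    )
    l_u = tree.mean_branch_length
    pe_v, alt_v = [], []
    for k, isl in enumerate(incidence.island_ids):
        path_branches = set()
        for j, g in enumerate(incidence.genus_names):
            if incidence.matrix[k, j]:
                path_branches |= set(tree.path_to_root(g))
        s_pe = s_alt = 0.0
        for b in path_branches:
            r = len(branch_islands[b])
            r_eff = r
            if variant == "restricted":
                has_cont = any(
                    cont[j] and tree.desc[b, tree.tip_index[g]]
                    for j, g in enumerate(incidence.genus_names)
                )
                if has_cont:
                    r_eff = n_max
            s_pe += tree.branch_lengths[b] / r_eff
            s_alt += l_u / r_eff
        pe_v.append(s_pe)
        alt_v.append(s_alt)
    return np.array(pe_v), np.array(alt_v)


class TestBranchRanges:
    def test_expanded_hand_union(self, toy_tree, toy_incidence):
        rt = branch_ranges(toy_tree, toy_incidence)
        r_by_tip = {  # branch index via the terminal branch of each tip
            lab: rt.r[toy_tree.tip_branch[toy_tree.tip_index[lab]]]
            for lab in "ABC"
        }
        assert r_by_tip == {"A": 2, "B": 1, "C": 2}
        internal = [b for b in range(toy_tree.n_branches)
                    if b not in set(toy_tree.tip_branch)]
        assert [rt.r[b] for b in internal] == [2]  # the AB branch

    def test_restricted_rule_by_hand(self, toy_tree, toy_incidence, toy_annotations):
        rt = branch_ranges(toy_tree, toy_incidence, toy_annotations, "restricted", n_max=3)
        c_branch = toy_tree.tip_branch[toy_tree.tip_index["C"]]
        assert rt.r_effective[c_branch] == 3
        a_branch = toy_tree.tip_branch[toy_tree.tip_index["A"]]
        assert rt.r_effective[a_branch] == 2  # untouched

    def test_parent_range_dominates_children(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree, inc, _ = random_world(rng)
            rt = branch_ranges(tree, inc)
            for b in range(tree.n_branches):
                p = tree.parent[b]
                if p >= 0:
                    assert rt.r[p] >= rt.r[b]

    def test_genus_on_zero_islands(self, toy_tree):
        # incidence missing genus B entirely: its terminal branch has R=0
        inc = IncidenceMatrix(["I1"], ["A"], np.array([[1]]))
        rt = branch_ranges(toy_tree, inc)
        b_branch = toy_tree.tip_branch[toy_tree.tip_index["B"]]
        assert rt.r[b_branch] == 0 and not rt.presence[:, b_branch].any()

    def test_restricted_without_flags_is_config_error(self, toy_tree, toy_incidence):
        with pytest.raises(ConfigurationError):
            branch_ranges(toy_tree, toy_incidence, None, "restricted")


class TestMetricValues:
    def test_toy_expanded_hand_computation(self, toy_tree, toy_incidence):
        s = compute_scores(toy_tree, toy_incidence)
        np.testing.assert_allclose(s.pe, [1.0, 3.0, 1.0], rtol=1e-12)
        assert s.l_uniform == pytest.approx(1.25)
        np.testing.assert_allclose(s.pe_alt, [1.25, 3.125, 0.625], rtol=1e-12)
        np.testing.assert_allclose(s.rpe, [0.8, 0.96, 1.6], rtol=1e-12)

    def test_toy_restricted_hand_computation(self, toy_tree, toy_incidence, toy_annotations):
        s = compute_scores(toy_tree, toy_incidence, toy_annotations, "restricted", n_max=3)
        assert s.pe[2] == pytest.approx(2.0 / 3.0, rel=1e-12)  # I3: l=2, R->3

    def test_single_island_is_faiths_pd(self, toy_tree):
        """With one island all R_c = 1: PE equals the spanned branch length."""
        inc = IncidenceMatrix(["only"], ["A", "C"], np.array([[1, 1]]))
        s = compute_scores(toy_tree, inc)
        spanned = set(toy_tree.path_to_root("A")) | set(toy_tree.path_to_root("C"))
        assert s.pe[0] == pytest.approx(sum(toy_tree.branch_lengths[b] for b in spanned))

    def test_functional_api_matches_compute_scores(self, toy_tree, toy_incidence):
        rt = branch_ranges(toy_tree, toy_incidence)
        pe_v = pe(toy_tree, rt, toy_incidence)
        alt_v = pe_alt(toy_tree, rt, toy_incidence)
        s = compute_scores(toy_tree, toy_incidence)
        np.testing.assert_allclose(pe_v, s.pe)
        np.testing.assert_allclose(alt_v, s.pe_alt)
        np.testing.assert_allclose(rpe(pe_v, alt_v), s.rpe)

    def test_uniform_branch_lengths_give_rpe_one(self):
        t = DatedTree.from_newick_string("((A:2,B:2):2,(C:2,D:2):2);")
        inc = IncidenceMatrix(
            ["I1", "I2"], ["A", "B", "C", "D"], np.array([[1, 1, 0, 0], [0, 1, 1, 1]])
        )
        s = compute_scores(t, inc)
        np.testing.assert_allclose(s.rpe, 1.0, rtol=1e-12)

    def test_rpe_invariant_under_global_rescaling(self, toy_tree, toy_incidence):
        s1 = compute_scores(toy_tree, toy_incidence)
        scaled = DatedTree.from_newick_string("((A:7,B:7):7,C:14);")  # x7
        s2 = compute_scores(scaled, toy_incidence)
        np.testing.assert_allclose(s1.rpe, s2.rpe, rtol=1e-12)

    def test_zero_length_branches_affect_rpe_only_via_pealt(self):
        t = DatedTree.from_newick_string("((A:0,B:1):1,C:2);")
        inc = IncidenceMatrix(["I1"], ["A"], np.array([[1]]))
        s = compute_scores(t, inc)
        assert s.pe[0] == pytest.approx(1.0)  # 0 + 1
        assert s.pe_alt[0] == pytest.approx(2 * t.mean_branch_length)

    def test_bad_l_uniform_rejected(self, toy_tree, toy_incidence):
        with pytest.raises(ConfigurationError):
            compute_scores(toy_tree, toy_incidence, l_uniform=0.0)


class TestOracleEquivalence:
    def test_brute_force_matches_production(self):
        rng = np.random.default_rng(11)
        for _ in range(8):
            tree, inc, ann = random_world(rng, n_tips=6, n_islands=5)
            for variant in ("expanded", "restricted"):
                s = compute_scores(tree, inc, ann, variant)
                bf_pe, bf_alt = brute_force_scores(tree, inc, ann, variant)
                np.testing.assert_allclose(s.pe, bf_pe, rtol=1e-12, atol=1e-12)
                np.testing.assert_allclose(s.pe_alt, bf_alt, rtol=1e-12, atol=1e-12)


class TestInvariants:
    def test_conservation_of_total_pe(self):
        """Sum over islands of PE equals the summed lengths of branches
        present on at least one island (each contributes l_c/R_c, R_c times)."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            tree, inc, _ = random_world(rng, n_tips=12, n_islands=8)
            rt = branch_ranges(tree, inc)
            s = compute_scores(tree, inc)
            expected = tree.branch_lengths[rt.r > 0].sum()
            assert s.pe.sum() == pytest.approx(expected, rel=1e-9)
            expected_alt = s.l_uniform * (rt.r > 0).sum()
            assert s.pe_alt.sum() == pytest.approx(expected_alt, rel=1e-9)

    def test_adding_genus_never_decreases_pe(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            tree, inc, _ = random_world(rng, n_tips=10, n_islands=6)
            s0 = compute_scores(tree, inc)
            zeros = np.argwhere(inc.matrix == 0)
            if not len(zeros):
                continue
            k, j = zeros[rng.integers(len(zeros))]
            m2 = inc.matrix.copy()
            m2[k, j] = 1
            inc2 = IncidenceMatrix(inc.island_ids, inc.genus_names, m2)
            s1 = compute_scores(tree, inc2)
            assert s1.pe[k] >= s0.pe[k] - 1e-12

    def test_restricted_dominated_by_expanded(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            tree, inc, ann = random_world(rng, n_tips=10, n_islands=6)
            se = compute_scores(tree, inc, ann, "expanded")
            sr = compute_scores(tree, inc, ann, "restricted")
            assert (sr.pe <= se.pe + 1e-12).all()


class TestRestrictIslands:
    def test_island_subset_rules(self, toy_incidence, toy_annotations):
        # I3 holds only continental C -> excluded; I1, I2 hold A (insular)
        assert restrict_islands(toy_incidence, toy_annotations) == ["I1", "I2"]

    def test_all_continental_excludes_all(self, toy_incidence):
        ann = GenusAnnotations(continental={g: True for g in "ABC"})
        assert restrict_islands(toy_incidence, ann) == []

    def test_all_insular_keeps_all(self, toy_incidence):
        ann = GenusAnnotations(continental={g: False for g in "ABC"})
        assert restrict_islands(toy_incidence, ann) == ["I1", "I2", "I3"]
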