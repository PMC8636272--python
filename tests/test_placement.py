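"""Branch-marker calling and SNP support/conflict placement."""

import numpy as np
import pandas as pd
import pytest

from sedadna.placement import (
    BranchMarker,
    call_branch_markers,
    collect_observations,
    haplogroup_of,
    markers_from_tsv,
    markers_to_tsv,
    path_score,
    place_sample,
)
from sedadna.simulate import (
    DamageModel,
    inject_homoplasy,
    simulate_mito_panel,
    simulate_mito_reads,
)
from sedadna.tree import RootedTree, TreeNode


def brute_force_scores(tree, support, conflict, exclude=("OUT",)):
    """Oracle: explicit path enumeration for every candidate node."""
    scores = {}
    total_support = sum(support.values())
    for node in tree.preorder():
        if node in exclude:
            continue
        path = set(tree.branch_path(node))
        s = sum(support.get(b, 0) for b in path)
        c = sum(conflict.get(b, 0) for b in path)
        scores[node] = s - c - (total_support - s)
    return scores


def _observations(markers, derived_at=(), ancestral_at=()):
    """Build an observation table showing chosen branches derived/ancestral."""
    rows = {}
    for m in markers:
        if m.branch in derived_at:
            rows[m.position] = {"n_ancestral": 0, "n_derived": 3, "n_other": 0}
        elif m.branch in ancestral_at:
            rows[m.position] = {"n_ancestral": 3, "n_derived": 0, "n_other": 0}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "position"
    return df


@pytest.fixture(scope="module")
def panel_and_markers(mito_panel):
    markers, log = call_branch_markers(
        mito_panel.tree, mito_panel.tip_alignment(), mito_panel.outgroup
    )
    return mito_panel, markers, log


class TestMarkerCalling:
    def test_recovers_simulator_branch_site_map_exactly(self, panel_and_markers):
        panel, markers, log = panel_and_markers
        truth = {
            (b, p, a, d)
            for b, sites in panel.branch_sites.items()
            for p, a, d in sites
        }
        called = {(m.branch, m.position, m.ancestral, m.derived) for m in markers}
        assert called == truth  # perfect precision and recall
        assert log.n_homoplasy == 0

    def test_singleton_derived_marks_terminal_branch(self):
        tree = RootedTree(
            [
                TreeNode("R", None, ["OUT", "I"]),
                TreeNode("OUT", "R"),
                TreeNode("I", "R", ["T1", "T2"]),
                TreeNode("T1", "I"),
                TreeNode("T2", "I"),
            ]
        )
        aln = {"OUT": "AC", "T1": "AT", "T2": "AC"}
        markers, _ = call_branch_markers(tree, aln, "OUT")
        assert len(markers) == 1
        assert markers[0].branch == "T1" and markers[0].position == 1
        assert markers[0].ancestral == "C" and markers[0].derived == "T"

    def test_homoplasious_column_skipped_and_logged(self, mito_panel):
        aug = inject_homoplasy(mito_panel, 3, seed=50)
        markers, log = call_branch_markers(
            aug.tree, aug.tip_alignment(), aug.outgroup
        )
        assert log.n_homoplasy == 3
        homoplasy_pos = {p for p, _, _, _ in aug.homoplasy_sites}
        assert set(log.homoplasy_columns) == homoplasy_pos
        assert not any(m.position in homoplasy_pos for m in markers)

    def test_gapped_and_multiallelic_columns_skipped(self):
        tree = RootedTree(
            [
                TreeNode("R", None, ["OUT", "I"]),
                TreeNode("OUT", "R"),
                TreeNode("I", "R", ["T1", "T2"]),
                TreeNode("T1", "I"),
                TreeNode("T2", "I"),
            ]
        )
        aln = {"OUT": "A-G", "T1": "CTG", "T2": "G-G"}
        markers, log = call_branch_markers(tree, aln, "OUT")
        assert markers == []
        # col 0: three alleles; col 1: gapped; col 2: invariant
        assert log.n_gapped == 1 and log.n_multiallelic == 1 and log.n_invariant == 1

    def test_missing_outgroup_rejected(self, mito_panel):
        with pytest.raises(ValueError, match="outgroup"):
            call_branch_markers(mito_panel.tree, mito_panel.tip_alignment(), "nope")

    def test_tsv_round_trip(self, panel_and_markers, tmp_path):
        _, markers, _ = panel_and_markers
        markers_to_tsv(markers, tmp_path / "m.tsv")
        assert markers_from_tsv(tmp_path / "m.tsv") == list(markers)


class TestObservations:
    def test_tip_reads_show_path_markers_derived(self, panel_and_markers):
        panel, markers, _ = panel_and_markers
        reads, _ = simulate_mito_reads(
            panel, "T1", 10.0, dmg=DamageModel.none(), seed=51
        )
        obs = collect_observations(reads, panel.root_sequence, markers, 8)
        path = set(panel.tree.branch_path("T1"))
        for m in markers:
            if m.position not in obs.index:
                continue
            row = obs.loc[m.position]
            if m.branch in path:
                assert row.n_derived > 0 and row.n_ancestral == 0
            else:
                assert row.n_derived == 0

    def test_zero_reads_empty_tallies(self, panel_and_markers):
        panel, markers, _ = panel_and_markers
        obs = collect_observations([], panel.root_sequence, markers, 5)
        assert obs.empty or (obs.sum(axis=1) == 0).all()

    def test_n_base_not_tallied(self, panel_and_markers):
        from sedadna.simulate import Read

        panel, markers, _ = panel_and_markers
        m = markers[0]
        lo = max(0, m.position - 20)
        frag = panel.root_sequence[lo : m.position] + "N" + panel.root_sequence[
            m.position + 1 : m.position + 21
        ]
        obs = collect_observations(
            [Read("r1", frag)], panel.root_sequence, markers, 5
        )
        if m.position in obs.index:
            assert obs.loc[m.position].sum() == 0


class TestPlacement:
    def test_tip_source_places_on_terminal_branch(self, panel_and_markers):
        panel, markers, _ = panel_and_markers
        reads, _ = simulate_mito_reads(panel, "T4", 5.0, dmg=DamageModel.none(), seed=52)
        obs = collect_observations(reads, panel.root_sequence, markers, 8)
        p = place_sample(
            panel.tree, markers, obs, min_markers=5, exclude_nodes=["OUT"]
        )
        assert p.node_id == "T4" and not p.ambiguous
        assert p.score >= p.runner_up

    def test_internal_source_places_at_internal_node(self, panel_and_markers):
        panel, markers, _ = panel_and_markers
        internal = [
            n
            for n in panel.tree.preorder()
            if not panel.tree.is_tip(n)
            and n not in (panel.tree.root_id,)
        ]
        source = internal[1]
        reads, _ = simulate_mito_reads(
            panel, source, 8.0, dmg=DamageModel.none(), seed=53
        )
        obs = collect_observations(reads, panel.root_sequence, markers, 8)
        p = place_sample(panel.tree, markers, obs, min_markers=5, exclude_nodes=["OUT"])
        assert p.node_id == source

    def test_shared_stem_support_with_both_clade_conflicts(self):
        # two sister clades under a stem: support on the stem, conflicts at
        # both clades' private markers -> placement at the shared node
        tree = RootedTree(
            [
                TreeNode("R", None, ["OUT", "STEM"]),
                TreeNode("OUT", "R"),
                TreeNode("STEM", "R", ["C1", "C2"]),
                TreeNode("C1", "STEM", ["T1", "T2"]),
                TreeNode("C2", "STEM", ["T3", "T4"]),
                TreeNode("T1", "C1"),
                TreeNode("T2", "C1"),
                TreeNode("T3", "C2"),
                TreeNode("T4", "C2"),
            ]
        )
        markers = [
            BranchMarker("STEM", 0, "A", "C", True),
            BranchMarker("STEM", 1, "A", "C", True),
            BranchMarker("C1", 2, "A", "C", True),
            BranchMarker("C2", 3, "A", "C", True),
        ]
        obs = _observations(markers, derived_at={"STEM"}, ancestral_at={"C1", "C2"})
        p = place_sample(tree, markers, obs, min_markers=2, exclude_nodes=["OUT"])
        assert p.node_id == "STEM" and not p.ambiguous

    def test_equal_sibling_support_ties_to_parent_flagged(self):
        tree = RootedTree(
            [
                TreeNode("R", None, ["OUT", "P"]),
                TreeNode("OUT", "R"),
                TreeNode("P", "R", ["T1", "T2"]),
                TreeNode("T1", "P"),
                TreeNode("T2", "P"),
            ]
        )
        markers = [
            BranchMarker("P", 0, "A", "C", True),
            BranchMarker("T1", 1, "A", "C", True),
            BranchMarker("T2", 2, "A", "C", True),
        ]
        obs = _observations(markers, derived_at={"P", "T1", "T2"})
        p = place_sample(tree, markers, obs, min_markers=1, exclude_nodes=["OUT"])
        assert p.node_id == "P" and p.ambiguous
        # oracle agreement: T1 and T2 tie at the max
        scores = brute_force_scores(tree, p.branch_support, p.branch_conflict)
        best = max(scores.values())
        assert {n for n, s in scores.items() if s == best} == {"T1", "T2"}

    def test_min_markers_gate_unplaced(self, panel_and_markers):
        panel, markers, _ = panel_and_markers
        obs = _observations(markers[:2], derived_at={markers[0].branch})
        p = place_sample(panel.tree, markers, obs, min_markers=10)
        assert p.node_id is None

    def test_path_scores_match_brute_force_on_random_trees(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            panel = simulate_mito_panel(int(rng.integers(4, 14)), 3, 3000, seed=seed)
            support = {
                b: int(rng.integers(0, 4)) for b in panel.branch_sites
            }
            conflict = {
                b: int(rng.integers(0, 3)) for b in panel.branch_sites
            }
            oracle = brute_force_scores(panel.tree, support, conflict)
            for node, expect in oracle.items():
                assert path_score(panel.tree, node, support, conflict) == expect

    def test_transversions_only_ignores_transition_markers(self):
        tree = RootedTree(
            [
                TreeNode("R", None, ["OUT", "I"]),
                TreeNode("OUT", "R"),
                TreeNode("I", "R", ["T1", "T2"]),
                TreeNode("T1", "I"),
                TreeNode("T2", "I"),
            ]
        )
        markers = [
            BranchMarker("T1", 0, "C", "T", False),  # transition (damage-prone)
            BranchMarker("T1", 1, "A", "C", True),
            BranchMarker("T2", 2, "G", "C", True),
        ]
        obs = _observations(markers, derived_at={"T1"}, ancestral_at={"T2"})
        p = place_sample(
            tree, markers, obs, mode="transversions-only", min_markers=1,
            exclude_nodes=["OUT"],
        )
        assert "T1" in p.branch_support and p.branch_support["T1"] == 1  # tv only

    def test_damage_robustness_transversion_markers_keep_no_false_conflicts(
        self, panel_and_markers
    ):
        panel, markers, _ = panel_and_markers
        dmg = DamageModel(p1_ct=0.3, lambda_decay=0.3, seq_error=0.0)
        reads, _ = simulate_mito_reads(panel, "T2", 10.0, dmg=dmg, seed=54)
        obs = collect_observations(reads, panel.root_sequence, markers, 10)
        p = place_sample(
            panel.tree, markers, obs, mode="transversions-only", min_markers=5,
            exclude_nodes=["OUT"],
        )
        path = set(panel.tree.branch_path("T2"))
        tv_by_branch = {}
        for m in markers:
            if m.transversion:
                tv_by_branch.setdefault(m.branch, 0)
        # conflicts at transversion markers only arise off the true path
        for branch, c in p.branch_conflict.items():
            if branch in path:
                assert c == 0


class TestHaplogroups:
    def _placement(self, node):
        from sedadna.placement import Placement

        return Placement("s", node, 1.0, 0.0, {}, {}, 20, False, "all-sites")

    def test_labelled_clade_and_basal_and_unplaced(self, mito_panel):
        tree = mito_panel.tree
        internal = [
            n for n in tree.preorder()
            if not tree.is_tip(n) and n != tree.root_id
        ]
        labels = {internal[1]: "1DE"}
        inside_tip = sorted(tree.clade_tips(internal[1]))[0]
        assert haplogroup_of(self._placement(inside_tip), tree, labels) == "1DE"
        assert haplogroup_of(self._placement(tree.root_id), tree, labels) == "basal"
        assert haplogroup_of(self._placement(None), tree, labels) == "unplaced"
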