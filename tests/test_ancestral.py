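"""Unit and property tests for the Dollo inference engine."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_binary_newick, random_presence
from leca_trace.ancestral import (
    LecaRule,
    build_reports,
    classify_leca,
    dollo_infer,
    dollo_oracle,
    leca_counts,
    map_events,
    mrca,
    tentative_losses,
)
from leca_trace.formats import (
    LecaStatus,
    TaxonMap,
    ValidationError,
    parse_tree,
)
from leca_trace.lineage_summary import binarize


def path_intersection_mrca(tree, tips):
    """Independent MRCA oracle: deepest node on every root-to-tip path."""
    paths = []
    for t in tips:
        node = tree.node(t)
        path = []
        while node is not None:
            path.append(node.label)
            node = node.parent
        paths.append(list(reversed(path)))  # root-first
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # deepest shared = last shared prefix element of any root-first path
    deepest = None
    for label in paths[0]:
        if label in common:
            deepest = label
    return deepest


class TestMrca:
    def test_opisthokonta(self, fig2_tree):
        assert mrca(fig2_tree, ["Metazoa", "Dikarya"]).label == "Opisthokonta"

    def test_all_tips_gives_root(self, fig2_tree):
        assert mrca(fig2_tree, fig2_tree.tip_labels) is fig2_tree.root

    def test_singleton(self, fig2_tree):
        assert mrca(fig2_tree, ["Metazoa"]).label == "Metazoa"

    def test_empty_set_rejected(self, fig2_tree):
        with pytest.raises(ValidationError):
            mrca(fig2_tree, [])

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_path_intersection(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            tree = parse_tree(random_binary_newick(rng, int(rng.integers(3, 12))))
            tips = tree.tip_labels
            k = int(rng.integers(1, len(tips) + 1))
            chosen = list(rng.choice(tips, size=k, replace=False))
            assert mrca(tree, chosen).label == path_intersection_mrca(tree, chosen)


class TestDolloInfer:
    def test_single_lineage_gain(self, fig2_tree):
        presence = {t: int(t == "Metazoa") for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence, "Apc16")
        assert hist.gain_node == "Metazoa"
        assert hist.loss_edges == frozenset()
        assert hist.gain_edge(fig2_tree) == ("Holozoa", "Metazoa")

    def test_all_present_gain_at_root(self, fig2_tree):
        presence = {t: 1 for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence)
        assert hist.gain_node == fig2_tree.root.label
        assert hist.loss_edges == frozenset()

    def test_spec_six_tip_example(self):
        tree = parse_tree("(((A,B),C),((D,E),F));")
        presence = {t: int(t in ("A", "D")) for t in tree.tip_labels}
        hist = dollo_infer(tree, presence)
        assert hist.gain_node == tree.root.label
        loss_children = {child for _, child in hist.loss_edges}
        assert loss_children == {"B", "C", "E", "F"}
        min_losses, _ = dollo_oracle(tree, presence)
        assert min_losses == 4 == hist.n_losses

    def test_all_absent(self, fig2_tree):
        presence = {t: 0 for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence)
        assert hist.gain_node is None
        assert hist.loss_edges == frozenset()
        assert not any(hist.node_states.values())

    def test_tip_mismatch_rejected(self, fig2_tree):
        with pytest.raises(ValidationError, match="presence vector"):
            dollo_infer(fig2_tree, {"Metazoa": 1})

    @pytest.mark.parametrize("seed", range(5))
    def test_properties_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(40):
            tree = parse_tree(random_binary_newick(rng, int(rng.integers(3, 10))))
            presence = random_presence(rng, tree.tip_labels, p=float(rng.uniform(0.2, 0.8)))
            hist = dollo_infer(tree, presence)
            # tip fidelity
            for t in tree.tip_labels:
                assert hist.node_states[t] == bool(presence[t])
            # maximality: no loss edge ancestor of another
            loss_children = [tree.node(c) for _, c in hist.loss_edges]
            for a in loss_children:
                for b in loss_children:
                    if a is not b:
                        assert a not in b.ancestors()
            # single gain conservation
            if any(presence.values()):
                assert hist.gain_node is not None
            else:
                assert hist.gain_node is None
            # oracle equivalence
            min_losses, argmin = dollo_oracle(tree, presence)
            if hist.gain_node is not None:
                assert hist.n_losses == min_losses
                assert hist.gain_node in argmin

    def test_oracle_trivial_cases(self, small_tree):
        all_present = {t: 1 for t in small_tree.tip_labels}
        min_losses, argmin = dollo_oracle(small_tree, all_present)
        assert min_losses == 0
        assert small_tree.root.label in argmin
        # presence confined to one subtree: root never optimal
        one_side = {t: int(t in ("A", "B")) for t in small_tree.tip_labels}
        _, argmin = dollo_oracle(small_tree, one_side)
        assert small_tree.root.label not in argmin

    def test_polytomy_losses_counted_per_child(self):
        tree = parse_tree("((A,B,C,D)P,(E,F)Q);")
        presence = {"A": 1, "B": 0, "C": 0, "D": 1, "E": 0, "F": 0}
        hist = dollo_infer(tree, presence)
        assert hist.gain_node == "P"
        assert {c for _, c in hist.loss_edges} == {"B", "C"}


class TestClassifyLeca:
    def test_scc4_flips_between_modes(self, fig2_tree, table2_profile, taxon_map):
        m = binarize(table2_profile)
        presence = m.presence_of("Scc4")
        hist = dollo_infer(fig2_tree, presence, "Scc4")
        assert classify_leca(hist, presence, taxon_map, LecaRule("MRCA")) == LecaStatus.PRESENT
        assert (
            classify_leca(hist, presence, taxon_map, LecaRule("CONSERVATIVE", 2))
            == LecaStatus.ABSENT
        )

    def test_securin_absent_under_both(self, fig2_tree, table2_profile, taxon_map):
        m = binarize(table2_profile)
        presence = m.presence_of("Securin")
        hist = dollo_infer(fig2_tree, presence, "Securin")
        for rule in (LecaRule("MRCA"), LecaRule("CONSERVATIVE", 2)):
            assert classify_leca(hist, presence, taxon_map, rule) == LecaStatus.ABSENT

    def test_all_absent_is_no_data(self, fig2_tree, taxon_map):
        presence = {t: 0 for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence)
        assert classify_leca(hist, presence, taxon_map) == LecaStatus.NO_DATA

    def test_missing_side_rejected(self, fig2_tree):
        presence = {t: 1 for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence)
        with pytest.raises(ValidationError, match="root side"):
            classify_leca(hist, presence, TaxonMap())

    def test_rule_nesting(self, fig2_tree, combined_profile, taxon_map):
        m = binarize(combined_profile)
        for comp in m.components:
            presence = m.presence_of(comp)
            hist = dollo_infer(fig2_tree, presence, comp)
            cons = classify_leca(hist, presence, taxon_map, LecaRule("CONSERVATIVE", 2))
            mrca_mode = classify_leca(hist, presence, taxon_map, LecaRule("MRCA"))
            if cons == LecaStatus.PRESENT:
                assert mrca_mode == LecaStatus.PRESENT

    def test_invalid_rule(self):
        with pytest.raises(ValidationError):
            LecaRule("BOGUS")
        with pytest.raises(ValidationError):
            LecaRule("MRCA", 0)


class TestMapEvents:
    def test_root_gains_match_mrca_present_count(
        self, fig2_tree, combined_profile, taxon_map, inventory
    ):
        reports, histories = build_reports(
            combined_profile, fig2_tree, taxon_map, LecaRule("MRCA"), inventory=inventory
        )
        counts = map_events(histories, fig2_tree, taxon_map)
        root_edge = (None, fig2_tree.root.label)
        present = leca_counts(reports)[LecaStatus.PRESENT]
        assert counts[root_edge]["gains"] == present == 24

    def test_single_all_present_component(self, fig2_tree):
        presence = {t: 1 for t in fig2_tree.tip_labels}
        hist = dollo_infer(fig2_tree, presence, "x")
        counts = map_events([hist], fig2_tree)
        assert counts == {(None, "LECA"): {"gains": 1, "losses": 0, "tentative_losses": 0}}

    def test_loss_conservation(self, fig2_tree, combined_profile, taxon_map):
        _, histories = build_reports(combined_profile, fig2_tree, taxon_map)
        counts = map_events(histories, fig2_tree)
        total_edges = sum(c["losses"] for c in counts.values())
        total_hist = sum(h.n_losses for h in histories)
        assert total_edges == total_hist

    def test_mixed_trees_rejected(self, fig2_tree, small_tree):
        presence = {t: 1 for t in small_tree.tip_labels}
        hist = dollo_infer(small_tree, presence)
        with pytest.raises(ValidationError, match="different tree"):
            map_events([hist], fig2_tree)

    def test_tentative_losses_require_all_P_subtree(self):
        tree = parse_tree("((A,B)L,(C,D)R,E);")
        taxa = TaxonMap(
            species_lineage={t: t for t in "ABCDE"},
            genome_status={"C": "P", "D": "C"},
        )
        # single-tip loss of an ongoing genome: tentative
        presence = {"A": 1, "B": 1, "C": 0, "D": 1, "E": 1}
        hist = dollo_infer(tree, presence, "g")
        assert hist.loss_edges == frozenset({("R", "C")})
        assert tentative_losses(hist, tree, taxa) == frozenset({("R", "C")})
        # whole-clade loss over mixed statuses: not tentative
        presence2 = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1}
        hist2 = dollo_infer(tree, presence2, "g")
        assert hist2.loss_edges == frozenset({(tree.root.label, "R")})
        assert tentative_losses(hist2, tree, taxa) == frozenset()
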