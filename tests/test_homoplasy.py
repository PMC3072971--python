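import numpy as np
import pandas as pd
import pytest

from spiculevo import (
    AncestralReconstruction,
    CharacterColumn,
    DepthMetadata,
    MkModel,
    call_states,
    count_events,
    homoplasy_report,
    independent_origins,
    marginal_asr,
    parse_newick,
    simulate_loss_scenario,
    simulate_mk_character,
    simulate_tree,
    stratify_by_depth,
)
from spiculevo.homoplasy import HIGH, MODERATE, Call


def recon_from_posteriors(post, k=2, name="c", klass=None):
    post = np.asarray(post, dtype=float)
    return AncestralReconstruction(
        character=name, char_class=klass, k=k, rate=0.1,
        log_likelihood=-1.0, posteriors=post,
    )


def calls_from_states(tree, node_states):
    """Hand-built HIGH calls: node id -> state (None for ambiguous)."""
    return {
        i: Call(s, HIGH) if s is not None else Call(None, None)
        for i, s in node_states.items()
    }


class TestCallStates:
    @pytest.mark.parametrize(
        "post,state,tier",
        [
            ((0.97, 0.03), 0, HIGH),
            ((0.70, 0.30), 0, MODERATE),
            ((0.60, 0.40), None, None),
            ((0.03, 0.97), 1, HIGH),
            ((0.95, 0.05), 0, MODERATE),  # boundary: p == high is MODERATE
            ((0.65, 0.35), None, None),   # boundary: p == moderate is ambiguous
        ],
    )
    def test_threshold_rules(self, post, state, tier):
        rec = recon_from_posteriors([post])
        call = call_states(rec)[0]
        assert (call.state, call.tier) == (state, tier)

    def test_invalid_thresholds_raise(self):
        rec = recon_from_posteriors([(0.9, 0.1)])
        with pytest.raises(ValueError):
            call_states(rec, high=0.6, moderate=0.7)

    def test_tips_called_high_missing_ambiguous(self, three_tip_tree):
        col = CharacterColumn("c", {"A": 0, "B": 1, "C": -1})
        rec = marginal_asr(three_tip_tree, col, MkModel(k=2, rate=0.5))
        calls = call_states(rec)
        tip_ids = {three_tip_tree.tip_label(nd): nd.index
                   for nd in three_tip_tree.postorder() if nd.is_leaf()}
        assert calls[tip_ids["A"]] == Call(0, HIGH)
        assert calls[tip_ids["B"]] == Call(1, HIGH)
        assert calls[tip_ids["C"]].ambiguous


class TestCountEvents:
    def tree(self):
        # postorder ids: A=0 B=1 (AB)=2 C=3 D=4 (CD)=5 (ABCD)=6? depends;
        # resolve ids programmatically in tests instead.
        return parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")

    def node_id(self, tree, tips):
        tips = set(tips)
        for nd in tree.postorder():
            below = (
                {tree.tip_label(nd)} if nd.is_leaf() else tree.leafset_below(nd)
            )
            if below == tips:
                return nd.index
        raise AssertionError(f"no node with tip set {tips}")

    def test_all_present_no_events(self):
        tree = self.tree()
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        assert len(count_events(calls, tree)) == 0

    def test_single_clade_loss_counted_once_on_stem(self):
        tree = self.tree()
        lost = self.node_id(tree, {"A", "B"})
        a, b = self.node_id(tree, {"A"}), self.node_id(tree, {"B"})
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        for i in (lost, a, b):
            calls[i] = Call(0, HIGH)
        ev = count_events(calls, tree, "c", HIGH)
        assert list(ev["event"]) == ["loss"]
        assert int(ev["child"].iloc[0]) == lost  # the stem edge, not deeper ones

    def test_two_disjoint_clades_two_losses(self):
        tree = self.tree()
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        for tips in ({"A", "B"}, {"D", "E"}):
            cid = self.node_id(tree, tips)
            calls[cid] = Call(0, HIGH)
            for t in tips:
                calls[self.node_id(tree, {t})] = Call(0, HIGH)
        ev = count_events(calls, tree, "c", HIGH)
        assert (ev["event"] == "loss").sum() == 2

    def test_ambiguous_node_breaks_chain(self):
        tree = self.tree()
        lost = self.node_id(tree, {"A", "B"})
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        calls[lost] = Call(None, None)  # ambiguous stem
        for t in ("A", "B"):
            calls[self.node_id(tree, {t})] = Call(0, HIGH)
        ev = count_events(calls, tree, "c", HIGH)
        # no event through the ambiguous node: the tip edges hang off an
        # ambiguous parent, and the stem's child is not confidently absent
        assert len(ev) == 0

    def test_moderate_tier_includes_weaker_calls(self):
        tree = self.tree()
        lost = self.node_id(tree, {"A", "B"})
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        calls[lost] = Call(0, MODERATE)
        for t in ("A", "B"):
            calls[self.node_id(tree, {t})] = Call(0, HIGH)
        assert len(count_events(calls, tree, "c", HIGH)) == 0
        ev = count_events(calls, tree, "c", MODERATE)
        assert list(ev["event"]) == ["loss"]
        assert list(ev["tier"]) == [MODERATE]

    def test_tier_monotonicity_on_random_reconstructions(self):
        for seed in range(10):
            tree = simulate_tree(24, seed=seed)
            col = simulate_mk_character(tree, 2, 0.6, seed + 50, "c")
            rec = marginal_asr(tree, col, MkModel(k=2, rate=0.6))
            calls = call_states(rec)
            n_high = len(count_events(calls, tree, "c", HIGH))
            n_mod = len(count_events(calls, tree, "c", MODERATE))
            assert n_high <= n_mod

    def test_maximality_no_nested_same_type_events(self):
        for seed in range(10):
            tree = simulate_tree(32, seed=100 + seed)
            col = simulate_mk_character(tree, 2, 0.8, seed, "c")
            rec = marginal_asr(tree, col, MkModel(k=2, rate=0.8))
            ev = count_events(call_states(rec), tree, "c", MODERATE)
            for etype in ("loss", "gain"):
                children = list(ev[ev["event"] == etype]["child"])
                clades = [tree.leafset_below(tree.node(c))
                          if not tree.node(c).is_leaf()
                          else {tree.tip_label(tree.node(c))}
                          for c in children]
                opposite = [tree.leafset_below(tree.node(c))
                            if not tree.node(c).is_leaf()
                            else {tree.tip_label(tree.node(c))}
                            for c in ev[ev["event"] != etype]["child"]]
                for i in range(len(clades)):
                    for j in range(len(clades)):
                        if i != j and clades[j] < clades[i]:
                            # nested same-type events only via an intervening
                            # opposite event between them
                            assert any(
                                clades[j] <= o < clades[i] for o in opposite
                            )

    def test_duality_losses_of_present_equal_origins_of_absent(self):
        tree = self.tree()
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        for tips in ({"A", "B"}, {"D", "E"}):
            cid = self.node_id(tree, tips)
            calls[cid] = Call(0, HIGH)
            for t in tips:
                calls[self.node_id(tree, {t})] = Call(0, HIGH)
        losses = (count_events(calls, tree, "c", HIGH)["event"] == "loss").sum()
        origins_absent = independent_origins(calls, tree, "c", state=0, tier=HIGH)
        assert losses == origins_absent == 2


class TestIndependentOrigins:
    def test_root_origin_when_fixed_present(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        calls = {nd.index: Call(1, HIGH) for nd in tree.postorder()}
        assert independent_origins(calls, tree, state=1, tier=HIGH) == 1

    def test_two_gain_clades(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        calls = {nd.index: Call(0, HIGH) for nd in tree.postorder()}

        def nid(tips):
            tips = set(tips)
            for nd in tree.postorder():
                below = ({tree.tip_label(nd)} if nd.is_leaf()
                         else tree.leafset_below(nd))
                if below == tips:
                    return nd.index

        for tips in ({"A", "B"}, {"D", "E"}):
            calls[nid(tips)] = Call(1, HIGH)
            for t in tips:
                calls[nid({t})] = Call(1, HIGH)
        assert independent_origins(calls, tree, state=1, tier=HIGH) == 2


class TestStratifyByDepth:
    def setup_events(self):
        tree = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        def nid(tips):
            tips = set(tips)
            for nd in tree.postorder():
                below = ({tree.tip_label(nd)} if nd.is_leaf()
                         else tree.leafset_below(nd))
                if below == tips:
                    return nd.index
        events = pd.DataFrame(
            [
                {"character": "c", "parent": 0, "child": nid({"A", "B"}),
                 "event": "loss", "tier": HIGH},
                {"character": "c", "parent": 0, "child": nid({"D", "E"}),
                 "event": "loss", "tier": HIGH},
            ]
        )
        return tree, events

    def test_consensus_attribution(self):
        tree, events = self.setup_events()
        meta = DepthMetadata(
            {"A": "deep", "B": "deep", "C": "shallow", "D": "shallow", "E": "deep"}
        )
        ev, summary = stratify_by_depth(events, meta, tree)
        assert list(ev["habitat"]) == ["deep", "mixed"]

    def test_both_habit_species_excluded(self):
        tree, events = self.setup_events()
        meta = DepthMetadata(
            {"A": "deep", "B": "both", "C": "shallow", "D": "both", "E": "both"}
        )
        ev, _ = stratify_by_depth(events, meta, tree)
        assert list(ev["habitat"]) == ["deep", "unknown"]

    def test_missing_metadata_names_tip(self):
        tree, events = self.setup_events()
        meta = DepthMetadata({"A": "deep", "B": "deep", "C": "shallow", "D": "shallow"})
        with pytest.raises(ValueError, match="E"):
            stratify_by_depth(events, meta, tree)


class TestHomoplasyReport:
    def test_all_constant_matrix_zero_events(self):
        tree = simulate_tree(16, seed=5)
        meta = DepthMetadata({t: "shallow" for t in tree.tip_labels})
        recons = {}
        for name in ("c1", "c2"):
            col = CharacterColumn(name, {t: 1 for t in tree.tip_labels})
            recons[name] = marginal_asr(tree, col, MkModel(k=2, rate=1e-8))
        rep = homoplasy_report(recons, meta, tree)
        assert rep.per_character[["losses_high", "gains_high"]].to_numpy().sum() == 0
        assert len(rep.events) == 0

    def test_one_planted_loss_per_character_reported(self):
        tree = simulate_tree(48, seed=17)
        meta = DepthMetadata({t: "deep" for t in tree.tip_labels})
        recons = {}
        from spiculevo import MkCharacterModel

        for i in range(4):
            col, _ = simulate_loss_scenario(tree, 1, 3, 300 + i, f"c{i}")
            recons[f"c{i}"] = MkCharacterModel(tree, col).fit().reconstruction()
        rep = homoplasy_report(recons, meta, tree)
        assert list(rep.per_character["losses_moderate"]) == [1, 1, 1, 1]
        assert rep.per_character["gains_moderate"].sum() == 0

    def test_class_totals_are_sums(self, default_fixture):
        from spiculevo import MkCharacterModel

        fx = default_fixture
        recons = {
            c.name: MkCharacterModel(fx.tree, c).fit().reconstruction()
            for c in fx.matrix.columns()
        }
        rep = homoplasy_report(recons, fx.meta, fx.tree)
        for klass in ("megasclere", "microsclere"):
            sub = rep.per_character[rep.per_character["char_class"] == klass]
            tot = rep.class_totals[rep.class_totals["char_class"] == klass]
            assert int(tot["losses_high"].iloc[0]) == int(sub["losses_high"].sum())
            assert int(tot["gains_high"].iloc[0]) == int(sub["gains_high"].sum())
        assert "Homoplasy report" in rep.summary_text()
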