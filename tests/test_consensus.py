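import numpy as np
import pytest

from taxvote.consensus import (
    ConsensusLabel,
    Strategy,
    WeightConfig,
    decide,
    fit_weights,
    merge_all,
    project_vote,
    tally_votes,
)
from taxvote.errors import ConfigError
from taxvote.io_formats import UNKNOWN, AssignmentSet, TruthSet
from taxvote.taxonomy import UNCLASSIFIED

from helpers import oracle_merge_read, random_instance


class TestWeightConfig:
    def test_rejects_negative(self):
        with pytest.raises(ConfigError):
            WeightConfig({"a": -1.0})

    def test_rejects_all_zero(self):
        with pytest.raises(ConfigError):
            WeightConfig({"a": 0.0, "b": 0.0})

    def test_missing_tool_is_config_error(self):
        with pytest.raises(ConfigError, match="no weight"):
            WeightConfig({"a": 1.0})["b"]


class TestProjectVote:
    def test_strain_projects_down_to_species(self, toy_tree):
        assert project_vote(toy_tree, 9, "species") == 5

    def test_above_rank_becomes_unclassified(self, toy_tree):
        assert project_vote(toy_tree, 3, "species") == UNCLASSIFIED

    def test_unclassified_is_fixed_point(self, toy_tree):
        assert project_vote(toy_tree, UNCLASSIFIED, "species") == UNCLASSIFIED


class TestTallyVotes:
    WEIGHTS = WeightConfig({"A": 2.0, "B": 1.0, "C": 1.5})

    def test_recall_hand_tally(self, toy_tree):
        votes = {"A": 5, "B": 6, "C": 6}
        tally = tally_votes(votes, self.WEIGHTS, Strategy.RECALL, "species", toy_tree)
        assert tally == {5: 2.0, 6: 2.5}

    def test_recall_drops_abstentions(self, toy_tree):
        votes = {"A": 5, "B": UNCLASSIFIED, "C": UNCLASSIFIED}
        tally = tally_votes(votes, self.WEIGHTS, Strategy.RECALL, "species", toy_tree)
        assert tally == {5: 2.0}

    def test_precision_pools_abstentions_under_unknown(self, toy_tree):
        votes = {"A": 5, "B": UNCLASSIFIED, "C": UNCLASSIFIED}
        tally = tally_votes(votes, self.WEIGHTS, Strategy.PRECISION, "species", toy_tree)
        assert tally == {5: 2.0, UNKNOWN: 2.5}

    def test_votes_projected_before_tallying(self, toy_tree):
        votes = {"A": 9, "B": 5, "C": 3}  # strain, species, genus
        tally = tally_votes(votes, self.WEIGHTS, Strategy.RECALL, "species", toy_tree)
        assert tally == {5: 3.0}  # genus vote is above species -> dropped

    def test_raw_voting_behind_flag(self, toy_tree):
        votes = {"A": 9, "B": 5, "C": 3}
        tally = tally_votes(
            votes, self.WEIGHTS, Strategy.RECALL, "species", toy_tree, project=False
        )
        assert tally == {9: 2.0, 5: 1.0, 3: 1.5}


class TestDecide:
    def test_argmax(self, toy_tree):
        label = decide({5: 2.0, 6: 2.5}, Strategy.RECALL, toy_tree, read_id="r")
        assert label == ConsensusLabel("r", 6, 2.5)

    def test_unknown_needs_strict_win(self, toy_tree):
        label = decide({5: 2.0, UNKNOWN: 2.5}, Strategy.PRECISION, toy_tree)
        assert label.verdict == UNKNOWN
        tied = decide({5: 2.5, UNKNOWN: 2.5}, Strategy.PRECISION, toy_tree)
        assert tied.verdict == 5 and tied.tie_resolved

    def test_tied_taxids_collapse_to_lca(self, toy_tree):
        label = decide({5: 1.0, 6: 1.0}, Strategy.RECALL, toy_tree)
        assert label.verdict == 3 and label.tie_resolved

    def test_tie_lca_at_root_is_unclassified(self):
        from taxvote.taxonomy import TaxonomyTree

        # two superkingdoms that only meet at the root
        tree = TaxonomyTree({1: (1, "no rank"), 2: (1, "superkingdom"), 3: (1, "superkingdom")})
        label = decide({2: 1.0, 3: 1.0}, Strategy.RECALL, tree, read_id="r")
        assert label.verdict == UNCLASSIFIED and label.tie_resolved

    def test_empty_tally_is_unclassified(self, toy_tree):
        assert decide({}, Strategy.RECALL, toy_tree).verdict == UNCLASSIFIED


class TestMergeAll:
    def test_single_tool_identity(self, toy_tree):
        aset = AssignmentSet("solo", {"r1": 9, "r2": UNCLASSIFIED, "r3": 6})
        result = merge_all([aset], toy_tree, target_rank="species")
        assert result.assignments.assignments == {"r1": 5, "r2": UNCLASSIFIED, "r3": 6}

    def test_unanimity_gives_sum_of_weights(self, toy_tree):
        sets = [AssignmentSet(f"t{i}", {"r": 5}) for i in range(3)]
        weights = WeightConfig({"t0": 1.0, "t1": 2.0, "t2": 0.5})
        result = merge_all(sets, toy_tree, weights=weights)
        assert result.labels["r"] == ConsensusLabel("r", 5, 3.5)

    def test_missing_read_counts_as_unclassified_vote(self, toy_tree):
        sets = [AssignmentSet("a", {"r": 5}), AssignmentSet("b", {})]
        recall = merge_all(sets, toy_tree, strategy="merge")
        assert recall.tallies["r"] == {5: 1.0}
        precision = merge_all(sets, toy_tree, strategy="merge_p")
        assert precision.tallies["r"] == {5: 1.0, UNKNOWN: 1.0}

    def test_empty_tool_list_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            merge_all([], toy_tree)

    def test_duplicate_tool_names_rejected(self, toy_tree):
        sets = [AssignmentSet("a", {"r": 5}), AssignmentSet("a", {"r": 6})]
        with pytest.raises(ConfigError, match="duplicate"):
            merge_all(sets, toy_tree)

    def test_strict_unanimity_flag(self, toy_tree):
        sets = [
            AssignmentSet("a", {"r": 5, "s": 5}),
            AssignmentSet("b", {"r": 6, "s": 5}),
            AssignmentSet("c", {"r": 5, "s": UNCLASSIFIED}),
        ]
        result = merge_all(sets, toy_tree, unanimity=True)
        assert result.assignments.assignments["r"] == UNCLASSIFIED  # split vote
        assert result.assignments.assignments["s"] == 5  # abstention is not dissent


class TestOracleEquivalence:
    """merge_all against the independent brute-force enumerator."""

    @pytest.mark.parametrize("strategy", ["merge", "merge_p"])
    def test_random_instances_match_oracle(self, toy_tree, strategy):
        rng = np.random.default_rng(42)
        for _ in range(300):
            votes, weights = random_instance(rng, toy_tree)
            sets = [AssignmentSet(t, {"r": v}) for t, v in votes.items()]
            result = merge_all(
                sets, toy_tree, weights=weights, strategy=strategy, target_rank="species"
            )
            expected = oracle_merge_read(toy_tree, votes, weights, strategy, "species")
            assert result.assignments.assignments["r"] == expected
            # argmax certificate
            tally = result.tallies["r"]
            if tally:
                assert result.labels["r"].winning_weight == max(tally.values())

    @pytest.mark.parametrize("strategy", ["merge", "merge_p"])
    def test_weight_scale_invariance(self, toy_tree, strategy):
        rng = np.random.default_rng(7)
        for _ in range(100):
            votes, weights = random_instance(rng, toy_tree)
            sets = [AssignmentSet(t, {"r": v}) for t, v in votes.items()]
            base = merge_all(sets, toy_tree, weights=weights, strategy=strategy)
            for c in (0.25, 4.0):
                scaled = merge_all(
                    sets, toy_tree,
                    weights={t: w * c for t, w in weights.items()},
                    strategy=strategy,
                )
                assert scaled.assignments.assignments == base.assignments.assignments

    @pytest.mark.parametrize("strategy", ["merge", "merge_p"])
    def test_tool_order_permutation_invariance(self, toy_tree, strategy):
        rng = np.random.default_rng(11)
        for _ in range(100):
            votes, weights = random_instance(rng, toy_tree)
            sets = [AssignmentSet(t, {"r": v}) for t, v in votes.items()]
            base = merge_all(sets, toy_tree, weights=weights, strategy=strategy)
            perm = list(sets)
            rng.shuffle(perm)
            permuted = merge_all(perm, toy_tree, weights=weights, strategy=strategy)
            assert permuted.assignments.assignments == base.assignments.assignments

    def test_precision_containment(self, toy_tree):
        rng = np.random.default_rng(23)
        for _ in range(200):
            votes, weights = random_instance(rng, toy_tree)
            sets = [AssignmentSet(t, {"r": v}) for t, v in votes.items()]
            recall = merge_all(sets, toy_tree, weights=weights, strategy="merge")
            precision = merge_all(sets, toy_tree, weights=weights, strategy="merge_p")
            verdict_p = precision.assignments.assignments["r"]
            if verdict_p > 0:
                assert recall.assignments.assignments["r"] == verdict_p


class TestFitWeights:
    def _sets_with_accuracy(self, n_correct, n_total, tool):
        # truth: all reads are species 5; wrong calls go to sibling 6
        assignments = {
            f"r{i}": (5 if i < n_correct else 6) for i in range(n_total)
        }
        return AssignmentSet(tool, assignments)

    def test_accuracy_proportional_normalized(self, toy_tree):
        truth = TruthSet({f"r{i}": (5, False) for i in range(20)})
        sets = [
            self._sets_with_accuracy(18, 20, "good"),
            self._sets_with_accuracy(9, 20, "meh"),
        ]
        weights = fit_weights(sets, truth, "species", toy_tree)
        assert weights["good"] == pytest.approx(1.0)
        assert weights["meh"] == pytest.approx(0.5)

    def test_single_tool_gets_one(self, toy_tree):
        truth = TruthSet({"r0": (5, False)})
        weights = fit_weights([AssignmentSet("solo", {"r0": 5})], truth, "species", toy_tree)
        assert weights["solo"] == 1.0

    def test_zero_accuracy_tool_gets_zero(self, toy_tree):
        truth = TruthSet({f"r{i}": (5, False) for i in range(4)})
        sets = [
            self._sets_with_accuracy(4, 4, "good"),
            self._sets_with_accuracy(0, 4, "bad"),
        ]
        weights = fit_weights(sets, truth, "species", toy_tree)
        assert weights["bad"] == 0.0

    def test_all_zero_falls_back_to_equal(self, toy_tree, caplog):
        truth = TruthSet({f"r{i}": (5, False) for i in range(4)})
        sets = [self._sets_with_accuracy(0, 4, "a"), self._sets_with_accuracy(0, 4, "b")]
        with caplog.at_level("WARNING"):
            weights = fit_weights(sets, truth, "species", toy_tree)
        assert weights["a"] == weights["b"] == 1.0

    def test_empty_truth_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            fit_weights([AssignmentSet("a", {})], TruthSet({}), "species", toy_tree)
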