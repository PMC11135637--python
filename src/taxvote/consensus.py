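"""Weighted-voting integration of per-read classifier outputs.

Two strategies are offered:

* ``RECALL`` ("merge"): unclassified votes are dropped from the tally, so
  any tool that assigns a taxon can carry a read. High recall.
* ``PRECISION`` ("merge_p"): unclassified votes accumulate under an
  UNKNOWN candidate; when that candidate strictly wins the vote, the read
  is called unknown. High precision on organisms missing from references.

Every vote is projected to the target rank before tallying (tools emit
mixed depths — strains, species, genera), the candidate with the highest
aggregate weight wins, and tied leading taxids collapse to their lowest
common ancestor (to the unclassified verdict if that LCA is the root).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .io_formats import UNKNOWN, AssignmentSet, TruthSet
from .taxonomy import UNCLASSIFIED, TaxonomyTree

log = logging.getLogger(__name__)


class Strategy(Enum):
    RECALL = "merge"
    PRECISION = "merge_p"


def resolve_strategy(value) -> Strategy:
    if isinstance(value, Strategy):
        return value
    for s in Strategy:
        if value in (s.value, s.name, s.name.lower()):
            return s
    raise ConfigError(f"unknown strategy {value!r}; expected 'merge' or 'merge_p'")


@dataclass(frozen=True)
class WeightConfig:
    """Per-tool nonnegative vote weights; at least one must be positive."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ConfigError("weight config is empty")
        for tool, w in self.weights.items():
            if not math.isfinite(w) or w < 0:
                raise ConfigError(f"weight for {tool!r} must be finite and >= 0, got {w}")
        if not any(w > 0 for w in self.weights.values()):
            raise ConfigError("at least one tool weight must be strictly positive")

    @classmethod
    def equal(cls, tool_names: Iterable[str]) -> "WeightConfig":
        return cls({name: 1.0 for name in tool_names})

    def __getitem__(self, tool: str) -> float:
        try:
            return self.weights[tool]
        except KeyError:
            raise ConfigError(f"no weight configured for tool {tool!r}") from None

    def __contains__(self, tool: str) -> bool:
        return tool in self.weights

    def items(self):
        return self.weights.items()

    def scaled(self, factor: float) -> "WeightConfig":
        return WeightConfig({t: w * factor for t, w in self.weights.items()})


@dataclass(frozen=True)
class ConsensusLabel:
    """Verdict for one read: a taxid, UNCLASSIFIED (0) or UNKNOWN (-1)."""

    read_id: str
    verdict: int
    winning_weight: float
    tie_resolved: bool = False


@dataclass
class MergeResult:
    assignments: AssignmentSet
    labels: dict[str, ConsensusLabel]
    tallies: dict[str, dict[int, float]] = field(default_factory=dict)


def project_vote(
    tree: TaxonomyTree, label: int, target_rank: str
) -> int:
    """Project a vote to the target rank; above-rank assignments become
    unclassified (a genus call cannot vote at species level)."""
    if label == UNCLASSIFIED:
        return UNCLASSIFIED
    ancestor = tree.ancestor_at_rank(label, target_rank)
    return UNCLASSIFIED if ancestor is None else ancestor


def tally_votes(
    votes: Mapping[str, int],
    weights: WeightConfig,
    strategy: Strategy | str,
    target_rank: str,
    tree: TaxonomyTree,
    project: bool = True,
    _projection_cache: dict[int, int] | None = None,
) -> dict[int, float]:
    """Aggregate one read's per-tool labels into candidate -> weight.

    Under RECALL unclassified votes contribute nothing; under PRECISION
    they accumulate under the UNKNOWN candidate. Tools are visited in
    sorted name order so float accumulation is independent of input order.
    """
    strategy = resolve_strategy(strategy)
    cache = _projection_cache if _projection_cache is not None else {}
    tally: dict[int, float] = {}
    for tool in sorted(votes):
        label = votes[tool]
        weight = weights[tool]
        if project and label != UNCLASSIFIED:
            try:
                label = cache[label]
            except KeyError:
                cache[label] = project_vote(tree, label, target_rank)
                label = cache[label]
        if label == UNCLASSIFIED:
            if strategy is Strategy.PRECISION:
                tally[UNKNOWN] = tally.get(UNKNOWN, 0.0) + weight
            continue
        tally[label] = tally.get(label, 0.0) + weight
    return tally


def decide(
    tally: Mapping[int, float],
    strategy: Strategy | str,
    tree: TaxonomyTree,
    read_id: str = "",
) -> ConsensusLabel:
    """Pick the verdict: argmax by aggregate weight.

    An empty tally yields UNCLASSIFIED. UNKNOWN wins only by strict
    maximum (a tie between UNKNOWN and a taxid resolves to the taxid);
    tied leading taxids are replaced by their LCA, and by UNCLASSIFIED
    when that LCA is the root.
    """
    resolve_strategy(strategy)  # validated for interface symmetry
    if not tally:
        return ConsensusLabel(read_id, UNCLASSIFIED, 0.0)
    winning_weight = max(tally.values())
    winners = sorted(label for label, w in tally.items() if w == winning_weight)
    taxid_winners = [label for label in winners if label != UNKNOWN]
    if not taxid_winners:
        return ConsensusLabel(read_id, UNKNOWN, winning_weight)
    if len(taxid_winners) == 1:
        return ConsensusLabel(
            read_id, taxid_winners[0], winning_weight, tie_resolved=len(winners) > 1
        )
    ancestor = tree.lca(taxid_winners)
    verdict = UNCLASSIFIED if ancestor == tree.root else ancestor
    return ConsensusLabel(read_id, verdict, winning_weight, tie_resolved=True)


def merge_all(
    tool_sets: Sequence[AssignmentSet],
    tree: TaxonomyTree,
    weights: WeightConfig | Mapping[str, float] | None = None,
    strategy: Strategy | str = Strategy.RECALL,
    target_rank: str = "species",
    project: bool = True,
    unanimity: bool = False,
) -> MergeResult:
    """Build the consensus over the union of read_ids of all tool sets.

    A read absent from one tool's set counts as an unclassified vote from
    that tool. With ``unanimity=True`` (off by default) a read is only
    assigned when all classified votes agree on a single projected taxon.
    """
    if not tool_sets:
        raise ValueError("merge_all needs at least one tool set")
    names = [s.tool_name for s in tool_sets]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate tool names in merge input: {names}")
    strategy = resolve_strategy(strategy)
    if weights is None:
        weights = WeightConfig.equal(names)
    elif not isinstance(weights, WeightConfig):
        weights = WeightConfig(dict(weights))
    for name in names:
        weights[name]  # raises ConfigError when a voting tool has no weight

    by_name = {s.tool_name: s for s in sorted(tool_sets, key=lambda s: s.tool_name)}
    all_reads = sorted(set().union(*(s.assignments.keys() for s in tool_sets)))

    cache: dict[int, int] = {}
    labels: dict[str, ConsensusLabel] = {}
    tallies: dict[str, dict[int, float]] = {}
    assignments: dict[str, int] = {}
    for read_id in all_reads:
        votes = {name: s.assignments.get(read_id, UNCLASSIFIED) for name, s in by_name.items()}
        tally = tally_votes(
            votes, weights, strategy, target_rank, tree,
            project=project, _projection_cache=cache,
        )
        if unanimity and len([c for c in tally if c != UNKNOWN]) > 1:
            label = ConsensusLabel(read_id, UNCLASSIFIED, 0.0)
        else:
            label = decide(tally, strategy, tree, read_id=read_id)
        labels[read_id] = label
        tallies[read_id] = tally
        assignments[read_id] = label.verdict

    name = "merge" if strategy is Strategy.RECALL else "merge_p"
    return MergeResult(
        assignments=AssignmentSet(tool_name=name, assignments=assignments),
        labels=labels,
        tallies=tallies,
    )


def fit_weights(
    tool_sets: Sequence[AssignmentSet],
    truth: TruthSet,
    target_rank: str,
    tree: TaxonomyTree,
) -> WeightConfig:
    """Accuracy-proportional weights from a tuning set.

    Each tool's weight is its accuracy at ``target_rank`` on ``truth``,
    normalized so the best tool gets 1.0. If every tool scores zero, equal
    weights are returned with a warning. This is optional tooling — weights
    are normally supplied by the user.
    """
    from .evaluation import confusion_at_rank  # local import avoids a cycle

    if not tool_sets:
        raise ValueError("fit_weights needs at least one tool set")
    if len(truth) == 0:
        raise ValueError("fit_weights needs a non-empty truth set")
    accuracies: dict[str, float] = {}
    for aset in tool_sets:
        conf = confusion_at_rank(aset, truth, target_rank, tree)
        accuracies[aset.tool_name] = (conf.tp + conf.tn) / conf.n_total
    best = max(accuracies.values())
    if best == 0:
        log.warning("all tools scored zero accuracy; falling back to equal weights")
        return WeightConfig.equal(accuracies)
    return WeightConfig({tool: acc / best for tool, acc in accuracies.items()})
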