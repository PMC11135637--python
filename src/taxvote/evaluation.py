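"""Rank-resolved scoring of assignment sets against ground truth.

Simulated reads all have a target organism, so the classical confusion
matrix degenerates: with no out-of-reference reads there are no true
negatives, and the false-positive rate is therefore redefined as the
fraction of *all* evaluated reads assigned to a wrong taxon (FP / total).

Per-read accounting at a rank:

* in-reference read — prediction projects to the truth projection -> TP;
  abstention (unclassified/unknown, or assignment above the rank) -> FN;
  any other taxon -> FP.
* out-of-reference read (flagged in truth) — abstention -> TN; any
  assigned taxon -> FP.

The out-of-reference branch generalizes the degenerate matrix and reduces
exactly to it when no read carries the flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import EvaluationError
from .io_formats import UNKNOWN, AssignmentSet, TruthSet
from .taxonomy import UNCLASSIFIED, TaxonomyTree


@dataclass(frozen=True)
class RankConfusion:
    tp: int
    fp: int
    fn: int
    tn: int
    rank: str
    n_total: int

    def __post_init__(self) -> None:
        if self.tp + self.fp + self.fn + self.tn != self.n_total:
            raise ValueError("confusion counts must sum to n_total")


@dataclass(frozen=True)
class Metrics:
    """Accuracy, precision, recall and the modified FPR.

    Zero-denominator precision/recall are ``None`` (serialized null),
    never 0 — an abstainer must not be rewarded with a perfect score.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    fpr: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "fpr": self.fpr,
        }


def confusion_at_rank(
    assignments: AssignmentSet,
    truth: TruthSet,
    rank: str,
    tree: TaxonomyTree,
) -> RankConfusion:
    """Tally TP/FP/FN/TN for one assignment set at one rank.

    Every read in ``truth`` is scored; reads present in truth but absent
    from the assignments count as unclassified (FN in-reference, TN
    out-of-reference). A read in the assignments but missing from truth is
    an error.
    """
    extra = set(assignments.assignments) - set(truth.records)
    if extra:
        raise EvaluationError(
            f"{len(extra)} read(s) in assignments missing from truth, "
            f"e.g. {sorted(extra)[:3]}"
        )

    proj_cache: dict[int, int | None] = {}

    def project(taxid: int) -> int | None:
        try:
            return proj_cache[taxid]
        except KeyError:
            proj_cache[taxid] = tree.ancestor_at_rank(taxid, rank)
            return proj_cache[taxid]

    tp = fp = fn = tn = 0
    for read_id, (true_taxid, out_of_reference) in truth.records.items():
        predicted = assignments.assignments.get(read_id, UNCLASSIFIED)
        abstained = predicted in (UNCLASSIFIED, UNKNOWN)
        if out_of_reference:
            if abstained:
                tn += 1
            else:
                fp += 1
            continue
        true_proj = project(true_taxid)
        if true_proj is None:
            raise EvaluationError(
                f"truth taxid {true_taxid} for read {read_id!r} does not "
                f"project at rank {rank!r}"
            )
        if abstained:
            fn += 1
            continue
        pred_proj = project(predicted)
        if pred_proj is None:
            fn += 1  # assignment sits above the rank: nothing asserted here
        elif pred_proj == true_proj:
            tp += 1
        else:
            fp += 1
    return RankConfusion(tp=tp, fp=fp, fn=fn, tn=tn, rank=rank, n_total=len(truth))


def metrics(confusion: RankConfusion) -> Metrics:
    n = confusion.n_total
    if n <= 0:
        raise ValueError("metrics need n_total > 0")
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    return Metrics(
        accuracy=(tp + tn) / n,
        precision=tp / (tp + fp) if tp + fp > 0 else None,
        recall=tp / (tp + fn) if tp + fn > 0 else None,
        fpr=fp / n,
    )


def evaluate_many(
    tool_sets: Sequence[AssignmentSet],
    truth: TruthSet,
    ranks: Sequence[str],
    tree: TaxonomyTree,
) -> dict[str, dict[str, Metrics]]:
    """Metrics for every (tool set, rank) pair: tool -> rank -> Metrics."""
    table: dict[str, dict[str, Metrics]] = {}
    for aset in tool_sets:
        table[aset.tool_name] = {
            rank: metrics(confusion_at_rank(aset, truth, rank, tree)) for rank in ranks
        }
    return table
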