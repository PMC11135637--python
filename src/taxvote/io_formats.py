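"""Readers and writers for per-read classifier outputs, truth and reports.

Supported classifier-output dialects (column maps are bit-exact, extra
columns ignored):

============  ===================================================================
kraken2       5 TSV cols: C/U flag, read_id, taxid, length, k-mer string
centrifuge    TSV with header; cols readID, seqID, taxID, score, ...;
              multiple rows per read allowed (collapsed to their LCA);
              seqID "unclassified" or taxid 0 means unclassified
kaiju         3+ TSV cols: C/U flag, read_id, taxid
clark         CSV: Object_ID, Length, Assignment; "NA" means unclassified
generic_tsv   2 TSV cols: read_id, taxid; taxid 0 means unclassified
============  ===================================================================

Reads are never touched: these files carry labels only.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .errors import ConfigError, ParseError
from .taxonomy import UNCLASSIFIED, TaxonomyTree, _iter_lines, load_taxonomy

log = logging.getLogger(__name__)

DIALECTS = ("kraken2", "centrifuge", "kaiju", "clark", "generic_tsv")

#: Conventional file extension per dialect (used by fixture emission).
DIALECT_EXTENSIONS = {
    "kraken2": ".kraken2",
    "centrifuge": ".centrifuge.tsv",
    "kaiju": ".kaiju.out",
    "clark": ".clark.csv",
    "generic_tsv": ".tsv",
}

#: Sentinel used by the consensus for "unknown organism" verdicts. Kept
#: negative so it can never collide with a real taxid; assignment sets
#: produced by parsers only ever contain UNCLASSIFIED or positive taxids.
UNKNOWN = -1


@dataclass
class AssignmentSet:
    """One tool's (or the consensus') per-read label map.

    Labels are positive taxids, :data:`~taxvote.taxonomy.UNCLASSIFIED` (0)
    or — for consensus sets only — :data:`UNKNOWN` (-1).
    """

    tool_name: str
    assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for read, label in self.assignments.items():
            if not isinstance(label, int) or label < UNKNOWN:
                raise ValueError(f"invalid label {label!r} for read {read!r}")

    def __len__(self) -> int:
        return len(self.assignments)

    def get(self, read_id: str, default: int = UNCLASSIFIED) -> int:
        return self.assignments.get(read_id, default)


@dataclass
class TruthSet:
    """Ground truth: read_id -> (true taxid, out-of-reference flag)."""

    records: dict[str, tuple[int, bool]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def taxid(self, read_id: str) -> int:
        return self.records[read_id][0]

    def is_out_of_reference(self, read_id: str) -> bool:
        return self.records[read_id][1]


# -- classifier-output parsing ------------------------------------------------


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"non-integer {what}: {text!r}", lineno) from None


def _iter_kraken2(lines) -> Iterator[tuple[int, str, int]]:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError("kraken2 row needs at least 3 tab-separated fields", lineno)
        flag, read_id = fields[0], fields[1]
        if flag not in ("C", "U"):
            raise ParseError(f"kraken2 classified flag must be C or U, got {flag!r}", lineno)
        taxid = _parse_int(fields[2], "taxid", lineno)
        yield lineno, read_id, UNCLASSIFIED if flag == "U" or taxid == 0 else taxid


def _iter_kaiju(lines) -> Iterator[tuple[int, str, int]]:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError("kaiju row needs at least 2 tab-separated fields", lineno)
        flag, read_id = fields[0], fields[1]
        if flag not in ("C", "U"):
            raise ParseError(f"kaiju classified flag must be C or U, got {flag!r}", lineno)
        if flag == "U":
            yield lineno, read_id, UNCLASSIFIED
            continue
        if len(fields) < 3:
            raise ParseError("classified kaiju row lacks a taxid field", lineno)
        taxid = _parse_int(fields[2], "taxid", lineno)
        yield lineno, read_id, UNCLASSIFIED if taxid == 0 else taxid


def _iter_centrifuge(lines) -> Iterator[tuple[int, str, int]]:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if lineno == 1 and fields[0] == "readID":
            continue
        if len(fields) < 3:
            raise ParseError("centrifuge row needs at least 3 tab-separated fields", lineno)
        read_id, seq_id = fields[0], fields[1]
        taxid = _parse_int(fields[2], "taxid", lineno)
        if seq_id == "unclassified" or taxid == 0:
            yield lineno, read_id, UNCLASSIFIED
        else:
            yield lineno, read_id, taxid


def _iter_clark(lines) -> Iterator[tuple[int, str, int]]:
    reader = csv.reader(lines)
    for lineno, row in enumerate(reader, start=1):
        if not row or not "".join(row).strip():
            continue
        if lineno == 1 and row[0].strip() == "Object_ID":
            continue
        if len(row) < 3:
            raise ParseError("clark row needs at least 3 comma-separated fields", lineno)
        read_id, assignment = row[0].strip(), row[2].strip()
        if assignment == "NA":
            yield lineno, read_id, UNCLASSIFIED
        else:
            yield lineno, read_id, _parse_int(assignment, "assignment", lineno)


def _iter_generic(lines) -> Iterator[tuple[int, str, int]]:
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError("generic row needs 2 tab-separated fields", lineno)
        taxid = _parse_int(fields[1], "taxid", lineno)
        yield lineno, fields[0], UNCLASSIFIED if taxid == 0 else taxid


_DIALECT_ITERATORS = {
    "kraken2": _iter_kraken2,
    "centrifuge": _iter_centrifuge,
    "kaiju": _iter_kaiju,
    "clark": _iter_clark,
    "generic_tsv": _iter_generic,
}

#: Dialects in which one read may legitimately occupy several rows.
_MULTIHIT_DIALECTS = frozenset({"centrifuge"})


def parse_classifier_output(
    source,
    dialect: str,
    tool_name: str,
    tree: TaxonomyTree | None = None,
    on_unknown_taxid: str = "demote",
) -> AssignmentSet:
    """Parse one tool's per-read output into an :class:`AssignmentSet`.

    Multi-hit reads (centrifuge) are collapsed to the LCA of their candidate
    taxids, which requires ``tree``. Taxids absent from ``tree`` are demoted
    to unclassified with a warning by default; ``on_unknown_taxid="strict"``
    raises instead.
    """
    if dialect not in DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if on_unknown_taxid not in ("demote", "strict"):
        raise ConfigError(f"on_unknown_taxid must be 'demote' or 'strict'")

    multihit = dialect in _MULTIHIT_DIALECTS
    candidates: dict[str, set[int]] = {}
    single: dict[str, int] = {}
    n_demoted = 0

    for lineno, read_id, label in _DIALECT_ITERATORS[dialect](_iter_lines(source)):
        if label != UNCLASSIFIED and tree is not None and label not in tree:
            if on_unknown_taxid == "strict":
                raise ParseError(f"taxid {label} not in the loaded taxonomy", lineno)
            n_demoted += 1
            label = UNCLASSIFIED
        if multihit:
            bucket = candidates.setdefault(read_id, set())
            if label != UNCLASSIFIED:
                bucket.add(label)
        else:
            if read_id in single and single[read_id] != label:
                raise ParseError(
                    f"duplicate read {read_id!r} with conflicting labels", lineno
                )
            single[read_id] = label

    if n_demoted:
        log.warning(
            "%s: demoted %d assignments with taxids absent from the taxonomy",
            tool_name,
            n_demoted,
        )

    if multihit:
        assignments: dict[str, int] = {}
        for read_id, taxids in candidates.items():
            if not taxids:
                assignments[read_id] = UNCLASSIFIED
            elif len(taxids) == 1:
                assignments[read_id] = next(iter(taxids))
            else:
                if tree is None:
                    raise ConfigError(
                        f"read {read_id!r} has multiple hits; a taxonomy is "
                        "required to collapse them to their LCA"
                    )
                assignments[read_id] = tree.lca(taxids)
    else:
        assignments = single

    return AssignmentSet(tool_name=tool_name, assignments=assignments)


def write_classifier_output(sink, aset: AssignmentSet, dialect: str) -> None:
    """Serialize an assignment set in a given dialect (rows sorted by read)."""
    if dialect not in DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    items = sorted(aset.assignments.items())
    if dialect == "kraken2":
        for read_id, label in items:
            if label > 0:
                sink.write(f"C\t{read_id}\t{label}\t150\t{label}:1\n")
            else:
                sink.write(f"U\t{read_id}\t0\t150\t\n")
    elif dialect == "centrifuge":
        sink.write("readID\tseqID\ttaxID\tscore\n")
        for read_id, label in items:
            if label > 0:
                sink.write(f"{read_id}\tseq{label}\t{label}\t100\n")
            else:
                sink.write(f"{read_id}\tunclassified\t0\t0\n")
    elif dialect == "kaiju":
        for read_id, label in items:
            if label > 0:
                sink.write(f"C\t{read_id}\t{label}\n")
            else:
                sink.write(f"U\t{read_id}\t0\n")
    elif dialect == "clark":
        sink.write("Object_ID,Length,Assignment\n")
        for read_id, label in items:
            sink.write(f"{read_id},150,{label if label > 0 else 'NA'}\n")
    else:  # generic_tsv
        for read_id, label in items:
            sink.write(f"{read_id}\t{label if label > 0 else 0}\n")


# -- truth --------------------------------------------------------------------


def parse_truth(source) -> TruthSet:
    """Parse a 2-3 column TSV: read_id, true taxid, optional 0/1 flag."""
    records: dict[str, tuple[int, bool]] = {}
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ParseError("truth row needs at least 2 tab-separated fields", lineno)
        read_id = fields[0]
        taxid = _parse_int(fields[1], "taxid", lineno)
        flag = False
        if len(fields) >= 3 and fields[2].strip():
            if fields[2].strip() not in ("0", "1"):
                raise ParseError(
                    f"out-of-reference flag must be 0 or 1, got {fields[2]!r}", lineno
                )
            flag = fields[2].strip() == "1"
        if read_id in records:
            raise ParseError(f"duplicate read_id {read_id!r} in truth", lineno)
        records[read_id] = (taxid, flag)
    return TruthSet(records)


def write_truth(sink, truth: TruthSet) -> None:
    for read_id in sorted(truth.records):
        taxid, flag = truth.records[read_id]
        sink.write(f"{read_id}\t{taxid}\t{1 if flag else 0}\n")


# -- consensus / metrics output ----------------------------------------------


def write_consensus(
    sink,
    consensus: AssignmentSet,
    tallies: Mapping[str, Mapping[int, float]] | None = None,
) -> None:
    """Write the consensus as TSV: read_id, label, reason, winning_weight.

    Both abstention verdicts serialize as label "U"; the reason column
    distinguishes plain unclassified from a winning unknown vote.
    """
    sink.write("read_id\tlabel\treason\twinning_weight\n")
    for read_id in sorted(consensus.assignments):
        label = consensus.assignments[read_id]
        if label == UNKNOWN:
            label_txt, reason = "U", "unknown_weight"
        elif label == UNCLASSIFIED:
            label_txt, reason = "U", "unclassified"
        else:
            label_txt, reason = str(label), ""
        weight_txt = ""
        if tallies is not None:
            tally = tallies.get(read_id, {})
            weight_txt = f"{max(tally.values()):.10g}" if tally else "0"
        sink.write(f"{read_id}\t{label_txt}\t{reason}\t{weight_txt}\n")


def _metrics_to_dict(m) -> dict:
    if hasattr(m, "as_dict"):
        return m.as_dict()
    return dict(m)


def write_metrics(sink, table: Mapping[str, Mapping[str, object]], fmt: str = "json") -> None:
    """Write a tool -> rank -> metrics table as JSON or TSV.

    Undefined metrics (zero denominators) serialize as JSON ``null`` /
    TSV ``NA`` — never as 0.
    """
    if fmt == "json":
        obj = {
            tool: {rank: _metrics_to_dict(m) for rank, m in by_rank.items()}
            for tool, by_rank in table.items()
        }
        json.dump(obj, sink, indent=2, sort_keys=True)
        sink.write("\n")
    elif fmt == "tsv":
        sink.write("tool\trank\taccuracy\tprecision\trecall\tfpr\n")
        for tool in sorted(table):
            for rank in sorted(table[tool]):
                d = _metrics_to_dict(table[tool][rank])
                cells = [
                    "NA" if d[k] is None else f"{d[k]:.10g}"
                    for k in ("accuracy", "precision", "recall", "fpr")
                ]
                sink.write(f"{tool}\t{rank}\t" + "\t".join(cells) + "\n")
    else:
        raise ConfigError(f"unknown metrics format {fmt!r}; expected 'json' or 'tsv'")


def read_metrics(source) -> dict:
    """Read back a JSON metrics report (round-trip partner of write_metrics)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return json.load(fh)
    return json.load(source)


# -- run configuration --------------------------------------------------------


def load_run_config(path) -> dict:
    """Load the flat YAML config: tool weights, strategy, target_rank.

    Returns a dict with keys ``weights`` (possibly empty dict), ``strategy``
    and ``target_rank`` (either possibly None).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    weights = raw.get("weights", {})
    if not isinstance(weights, dict):
        raise ConfigError("'weights' must map tool names to numbers")
    for tool, w in weights.items():
        if not isinstance(w, (int, float)):
            raise ConfigError(f"weight for {tool!r} is not a number: {w!r}")
    return {
        "weights": {str(t): float(w) for t, w in weights.items()},
        "strategy": raw.get("strategy"),
        "target_rank": raw.get("target_rank"),
    }


# -- fixture directories ------------------------------------------------------


def load_fixture_dir(directory) -> tuple[TaxonomyTree, TruthSet, list[AssignmentSet]]:
    """Load a simulated fixture directory via its ``manifest.json``."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json in {directory}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    tree = load_taxonomy(
        directory / manifest["taxonomy"]["nodes"],
        directory / manifest["taxonomy"]["names"],
    )
    with open(directory / manifest["truth"], encoding="utf-8") as fh:
        truth = parse_truth(fh)
    tool_sets = []
    for entry in manifest["tools"]:
        with open(directory / entry["path"], encoding="utf-8") as fh:
            tool_sets.append(
                parse_classifier_output(fh, entry["dialect"], entry["name"], tree=tree)
            )
    return tree, truth, tool_sets
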