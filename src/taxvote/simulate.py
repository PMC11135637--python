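"""Synthetic taxonomies, ground truth and classifier outputs.

Read-level sequence simulation is deliberately out of scope: what the
consensus and evaluation layers consume are per-read *labels*, so the
simulator draws each synthetic tool's output directly from a controlled
error profile — correct call, over-specific strain call, sibling-species
miss, distant miss, or abstention — instead of simulating sequencers.

Everything is reproducible from a single master seed: the taxonomy is a
deterministic function of its branching plan, and each synthetic tool
derives its RNG stream from (master seed, tool seed offset).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .io_formats import (
    DIALECT_EXTENSIONS,
    DIALECTS,
    AssignmentSet,
    TruthSet,
    write_classifier_output,
    write_truth,
)
from .taxonomy import DEFAULT_RANKS, NO_RANK, UNCLASSIFIED, TaxonomyTree, TaxonNode, write_taxonomy

_PROB_TOL = 1e-9

#: Children per node at each rank. The product down to "species" is the
#: number of species leaves; defaults give 2 * 5 * 3 = 30 species in 10
#: genera of 3 species each, every species with 2 strains.
DEFAULT_BRANCHING: dict[str, int] = {
    "superkingdom": 2,
    "phylum": 1,
    "class": 1,
    "order": 1,
    "family": 1,
    "genus": 5,
    "species": 3,
    "strain": 2,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 30
    out_of_reference_fraction: float = 0.10
    n_reads: int = 10_000
    abundance: str = "uniform"  # or "lognormal"
    lognormal_sigma: float = 1.0
    seed: int = 0
    rank_ladder: tuple[str, ...] = DEFAULT_RANKS
    branching: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_BRANCHING))

    def __post_init__(self) -> None:
        if self.n_species <= 0:
            raise ConfigError("n_species must be positive")
        if not 0 <= self.out_of_reference_fraction < 1:
            raise ConfigError("out_of_reference_fraction must lie in [0, 1)")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")
        if self.abundance not in ("uniform", "lognormal"):
            raise ConfigError("abundance must be 'uniform' or 'lognormal'")
        for rank in self.rank_ladder:
            if self.branching.get(rank, 1) < 1:
                raise ConfigError(f"branching factor for {rank!r} must be >= 1")

    @property
    def n_out_of_reference(self) -> int:
        return int(round(self.out_of_reference_fraction * self.n_species))


@dataclass(frozen=True)
class ToolProfile:
    """Error model of one synthetic classifier.

    The five outcome probabilities must sum to 1. On out-of-reference
    reads the tool abstains with ``oor_abstain_prob`` and otherwise
    assigns a uniformly random in-reference species.
    """

    tool_name: str
    p_correct: float
    p_overspecific: float = 0.0
    p_sibling_miss: float = 0.0
    p_distant_miss: float = 0.0
    p_unclassified: float = 0.0
    oor_abstain_prob: float = 1.0
    seed_offset: int = 0

    def __post_init__(self) -> None:
        probs = self.probabilities
        if any(p < 0 or p > 1 for p in probs):
            raise ConfigError(f"{self.tool_name}: probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > _PROB_TOL:
            raise ConfigError(
                f"{self.tool_name}: outcome probabilities sum to {sum(probs)!r}, not 1"
            )
        if not 0 <= self.oor_abstain_prob <= 1:
            raise ConfigError(f"{self.tool_name}: oor_abstain_prob must lie in [0, 1]")

    @property
    def probabilities(self) -> tuple[float, float, float, float, float]:
        return (
            self.p_correct,
            self.p_overspecific,
            self.p_sibling_miss,
            self.p_distant_miss,
            self.p_unclassified,
        )


def default_profiles() -> list[ToolProfile]:
    """Eight heterogeneous synthetic classifiers.

    Names follow well-known tools purely for readability; no behavioral
    fidelity to any real classifier is claimed.
    """
    return [
        ToolProfile("kraken2", 0.86, 0.05, 0.05, 0.02, 0.02, oor_abstain_prob=0.5, seed_offset=1),
        ToolProfile("krakenuniq", 0.84, 0.04, 0.05, 0.02, 0.05, oor_abstain_prob=0.6, seed_offset=2),
        ToolProfile("centrifuge", 0.82, 0.02, 0.08, 0.04, 0.04, oor_abstain_prob=0.4, seed_offset=3),
        ToolProfile("clark", 0.88, 0.00, 0.06, 0.02, 0.04, oor_abstain_prob=0.3, seed_offset=4),
        ToolProfile("clark_s", 0.85, 0.00, 0.08, 0.03, 0.04, oor_abstain_prob=0.35, seed_offset=5),
        ToolProfile("k_slam", 0.75, 0.03, 0.10, 0.05, 0.07, oor_abstain_prob=0.5, seed_offset=6),
        ToolProfile("megablast", 0.80, 0.10, 0.05, 0.03, 0.02, oor_abstain_prob=0.2, seed_offset=7),
        ToolProfile("kaiju", 0.72, 0.02, 0.10, 0.06, 0.10, oor_abstain_prob=0.7, seed_offset=8),
    ]


# -- taxonomy -----------------------------------------------------------------


def simulate_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Ladder-complete deterministic tree per the config's branching plan.

    Root (taxid 1, "no rank") holds a single transparent "no rank" child
    (mimicking NCBI's "cellular organisms") under which the ladder unfolds.
    Every species receives at least one strain child.
    """
    ladder = config.rank_ladder
    if "species" not in ladder:
        raise ConfigError("rank ladder must contain 'species'")
    species_depth = ladder.index("species")
    n_leaves = 1
    for rank in ladder[: species_depth + 1]:
        n_leaves *= config.branching.get(rank, 1)
    if n_leaves < config.n_species:
        raise ConfigError(
            f"branching plan yields {n_leaves} species < n_species={config.n_species}"
        )

    nodes: dict[int, TaxonNode] = {1: TaxonNode(1, NO_RANK, "root")}
    nodes[2] = TaxonNode(1, NO_RANK, "cellular organisms")
    next_id = 3
    frontier = [2]
    for rank in ladder:
        new_frontier: list[int] = []
        for parent in frontier:
            for _ in range(config.branching.get(rank, 1)):
                nodes[next_id] = TaxonNode(parent, rank, f"{rank}_{next_id}")
                new_frontier.append(next_id)
                next_id += 1
        frontier = new_frontier
    return TaxonomyTree(nodes, rank_ladder=ladder)


# -- truth --------------------------------------------------------------------


def simulate_truth(tree: TaxonomyTree, config: SimulationConfig) -> TruthSet:
    """Draw ``n_reads`` species labels and flag out-of-reference species.

    Exactly ``round(fraction * n_species)`` species are flagged; all reads
    drawn from them carry the flag.
    """
    species = tree.taxids_at_rank("species")[: config.n_species]
    if len(species) < config.n_species:
        raise ConfigError(
            f"tree has only {len(species)} species, need {config.n_species}"
        )
    rng = np.random.default_rng([config.seed, 1])
    oor_indices = set(
        rng.choice(config.n_species, size=config.n_out_of_reference, replace=False).tolist()
    )
    if config.abundance == "uniform":
        probs = np.full(config.n_species, 1.0 / config.n_species)
    else:
        draws = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=config.n_species)
        probs = draws / draws.sum()
    picks = rng.choice(config.n_species, size=config.n_reads, p=probs)
    records = {
        f"r{i:06d}": (species[k], k in oor_indices) for i, k in enumerate(picks.tolist())
    }
    return TruthSet(records)


# -- tool outputs -------------------------------------------------------------


def _species_context(tree: TaxonomyTree, truth: TruthSet):
    """Per-species lookup tables used when drawing erroneous calls."""
    species = tree.taxids_at_rank("species")
    genus_of = {s: tree.ancestor_at_rank(s, "genus") for s in species}
    by_genus: dict[int, list[int]] = {}
    for s in species:
        by_genus.setdefault(genus_of[s], []).append(s)
    strains_of = {
        s: [c for c in tree.children(s) if tree.rank(c) == "strain"] for s in species
    }
    siblings_of = {s: [x for x in by_genus[genus_of[s]] if x != s] for s in species}
    distant_of = {
        g: [x for x in species if genus_of[x] != g] for g in by_genus
    }
    flagged = {taxid for taxid, oor in truth.records.values() if oor}
    in_reference = [s for s in species if s not in flagged]
    if not in_reference:
        raise ConfigError("every species is flagged out-of-reference")
    return genus_of, strains_of, siblings_of, distant_of, in_reference


def simulate_tool_outputs(
    tree: TaxonomyTree,
    truth: TruthSet,
    profiles: Sequence[ToolProfile],
    master_seed: int,
) -> list[AssignmentSet]:
    """Sample each synthetic tool's per-read labels from its profile.

    Outcome categories: correct species / strain child of the true species
    (over-specific) / other species in the true genus / species outside the
    true genus / unclassified. A sibling miss with no sibling available
    falls back to a distant miss.
    """
    if not profiles:
        raise ValueError("simulate_tool_outputs needs at least one profile")
    genus_of, strains_of, siblings_of, distant_of, in_reference = _species_context(tree, truth)

    reads = sorted(truth.records)
    true_taxids = [truth.records[r][0] for r in reads]
    oor_flags = [truth.records[r][1] for r in reads]
    n = len(reads)

    outputs: list[AssignmentSet] = []
    for profile in profiles:
        rng = np.random.default_rng([master_seed, profile.seed_offset])
        probs = np.asarray(profile.probabilities, dtype=float)
        categories = rng.choice(5, size=n, p=probs / probs.sum())
        picks = rng.integers(0, np.iinfo(np.int64).max, size=n)
        oor_uniform = rng.random(n)

        assignments: dict[str, int] = {}
        for i, read_id in enumerate(reads):
            true_sp = true_taxids[i]
            if oor_flags[i]:
                if oor_uniform[i] < profile.oor_abstain_prob:
                    assignments[read_id] = UNCLASSIFIED
                else:
                    assignments[read_id] = in_reference[picks[i] % len(in_reference)]
                continue
            cat = categories[i]
            if cat == 0:
                assignments[read_id] = true_sp
            elif cat == 1:
                strains = strains_of[true_sp]
                assignments[read_id] = (
                    strains[picks[i] % len(strains)] if strains else true_sp
                )
            elif cat == 2 and siblings_of[true_sp]:
                sibs = siblings_of[true_sp]
                assignments[read_id] = sibs[picks[i] % len(sibs)]
            elif cat in (2, 3):
                others = distant_of[genus_of[true_sp]]
                assignments[read_id] = (
                    others[picks[i] % len(others)] if others else UNCLASSIFIED
                )
            else:
                assignments[read_id] = UNCLASSIFIED
        outputs.append(AssignmentSet(tool_name=profile.tool_name, assignments=assignments))
    return outputs


# -- fixture emission ---------------------------------------------------------


def emit_fixtures(
    tree: TaxonomyTree,
    truth: TruthSet,
    outputs: Sequence[AssignmentSet],
    directory,
    dialects: Sequence[str] | None = None,
    extra_manifest: Mapping | None = None,
) -> dict:
    """Write taxonomy dump, truth TSV and tool files (rotating dialects).

    Tool i is written in ``DIALECTS[i % len(DIALECTS)]`` unless an explicit
    dialect list is given, so every parser gets exercised by default.
    Returns the manifest (also written as ``manifest.json``).
    """
    directory = Path(directory)
    (directory / "taxonomy").mkdir(parents=True, exist_ok=True)
    (directory / "tools").mkdir(parents=True, exist_ok=True)

    with open(directory / "taxonomy" / "nodes.dmp", "w", encoding="utf-8") as nodes_fh:
        with open(directory / "taxonomy" / "names.dmp", "w", encoding="utf-8") as names_fh:
            write_taxonomy(tree, nodes_fh, names_fh)
    with open(directory / "truth.tsv", "w", encoding="utf-8") as fh:
        write_truth(fh, truth)

    if dialects is None:
        dialects = [DIALECTS[i % len(DIALECTS)] for i in range(len(outputs))]
    if len(dialects) != len(outputs):
        raise ConfigError("need one dialect per tool output")

    tools = []
    for aset, dialect in zip(outputs, dialects):
        rel = f"tools/{aset.tool_name}{DIALECT_EXTENSIONS[dialect]}"
        with open(directory / rel, "w", encoding="utf-8") as fh:
            write_classifier_output(fh, aset, dialect)
        tools.append({"name": aset.tool_name, "dialect": dialect, "path": rel})

    manifest = {
        "taxonomy": {"nodes": "taxonomy/nodes.dmp", "names": "taxonomy/names.dmp"},
        "truth": "truth.tsv",
        "tools": tools,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def simulate_dataset(
    config: SimulationConfig, profiles: Sequence[ToolProfile] | None = None
) -> tuple[TaxonomyTree, TruthSet, list[AssignmentSet]]:
    """Convenience wrapper: taxonomy + truth + tool outputs in one call."""
    if profiles is None:
        profiles = default_profiles()
    tree = simulate_taxonomy(config)
    truth = simulate_truth(tree, config)
    outputs = simulate_tool_outputs(tree, truth, profiles, master_seed=config.seed)
    return tree, truth, outputs
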