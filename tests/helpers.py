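"""Independent brute-force oracles used to cross-check the consensus path.

Everything here is written from the stated voting rules directly —
projection by explicit parent-chain walks, LCA by chain intersection,
tallies by plain enumeration — and never calls into the functions it
checks (`project_vote`, `tally_votes`, `decide`, `merge_all`).
"""

from __future__ import annotations

from taxvote.taxonomy import TaxonomyTree

ORACLE_UNCLASSIFIED = 0
ORACLE_UNKNOWN = -1


def make_toy_tree() -> TaxonomyTree:
    """Two genera under one family; strains 9/14/15 under species 5/6/7."""
    return TaxonomyTree({
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        10: (2, "phylum", "P1"),
        11: (10, "class", "C1"),
        12: (11, "order", "O1"),
        13: (12, "family", "F1"),
        3: (13, "genus", "G1"),
        4: (13, "genus", "G2"),
        5: (3, "species", "S1"),
        6: (3, "species", "S2"),
        7: (4, "species", "S3"),
        9: (5, "strain", "S1-a"),
        14: (6, "strain", "S2-a"),
        15: (7, "strain", "S3-a"),
    })


def oracle_chain(tree, taxid) -> list[int]:
    out = [taxid]
    while out[-1] != tree.root:
        out.append(tree.parent(out[-1]))
    return out


def oracle_project(tree, label, rank) -> int:
    if label == ORACLE_UNCLASSIFIED:
        return ORACLE_UNCLASSIFIED
    for ancestor in oracle_chain(tree, label):
        if tree.rank(ancestor) == rank:
            return ancestor
    return ORACLE_UNCLASSIFIED


def oracle_lca(tree, taxids) -> int:
    chains = [oracle_chain(tree, t) for t in taxids]
    common = set(chains[0]).intersection(*map(set, chains[1:]))
    for t in chains[0]:
        if t in common:
            return t
    raise AssertionError("no common ancestor")


def oracle_tally(tree, votes, weights, strategy, rank) -> dict[int, float]:
    tally: dict[int, float] = {}
    for tool in sorted(votes):
        label = oracle_project(tree, votes[tool], rank)
        if label == ORACLE_UNCLASSIFIED:
            if strategy == "merge_p":
                tally[ORACLE_UNKNOWN] = tally.get(ORACLE_UNKNOWN, 0.0) + weights[tool]
            continue
        tally[label] = tally.get(label, 0.0) + weights[tool]
    return tally


def oracle_decide(tree, tally, strategy) -> int:
    """Returns the verdict label only (taxid, 0 unclassified, -1 unknown)."""
    if not tally:
        return ORACLE_UNCLASSIFIED
    top = max(tally.values())
    winners = [lab for lab, w in tally.items() if w == top]
    taxids = sorted(w for w in winners if w != ORACLE_UNKNOWN)
    if not taxids:
        return ORACLE_UNKNOWN
    if len(taxids) == 1:
        return taxids[0]
    ancestor = oracle_lca(tree, taxids)
    return ORACLE_UNCLASSIFIED if ancestor == tree.root else ancestor


def oracle_merge_read(tree, votes, weights, strategy, rank) -> int:
    return oracle_decide(tree, oracle_tally(tree, votes, weights, strategy, rank), strategy)


def random_instance(rng, tree, n_tools=8, max_candidates=6):
    """One random voting instance: (votes, weights) over dyadic weights.

    Weights are multiples of 1/2 so float sums are exact and ties are
    unambiguous regardless of accumulation order.
    """
    species = tree.taxids_at_rank("species")
    strains = tree.taxids_at_rank("strain")
    pool = species + strains + [ORACLE_UNCLASSIFIED]
    k = int(rng.integers(1, max_candidates + 1))
    candidates = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
    tools = [f"tool{i}" for i in range(n_tools)]
    votes = {t: int(candidates[int(rng.integers(0, len(candidates)))]) for t in tools}
    weights = {t: float(rng.integers(1, 9)) / 2.0 for t in tools}
    return votes, weights
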