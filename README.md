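# taxvote

Weighted-voting consensus over per-read outputs of multiple taxonomic
classifiers, with rank-resolved benchmarking and a synthetic data
generator so the whole pipeline is testable offline.

Metagenomic classifiers disagree: some over-specify (strain calls for
species-level evidence), some misassign sibling species, some abstain.
`taxvote` integrates their per-read results by weighted voting in two
strategies:

* **merge** (high recall) — unclassified votes are dropped; the taxon with
  the highest aggregate weight wins.
* **merge_p** (high precision) — unclassified votes pool under an
  *unknown* candidate; when that candidate strictly outweighs every taxon,
  the read is called unknown (useful for organisms absent from all
  reference databases).

All votes are projected to the target rank before tallying; tied leading
taxa collapse to their lowest common ancestor. Scoring uses a confusion
matrix adapted to simulated data where every read has a target organism
(no true negatives unless reads are flagged out-of-reference), with the
false-positive rate defined as FP / total reads.

## Library overview

| module               | contents                                                        |
|----------------------|-----------------------------------------------------------------|
| `taxvote.taxonomy`   | NCBI-dump parser, lineages, rank projection, LCA                |
| `taxvote.io_formats` | kraken2 / centrifuge / kaiju / clark / generic TSV dialects, truth, reports |
| `taxvote.consensus`  | `merge_all`, `tally_votes`, `decide`, `fit_weights`             |
| `taxvote.evaluation` | `confusion_at_rank`, `metrics`, `evaluate_many`                 |
| `taxvote.simulate`   | synthetic taxonomy / truth / classifier outputs, fixture emission |

```python
import taxvote as tv

tree, truth, outputs = tv.simulate_dataset(tv.SimulationConfig(seed=1))
result = tv.merge_all(outputs, tree, strategy="merge_p", target_rank="species")
table = tv.evaluate_many([result.assignments] + outputs, truth,
                         ["species", "genus"], tree)
```

## CLI

```sh
# synthetic benchmark: taxonomy dump, truth TSV, 8 classifier outputs
taxvote simulate --out fixtures --seed 1 --n-species 30 --n-reads 10000

# weighted-voting consensus (equal weights unless --weights YAML given)
taxvote merge --fixture-dir fixtures --strategy merge_p --rank species \
    --out consensus.tsv

# per-tool + consensus metrics at several ranks (JSON + TSV)
taxvote evaluate --fixture-dir fixtures \
    --ranks species,genus,phylum,superkingdom --out-prefix metrics

# or everything in one go
taxvote run-all --out run1 --seed 1
```

Classifier files can also be given explicitly, with a taxonomy dump:

```sh
taxvote merge --input kraken2=kraken2:sample.kraken2 \
    --input kaiju=kaiju:sample.kaiju.out \
    --nodes nodes.dmp --names names.dmp --out consensus.tsv
```

Weights/strategy config (`--weights weights.yaml`):

```yaml
strategy: merge        # or merge_p
target_rank: species
weights:
  kraken2: 1.0
  kaiju: 0.6
```

Explicit flags override the config file. `fit_weights` can derive
accuracy-proportional weights from a tuning set with known truth; weights
are otherwise the user's choice. Exit codes: 0 ok, 2 config error, 3
parse error, 4 evaluation error.

## Tests and acceptance report

```sh
python -m pytest -q                                    # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the property-based acceptance criteria
(brute-force vote-oracle equivalence, metric identities, Merge(P) ⊆ Merge
containment, weight-scale and tool-order invariance, the all-perfect
no-error limit, ensemble gain over the best single tool, weight recovery,
dataset-design fidelity) and prints a pass/fail summary to stderr. The
source study reports its comparative results as boxplots only, so there
are no numeric targets to reproduce and the JSON report is an empty
object by design.
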