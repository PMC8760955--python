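# abhumanize

Antibody humanness scoring and greedy framework humanization over
IMGT-numbered variable-domain sequences.

The package trains per-V-gene random-forest classifiers that separate human
from non-human antibody sequences, calibrates a classification threshold by
maximizing Youden's J on a validation split, and uses the resulting humanness
score to drive a greedy humanizer: at each step every single-site framework
substitution is scored and the best one applied until a target score is
reached. CDR residues and the conserved cysteines (IMGT 23/104) are never
mutated. Evaluation utilities compare tool-suggested mutation sets against
experimentally derived ones (overlap ratio, adjusted overlap ratio, mutation
ratio), with a Monte-Carlo random-humanization baseline, positional category
accounting and ADA-immunogenicity correlation. A built-in repertoire
simulator generates labeled human/mouse/rat training data with
species-distinguishing framework signature residues and region-dependent
somatic hypermutation, so the whole pipeline is testable end to end without
external data.

## Modules

| module | what it does |
| --- | --- |
| `abhumanize.ab_sequence` | IMGT positions (1-128 + insertion codes), FR/CDR regions, `NumberedSequence`, quality filtering (duplicates, cysteine errors, missing FR1), one-hot encoding, CSV/FASTA I/O |
| `abhumanize.repertoire_sim` | germline templates and labeled synthetic repertoires with configurable SHM rates and QC-artifact injection |
| `abhumanize.humanness_classifier` | dataset splitting, RF training (200 estimators by default), Youden's-J / MCC threshold calibration, rank-statistic ROC/AUC, kappa/lambda chain-type classifier, feature importances |
| `abhumanize.humanizer` | greedy single-site framework mutation loop with trajectory recording; wrong-model negative-control mode |
| `abhumanize.evaluation` | mutation-set diffs, OR/AOR/mutation-ratio, panel aggregation, random baseline, ADA R², interface/Vernier category stats; bundles a 25-therapeutic reference panel |
| `abhumanize.cli_io` | `abhumanize` CLI, model archives (JSON metadata + joblib payload), report writing |

## CLI

```bash
# simulate a labeled repertoire (numbered CSV)
abhumanize simulate --n 1000 --chain heavy --seed 7 --out repertoire.csv

# train + calibrate one V-gene model (writes a model archive directory)
abhumanize train --positives pos.csv --negatives neg.csv \
    --chain heavy --v-gene V1 --seed 7 --out models/v1

# score sequences against every model of their chain
abhumanize score --models models/ --input seqs.csv --out scores.csv

# greedy humanization (trajectory CSV + final FASTA)
abhumanize humanize --model models/v1 --input precursor.csv \
    --target 0.95 --out-prefix runs/campaign1

# compare tool vs experimental mutation sets
abhumanize evaluate --sequences all.csv --tool-pairs tool.csv \
    --exp-pairs exp.csv --out report.csv
```

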