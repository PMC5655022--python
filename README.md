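# playmetrics

Recognition of therapy progress in children from tablet-game behavioural
telemetry. The package covers the full pipeline:

1. **Session model** (`playmetrics.session`) — a JSON Lines format for
   gameplay recordings (touch, inertial-motion and game-flow streams) for
   five games: *boxes*, *sharing*, *pinwheel*, *creativity*, *cat and dog*.
2. **Kinematics** (`playmetrics.kinematics`) — shared signal operators:
   path length/straightness/speed, directional tilt-episode detection,
   oscillation counting, acceleration sign-flip rates, threshold
   exceedance, stimulus/tap reaction-time matching.
3. **Game features** (`playmetrics.game_features`) — per-game extractors
   against a canonical registry of named features (boxes 29, sharing 44,
   pinwheel 41, creativity 41, cat and dog 27; 182 total). A TSV manifest
   ships in `playmetrics/data/`.
4. **Assessment** (`playmetrics.assessment`) — a 74-item therapist
   questionnaire over ten developmental areas; item ratings rescale to
   [0, 100], area scores are unweighted means, and *progress* between two
   sessions means a strict increase of the area score.
5. **Datasets** (`playmetrics.dataset`) — labelled difference vectors
   between session pairs (`first_last` or `consecutive` pairing), explicit
   missing-value imputation, min-max normalization and PCA in the four
   variants raw / raw+PCA / norm / norm+PCA.
6. **Models** (`playmetrics.models`) — decision tree, Gaussian naive
   Bayes, tree-augmented Bayesian network, small feedforward network,
   random forest, bagging, AdaBoost and rotation forest; 10×-repeated
   stratified 10-fold cross-validation with t-based confidence intervals
   and per-class precision/recall/F. Preprocessing is re-fit inside each
   training fold.
7. **Relevance** (`playmetrics.relevance`) — Pearson/Spearman correlation
   of feature deltas with evaluation deltas, information gain against
   progress labels, and per-area indicator ranking.
8. **Simulator** (`playmetrics.simulate`) — synthetic cohorts with latent
   drifting skills, game recordings whose kinematics are monotone in the
   linked skills, noisy questionnaire readouts, and ground truth for
   recovery tests. A scripted mode produces deterministic perfect-play
   fixtures.

## CLI

```sh
playmetrics simulate --seed 1 --n-children 10 --out cohort/
playmetrics extract  --cohort cohort/ --out features/
playmetrics label    --cohort cohort/ --out scores.csv
playmetrics build    --cohort cohort/ --game boxes --area fine_motor \
                     --mode consecutive --out dataset.csv
playmetrics train    --dataset dataset.csv --models decision_tree,random_forest \
                     --out cv.csv
playmetrics rank     --cohort cohort/ --out relevance.tsv
playmetrics all      --seed 1 --n-children 10 --games boxes,catdog --out results/
```

Results CSVs report percentages at two decimals; a provenance JSON records
the configuration and seed needed to reproduce every output byte-for-byte.

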