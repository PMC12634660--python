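# soseq

Analysis of behavioral **syllable** sequences recorded from mice in
solitary and dyadic (social) open-field contexts.

Modern behavioral decomposition tools (e.g. keypoint-based motion
sequencing) label every video frame with one of a few dozen recurring
behavioral units — syllables.  `soseq` is the downstream half of such a
study: given frame-wise syllable labels, body-centroid tracks and
experimenter-scored contact bouts, it quantifies how a social context
restructures the behavioral repertoire.  It is written for behavioral
neuroscientists and computational ethologists who have decomposition
output in hand and want the statistics, not the pose model.

## What it computes

Let a recording yield bouts (maximal runs of one syllable) with onset
proportions $p_s$ and frame proportions.  The package provides:

* **Context modulation** — per-syllable two-sided Mann-Whitney U on
  per-animal onset proportions (solitary vs dyadic), Benjamini-Hochberg
  corrected; the significant set is the *dyadic-modulated* (DM) set.
* **Transition networks** — bout-transition matrices $P_{ij} =
  \Pr(\text{next bout} = j \mid i)$ (zero diagonal, rows sum to 1) and
  **eigenvector centrality**: the dominant *left* eigenvector of $P$,
  i.e. incoming influence, computed by power iteration and checked
  against $cP = c$.  Per-edge context contrasts report which modulated
  transitions target DM syllables.
* **Composition divergence** — event-aligned Kullback-Leibler divergence
  $D_{KL}(p\,\|\,q)=\sum_s p_s \ln (p_s/q_s)$ (nats) between the
  syllable (or two-mouse joint) composition around scored contact onsets
  and the overall dyadic composition, with a clean 5 s (125-frame)
  pre-contact baseline, a bootstrap significance band, and a
  bout-order-shuffle negative control.
* **Syntax analysis** — length-3 syntaxes (ordered bout triples),
  onset-aligned z-score time-courses, and **syntax families**: all
  triples within Hamming distance ≤ 1 (position-wise substitutions) of a
  reference triple, e.g. (9,0,10) belongs to the (9,0,5) family while
  (0,5,10) does not.
* **Parametric social classes** — each syntax occurrence maps to
  $(x, y)$ = (inter-mouse distance at its start, change of that distance),
  classified as contact ($x<100$ mm, $x+y<100$ mm), approach ($x>100$,
  $x+y<100$), leave ($x<100$, $x+y>100$) or far-stationary, plus matched
  control classes; class-family association tests and a class-wise
  $D_{KL}$ matrix.
* **Usage PCA** — per-track syllable/syntax proportion PCA with DM-vs-DU
  loading contrasts and silhouette-based context separation.
* **Synthetic experiments** — a fully seeded semi-Markov generator that
  plants recoverable effects (usage/centrality modulation of a syllable
  subset, contact-composition bias, family-coupled approach/leave
  episodes) at the study's conditions: 32 syllables, 10-frame median
  bouts at 25 Hz, 20-minute recordings, a 453 mm arena with corner
  preference.

## Worked example

Simulate a small experiment (8 animals per context, 10-minute
recordings) and run the full pipeline:

```sh
cat > cfg.json <<'EOF'
{"n_animals_per_context": 8, "duration_s": 600}
EOF
soseq simulate --config cfg.json --out demo --seed 42
soseq run-all --data demo --out demo_out --seed 42
```

`run-all` prints the summary it also writes to `demo_out/summary.json`;
with the calls above it includes:

```
"n_retained_syllables": 29,
"dm_syllables": [24, 25, 27, 30, 31],
"centrality_significant": [24, 30],
"imd_quartiles_mm": [204.2, 326.7, 398.1, 572.9],
"corner_occupancy": 0.417,
"class_counts": {"approach": 344, "contact": 632,
                 "far_stationary": 7174, "leave": 344},
"dkl_active_post_onset_significant_fraction": 0.231,
"top_syntaxes_active": [[25, 0, 12], [24, 25, 26], [5, 11, 4], [1, 4, 0]],
"pc5_variance_fraction": 0.718,
"context_silhouette_scaled": 0.41
```

Reading this: 29 of 32 syllables survive the 0.5% onset filter; five are
flagged dyadic-modulated, all from the planted subset (ids 24–31 —
smaller groups lose some power against the 20-animal default); two of
them also change network centrality.  Mice spend 42% of frames within
100 mm of a corner; most 30-frame windows are far-stationary, with
symmetric approach/leave tails.  Syllable composition diverges
significantly after active-contact onsets (23% of early post-onset bins),
the planted greeting triple (24,25,26) appears in the top contact-aligned
syntaxes, and the standardized-PCA silhouette separates contexts (0.41)
while light-cycle groups do not separate.  Outputs include per-stage CSVs
(`dm_tests.csv`, `centrality.csv`, `edge_tests.csv`,
`dkl_timecourse_*.csv`, `class_dkl_matrix.csv`, `pca_loadings.csv`), a
Newick dendrogram of trajectory similarity and a GraphML export of the
modulation network.

Every stage is also callable from Python (`soseq.syllables`,
`soseq.network`, `soseq.composition`, `soseq.syntax`, `soseq.kinematics`,
`soseq.pca`) on a `Dataset` loaded with `soseq.load_dataset` or generated
with `soseq.generate_experiment`.

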