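# polarstates

Polarity-considered EEG microstate labeling and single-trial oddball
classification.

## The problem

In an oddball paradigm, rare "target" stimuli evoke event-related potential
components (N200, P300) against frequent "standard" stimuli. Detecting
targets from single trials is the core of P300-based brain–computer
interfaces, but raw multichannel EEG is high-dimensional and noisy.
Microstate analysis compresses each moment of EEG into one symbol: the
index of the template topography with the highest spatial correlation
(winner-take-all). Classic microstate labeling discards the *polarity* of
the map — a topography and its negation count as the same state — yet the
N200/P300 sequence is precisely a polarity-structured progression. This
package keeps polarity: each of the k base templates `T_1..T_k` is paired
with its negation, and labeling runs over the 2k signed maps

    label(x) = argmax_j corr(x̄, T_j),   T_{k+i} = -T_i,

where `x̄` is the average-referenced window-mean topography. For k = 5 base
maps (A–E), epochs become sequences over ten signed states A±…E±, encoded
as integers 0–9. Those one-dimensional sequences are the classification
features.

The package is aimed at EEG/BCI researchers who want to run, probe, or
extend this pipeline: labeling, template derivation (GFP peaks +
polarity-invariant modified K-means), trial balancing, occurrence-frequency
maps, temporal generalization matrices, nested cross-validated
classification with six model families, cluster-corrected permutation
statistics with FDR across labels, and template-weighted topographic
reconstruction scored with global dissimilarity
`DISS(u, v) = ||u/‖u‖ − v/‖v‖|| ∈ [0, 2]`.

Because the oddball recordings the method was developed on are not
redistributable, a first-class synthetic-data module generates 32-channel
oddball sessions with planted signed-microstate dynamics and ground-truth
label tracks, so every stage is testable end to end.

## Worked example

Simulate a standard oddball session (320 standard / 80 target trials,
−200 to 1000 ms at 1000 Hz), encode it as polarity-signed label sequences
over 0–400 ms, balance the classes, and classify:

```sh
$ polarstates simulate --seed 7 --out work/epochs.h5
simulate: wrote 400 trials to work/epochs.h5

$ polarstates label --templates work/epochs_templates.tsv \
    --epochs work/epochs.h5 --step-ms 10 --balance --seed 7 \
    --out work/labels.tsv
label: 160 trials x 40 windows -> work/labels.tsv

$ polarstates classify --labels work/labels.tsv \
    --model random_forest --cv-seed 7 --out work/clf.json
classify[random_forest]: mean F1=0.560 AUC=0.618
```

The label file holds one row per trial, one integer 0–9 per 10 ms window.
`balance` kept all 80 target trials and a seeded random 80 of the 320
standard trials. The Random Forest, evaluated by nested five-fold
cross-validation (inner five-fold grid search maximizing F1), separates
target from standard trials clearly above the 0.5 chance level — the
planted oddball effect (C+/E+ occupancy early, C−/D−/E− in the N200/P300
range) survives the compression to ten symbols. A session generated with
`--null` (identical label priors for both classes) yields AUC ≈ 0.5.

Other stages follow the same pattern: `polarstates freq` writes per-class
occurrence-frequency maps and their target-minus-standard difference,
`tgm` the temporal generalization matrix, `stats` cluster-corrected
permutation tests across participants, `reconstruct` per-window DISS
between template-weighted reconstructions and the grand-averaged EEG, and
`run` chains everything. The library API (`import polarstates`) exposes
each stage as a plain function on plain containers; see `docs/methods.md`
for the model, conventions and parameter defaults.

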