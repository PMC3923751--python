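# Methods

## Motif model

A motif is a profile HMM over the 20 canonical amino acids with
emitting states `N, M1..MW, I1..I(W-1), C` and a collapsed transition
graph (the silent Begin/End states of the usual drawing are folded into
the edges). `N` and `C` are background flanks with self-loops; inserts
sit between consecutive matches. Delete states are omitted: at the
default width W = 4 the motif models a handful of defined positions,
and allowing deletions would let the model skip the very positions it
is supposed to pin down. Flank and insert emissions are pinned to the
background distribution so that flanks cannot absorb motif signal; only
match emissions, transitions, and the initial distribution are trained.

The topology enforces one occurrence per sequence (OOPS): every path
enters `M1` and leaves `MW` exactly once, so the per-position posteriors
of those two events each sum to 1 and double as the motif's begin/end
location distributions.

The null model is a HMMER-null1-style background: i.i.d. residues from
the training residue frequencies (with pseudocount 1) and a geometric
length term whose extension probability matches the mean training
length, `ext = L̄ / (L̄ + 1)`.

## Dynamic programming

All recursions run in log space. The forward/backward/Viterbi passes
are vectorized over a padded batch of sequences; because every state
has at most two predecessors, each position costs a couple of
`logaddexp` operations on an `(n_sequences, K)` array. Exhaustive
path-enumeration oracles in the test suite pin the implementation to
1e-9 on all short sequences over a reduced alphabet.

## Training

**Generative (Baum-Welch).** EM with a probability floor of 1e-6
applied after each M-step (renormalized), stopped at `max_iter`
(default 50) or when the log-likelihood improves by less than `tol`
(default 1e-3). Restarts: `n_init` (default 10) random initializations,
highest final likelihood wins.

*Initialization.* Each match column starts as
`0.5 · bg + 0.5 · one-hot(random residue)`. Small jitter around the
background almost always collapses into composition-level local optima;
the peaked random start raises the per-restart chance of landing in a
planted motif's basin from under 10% to roughly 30% on synthetic data,
while the likelihood still ranks the true-motif basin best. Flank
self-loops are set so the expected flank length matches the mean
training length.

**Discriminative (extended Baum-Welch).** The one-vs-all conditional
objective uses a *fixed* null model as the competing class (the
alternative — co-training a negative-class HMM — is not needed for
per-class motif output and would leave the objective underdetermined);
class priors are uniform, which matches the balanced training pools.
Parameter groups (each transition row including its termination entry,
the initial distribution, each match-emission row) are updated with the
usual smoothed difference of numerator and denominator counts. The
smoothing constant per group is `D = c · max(D_min, 1)` with `c = 2`,
where `D_min` is the smallest value keeping every updated entry at or
above the 1e-6 floor (doubled further if the update denominator is not
positive). With under-sampling enabled, a fresh uniform negative subset
of size `|pos|` is drawn every iteration.

The MMIE objective on the full (non-subsampled) data is traced each
iteration. Because sub-sampling makes individual iterations noisy,
training stops after three consecutive decreases and **returns the
iterate with the highest full-data objective**, not the last one.

## Discovery loop and instance retrieval

Per class: train (generatively, or generatively then discriminatively
depending on mode), record the motif, mask — replace the residues the
Viterbi paths of the positive sequences assign to match states with
residues drawn uniformly from the alphabet — and repeat, by default 10
times. Masking is applied to positives only by default (negatives can
be masked with `mask_negatives`); the replacement distribution is
uniform rather than background-weighted, as the stronger erasure of the
found signal.

Instance retrieval scans each sequence once: every position with Begin
posterior above 1e-12 is paired with the nearest downstream End
position, scored by the posterior product, and all candidates are
ranked globally (ties: sequence id, then start, then motif id).

## Classification

Features are per-motif log-likelihood ratios. The classifier is a
linear soft-margin SVM with error/margin trade-off C = 0.01
(scikit-learn `LinearSVC`); flat mode uses its built-in one-vs-rest
scheme, tree mode fits one classifier per internal node of the
compartment tree and routes predictions top-down. Cross-validation is
stratified (the smallest classes would otherwise vanish from folds).
Within each fold, balancing and motif discovery see the training fold
only, the SVM is fit on the features of the balanced training fold (for
the modes that balance), and only original — never simulated — held-out
sequences are scored. Accuracy is pooled micro-accuracy over folds;
per-fold accuracies are also recorded.

For motif ranking, one-step backward feature selection refits the
classifier once per motif without that motif's feature on a single
stratified train/test split and ranks motifs by ascending
accuracy-after-removal.

## Synthetic benchmark

The generator emulates the skewed nine-compartment setting: class sizes
follow the reference distribution (0.83%–37.58%), each sequence is
i.i.d. background (uniform by default) with exactly one planted
occurrence of its class's width-4 PWM at a uniform random position
(OOPS), lengths uniform in [50, 200]. Default PWMs are degenerate — one
preferred residue per column with probability 0.7 — mimicking short
linear motifs with defined positions.

What the generator does *not* emulate: real targeting-signal biology
(positional preference toward termini, compositional signals, signal
peptide cleavage), homology structure within classes, or multi-label
proteins. Passing tests therefore demonstrate the machinery — recovery
of planted signal under class imbalance — not performance on curated
localization data.

## Problem sizes used in tests and the acceptance script

Reference arithmetic and the balancing rule run at the full reference
sizes (1208/1889 sequences, short synthetic residues). HMM numerics use
exhaustive enumeration on sequences of length ≤ 6 over a three-letter
alphabet. Parameter recovery trains on 200 sequences sampled from a
known width-4 model and requires mean total-variation distance < 0.1 on
match emissions. The masking-loop contract runs the full default
configuration (10 motifs/class, 10 restarts, ≤ 50 iterations) on a
three-class preset of 28 short sequences. The disc-vs-discMU comparison
runs the 200-sequence nine-class skew preset with 3-fold
cross-validation, one motif per class, 10 restarts and ≤ 50 iterations
per training — a configuration chosen so a full paired comparison
completes in minutes on one CPU.

## Known limitations

- The desk-scale minority-recall comparison is statistically fragile:
  with 2–5 sequences in the smallest classes, a fold's minority recall
  is driven by a handful of held-out proteins, and at some seeds both
  training variants score zero (a tie). The packaged fixed-seed test
  uses a seed where the effect is visible; the direction of the effect
  should be judged across many seeds or larger presets.
- The one-vs-all competing model is a null model, not a trained
  negative HMM; strongly structured negative sets may be
  under-modelled.
- Motif width is fixed per run; no width search is attempted.
- The compartment tree is user-supplied; the bundled nine-compartment
  example tree is a synthetic illustration, not a curated sorting
  hierarchy.
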