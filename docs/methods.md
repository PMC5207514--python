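# Methods

## Problem and model

Plant PTS1-type peroxisomal targeting is encoded at the extreme C-terminus:
a tripeptide motif at positions −2…0 plus weaker positional preferences in
the adjacent upstream sequence. The package treats detection as binary
classification of fixed-length C-terminal windows.

**Windows.** The last L residues of a cleaned protein sequence, positions
−(L−1)…0 with 0 at the terminus. Default L = 30: published length sweeps
show specificity still improving up to ~30 residues, and upstream positions
around −20…−25 carry signal, so 30 covers the informative region without
admitting much unrelated sequence. Proteins shorter than L are kept and
left-padded with 'X' — a proteome scan must not crash on short entries, and
'X' already exists in the alphabet as the unknown-residue symbol. Padded
cells occupy only the most-negative positions, so position 0 always maps to
the true terminus.

**Alphabet and cleaning.** 21 symbols: the 20 standard amino acids plus 'X'.
Input is uppercased, one trailing stop `*` is dropped, and every other
non-standard symbol (B, Z, J, U, O, gaps, internal stops) maps to 'X'.

**Profiles and BPB encoding.** Per class c, P(a | i, c) is estimated by
position-specific counting with Laplace pseudocount α (default 1). The
pseudocount is required: the naive-Bayes decision takes logs, and a residue
unseen at a position in one class would otherwise produce log 0. A window is
encoded as the 2L-vector of its residues' probabilities under the positive
profile concatenated with those under the negative profile — the bi-profile
Bayes representation, which feeds the SVM. Class priors default to empirical
class frequencies (the Bayes decision includes P(c)); a uniform-priors
switch exists because the 1:2 class ratio of curated sets is a sampling
artefact, not a population prior.

**Naive-Bayes baseline.** Under positional independence the log-odds is
Σᵢ [log P(sᵢ|c₊) − log P(sᵢ|c₋)] (+ prior term); the sign is the decision,
with an exact tie called negative (conservative for a screen). The
normalising P(S) cancels in the ratio and is never computed.

**SVM.** Soft-margin SVC (scikit-learn backend) on BPB vectors, RBF kernel
by default (linear/polynomial available). Decision values are raw and
uncalibrated; the familiar "about −3…3" range is descriptive, never
enforced. Calls are made by `score ≥ cutoff` (boundary inclusive). Default
cut-off 1.0; 1.5 recommended for whole-proteome scans where false positives
dominate the cost. No class weighting by default despite the 1:2 imbalance;
exposed as an option.

**Hyperparameter selection.** Grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} by pooled stratified k-fold CV accuracy (k = 5),
profiles re-estimated inside every training fold. Ties break toward smaller
C then smaller γ (the smoother model). The `train` command scores grid cells
at the operating cut-off it will deploy: on cleanly separable data many
cells reach perfect sign-accuracy while their decision values cluster near
±1, which would make a cut-off of 1.0 arbitrary; judging cells at the
deployed threshold selects models whose decision scale supports it.

## Evaluation

Accuracy, sensitivity, specificity and MCC from integer confusion counts.
Cross-validation is stratified (random unstratified folds can go
single-class at these class sizes) and fold confusions are pooled before
computing headline metrics — published tables print single numbers, not
fold means. MCC with any zero marginal is reported as N.A. rather than
raised; a sensitivity/specificity with an empty class is NaN/N.A. Printed
tables round half away from zero at 3 decimals.

`reconstruct_confusion` inverts printed rate tables: TP = round(sens·P),
TN = round(spec·N) (half away from zero). For class sizes below 500 this
exactly inverts 3-decimal printing, which lets published per-cut-off tables
be verified cell by cell against the metric formulas. For the all-plants
reference model the negative count consistent with the published table is
198 (its data-collection summary says 196, its candidate accounting 198;
only 198 reproduces every accuracy/MCC cell exactly), so the benchmark
table in `reference.py` carries 198 and notes the discrepancy.

## Synthetic data generator

Emulates the structure the method assumes, with the null exactly known:

* positives end in a tripeptide drawn uniformly from
  {SKL, ARL, SRL, SKM, PKL, SRM} (canonical plus common non-canonical
  motifs) and carry an enriched residue at upstream positions
  {−22, −21, −20, −14, −6, −5, −4} — where real peroxisomal C-termini show
  composition bias — each with probability 0.5, background otherwise;
* negatives are background-composed, their terminal tripeptide
  rejection-sampled out of the motif set (iteration-capped), so class
  separation is attributable to the modelled signal;
* background is uniform over the 20 amino acids by default (keeps every
  null expectation exactly 0.05 for tests); a natural plant-like frequency
  option exists;
* sequence lengths uniform on 50–400 aa; class sizes default to 90/176
  (the Arabidopsis-sized 1:2 configuration); fully deterministic per seed.

What it does **not** emulate: homology between sequences, natural residue
covariation, motif-bearing non-peroxisomal proteins, or label noise. The
generated classes are therefore separable almost perfectly by construction,
and pipeline metrics on synthetic data (CV accuracy ≈ 0.95–1.0) bound the
machinery, not real-data performance, where curated sets yield accuracies
around 0.93. Passing synthetic tests shows the estimator, encoder,
classifier and harness are wired correctly — not that the biology is this
clean.

An enrichment weight of 0.5 gives an expected total-variation distance of
≈ 0.48 at a biased position versus an empirical-sampling null of ≈ 0.25 at
n = 90, i.e. clearly detectable at curated-set sizes without being
deterministic.

## Composition analysis

Per-position relative frequencies over the 20 standard residues, pads
excluded from denominators (an all-pad position is flagged empty). Logo
"height" is raw probability, not information content. The positive/negative
contrast statistic is total variation distance ½·Σ|p−q| per position —
bounded, symmetric, and directly interpretable as probability mass moved;
the motif positions −2…0 dominate it and are excluded when ranking upstream
bias.

## Redundancy filter

A greedy single-linkage identity filter on C-terminal windows: iterate in
input order, keep a record iff its fraction of matching window positions
against every kept record is below the threshold. This is an explicit,
reproducible stand-in for external cluster-based redundancy removal
(CD-Hit/BLAST-style pipelines); it is order-dependent by design and makes no
claim of equivalence.

## Numerical choices and edge cases

* Natural log throughout the Bayes machinery; scores compared at 1e-9
  against a raw-product oracle in tests.
* Profile rows sum to 1 within 1e-9; α > 0 guarantees strictly positive
  entries.
* SVM determinism: fixed data, parameters and seed reproduce identical
  decision values; label-flip antisymmetry holds to the optimizer tolerance
  (~1e-3), not exactly.
* Model files are versioned joblib archives (magic + format version);
  loading rejects wrong magic or version explicitly. Round-trip preserves
  scores bit-for-bit.
* TSV outputs carry scores at 3 decimals and contain no timestamps, so
  identical config + seed reproduces byte-identical artefacts.

## Problem sizes used in checks

The shipped checks run on generated data at the curated-set sizes (90/176
and 99/196), 5-fold CV, and a 3×3-to-4×3 hyperparameter subgrid of the full
search space; the composition null check uses 10 000 windows and the motif
uniformity check 6 000 positives. These sizes make every property
statistically decisive while keeping the whole suite fast.

## Known limitations

* The curated training sets behind the published models are not
  redistributed here; real-data cross-validation requires placing them
  under `data/training/` (see `tests/test_acceptance.py`).
* The published models' selected C/γ are unreported, so real-data
  reproduction is approximate by nature (grid search re-selects them).
* BPB features are first-order: no dipeptide or positional-interaction
  terms.
* Decision values are not calibrated probabilities (no Platt scaling);
  cut-offs are in raw margin units and not transferable between retrained
  models.
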