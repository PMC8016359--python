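# Methods

## Problem

Lysine phosphoglycerylation is a reversible post-translational
modification in which 1,3-bisphosphoglycerate reacts with a lysine side
chain to form 3-phosphoglyceryl-lysine (pgK). Curated site data are
heavily imbalanced: roughly one modified lysine per 29 unmodified ones.
`pgksite` predicts, for a candidate lysine in a protein sequence,
whether it is a phosphoglycerylation site, using only the local sequence
context.

## Windows

A candidate site is represented by the fragment of `2ζ + 1` residues
centred on the lysine (default `ζ = 14`, window length 29; any `ζ` in
1–32 is accepted). Positions that fall off a protein terminus are filled
with the dummy residue `X`, and nonstandard letters (B, J, O, U, Z, `*`,
`-`) are folded into `X` at parse time, so every window lives on a
closed 21-letter alphabet. The canonical alphabet order is the 20
standard residues alphabetically followed by `X`; the order is a
convention (it makes table exports and tests bit-stable), not a
modelling choice. Site positions are 1-based. When a dataset annotates
only modified sites, every other lysine of the same proteins can be
taken as unmodified (`negative_sites_from_lysines`); an explicit
negative list overrides this.

## Sequence-coupling features

Let `Q1 … Q2ζ` be the flank residues (left to right, centre excluded).
Each subset of windows — modified and unmodified separately — yields one
probability table per flank position:

* positions `ζ` and `ζ + 1` (immediately adjacent to K): the marginal
  frequency of each of the 21 residues at that position, denominator the
  subset size;
* every other position: the conditional probability of its residue given
  the residue at the neighbouring position *closer to K*
  (`P(Q1|Q2) … P(Qζ−1|Qζ)` on the left, `P(Qζ+2|Qζ+1) … P(Q2ζ|Q2ζ−1)`
  on the right), a 21×21 = 441-entry table per position.

Estimates are maximum-likelihood count ratios with no smoothing; 0/0 is
defined as 0, which keeps all entries in [0, 1] and every feature
component in [−1, 1]. `X` participates fully, as outcome and as
conditioning residue. A window is encoded as the `2ζ`-vector of
positive-table minus negative-table lookups for its actual residues
(28 dimensions at the default `ζ`).

Two estimation details were genuinely open and are fixed as follows.
The marginal denominator is the subset size (every window has *some*
residue, possibly `X`, at each position), not an `X`-excluding count.
And when a window that belongs to the fitting subset is encoded, its own
counts stay in the tables — there is no leave-one-out correction. The
second choice matters a great deal; see "Leakage" below.

## Cost-sensitive SVM

The classifier is a soft-margin RBF-kernel SVM. With `n` training
samples of which `q` are positive, slack penalties are

    C+ = C·n / (2q),    C− = C·n / (2(n − q)),

so `q·C+ = (n − q)·C− = C·n/2` exactly: both classes carry equal total
misclassification budget, and at balance both reduce to the base cost
`C`. The quadratic program is solved by scikit-learn's `SVC`; the
per-class penalties are applied exactly by setting the solver's `C` to
`C−` and weighting the positive class by `C+/C−`. Features are not
standardised before the kernel — components are already bounded
probability differences. Labels are +1 (modified) / −1 internally.

Hyperparameters are scanned on the grid `C ∈ {2⁰ … 2⁸}`,
`γ ∈ {2⁻¹ … 2⁻⁸}` (72 points) by pooled cross-validated AUC; ties break
towards smaller `C`, then larger `γ`. The default final model uses
`C = 2⁰`, `γ = 2⁻²`, the modal selection across repeated runs.

## Validation protocols

`repeated_cv` runs stratified 10-fold cross-validation repeated 10 times
(both counts configurable). Within a repeat, out-of-fold decision scores
are pooled over the 10 folds, predictions are thresholded at score 0,
and the confusion metrics (Sn, Sp, precision, ACC, MCC) plus the pooled
AUC are computed once on the pooled predictions; means and standard
deviations are reported over repeats. Repeat `r` shuffles with seed
`seed + r`, so each repeat is independently reproducible. Folds are
stratified by label: with ~111 positives in 10 folds, unstratified
splits risk positive-free training folds. Degenerate metric
denominators (no predicted positives; a zero MCC factor) return 0. AUC
uses the rank (Mann-Whitney) formulation with ties counted one half.

Two protocols differ in where feature extraction happens:

* `paper` — the coupling tables are fitted once on the **full** dataset
  before the folds are drawn. This reproduces the published validation
  ordering (features first, split second).
* `nested` (default) — the tables are refitted inside every fold on the
  training windows only, so held-out windows never touch the tables
  that encode them.

`independent_test` fits tables and classifier on the full benchmark set
and scores windows from disjoint proteins (an overlap triggers a warning
naming the offending accessions).

## Leakage

The `paper` protocol is kept because it is the published procedure, but
it is not sound, and the package makes the consequence easy to see.
With only ~111 positive windows, a positive window's own residue pairs
contribute on the order of 1/5 to the sparse positive-table conditionals
that encode it (each conditioning residue is seen only ~5 times), while
the 3249-window negative tables dilute each negative's self-contribution
to ~1/150. Positive windows therefore receive systematically large
encoded components *because they were in the fitting set*, and 10-fold
CV under the `paper` protocol returns near-perfect pooled metrics
(ACC ≈ 1, AUC ≈ 1) on essentially any dataset of this shape — including
synthetic data whose true class signal is far weaker. The `nested`
protocol on the same data reports the leakage-free picture (AUC ≈ 0.90
under the default synthetic conditions, with much lower sensitivity at
the score-0 threshold). A regression test asserts the direction
`AUC(paper) ≥ AUC(nested)` as a tendency over 20 seeds.

The same mechanism explains why a transfer evaluation is harsher than
cross-validation: windows from fresh proteins carry no self-count lift,
so their encoded components are smaller than those of every training
positive, and the SVM's threshold — learned on lifted features —
under-calls them. On synthetic data this shows up as good independent
ranking (AUC ≈ 0.87) but near-zero independent sensitivity at threshold
0. Published independent-test figures for this family of predictors are
much higher; whatever properties of the real curated sequences produce
that (sharper real motifs, non-uniform residue composition, residual
homology between benchmark and later additions) are exactly the features
the generator deliberately does not simulate, so the package asserts the
transfer behaviour only qualitatively, not at the published values.

## Synthetic data generator

The generator emulates the structure the predictor feeds on, with known
ground truth:

* proteins drawn i.i.d. from a background distribution (default uniform
  over the 20 standard residues — real composition is not needed for
  correctness tests);
* site centres on non-overlapping slots at least `ζ` residues from
  either terminus, so generated windows carry no padding and the
  generating tables exist in closed form;
* positive-site flanks drawn per offset from an exponentially tilted
  background `p(a) ∝ bg(a)·exp(tilt_o(a))` ("motif" tilts: a fixed
  primary residue per offset at strength `s`, a secondary at `s/2`);
* optional first-order coupling `c`: a positive flank residue copies its
  inner neighbour with probability `c`, giving the conditional truth
  `P(a|b) = c·1[a=b] + (1−c)·tilt_o(a)`;
* negative-site flanks are plain background.

Defaults mirror the curated data shapes: a benchmark-shaped set of
111/3249 sites on 160 proteins of 500–900 residues, and an
independent-shaped set of 41/1334 sites on 33 longer proteins (1100–1600
residues, matching the higher per-protein site density of that set).
Motif strength 2.0 (the primary residue is ~7-fold enriched over
background, ~26% frequency) with coupling 0.15 was chosen once as a
plausible strength for a clear PTM flank preference; "strong enrichment"
in the end-to-end tests means strength 3.0. What the generator does not
simulate: real amino-acid composition, homology/redundancy between
proteins, position-correlated motifs beyond first order, and `X`-padded
termini windows. Passing tests therefore demonstrate correctness of the
machinery and the qualitative behaviour of the method, not performance
on real proteomes.

`recovery_check` compares fitted tables with the closed-form truth. The
pass/fail verdict uses the marginal tables (estimated from the whole
subset; at 10⁴ sites per class the maximum deviation is well under
0.02). Conditional deviations are reported alongside, restricted to
conditioning residues actually observed, because each conditional
column rests on only ~n/21 samples and converges ~4–5× more slowly.

## Numerical and implementation choices

* Probability tables are dense numpy arrays; fitting is vectorised
  counting (`np.add.at`), exact, and tested against a nested-loop
  enumeration.
* `SVC` shrinking and a fixed `random_state` make refits on identical
  input bit-reproducible; the decision threshold is score 0 and scores
  are always exposed so users can re-threshold.
* Table exports are CSV: 441 pair-labelled rows (`a|b`) for the
  conditional tables, 21 rows for the marginals, one column per
  subset/position, with `ζ` and the subset sizes in a header comment so
  a model round-trips through the files.
* Problem sizes in the test-suite and in `scripts/acceptance.py` (10
  repeats of 10-fold CV at 3360 windows; 2×10⁴ sites for recovery;
  3-seed null calibration) keep every run in seconds while leaving the
  statistical assertions comfortably away from their thresholds.

## Known limitations

The encoder has no smoothing, so rare conditioning residues produce
coarse, high-variance probabilities — that sparsity is integral to how
the published procedure behaves, and is left as-is. The `paper`
protocol should be used only to study the published numbers, never to
estimate real generalisation. Redundancy reduction (e.g. clustering at
40% identity) is out of scope: datasets are consumed as given.
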