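# pgksite

Prediction of lysine phosphoglycerylation sites from protein sequence.

Phosphoglycerylation is a reversible lysine modification (3-phosphoglyceryl-
lysine, pgK) formed by reaction with the glycolytic intermediate 1,3-BPG;
curated site data are heavily imbalanced (~1 modified : 29 unmodified
lysines). `pgksite` implements a sequence-coupling predictor for such
sites and the evaluation protocols used to benchmark it, plus a synthetic
data generator with known ground truth so the whole pipeline is testable
without any external download.

## Method

Each candidate lysine is cut into a window `Q1…QζKQζ+1…Q2ζ` of
`2ζ + 1` residues (default `ζ = 14`, length 29), `X`-padded at protein
termini. From the modified (`+`) and unmodified (`−`) window subsets the
package estimates, per flank position, either the marginal residue
probability (the two positions adjacent to K) or the conditional
probability of the residue given its neighbour closer to K, over the
21-letter alphabet (20 standard residues + `X`, 441 pairs per table).
The feature vector is the difference of lookups,

    Θ(K) = Θ+(K) − Θ−(K)   ∈ [−1, 1]^(2ζ),

28-dimensional at the default `ζ`. Classification is a soft-margin RBF
SVM with class-dependent slack penalties

    C+ = C·n/(2q),   C− = C·n/(2(n−q)),

(`q` positives among `n` samples), so `q·C+ = (n−q)·C− = C·n/2` — the
imbalance correction. Hyperparameters are selected on the grid
`C ∈ {2⁰…2⁸}`, `γ ∈ {2⁻¹…2⁻⁸}` by pooled cross-validated AUC; the
default final model uses `C = 2⁰`, `γ = 2⁻²`. Evaluation is repeated
stratified 10-fold cross-validation with fold-pooled metrics
(Sn, Sp, precision, ACC, MCC, AUC) and an independent test on disjoint
proteins. Two CV protocols are provided: `paper` (coupling tables fitted
on the full dataset before splitting, reproducing the published
validation ordering and its optimistic numbers) and the leakage-free
`nested` default — see `docs/methods.md` for why they differ so much.

## Worked example

```bash
python examples/02_crossval_protocols.py
```

prints, for a benchmark-shaped synthetic dataset (111 modified / 3249
unmodified sites):

```
benchmark-shaped dataset: 111+ / 3249-
 paper: Sn=1.0000 Sp=1.0000 Pre=1.0000 ACC=1.0000 MCC=1.0000 AUC=1.0000
nested: Sn=0.0090 Sp=1.0000 Pre=1.0000 ACC=0.9673 MCC=0.0933 AUC=0.9026
```

The `paper` row shows what full-dataset feature extraction yields under
10-fold CV — near-perfect pooled metrics driven by each held-out
window's own counts sitting in the probability tables. The `nested` row
refits the tables inside every fold and is the honest estimate: good
ranking (AUC 0.90) but low sensitivity at the default score-0 threshold.
The other examples cover encoding (`01`), the independent test (`03`)
and parameter recovery of the generating tables (`04`).

A command-line interface wraps the same library functions:

```bash
pgksite simulate data/ --n-pos 111 --n-neg 3249
pgksite segment data/proteins.fasta data/sites.tsv windows.tsv
pgksite crossval windows.tsv runs/cv --protocol nested --params 1,0.25
pgksite train windows.tsv model.joblib && pgksite predict model.joblib query.fasta out.tsv
```

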