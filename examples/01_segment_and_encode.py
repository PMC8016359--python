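"""Segment lysine sites into windows and encode them as coupling features.

Builds a tiny synthetic dataset, cuts the 29-residue X-padded window
around each annotated lysine, fits the positive/negative probability
tables, and prints one encoded feature vector.
"""

import numpy as np

import pgksite as pg

spec = pg.SyntheticSpec(
    n_proteins=20, length_range=(300, 450), n_pos_sites=25, n_neg_sites=150,
    enrichment=pg.motif_enrichment(14, 2.0), seed=0,
)
data = pg.generate(spec)
dataset = pg.build_dataset(data.proteins, data.annotations, zeta=14)
print(f"{len(dataset)} windows of length 29 "
      f"({dataset.n_positive} modified, {dataset.n_negative} unmodified)")

model = pg.fit_model(dataset)
X, y = pg.encode_dataset(dataset, model)
w = dataset.subset("positive")[0]
print(f"\nfirst positive window {w.protein_id}:{w.position}  {w.residues}")
vec = pg.encode_window(w, model)
print("feature vector (28 components, one per flank position):")
print(np.array2string(vec, precision=3))
print(
    "\nEach component is the positive-minus-negative probability of the\n"
    "window's residue at that flank position (conditional on the neighbour\n"
    "closer to K, marginal for the two centre-adjacent positions); values\n"
    "above zero mean the residue is more typical of modified sites."
)
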