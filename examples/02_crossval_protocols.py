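"""Compare the two cross-validation protocols on a benchmark-shaped dataset.

'paper' fits the coupling tables once on the full dataset before the
folds are drawn, so every held-out window has contributed to the tables
that encode it; 'nested' refits the tables inside each training fold.
The gap between the two is the information leak of full-dataset feature
extraction.
"""

import pgksite as pg

data = pg.generate(pg.benchmark_like_spec(seed=1))
dataset = pg.build_dataset(data.proteins, data.annotations, zeta=14)
print(f"benchmark-shaped dataset: {dataset.n_positive}+ / {dataset.n_negative}-")

for protocol in ("paper", "nested"):
    cfg = pg.CVConfig(folds=10, repeats=3, protocol=protocol, seed=0)
    res = pg.repeated_cv(dataset, cfg, hyperparams=pg.HyperParams())
    m = res.mean
    print(
        f"{protocol:>6}: Sn={m.sn:.4f} Sp={m.sp:.4f} Pre={m.precision:.4f} "
        f"ACC={m.acc:.4f} MCC={m.mcc:.4f} AUC={m.auc:.4f}"
    )

print(
    "\nThe 'paper' row reproduces the near-perfect pooled metrics that\n"
    "full-dataset feature fitting produces on any dataset of this shape;\n"
    "the 'nested' row is the leakage-free estimate of the real signal."
)
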