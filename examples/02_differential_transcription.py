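"""Differential transcription with a batch covariate.

Simulates gene-body counts for two conditions across two batches with a
strong gene-specific batch effect plus 50 genes carrying a true 2-fold
condition effect, then fits the negative-binomial GLM twice: once with
the batch covariate in the design and once without.  The comparison
shows why modeling known covariates matters: the batch-aware model
recovers most planted genes while the batch-free model loses power to
the inflated dispersion estimates.
"""

import numpy as np
import pandas as pd

from nascentq import diff

rng = np.random.default_rng(1)
n_null, n_true = 200, 50
rows = [
    {"sample_id": f"{c}_{b}_{i}", "condition": c, "batch": b}
    for c in ("ctrl", "treat") for b in ("b1", "b2") for i in range(2)
]
meta = pd.DataFrame(rows)
n_genes = n_null + n_true
truth = np.zeros(n_genes, dtype=bool)
truth[n_null:] = True
batch_affected = rng.random(n_genes) < 0.5
batch_dir = rng.choice([1.0, -1.0], size=n_genes)
size = 20.0  # NB size parameter: dispersion 0.05
cols = {}
for _, row in meta.iterrows():
    mult = np.ones(n_genes)
    if row["condition"] == "treat":
        mult[truth] *= 2.0
    if row["batch"] == "b2":
        mult *= np.where(batch_affected, 3.0 ** batch_dir, 1.0)
    mean = 500.0 * mult
    cols[row["sample_id"]] = rng.negative_binomial(size, size / (size + mean))
counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

for covs, label in (((), "without batch"), (("batch",), "with batch")):
    design = diff.DesignTable(meta.copy(), covariates=covs)
    res = diff.fit_differential(counts, design, ("treat", "ctrl"))
    called = res["fdr"].fillna(1.0).to_numpy() < 0.05
    print(
        f"model {label:>13}: {called[truth].sum():2d}/{n_true} true genes "
        f"recovered, {called[~truth].sum():2d}/{n_null} null genes called "
        "(FDR < 0.05)"
    )
print(
    "\nRecovered = planted 2-fold genes passing FDR < 0.05; the batch-aware "
    "design\nabsorbs the confounder instead of paying for it as dispersion."
)
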