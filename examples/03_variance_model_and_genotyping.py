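"""Variance-model calibration and two-stage copy-number genotyping.

Estimates the overdispersion scale alpha and background variance from
subdivided invariant loci, then genotypes a simulated cohort: CNV
identification by z-test with global BH-FDR, genotype assignment by
Gaussian MAP with LOD confidence.
"""

import numpy as np
import pandas as pd

import copydepth as cd
from copydepth.variance import DEFAULT_SEGMENT_SIZES

# --- calibrate the variance model on invariant 50 kb loci -----------------
frames = []
for i, size in enumerate(DEFAULT_SEGMENT_SIZES):
    n_seg = 100 * (50_000 // size)
    loci = [cd.SimLocus(f"V{size}_{j}", size, 0.45, E2=size * 200 / 3000)
            for j in range(n_seg)]
    cfg = cd.SimConfig(1, loci, np.full((n_seg, 1), 2), seed=10 + i,
                       alpha=2.5, sigma2_bg=0.002)
    counts, _ = cd.simulate_counts(cfg)
    counts = counts.rename(columns={"r_raw": "r_adj"})
    counts["size"] = size
    frames.append(counts.drop(columns="sample_id"))
pairs = cd.build_variance_dataset(pd.concat(frames, ignore_index=True))
model = cd.estimate_model(pairs)
print(f"fitted variance model: alpha = {model.alpha:.2f} (true 2.5), "
      f"sigma2_bg = {model.sigma2_bg:.4f} (true 0.002)")

# --- genotype a cohort with known truth ------------------------------------
rng = np.random.default_rng(20)
truth = rng.integers(0, 5, size=(99, 30))          # genotypes 0..4
loci = cd.uniform_loci(99, seed=21)                # ~3 kb loci, E2 ~ 200
cfg = cd.SimConfig(30, loci, truth, seed=22, alpha=2.5, sigma2_bg=0.002)
counts, truthset = cd.simulate_counts(cfg)
counts = counts.rename(columns={"r_raw": "r_adj"})  # no GC bias planted here

calls = cd.genotype_run(counts, model, cd.GenotypeModel(c_max=10))
matrix = calls.pivot(index="locus_id", columns="sample_id", values="cng")
acc = (matrix.to_numpy() == truthset.genotypes.to_numpy()).mean()
print(f"{len(calls)} genotype calls; {int(calls['is_cnv'].sum())} flagged as CNV "
      f"at Q < 5%; exact-genotype accuracy vs truth = {acc:.1%}")
best = calls.loc[calls["is_cnv"], "lod"].median()
print(f"median LOD among CNV calls = {best:.1f} "
      "(LOD 2 = 100-fold posterior margin over the runner-up genotype)")
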