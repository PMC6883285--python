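# refstab

Reference-gene stability evaluation for RT-qPCR miRNA normalization.

Relative miRNA quantification by RT-qPCR stands or falls with the choice of
reference genes: the 2^–ΔΔCq fold change of a target is only as reliable as
the assumption that the normalizers are stably expressed across tissues and
experimental groups. `refstab` implements the complete candidate-evaluation
workflow used in reference-gene validation studies — for example, screening
snoRNA/snRNA normalizers (sno202, sno420, U6, …) across neuronal tissues in
a nerve-injury mouse model — as a tested, reusable Python library with a
thin `refstab` command-line front end.

## What it computes

Given a Cq table (samples × candidate genes, with group labels and
technical replicates) and optionally the raw amplification curves:

* **Per-reaction efficiency and Cq** — baseline correction, a
  window-of-linearity search, and regression of log₁₀ fluorescence on
  cycle: `E = 10^slope` per reaction, plus both the regression Cq and the
  fixed-threshold Cq (log-linear interpolation at a threshold, default 0.1).
* **Replicate QC** — duplicates are averaged; a duplicate SD above
  0.167 cycles cannot resolve a 2-fold change, so genes exceeding it at the
  tissue level are flagged (with an explicit keep-override).
* **Four stability statistics**
  * *BestKeeper*: per-gene Cq SD and Pearson r against the BestKeeper
    index (per-sample geometric mean of all candidates' Cq); mean of the
    two ranks; SD > 1 marks a candidate inappropriate.
  * *Comparative ΔCq*: mean over partners of SD(Cq_g − Cq_h).
  * *geNorm*: stability M (mean SD of pairwise log₂ expression ratios),
    stepwise worst-gene exclusion to the most stable pair, and the
    pairwise variation V(n/n+1) with the V < 0.15 rule for the optimal
    number of references.
  * *NormFinder*: a model-based decomposition of each gene's variation
    into intra-group variance and inter-group deviation, combined into the
    stability value ρ, with the best two-gene combination.
* **Consensus** — the arithmetic mean of the four method ranks (geNorm's
  final pair tied at 1.5), plus a geometric-mean variant and a
  setting-comparison report (per-gene rank deltas, Spearman ρ).
* **2^–ΔΔCq quantification** — multi-reference normalization (arithmetic
  mean Cq of the references), calibrator-group scaling, one-way ANOVA and
  Tukey post-hoc across groups.
* **Synthetic data** — a generator with known ground truth (per-gene noise
  ladder, shared per-sample loading shifts, planted group effects, known
  per-amplicon efficiencies and plateau behavior), so every stage is
  testable without any download.

## Worked example

```python
from refstab import paper_like_config, run_stability_suite, simulate_cq_dataset

ds, truth = simulate_cq_dataset(paper_like_config(seed=1))  # 16 mice, 11 candidates
suite = run_stability_suite(ds)
print(suite.consensus.table.round(3))
```

prints (abridged):

```
        bestkeeper  deltacq  genorm  normfinder  overall_score  overall_rank
gene
sno429         1.5      1.0     1.5         1.0          1.250           1.0
sno420         1.5      2.0     1.5         2.0          1.750           2.0
sno234         5.5      3.0     3.0         6.0          4.375           3.0
...
sno251         9.5      9.0     9.0        10.0          9.375          10.0
sno292        10.0     11.0    11.0        11.0         10.750          11.0
```

Lower scores mean more stable expression. The generator planted a
+0.8-cycle injury shift on sno292, and the consensus places it last;
`suite.genorm.optimal_n == 2` says the best pair of references already
suffices (every V < 0.15). See `examples/` for narrative scripts covering
efficiency estimation from curves, replicate QC, and 2^–ΔΔCq
quantification of an upregulated target miRNA.

The same analyses run from the shell:

```bash
refstab simulate --seed 1 --out-dir sim --curves
refstab qc         --input sim/cq.csv     --sd-cutoff 0.167 --keep U6 --out-dir out
refstab efficiency --input sim/curves.csv --threshold 0.1 --window-points 4 --out-dir out
refstab consensus  --input sim/cq.csv     --out-dir out
refstab quantify   --input sim/cq.csv --target sno420 --refs sno429,sno202 \
                   --calibrator non-treated --out-dir out
```

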