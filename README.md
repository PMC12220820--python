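# thanatoset

Tools for quantifying **pan-programmed-cell-death (pan-PCD) activity** in
injured tissue from bulk and single-cell transcriptomics, and for screening
perturbation libraries for compounds that reverse a pan-PCD signature.

After spinal cord injury (and many other insults), multiple programmed
cell death modalities — apoptosis, necroptosis, pyroptosis, ferroptosis,
autophagy-dependent death, lysosome-dependent death, and others — act as an
interconnected network rather than in isolation. This package treats them
as one signature: it derives an injury-specific *core pan-PCD gene panel*
from multi-model expression data, scores individual cells for panel
activity, stratifies cells into high/low activity populations, compares
conditions (e.g. adult vs neonatal) with a slope statistic, and screens
drug-perturbation profiles for signature reversers. It is aimed at
computational biologists analysing injury time courses who want a tested,
scriptable alternative to stitching together half a dozen R packages.

## Methods at a glance

**Panel derivation.** Per acute time point, injured vs sham differential
expression uses the empirical-Bayes moderated t-statistic: per-gene pooled
variances s²_g with d residual df are shrunk toward a prior (d₀, s₀²)
estimated by moment matching on log s²_g, giving the posterior variance
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) and t = logFC / (s̃_g·√(1/n_A + 1/n_B))
with d₀ + d df. DEGs (|log₂FC| > 1.5, p < 0.05, strict) are pooled over
time points, intersected with a curated pan-PCD catalog, filtered in each
additional injury model by a two-sided Wilcoxon rank-sum test (p < 0.05),
and intersected across models.

**Cell scoring.** Each cell's genes are ranked by expression (seeded random
tie-breaks); the activity score is the recovery-curve AUC

    score = Σ_{j≤k} R(j) / Σ_{j≤k} min(j, m),   k = ⌈0.05·n⌉,

where R(j) counts panel genes at rank ≤ j and m is the panel size in the
measured universe. Cells are called *high* when score > threshold, with
the threshold at the kernel-density valley between the two largest modes
of the score distribution (fallback: mean + 2·sd). Per cell type, pan-PCD
sensitivity is the OLS slope of score on a sham/injured indicator
(`lm(score ~ group)`), identical to the difference of group means, with
95% t-based confidence intervals; slope ratios get cell-level bootstrap
CIs.

**Reversal screening.** A query signature (up/down panel genes by contrast
log-fold-change sign) is compared against each compound's ranked profile
with the classic two-tag Kolmogorov–Smirnov connectivity score, scaled per
library to [−100, 100]; permutation p-values come from random tag sets.
Compounds negative and significant (p < 0.05) in every dataset pass the
multi-dataset consensus. A Spearman correlation mode and a preranked
running-sum enrichment scorer (ES/NES with permutation null) are included.

Every stage has a synthetic-data generator with planted ground truth
(`thanatoset.simulate`), so the whole pipeline is testable offline.

The packaged catalog (`data/pan_pcd_pathways.synthetic.gmt`, 963 genes
across 13 PCD pathways) and core panel
(`data/thanatoset_panel.synthetic.tsv`, 68 genes spanning 7 pathways) are
deterministic **synthetic stand-ins**: they are seeded with literature PCD
genes and padded with clearly synthetic `Pcds####` symbols to realistic
cardinalities, and exist to exercise the I/O and counting contracts — they
are not a curated biological resource.

## Worked example

```python
import thanatoset as ts

# simulate a 3-model bulk injury time course with 30 planted core responders
per_model, truth = ts.simulate_bulk_timecourse(ts.BulkSimConfig(seed=1))
from thanatoset.pipeline import derive_panel_from_sim
panel, details = derive_panel_from_sim(per_model, truth)
print(len(panel.genes), details["per_model_retained"])
# 30 {'crush': 40, 'contusion': 30, 'hemisection': 33}

# score simulated cells and stratify at the automatic threshold
cfg = ts.CellSimConfig(seed=1, panel=tuple(panel.genes))
adata, cell_truth = ts.simulate_cell_population(cfg)
scores = ts.score_cells(adata, panel, seed=2)
thr = ts.detect_threshold(scores["auc_score"])
strat = ts.stratify_cells(scores, thr.threshold)
print(thr.method, round(thr.threshold, 3))
# bimodal_minimum 0.099
print(ts.stratum_summary(strat, by="group")[["group", "high_fraction"]])
#      group  high_fraction
# 0  injured         0.5640
# 1     sham         0.1965
```

The derivation recovers exactly the 30 planted core responders (the 10
extra crush-model genes are removed by the contusion/hemisection rank-sum
filters). The score distribution is bimodal; the detected threshold
separates cells so that the high-activity fraction rises from ~19% in sham
to ~56% in injured arms, close to the planted prevalences of 0.2 and 0.6.

The same stages are available from the shell:

```bash
thanatoset simulate --kind bulk -o sim/ --seed 1
thanatoset derive --sim-dir sim/ -o panel/
thanatoset benchmark --seed 1 -o report.json
```

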