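# mechanoscreen

Analysis toolkit for **stiffness-sorted, genome-wide CRISPR knockout
screens** — pooled screens in which Cas9-expressing cells carrying single
gene knockouts are driven through a ridged microfluidic device that sorts
them by mechanical phenotype into five outlets, and the shift in sgRNA
abundance between the inlet and each outlet reveals which knockouts stiffen
or soften cells. The package covers the full computational arc of such an
experiment, plus the two biophysical assays used to characterise the sorted
populations:

- **Guide quantification** (`mechanoscreen.quant`): protospacer extraction
  from amplicon FASTQ (vector anchor `TTGTGGAAAGGACGAAACA` followed by the
  20-nt guide), exact-match counting against the library, mapping/QC
  reports including the Gini index of guide counts, and cells-per-guide
  coverage arithmetic.
- **Gene-level enrichment** (`mechanoscreen.enrichment`): summed guide
  counts per gene, median-of-ratios size factors, negative-binomial
  dispersion estimation, a per-gene NB Wald test of each outlet against the
  inlet (log μ_gj = log s_j + β₀ + β₁·[outlet]), Benjamini–Hochberg
  adjustment, and hit classification at padj < 0.001.
- **Hit prioritization** (`mechanoscreen.prioritize`): functional-category
  flags, expression terciles, the >100-fold guide-level enrichment filter,
  and bottom-vs-top expression-tercile Kaplan–Meier / log-rank survival
  filters on both overall and progression-free survival.
- **AFM force-curve analysis** (`mechanoscreen.afm`): two-stage contact
  point detection (line-intersection estimate, then an iterative
  minimum-residual sweep) and spherical-indenter Hertz fitting,
  F = (4/3)·E_r·√R·δ^{3/2} with cantilever-compliance-corrected
  indentation δ = (z − z₀) − F/k.
- **Trajectory metrics** (`mechanoscreen.tracks`): per-ridge deflection Δy
  and interaction time τ from tracker-exported cell tracks, cumulative
  statistics over the first 5 ridges, outlet fractions, and Welch /
  Brown–Forsythe group comparisons.
- **Synthetic data** (`mechanoscreen.synthetic`): generators for every
  input above with known ground truth — the package's own recovery and
  calibration tests run against them.

## Worked example

The bundled demo simulates a 200-gene × 4-guide screen with 8 planted
stiffening knockouts (150-fold sorting weight into outlet 4), writes FASTQ,
re-counts it, runs QC, enrichment and the candidate cascade, and fits a
small AFM batch:

```bash
mechanoscreen demo --seed 1 --out demo_ws
```

Selected output (`demo_ws/summary.json`):

```
"planted_genes":        ["GENE0002", "GENE0011", "GENE0017", "GENE0054",
                         "GENE0062", "GENE0084", "GENE0114", "GENE0117"]
"enriched_per_outlet":  {"outlet4": 8, "outlet5": 4}
"candidates":           ["GENE0002", "GENE0011", "GENE0017", "GENE0054",
                         "GENE0062", "GENE0084", "GENE0117"]
"afm": {"mean_control_Pa": 800.6, "mean_transduced_Pa": 1599.9,
        "welch_p": 4.1e-28, "exceed_frac": 1.0}
"tracks": {"mean_cumulative_deflection_um": 9.21,
           "outlet_fractions": [0.07, 0.65, 0.28, 0.0, 0.0]}
```

All 8 planted genes are recovered as significantly enriched in outlet 4
(padj < 0.001; the planted gene GENE0002 fits log2FC = 7.41 ≈ log2 150 with
a 247-fold best guide), and 7 of 8 survive the full five-filter cascade
(one fails the survival filter by chance in this draw). The per-sample QC
shows the positive-selection signature directly — the Gini index rises
from ≈ 0.33 in the inlet replicates to ≈ 0.88 in the outlet-4 replicates
because a handful of stiffening knockouts dominate the sorted subset.

The same stages are available as composable subcommands
(`simulate-screen`, `count`, `qc`, `enrich`, `prioritize`, `afm-fit`,
`tracks-analyze`, `simulate-afm`, `simulate-tracks`) and as plain library
calls; `mechanoscreen <cmd> --help` documents each.

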