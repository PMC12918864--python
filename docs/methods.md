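# Methods

This note documents the models implemented by `mechanoscreen`, the
assumptions behind them, the defaults that matter, and the numerical
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Screen quantification

Amplicon reads carry a constant vector segment immediately upstream of the
20-nt protospacer. The counting anchor is the 19-nt literal
`TTGTGGAAAGGACGAAACA` (the printed adapter's trailing `NNN` are wildcard
positions and are dropped); extraction takes the 20 bases following the
first exact anchor occurrence. Matching against the library is **exact**
by default: it is a pure function of the read multiset, deterministic, and
round-trips the synthetic generator bit-for-bit. A 1-mismatch rescue
(unambiguous single-substitution neighbours only) exists behind
`mismatch_rescue=True` but is off by default, since fuzzy matching trades
auditability for a small mapping-rate gain. Reads without the anchor or
too short to contain a full protospacer are tallied as *unextracted*,
extracted-but-unknown sequences as *unmapped*; mapped + unmapped +
unextracted equals the read total per sample by construction.

Per-sample QC reports totals, the zero-count guide fraction, mean reads
per guide, and the **Gini index** of the raw count vector (zeros
included). The Gini index uses the sorted form
G = Σᵢ (2i − n − 1) x₍ᵢ₎ / (n² x̄), which equals the pairwise
mean-absolute-difference definition (the tests verify agreement with the
O(n²) oracle to 1e-12). Under positive selection a few knockouts dominate
a sorted outlet and its Gini rises relative to the inlet — the QC table
makes that signature directly visible.

Coverage arithmetic is the plain product rule: cells per guide =
n_cells × infection_efficiency / n_guides.

## Gene-level enrichment model

Counts for the 4–6 guides of a gene are summed into a gene × sample
matrix; the test is then a per-gene negative-binomial log-linear model

  log μ_gj = log s_j + β₀g + β₁g · [sample j is outlet],

with variance μ + α μ². Positive β₁ (reported as log2FC = β₁/ln 2) means
enrichment in the outlet. Each outlet is contrasted against the pooled
inlet replicates in its own two-condition fit, and BH adjustment is
applied within each contrast.

**Size factors** are classic median-of-ratios: the reference profile is
the per-gene geometric mean over samples (genes positive in every sample
only), s_j is the median ratio to it, and the vector is rescaled to
geometric mean 1. This absorbs both sequencing depth and the global
compositional shift that strong positive selection induces (when a few
genes soak up reads, every neutral gene's raw ratio drops by the same
factor, which the median captures).

**Dispersion** is estimated in two steps. A gene-wise method-of-moments
estimate pools within-condition moments of normalized counts,
α̂ = (var − mean)/mean², floored at α_min = 1e-8. A parametric trend
α(μ) = a₁/μ + a₀ is then least-squares fitted over genes with above-floor
estimates. The working dispersion is the **trend value**, except for
dispersion outliers — genes whose log α̂ exceeds the trend by more than
2 robust residual SDs keep their own (larger) estimate. Two deliberate
properties of this rule:

- Fitting the trend only on genes with positive moment estimates biases
  it slightly upward, which compensates the small-sample optimism of the
  normal Wald reference (8 samples is far from asymptopia); the
  combination is what makes the null type-I rate land at ~0.05 in the
  calibration study the acceptance script reruns.
- The outlier escape prevents genuinely noisy genes from borrowing a low
  trend and generating false positives.

This is a simplified take on the empirical-Bayes machinery of full
differential-expression packages: no shrinkage of gene estimates toward
the trend, no outlier refitting via Cook's distance, no independent
filtering. Hit lists are therefore comparable in character but not
numerically identical to theirs.

**Fitting** is by iteratively reweighted least squares with NB weights
w = μ/(1 + αμ), vectorised across genes (each iteration solves a 2×2
system per gene in closed form). Tolerance 1e-8 on β, 100 iterations
maximum; non-converged genes are flagged and assigned p = 1 rather than
dropped. SE(β₁) comes from the Fisher information at the optimum; the
Wald z = β₁/SE is referred to the standard normal, two-sided. Genes with
all-zero counts across both conditions are excluded and reported as
untested.

**Guide-level fold changes** use normalized means with pseudocount 0.5:
FC = (outlet mean + 0.5)/(inlet mean + 0.5); the gene summary is the max
over member guides, so a gene passes the 100-fold filter if any of its
guides does. The pseudocount keeps zero-inlet guides finite while barely
perturbing well-covered ones (2 vs 250 normalized reads gives
250.5/2.5 = 100.2).

## Hit prioritization

A gene is a final candidate iff it passes a conjunction of five filters:
significantly **enriched** in the designated outlet (default `outlet4`,
padj < 0.001); member of a whitelisted **functional category**
(cytoskeleton, adhesion & migration, cell cycle, and the MAPK / Wnt /
Notch / PI3K / JNK / TGFb signaling pathways by default; categories are a
user-supplied two-column table); **top expression tercile** in the
screened line; best-guide **fold change > 100**; and log-rank
**p < 0.05 in both OS and PFS** when patients are split into expression
terciles. Filters are commutative booleans — relaxing any one can only
grow the candidate set, and genes missing from a lookup table fail that
filter with the reason recorded, never silently.

Terciles are rank-based (stable sort, ties toward the lower tercile,
group sizes differing by at most one), hence invariant under monotone
transforms of the expression scale — deliberate, since expression tables
may arrive on any normalization. The survival split discards the middle
tercile and contrasts bottom vs top; the reported effect size is the
difference of Kaplan–Meier medians (low-expression minus high-expression,
months), with the median defined as the earliest time with S(t) ≤ 0.5
(undefined and flagged when the curve never crosses).

Survival is computed from user-supplied patient tables only; reproducing
any specific cohort database is out of scope.

## AFM Hertz analysis

A force curve is the approach segment only: piezo extension z (nm)
against cantilever force F (pN), with spring constant k and probe radius
R from the file header or CLI. Defaults mirror a typical cell-indentation
setup: R = 3660 nm (7.32 μm polystyrene bead), k = 30 pN/nm, 10 nN force
trigger; curves of 1024 points over 4 μm.

Stage 1 estimates the contact point as the intersection of a line fitted
to the first 40% of samples (baseline) with a line fitted to the last 20%
(in contact). Both fractions are configurable and must bracket the true
contact point — a contact point inside the baseline window corrupts the
baseline fit (the batch interface exposes `--baseline-frac` for shallow
curves). Near-parallel lines raise a degeneracy flag and fall back to the
first sample exceeding baseline + 3 noise SDs.

Stage 2 sweeps every sample within ±25 samples (configurable) of the
estimate as a candidate contact point z₀. For each candidate: subtract
the baseline line, form the compliance-corrected indentation
δ = (z − z₀) − F/k, and fit E_r by least squares of F against
(4/3)√R δ^{3/2} over δ > 0 up to the trigger force. Because the Hertz
force is linear in E_r, this closed form reaches the same optimum as a
nonlinear fit with no initialization concerns. The residual sum of
squares is evaluated over the whole pre-trigger curve (model: baseline
before contact, Hertz after), making candidates with different contact
points directly comparable; the minimum-rss candidate wins. If the
optimum lands on the window edge the window doubles and recentres until
it is interior — so a poor stage-1 estimate still converges to the
curve-wide minimum. Flags (`negative-modulus`, `poor-fit` at r² < 0.8,
boundary conditions) propagate instead of raising, so batch runs always
complete.

The reported quantity is the reduced modulus E_r; `young_modulus`
converts via E = E_r(1 − ν²) with ν defaulting to 0.5 (incompressible
cell, rigid probe). Group comparisons report Welch and Brown–Forsythe
tests plus the fraction of the perturbed group exceeding the control
maximum.

Unit note: rescaling the force calibration rescales F and k together,
leaving δ unchanged, so fitted E_r scales exactly with the calibration;
rescaling F alone does not have this property because of the compliance
term.

## Trajectory metrics

Geometry: ridge centerline anchors x₀ᵢ at reference height y_ref, angle θ
to the flow axis (default 45°), and an interaction window of full width w
(default 30 μm ≈ ridge footprint plus one cell diameter — the tracker
marks cell centers, so the window must include the approach). The default
device has 14 ridges; outlet boundaries partition the channel height into
5 bins with positive y toward the stiffest outlet (outlet 5).

A cell interacts with ridge i while its along-flow distance to the
inclined centerline, u = x − [x₀ᵢ + (y − y_ref)·tanθ], satisfies
|u| ≤ w/2; the per-ridge window is the longest contiguous frame run
inside (earliest on ties). Δyᵢ is y(last) − y(first) of that run —
start-to-end, not peak-to-trough — and τᵢ is the run length over the
frame rate (default 2500 fps). Cumulative metrics sum the first 5 ridges,
with never-entered ridges contributing zero. Predicted outlet is the bin
of the final y. Tracks under 2 frames are excluded and listed; fragments
are analysed as-is, never re-linked.

Interaction time is invariant to y-noise, and deflection is unbiased
under symmetric position noise since it is a difference of two noisy
endpoints.

## Synthetic data

The generators emulate the statistical structure each stage assumes, not
the physics upstream of it:

- **Library**: uniform-random unique ACGT protospacers; genes
  `GENE0001…`. Real libraries are sequence-biased; nothing downstream
  uses sequence content beyond exact identity, so this does not limit
  what the tests show.
- **Screen counts**: inlet abundances are log-normal (σ = 0.5) and
  normalized, mimicking uneven library representation so the Gini QC has
  signal. Sorting effects are per-outlet multiplicative weights on a
  gene's abundance, renormalized to a simplex — outlet profiles stay
  proper distributions and strong effects induce the same compositional
  shift real positive selection does. Counts are NB draws with guide-level
  dispersion defaulting to 0.1 (typical of a well-executed pooled screen);
  dispersion → 0 recovers Poisson. Note that summing g guides of
  dispersion α yields gene-level dispersion ≈ α/g.
- **FASTQ**: each read is anchor + protospacer + random filler at read
  length 75 with constant quality `I` (quality is unused downstream);
  per-sample record counts equal the count-column sums exactly. No
  sequencing-error profile is simulated — the round-trip identity is the
  point, and error tolerance is a separate (off-by-default) matching
  concern.
- **Force curves**: the forward model solves, per z-point, the
  self-consistent balance F = (4/3)E_r√R δ^{3/2} with
  δ = (z − z₀) − F/k by bracketed root-finding (tolerance 1e-9 nm scale),
  then adds baseline tilt and Gaussian force noise. It contains no
  adhesion, viscoelasticity, or drift.
- **Tracks**: cells advance at constant speed (default 5000 μm/s) between
  ridges; inside each window u ramps linearly across while the drawn Δy
  is gained over the window's interior, padded by 1.5 frame intervals at
  each end so the first/last sampled in-window frames carry the pre/post
  y exactly — making noiseless cumulative-deflection recovery exact
  rather than sampling-phase dependent. Dwell times are floored at the
  traversal time and a few frame intervals (sub-frame dwell is
  unresolvable at any fps); the truth table records realized values.
  Per-cell latent stiffness scores couple Δy and dwell to a common axis
  when the gains are nonzero.

Passing tests on these generators demonstrates correctness of the
analysis contracts (recovery, calibration, conservation, invariances) —
not robustness to artefacts the generators omit (index hopping, PCR
jackpots, adhesion, track fragmentation bias).

## Problem sizes and defaults in the checks

The self-checks run at deliberately desk-friendly scales chosen once: the
round-trip at 200 genes × 4 guides × 6 samples (~1M reads); null
calibration at 2000 genes with 4+4 replicates and depth 300 reads/guide;
planted recovery at 50/1000 genes with 8-fold effects; Hertz recovery
over E_r ∈ {0.5, 1, 5} kPa, noiseless and at 5 pN noise (100 curves);
trajectory nulls over 200 seed pairs of 30 tracks on a 6-ridge geometry
and power at 280 tracks/group; the demo at 200 genes with 8 planted
150-fold knockouts. Full-scale libraries (19,114 genes / 76,441 guides)
are exercised only where cheap (library generation, coverage arithmetic).

## Known limitations

- The Wald test relies on a normal reference; calibration is empirical at
  the replicate counts studied (4+4), not guaranteed at 2+2.
- Genes with zero inlet counts in every replicate get an infinite-FC flag
  through the pseudocount path rather than a meaningful log2FC SE.
- The contact-point sweep assumes a single contact event and a monotone
  approach; curves with snap-in adhesion or multiple contacts will fit
  but carry a low r².
- Ridge windows are geometric; a cell that stalls just outside w/2 is
  invisible to the interaction-time metric.
- Survival filtering treats each gene marginally; no multivariate
  adjustment across candidate genes is attempted.
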