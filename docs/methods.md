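# Methods

## Data model

The canonical object is a sparse cells × gRNAs matrix of UMI counts with
unique cell barcodes and guide ids, optional per-cell batch labels, and
optional per-guide metadata (target gene, targeting/non-targeting flag).
Cell Ranger triplets (`matrix.mtx[.gz]`, `features.tsv[.gz]`,
`barcodes.tsv[.gz]`) are read with guide features selected by the third
features column (default `CRISPR Guide Capture`) and transposed to
cells × gRNAs; plain CSV count tables are accepted in wide
(gRNAs × cells) or long (`cell,gRNA,count`) dialect.  Barcode suffixes
are kept verbatim so joins against expression matrices are exact.
Assignments are sets of (cell, guide) calls with an optional posterior
probability, serialized as `cell,guide,prob,method` CSV.

## Assignment models

**Threshold family.** `umi_threshold` calls every entry with k ≥ t; the
comparison is inclusive, so t = 1 means "any nonzero".  `maximum` and
`ratio` call the per-cell argmax guide (the latter only when its share
of the cell's guide UMIs reaches r).  Ties for the argmax are never
called: at the counts where ties occur the evidence is genuinely
ambiguous, and an arbitrary tie-break would manufacture calls.  At r = 0
the ratio rule reduces exactly to the maximum rule.

**Per-gRNA mixtures ("across cells").** Each guide's counts across cells
are a two-component mixture of ambient background and true presence.
Four variants: Gaussian–Gaussian on log2(k+1) with zeros included (the
model Cell Ranger applies), the same restricted to nonzero counts,
Poisson background on raw counts, and negative-binomial background
(mean λ, dispersion α; variance λ + λ²/α, Poisson as α → ∞).  The
log-normal signal density on raw counts is the Normal density at
log2(k+1) with the change-of-variables factor 1/((k+1)·ln 2) — a
concretization we validate by parameter recovery.  All fits are EM with
exact M-steps: Gaussian moments in closed form; λ as a weighted mean
(its MLE for any fixed α); α by bounded scalar maximization of the
weighted NB log-likelihood, keeping the previous value when the search
lands on a marginally worse point of the (often flat) profile.  This
makes the log-likelihood non-decreasing by construction, which the tests
assert.  Initialization is deterministic (10th/90th percentile locations,
mixing weight from the fraction below their midpoint); a seeded random
initialization exists for robustness checks, and on separated data five
random restarts agree on the decision threshold.

A cell is called when its posterior signal probability exceeds
`prob_cutoff` (default 0.5).  The per-guide integer decision threshold
(smallest count whose posterior exceeds the cutoff) is recorded for
diagnostics.  Cells with zero total guide UMIs are excluded from every
fit and never assigned.  Guides whose fit is degenerate (all counts
equal, or fewer than two distinct nonzero values for the nonzero-only
variant) are skipped with a warning and produce no calls.

*Numerical choices.* The Gaussian scale floor is σ ≥ 0.25 on the
log2(k+1) axis (configurable).  Counts live on a lattice whose spacing
near the origin is log2(2) − log2(1) ≈ 0.58; a component narrower than
about half that spacing wraps a single repeated count value in a density
spike, which dominates the likelihood and produces degenerate splits.
The identifiability constraint labels the higher-mean component as
signal (components are swapped after EM if needed).

*Unimodality guard (nonzero-only model).* Dropping zeros removes the
background class the full model relies on.  When a guide has essentially
no ambient counts, its nonzero counts form a single signal cluster and a
forced two-component fit would split it in half.  The nonzero fit
therefore declares the data unimodal — all nonzero counts are signal —
when the lower component sits at ≥ 2 on the log2 axis (≥ ~3 UMIs; ambient
molecules come in ones and twos, so a "background" centered there is not
ambient) and the components are weakly separated (Ashman's
D = √2·|μ₁−μ₀|/√(σ₀²+σ₁²) < 2) or a single Gaussian wins by BIC.  The
guard cannot fire in the many-guide ambient regime, where the lower
component sits at ~1 UMI.  Limitation: a guide whose nonzero counts are
*pure ambient* (no truly infected cells at all) is unimodal at low
counts and still mis-called; its decision threshold degenerates to 1,
which is visible in the assignment parameters.

**Poisson GLM with library-size offset.** Per guide,
k_c ~ Poisson(exp(β₀ + β₁ z_c + log L_c)) with latent z_c ∈ {0,1},
P(z=1) = π.  The M-step is two weighted rate estimates (closed form);
β₁ > 0 is enforced by component relabeling; π can be fixed (e.g. 0 for a
pure-background null).  The fit is invariant to rescaling all library
sizes (β₀ shifts, responsibilities unchanged).  With equal library sizes
its decision boundary agrees with the Poisson mixture's within one
count.

**Beta mixtures on maximal relative frequency.** Per batch, the clipped
top-guide fraction f ∈ [ε, 1−ε] (ε = 1e-4; the clip affects only cells
whose counts come from a single guide) is fitted with a 2- or
3-component Beta mixture.  The M-step maximizes each component's
weighted Beta log-likelihood numerically (no closed form exists),
warm-started from the current shapes with method-of-moments
initialization; initial chunks are sliced over *distinct* frequencies so
a dominant clip-boundary spike cannot seed duplicate components, and
components that nonetheless collapse onto each other during EM (same
mean and concentration within tolerance) are merged afterwards —
exchangeable duplicates would otherwise split the posterior and silently
suppress all calls.  The learnt threshold is the smallest frequency on a
1e-4 grid whose top-component posterior exceeds the cutoff; a cell is
called when its top guide is unique and its frequency reaches the
batch's threshold.  Under the fitted ordered components the posterior is
monotone in f, so this equals the posterior rule while making the
internal consistency exact: on a single batch, 2-Beta calls equal ratio
calls at the learnt threshold.  With three components only the top
component produces calls; cells dominated by the middle component are
reported as ambiguous in a side output.  Batches with fewer than 10
cells fall back to the pooled fit.

## Evaluation framework

Uniquely assigned cells (exactly one call) are the analysis unit.
Control cells are those uniquely assigned to any non-targeting guide.
Pairwise assignment concordance is the Jaccard index over
uniquely-assigned (cell, guide) pairs, defined as 1.0 for two empty
assignments.  Target downregulation per targeting guide is
log2[(mean normalized target expression in its cells + p) /
(mean in control cells + p)], pseudocount p = 0.01, on the linear
counts-per-10k scale — on this scale a simulated 2^−k knockdown reads
out as −log2FC ≈ k; log1p CP10K is provided as the conventional
representation (the rank tests are invariant to it).  Discoveries are
(targeting gRNA, gene) pairs significant in a two-sided Mann–Whitney
test of normalized expression (assigned vs control cells) after
Benjamini–Hochberg across all tested pairs at FDR 0.05; significant
(guide, own-target) pairs are counted separately.  False discoveries
test each non-targeting guide's cells against the remaining controls,
where no true effect exists.  The threshold grid search runs
`umi_threshold` or `ratio` over a grid and picks the value with the most
significant target genes, breaking ties toward the smaller threshold.
The built-in rank-sum test is plumbing that makes discovery counts
computable and calibrated; it is not equivalent to conditional
randomization tests used in dedicated screen-analysis packages.

## Synthetic screens

The generator emulates what assignment methods actually face:

* infections per cell ~ zero-truncated Poisson(`moi_lambda`)
  (transduced cells are selected, so every cell carries ≥ 1 guide; an
  untruncated mode models unselected populations), guides drawn
  uniformly;
* true-guide UMIs ~ NB(`signal_mean`·depth_c, `signal_dispersion`);
* ambient background ~ Poisson(`ambient_rate`·depth_c·batch multiplier)
  per (cell, guide), optionally Dirichlet-weighted so guides contribute
  unequally to the ambient pool;
* depth_c ~ log-normal with unit mean and scale `depth_sigma`;
* paired NB expression (deliberately small — on the order of a hundred
  genes — to keep differential expression at desk scale) with each
  targeting guide's target gene scaled by 2^(−`knockdown_log2fc`) in the
  cells that truly carry the guide; `guides_per_target` guides share a
  target gene, as in real screens.

All outputs are pure functions of the seeded configuration.  The
semi-synthetic aggregation transform randomly partitions guides into
fewer groups and sums their counts, conserving per-cell totals exactly.

### Named scenarios

* `separated` — 2000 cells, 20+6 guides, MOI 0.05, ambient 0.0005/guide,
  NB(60, 10) signal: essentially noise-free.  Every strategy should
  recover the truth (F1 ≥ 0.95).  MOI 0.05 keeps the recall ceiling of
  single-call-per-cell methods (maximum, Beta) near 0.975, so the
  scenario tests separation rather than multi-infection.  Near-zero
  ambient matters for the Beta methods: clipping creates a frequency
  spike at 1−ε, and a cell with even one ambient count sits far below
  it, out of reach of the learnt threshold.
* `contaminated` — 3000 cells, ambient 0.5/guide against NB(12, 1.5)
  signal, deep expression (mean 100).  Ambient counts genuinely cross
  the decision thresholds, so posterior confidence is informative:
  restricting any probabilistic method to posterior ≥ 0.9 removes
  disproportionately wrong calls and never weakens the median target
  downregulation.  Uniform contamination and low expression noise are
  what make that a deterministic property rather than a coin flip; the
  full Gaussian mixture typically multi-assigns so many cells here that
  no uniquely assigned controls remain and its metric is undefined —
  itself the documented pathology.
* `many_guides` — 10000 cells, 500+10 guides, ambient 0.05/guide: ~95%
  of each guide column is zeros.  The full Gaussian mixture's background
  component collapses onto the zeros and the signal component absorbs
  everything nonzero, driving decision thresholds to 1 and
  multi-assigning nearly every infected cell; the nonzero-only variant
  keeps a real ambient/signal split and thresholds of ~4–8.  Aggregating
  the guides into 20 groups densifies the columns and restores the full
  model's behavior.
* `two_batch` — two batches with 1× and 6× ambient.  The learnt Beta
  thresholds differ by batch; imposing the clean batch's stricter
  threshold globally cuts into the contaminated batch's true cells.  (In
  an all-infected low-MOI population a permissive global threshold is
  *not* strictly worse at pair level — every cell's top guide is almost
  always a true guide — so batch adaptivity shows up as robustness
  against the mismatched threshold, not as an unconditional F1 win.)
* `null` — knockdown 0 everywhere, 10 targeting + 10 non-targeting
  guides, ~200 cells per guide: calibration of the discovery counts.

### What the simulator does not model

Transcriptome-wide co-expression structure, doublets beyond
multi-infection, guide-sequence errors upstream of counting, and cell
states modulating capture.  Passing tests on these screens demonstrates
the statistical machinery (model recovery, threshold learning,
calibration, the documented failure modes) — not that any particular
method is best on a given real dataset, which is exactly the comparison
the evaluation framework exists to run per dataset.

## Problem sizes

The test suite and the reproduction script use desk-scale screens (up to
10000 cells × 510 guides, 5000-observation model fits, 20-replicate null
calibration), chosen so the full pipeline — simulation, all ten
strategies, evaluation — runs end to end in about a minute on one CPU.

## Known limitations

* The EM concretizations of the Poisson-Gaussian, NB-Gaussian and Beta
  models are validated by parameter recovery and internal-consistency
  properties, not by numerical agreement with any external variational
  implementation.
* The NB dispersion is weakly identified when the background is nearly
  Poisson (the profile likelihood is flat in α), which can move the
  tail-driven decision threshold by one count.
* Frequency-based methods cannot distinguish an uninfected cell whose
  single ambient count yields f = 1−ε from a cleanly infected cell; in a
  zero-truncated low-MOI population this is immaterial, in unselected
  populations it is not.
* The rank-sum discovery counts are conservative, simple plumbing;
  absolute discovery numbers are not comparable to conditional
  randomization tests.
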