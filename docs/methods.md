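# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Differential expression (deg module)

Per gene, log2 expression is modelled as a fixed-effects three-way factorial
ANOVA over genotype × sulfur condition × tissue with all interactions,
fitted by ordinary least squares. The three factors are fixed as the only
crossed factors of the study design. The fit requires a balanced design
(equal replicates in every cell, at least 2); the sums of squares are
computed by the classical balanced-design decomposition, vectorised over
genes, which on a balanced design coincides with the OLS type-I/type-III
ANOVA (verified against `statsmodels.anova_lm` in the tests).

The DEG gate uses the p-value of the *condition contrast within each
genotype × tissue*: because the model is saturated, fitted cell means are
sample cell means and the contrast t-test uses the pooled within-cell
variance with its full residual degrees of freedom (16 for a 2×2×2 design
with n = 3). The condition main-effect p-value is available instead via
`p_source="condition_main_effect"`. Fold change is reported on the linear
scale, FC = 2^Δ where Δ is the log2 mean difference (stressed − reference),
sign-coded as −1/FC when below 1 so that the "±1.5" filter reads naturally;
the FC boundary is inclusive, the p boundary strict. No multiple-testing
correction is applied by default, matching the raw p < 0.05 filter;
Benjamini–Hochberg per contrast is available behind `bh=True`.

Degenerate inputs: a gene constant in all samples reports p = 1 for every
term and contrast (no effect); a gene with zero residual variance but a
non-zero effect is reported as p = 0 (perfect separation). A factor with a
single level or an unbalanced design raises a `DegenerateDesignError`
naming the problem. Rows with missing values are dropped with a logged
count before fitting.

## Set algebra (sets module)

Partitions are exact set algebra; identifiers are compared case-sensitively
after whitespace stripping, and duplicates within an input collapse with a
logged warning. Overlap percentages are returned as exact floats;
`round_half_up` provides the nearest-integer report rendering (round half
up, so 41.5 → 42). Residue intervals are 1-based inclusive throughout
(G92..R405 spans 314 residues).

## Family enrichment (enrichment module)

The categorisation step is implemented as the one-sided hypergeometric
(Fisher exact enrichment tail) against the annotation universe, the
standard replacement for web-tool overrepresentation services; the flagging
threshold defaults to p < 0.01, uncorrected, with an optional BH flag. The
universe defaults to all genes in the annotation; callers can pass the
array universe instead. Query genes outside the universe are dropped with a
logged count.

## Network hubs (hubs module)

The interaction network is a plain undirected simple graph: evidence types,
directionality and species namespaces are flattened to unordered ID pairs,
one edge per pair; self-loops in input edge lists are dropped with a logged
count. Degree-within-set counts the node's neighbors inside each query set;
the invariant degree_in_set ≤ degree_total is asserted on construction.

Hub selection uses an inclusive threshold (degree-within-set ≥ 10 for the
primary tier, ≥ 3 for the annotation tier), ranked by degree descending
with node-id ties ascending. The differential rule flags nodes differing by
at least 9 partners *and* at least 20% relative to each other; "in relation
to each other" is ambiguous, so the denominator is max(d₁, d₂) — the
symmetric, conservative reading — with `min` and `mean` exposed as options.
Proteomic hub analysis conditions the degree counts on the co-purifying
proteins and their first neighbors (`expand_first_neighbors`); when the
bait is among the seeds, callers should exclude it from its own
degree-within-set (it trivially touches every prey).

## TAP scoring (tap module)

Abundance is the mean over *detected* bait replicates (two or one) divided
by the molecular weight in kDa. Specificity is mean detected bait intensity
over mean detected control intensity, with the background set to the
arbitrary value 1 when the protein is never detected in the control — so
control-absent specificities equal the bait intensity and are
intensity-scale dependent (a documented consequence of the convention;
scaling all intensities by c scales exactly those specificities by c).
`detected_in_control` is reported alongside so users can filter on presence
instead. "Not detected" is NaN, never numeric 0; a control *detected* at
exactly 0 is floored to the smallest positive detected intensity in the
table, logged. No published numeric cutoff defines the per-condition
interactome lists, so the call is explicit: control-absent proteins pass on
presence, control-detected ones need specificity ≥ 2 by default (both
configurable).

## Synthetic data (simulate module)

The expression generator emulates a normalized two-genotype ×
two-condition × two-tissue × 3-replicate log2 microarray matrix: gene
baselines ~ Normal(8, 2), planted DEGs shifted ±2 log2 units in the
stressed condition of their contrast (round(fraction × n_genes) genes per
contrast, drawn independently per contrast), i.i.d. Gaussian noise with
sd 0.25. Defaults (1000 genes, 10% planted, log2FC 2, sd 0.25, n = 3) are
the validation conditions used throughout the tests. It does not emulate
probe-level effects, normalization artefacts, correlated genes, or
between-replicate batch structure — so passing recovery tests demonstrate
the pipeline's correctness, not its power on real arrays.

The network generator draws background degrees from a truncated power law
with exponent 2.5 (PPI-like topology). Because that law's mean on support
[1, cutoff] is bounded by ≈1.95, draws are rescaled to the requested
background mean (shape preserved), paired configuration-model style, and
simplified; planted hubs are then wired to uniformly sampled partners until
their degree reaches the requested hub degree. The TAP generator gives
background proteins log-normal intensities in both bait and control runs
(bait ≈ control, i.e. specificity ≈ 1) and planted specific interactors
bait-only intensities at a higher scale; molecular weights are log-normal
around 45 kDa. Replicates are 1 or 2, mirroring purifications analyzed in
duplicate or singly.

All generators take a single integer seed feeding one `numpy` RNG stream
each; identical parameters and seed give byte-identical outputs.

## Pipeline

`run_pipeline` chains the stages on synthetic inputs and writes every stage
table, id-set files, `summary.json` and a manifest. Problem sizes default to
1000 genes / 1000 network nodes / ~75 proteins per purification, which keeps
a full run under a second while leaving every stage non-trivial. The TAP
stage simulates, per tissue, a core set of constitutive bait interactors
shared by all three growth conditions plus condition-specific interactors,
so the three-condition Venn has a non-degenerate triple intersection. The
manifest records config, seed, package version and a timestamp; everything
else is byte-deterministic under a fixed seed and the summary percentages
equal recomputation from the emitted set files (tested).

## Known limitations

- The ANOVA requires a balanced design; unbalanced studies must be
  subsampled or handled upstream.
- DEG sets planted independently per contrast make the between-genotype
  overlap of synthetic DEG sets small, unlike real studies where stress
  responses are strongly shared between lines; the overlap statistics are
  therefore exercised on worked-example set sizes as well.
- Hub analysis offers thresholds and rankings only; no permutation null for
  hub enrichment is implemented.
- Published degree tables depend on the interaction-database release and
  are not reproduction targets; the resolved thresholds (≥10, ≥3, diff ≥9
  and ≥20%) are.
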