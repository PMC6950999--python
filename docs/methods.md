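# Methods

## Scope and model

`dmppipe` implements a mass-univariate two-group differential methylation
analysis for 450K-style arrays. The scientific question it encodes: which
CpG probes show a stable methylation difference between trisomy-21 and
euploid neural cells, where "stable" means the difference is present at
two differentiation stages (neural progenitor cells and their 30-day
differentiated derivatives)?

The statistical model is deliberately simple, matching the scale of the
design it serves (two donors per group per stage, i.e. a pooled 4-vs-4
contrast): per probe, a pooled-variance two-sample *t* test on β values
with df = n₁ + n₂ − 2. Testing is done on β values rather than M-values;
β is the quantity all downstream thresholds are phrased in (|Δβ| screens
and cut-offs), and at the effect sizes of interest (|Δβ| ≥ 0.15) the
heteroscedasticity advantage of M-values is immaterial. No
moderated-variance shrinkage is applied: with a |Δβ| > 0.1 screen ahead
of FDR, the probes that reach testing carry large effects, and the
degenerate-variance case is handled explicitly instead (zero pooled
variance with a non-zero mean difference is flagged and reported with
p = 0; with a zero difference, p = 1).

### Calling rules and their order

1. Detection filter: a probe/sample cell is called when detection
   *p* < 0.01 (strict). The default policy excludes a probe from testing
   if it fails in *any* sample; per-sample masking is available but the
   testing path expects complete matrices.
2. Screen: |Δβ| > `delta_screen` (default 0.1). This mirrors a
   betaThreshold-style pre-screen: FDR is computed *over the screened
   set*, not over all probes. The ordering matters and is fixed:
   detection → screen → BH.
3. Emission: *q* < 0.05 and |Δβ| > 0.15. Direction is the sign of
   Δβ = mean(T21) − mean(control); "hyper" means more methylated in T21.
4. Stability (`per_stage_intersect` mode): the per-stage 2-vs-2 calls are
   intersected on probe id with equal direction; Δβ is reported as the
   stage mean and p/q conservatively as the per-stage maximum. The pooled
   4-vs-4 contrast is the default mode because it is the better-powered
   reading of the design; both modes are first-class and tested.

### Annotation geometry

Coordinates are 1-based inclusive internally; BED I/O converts to/from
0-based half-open. Island/shore/shelf classes use closed boundaries:
shore = edge distance 1–2000 bp, shelf = 2001–4000 bp (a probe exactly
2000 bp away is a shore, exactly 4000 bp a shelf). N is the
lower-coordinate side. Nearest island is chosen by edge distance with
ties broken toward the lower-coordinate island. Gene regions are
assigned strand-aware with priority TSS200 > TSS1500 > 5′UTR > first
exon > body > 3′UTR within a gene; across genes, the first gene in
ascending transcription-start order wins. A published manifest encodes
"first gene" as manifest column order, which a recomputing pipeline does
not have; ascending tx_start is the deterministic stand-in, and a
pass-through mode honours supplied annotation columns when exact
replication of a published annotation is needed.

### Enrichment conventions

Two-sided Fisher tests use the point-probability (minimum-likelihood)
convention with the customary 1 + 1e-7 tolerance factor, via
scipy.stats.fisher_exact. Chromosome and region-class tests compare DMP
counts against the full array background and report raw two-sided p at
0.05 alongside BH q (no correction is applied to the 0.05 call itself;
the q column lets users choose). Any zero margin yields p = 1 with an
undefined odds ratio. The hyper/hypo split is tested with an exact
two-sided binomial against 0.5; a Fisher-versus-background mode exists
because a published split of 282/500 hypomethylated was reported with
p = 0.049, which no exact binomial against 0.5 reproduces — both modes
are exposed so the choice is explicit. Gene-set overrepresentation is
one-sided (enrichment), as is conventional for functional-category
tools; ontology content is out of scope and categories are user-supplied
(GMT).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not array chemistry:

* **Layout.** Chromosomes are user-specified. Islands (300–1500 bp) are
  placed non-overlapping with ≥ 9 kb gaps at a default density of 9 per
  Mb, and ~70% of gene transcription starts are anchored at islands —
  both near human genome-wide figures — so that a realistic fraction of
  island/shore probes acquires a gene assignment. Probe placement targets
  island/shore/shelf fractions of 0.31/0.23/0.10 (450K-like), remainder
  uniform. Probe design type (I/II) is a label with an optional mean
  shift (`type2_shift`) used only to exercise normalization.
* **β values.** A probe's baseline mean is drawn from a two-component
  beta mixture (modes 0.10 and 0.85, equal weights, concentration 25),
  reproducing the bimodal array-wide β distribution. Per-sample values
  are Beta(β·φ, (1−β)·φ) with precision φ = 200 (per-probe SD ≈ 0.02 at
  mid-range), which keeps values in [0, 1] without truncation artefacts.
  The defaults were chosen once as plausible for a clean cell-line
  experiment; the real study does not state its variance structure.
* **Planted effects.** `n_planted` probes (default 500, the study-scale
  count) receive a signed group-mean difference; |Δβ| ~ N(0.3, 0.04)
  truncated ≥ 0.16, direction hypo with probability `direction_mix`.
  Effects are present at both stages when `consistent_across_stages`
  (default), else only at the first. A probe's baseline is redrawn until
  the effect fits inside [0.02, 0.98] for the drawn direction — a probe
  must have methylation to lose before it can be hypomethylated — so the
  direction mix stays exactly binomial and clamping is reserved for
  user-forced extremes (clamped effects are counted and warned about).
  The truth table records realized deltas.
* **Intensities.** Total intensity per cell is gamma (shape 20, mean
  4000), split as M = βT, U = (1−β)T, so recomputing β with offset α
  biases by at most α/(M+U+α) (~1.2% at the nominal total). Detection
  failures (rate default 0.003, giving call rates ≈ 99.7%) receive
  detection p ≥ 0.01 and attenuated signal.

What the generator does **not** emulate: dye bias, batch effects, probe
cross-reactivity, SNP-affected probes, spatially correlated methylation
(neighbouring-probe correlation), cell-composition heterogeneity, or
type-II chemistry beyond an optional mean shift. Passing tests therefore
demonstrate correctness of the pipeline's logic and calibration of its
error control under clean bimodal data — not robustness to those
real-data artefacts.

## Normalization

The within-array step is a deterministic subset-quantile adjustment:
within each sample, type-II values are mapped onto the type-I empirical
quantile function (plotting positions (r−1)/(n−1), linear
interpolation). It is rank-preserving within type, idempotent, and exact
identity when the two type distributions coincide. The CpG-content
random-subset matching of the full published procedure is not
reproduced: the generator carries no CpG-content chemistry, so there is
nothing for it to match on. Because mapping against a finite type-I
reference resamples tail values per sample, normalization is **off by
default** in the pipeline and intended for data with a genuine
type-specific shift (e.g. `type2_shift` simulations, where it removes a
+0.1 shift to within 0.01); applying it to data with no type effect can
only add noise.

## Numerical and design notes

* BH q-values delegate to statsmodels (`fdr_bh`); Fisher to scipy;
  hierarchical clustering (reporting only; Euclidean, average linkage,
  scipy's deterministic tie-break) to scipy.cluster. The per-probe t is
  implemented directly because its degenerate-variance contract is part
  of the calling semantics; it is verified against an independently
  coded textbook formula.
* Manhattan export floors p at 1e-300 (−log₁₀ = 300) and orders
  chromosomes 1–22, X, Y.
* All randomness flows through numpy Generators seeded from a single run
  seed; identical seed + config gives byte-identical reports.
* Problem sizes in the test and acceptance runs (2 000–20 000 probes,
  2 chromosomes) are scaled-down frames of the ~485 000-probe array:
  they keep per-probe statistics and funnel structure intact while
  making full-cascade property checks (10-seed null and recovery
  simulations) quick to run; the study-scale funnel run uses 20 000
  probes and the study's planted count of 500.
* The published 37-gene DNA-binding summary ships as package data;
  counts derived from it (e.g. 12 of 37 genes differentially expressed)
  are recomputed from the table at run time, never hard-coded.

## Known limitations

* With one donor pair per group-stage cell, the per-stage 2-vs-2
  contrasts in `per_stage_intersect` mode have minimal degrees of
  freedom (df = 2); the pooled mode conflates stage and residual
  variance. Both are faithful to the design being modelled, not
  improvements on it.
* The pipeline treats samples as independent; donor pairing across
  stages is not modelled.
* No surrogate-variable/batch correction and no cell-composition
  deconvolution.
* Open-sea probes on island-free chromosomes report distance −1 (no
  island to measure from).
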