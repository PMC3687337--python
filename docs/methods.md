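# Methods

## Two-sample peak normalization

The comparison takes two peak catalogs (knockout and wild type) and, for
every peak region of the union catalog, the read count of **both** samples
over that region. Counts may be supplied directly or recomputed from read
placements (a read is attributed to a region when its strand-shifted
midpoint falls inside the half-open interval).

**Pairing.** A peak of one catalog is *common* when it overlaps a peak of
the other catalog by at least `min_overlap_bp` (default 1 bp, half-open
coordinates, so touching intervals do not overlap). Matching is one-to-one:
each knockout peak takes the wild-type peak of maximal overlap (ties go to
the leftmost), and a matched peak is removed from further matching. This
guarantees the partition |common| + |unique| = |catalog| on each side.
Common pairs are represented by the knockout peak's interval in the union
table.

**Densities.** Read density is count / length × 1000 (reads per kb);
a raw-count mode is available. The *pseudocount* exists so that
unique-peak regions with zero reads in the other sample get a finite log
density. It is applied as a floor, `max(count, pseudocount)` with default
1 read, rather than added to every count: an additive pseudocount shifts
log densities wherever counts are small in one sample, which measurably
biases the fitted intercept downward (about −0.03 at the count scale of
the default synthetic experiment, estimated on 200 000 simulated peaks),
while the floor touches only degenerate counts and leaves the regression
unbiased. The additive convention remains available via
`additive_pseudocount=True`.

**M-A fit.** With M = log2(d_KO/d_wt) and A = ½·log2(d_KO·d_wt), a robust
line M = c0 + c1·A is fitted over common peaks only — unique peaks never
enter the fit. The fit is iteratively reweighted least squares with Huber
weights (tuning constant 1.345, 95% Gaussian efficiency; Tukey bisquare
available), at most 50 iterations, convergence when coefficients change by
less than 1e-8 (statsmodels RLM). At least 10 common peaks are required;
fewer is an error, not a silent fallback. An optional mask peak set
excludes overlapping common peaks from the fit (they are still normalized
and classified); this supports normalizing a histone mark against a
catalog of binding sites where the mark is expected to change.

**Classification.** M_norm = M − (c0 + c1·A), extrapolated to every union
region. Labels use strict inequalities: M_norm > 1 → KO-specific,
M_norm < −1 → wild-type-specific, otherwise common; boundary values are
common. The threshold (default 1, i.e. twofold) is configurable but the
strictness is not.

## Genomic annotation of peaks

A peak is anchored at its summit when present, else its midpoint.
Compartment windows are strand-oriented offsets from the TSS (TSS =
`tx_start` on +, `tx_end − 1` on −): distal promoter −10 000 to −4 000,
proximal promoter −4 000 to +2 000, both half-open in offset space.
Precedence when an anchor satisfies several definitions across genes:
proximal promoter > distal promoter > exon > intron > intergenic — the
promoter call is the biologically prioritized claim, and intergenic is
defined purely residually. Classification is total and single-valued;
compartment fractions over a peak set sum to 1 by construction.

Peak-to-gene assignment is nearest-TSS: the gene whose TSS minimizes the
absolute distance to the anchor, ties broken by the lexicographically
smaller symbol, one gene per peak. Chromosomes without genes yield the
sentinel `unassigned`, excluded from target sets. Duplicate gene symbols
in an annotation are collapsed to the longest transcript before any query,
so every symbol has one deterministic TSS. Target genes are grouped by
binding location: a peak is a "promoter" peak of its nearest gene when its
anchor lies in that gene's proximal window, otherwise "distal"; genes then
partition into distal-and-promoter / distal-only / promoter-only.

## Enrichment statistics

**Overlap enrichment.** For a target set T and signature S inside a
universe U (default: all annotation symbols; symbols outside U are dropped
with a warning), the enrichment score is observed/expected overlap,
ES = k / (|T|·|S|/|U|), and the p-value is Fisher's exact test on the 2×2
membership table, one-sided for enrichment by default (two-sided by flag).
The test suite verifies the p-value against an exhaustive hypergeometric
tail enumeration with exact integer binomials for every feasible table
with |U| ≤ 50.

**GSEA-style running score.** Genes are ranked by signal-to-noise,
(mean_KO − mean_wt)/(sd_KO + sd_wt), each sd floored at
max(0.2·|mean|, 0.2); ties break by symbol; a preranked mode bypasses the
metric. Walking the ranked list, set members increment the running sum
proportionally to |score|^p (p = 1 by default, normalized to sum 1) and
non-members decrement 1/(N − n_hits); the ES is the signed extremum, and
the profile returns to 0 at the list end. The null is *gene-set
permutation*: `n_perm` (default 1000) random same-size sets drawn from the
ranked genes. NES divides ES by the mean |ES| of same-signed permutations;
the nominal p is the same-signed tail fraction (reported as 1/n_perm when
no permutation is at least as extreme); FDR compares observed |NES| to the
pooled permuted |NES| distribution (ratio of tails, clipped to [0, 1]).
All permutation results are bit-reproducible under a fixed seed.

## Expression integration

Differential expression is a per-gene two-tailed t-test on log2 values
with a fold filter: pass ⇔ |mean_KO − mean_wt| ≥ log2(1.5) and p ≤ 0.05
(both cutoffs configurable, direction restrictable). The default is
Welch's unequal-variance form for robustness; the pooled form is a flag.
No multiple-testing correction is applied by the filter itself —
Benjamini–Hochberg q-values can be reported alongside. The t-test's type-I
rate is verified at ~5% on a 2000-gene null simulation.

`fraction_bound` reports |up ∩ targets| / |up| — the fraction of
upregulated genes whose loci carry a peak. `ratio_by_group` summarizes
per-gene KO/wt log2 expression ratios (mean over replicates) as
five-number summaries per gene group. `delta_delta_ct` implements qPCR
relative quantification, 2^−ΔΔCt.

## Synthetic experiment generator

The generator emulates the data structure the pipeline assumes, with known
ground truth, on one synthetic chromosome.

* **Annotation**: `n_genes` non-overlapping genes in uniform slots (error
  if fewer than 30 kb of room per gene), random strand, 2–5 exons, 4–12 kb
  long, 10–14 kb into their slot so promoter windows stay inside the slot.
* **Peaks**: `n_common` null peaks placed uniformly without overlap, plus
  `n_diff_ko` + `n_diff_wt` differential peaks placed in a promoter or
  distal window of designated target genes. Widths are 1.5–2.5 kb, the
  typical scale of histone-mark enrichment regions. Per peak,
  A ~ Uniform(4, 12) log2 reads/kb; log2 densities are
  KO = A + L/2 + ε/2 and wt = A − L/2 − ε/2 with L = c0 + c1·A and
  ε ~ Normal(0, noise_sd), so raw M is exactly c0 + c1·A + ε and the
  average log2 density is exactly A. Differential peaks add ±Δm to the
  knockout side and appear **only** in the catalog of the sample where
  they are enriched, as a peak caller would see them; counts for both
  samples are still emitted over every region. Counts are
  round(density × length / 1000).
* **Reads**: per region, exactly `count` reads with midpoints uniform in
  the region, so midpoint counting recovers the counts exactly.
* **Signature**: `signature_size` genes drawn without replacement with
  odds `rho` for knockout-target genes versus background.
* **Expression**: per-gene baseline Normal(7, 1) log2 units; knockout
  replicates add `beta` at knockout-target genes; residual
  Normal(0, expr_sd) per cell; `n_reps` replicates per condition.

Defaults (the study conditions every end-to-end test uses): n_genes = 1000,
chrom_length = 5×10⁷, n_common = 2000, n_diff = 200 + 200, c0 = 0.4,
c1 = 0.1, noise_sd = 0.3, Δm = 2.5, signature_size = 150, rho = 8,
beta = 1.0, n_reps = 4, expr_sd = 0.3, seed = 20130618. One seed
sequence spawns independent per-stage generators, so outputs are
byte-identical under a fixed seed and stages can be regenerated
independently.

What the generator does **not** model: GC and mappability bias, fragment
size, inter-peak background signal, multi-isoform TSS structure,
correlated replicate noise, probe-level microarray effects. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated generative model, not performance on the noise
structure of real libraries.

## Verified end-to-end properties

On the default conditions the test suite checks (all computed, not
asserted constants): recovery of (c0, c1) within ±0.05; invariance of the
fit to masked contaminated peaks (1e-6); specific-peak sensitivity ≥ 0.90
and specificity ≥ 0.95 against truth; mean normalized M of fitted peaks
within ±0.05 of 0; shift-equivariance of normalization; unit expectation
of the overlap ES for random sets; exactness of the Fisher p against
enumeration (|U| ≤ 50); agreement of pairing and Venn partitions with
quadratic scans (100 random instances ≤ 200 peaks); GSEA power
(p ≤ 0.01 for a top-5% set at 1000 permutations) and bit-reproducibility;
t-test type-I calibration, knockout-target ratio median within ±0.15 of
beta, and ≥ 90% power at the 1.5-fold/p ≤ 0.05 filter; and byte-identical
reruns of the full pipeline. Scaled-down problem sizes (60–120 genes,
80–120 common peaks, 150–200 permutations) are used where the property
under test is structural rather than statistical.

## Known limitations

* Two samples only; multi-sample normalization is out of scope.
* One TSS per gene symbol (longest transcript); no isoform-aware windows.
* The union-catalog convention measures both samples' reads over every
  region; it does not model blacklist filtering or input subtraction.
* The GSEA FDR is the simple pooled ratio-of-tails estimate; it is
  informative for small set collections but not a calibrated q-value for
  large ones.
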