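# Methods

`triadex` analyses gene expression inheritance in F1 hybrids relative to
their parents. Its substrate is a bulk RNA-seq count matrix over *triads* —
(female parent, male parent, hybrid) genotype sets — plus companion
phenotype, annotation and qPCR tables. This note documents the models,
their parameters and defaults, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Differential expression

All three pairwise contrasts of a triad (hybrid vs female, hybrid vs male,
male vs female) are tested with one internal negative-binomial Wald test so
the downstream pattern classification is internally consistent.

**Normalization.** Median-of-ratios size factors: for genes detected in
every library, the per-sample median of log(count / gene geometric mean),
exponentiated and rescaled so the factors have geometric mean 1. When no
gene is detected everywhere (very sparse inputs), upper-quartile scaling of
nonzero counts is used instead. CPM divides counts by
`size_factor × geometric-mean library size`; this makes the factors carry
all between-sample depth differences exactly once, so rescaling one library
leaves its CPM column unchanged after factor recomputation. FPKM further
divides by gene length in kb and requires a gene-length table.

**Dispersion.** Per-gene method-of-moments estimates pooled within groups
(`var(count/sf) = μ/sf + α μ²` solved for α), a least-squares mean trend
`α(μ) = a0 + a1/μ` fitted through the usable estimates, and shrinkage of the
gene estimates toward the trend with weight `shrink_weight` (default 0,
i.e. the floored trend itself). Full shrinkage is the default because at 2–3
replicates the raw moment estimates are so noisy that any appreciable
per-gene weight makes the Wald test anti-conservative (measured type-I
~0.06–0.09 at weight 0.25–0.5 versus ~0.05 at weight 0, μ = 100,
dispersion 0.05, 3 + 3 replicates). The dispersion floor is 1e−4.

**Test.** log2 fold change of size-factor-normalized group means with
pseudocount 0.5; delta-method standard error from the NB variance; Wald z
against the standard normal; two-sided p; Benjamini–Hochberg q over tested
genes. Genes with fewer than `min_total` (default 10) summed counts across
the contrast are excluded from testing and reported untested. A gene is
"up" when `log2FC > fc_threshold` (strict) and the p-value (raw by default;
BH q with `use_adjusted`) is `< alpha` (strict); "down" symmetric. Defaults
`fc_threshold = 1`, `alpha = 0.05` match the conventional DEG criterion
|log2FC| > 1, p < 0.05.

## Pattern classification

Each gene's three DE states (each up/down/ns) map deterministically onto
the classical inheritance-mode groups: conserved (0), additive (1–2),
male/female expression-level dominance (3–4 / 5–6), downregulated
overdominance (7–9), upregulated overdominance (10–12), ambiguous (13).
The full 27-combination table is enumerable (`enumerate_groups`) and each
informative group corresponds to exactly one combination.

Design choices a maintainer should know:

* **"Hybrid matches a parent" is an accepted null** — the corresponding
  contrast is ns. With few replicates this conflates "equal" with
  "underpowered"; ELD calls are therefore power-limited, a known caveat of
  this classification family.
* **Direction consistency.** ELD requires the hybrid-vs-other-parent
  direction to agree with the parent-vs-parent direction; additivity
  requires both hybrid-parent contrasts significant in opposite directions
  *and* consistent with the parental ordering (strict betweenness).
  Direction-inconsistent triples — possible because test calls are not
  transitive — go to the ambiguous bin rather than being forced into a
  geometry they contradict. This leaves 14 of the 27 combinations
  ambiguous.
* **Within-rollup numbering** (e.g. which of 7/8/9 has female > male) is
  this package's canonical convention: the first index of each
  overdominant sub-triple has the female parent high, the middle has
  parents equivalent, the last has the male parent high. Swapping the
  female/male labels maps 1↔2, 3↔5, 4↔6, 7↔9, 10↔12 and fixes 0, 8, 11, 13.
* Genes failing the count filter are reported as group 0 with a
  `low_expression` flag, never dropped silently.

## Gene-set algebra

Venn partitions of 2–3 named DEG sets into disjoint regions (an UpSet-style
membership table for more); the cross-hybrid common overdominant set (a
gene must be OD in *every* hybrid; OD-up and OD-down pooled by default,
with a flag requiring matched direction); and per-gene z-scores (population
n denominator; constant rows returned as zeros and flagged) for exporting
shared-gene expression profiles.

## Enrichment

One-sided hypergeometric over-representation per term, computed through the
stable survival function, BH correction across tested terms, rich factor
k/K. The background universe defaults to all annotated genes (the analysis
universe is rarely the whole genome and the choice materially shifts p;
it is explicit and configurable). Two presets mirror common reporting
conventions: `go` flags raw p < 0.01, `kegg` flags BH q ≤ 0.05. No GO-DAG
propagation is performed — annotation is taken as given flat sets (stated
limitation). An independent log-gamma combinatorial sum
(`hypergeom_bruteforce`) is kept in the package as the reference oracle;
the two routes agree to < 1e−10 over the full lattice N ≤ 60.

## Heterosis

MPV = (mean P1 + mean P2)/2; MPH% = 100 (H − MPV)/MPV; BPH% relative to the
better parent. Significance of the hybrid against the mid-parent level uses
a Welch two-sample t-test of hybrid replicates against replicate-wise
mid-parent composites (P1ᵢ + P2ᵢ)/2 — robust to unequal variances and to
the composite's smaller spread; with unequal parent replicate counts it
falls back to a one-sample t against the scalar MPV (logged). Marks follow
the two-star convention: `**` p < 0.01, `*` 0.01 ≤ p < 0.05. The composite
construction is a design choice: the procedure behind published mid-parent
stars is rarely stated, so the package picks one defensible test and
documents it rather than guessing a specific historical one.

## qPCR

2^−ΔΔCt relative quantification: per-replicate ΔCt = Ct(target) −
Ct(reference), genotype-mean ΔΔCt against a calibrator genotype (default
the shared female parent, so all genotypes display on one scale), fold =
2^−ΔΔCt with the replicate SD of ΔCt propagated to a fold range. Plate-wide
Ct shifts cancel; changing the calibrator rescales all folds by one common
factor. Concordance with RNA-seq folds is summarized by Spearman rank
correlation and the fraction of matching up/down directions. Primer
efficiency is assumed 100% (no Pfaffl correction) — stated limitation.

## Synthetic data

The generator emulates the emulated study design end to end: one female
parent (A) × three male parents (B, C, D) → hybrids (H, M, L), two tissues,
3 replicates → 42 libraries; five plants per genotype per timepoint for
biomass at 10/20/30 DAE. Defaults: 2000 genes; class proportions 70%
conserved and 6% each of additive, M-ELD, F-ELD, OD-up, OD-down; planted
effect |log2FC| = 2; baseline means log-normal (median 150, log-sd 1);
NB dispersion α(μ) = 0.05 + 1/μ; library-size log-sd 0.1; biomass CV 10%
with hybrid means planted at MPV × (1 + MPH target) (defaults: H gains up
to +20% by 30 DAE, M tracks its mid-parent, L lags −15%); Ct noise
0.25 cycles. All sub-generators draw from label-derived sub-streams of one
seed, so adding a generator never perturbs the others and equal seeds give
byte-identical outputs.

Class geometries: conserved — all genotypes equal; ELD — parents 2^|lfc|
apart, hybrid at the matched parent; overdominant — parents equal, hybrid
2^±|lfc| beyond them; **additive — hybrid at the geometric (log-scale)
mid-parent**. The geometric choice is deliberate: fold-change thresholds
and the NB test operate on the log scale, where additivity of allelic
contributions places the hybrid symmetrically ±|lfc|/2 from both parents.
The arithmetic mid-parent would sit only log2(2e/(1+e)) ≈ 0.68 log2 units
from the high parent at e = 4, below what a 3-replicate NB test at
dispersion 0.05 can resolve reliably (log2FC sd floor ≈ 0.26), making
planted additivity undetectable by construction rather than by noise.

**Recovery configuration.** Parameter-recovery checks classify with
`fc_threshold = 0.5` — half the smallest planted margin (the additive
±1.0) — because a threshold equal to the margin rejects half of the true
calls however deep the sequencing; the pipeline's analysis default remains
`fc_threshold = 1`. Recovery runs use constant dispersion 0.05 and 5000
genes per tissue; at these settings every planted rollup is recovered at
≥ 0.87 and planted-conserved genes leak into overdominant groups at well
under the per-contrast false-positive rate.

What the simulator does **not** emulate: GC/length biases, batch effects,
isoform structure, correlated genes, outlier libraries, allele-specific or
homoeolog-resolved expression, and annotation term overlap structure.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not robustness to every artifact of real
libraries.

## Numerical details and degenerate inputs

Strict inequalities throughout the DEG criterion (log2FC exactly at the
threshold is ns). Identical counts give log2FC 0 and p = 1 exactly. The SE
floor is 1e−8; all-zero matrices are errors for size factors; a group with
fewer than 2 replicates is an error, never a silent fallback. Enrichment
sorts by (p, term id) for deterministic output; BH is applied only over
tested genes/terms. Zero-variance heterosis inputs return p = 1. Problem
sizes in tests (2000 null genes for calibration, 5000-gene recovery runs,
10 000 phenotype null trials) were chosen to make Monte-Carlo error small
relative to the tolerances being checked.
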