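# Methods

## Study design being modelled

The pipeline targets a two-population bulk RNA-seq design. The
ligand-bearing population is cultured oligodendrocyte precursor cells
(OPCs) in four groups — wild type (WT) or TNFR2-knockout (KO), each
non-stimulated (NS) or stimulated (St) for a few hours with a
TNF/IFNγ/IL1β cocktail. The receptor-bearing population is spinal-cord
microglia profiled in vivo, naïve or at acute EAE. Each cell
type/condition group carries 3–4 biological replicates; the per-group
count is a single configuration knob (`n_replicates`) rather than a mixed
3/4 layout, because the original design does not specify which groups had
the fourth replicate.

Four pairwise DE comparisons structure the OPC side: KO-NS vs WT-NS,
WT-St vs WT-NS, KO-St vs KO-NS, and KO-St vs WT-St. Throughout, log2FC is
oriented as (right-hand group label first): `log2FC = mean(B) − mean(A)`
for "B vs A".

## Synthetic-data generator

Counts follow a negative binomial law, the standard bulk RNA-seq model:
gene g in sample s has mean μ(g, s) = 2^(β(g) + δ(g, group(s))) · f(s) and
variance μ + μ²/φ with size parameter φ (`dispersion`, default 10, i.e.
a biological CV of ~32% on top of Poisson noise — typical of cultured
replicates).

- β(g): per-gene baseline, log₂-normal around `baseline_mean` (default 100
  counts) with SD `gene_mean_sd_log2` = 0.35. This gives a moderate
  between-gene spread; real expression distributions are far heavier
  tailed (spanning 4–5 orders of magnitude), which is deliberately not
  emulated — the generator is a calibration instrument, not a portrait of
  a transcriptome.
- f(s): per-sample library-size factor, log-normal(0, 0.1), so that
  normalization is non-trivial.
- δ: planted effects. `n_de_up`/`n_de_down` genes shift by ±`de_log2fc`
  (default 2) in both genotypes' stimulated OPC groups. Active
  ligand–receptor pairs take their ligands from the planted up-genes;
  their receptor genes are elevated by `receptor_log2fc` (default
  = `de_log2fc`) in microglia in both conditions — constitutively
  expressed receptors — plus `eae_log2fc` (default 1) extra at EAE,
  mirroring receptor up-regulation in inflamed microglia.

Transcript lengths are uniform on `gene_length_range` (default
1000–3000 bp, the bulk of mRNA lengths). Gene ids are synthetic
(`G000001`…); `alias_gene_names=True` renames the first three planted
pairs to Ccl2/Ccr5, Csf1/Csf1r, Cx3cl1/Cx3cr1 for readable fixtures.

All three generator entry points (counts, annotation, pair list) derive
independent random streams from the single `seed`, so any subset of
outputs is bit-reproducible.

**What passing tests show, and what they do not.** The generator matches
the analysis' distributional assumptions exactly, so green tests certify
the *procedure* (arithmetic, null construction, calibration, recovery
under the stated effect sizes). They do not certify behaviour under
heavy-tailed expression, outlier replicates, batch structure, or
misspecified dispersion — none of which the generator emulates.

## Normalization

CPM and FPKM use the raw column sum as library size; the true mapped-read
totals of a real experiment are not recoverable from a count matrix, and
no TMM/effective-library correction is applied (FPKM is the target
quantity; a composition-robust scheme is out of scope). Consequence worth
knowing: when many genes shift in one direction in one group, per-sample
totals shift too, and CPM/FPKM fold changes are compressed by the
composition change (≈0.3–0.4 log₂ units under the generator's default
asymmetric planting). The raw-count group-mean ratio is unbiased and is
what the recovery tests check against.

Log transforms are base 2 with pseudocount 1 — matching the log2CPM /
log2FC conventions of the DE filter — both exposed as arguments. A
log-transformed matrix records its transform and pseudocount and refuses a
second log.

## DE filtering

"Adjusted p-value" is Benjamini–Hochberg (the edgeR default; delegated to
statsmodels). Filters are inclusive at their boundaries: p_adj ≤ α
(default 0.05), mean log2CPM ≥ 1, |log2FC| ≥ 0.585. The abundance value is
the comparison-wide mean log2CPM. A `significance_only` mode applies only
the adjusted-p rule, for headline DE totals counted before the
abundance/effect floors. With a zero effect floor, a gene at log2FC
exactly 0 has no direction and is assigned to neither set.

The built-in two-group test is a Welch t-test on log2CPM. It exists so the
pipeline runs end to end; it is noticeably conservative at n = 3–4
(null-world raw-positive fraction ≈3% at α = 0.05) and underpowered
relative to an NB count-model fit, which is intentionally not
reimplemented. Genes with zero variance in both groups get p = 1 and are
never flagged, avoiding NaN propagation; their log2FC is still reported.
With `dispersion` = 10 the per-gene log2FC estimator has SD ≈ 0.34 at
n = 4, so individual planted effects of 2 are recovered within ±3 SE
(≈±1), not within ±0.5; tests assert the former.

## UpSet decomposition

Exclusive-intersection semantics: each gene belongs to exactly one
membership pattern; empty patterns are omitted; class sizes sum to the
union size. The red category is read as the exclusive triple intersection
of the three stimulation-involving comparisons (standard UpSet reading of
the plot column); an inclusive mode (intersection regardless of the fourth
set) is provided because prose descriptions of "shared" gene sets are
ambiguous between the two conventions. Up and down directions are
decomposed independently.

## Ligand–receptor interaction analysis

Score: mean of the ligand's average log-FPKM (OPC samples of one
genotype×condition) and the receptor's average log-FPKM (microglia samples
of one condition). Scores are translation-equivariant (adding c to all log
values adds c to every score) and are comparable within a run.

Null: gene-role randomization. Each draw picks a ligand-role gene and a
receptor-role gene independently and uniformly from the expressed universe
(genes present in both matrices with mean log-FPKM > 0 in each, per
context; the floor is configurable) and scores them in the same context.
The two roles are evaluated in different matrices, so a coincident draw is
a valid assignment, and the exhaustive reference space is all |U|²
ordered role pairs. One-sided (high score = interaction), ties counted as
extreme, add-one estimator — so p ∈ (0, 1] with granularity
1/(n_perm + 1) and exact-zero p-values cannot occur. No multiple-testing
correction is applied across pairs by default (each pair's p is reported
per context); BH can be applied downstream via `bh_adjust`.

Because the null holds the context fixed and randomizes only roles, the
test asks "is this pair's combined expression high relative to arbitrary
gene pairings here?" — it rewards any pairing of two highly expressed
genes, including re-combinations of a genuinely induced ligand with an
unrelated abundant receptor. Ranking by score inherits the same property.
This is intrinsic to expression-level pair scoring, not an implementation
artifact, and is visible in the default simulation: with several planted
DE genes, cross-pairings can outscore a planted pair.

Per-(context, pair) random streams are spawned from one seed via
`numpy.random.SeedSequence`, making the full table deterministic under
(inputs, seed, n_perm) while keeping pairs' nulls independent.

## Problem sizes

Default analyses use 2000 genes × 18 samples, 200 pairs and 1000
permutations per pair (a full 8-context run is ~1.6 M null scores — a few
seconds, since each null score is a sum of two precomputed gene means).
Calibration experiments in the tests and the reproduction script use
1000-gene studies: 20 replicate null worlds for type-I error and 100
replicate studies for planted-pair recovery. These sizes give Monte-Carlo
error comfortably below the asserted tolerances.

## Known limitations

- FPKM/CPM composition bias (above); no TMM.
- The Welch plumbing test is not a substitute for a count-model DE fit.
- The expressed-universe floor (mean log-FPKM > 0) is a crude expression
  filter; very small universes make the permutation null coarse.
- Single-cell semantics (cluster means, cell-label permutation) are out of
  scope; the pair list is taken as given and is not ortholog-mapped.
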