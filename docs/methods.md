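# Methods

This note documents the statistical procedures implemented in
`stagemirror`, the synthetic-data generator that exercises them, the
numerical choices that were genuinely open, and the limits of what the
package's tests demonstrate about real data.

## 1. Consensus differential expression

**Normalization.** Counts are normalized to RPM
(`counts · 10⁶ / column sum`) and RPKM (`RPM · 10³ / length_bp`). Both are
reporting scales; the count-model caller works on raw counts with size
factors.

**Callers.** Three lightweight callers sit behind one registry so that
output from heavyweight count-model packages can replace any of them as a
TSV of (gene, log2fc, pvalue):

* `nb_exact` — a negative-binomial conditional exact test. Counts are
  modeled as NB with variance `μ + φμ²`. Size factors are median-of-ratios
  against the per-gene geometric-mean reference (composition-robust;
  library-size ratios are the fallback when fewer than 50 genes are
  expressed in every sample). A single common dispersion is estimated by
  pooled method of moments on size-factor-normalized counts,
  `φ̂ = mean[(v − m·mean(1/s))/m²]` over well-expressed genes in both
  groups, floored at 10⁻⁸. The test conditions on the per-gene total
  `k = k_A + k_B` of group sums (group-sum dispersion `φ·Σs_j²/(Σs_j)²`)
  and sums the probabilities of all splits no more likely than the
  observed one — the classical two-sided exact construction. For totals
  above 20 000 the support is windowed around the conditional mean.
* `lognorm_t` — Welch's t-test per gene on `log2(RPM + 0.5)`.
* `perm_mean` — permutation test on the difference of group means of
  `log2(RPM + 0.5)`; exhaustive over all group labelings when there are at
  most 10⁴ (e.g. C(12,6) = 924 at n = 6+6), otherwise 10⁴ seeded
  Monte-Carlo draws with an add-one estimator.

All callers share one log2FC estimator — `log2((m₂ + 0.5)/(m₁ + 0.5))` on
group-mean RPM; the pseudocount of 0.5 avoids infinities at zero counts.
Each caller's p-values are BH-adjusted over all genes.

**Consensus rule.** A gene is a consensus DEG iff its FDR is strictly
below 0.1 in *every* caller and the consensus log2FC (arithmetic mean of
caller log2FCs; the callers share the estimator, so this is the common
value) strictly exceeds 0.5 in magnitude. Direction is the sign of the
consensus log2FC. All thresholds in the package are strict inequalities.

**PCA.** The 300 most variant genes on `log2(RPM + 1)` (a documented
stand-in for a model-based variance stabilization, which is out of scope)
feed an SVD-based PCA; variance ties break by gene id, and each
component's sign is fixed so its largest-|loading| gene loads positively —
both purely for determinism.

## 2. Probe harmonization of the staged cohort

Probe-level log-intensities are compared stage-vs-normal per probe with
Welch's t (or an optional moderated variant: pooled variance shrunk toward
the mean variance with prior weight d₀ = 4, df = d₀ + n₁ + n₂ − 2). Probes
then collapse to genes:

* gene logFC = arithmetic mean of probe logFCs;
* genes with at least two probes of strictly opposite nonzero logFC sign
  are **excluded entirely** and reported with their probe logFCs (a probe
  with logFC exactly 0 is sign-neutral);
* gene p = min probe p × probe count, capped at 1 (Bonferroni-min). This
  is a deliberately simple stand-in: no principled probe-aware model is
  attempted, and the rule is recorded in the profile's metadata;
* BH runs across genes *within each stage* (the smallest family
  consistent with a per-gene, per-stage FDR), so stages are independent
  testing families. Differential flag: FDR < 0.1, strict.

The stage vocabulary is closed (normal, posAD, proAD, defAD); unknown
labels are rejected rather than ignored, to fail fast on mislabeled
sample sheets.

## 3. Stage matching

The correlation universe is the consensus DEG members intersected with
the non-excluded cohort genes (an option widens to all shared genes).
Pearson r and its t-transform p-value are computed per stage; direction
concordance is `100 · #(sign-agreeing pairs) / #(both-nonzero pairs)` —
zero logFCs leave the denominator because their sign is undefined.
Keyword-restricted correlations intersect the universe with the union of
gene sets whose names contain the keyword (case-insensitive substring);
restrictions with fewer than 3 genes are reported not-computable, never
as r = 0. The sample-wise matrix correlates every pair of samples over
common genes after within-dataset gene centering (removing platform
offsets); the assignment rule picks the stage with maximal r and flags
ambiguity when the runner-up is within 0.02 (a documented constant — by
eye the choice is obvious, in code a tie needs a rule).

## 4. Enrichment

* **ORA**: right-tail hypergeometric, `p = P(X ≥ k)`, BH < 0.05 across
  tested sets. The default universe is all genes tested for DE.
* **Per-pathway Wilcoxon**: for each set with strictly more than 10 DEG
  members, a two-sample rank-sum of in-set vs out-of-set DEG log2FCs
  (exact for small tie-free samples, normal approximation with continuity
  correction otherwise); reported at unadjusted p < 0.05. The two-sample
  reading is a documented choice — comparing against zero instead is
  available as `mode="one_sample"` without any claim of equivalence.
* **Preranked GSEA**: genes ranked by log2FC descending (ties by gene id),
  hit increments `|log2FC|¹/NR`, miss decrements `1/(N − N_h)`; ES is the
  signed extreme of the running sum. Null: random same-size gene sets
  (gene-label permutation), seeded; `p = (1 + #{same-sign |null| ≥ |ES|})
  / (1 + #same-sign)`, bounded below by `1/(B+1)`;
  `NES = ES / mean |same-sign null ES|`. Defaults minSize 15, maxSize 500.
* **Common-gene nuclear analysis**: common-up genes are up-DEGs with stage
  logFC > +0.1 (common-down symmetric), analyzed separately by ORA at
  *unadjusted* p < 0.05 and filtered to sets whose names contain a nuclear
  keyword (transcription, chromatin, chromosome, histone, DNA). The
  unadjusted threshold here vs BH for the main ORA is intentional: the two
  call sites keep their own conventions rather than being unified.

## 5. Acetylation concordance

Per gene across call tables: **down** if every dataset reporting a change
calls down, **up** symmetric, **any** if at least two datasets disagree
(a gene called in a single dataset can never be 'any'), **uncalled**
otherwise. Absence from a dataset never breaks concordance. Upset-style
exclusive intersections partition each DEG direction set over the four
classes; over-representation of each (direction × class) pair uses the
right-tail hypergeometric against the DE-tested gene universe (the
genome-wide baseline; swappable), BH-adjusted across the six tested pairs
in one call.

## 6. The synthetic-data generator

The generator's defaults are the desk-scale study conditions used by the
test suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | gene universe |
| n_per_group | 6 | samples per condition |
| frac_de | 0.10 | planted DE fraction (half up, half down) |
| lfc_magnitude | 2.0 | planted \|log2FC\| |
| nb_dispersion | 0.05 | NB dispersion φ (variance μ + φμ²) |
| library_size_mean | 10⁶ | reads per sample (log-normal, σ = 0.15) |
| stage samples | 20 per stage | scaled-down cohort (the real cohort's 110/110/83/163 are one config away) |
| target_r | −0.3 / +0.6 / 0.0 | planted stage correlations (posAD/proAD/defAD) |
| stage_effect_sd | 0.5 | scale of gene-level stage effects (log2) |
| noise_sd | 0.3 | per-sample intensity noise (log2) |
| probes_per_gene | 2 | mean of 1 + Poisson(1) probes per gene |
| frac_discordant_genes | 0.05 | genes given one sign-flipped probe |
| acetylation | 3 datasets, coverage 0.6, concordance 0.9 | call tables |

**Counts.** Relative abundances are log-normal(0, 1); per-sample expected
means are `abundance · 2^β · library`, with β = ±lfc_magnitude for planted
genes; counts are NB draws. Because total-count normalization is part of
the analyzed method, the linear-space mass imbalance of symmetric ±2
log2FCs (≈ +11%) is left in the data — it is exactly the composition
artifact a robust caller must absorb.

**Stage correlations.** Gene-level stage effects for DE genes are
`stage_effect_sd · (r·t̂ + √(1−r²)·ε̂)` with t̂ the standardized truth
log2FCs and ε̂ standardized noise *orthogonalized against t̂*, so the
planted correlation is exact (to 10⁻⁶, verified at generation time) at the
expected level; non-DE genes drift with σ = 0.05. Probes inherit their
gene's effect exactly; intensities add a per-probe offset (σ = 0.25) and
per-sample noise.

**Discordant probes.** Discordant genes are drawn from the non-DE pool —
excluding them downstream then cannot disturb the planted correlations,
which live on the DE set — and receive one extra probe whose per-stage
effect has flipped sign and resampled magnitude. Both the flipped probe
and the gene's regular probes are planted at |logFC| ≥ 0.75 so the
opposite signs are estimable at 20 samples per stage and exclusion is
deterministic. Note that the exclusion rule also removes a substantial
number of *ordinary* multi-probe genes whose true stage effect is near
zero (their probe logFC signs are coin flips) — an aggressive but faithful
consequence of the sign-discordance rule, and one reason the rule's
real-world cost is worth knowing.

**Gene sets and acetylation calls.** Planted enriched sets draw 90% of
members from the DE genes; a configurable fraction of set names embeds
keywords so keyword-restricted analyses have matches. Acetylation datasets
call an independent coverage-fraction of genes; called DE genes agree with
their true direction with the planted concordance probability, non-DE
genes are fair coins.

**What the generator does not emulate:** read-level data, probe sequence
or array physics, multiple brain regions (one unnamed region surrogate),
correlated noise between samples, gene–gene correlation, and realistic
GO-style set overlap structure. Passing tests therefore demonstrate the
pipeline's statistical correctness and its recovery behavior under the
stated generative model — not performance on any particular real cohort.

## 7. Determinism and numerics

Every random draw flows from an explicit seed; the pipeline fans one
global seed out to per-stage seeds by stable SHA-256 hashing of stage
names, and identical config + seed reproduce byte-identical outputs (all
floats are written with repr-faithful `%.10g`). Ties are always broken by
identifier (variance ranking, GSEA ranking, stage assignment order).
Degenerate inputs have defined behavior: zero-variance genes give p = 1
when group means agree, zero-logFC probes are sign-neutral, correlations
on constant vectors raise a dedicated error rather than returning NaN, and
empty Wilcoxon results warn instead of failing.

## 8. Problem sizes

The test suite and acceptance script run at the defaults above: 2000
genes, 6+6 count samples, 80 cohort samples, 100 gene sets, 3 acetylation
datasets, 10–20 seeds per Monte-Carlo claim and 100–1000 permutations for
GSEA — sizes chosen so a complete verification runs in minutes on one CPU
while every recovery criterion (recall/precision of planted DE, ±0.1 on
planted correlations, exclusion completeness, enrichment sensitivity) is
comfortably measurable. The real cohort sizes are reachable purely through
configuration.

## 9. Known limitations

* The three built-in callers are deliberately lightweight; they are
  calibrated and validated against oracles here, but they are not
  replacements for mature count-model packages on real data — the
  intended real-data route is importing external caller output.
* The Bonferroni-min gene p after probe collapse is conservative and
  ad hoc; an explicit probe-aware linear model would be preferable when
  probe counts are large.
* The per-pathway Wilcoxon's comparison population is a genuine modeling
  ambiguity; both supported modes are labelled in the output.
* ORA assumes exchangeable genes within the universe; no coverage or
  length bias correction is attempted.
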