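# Methods

## Scope and data model

The pipeline starts from *normalized* log2 expression matrices (features ×
samples) with a sample design (treatment ∈ {saline, morphine}, strain,
replicate), a pair-level target-prediction table (miRNA, mRNA, mirSVR,
optional PhastCons), hot-plate latency records, qRT-PCR Ct records,
luciferase well readings and densitometric band intensities. Array
preprocessing, probe summarization, GEO formats and the computation of
mirSVR/PhastCons scores themselves are out of scope: those are consumed,
not produced.

Feature ids may repeat within a matrix (distinct probes can share a miRNA
name — mature and star strands are distinct tokens, but array reports
occasionally carry true duplicates), so the data model never assumes a
unique feature index; sample ids are strictly unique. Ids are
case-preserved and matched case-insensitively, with a logged warning when
two spellings collide.

## Behavioral scoring

%MPE = 100·(min(test, c·b) − b)/((c−1)·b) with baseline b and cutoff
factor c (default 4). The baseline is the *per-genotype, per-injection-day*
saline-group mean: published vehicle baselines differ by day (6.4–9.4 s),
so a pooled baseline would bias day-specific scores. Latencies above the
cutoff clamp to 100 (flagged); latencies below baseline give negative %MPE
(hyperalgesia) and are reported unclamped. The module emits per-cell
mean/SEM trajectories and a first-minus-last `tolerance_delta`, plus a
plain equal-variance two-group genotype comparison per injection day.
Repeated-measures ANOVA with cage-order covariates is deliberately out of
the core contract — it is stock statsmodels territory, whereas the %MPE
transform and baseline convention are the substance here — and cage
structure is not part of the data model.

## Assay quantification

Comparative Ct uses a fixed amplification efficiency of 2 (no efficiency
correction), a single reference gene per sample (multiple reference wells
are averaged), and condition-level ΔCt as the mean over biological
replicates. Luciferase wells are normalized Renilla/firefly per well,
averaged technical-first within biological replicates (avoiding
pseudo-replication), and expressed as percent of a control condition.
Densitometry reports per-group target/actin ratios, the ratio of group
means, and an equal-variance two-sample t test — consistent with the
degrees of freedom a 4 + 4 design implies (t with df = 6).

## Differential expression

Per feature, the equal-variance two-sample t test on log2 intensities;
with two groups this is exactly the one-way ANOVA (F = t²), so the
"ANOVA at 10% FDR" convention of array packages is reproduced without any
package dependence. Log2 intensities (not linear) are tested, the standard
choice for normalized array data. Zero-within-group-variance features are
not dropped: when the group means differ, p is floored at machine epsilon
with a warning (the feature is maximally inconsistent with the null); when
both groups are constant and equal, p = 1 (no evidence). Multiple testing
uses the BH linear step-up at `fdr_q` (default 0.10) with stable-sort tie
breaking; q-values are the usual monotone adjusted p-values so the
significance flag and `q ≤ fdr_q` coincide.

Cross-strain refinement (`strain_specific`) retains features
FDR-significant in the tolerance-susceptible strain with no raw evidence
(p > 0.05) in the resistant strain. This mirrors the qualitative
susceptible-vs-resistant contrast; it is a screening filter, not an
interaction test.

## Integration

Predictions are aggregated to pair level before filtering: mirSVR scores
of multiple sites on one 3′-UTR are **summed** to a combined pair score
(the convention used when a combined score is reported for a two-site
3′-UTR), PhastCons takes the per-site maximum. "Good-score" filtering
keeps mirSVR ≤ −0.10; strict mode additionally requires PhastCons ≥ 0.57
(the microRNA.org conventions; both config-exposed since the source
publishes no numeric cutoffs). In the default mode a missing PhastCons
passes — filtering is on mirSVR alone.

Pairing classifies each kept edge whose miRNA and mRNA are both
significant by direction concordance. Direction *calls* are used, not
sample-level correlation coefficients: with n = 4 per cell, per-feature
correlations are noise, while the sign of a called log2 fold change is
stable. Opposite directions ⇒ `negatively_correlated` (canonical
repression); same direction ⇒ `positively_correlated` (the activation
case). With duplicate probes per feature id, the probe with the largest
|log2fc| carries the direction.

Over-targeting is a one-sided (upper-tail) hypergeometric test per
significant miRNA — "over-target" is inherently one-directional. The
universe defaults to all assayed mRNAs; a config switch restricts it to
predicted mRNAs, since the choice is not uniquely pinned by the source.
Raw significance (p < 0.05) and BH-FDR pass are reported as separate
flags because small-n studies routinely find raw-significant
over-targeting that fails FDR. The tail itself is computed by
`scipy.stats.hypergeom.sf` (stable log-space); tests verify it against
brute-force draw enumeration.

Prioritization is a rank-sum over three criteria (paired-DE-target count,
best paired mirSVR, over-targeting q) with average ranks on ties, then
strain-specificity and lexicographic id as residual tie-breakers; the
output ranking is a deterministic permutation of the candidates.

## Synthetic data

The generators emulate the study design: two strains × two treatments ×
4 replicates; 780 miRNA and 1000 mRNA features with baseline log2 levels
~ Normal(8, 1.5) and Gaussian log2 noise (sd 0.5 — typical residual noise
for normalized arrays; heavier-tailed options deferred).

* **Planted DE miRNAs** (47, matching the reported count) receive log2
  effects drawn from the upper half of the reported fold-change range
  (|log2FC| ∈ {2.13 … 4.38}), signed 70% up / 30% down per the reported
  33:14 split, in the morphine × susceptible cell only. The weaker
  reported effects (|log2FC| down to ~0.34) are *below detection power*
  at n = 4 and sd 0.5 (per-feature power ≈ 0.25–0.6 at the BH-adjusted
  level); planting them would make recovery targets unattainable at the
  study's own sample size, so the default palette models the detectable
  regime and the limitation is stated here rather than hidden.
* **Planted pairs** (80 target mRNAs) shift each target by −gain·effect
  (repress) or +gain·effect (activate, ~10% of non-hub pairs); gain
  defaults to 1.
* **The hub** emulates the many-target archetype: effect +4.07, 15
  repressive planted pairs, 85 additional passing decoy predictions to
  non-DE mRNAs (100 predicted targets in total), and pair scores drawn
  from U(−1.5, −1.2) so it holds the most negative paired score by
  construction. Every other planted miRNA carries a baseline of 20
  passing decoy predictions — real prediction tables list tens to
  hundreds of targets per miRNA, and without this baseline a miRNA's
  prediction set can collapse onto its planted pairs alone, a degenerate
  k = n configuration that cannot occur in real tables.
* **Filter exercise**: 10% of non-hub planted pairs are deliberately
  scored above the mirSVR cutoff; 300 global decoy predictions span the
  cutoff (U(−0.6, 0)).
* **Latencies**: saline ~ Normal(7.0, 0.8) s truncated positive (within
  the published 6.4–9.4 s baseline range); morphine latency at injection
  i is min(cutoff, baseline + 19·r^(i−1) + noise) with decay rate r = 0.5
  (susceptible) or 1.0 (resistant) and 1.5 s observation noise; 19 s is
  an ED90-like acute effect (%MPE ≈ 90 at a 4× cutoff). 8 animals per
  group, 3 injections 48 h apart.
* **Ct records**: reference ~ Normal(20, 0.2) cycles per sample; target
  Ct = reference + per-gene offset − planted log2 fold (treated only)
  + noise, so the comparative-Ct method inverts the construction exactly
  at zero noise. 6 samples per condition.

Every generator is a pure function of (spec, seed); truth tables
(planted effects, planted pairs with expected pairing class and filter
status) are written alongside the data so recovery tests never re-derive
ground truth.

What the generators do **not** model: probe-level array physics, dye
bias, spatial artifacts, batch structure, correlated features,
heavy-tailed noise, animal dropout, cage effects. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under
idealized Gaussian conditions, not robustness to real array pathology.

## Numerical and design choices

* p-values are clipped to [machine ε, 1]; BH uses a stable sort, so ties
  keep input order.
* The hypergeometric scan excludes miRNAs with no in-universe predictions
  (n = 0) with a log entry; a single tested miRNA has q = p.
* `pair_expression` output is sorted (miRNA id, then mirSVR ascending),
  making class counts invariant to input order.
* Expression readers hard-fail on unmatched sample columns, duplicated
  sample columns and non-numeric cells (naming the offending feature and
  sample); design rows absent from the matrix are dropped with a warning.
* Delimiters are auto-detected (tab preferred, comma accepted); decimal
  point only.
* All stage outputs carry a commented header with the config hash and
  seed; the run manifest pins input SHA-256 digests and per-stage row
  counts, and excludes timestamps so reruns are byte-comparable.
* CLI exits non-zero when warnings were logged unless `--allow-warnings`
  is passed, so silent data quirks cannot slip through batch runs.

## Problem sizes in the test suite

The packaged simulations use 780 miRNA / 1000 mRNA features, n = 4 arrays
per cell, 50 seeds for recovery checks in the test suite (30 in the
acceptance script) and ~1800 features for null calibration — sizes chosen
to match the study's scale while keeping a full suite run to a few
seconds.

## Known limitations

* Direction-based pairing cannot distinguish direct targeting from
  co-regulation; it is a screening tool.
* The over-targeting universe is ambiguous in the source convention
  (assayed vs predicted mRNAs); both are implemented, neither asserted
  as canonical.
* Printed-table fixtures carry the source's own internal inconsistencies
  (a miRNA log2 value differing in the third decimal between two tables;
  one typeset-lost pairing row, retained as an explicit `missing` marker;
  an mRNA universe reported variously as 77 and 78). The fixtures
  transcribe what was printed and the package asserts nothing the source
  contradicts.
* Small planted effects (< ~1.5 log2) are not recoverable at n = 4 and
  are excluded from the default palette by design; users studying weak
  effects should raise `n_per_cell` or lower `noise_sd` in `SynthSpec`.
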