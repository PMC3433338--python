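# Methods

## Signal model

Pyrosequencing dispenses the four dNTPs one at a time in a fixed,
assay-specific order. When the dispensed base is complementary to the
template at the current synthesis position it is incorporated and the
emitted light is proportional to the number of bases incorporated at that
dispensation; a homopolymer run of length *k* gives a peak of height *k* in
per-copy units (1.0 = one incorporation). `chemistry.incorporation_walk`
implements this as a cursor walk over the read's run-length encoding: each
dispensation consumes the maximal matching run at the cursor, the cursor
never retreats, and read bases left after the last dispensation contribute
nothing.

All sequences are stored in *read space* — the analyzed (synthesized-strand)
sequence, not the template. Assays sequenced with a reverse primer (KRAS
codon 61, BRAF codon 600) store the already reverse-complemented context, so
variant edits are read-space coordinates throughout.

A specimen is an additive two-component mixture: expected height
`h_i = (1-f)·w_i + f·m_i`, exactly linear in the mutant fraction `f`.
Chemistry non-idealities (incomplete incorporation, plus/minus frameshift
carry-over, apyrase kinetics, light saturation) are not modelled; the whole
analysis rests on peak heights being proportional to incorporations.

## Assay catalog

Eight built-in assays cover EGFR codons 719, 746–753, 768 (+ insertions),
790 and 858, KRAS codons 12/13 and 61, and BRAF codon 600. Each assay stores
the printed (possibly IUPAC-degenerate) target, the wildtype resolution of
its degenerate positions, the dispensation order, and a variant catalog of
read-space edits (substitution, deletion, insertion, and deletion–insertion
for the composite exon-19 events). The exon-19 assay ships ten common
COSMIC-style deletions centred on the bracketed 15-bp block; the set is
catalog data and can be replaced via a user JSON catalog. One mutation per
specimen is assumed; compound genotypes are out of scope.

Two derived position sets drive preprocessing:

* **Unexpected positions** — dispensations with zero expected signal under
  wildtype *and every catalog variant* (for BRAF: {1, 3, 6}). Signal there
  can only be background.
* **Reference positions** — dispensations with expected height exactly 1.
  Whenever a subset of the (explicit or derived) reference set stays
  single-copy under *every* catalog variant, that shared subset calibrates
  every hypothesis: such peaks have height exactly one copy-unit no matter
  which mutation the specimen actually carries, so the per-copy unit B is
  unbiased by the unknown truth. This holds for all eight built-in assays
  (even exon 19, where dispensations 2–5 precede every deletion). Only for a
  catalog with an empty intersection does the set become
  hypothesis-specific (positions single-copy under wildtype and the named
  candidate). We initially used hypothesis-specific sets everywhere and
  measured a systematic cross-bias: a competitor hypothesis could be
  calibrated on a peak the true mutation had altered, inflating its
  evidence (G719A pyrograms at f = 0.10 were misread as G719C in ~9% of
  noisy replicates; the shared rule removes the bias).

## Preprocessing

Per pyrogram (never per plate):

* **Artifact cutoff** — twice the arithmetic mean of the heights at the
  unexpected positions. Observed peaks strictly below the cutoff are flagged
  as non-specific; a peak equal to the cutoff is kept. Flagged peaks are
  zeroed (not excluded), keeping vector shapes fixed. An empty unexpected
  set yields cutoff 0 plus a warning.
* **Reference stats** — B = mean height at the reference positions
  (instrument units per copy) and its sample (n−1) standard deviation.
  B = 0 makes the pyrogram unanalyzable.
* **Normalization** — divide by B, zero the flagged peaks. The downstream
  pipeline is therefore invariant to any positive rescaling of the signal.

## Quantification and calling

For each catalog variant the mutant fraction minimizes
`Σ_i (h_i − [(1−f)·w_i + f·m_i])²` over f ∈ [0, 1]; with d = m − w the
unconstrained optimum is `d·(h − w) / d·d`, clipped (and flagged when
clipping was needed). Candidates are ranked by root-mean-square residual,
ties broken lexicographically; the best fit is flagged ambiguous when the
two lowest residuals differ by less than 10% relatively.

The published exon-21 L858R formula
`[(1/3)·A/B + (1 − C/B) + (1 − D/E)] / 3 × 100` is implemented verbatim
(A = dispensation-3 G peak, C/D/E = dispensations 4/5/7, B = mean of the
single-copy dispensations {2, 9, 11, 12, 14}); the three terms keep equal
weight. On ideal exon-21 mixtures it equals the least-squares estimate —
both are exactly 100 f. Formulas for the other mutations are not published,
so the least-squares estimator serves uniformly.

The call rule: mutant only when the estimated percentage strictly exceeds
the threshold (default 5%, the assay's validated sensitivity); equality is
not called. A wildtype short-circuit applies only when the pyrogram fits the
wildtype pattern within tolerance (default rms ≤ 0.15 per-copy units) *and*
no candidate fits strictly better — a plain wildtype-first screen would
swallow low-fraction mutants up to rms ≈ tolerance and move the detection
boundary off 5%. Specimens whose best fit is poor (rms > 3× tolerance) are
indeterminate.

**BRAF V600K discriminator.** V600K differs from V600E subtly: besides the
mutant T at dispensation 4, the peaks at dispensations 7 and 8 drop below
normal. The rule — both below B − 2·SD (SD from reference dispensations
{9, 10, 12}) with a surviving T signal at dispensation 4 — confirms or
vetoes the V600E/V600K choice, but only when the two fits are within the
10% ambiguity margin: it resolves genuinely confusable pyrograms and never
overrides a decisive least-squares verdict. An unguarded override measurably
hurts: with 3% peak noise the 3-peak sample SD is unstable and the rule
false-fires on clean V600E pyrograms several percent of the time.

## Per-peak attribution and reports

Each fitted peak splits into a wildtype contribution `(1−f)·w_i·s` and a
mutant contribution `f·m_i·s` (s = B, instrument units). Labels: `WT` /
`Mut` when one allele contributes, `Mixed` when both do, `Noise` for
artifact-flagged peaks, `Absent` when neither allele produces signal.
Reports render as lossless JSON, a fixed-column TSV attribution table, or
human-readable text.

The 2×2 concordance utility is the standard Pearson chi-square (df = 1,
no Yates correction) with its upper-tail p. On the published call totals
[[347, 1028], [351, 1024]] it gives χ² ≈ 0.0307 (p ≈ 0.861), not the
0.061 / 0.8046 printed alongside those totals; the method behind the
printed value is unstated, and this utility makes no attempt to match it.

## Synthetic pyrograms

The generator emulates a measured run: scale × expected mixture pattern,
plus i.i.d. Gaussian peak noise (sd as a fraction of scale, default 3% —
a typical well-behaved run), plus small uniform non-specific peaks at the
unexpected positions (default 1–5% of scale), truncated at zero. All
randomness flows from the config seed. It does **not** emulate baseline
drift, per-nucleotide response differences, incomplete incorporation or
inter-dispensation crosstalk, so passing tests demonstrate correctness of
the analysis pipeline under its own signal model, not performance on any
particular instrument's raw data.

## Numerical choices and problem sizes

* Per-copy units with instrument scale estimated from reference peaks;
  1e-12 tolerance on mixture fractions summing to one.
* Fraction estimates are exact to ~1e-15 on noiseless data; recovery tests
  assert 1e-9 across the full f grid for all 35 built-in variants.
* The detection-boundary test bisects to 1e-6 in fraction (0.0001
  percentage points).
* Stochastic robustness is evaluated at f = 0.10 with 3% peak noise, 200
  replicates per variant (seeds derived from a CRC of assay, variant and
  replicate index). Thirty-four of the 35 variants identify correctly in
  ≥95.5% of replicates (2000-replicate estimates). BRAF V600E sits at
  ~93%: an oracle version of the same residual-ranking statistic with
  perfect calibration caps at ~90% because low-fraction V600K/V600R
  mixtures are geometrically close to V600E ones (pattern-difference
  angles near 45°), and the two-SD rule recovers only part of the gap —
  it fails exactly when the same dispensation-7/8 noise dip fools both
  the ranking and the rule. This is a limitation of the method at those
  conditions, not of the implementation; at f ≥ 0.15 or noise ≤ 2% the
  rate clears 95% comfortably.

## Known limitations

* Quantification assumes exactly one catalog mutation; off-catalog indels
  and compound mutations are not searched.
* No confidence intervals on the mutant fraction (point estimates only).
* The TSV dialect is this package's own; proprietary instrument run files
  are not parsed.
* Clinical concordance of the original software was established on 1375
  specimens that are not publicly available; nothing here re-evaluates
  clinical performance.
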