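# Methods

This note documents the models, statistics and numerical choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Synonymous codon recoding (`slamkit.codon`)

An alternative-codon-usage (ACU) allele preserves a protein while rewriting
the mRNA sequence, destroying sequence-level cis-elements (localization
signals, RNA–protein contact sites) as a side effect. The recoder replaces
every codon whose synonymous family has at least two members, outside
caller-supplied protected intervals. Met (ATG), Trp (TGG) and stop codons are
never changed; internal stop codons (legitimate in constructs such as
GFP-stop fusions) are preserved with a warning.

Because "replace with another suitable codon according to usage frequency"
admits two readings, both are implemented:

* **max-frequency-alternative** (default): deterministic; each codon becomes
  the most frequent synonymous codon other than itself, ties broken
  lexicographically. This maximizes divergence while staying in commonly used
  codons.
* **usage-weighted-sample**: the replacement is drawn from the family
  excluding the original, with probabilities proportional to usage; seeded
  and reproducible.

Protected intervals that are not codon-aligned are expanded outward to codon
boundaries (with a warning) — conservative in the sense that protected bases
are never mutated. The *D. melanogaster* codon-usage table ships as a data
file (`data/dmel_codon_usage.tsv`, within-family relative frequencies); any
table with the same schema can be supplied, since usage is an input, not a
constant. Non-goals: CAI optimization, secondary-structure and motif
avoidance.

## RIP-seq enrichment calling (`slamkit.rip`)

Per transcript, the enrichment factor is the ratio of IP to control
abundance, combined across replicate pairs. Three points the experimental
description leaves open are explicit, documented defaults:

* **Filter statistic**: "weakly expressed" transcripts are removed when their
  *maximum raw count across all samples* is below `min_count` (50 for the
  antibody design, 10 for the GFP-binder design; strict `<`). The maximum
  keeps transcripts detectable in either fraction; the alternative readings
  (IP-only, control-only, total) are a one-line configuration change.
* **Normalization**: counts-per-million per sample before the ratio, because
  IP and lysate libraries differ in depth; `none` reproduces a literal ratio
  of raw transcript numbers.
* **Replicate combination**: geometric mean of per-pair ratios (log-scale
  averaging is the natural scale for fold changes); arithmetic mean of
  ratios is available.

A pseudocount (default 1) is added to both numerator and denominator; with
pseudocount 0 a zero control value raises rather than emitting infinity. The
call threshold is strict (> 4-fold). Two experiments are intersected as sets;
the Venn summary reports shared and exclusive counts. Note that CPM
normalization makes calling compositional: planting many strongly enriched
transcripts inflates the IP library and shrinks every ratio by the same
factor (~1.3 under the default simulation), which is why an 8-fold planted
effect is called at ~6-fold observed.

No dispersion-based differential-expression model is fitted — the method is
deliberately the threshold-on-ratio procedure, not a DESeq2-style test.

## Kinetic fits (`slamkit.kinetics`)

**Chase decay.** I(t) = I0·exp(−k·t) is fitted by nonlinear least squares
initialized from a log-domain linear regression; on noiseless data the two
agree to machine precision (tested to 1e−9). The half-life t½ = ln2/k is
reported with the window span, so an extrapolated estimate (window shorter
than t½, as in a 10-min chase of a 40-min half-life protein) is visible in
the result. Flat or increasing traces are flagged (k ≤ 0, t½ = ∞) rather
than rejected; a log-linear slope below 1e−12/min counts as flat. No
background subtraction is applied by default.

A caveat that the tests document quantitatively: a single 11-point, 10-min
recording with 2% intensity noise determines k only to ≈12% (one relative
standard error), so a single-trace half-life estimate scatters by several
minutes and the within-10% recovery rate across seeds is ≈60%, not ≥95%.
Averaging per-recording fits across ~10 recordings brings the estimate to
within a few percent; the analysis driver and the acceptance script report
that multi-recording mean.

**FRAP.** Post-bleach recovery is fitted by OLS over a window; the slope m is
the recovery rate. Traces with an unbleached-area reference series can be
normalized pointwise first, cancelling acquisition photobleaching exactly
when signal and reference bleach proportionally. Rates are compared by slope
ratio and overlap of t-based confidence intervals (default 95%). Full
reaction–diffusion FRAP modelling and mobile-fraction decomposition are out
of scope.

## ΔCq quantification (`slamkit.qpcr`)

Technical duplicates are averaged on the Cq scale (standard practice; spreads
above 0.5 cycles are flagged), then ratio = E^(−ΔCq) with
ΔCq = Cq(target) − Cq(reference). The amplification efficiency E defaults to
2.0 (perfect doubling) and is configurable in (1, 2]; equal efficiency across
primer pairs is an assumption stated in every report. Per-sample ratios are
combined by geometric mean. No ΔΔCq reference-gene step exists because the
designs quantify one target against another within the same sample. No-RT
controls pass when their Cq trails the template by ≥ 5 cycles or is
undetermined. With 0.2-cycle duplicate noise a single sample's ratio
estimate carries a ≈ 2^0.2 ≈ 1.15× error factor; recovery of a planted ratio
within 15% is therefore a property of the mean across many tables, not of
every individual table.

## Furrow-canal profiles (`slamkit.fc`)

Aggregation is hierarchical: furrow intensities → embryo mean → grand mean
across embryos, with SEM = sd(embryo means)/√n (ddof = 1; a single embryo
yields SEM 0 with a warning). Embryos carry equal weight regardless of
furrow count, so scoring extra furrows in one embryo cannot bias the
profile. Stage times are caller-provided minutes relative to mitosis 13;
staging from morphology is upstream of this package, as is image
segmentation — the interface is the per-furrow intensity table. Fold changes
divide grand means between stages. Group comparisons use the two-sample
Student t test (pooled variance by default, Welch by flag); the degenerate
all-equal case returns t = 0, p = 1.

## Feedback accumulation model (`slamkit.feedback`)

The model is an explicit minimal choice, not a fit:

    feedback: dP/dt = (α + β·P)·(1 − P/Pmax)
    linear:   dP/dt = α·(1 − P/Pmax)

α (a.u./min) is basal, protein-independent delivery to the compartment;
β (1/min) lumps the positive feedback (protein recruits its own mRNA, which
boosts local synthesis) into one coefficient that deliberately does not
distinguish the mechanistic step; the saturation factor turns accumulation
off as full levels are approached. Defaults (α = 0.2, β = 0.6, Pmax = 100,
T = 15 min, dt = 0.01 min) put the rise inside a cellularization-onset-scale
window. Integration is fixed-step RK4; halving dt changes P(T) by < 1e−6
relative, the unbounded (Pmax → ∞) solution matches the closed form
(P0 + α/β)e^{βt} − α/β to 1e−6, and a step that overshoots Pmax by > 1% (or
diverges) raises a step-size error.

Switch-likeness is scored as max instantaneous slope over mean slope of the
rise (1 for a straight line). The documented contrast sweep covers the
feedback-dominated regime — α ∈ {0.1, 0.2, 0.5}, β ∈ {0.3, 0.6, 1.0},
Pmax ∈ {50, 100}, P0 ∈ {0, 2} — where the feedback trace out-scores the
linear trace at every point (worst gain 1.32). Outside that regime the
contrast is uninformative by construction: as β → 0 the modes coincide, and
when basal delivery dominates or both traces fully saturate early in the
window, the saturating-exponential "linear" trace concentrates its slope at
t = 0 and the score comparison degenerates. All conclusions drawn from this
model are model-dependent and labelled as such in the outputs.

## Synthetic data (`slamkit.synthetic`)

Generators are pure functions of (parameters, seed) and emit objects that
pass the consuming module's validators.

**Counts.** Two IP/control experiments with negative-binomial counts
(variance m + φm²; Poisson at φ = 0). Defaults encode the study conditions:
2,000 transcripts, library depth 10⁶, 4 replicate pairs (the experimental
design used 2–4 biological replicates), dispersion φ = 0.01 (the replicate
reproducibility scale of genetically uniform material), baseline abundances
log-uniform over a 10-fold range chosen so the weakest transcripts sit
comfortably above the count filter, planted sets of 102 and 16 transcripts
sharing 3, effect 8-fold, with the bait (`slam`, always in the shared set)
at 20-fold so it ranks first. Under these conditions the worst-case planted
transcript clears the 4-fold threshold by ≈4.8 standard errors of its
combined log-ratio, so the exact 99/3/13 Venn structure is recovered with
high probability in every seed. What this does **not** emulate: mapping
biases, gene-length effects, contaminant RNAs, batch structure between IP
and lysate libraries, or the unknown upstream read-counting pipeline —
which is precisely why the printed transcript counts of the original
sequencing experiment are reproduced here in planted form rather than
re-derived from deposited reads.

**Traces.** Decay: I0·2^(−t/t½) + Gaussian noise (defaults: t½ = 40 min, 11
points over 10 min, sd = 2 a.u. on I0 = 100). Recovery: a line with Gaussian
noise. Real recordings additionally drift, bleach and saturate; the
reference-normalization path covers proportional bleaching only.

**Cq tables.** Reference reactions at Cq ≈ 20; target shifted by
−log_E(ratio); duplicates with 0.2-cycle Gaussian noise; no-RT rows 15
cycles above template. Pipetting outliers and efficiency differences between
primer pairs are not modelled.

**Furrow measurements.** A low→high step (defaults 10 → 60, the 6-fold
scale) at stage time 0, three embryos × 10 furrows per stage and channel,
multiplicative per-embryo effects (5%) plus additive per-furrow noise.
Gradual ramps, embryo-to-embryo staging error and background structure are
not modelled, so passing tests demonstrate the arithmetic of the
aggregation, not robustness to those effects.

## Problem sizes in the test suite

The suite regenerates all inputs at run time: recoding properties run on
~50–1,200-codon sequences over 100+ seeds, enrichment recovery on 10–20
seeds of the full 2,000-transcript design, kinetic and qPCR recoveries on
50–100 seeded traces/tables, and the feedback sweep on all 36 grid points.
The whole suite completes in well under a minute on one core.
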