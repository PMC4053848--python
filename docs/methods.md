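# Methods

`smaugkit` re-creates, on synthetic data with known ground truth, the
computational chain used to study Smaug-mediated translational repression
in the early *Drosophila* embryo: polysome-gradient translation indices,
SAM-style significance calls, kernel-density deconvolution of the
repressed-gene count, and a Boltzmann-ensemble scoring engine for Smaug
recognition elements (SREs). This note records the models, the parameter
choices that matter, and the places where the design was genuinely open.

## Translation index

Sucrose-gradient fractions are pooled into four pools (fractions 1–4,
5–6, 7–9, 10–12). For a gene with pool levels p1..p4 the translation
index is

    TI = log2( sqrt(p3 * p4) / p1 )

i.e. the geometric mean of the polysomal pools over the free pool, on a
log2 scale. Pool 2 is a mixed population and is excluded by default; an
`include_pool2` mode adds it to the geometric mean, and an
arithmetic-mean mode exists behind a flag (narrative descriptions of
this quantity say "average" while the operational definition is the
geometric mean; we follow the operational form). Genes with nonpositive
pool-1 signal are flagged unquantifiable (NaN) and excluded downstream;
zero polysomal signals are floored at 1e-6 before the logarithm.
ΔTI = TI(mutant) − TI(wild type); derepressed genes move up. Linear
fold changes are reported as 2^ΔTI rounded to two decimals, matching the
printed convention (1.57 → 2.97, −0.01 → 0.99).

## Normalization

Quantile normalization first (every sample forced onto the per-rank
cross-sample mean distribution, ties averaged), then a per-sample linear
rescaling x ↦ a·x + b with (a, b) least-squares fitted so the sample's
spike-in signals match the cross-sample mean spike-in signal. The fit is
on linear intensities. The rescaling is idempotent and exactly inverts a
per-sample affine distortion. Note that quantile normalization across
pool samples with genuinely different signal distributions compresses
part of the biological pool structure (the realized ΔTI separation
shrinks from 1.5 to ≈0.9 on default synthetic data); this is a property
of the protocol being emulated, not a defect of the generator.

## SAM-style significance calls

The moderated statistic is d = (mean(B) − mean(A)) / (s + s0) with the
pooled standard error s and an exchangeability damper s0, set by default
to the 5th percentile of the per-gene s distribution. One-class analysis
uses d = mean/(s + s0) with a sign-flip null; two-class unpaired uses a
label-permutation null (all distinct permutations when fewer than
`n_perm` = 1000 exist). For a threshold t,

    FDR(t) = median over permutations of #{|d*| >= t} / #{|d| >= t},

and a gene's q-value is the minimum FDR over thresholds it passes,
clipped to [0, 1]; q is monotone nonincreasing in |d| by construction.
Expressed-gene sets are the intersection across genotypes of the
per-genotype unions of one-class calls over the four pools.

Normalization applies to the polysome arrays. RIP matrices are analyzed
as raw per-replicate log-ratios: quantile normalization across IP,
mock-IP and input arrays would force identical marginals on samples
whose distributions genuinely differ — the IP upper tail *is* the
binding signal — and in simulation biases null-gene enrichment by about
−0.5 log2 units. Per-array scale factors appear in the log-ratios as
additive constants with zero expectation; they cancel in binder ranking
and in regression, and are small against the per-site enrichment. A
rank-preserving per-sample `median_scale` utility exists for designs
where a location correction is appropriate.

Operating characteristics: on pure-null data the realized call rate at
the 5% cutoff is conservative (≈0.2–1%). The spike-in power study uses
6 replicates per class because that is the smallest design in which a
3σ shift is in-principle separable from ~1000 nulls at FDR 5% with 90%
power; with 3–4 replicates the t-like statistic itself caps power at
~55–85% no matter how the FDR is estimated.

## Deconvolution of the repressed-gene count

Positive and negative reference densities are Gaussian-kernel estimates
of the ΔTI distribution of the top-N and bottom-N binders (N ∈ {250,
500, 1000} at full scale), with the normal-reference bandwidth
h = sd·(4/3n)^(1/5), evaluated on 100 equally spaced grid points.
Both references are evaluated on a common grid spanning the pooled ΔTI
range: with per-reference grids, any gene outside a reference's range
would be clamped to an edge density of order φ(1)/(n·h), leaking ~5% of
probability mass; on a common grid the far tails decay genuinely toward
the 1e-12 floor. Lookups use the closest grid point at or above x,
clamped to the last point beyond the grid. Each gene's positive
probability is f⁺/(f⁺+f⁻) (0.5 if both densities are floored), and the
expected repressed count is the sum of these probabilities.

Two structural properties of this estimator are worth knowing. First,
even with exact densities it over-counts by n·(1−2π)·∫f⁺f⁻/(f⁺+f⁻),
where π is the true positive fraction; with the default mixture
(shift 1.5, component sd 0.4) this intrinsic bias is ≈+6%, and the
component widths were chosen so that the bias stays well inside the
recovery tolerance the generator is designed to test. Second, the
positive reference must actually be positive: if N exceeds the number
of true positives, the top-N set is necessarily contaminated and genes
in the null bulk receive probability ≈ (1−α)/(2−α) for contamination
fraction 1−α, inflating the estimate (on default synthetic data, N=1000
against 600 planted positives yields ≈1000 instead of 600). The
estimator is reported as defined; the contaminated-reference regime is a
known failure mode, not something the implementation corrects for.

If both references are drawn from the same distribution (a fully null
cohort with an uninformative ranking), f⁺ ≈ f⁻ everywhere and the
estimator returns ≈ n/2 by symmetry — it measures resemblance to the
positive reference, not evidence of an effect.

## SRE scoring engine

Secondary structures are scored by a simplified pair-energy model:
canonical pairs only (GC −3, AU −2, GU −1 in model energy units, a +1
loop-closure charge per pair), hairpin loops of at least 3 nt, no
pseudoknots, optional maximum pair span. The partition function and
base-pair probabilities come from a McCaskill-style inside–outside
dynamic program (adaptive rescaling keeps GC-rich windows inside double
range); structures are drawn i.i.d. by stochastic traceback. An
exhaustive enumerator that evaluates energies directly from dot-bracket
strings provides an independent cross-check on short sequences.

Temperature enters through exp(−E/RT) with RT = T[K]/745 ≈ 0.40 units
at 25 °C. The divisor calibrates the energy unit: it makes a perfect
5-bp GC stem carry ~e^25 of weight against the open chain, comparable to
the decisiveness such stems have under nearest-neighbor (Turner)
energies. Mapping the unit to kcal/mol (RT ≈ 0.59) would leave the model
markedly floppier than real RNA, because the per-pair form has no
stacking cooperativity: isolated pairs then compete entropically with
stems, and a planted hairpin's closing pair forms with only ~0.90
probability even in an inert context.

The two-stage search mirrors the field's procedure: (1) a prescan of
locally averaged pair probabilities (170-nt sliding windows, pair span
≤ 120, single full-length window for shorter sequences) marks a CNGG
occurrence as a candidate when the base 5′ of it can pair one of the
five bases 3′ of it with probability > 0.01 (the "one of five" rule is
read as a maximum over the five partners, not a sum); (2) each candidate
is scored in 36 windows (75 nt upstream through 40 downstream, sliding
one nucleotide at a time to 40 upstream through 75 downstream, truncated
at transcript ends), sampling 3000 structures per window; a sampled
structure counts as an SRE when the site base is the 5′-most unpaired
base of a hairpin loop of 4–8 nt. The site probability is the mean over
windows; a transcript's score is the sum over candidate sites, with
per-region subtotals (5′UTR/ORF/3′UTR) assigned by the position of the
C. Windows are folded globally (span limited only by window length).
Variant loops (alternative 4-mer patterns, fixed closing-base identity,
exact loop lengths) run the identical pipeline with the constraint
substituted; the precise altered stem-loops of interest are supplied by
the user as `VariantSpec`s, not hard-coded. Per-(site, window) random
streams are derived from (seed, site position, window index), so results
are independent of scoring order.

## Synthetic data generator

Transcripts are compact minigenes (45 nt 5′UTR, 70 nt ORF, 45 nt 3′UTR
by default) over an AU-rich background (A 0.45, C 0.10, G 0.10, U 0.35),
matching both the base composition of maternal UTR sequence and a
constraint of the simplified energy model: without stacking
cooperativity, context G/C bases entropically steal planted-stem
partners, so detectable planted SREs require a G/C-poor background. A
configurable fraction of genes (default 30%) receives 1–3 planted
hairpins — a CNGGN loop (second position and tail random, lengths
weighted toward the 5-nt loop) on a GC-only "CGCGG" stem chosen to have
a dominant register and no internal CNGG motif. Negatives are redrawn
until a fast string heuristic finds no accidental strong SRE.

Expression: per-gene abundance is lognormal (2^N(10, 1)); wild-type TI ~
N(0, 1); ΔTI follows the two-component mixture N(1.5, 0.4) for planted
genes and N(0, 0.4) for the rest. Pool allocation inverts the TI
definition: pool 2 receives a fixed 10% of the gene's mass (the mixed
pool is unmodeled by the TI, so this share is a declared stand-in), and
the remainder is split p1 : p3 = p4 with p3/p1 = 2^TI, which reproduces
the drawn TI exactly in the noise-free limit. Measurements multiply in
per-sample scale factors (2^N(0, 0.2)) and lognormal noise (2^N(0,
0.15) per intensity). Spike-in rows (8 by default) have known constant
abundances on a geometric ladder. RIP matrices have Smaug IP / mock IP /
input roles with 4 replicates; IP enrichment is 1 log2 unit per planted
site. The in-silico puromycin treatment moves 90% of pools-3/4 mass
into pool 1.

What the generator does **not** emulate: probe-level microarray
structure (mismatch probes, probe sets), realistic transcript lengths
(kilobase mRNAs would make ensemble scoring of thousands of genes
intractable and, under the no-stacking model, would wash out specific
structure anyway), secondary-structure context around planted sites
beyond composition, and any relationship between expression level and
binding. Passing recovery tests therefore demonstrates the internal
consistency of the analysis chain under its own assumptions, not
performance on real microarray data.

## Problem sizes used in tests and the acceptance script

Deconvolution recovery runs at the full cohort scale (2000 genes, five
seeds). SAM operating characteristics use 300×6 null matrices over 20
seeds and one 1000×12 spike matrix. The end-to-end study uses 120–150
genes with SRE scoring on a truth-stratified subset of 50–60 genes at
150–200 samples per window; the planted-hairpin acceptance construct is
scored at the full 3000 samples × 36 windows. These sizes keep a
complete run to a few minutes while leaving every statistical claim
testable at its stated tolerance.

## Known limitations

* The energy model is a caricature: no stacking, no dangles, a single
  loop charge. All quantitative structure statements are relative to
  this model; the engine is behind a small interface so a
  nearest-neighbor backend could be substituted.
* Loops of 6–8 nt are weakly resolved: alternative closing registers of
  equal pair count carry comparable Boltzmann weight, so their site
  probabilities plateau around 0.3–0.7 even for perfect stems, and loop
  tails must avoid self-complementarity (a CUGGCA loop pairs its own U
  and A) for a planted site to be scored at all.
* The permutation FDR inherits SAM's conservativeness when many genes
  carry strong effects (differentially expressed genes contaminate the
  permuted null).
* The deconvolution estimator's contaminated-reference failure mode
  (N larger than the true positive count) is reported, not corrected.
* Quantile normalization across pools discards part of the pool-level
  signal by construction; ΔTI-based inferences remain valid because
  both genotypes and both reference sets are distorted alike.
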