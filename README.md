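# smaugkit

Smaug is an RNA-binding protein that clears maternal mRNAs during the
maternal-to-zygotic transition of the early *Drosophila* embryo, both by
repressing their translation and by triggering their decay. It binds
stem-loops whose loop matches the consensus CNGGN₀₋₄ (Smaug recognition
elements, SREs). Genome-wide, its reach is measured by two microarray
designs: RIP-Chip (Smaug IP vs mock IP vs input) for binding, and
polysome gradients split into four pools for translation, summarized per
gene by the translation index

&nbsp;&nbsp;&nbsp;&nbsp;TI = log₂( √(p₃·p₄) / p₁ ),

the log-ratio of polysomal signal (geometric mean of pools 3 and 4) to
free-mRNA signal (pool 1). Genes whose TI rises in a *smaug* mutant
(ΔTI > 0) are candidates for Smaug-mediated translational repression.

`smaugkit` implements that analysis chain as a tested Python package and
exercises it on synthetic data with known ground truth:

* **simulate** — minigene transcriptomes with planted SRE hairpins, and
  polysome/RIP intensity matrices with replicate structure, spike-in
  rows, per-sample scale factors and lognormal noise
  (`smaugkit.simulate`);
* **normalize** — quantile normalization plus spike-in-anchored linear
  rescaling Y = aX + b per sample (`smaugkit.normalize`);
* **translation index** — pool mapping, TI/ΔTI, ranks, Wilcoxon and
  Fisher comparisons, linear fold-change reporting (`smaugkit.ti`);
* **SAM-style statistics** — moderated d = Δmean/(s+s₀) with
  permutation/sign-flip FDR, one-class and two-class unpaired
  (`smaugkit.sam`);
* **target-count deconvolution** — kernel density estimates of ΔTI for
  top-N vs bottom-N binders, per-gene positive probabilities
  f⁺/(f⁺+f⁻), expected repressed-gene count (`smaugkit.deconvolve`);
* **SRE scoring** — a two-stage scan: local pair-probability prescan of
  CNGG candidates, then Boltzmann-ensemble structure sampling over 36
  overlapping windows per site; transcript score = Σ site probabilities,
  with variant-loop support (`smaugkit.fold`, `smaugkit.sre`);
* **association** — regression of binding on consensus/variant scores,
  Spearman correlations, group medians, four-class partitions and
  overlap statistics (`smaugkit.assoc`).

The folding engine is a McCaskill-style inside–outside dynamic program
over a simplified pair-energy model (GC −3, AU −2, GU −1, +1 per loop
closure, RT ≈ 0.40 units at 25 °C), with exact stochastic traceback
sampling and an exhaustive enumerator as an independent oracle — see
`docs/methods.md` for the model, its calibration and its limits.

## Worked example

The `analysis/` directory is a numbered narrative over one synthetic
study (configuration in `analysis/config.yaml`: 150 genes, 30% with
planted SREs, ΔTI mixture N(1.5, 0.4) vs N(0, 0.4), seed 7):

```
cd analysis
python 01_simulate.py
python 02_normalize_and_ti.py
python 03_sam_calls.py
python 04_estimate_targets.py
python 05_sre_scores.py       # the thermodynamically heavy step
python 06_association.py
```

Outputs land in `results/`. A run prints, among other lines:

```
simulated 150 transcripts (45 with planted SREs, 105 clean)
TI computed for 150 genes
  rank   1  g00044  dTI +1.07 (linear fold-change 2.10)
expressed in both genotypes (union of pools, intersected): 150
derepressed in the mutant at FDR<5%: 22
bound in Smaug vs mock RIPs at FDR<5%: 45
N=  25: expected repressed genes = 56.2
N=  40: expected repressed genes = 59.2
planted ground truth: 45
```

and step 06 prints:

```
binding ~ SRE-score regression:
  const      coef +0.662  (t=+4.40, p=5e-05)
  consensus  coef +1.514  (t=+2.67, p=0.0099)
  ANGG       coef -3.160  (t=-0.66, p=0.51)
  CNAG       coef +20.941  (t=+1.78, p=0.08)
  CNGA       coef -3.758  (t=-0.56, p=0.58)
Spearman(consensus score, binding) = 0.72 (p=9.1e-11)
Spearman(consensus score, dTI)     = 0.68 (p=2e-09)
median consensus score: planted 0.05 vs clean 0.00 (Wilcoxon p=3.6e-12)
bound & repressed overlap: 21 genes (47% of bound, 95% of repressed)
```

Reading: all 150 genes pass the expressed filter; the two-class SAM
call at FDR < 5% is conservative on 3 replicates (22 of 45 planted
genes called), while the RIP contrast recovers the 45 planted binders
exactly; the density deconvolution — which does not threshold but sums
per-gene positive probabilities — estimates 56–59 repressed genes
against 45 planted (the quantile-normalization step compresses the
realized ΔTI separation, which costs the small-N references some
resolution; at full scale, 2000 genes and N = 250/500, the estimate
lands within a few percent of truth). The regression finds a
significantly positive consensus-SRE coefficient while the
altered-invariant loop variants (which do not match the CNGG scan) stay
within 2 standard errors of zero.

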