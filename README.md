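# mockdebias

Mock-community based quality control and de-biasing of 16S rRNA amplicon
data: reference-based triage of amplicon sequence variants (ASVs) and
correction of DNA-extraction bias using bacterial morphology.

## The problem

Relative abundances measured by amplicon sequencing are systematically
distorted. Cell lysis efficiency differs between taxa (thick-walled
gram-positives resist extraction, gram-negative rods lyse easily), PCR
produces chimeric sequences, and reagents contribute contaminant reads
(the "kitome"). Mock communities — defined mixtures of known strains,
sequenced as dilution series alongside DNA-only mocks and negative
controls — make these distortions measurable. This package implements the
full analysis a mock-community experiment enables:

1. **ASV triage.** Each ASV is compared against the expected reference
   sequences (trimmed to a fixed window, 279 bp by default) by Levenshtein
   distance LV. `LV = 0` is an exact match; `1 ≤ LV ≤ 8` a sequence error
   (ties resolved with a Jukes–Cantor model distance); sequences with
   `LV > 8` are greedily segmented into longest common substrings shared
   with the references — if more than 95% of the ASV (266 of 279 bp) is
   exactly explained by parts of two or three taxa it is a chimera;
   everything else is unclassified (contaminants, foreign taxa). ASVs with
   `LV ≤ 4` are accepted and collapsed to species-level compositions.
2. **Extraction bias estimation.** Following the multiplicative
   (compositional) bias model, the observed composition is
   `observed_i ∝ reference_i · bias_i`, where the reference is the DNA mock
   (same taxa, no extraction step) or the nominal expected composition.
   The per-sample estimate is the centered ratio
   `b = (observed/reference) / gm(observed/reference)`; dilutions are
   pooled per protocol by element-wise geometric mean. Bias vectors have
   geometric mean 1 — only ratios are identifiable in compositions.
3. **Morphology-based correction.** Per-taxon bias is summarized by
   geometric mean within morphology groups (gram stain/cell-wall ×
   shape), giving one factor per group × protocol (3 × 8 = 24 at the
   defaults) from a single training sample per protocol. Corrected
   compositions are `observed_i / factor(group(i), protocol)`, re-closed.
   Because the factors attach to morphology, they transfer to taxa that
   were never in the training mock.
4. **Contaminant profiling.** Recurrent unclassified ASVs are k-means
   clustered on their relative-abundance profiles over mock and control
   samples and each cluster is assigned an origin (buffer kitome,
   skin-like, inconclusive) by an explicit abundance-ratio rule; chimera
   and contaminant read fractions are correlated with bacterial input
   cells (Spearman).

A fully ground-truthed synthetic generator (`mockdebias.simulate`)
produces the whole study design — even/staggered/spike-in mocks over a
10⁴–10⁸ input-cell dilution series under 8 extraction protocols, DNA
mocks, negative controls, skin samples, planted bias, sequence errors,
chimeras and contaminants — so every stage is testable without any
download.

## Worked example

The `analysis/` scripts run the complete study on the synthetic data:

```bash
python analysis/01_simulate.py --seed 1      # writes results/simulated/
python analysis/02_classify.py
python analysis/03_estimate_bias.py
python analysis/04_correct.py
python analysis/05_evaluate.py
python analysis/06_contaminants.py --seed 1
```

Output of the run above:

```
wrote 9 files to results/simulated
  136 samples (120 cell-mock), 2714 ASVs
classified 2714 ASVs: sequence_error=2512, chimera=151, exact=33, unclassified=18
mean read fractions: exact=0.885 error=0.014 chimera=0.010 unclassified=0.091
estimated bias for 120 samples, 8 pooled protocols
  Q_S_q: most over-represented T06 (3.15x), most under-represented T07 (0.41x)
  ...
trained 24 correction factors (3 groups x 8 protocols)
corrected 120 samples; median Bray-Curtis to reference 0.176 -> 0.058
120 samples: median distance 0.176 -> 0.058 (67% reduction of the median)
significant reduction (BH-adjusted p < 0.05) in 23/24 strata
clustered 18 prevalent unclassified ASVs: skin_like=10, buffer_q=4, buffer_z=4
  chimera fraction vs input cells: rho=+0.39 (p=1.2e-05)
  contaminant fraction vs input cells: rho=-0.96 (p=3e-66)
```

Reading this: the 33 reference copy variants are recovered exactly; most
unique ASVs are low-abundance sequence errors carrying only 1.4% of reads;
protocol-specific bias spans ~8-fold between the most over- and
under-represented taxon; dividing by the 24 morphology-group factors cuts
the median Bray–Curtis distance to the reference composition from 0.176
to 0.058; contaminant clusters separate cleanly by extraction buffer, and
the planted dependencies on input cells (chimeras up, contamination down)
are recovered with the right signs.

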