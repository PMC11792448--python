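# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mockdebias`.

## ASV triage against mock references

**Reference set.** One or more 16S copy variants per taxon, all trimmed to
`trim_len` (default 279 bp, a primer-trimmed V1–V3 window). FASTA ids
follow `<taxon>_<variant>`, taxon = substring before the last underscore;
sequences are uppercased on read and IUPAC ambiguity codes are rejected —
the distance primitives assume a pure A/C/G/T alphabet.

**Levenshtein bands.** The minimum unit-cost edit distance (LV) between an
ASV and any copy variant drives the classification:

| band | category |
|---|---|
| LV = 0 | exact |
| 1 ≤ LV ≤ `error_lv_max` (8) | sequence_error |
| LV > 8, LCS coverage rule met | chimera |
| LV > 8 otherwise | unclassified |

Only ASVs with LV ≤ `accept_lv` (4) are accepted into species-level
compositions. The 5–8 band is reported as sequence error in triage
summaries but excluded from compositions: the two thresholds serve
different purposes (triage accounting vs. trustworthy abundances) and are
both configurable. The edit distance is computed with `edlib`; the test
suite verifies it against an exhaustive recursive oracle.

**Tie resolution.** When two or more taxa are equidistant at minimal LV
(typical for near-identical species pairs), the tie is broken by a
nucleotide-substitution-model distance: each candidate's closest variant
is aligned to the ASV end-gap-free (Biopython `PairwiseAligner`, match 1 /
mismatch −1 / gap open −2 / extend −0.5, free end gaps) and the
Jukes–Cantor distance d = −(3/4)·ln(1 − 4p/3) computed from the mismatch
proportion p over paired columns. The smallest d wins; ties within 1e-12
(e.g. identical closest variants) stay `ambiguous` and such ASVs are
excluded from species compositions. Jukes–Cantor is this package's choice
of substitution model; any model monotone in p would order candidates
identically except through its treatment of saturation (p ≥ 0.75 →
distance +∞).

**Chimera rule.** Candidates (LV > 8) are greedily segmented: repeatedly
take the longest common substring between the still-unmasked ASV positions
and any reference variant (ties: leftmost start on the ASV, then taxon
name), record the segment, mask it, stop after `max_chimera_parts` (3)
parts or when the best run falls below `lcs_floor` (20 nt, which prevents
spurious short matches inflating coverage). A chimera is called iff the
segments cover at least `min_cov` bases — the smallest integer strictly
greater than `chimera_cov_frac · trim_len`, i.e. 266 of 279 at the 0.95
default — and involve exactly two or three distinct taxa. Coverage counts
non-overlapping masked bases in the ASV's own coordinates. The parent pair
is the two distinct taxa owning the longest segments; a three-part call
whose parts span only two taxa keeps the trimera flag with a two-species
parent pair. Four-or-more-part chimeras fall through to unclassified by
construction. The search is seed-and-extend over an exact k-mer index with
k = `lcs_floor`: any common substring of length ≥ k contains a shared
k-mer, so the result equals the true longest common substring whenever it
matters, at a fraction of the quadratic DP cost.

Chimeras between the near-identical reference pair cannot be detected by
this (or any reference-distance) rule: their chimeras sit within the
sequence-error band of either parent.

## Extraction bias model

Observed mock compositions are modeled as multiplicative distortions of
the input composition, `observed ∝ reference ⊙ bias`. All operations are
compositional:

* **Reference composition** — element-wise geometric mean of the DNA-mock
  replicate compositions, re-closed. The geometric mean is the natural
  pooling under a multiplicative model; taxa at zero in any replicate have
  no defined log and are excluded (they could not serve as denominators).
  Spike-in communities use their nominal expected composition (they have
  no DNA mock).
* **Per-sample bias** — the centered ratio `r/gm(r)`, `r = observed/
  reference`, over the evaluable taxon subset. Taxa undetected in a sample
  are dropped for that sample rather than imputed (pseudocounts would leak
  depth-dependent artifacts into a ratio estimator); samples retaining
  fewer than two taxa are excluded. The 0.5 / 1e-5 zero replacements are
  reserved for log-scale distance computations, never used in bias
  estimation.
* **Evaluable taxa** — all reference taxa for even and spike-in mocks; for
  the staggered mock only taxa with expected relative abundance ≥
  `staggered_min_expected` (7e-4), because rarer members are not
  consistently detected and their near-zero ratios would dominate the
  geometric statistics.
* **Protocol pooling** — dilutions are treated as replicates: element-wise
  geometric mean across a protocol's samples, re-centered. Pooling happens
  within each mock class (different designs cover different taxa); the
  even-mock pool is the primary per-protocol estimate.

Bias is identifiable only up to a scalar, so every vector is centered to
geometric mean 1; closure after correction absorbs any global scale.

## Morphology-based correction

Per-taxon bias from a designated training sample (default: the 10⁶-cell
even mock of each protocol) is summarized by geometric mean within each
morphology group, yielding a group × protocol factor table (3 × 8 = 24 at
the defaults). Correction divides observed relative abundances by the
factor of the taxon's group and re-closes. Group membership is
configuration data (TSV: taxon, gram, shape, group) — the package ships no
organism-to-group assignments. Strict mode rejects taxa without a factor;
lenient mode passes them through with factor 1, the sensible behavior for
environmental samples where only annotatable taxa can be corrected.

The correction is exact when bias is constant within groups; its value on
real data depends on how much of the bias variance morphology explains.

## Evaluation statistics

* **Bray–Curtis** Σ|x−y| / Σ(x+y) (half the L1 distance for closed
  vectors); **Aitchison** — Euclidean distance of centered-log-ratio
  transforms after replacing zero relative abundances by 1e-5.
* **Wilcoxon signed-rank** — own implementation with an exact null
  (generating-function convolution over sign assignments, midranks doubled
  to integers) for n ≤ 25, normal approximation with tie and continuity
  correction beyond; zero differences dropped, ties midranked. Exactness
  is verified against full 2ⁿ enumeration in the tests.
* **Spearman** — tie-corrected rho; for n ≤ 9 the two-sided p is exact by
  full permutation enumeration.
* **Benjamini–Hochberg** across strata of a report (one family per
  evaluation table; the family definition is a configuration choice).
* Percent reduction is reported both as 1 − median_after/median_before and
  as the median of per-sample reductions — the two conventions differ and
  both are useful.

## Synthetic study generator

`GeneratorConfig` defines the study conditions; defaults describe a full
mock-community experiment:

| parameter | default | meaning |
|---|---|---|
| n_taxa / n_spike_taxa | 8 / 3 | mock and spike-in community sizes |
| variants_per_taxon | 3 | 16S copy variants (within LV ≤ 2 of the taxon base) |
| trim_len | 279 bp | reference window |
| close_pair_lv | 6 | engineered near-identical species pair |
| inter_taxon_min_lv | 20 | separation of all other taxon pairs |
| protocols | 8 | kit {Q,Z} × lysis {S,T} × buffer {q,z} |
| group_log_bias_means | derived | see below |
| within_group_log_sd | 0.2 | taxon-level spread around the group mean |
| dilutions | 10⁴…10⁸ | bacterial input cells |
| depth | 30 000 | reads per sample |
| chimera_rate_max | 0.13 at 10⁸ | chimeric read fraction, linear in input cells |
| contaminant_cells | 200 | reagent load; read share C/(C+N) |
| cross_contaminant_cells | 20 | skin leakage into mocks, share X/(X+N) |
| random_error_rate / recurrent_error_rate | 0.002 / 0.003 | sequence-error read fractions |

Morphology-structured bias: groups get log-bias means spread over
[−1.2, 0.6] (≈ 3.3× underrepresentation of the hardest-to-lyse group to
1.8× overrepresentation of gram-negative rods), scaled by 0.7 under tough
lysis — bead beating mitigates but does not remove lysis bias — with small
kit/buffer modifiers. Each taxon's log bias adds Normal(0, σ_w) noise to
its group mean, drawn once per protocol: bias is a property of
taxon × protocol, not of individual samples. Chimera parents are drawn
with probability ∝ abundance_i · abundance_j · exp(−LV(i,j)/30),
reflecting preferential chimera formation between abundant and similar
templates; breakpoints are uniform in [40, trim_len − 40]. Contaminants
come from fixed per-buffer kitome pools (4 ASVs, Dirichlet(10) weights —
few, consistent, comparably abundant buffer contaminants) mixed 85:15
with a skin-like pool (the most abundant skin taxa); negative controls
contain contaminants plus a small mock cross-contamination fraction. A
`sampling="exact"` mode replaces all multinomial sampling with expected
(real-valued) counts for noiseless identifiability checks.

The linear chimera–input relationship and the C/(C+N) contamination decay
are the simplest monotone mechanisms producing the qualitative
dependencies the analysis tests for (both are config-pluggable); the
generator makes no attempt at sequencer error-profile realism, quality
scores, read-length variation or paired-end structure. Passing tests on
synthetic data demonstrate that the pipeline recovers what the generative
model plants — multiplicative group-structured bias, exact-fragment
chimeras, profile-consistent contaminants — not that real extraction bias
is fully morphology-explained.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng(seed)`; fixture
  writing is byte-deterministic for a given config.
* Geometric means are computed in log space; closure requires a positive
  sum and centering requires strictly positive entries (enforced).
* The coverage threshold uses a 1e-9 fudge before flooring so that exact
  products (0.95 × 280) still take the "strictly greater" branch.
* k-means (scikit-learn, k-means++, 10 restarts) runs on raw relative
  abundances over mock and control samples only; skin samples enter only
  the origin-labeling rule (mean-abundance ratio ≥ 5× between sample
  groups). Labels attach to clusters, so ASVs in mixed clusters can be
  misattributed; recovery statements are aggregates over replicate
  studies.
* Evaluation pools the improvement tests over replicate seeded studies per
  protocol; single-protocol strata with fewer than 4 paired samples report
  medians without a p-value (the one-sided exact minimum at n = 4 is
  1/16).

## Known limitations

* No reference-free (de novo) chimera detection; chimeras involving
  non-mock parents land in "unclassified".
* No bootstrap uncertainty on bias estimates.
* Correction quality degrades gracefully with within-group bias spread but
  is not guaranteed to improve any individual sample.
* The staggered evaluability threshold is an expected-abundance rule, not
  a per-sample detection model.
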