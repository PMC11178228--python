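# Methods

This note documents the models implemented in `splicescreen`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used
throughout.

## 1. Synthetic genome

`simulate.GenomeSpec` emulates a fission-yeast-like gene architecture:

| parameter | default | rationale |
|---|---|---|
| `frac_intron_genes` | 0.43 | fraction of intron-bearing genes in *S. pombe* |
| `intron_count_probs` | geometric decay over 1..15 | most intronic genes carry 1–2 introns; the organism's maximum is 15 |
| `intron_len_mean` | 83 nt (lognormal, σ=0.35, min 30) | the organism's mean intron length; the floor leaves room for the splice motifs |
| `exon_len_mean` | 250 nt (lognormal, σ=0.6, min 30) | typical short-exon scale; not fitted to data |
| `consensus_5ss` / `consensus_bp` / `consensus_3ss` | GTAAGT / CTAAC / TAG | canonical donor, branch-point and acceptor motifs |
| `degeneracy` | 0.15 | per-position substitution probability; yields donor sites of intermediate conservation, qualitatively matching the organism's degenerate splice sites |
| `bp_offset` | 10 nt | distance between the last branch-point base and the intron 3' end; branch-point position is a modelling choice (annotations rarely state it) and is configurable |

The invariant GT/AG terminal dinucleotides are exempt from degeneracy
mutation by default so every generated intron remains annotatable; the
exemption can be switched off for scenarios that need fully mutable
donors. Genes are placed on a single chromosome with random intergenic
spacers and random strand; intron coordinates are genomic, 1-based and
inclusive, with `intron_index` counted along the transcript (so intron
1 of a minus-strand gene has the highest genomic coordinates). Intron
bodies are A/T-rich (A+T ≈ 0.68) relative to exons, mimicking the
composition bias of yeast introns.

## 2. Defect models

Wild-type per-intron efficiency is drawn once per intron from
`Beta(30, 1.5)` (mean ≈ 0.95 with a low-efficiency tail), giving the
mostly-high wild-type decile profile typical of fission yeast without
fitting any dataset. The baseline stream depends only on `(seed,
intron)` — never on the model kind — so wild-type and mutant truth
tables from one seed share baselines and are directly comparable.

* **none** — efficiencies equal the baseline draw.
* **transcription_coupled** — gene affected ~
  `Bernoulli(sigmoid(α + β·log rate))`; an affected gene multiplies
  *every* intron's baseline by a single shared severity draw
  `δ_g ~ Beta(a, b)`. Defaults `α=−4, β=1.5, δ_g ~ Beta(2, 6)` make
  affectedness rise from ~8% at the 16th rate percentile to ~97% at the
  98th, with a mean 4-fold efficiency reduction — a strong but not
  saturating gene-level defect.
* **motif_dependent** — per-intron efficiency
  `baseline · (1 − γ·m/6)` where `m` is the Hamming distance of the
  donor hexamer from the consensus. The penalty is per-intron and
  independent of siblings and of transcription rate.

Transcription rates are log-normal (`mu=3, sigma=1` on the natural-log
scale), an FPKM-like covariate with median ≈ 20. Slowed-transcription
scenarios (kinase inhibition style) are represented purely by a
multiplier ρ ∈ (0, 1] applied to rates before the defect model, so
lower rates lower the probability of a gene-level defect; no kinetic
elongation model is implemented.

## 3. Count emission

Junction evidence per intron boundary: reads observing a boundary
`n_b ~ Poisson(depth · rate)`, of which `Binomial(n_b, SE)` are
spliced. Gene-level counts are negative binomial with mean
`rate · fold_change · depth_factor` and size parameter `dispersion`
(variance `μ + μ²/dispersion`; `dispersion = inf` is exactly Poisson).
Replicates and wells draw from distinct named sub-seed streams
(`numpy.random.SeedSequence` spawn keys hashed from string paths), so
adding replicates, wells or genes never perturbs earlier draws.

## 4. Cytometry simulation and processing

Per cell, expression `X ~ LogNormal(expr_mu, expr_sigma)`; the red
channel reads `coupling_red · X` and the yellow channel
`coupling_yfp · SE · X`, each with multiplicative Gaussian noise
(CV 8%) and additive truncated-Gaussian autofluorescence.
Untransformed wild-type control wells have zero coupling. Scatter
channels plant 5% debris (small FSC, large SSC) and 4% doublets (low
FSC-H/FSC-A ratio) so the gates have work to do.

Processing follows the screen convention: hierarchical gating (scatter
→ singlet → optional fluorescence), channel medians over the gated
population, a 1000-event QC floor, subtraction of the control strain's
red median, then the YFP/RFP ratio. Choices worth noting:

* **Gate bounds.** Scatter gates default to the central 90% density
  box; the singlet band keeps FSC-H within ±25% of a least-squares
  linear fit against FSC-A. Data-dependent bounds are *resolved* once
  against a population, after which every gate is a pure interval
  filter — a resolved gate is idempotent by construction.
* **Correction order.** Medians are computed on raw values and the
  control median subtracted afterwards; per-event subtraction is not
  offered. Correction touches only the red channel by default (the
  screen's stated procedure); a `both` option also corrects YFP, which
  is the physically symmetric choice and is what the ratio-linearity
  test uses.
* **Hit testing.** Two-sided Welch t-test of replicate ratios against
  the reference strain's replicates; Welch is the robust default when
  replicate counts are tiny and variances unknown. Raw p-values by
  default (the screen reported none); Benjamini–Hochberg is a flag.
  At three replicates per group the Welch test is conservative: null
  calibration lands near 3% rejections at nominal 5%, so the null
  guarantee is one-sided (never above nominal plus binomial error).
* Negative fluorescence values (compensated data) are permitted and
  flow into the NA rules: the ratio is NA whenever corrected red ≤ 0
  or QC failed.

## 5. Splicing quantification and downstream comparisons

SE pools both boundaries: `(s₅+s₃)/(s₅+u₅+s₃+u₃)`, NA below
`min_coverage = 10` (a repo default, not a literature value). Pooling
is the symmetric choice among the several single- or dual-boundary
variants in circulation and is the only variant implemented. SAM
ingestion counts a skip as spliced support only when the skip matches
the annotated intron exactly with ≥ 6 aligned bases on each side, and a
contiguous alignment as unspliced support when it covers ≥ 6 bases on
each side of a boundary; deletions (D) preserve contiguity, and
unannotated skips go to a novel-junction tally. Donor/acceptor labels
are transcript-oriented (swapped for minus-strand introns).

Deciles are defined on wild-type SE ranks with ties broken by intron
id; `numpy.array_split` over the sorted order guarantees sizes differ
by at most one and the partition is deterministic. "Most affected"
defaults to the WT−mutant difference (descending); the mutant/WT ratio
variant is exposed and used by the co-splicing filters. Extreme
selection takes `floor(fraction·N)` introns (minimum 1). Introns NA in
either sample are excluded from rankings and decile tests, with the
exclusion count logged.

Donor/acceptor composition windows default to 3 exonic + 8 intronic nt
(5') and 8 intronic + 3 exonic nt (3'); position probability matrices
use the uniform-background information convention (0–2 bits, no
small-sample correction by default). The per-position comparison of a
set against the all-intron background — chi-square on base counts with
expected counts under background frequencies, rare cells (expected < 1)
pooled, bases impossible under the background treated as infinite
divergence when observed, Benjamini–Hochberg across positions, plus
per-position KL divergence — is an added quantitative statistic for
what is classically a visual logo comparison; outputs carry
`method=chi2-vs-background`. Because the set is a subset of its own
background, the test is slightly conservative, which is the safe
direction for claiming "no difference".

Co-splicing profiles condition on an anchor intron of a
three-intron gene satisfying `se_mut/se_wt < 0.5` (the affected filter)
or `> 0.9` (the unaffected control); "decrease of 50%" is implemented
as this *relative* ratio, consistent with the control's explicitly
relative definition, and both comparator and threshold are
configurable. Genes are restricted to exactly `n_introns` quantified
introns in both genotypes. The expression association compares
host-gene FPKM of the k = 50 worst vs best spliced introns with a
Welch t-test on log₁₀ FPKM (FPKM spans orders of magnitude; the log
scale is the conventional choice). In simulations FPKM is the
generator's true rate; for real count matrices
`fpkm_from_counts` computes count/(exon-union kb × library millions).
The cumulative mature fraction is a plain product — the independence
assumption is stated here and in output metadata; no co-splicing
correlation correction is applied.

## 6. Differential-expression surrogate

Size factors are median-of-ratios (median taken on the ratio scale,
over gene rows positive in every sample); testing is a two-sided Welch
t-test on `log2(normalized + 1)`; significance follows the volcano
rule: `|log2fc| ≥ 1` (inclusive) **and** `p < 0.05` (exclusive). This
module is deliberately a simplified, fully documented surrogate for a
shrinkage-based DE framework: it makes no claim of numerical agreement
with one, warns at two replicates per group (where the t-test is
underpowered), and labels all outputs `method=simplified-surrogate`.

## 7. Scenarios and problem sizes

The fixed scenarios in `splicescreen.scenarios` define the study
conditions of the recovery checks:

* **transcription_coupled** — default genome (1000 genes, degeneracy
  0.15, GT/AG protected), `α=−4, β=1.5`, rates LogNormal(3, 1),
  junction depth 3 reads per boundary per rate unit (median boundary
  coverage ≈ 120).
* **motif_dependent** — same size but degeneracy 0.3 with mutable
  terminal dinucleotides and full penalty `γ=1`. The donor hexamer
  must be fully mutable here: with GT protected, at most four
  mismatches are possible and a ≥ 50% single-intron knockdown —
  the event the anchor filter conditions on — would be vanishingly
  rare. γ=1 makes a consensus-distant donor abolish splicing of its
  own intron, the strong form of the motif mechanism.
* **screen** — 30 strains × 3 replicate wells on one 96-well plate
  with three autofluorescence-control wells, 2500 events per well,
  three planted strains at SE 0.45/0.55/0.65 against a 0.9 background.
  Null calibration runs 1000 reduced screens of 8 strains × 3
  replicate ratios drawn from the reference distribution, through the
  same hit-calling path as real plates.
* **high-coverage recovery** — 600 introns at 2500 expected reads per
  boundary (total coverage 5000), baseline-only truth.

These sizes keep a full acceptance run to well under a minute per
scenario batch while leaving each statistical readout far from its
decision boundary. `scripts/acceptance.py` derives every stream from
the single `--seed` via the sub-seed scheme.

## 8. What the generator does not emulate

Synthetic data are idealized in ways real data are not: junction counts
are exactly Poisson–binomial with no mappability, GC or positional
bias; cytometry events have no spectral spillover, drift or carry-over;
library composition effects beyond a global size factor are absent;
defect models are pure (real mutants likely mix mechanisms); and the
genome has no overlapping genes, alternative isoforms or annotation
errors. Passing recovery tests therefore demonstrates correctness of
the estimators and the discriminating power of the analyses under the
stated models — not robustness to artefacts these models exclude.

## 9. Known limitations

* The splicing-efficiency metric is a single pooled-boundary variant;
  alternative published parameterizations are not reproduced
  bit-for-bit.
* The DE surrogate has no dispersion shrinkage; at duplicate-level
  replication its power is limited and it says so at run time.
* Branch-point placement is fixed-offset, not sequence-predicted, and
  no polypyrimidine-tract scoring is implemented.
* FCS binary ingestion is not included; events enter as CSV tables
  with the standard channel columns.
* Logo rendering is left to external tools; the package emits the
  count/PPM/information tables a logo is drawn from.
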