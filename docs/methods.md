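# Methods

This note documents the statistical model behind `rrbsdmf`, the
assumptions of the synthetic-data generator, the numerical and design
choices that were genuinely open, and the limitations of both.

## Measurement model

RRBS measures methylation on MspI fragments. In-silico digestion cuts
at every CCGG occurrence, one base into the site (C^CGG); because CCGG
is its own reverse complement, scanning the forward strand is complete.
Fragments tile the reference without gaps; size selection keeps
40–220 bp (both bounds inclusive). CpG sites are forward-strand CG
dinucleotides; Bismark-style coverage input is 1-based and converted to
0-based half-open coordinates on read, with optional merging of a
reverse-strand record at pos+1 into the forward CpG.

A fragment's methylation level for one sample at one timepoint is the
read-weighted pooled fraction Σmeth / Σ(meth+unmeth) over its retained
CpGs (an unweighted mean of per-CpG fractions is available via
`pooling="mean"`). Read-weighting is the default because the
fragment-level test statistic is count-based and deep CpGs carry more
information. A fragment is *absent* for a sample unless at least
`min_cpgs=2` CpGs were observed with a pooled total of at least
`min_reads=10`; absence is what the complete-case filter later acts on.
These thresholds echo common RRBS practice and are plain configuration,
not claims about any particular external pipeline.

## Differential methylation across timepoints

Within one group, each fragment yields a k×n table (k = 3 timepoints,
n = participants). The test is one-way fixed-effects ANOVA with
timepoints as factor levels and participants as replicates:
F = MS_between / MS_within, df (k−1, k(n−1)), p from the upper tail of
the F distribution. Repeated measures on the same participant are
treated as independent replicates per timepoint — a deliberate match to
groupwise F-testing on small cohorts; a repeated-measures or
mixed-model variant is out of scope. Raw proportions are tested without
variance-stabilising transformation (e.g. arcsine); this choice is
visible here and in the calibration results below.

Degenerate fragments are defined rather than propagated as NaN: zero
within-timepoint variance with equal means gives F = 0, p = 1; zero
within-timepoint variance with unequal means gives a p = 0 sentinel and
a runtime warning.

Significance is a strict raw p < α with α = 0.05 and *no* multiplicity
correction by default — at n = 5 the cost of FDR control in true
positives is deliberately judged too high; Benjamini–Hochberg is
available behind `fdr=True`.

The biological-relevance filter works on group means in percent:
delta_early = m₂₄ − m₀, delta_late = m₄₈ − m₂₄, delta_gradual =
m₄₈ − m₀. "More than 10%" is interpreted as percentage *points*,
strictly greater than the threshold, on |delta|; both the threshold and
the strictness are configuration. delta_gradual is computed as
delta_early + delta_late so the additivity identity holds exactly in
floating point. Means stay unrounded throughout; rounding to printed
integers happens only at reporting.

Dedup assigns the earliest applicable category (early > late >
gradual). Specificity compares case DMFs against the control group's
*fully filtered* DMF set by fragment coordinate identity (the
coordinate string is the cross-sample fragment key); a flag switches
the comparison to the control's ANOVA-only set for sensitivity
analyses. The control arm runs the identical pipeline with its own
n (here 2, df (2, 3)).

## Feature annotation

Promoters are the strand-aware window −5 kb … +1 kb around the TSS,
clipped at coordinate 0. Precedence for a fragment overlapping several
features: promoter > exon/intron boundary (overlapping both an exon and
an intron of one gene) > exon > intron; intergenic means no overlap
with any promoter window or gene body. Ties between genes offering the
same feature go to the gene with the smallest |distance to TSS|
(fragment midpoint, strand-aware sign, reported so alternative
definitions can be audited), then lexicographic gene id. These
precedence rules are a documented choice — promoter wins because
promoter fragments are the distinct reportable class downstream.

## Temporal pattern taxonomy

Trajectories (m₀, m₂₄, m₄₈) in percent are classified by a decision
list on d1 = m₂₄−m₀, d2 = m₄₈−m₂₄, d3 = m₄₈−m₀:

0. *flat* if max(|d1|,|d2|,|d3|) < `flat_floor` (default 5);
1. *continuous* if d1, d2 share a nonzero sign and |d2| ≥ `kappa`
   (default 5), direction = sign(d1);
2. *late* if |d1| < `epsilon` (default 4.5), direction = sign(d2);
3. otherwise direction = sign(d1); *transient* if the trajectory
   reverses past baseline (sign(d2) = sign(d3) = −direction), else
   *early*.

Hyper = positive direction, hypo = negative. The defaults are the
values that maximise agreement (22 of 24) between this rule and the
published class assignments recomputed from the packaged promoter
table's rounded integer means. Two rows (DDX26B, FAM123B) cannot be
matched by any deterministic rule on printed means — each has a
near-identical printed shape to a row with a different published class
(FAM3A, TMEM187 respectively), because the original calls were
evidently made from patient-level unrounded trajectories. They are
frozen as known mismatches, not tuned away. The classifier also accepts
per-patient trajectories and classifies their unrounded mean when
available. The ninth *flat* class exists for robustness on unfiltered
input; it cannot occur on records that passed a ≥10-point delta filter
with `flat_floor` ≤ 10.

## CPET day-two metrics

Each deterioration flag is a strict inequality of day-two vs day-one
printed values (max HR in bpm, max workload in W, VO₂ peak in
mL/kg/min, anaerobic-threshold workload in W); equality sets no flag,
and AT-lower / AT-higher are mutually exclusive. Anaerobic-threshold
detection from breath-by-breath gas exchange is out of scope: the AT
workload is an input column. RER outside 0.7–1.4 draws a warning, not
an error. Cohort counts include the compound count (lower HR *and*
lower workload) and the complement count of participants whose AT came
at the same or a greater workload.

## Synthetic-data generator

The generator emulates the study conditions the pipeline assumes —
5 cases + 2 controls × 3 timepoints (0 h/24 h/48 h) — and is first-class
tested code, not a fixture.

**Genome.** Measured fragments (lengths uniform in 40–220 bp, CpG
counts uniform in 3–8 by default) are embedded between 8 kb uncuttable
spacers. Each measured fragment is `CGG` + body + `C` so junctions form
exactly one CCGG each; bodies are A/T filler with isolated planted CG
dinucleotides, which cannot create extra CCGG or CpG sites. Digesting
the returned sequence therefore yields *exactly* the requested number
of size-window fragments (the spacers fall outside the window), and the
spacers are wide enough that planted gene structures — promoter
windows, exon/intron/boundary geometries, on both strands for
promoters — never touch a neighbouring measured fragment. Configured
fractions of fragments are placed in promoter / exon / intron /
boundary / intergenic space (defaults 0.2/0.2/0.2/0.1/0.3).

**Truth.** Baseline methylation is Beta(α=0.8, β=0.8) per fragment —
the U-shaped, genome-like profile. Planted effects (percentage points)
are applied as: early — between t0 and t1 then held; late — between t1
and t2 only; gradual — half per interval. Hyper adds, hypo subtracts.
For planted fragments the baseline is rejection-sampled from the same
Beta restricted so the full effect fits inside [0.02, 0.98]; this keeps
the planted-class geometry exact (|Δ| equals the nominal effect in true
means) instead of letting clipping silently shrink effects for extreme
baselines. Null fragments are clipped into [0.02, 0.98] to avoid
degenerate binomials. A configurable fraction of planted effects is
copied to the controls ("shared"); otherwise controls hold baseline.

**Counts.** Per CpG, per sample, per timepoint: coverage is
1 + Poisson(mean_coverage − 1) (mean-parameterised with a floor of one
read; a negative-binomial alternative is available), and the methylated
count is Binomial(coverage, p) with p = the group's true fragment mean
at that timepoint plus a Gaussian offset per (patient, fragment) with
sd `patient_sd` = 3 points, constant across timepoints so each patient
has a coherent trajectory, clipped to [0, 1]. The 3-point default is a
plausibility choice — no per-patient variance estimates exist to
calibrate it — and is configurable.

**Randomness.** One integer seed feeds a `numpy` `SeedSequence`; genome
construction, truth planting and count simulation consume separate
spawned children, so identical configs give byte-identical datasets and
each stage is reproducible in isolation.

**What it does not emulate.** Read-level artefacts (FASTQ, alignment,
incomplete bisulphite conversion), SNP interference, non-CpG
methylation, correlated per-patient offsets across fragments, batch
effects, and real genomic CpG spatial structure. Passing recovery tests
therefore demonstrates the pipeline's statistical behaviour under its
own noise model, not performance on real libraries.

## Calibration and recovery results computed by the tests

Only quantities the suite or `scripts/acceptance.py` actually compute
are stated here.

*Type-I error.* Under the generator's null — per-fragment baseline
~ clipped Beta(0.8, 0.8), replicates Binomial(250 reads)/250, k = 3,
n = 5 — the ANOVA rejects at 0.049–0.052 for α = 0.05 over 10⁴
fragments (within 3 Monte-Carlo SE of nominal). On iid Beta(2, 2)
replicate noise the test is very slightly liberal (≈0.052 across
seeds), and on strongly bimodal iid Beta(0.8, 0.8) replicates more so
(≈0.058): the F-test's small-sample behaviour on bounded platykurtic
data. The calibration suite therefore uses the binomial read-sampling
null, which is the noise replicates actually exhibit in this design;
iid U-shaped replicate noise is not a realistic within-fragment model
(the U-shape describes variation *across* fragments).

*Recovery.* With 1 000 fragments, 50 planted 20-point
early-hypermethylation effects, coverage 50× and default thresholds,
the pipeline recovers all planted fragments as case-specific DMFs with
no null fragments in the specific set and every recovered direction
correct (seeds 1, 2, 7, 123, 99999). Problem sizes (10⁴ calibration
fragments, 10³ recovery fragments) are chosen so the whole suite runs
in well under a minute of compute for these stages.

## Known limitations

- The ANOVA ignores the repeated-measures correlation structure; with
  n = 5 this is a power/robustness trade-off, not an oversight.
- Raw p-values without FDR mean the genome-scale significant set is
  expected to contain ~5% of tested null fragments; the >10-point delta
  filter and the specificity subtraction are the practical guards.
- The delta filter on group means can reassign gradual effects to
  early/late when one interval's noisy delta crosses the threshold
  (see the README worked example).
- Pattern classification from rounded printed means cannot reproduce
  every published call (two frozen mismatches); unrounded per-patient
  input resolves this when available.
- Functional categories in link tables are consumed as an input
  mapping, never computed.
- PCA variance fractions depend on whether variables are scaled;
  centring-only is the default and scaling is a flag, so published
  variance percentages are not directly comparable unless the same
  choice is made.
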