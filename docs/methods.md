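# Methods

## The outlier model

The screen treats each probe's β-values across the cohort as an approximately
normal normative sample and asks whether one individual's value is extreme
against it. The statistic is the single-case t (Crawford–Howell):

    t = (x − m̄) / (s·√(1 + 1/n)),  df = n − 1,

where m̄, s, n are the mean, SD and count of the *other* samples' non-missing
β-values at that probe. This is exactly a pooled-variance two-sample t-test
with group sizes 1 and n (the test suite asserts agreement below 1e-10), and
it is the standard choice for one observation against a normative group: the
√(1 + 1/n) term accounts for the uncertainty of the normative mean, and the
degrees of freedom are well defined. β-values are tested on their native
scale, not as M-values: the downstream interpretation (monoallelic vs mosaic)
reads directly off β, and at the effect sizes that matter here (Δβ ≥ 0.05
over a tight background) the heteroscedasticity of β costs little power.

Assumptions: the cohort is exchangeable at each probe (no batch structure,
no relatedness between samples), at most a small minority of samples carry
any one epimutation (a common epimutation would inflate the rest SD and mask
itself), and the rest-group β distribution is unimodal and tight. The rest
SD is floored at 1e-6 so a numerically constant background yields a huge but
finite t rather than a division error.

## Multiplicity, regions, classification

p-values are two-sided and adjusted per sample by Benjamini–Hochberg across
all testable probes of that individual — the screen is "this person against
everyone else", repeated per person, so the FDR is controlled within each
such comparison. Missing β-values are excluded from the rest statistics; a
probe with fewer than `min_rest_n` (default 10) non-missing rest values has
no usable variance estimate and is marked untestable rather than guessed.

A region is a maximal run of consecutive testable probes — adjacent in
genomic order on one chromosome, untestable probes skipped — in which every
probe has q below the threshold (default 0.005) and the same direction, with
an optional `max_gap` in bp (default unlimited; 1 kb is a reasonable value
when probes are sparse). Runs shorter than `min_run` (default 3) are
discarded. Region coordinates span the first to last member probe, reported
0-based half-open; probe positions are 1-based throughout the manifest, and
conversion happens only at the BED boundary. Island annotation attaches
every island overlapping a region by at least 1 bp.

Hypermethylated regions over a low background (rest mean β < 0.10) are
classified by carrier mean β with configurable thresholds: ≥ 0.25 ⇒
monoallelic, 0.10–0.25 ⇒ mosaic, < 0.10 ⇒ low_level. The 0.25 cut separates
the two regimes the screen is calibrated to: a fully methylated single
allele reads ≈ 0.26–0.42 on the array, a one-allele-in-a-fraction-of-cells
mosaic reads ≈ 0.14–0.22. The 0.60 value documented as the upper edge of the
monoallelic band is descriptive, not an exclusion cut: a carrier mean above
it still implies at least one fully methylated allele, and the classifier
has no separate label for biallelic methylation. Hypomethylated regions are
retained and labelled `hypomethylated` (the test is symmetric and the
information free), and hyper regions over a high background fall back to
`low_level` — neither band model applies there.

## Synthetic cohorts

The generator emulates the screen's intended substrate: 46 samples ×
10,000 probes by default, probes laid out in contiguous blocks (island
blocks of 5 probes at 100 bp spacing, shore/open-sea blocks of 10) over four
synthetic chromosomes, with every island block registered in the island BED.
Baseline means are island 0.05, shore 0.30, open sea 0.85 — canonical array
behaviour — with Beta(m·s, (1−m)·s) noise at concentration s = 150, giving a
background SD of ≈ 0.018 at m = 0.05, comparable to a tight blood-methylation
probe.

A spike replaces a carrier's cells in an island block by draws centred on
e = (1−f)·m + f·λ·(0.5 + m/2): f is the fraction of cells carrying the
methylated allele and λ = 0.7 the attenuation with which the array reads a
truly hemimethylated locus (chosen so that f = 1 over m = 0.05 gives
e ≈ 0.37, inside the observed monoallelic band, without asserting a
mechanism for the compression). f = 0.35 with λ = 1 gives e ≈ 0.22, at the
upper edge of the mosaic band. Expression probes for a target gene are
generated as a − b·mean(β_region) + N(0, σ²) with per-probe baselines and
slope scales, i.e. noisy negative coupling to island methylation. The
variant table is a fixed boundary design: one record per consequence class,
REVEL scores at 0.64/0.65 bracketing the 0.644 cutoff, control MAFs
bracketing 0.1%, and a score-less missense record to exercise the warning
path.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real arrays: type I/II probe chemistry differences,
batch and chip effects, cell-composition heterogeneity of blood, sex
chromosomes, genuinely heavy-tailed probe distributions, and SNP-affected
probes. On real data those inflate the false-positive rate of any outlier
screen; the clean synthetic false-positive rate (≈ 0 regions per cohort at
q < 0.005) is an upper bound on specificity, not an estimate of it.

## Expression and burden stages

Multi-probe expression is summarized as PC1 across samples of the per-probe
centred matrix, sign-oriented to correlate positively with the probe of
highest SD and affinely rescaled to that probe's mean and SD, so scores read
in that probe's expression units; a single-probe gene returns the probe
unchanged. Correlation uses Pearson r with the exact t transform
t = r·√((n−2)/(1−r²)); |r| = 1 maps to p = 0 by continuity. The
tumor-vs-normal contrast is a paired t per probe (Wilcoxon signed-rank
available behind a flag), with probes ranked by |t|; an all-zero delta
vector returns t = 0, p = 1, and a constant non-zero delta returns p = 0.

The variant filter applies rarity first (control MAF ≤ 0.1%, computed as
100·AC/AN), then damage: LoF classes pass unconditionally, missense requires
REVEL > 0.644, everything else drops; a missense record without a REVEL
score is dropped with a warning rather than guessed. Burden comparison is a
two-sided Fisher exact test on the 2×2 allele table, with the
Haldane–Anscombe 0.5 correction applied to the odds ratio only when a cell
is zero. Carriers are counted as heterozygous (one allele each), and a
control cohort stated as individuals contributes 2N alleles — for the
590,031-individual reference this gives 1,180,062 control alleles and a
control MAF of 0.47% at AC = 5,542.

## Numerical and design choices

* FDR is computed by `statsmodels` (`fdr_bh`), checked in tests against a
  brute-force step-up enumeration; NaN p-values propagate as NaN q.
* Fisher p comes from `scipy.stats.fisher_exact`, checked against full
  hypergeometric enumeration for small tables; Pearson p is checked against
  a 10⁵-shuffle permutation null.
* Leave-one-out rest statistics are computed cohort-wide from per-probe
  sums and sums of squares (NaN-aware), so a full 46 × 10,000 scan runs in
  well under a second; variance is clipped at 0 before the square root to
  absorb cancellation error.
* Chromosomes sort chr1..chr22, chrX, chrY, then lexicographically, making
  "consecutive" deterministic for any manifest.
* Determinism: every stochastic component takes a seed; identical
  config + seed reproduces byte-identical pipeline outputs (hash-verified in
  the CLI manifest).
* Problem sizes in the repeated-cohort analyses (100 cohorts of 46 ×
  10,000 probes for spike recovery; 20 cohorts for the mosaic detection
  rate) were chosen to estimate rates to a few percent while keeping a full
  run in tens of seconds.

## Known limitations

The per-sample BH scope means a probe's q depends on the rest of that
sample's p-value distribution; a sample with massive global dysregulation
would dilute its own discoveries. Mosaic spikes at the lower edge of the
band (carrier β ≈ 0.15–0.2 over background ≈ 0.05) sit near the detection
boundary at 10,000 probes — single probes can miss the per-sample q cutoff
and break the 3-probe run, so mosaic sensitivity is materially below the
essentially perfect monoallelic sensitivity (the acceptance script reports
both). The classifier thresholds are calibrated to a low (< 0.10) background
and have no meaning for regions over intermediate backgrounds. The burden
stage assumes one shared control cohort per gene and heterozygous carriers;
it does not model relatedness, ancestry mismatch, or per-variant AN
variation beyond taking the maximum.
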