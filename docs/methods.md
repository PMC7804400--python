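# Methods

## The measurement model

Real-time qPCR reports the cycle number (Ct) at which a reaction's
fluorescence crosses a detection threshold. With per-cycle amplification
efficiency E (E = 1 is perfect doubling), a template load q reaches
threshold at

    Ct = C0 − log2(q) / log2(1 + E) + δ·[dye = FAM] + ε,   ε ~ N(0, σ²),

where C0 is the Ct of one unit of template and δ is an additive dye bias
on the FAM channel, modelling the unequal amplification of the two allele
probes that gDNA normalization exists to correct. A reaction whose noisy
Ct exceeds the run's cycle limit (`ct_max`, default 40) never crosses
threshold; it is exported as `Undetermined` rather than clamped, matching
real instrument exports. Censoring is applied after noise.

The simulator (`aseqpcr.simulate`) draws donor genotypes under
Hardy–Weinberg proportions from a minor allele frequency, loads gDNA wells
with the two alleles at the genotype's proportions (1:1 for
heterozygotes), and loads heterozygous cDNA wells at the assay's true
transcript ratio φ (FAM-allele : VIC-allele), scaled to a constant total
template. Homozygous samples carry one allele only, so their other channel
censors — which is what makes Ct-pair genotype calling possible. Ground
truth (genotypes, φ, dye orientation) is emitted alongside the plates.

Defaults: C0 = 24, E = 0.9, δ = 0, σ = 0.15, MAF = 0.4, five cDNA and
three gDNA replicates per sample, triplicate mixture wells — the replicate
depths of the standard assay design. σ = 0.15 per channel (≈ 0.2 Ct SD on
a per-replicate ΔCt) reflects a well-run 384-well instrument.

## Quantification

For one replicate well, ΔCt = Ct(FAM) − Ct(VIC) = −log2 of the FAM:VIC
template ratio at E = 1, plus the dye bias. The normalized value

    nΔCt = ΔCt(cDNA replicate) − mean ΔCt(all gDNA replicates of the assay)

uses heterozygous gDNA — an obligate 1:1 allele mixture — as the internal
balanced baseline, cancelling δ exactly (an invariant asserted by the test
suite to machine precision). nΔCt < 0 means the FAM-read allele is more
expressed; the reported fold change is 2^|nΔCt| with direction carried by
the allele label (e.g. `G>A`), avoiding sub-unity fold ambiguity.

2^|nΔCt| is an unbiased estimate of φ only at full efficiency; at E < 1 it
recovers φ^(1/log2(1+E)). The certification studies in
`aseqpcr.validation` therefore run at E = 1; with E = 0.9 and φ = 4 the
recovered value would be ≈ 4.5. Estimating E from dilution curves is out
of scope.

Replicates with either channel censored or above the Ct cut-off
(default 36, indicating too little template to quantify) are dropped; a
sample is dropped entirely when fewer than three replicates survive. The
cut-off is strict (`> 36`), so a replicate at exactly 36.0 is kept.

## Testing

Group differences are tested with the two-sided Mann–Whitney U rank-sum
test: each cDNA sample's replicate ΔCt values against the pooled gDNA
replicate ΔCt values (a per-sample-means comparator is available as an
option), and the assay-level verdict from all cDNA replicates pooled
against all gDNA replicates, at α = 0.05 with no multiple-testing
correction by default (a Benjamini–Hochberg option exists for per-sample
calls downstream of the tables). The exact U distribution is enumerated
when the pooled size is ≤ 12 without ties; otherwise the tie-corrected
normal approximation is used. Two identical constant groups return p = 1,
flagged `degenerate`. A Shapiro–Wilk screen documents non-normality of the
ΔCt groups but never switches the test: the pipeline is nonparametric
throughout.

The ASE call is driven by the pooled test alone; the fraction of
individually significant samples agreeing with the pooled sign is reported
as a consistency metric but does not gate the call. Disease status never
enters the ASE statistic — a PD-vs-control comparison of per-sample nΔCt
is reported separately.

## Assay calibration

Mixture series (homozygote gDNA mixed at 4:1, 2:1, 1.5:1, 1.25:1, 1:1,
1:1.25, 1:1.5, 1:2, 1:4, plus a heterozygous 1:1 control, in triplicate)
are summarized as per-ratio mean ΔCt and fitted by ordinary least squares
against log2(ratio) — the scale on which the model is linear. PASS
requires:

- |slope| within 0.3 of 1 (at E ≥ 0.8 the true slope magnitude is ≤ 1.18);
- R² ≥ 0.9;
- a monotone response: strictly monotone means, or — since per-replicate
  ΔCt noise is σ√2 and triplicate means invert small adjacent gaps quite
  often — no inversion against the fitted slope's direction larger than
  2.5 standard errors of that gap. A flat response (no direction) or a
  scrambled one still fails deterministically;
- the het control's mean within 2 combined standard errors of the fitted
  intercept (the dye-bias estimate). Both SEs are computed from the pooled
  within-group replicate SD, which is stable at triplicate depth. Being a
  two-sided 2-SE check, this intentionally flags ≈ 5% of good assays —
  calibration is a screen, and a false FAIL costs one re-run.

All four thresholds are configurable. The het control participates only in
QC, never in the fit.

## Genotype calling

Instrument software calls genotypes from two-dimensional endpoint
fluorescence; this pipeline carries only Ct values, so calls are made from
replicate Ct pairs: a channel censored or above the dropout Ct in every
replicate, with the other amplifying throughout, is a homozygote; both
channels amplifying with mean ΔCt within ±1.5 of the assay's dye-bias
estimate is a heterozygote; anything else is NO_CALL — never a forced
call. The dye-bias estimate is the median gDNA ΔCt of samples where both
channels amplify, computed once per assay (robust to imbalance outliers;
in gDNA all such samples are true 1:1 heterozygotes). Adequacy is
certified against simulation truth: 100% on noiseless data, ≥ 95% at
σ = 0.1.

## Marker selection

Filters compose in order: LD (r² ≥ threshold, inclusive) → transcribed
annotation (coding or UTR) → special regions (polymorphic inversion loci,
isoform-restricted markers) → failed assays → low expression (> 50% of
cDNA samples beyond the Ct cut-off; strictly more than half) → one marker
per (locus, gene) pair. Scoping the per-locus rule by gene keeps one
marker in each gene when a single lead SNP tags two genes. Within a group
a transcribed lead SNP always wins; otherwise highest r², ties broken
coding-over-UTR then lexicographic rsID — markers closest in LD to the
causal signal are favoured, and the outcome is insensitive to input row
order. Secondary association signals bypass the cap. A failed assay is a
status flag consumed by the workflow, not an automatic re-design; its
replacement is simply the next-best marker left in the gene.

The packaged candidate table reproduces a published selection worked
example (13 markers in 12 genes); fields the source does not print —
LD values of excluded candidates, the identities of the five
inversion-locus proxies — are synthetic placeholders and are marked as
such in the data file header. Upstream database-scale counts (thousands of
proxies per GWAS catalogue query) are not reproducible from packaged data
and are out of scope, as is querying LD databases directly.

## Certification studies and their problem sizes

`aseqpcr.validation` runs the full plate-to-verdict pipeline on simulated
cohorts of 30 heterozygous donors (5 cDNA / 3 gDNA replicates, σ = 0.15,
E = 1): 500 cohorts for the type-I error of the pooled test (the observed
rejection rate must sit inside the 99% binomial interval around α = 0.05)
and 100 cohorts per φ ∈ {1.25, 1.5, 2, 4} for fold-change recovery (median
within 10% of truth) and power (≥ 90% at φ ≥ 1.5). These sizes give stable
Monte-Carlo estimates while keeping the suite fast.

## What the simulator does and does not emulate

It emulates: exponential amplification with configurable efficiency, dye
bias, replicate noise, censoring at the cycle limit, Hardy–Weinberg
genotype sampling, homozygote single-channel dropout, and known true
allelic ratios. It does not emulate: donor-level random effects (all
replicates are independent given the design — real donors share RNA
quality and cellular composition, so real pooled p-values are
optimistic in comparison), per-cycle fluorescence curves, probe
thermodynamics, plate-position effects, cross-hybridization between
probes, or tissue-specific true ratios (φ is per assay, not per tissue).
Passing the certification studies therefore shows the statistics are
correct under the stated measurement model, not that the model captures
every failure mode of real plates.

## Numerical and degenerate-input conventions

- `Undetermined` is NaN in memory and a literal token on disk; it counts
  as "above cutoff" everywhere a threshold is applied.
- Empty cohorts yield empty, well-formed tables; zero gDNA heterozygotes
  or zero informative samples raise errors naming the assay.
- R² of a zero-variance response is defined as 0 (the flat calibration
  case, which fails on slope and monotonicity anyway).
- Identical seeds and configurations give byte-identical output files;
  timestamps are confined to logs.
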