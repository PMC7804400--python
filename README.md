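# aseqpcr

Allele-specific expression (ASE) analysis of GWAS risk loci from allelic
qPCR measurements.

Most disease-associated variants found by genome-wide association studies
are non-coding and are thought to act by altering gene regulation in *cis*.
A direct way to test this is allelic expression profiling: in an individual
heterozygous for a transcribed marker SNP, the two alleles of the mRNA can
be distinguished and quantified within the same sample, so any expression
imbalance between them is evidence of *cis*-regulatory variation — with all
*trans*-acting and environmental factors cancelling out by construction.
`aseqpcr` implements the complete analysis for the real-time qPCR version
of this design, in which the two alleles are read on separate fluorescent
dye channels (FAM/VIC) of an allele-discrimination genotyping assay.

## What the package does

1. **Marker selection** (`aseqpcr.selection`) — from a table of GWAS lead
   SNPs and their proxies, select one transcribed marker per locus:
   LD filter (r² ≥ 0.6), transcribed-annotation filter (coding/UTR),
   exclusion of inversion-locus and isoform-restricted markers, exclusion
   of unexpressed assays (majority of cDNA Ct > 36), and a per-locus best
   marker rule with an exemption for secondary association signals. A
   worked-example candidate table is packaged.
2. **Assay calibration** (`aseqpcr.calibration`) — verify an assay can
   quantify allelic ratio from gDNA mixtures of the two homozygotes at
   nine known ratios (4:1 … 1:4). Under exponential amplification,
   ΔCt = Ct(FAM) − Ct(VIC) is linear in log₂(ratio) with slope
   −1/log₂(1+E); assays with flat or scrambled responses fail.
3. **Genotype calling** (`aseqpcr.genotyping`) — identify heterozygous
   donors from gDNA Ct pairs (only heterozygotes are informative).
4. **ASE statistics** (`aseqpcr.ase`) — per-replicate ΔCt, gDNA-normalized
   nΔCt = ΔCt(cDNA) − mean ΔCt(gDNA) (heterozygous gDNA is an obligate
   1:1 mixture, so this cancels dye and amplification bias), fold change
   2^|nΔCt|, Ct > 36 exclusions, Shapiro–Wilk normality screen, and
   Mann–Whitney U rank-sum tests per sample and pooled per assay, plus
   cross-tissue classification (brain-specific vs concordant ASE).
5. **Synthetic plates** (`aseqpcr.simulate`) — a generative measurement
   model (Ct = C0 − log₂(q)/log₂(1+E) + dye bias + noise, censored at the
   cycle limit) producing gDNA/cDNA study plates, mixture series and
   ground-truth tables, so every stage is certified against known answers.

## Worked example

A zero-input demonstration that exercises every stage on simulated data
(one assay with a true two-fold allelic imbalance, one balanced):

```bash
aseqpcr demo --seed 1 --out-dir demo_out
```

Selection on the packaged candidate table keeps 13 transcribed markers in
12 genes (`selection_summary.json`: `"n_selected": 13, "n_genes": 12`),
excluding, among others, a low-expression assay (`LOW_EXPRESSION`), an
inversion-locus cluster (`INVERSION_LOCUS`) and a failed assay replaced by
its within-gene alternative (`ASSAY_FAILED`). Both simulated assays pass
mixture calibration (`calibration.tsv`):

```
assay_id   slope    intercept  r_squared  verdict
ASSAY01    -1.014   0.371      0.996      PASS
ASSAY02    -0.990   0.389      0.990      PASS
```

the fitted slope ≈ −1 reflecting perfect doubling per cycle and the
intercept recovering the simulated FAM dye bias of 0.4 Ct. The brain
result table (`ase_table_brain.tsv`) then reads:

```
Transcribed SNP  Gene   Het. samples  Risk allele  Observed ASE  Overall P value
ASSAY01          GENE1  29            A            A>B           3.5e-37
ASSAY02          GENE2  29            B            A=B           1.2e-01
```

ASSAY01's true two-fold imbalance is detected (`A>B`: the A allele is more
expressed; pooled Mann–Whitney P = 3.5 × 10⁻³⁷ across 29 heterozygotes),
while the balanced ASSAY02 is correctly reported `A=B`. The cross-tissue
table classifies ASSAY01 `concordant_ase` and ASSAY02 `no_ase`.

The same stages are available as library calls
(`run_selection`, `fit_calibration`, `call_cohort`, `analyze_assay`,
`compare_tissues`) and as file-to-file subcommands
(`aseqpcr select | calibrate | genotype | ase | compare`).

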