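# toxta

Analysis pipeline for a competence-regulated type II toxin-antitoxin
operon of the *Haemophilus influenzae* kind — a toxin gene (*toxT*)
followed by its antitoxin (*toxA*), sharing a CRP/Sxy-dependent (CRP-S)
competence promoter plus an internal antitoxin-repressed promoter ("P2")
inside the toxin CDS.  The package is for computational biologists who
want to reproduce, or stress on synthetic data, the four analyses such a
system invites:

1. **Deletion-allele scanning** of a genome cohort: extract the operon
   window via flanking anchor genes, align to the reference, and classify
   each genome as intact, toxT-internal deletion (178 bp),
   promoter-spanning deletion (306 bp), whole-operon deletion (1015 bp
   replaced by 87 bp of novel sequence), or novel.
2. **Selection statistics** on the antitoxin gene: codon-aware alignment,
   pairwise distances, and Nei–Gojobori (1986) dN/dS with Jukes–Cantor
   correction, ω = mean dN / mean dS over all pairs.
3. **RNA-seq quantification** of the competence regulon: midpoint
   fragment counting, DESeq2-style median-of-ratios size factors, FPKM,
   fold-change tables, and operon-level ratios vs wildtype.
4. **Promoter and cleavage analyses**: position-level fragment coverage
   with replicate SE; internal-TSS detection as a change point in
   fragment 5′-start profiles (two-segment Poisson fit, parametric
   bootstrap); batch-matched insert-size shift tests (rank-sum +
   permutation) for global mRNA cleavage; and a simplified k-mer
   depletion scan.

A first-class synthetic-data module generates the study's inputs: genome
cohorts carrying the natural alleles under a purifying-selection
substitution scheme, and stranded paired-end RNA-seq libraries (FASTQ +
truth SAM) from a calibrated two-promoter operon model with background
regulons, batch-specific lognormal insert sizes, and an optional
transcript-cleavage process.  See `docs/methods.md` for models,
parameters, and calibration.

## Worked example

Simulate wildtype and antitoxin-deletion libraries at t = 0, quantify,
and locate the internal promoter:

```bash
toxta simulate-rnaseq --genotype wildtype --genotype dtoxA \
    --timepoint 0 --replicates 2 --pairs 6000 --seed 5 --outdir sim
toxta quantify --manifest sim/manifest.tsv --outdir quant
toxta call-internal-tss --manifest sim/manifest.tsv --seed 1 --out tss.tsv
```

which prints

```
wrote 4 libraries to sim (seed=5)
quantified 4 libraries -> quant
internal TSS at +30 (p=0.004975)
```

The TSS call means the fragment 5′-start profile of the ΔtoxA libraries
steps up 30 nt downstream of the toxin start codon — transcription from
the antitoxin-repressed internal promoter, constitutively active once
the antitoxin is gone.  `quant/fold_changes.tsv` holds per-gene log2
ratios vs the wildtype baseline; the `toxT` row at t = 0 comes out at
3.04 in this small run (log2 9 ≈ 3.17 less the pseudocount's pull at low
counts) because derepressed P2 output raises baseline toxin transcript
~9-fold.
Truncated P2 transcripts cannot encode active toxin: the packaged
reference's only in-frame ATG downstream of P2 sits 30 bp from the gene
end and lacks a Shine-Dalgarno (see
`toxta.coverage.translatability_scan`).

Cohort scanning works the same way:

```bash
toxta simulate-cohort --composition published --divergence 0.02 \
    --seed 1 --out-prefix cohort
toxta scan-alleles --cohort cohort.fa --out calls.tsv
```

`calls.summary.tsv` then reports the published per-class counts
(97 toxT-internal / 45 promoter-spanning / 19 whole-operon / 20 intact)
and 162 genomes with a recognizable antitoxin gene out of 181.

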