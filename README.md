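# binqtl

Bin-map construction and QTL mapping for biparental RIL populations
genotyped by sequencing.

Genotyping-by-sequencing (GBS) of a recombinant inbred line (RIL) panel
yields dense but noisy parental-origin SNP calls. `binqtl` turns such calls
into trait loci, for geneticists and breeders working with biparental
populations (the default dimensions mirror a 275-line maize panel on ten
chromosomes, ~2,181 cM):

1. **QC** — keep SNPs where the parents are homozygous for different
   alleles, recode progeny A/B/H by parental origin (alleles carried by
   neither parent → missing), drop SNPs with segregation distortion
   (χ² vs. 1:1, p < 0.001) or poor call rates.
2. **Bin calling** — slide a 15-SNP window (call A or B when ≥11 of 15
   sites come from one parent, else H), merge equal adjacent windows into
   blocks, detect recombination breakpoints between blocks, and partition
   each chromosome into bins: maximal runs of 100-kb intervals containing
   no breakpoint in any line. Bins are the mapping markers.
3. **Linkage map** — adjacent-bin recombination fractions with the
   selfed-RIL correction R = 2r/(1+2r), converted to cM by the Kosambi map
   function d = 25·ln((1+2r)/(1−2r)).
4. **Phenotype adjustment** — REML mixed models: line BLUEs
   (fixed lines; random replicate, environment, line×environment) and
   variance components feeding the entry-mean broad-sense heritability
   H² = σG²/(σG² + σGY²/Y + σGL²/L + σGLY²/(YL) + σE²/(YLR)).
5. **QTL scan** — composite interval mapping by Haley–Knott regression on
   expected genotype scores, forward-selected marker cofactors with a 10-cM
   exclusion window, genome-wide LOD thresholds from 1,000 phenotype
   permutations (α = 0.05), 1.5-LOD support intervals, additive effects and
   phenotypic variance explained (PVE).
6. **Merging** — QTLs detected in different environments are one locus when
   their intervals overlap or their peaks are within 20 Mb (single-linkage),
   named `qPC<chrom>[-ordinal]`.

A first-class synthetic-data module simulates RIL genomes (Poisson
crossovers, single-seed descent, residual heterozygosity), GBS-like call
errors and missingness, and multi-environment replicated phenotypes with a
tunable heritability — so the whole chain is testable end to end without
sequencing data. Real genotypes can be supplied as VCF or a TSV matrix, and
phenotypes as CSV.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Run the simulate → qc → binmap → geneticmap → blue → scan → merge pipeline
on a small synthetic population (3 chromosomes × 120 cM, 120 lines, two
planted QTLs: +0.4 on chr1 at 30 Mb, −0.35 on chr2 at 60 Mb, H² = 0.81,
three environment-years × 3 replicates):

```python
from binqtl.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig.model_validate({
    "seed": 11,
    "genome": {"n_chrom": 3, "bp_lengths": [120_000_000] * 3,
               "cm_lengths": [120.0] * 3, "n_snps_per_chrom": [1500] * 3},
    "population": {"n_lines": 120},
    "trait": {"qtls": [{"chrom": "chr1", "pos_bp": 30_000_000, "effect": 0.4},
                       {"chrom": "chr2", "pos_bp": 60_000_000, "effect": -0.35}]},
    "scan": {"n_perm": 200},
})
manifest = run_pipeline(cfg, "demo_out")
```

The stage log of this run:

```
simulate    120 lines, 4,500 SNPs, 1,080 phenotype records, 921 true breakpoints
qc          4,500 -> 4,500 SNPs, 120 lines
binmap      720 bins, 889 detected breakpoints (7.4 per line)
geneticmap  720 markers, 321.8 cM total          (simulated truth: 360 cM)
blue        120 BLUEs, H2 = 0.758                (architecture tuned to 0.81)
scan        thresholds 2.6-2.9 LOD; 2-3 QTLs per environment
merge       2 consensus loci, 9 report rows
```

and the merged report (`demo_out/qtl_report.csv`, abridged):

```
Name  Chr  Env      Marker interval  Interval (Mb)  PVE    ADD    LOD
qPC1  1    HEB2019  mk54-mk61        26.40-31.50    36.69  0.42   17.37
qPC1  1    BLUE     mk55-mk60        27.00-31.10    41.84  0.41   26.56
qPC2  2    HEB2019  mk385-mk391      57.70-62.00    21.38  -0.34  10.85
qPC2  2    BLUE     mk386-mk391      58.20-62.00    29.31  -0.36  21.03
```

Both planted QTLs are recovered in every environment, with the true
positions (30 and 60 Mb) inside every interval, effect signs matching the
planted effects (+0.4 / −0.35; ADD is per female-parent allele), and each
locus given one consensus name across environments.

The same stages are exposed as a CLI:

```bash
binqtl run --seed 11 --config config.yaml --out demo_out
binqtl simulate / qc / binmap / geneticmap / blue / scan / merge / assoc / ddcq
```

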