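# brewtrace

Analyses for polyploid brewery yeast genomes: ploidy inference from flow
cytometry and SNP allele-frequency spectra, relatedness and clustering
(IBS, KING kinship, neighbor joining, PCA), divergence dating from shared
synonymous variants with a molecular clock, read-depth CNV calling with
kinship-pruned frequency estimation, structural-variant proximity
comparison, split-read translocation scanning with a detection power study,
and a sliding-window percentile growth-rate statistic.

Every analysis stage has a matching simulator in `brewtrace.synthetic_data`
(clock-like divergence of a strain pair against an outgroup, coverage tracks
with injected CNVs and end-slope artifacts, rearranged genomes with
error-free long reads and exact truth mappings, logistic growth curves,
two-peak fluorescence samples, paired SV call sets), so the whole pipeline
runs without external data.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end criteria (clock conversion,
tetraploid mode recovery, divergence-parameter recovery, CNV/SV/translocation
property suites, oracle equivalences).

## Library layout

| module | contents |
|---|---|
| `brewtrace.core_io` | VCF/FASTA/BED/bedGraph/PAF-like TSV readers and writers, `VariantTable`, `GenomeModel`, genotype-to-sequence projection, CDS concatenation |
| `brewtrace.synthetic_data` | all simulators + truth records |
| `brewtrace.ploidy` | cytometry peak finding, DNA-content ratios, allele-frequency modes, spore viability |
| `brewtrace.popgen` | genotype filters, IBS/KING matrices, NJ tree, PCA, π / d_xy / heterozygosity, branch-fraction divergence dating, clock conversions |
| `brewtrace.cnv` | coverage normalization, chromosome-end slope filter, ≥10 kb segment caller, kinship-pruned group frequencies, per-gene coverage |
| `brewtrace.sv` | SV support filter, read subsampling, closest-same-class proximity distances, one-sided Mann–Whitney tests with BH FDR |
| `brewtrace.transloc` | split-read selection, 20 kb contact matrix, candidate detection with control masking, repeat-vs-genic power experiment |
| `brewtrace.growth` | sliding-window 98th-percentile growth rate, dose-response tables |

## CLI

```sh
brewtrace simulate population --n-syn-sites 50000 --seed 1 --out-dir out/
brewtrace popgen date --vcf out/population.vcf --focal focal --relative relative
brewtrace simulate coverage --config cov.yaml --out-dir out/
brewtrace cnv call --bedgraph out/coverage.bedgraph --ploidy 4 --out-dir out/
brewtrace ploidy --cytometry cells.tsv
brewtrace sv filter --table calls.tsv --depth 60
brewtrace transloc detect --segments segments.tsv --genome-length 12000000
brewtrace growth --plate plate.tsv --map wells.yaml
```

Run `brewtrace --help` (or any subcommand with `--help`) for the full set of
options. Alignments in SAM/BAM form can be converted to the PAF-like TSV the
`transloc` commands expect with
`samtools view` + awk over (QNAME, read length, query span, RNAME, POS, end,
strand, flag class primary/supplementary/secondary).

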