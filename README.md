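# promvar

Promoter SNP-content analysis toolkit. Given a transcript annotation
table (UCSC genePred/refGene dialect) and a SNP table (UCSC common-SNP
dialect, or plain-text VCF), promvar:

1. **filters the transcript catalog** — curated accessions (`NM_` prefix),
   canonical chromosomes (1–22, X, Y), coding annotations only, and one
   transcript per distinct (chrom, strand, TSS) key;
2. **counts SNPs in strand-aware upstream windows** of the transcription
   start site (TSS) or the coding region start (CRS), for configurable
   window lengths and 5'UTR requirements (all coordinates 0-based
   half-open; only class-`single`, `by-1000genomes`-validated records
   count by default);
3. **derives the SNP-rich subset** (≥ 6 SNPs in the 500-bp TSS window by
   default);
4. **tests a gene group against the whole-catalog background**: at each
   threshold N = 1..20 the tail proportions of transcripts with ≥ N
   upstream SNPs are compared via the angular (arcsine square root)
   transformation, `y = 2·arcsin(√p)`, with statistic
   `(y1 − y2)/√(1/n1 + 1/n2)` referred to the standard normal;
5. **scores gene-set overlaps** with fold enrichment `(k/n)/(K/N_bg)`
   and the EASE score (one-sided Fisher exact p-value with the overlap
   count decremented by one), using the conventional screens
   (count ≥ 2, EASE ≤ 0.1, p < 0.05 flag).

A synthetic-data generator produces annotation + SNP datasets with
known structure (baseline density 3.7 SNPs/kb, a designated gene group
with elevated upstream density) for power/calibration studies, plus a
tiny hand-auditable fixture with a hand-written manifest.

## CLI

```sh
# write the tiny fixture, or simulate a dataset from a YAML spec
promvar simulate --fixture --out-dir fixture/
promvar simulate --spec sim.yaml --seed 1 --out-dir sim/

# per-transcript SNP contents for one analysis case
promvar count --annotation sim/annotation.tsv --snps sim/snps.tsv \
    --anchor TSS --window 500 --utr any --out contents.tsv \
    --rich-out snp_rich.tsv

# group-vs-background threshold sweep (N = 1..20)
promvar test --group sim/group_group1.txt --contents contents.tsv \
    --nmin 1 --nmax 20 --sided greater --out sweep.tsv

# gene-set fold enrichment + EASE scores
promvar enrich --query snp_rich_genes.txt --sets sets.gmt \
    --background all_genes.txt --out enrichment.tsv

# everything from one YAML config
promvar run --config config.yaml --out-dir results/
```

A `run` config chooses exactly one of `inputs:` (annotation + SNP
paths) or `simulation:` (SimulationSpec fields), plus optional
`groups:`, `cases:`, `test:`, `snp_filter:`, `snp_rich:` and
`enrichment:` sections; every option has a CLI override and all
randomness flows from the single seed.

## Layout

- `src/promvar/io_formats.py` — genePred/UCSC-SNP/VCF/GMT/TSV readers and writers
- `src/promvar/transcript_catalog.py` — selection criteria, 5'UTR lengths, anchors, upstream windows
- `src/promvar/snp_content.py` — SNP screening and per-window counting (binary search)
- `src/promvar/group_stats.py` — angular transform, two-proportion test, threshold sweeps, case matrix
- `src/promvar/enrichment.py` — fold enrichment, EASE/Fisher scores
- `src/promvar/synthetic_data.py` — simulator and the hand-auditable fixture
- `src/promvar/pipeline_cli.py` — `promvar` CLI and end-to-end pipeline
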