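# utrscout

Genome-wide discovery and characterization of bacterial 5′ untranslated
regions (5′UTRs) from strand-specific RNA-seq coverage, modeled on the
regulatory-element landscape of the ethanologen *Zymomonas mobilis*.

5′UTRs — the transcribed region between a transcription start site (TSS) and
the start codon — can act as *cis*-regulatory elements (riboswitches,
RNA thermometers, stability elements) that tune downstream gene expression
under stress. `utrscout` implements the complete computational side of a
5′UTR hunt:

- **utr_discovery** — call putative 5′UTRs by scanning strand-specific
  per-base coverage outward from each annotated translation start: extend
  while depth ≥ `min_depth` (gap tolerance `max_gap`, scan limit
  `max_scan`), then filter candidates for comparable expression with the
  adjacent gene (mean UTR depth / mean CDS depth ≥ 0.25), minimum length
  (≥ 35 nt, the shortest known UTR regulatory element), and prioritize
  metabolic-enzyme products.
- **candidate_annotation** — refine each TSS from 5′RACE reads carrying the
  45-nt ligated adapter (the base after the adapter is the mRNA 5′ end;
  the modal mapped position wins), encode the RT-PCR primer set A/B
  confirmation logic, join external Rfam / BLAST-conservation / stress-DE
  tables, and assemble + summarize the final candidate table. The published
  36-row candidate table ships as a fixture.
- **screen_analysis** — analyze the GFP reporter screen (per-sample median
  fluorescence over ≥ 50,000 flow-cytometry events, replicate fold changes
  vs. the rich-medium RMG control, and hit calling by a one-sample t-test on
  log₂ ratios with an effect floor), relative qPCR quantification by the
  comparative ΔΔC_T method (fold = 2^(−ΔΔC_T)), western band normalization to
  an internal control, and design of BsmBI-flanked UTR + 90 nt Golden Gate
  reporter inserts.
- **synthetic_data** — generate every pipeline input with planted ground
  truth (genome + GFF3, BEDGraph coverage plateaus, adapter-bearing RACE
  reads, log-normal fluorescence events, Ct tables), so the whole pipeline
  is testable end to end without external data.

## Worked example

Simulate a small study, discover the planted UTRs, refine the TSS from RACE
reads, and analyze the screen and qPCR tables:

```bash
cat > cfg.yaml <<EOF
n_genes: 6
genome_length: 30000
EOF
utrscout simulate --config cfg.yaml --outdir sim --seed 11
utrscout discover --gff sim/genes.gff3 --cov-plus sim/coverage_plus.bedgraph \
    --cov-minus sim/coverage_minus.bedgraph --fasta sim/genome.fasta
# 6 candidates -> candidates.tsv, candidates.bed
head -3 candidates.tsv | cut -f1-2,8-16
```

```
gene_id  gene_product         strand  tss   utr_start  utr_end  length  mean_utr_depth  mean_cds_depth  expression_ratio  flags
SYN0000  synthetic protein 0  -       4829  4720       4830     110     76.67           100.37          0.764             passed_comparable;passed_length
SYN0001  synthetic protein 1  -       7156  7029       7157     128     48.37           100.28          0.482             passed_comparable;passed_length
```

The planted truth (`sim/truth.json`) records `SYN0000` with a 110-nt UTR at
TSS 4829 and expression ratio 0.78 — the caller recovers the interval
exactly and measures the ratio from the Poisson coverage (0.764). RACE
refinement agrees:

```bash
utrscout race --reads sim/race_reads.fasta --fasta sim/genome.fasta --gff sim/genes.gff3
# gene_id  status  tss    support
# SYN0000  called  4829   10
utrscout screen --events sim/screen_events.csv
# 1 responsive strain x condition pairs -> screen_hits.tsv
utrscout qpcr --table sim/qpcr_ct.tsv --target hfq --reference reference \
    --treated ethanol_5 --control control
# {"ddct": -1.0, "fold": 2.0, "fold_sd": 0.0}
```

The screen hit is the simulated construct whose median fluorescence halves
under 5% ethanol (called "down", mirroring an ethanol-responsive UTR); the
qPCR table encodes a planted 2-fold induction, recovered exactly at zero
noise.

The library API mirrors the CLI — see `utrscout.discover`,
`utrscout.refine_tss_from_race`, `utrscout.screen_hits`,
`utrscout.ddct_fold`, `utrscout.design_reporter_insert`, and
`utrscout.datasets.simulate_dataset`.

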