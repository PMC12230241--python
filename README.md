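# sdlscreen

Analysis toolkit for synthetic-dosage-lethality (SDL) discovery screens:
scoring of two-arm time-course shRNA dropout screens with a weighted
differential cumulative change (WDC) statistic, pooled/arrayed CRISPR
validation screens, candidate prioritization against expression /
essentiality / survival / drug-response resources, single-cell CRISPR
(Perturb-seq) knockout triage, and downstream growth-kinetics and motif
analyses. A first-class synthetic-data module generates every input with
recorded ground truth, so the whole pipeline is testable offline.

## Modules

| module | what it does |
|---|---|
| `sdlscreen.synthdata` | simulators for shRNA screens, sgRNA count matrices, amplicon reads, Perturb-seq populations, patient cohorts, tumor growth, and motif-planted transcripts |
| `sdlscreen.shrna` | quantile normalization, background filtering, hairpin/gene WDC, permutation + t-test p values, hit calling, replicate QC, PR/F evaluation |
| `sdlscreen.crispr` | sgRNA counting from FASTQ (exact/1-mismatch), endpoint dropout scoring vs a no-Cas9 baseline, arrayed confluency hit rule, screen intersection |
| `sdlscreen.prioritize` | co-expression screen, expression/essential-gene filters, differential essentiality, natural-SDL survival contrast, drug-sensitivity tails, candidate ledger |
| `sdlscreen.perturbseq` | cell QC by UMI/guide counts, normalization, KO-efficiency checks, PCA+k-means clustering, KO-by-cluster composition, anchor-high tracing |
| `sdlscreen.downstream` | caliper tumor volumes, growth slope/doubling time, PDX group comparison, mito-stress metrics, RNA motif counting |
| `sdlscreen.cli` | the `sdl` command-line entry point |

## CLI

All stages are exposed under a single `sdl` command; every run writes a
`provenance.json` recording parameters, versions, and seeds.

```bash
# simulate a screen, then score it
sdl simulate-shrna --out sim/ --seed 7
sdl shrna-score --input sim/screen.tsv --out scores/ \
    --epsilon 0.5 --n-perm 1000 --alpha 0.05 --fold-threshold -1.0 --seed 7

# sgRNA counting and endpoint scoring
sdl crispr-count --fastq reads.fastq --library lib.csv --max-mismatch 1 --out counts.tsv
sdl crispr-score --counts counts.tsv --library lib.csv --out invivo/

# arrayed screen, prioritization, Perturb-seq, downstream analyses
sdl arrayed --input confluency.csv --out hits.tsv
sdl prioritize --strategy survival --config cfg.yaml --out survival.json
sdl perturbseq --mtx mtx_dir/ --guides guides.csv --target-map map.csv \
    --out triage/ --min-umis 5000 --k 10 --anchor PLK1
sdl motifs --fasta tx.fasta --out motifs.tsv
sdl growth --input growth.csv --out fits.tsv
sdl pdx-compare --input pdx.csv --out pdx.json
sdl mito --input mito.csv --out mito.tsv
```

Interchange formats are plain text: intensity/count/score TSVs, guide and
cohort CSVs, FASTA/FASTQ, MTX triplets with features/barcodes sidecars,
and JSON truth/provenance records.

## Notes on the statistic

For hairpin h with log2 signal x_t at ordered timepoints t = 0..T in each
arm and replicate, the weighted cumulative change is
`sum_t eps^(t+1) * (x_{t+1} - x_t)`; the WDC is the treatment-arm value
minus the control-arm value, averaged over replicates. Gene scores average
the k most negative hairpins (default 2). Significance combines a
pool-resampling permutation test (add-one corrected) with a two-sample t
test over per-(hairpin, replicate) weighted changes, and hits additionally
require the gene score to clear a fold threshold.
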