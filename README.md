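# clonetrace

Clonal barcode tracking and analysis: a pipeline for lentiviral cellular
barcoding experiments, from raw amplicon reads to clonal statistics,
spatial reconstruction of cut tumors, dissemination null models, and a 3D
growth simulator — plus a synthetic-data generator with known ground
truth so every stage is testable.

## Modules

| Module | Purpose |
| --- | --- |
| `clonetrace.barcode_io` | Sample sheets, barcode libraries, FASTQ demultiplexing into a replicate × barcode count matrix, TSV round trips |
| `clonetrace.qc_normalize` | Read-depth filter (default ≥ 8000 reads/replicate), replicate-support barcode filter, replicate pooling and normalization to frequency profiles |
| `clonetrace.clone_metrics` | Engraftment, cumulative clone-size curves, dispersion, biomass representation, fold-change classes, Shannon/Simpson diversity, log-frequency regression, organ overlap, group tests, tumor-volume/cell estimates |
| `clonetrace.spatial_reconstruction` | Hellinger distances between tumor pieces, stress-majorization 2D layout, hierarchical clustering with Newick export |
| `clonetrace.dissemination_null` | Multinomial subsampling null model (proportional shedding), analytic expected clone detection, empirical p-values |
| `clonetrace.tumor_growth_sim` | Gillespie birth/death/migration growth of barcoded cells on a 3D lattice; virtual cutting into octants/slabs/k-means regions |
| `clonetrace.synthetic_data` | Full synthetic experiments: heavy-tailed clone sizes, patchy tumor pieces, shedder/seeder structure, replicate noise, contaminant barcodes, optional FASTQ rendering |

## CLI

All stages are exposed under one `clonetrace` command:

```sh
# generate a synthetic experiment with ground truth (library, sheet, counts, FASTQ)
clonetrace synth --config synth.yaml --seed 42 --out-dir fixtures/ --fastq

# demultiplex reads into a count matrix
clonetrace count --reads fixtures/reads.fastq --library fixtures/library.fa \
    --sheet fixtures/sheet.tsv --max-mismatch 2 --out counts.tsv

# QC, pooling and normalization
clonetrace qc --counts counts.tsv --min-reads 8000 --min-replicates 2 \
    --out profiles.tsv --report qc_report.json

# clonal statistics and pairwise tissue comparisons
clonetrace metrics --profiles profiles.tsv --pairs tumor:lung,tumor:blood \
    --threshold-fold 10 --out metrics.json

# spatial reconstruction of tumor pieces
clonetrace spatial --profiles pieces.tsv --seed 7 --out layout.tsv \
    --dendrogram pieces.nwk

# proportional-shedding null model
clonetrace null --profiles profiles.tsv --pairs tumor:blood,tumor:lung \
    --replicates 1000 --seed 11 --out null.json

# 3D growth simulation with a virtual cut into 8 pieces
clonetrace simulate --seed 3 --target-cells 100000 --out cells.tsv \
    --cut 8 --cut-scheme octants --counts-out virtual_pieces.tsv
```

## Notes

- Frequency profiles always sum to 1; zeros are dropped after filtering,
  and no pseudocounts are used anywhere (log-scale comparisons are
  restricted to barcodes detected in both tissues).
- The growth simulator defaults to a desk-scale 1e5-cell target; rates
  (`birth_rate=1`, `death_rate=0.1`, `migration_rate` configurable) are
  exposed in `SimParams`.
- All randomness flows through explicit seeds; identical inputs and
  seeds reproduce outputs bit-for-bit.
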