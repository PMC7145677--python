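# enhcons

Weighted consensus enhancer calling from multi-assay epigenomic peak
tracks.

Enhancers are distal regulatory elements that no single assay detects
reliably: histone-mark ChIP-seq, DNase/ATAC accessibility, P300 or POLR2A
binding, TF ChIP-seq, eRNA transcription (GRO-seq/CAGE), reporter assays
(MPRA/STARR-seq) and ChIA-PET interactions each produce peak sets with
their own biases and error modes. `enhcons` integrates per-experiment peak
calls grouped into up to twelve such **evidence tracks** for one
tissue/cell type into a single **consensus enhancer track**, weighting
each track by how well it agrees with the others.

## Method

For each dataset, peaks longer than 2500 bp and peaks overlapping
promoters, exons or CTCF-defined insulators are removed; datasets with
merged peak coverage below 5 kb or above 10 Mb are discarded as
degenerate. Surviving fold enrichments are normalized by the dataset's
length-weighted mean signal,

    s'_i = s_i / ( Σ_i s_i·l_i / Σ_i l_i ),

so every dataset's length-weighted mean signal is 1. When one track holds
several datasets, their peaks are merged cluster-by-cluster into a peak
centered at the **average summit** with the **average peak width** (ASW).

Tracks are then compared pairwise with a region-count Jaccard index: the
peaks of both tracks are merged into union regions, and

    J(A_i, A_j) = (# union regions containing peaks of both tracks)
                / (# union regions).

Track *t*'s weight is its share of the total pairwise agreement,

    w_t = Σ_{j≠t} J(A_t, A_j) / Σ_k Σ_{j≠k} J(A_k, A_j),

so Σ_t w_t = 1. Candidate regions (the merged union of all tracks' peaks)
become consensus enhancers when supported by at least 50% of tracks
(both tracks when only two are available), scored as

    Score_combined = Σ_t w_t · L_t · Score_t / L_combined

summing over every contributing peak, with `L_t` the peak length,
`Score_t` its normalized signal and `L_combined` the consensus length.

## Worked example

`examples/build_consensus.py` plants 300 enhancers on a 50 Mb synthetic
genome, observes them with four imperfect assays (per-track sensitivity
0.8, positional jitter, one independent noise peak per true peak) and
runs the full pipeline:

```
tracks: ['P300', 'Histone', 'TF-binding', 'DHS']
track weights:
        P300  w = 0.2504
     Histone  w = 0.2569
  TF-binding  w = 0.2542
         DHS  w = 0.2385
consensus enhancers called: 305 (planted: 300)
recall    of planted enhancers: 0.9833
precision of consensus peaks:   0.9672
  single-track precision       P300: 0.4586
  single-track precision    Histone: 0.4659
  single-track precision TF-binding: 0.4567
  single-track precision        DHS: 0.4209
```

The weights are near-uniform because the four simulated assays are
equally reliable; the consensus recovers 98% of planted enhancers while
each individual track is wrong more than half the time — independent
noise rarely clears the ≥50%-support bar. The other scripts in
`examples/` demonstrate preprocessing, track similarity/weighting and the
shell workflow.

## Command line

```bash
enhcons synth --out scenario/ --seed 7         # synthetic benchmark files
enhcons build --manifest scenario/manifest.tsv \
    --promoters scenario/promoters.bed --exons scenario/exons.bed \
    --insulators scenario/insulators.bed --out results/
```

`build` writes `consensus.bed` (column 4 = supporting tracks, column 5 =
combined score), `similarity.tsv`, `weights.tsv`, `filter_report.tsv` and
`summary.json`. All thresholds (`--min-support`, `--max-peak-len`,
`--min-cov`, `--max-cov`, `--jaccard-mode`) are flags; a YAML `--config`
file can supply defaults, with flags winning.

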