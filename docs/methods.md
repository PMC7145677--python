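# Methods

## Model and assumptions

`enhcons` treats enhancer identification as an evidence-integration
problem. Each of up to twelve assay classes (P300, POLR2A, histone marks,
TF binding, DHS/ATAC, FAIRE, MNase, GRO-seq, CAGE, MPRA, STARR-seq,
ChIA-PET) contributes one *track* of peak intervals for a tissue/cell
type. The model's premises are:

- real enhancers tend to be detected by several independent assays at
  overlapping coordinates, while each assay's false positives are largely
  assay-specific;
- a track that agrees with many other tracks is more trustworthy, so its
  peaks should count for more;
- peak fold enrichments are only comparable after removing per-dataset
  scale: dividing by the length-weighted mean signal puts every dataset
  on a common scale where the length-weighted mean is 1.

No sequence, strand or genome-build logic is involved: the unit of
analysis is the half-open interval `[start, end)` in 0-based BED
coordinates, and two intervals interact iff they share at least one base
pair (book-ended intervals do not).

## Pipeline and parameter defaults

| stage | parameter | default | units | rationale |
|---|---|---|---|---|
| length cap | `max_peak_len` | 2500 | bp | enhancers are sub-kb to few-kb; longer peaks are usually broad domains. Strictly-greater removal (a 2500 bp peak is kept). |
| blacklist | — | user BEDs | — | promoters, exons and CTCF insulators are removed whole-peak on ≥1 bp overlap; truncation would manufacture artificial boundaries. |
| size gate | `min_cov`/`max_cov` | 5 kb / 10 Mb | bp | datasets with almost no, or genome-scale, merged peak coverage indicate failed experiments. "Size" is operationalized as merged bp coverage: it is format-independent, unlike file bytes or raw peak counts. |
| normalization | — | — | — | `s'_i = s_i/(Σs_i·l_i/Σl_i)`; runs **after** the filters so removed peaks cannot contaminate the denominator. |
| support rule | `min_support_fraction` | 0.5 | fraction of tracks | threshold `ceil(f·m)` supporting tracks; with exactly two tracks and `f ≥ 0.5`, both must support — one assay alone is never sufficient evidence. |
| similarity | `jaccard_mode` | `regions` | — | region-count intersection over union; a bp-level mode exists for sensitivity analysis (see below). |
| scoring | `score_overlap` | `full` | — | contributing peaks enter the score numerator with their full length; a `clipped` mode restricts to the overlap with the consensus interval. |

## Within-track merging (ASW)

When one track holds several datasets, pooled peaks are partitioned into
clusters of transitively overlapping peaks (single linkage, ≥1 bp). Each
cluster becomes one peak centered at the arithmetic mean of the member
summits (narrowPeak summit when present, interval midpoint otherwise)
with width equal to the rounded mean member length and signal equal to
the mean member normalized signal. Design points that were genuinely
open:

- *clustering rule*: single-linkage transitive overlap, the standard
  interval-merge semantics;
- *merged signal*: the arithmetic mean — it preserves the normalization
  scale, where taking the maximum would systematically inflate tracks
  with many datasets;
- *rounding*: half-up (`floor(x + 0.5)`), never banker's, so merged
  geometry cannot depend on integer parity; merged starts are clipped at
  0 (chromosome lengths are unknown to the tool unless supplied);
- *re-overlap*: averaged widths can exceed a cluster's span and create
  new overlaps between adjacent outputs, so the merge iterates to a
  fixed point (empirically one extra pass; hard error after 10).

## Similarity, weights and the consensus

The Jaccard numerator/denominator count **regions**, not base pairs: the
two tracks' peaks are single-linkage merged into union regions and the
index is the fraction of regions containing at least one peak from each
track. Whether the counts should instead be coverage totals is not
decidable in principle — both readings are coherent — so the bp-level
intersection-over-union is shipped behind `jaccard_mode="bp"` while
`regions` remains the default, reflecting that the discriminating events
are *loci*, not coverage mass. Both tracks empty gives 0; the similarity
matrix diagonal is 1 for non-empty tracks.

Track weights divide each track's off-diagonal row sum by the sum of all
off-diagonal entries. The printed index constraints of the weight formula
as usually stated (excluding `j = t` from a denominator in which `t` is
not bound) cannot hold simultaneously with weights summing to 1; the
off-diagonal reading is the unique one under which `Σ w_t = 1` exactly,
which the combined-score formula implicitly requires (m identical tracks
sharing a peak of score `s` must yield a consensus score of exactly `s`).
A similarity matrix with zero off-diagonal mass (no track overlaps any
other) falls back to uniform weights `1/m` with a logged warning rather
than dividing by zero.

Consensus candidates are the single-linkage merged union regions over all
tracks' peaks; support is the number of distinct tracks with ≥1 bp
overlap. Because every track with a member peak in a candidate overlaps
it, the candidate's span and its supporting-track set coincide with its
member peaks — no separate truncation step is needed, and consensus peaks
are mutually non-overlapping by construction. Tracks emptied by filtering
are dropped before `m` is counted. The pipeline refuses to run with fewer
than 2 surviving tracks and warns below 3.

## Synthetic benchmark

`SyntheticScenario` emulates the intended data regime: a set of planted
enhancers observed imperfectly by several independent assays.

Defaults: 50 Mb over two chromosomes; 300 planted enhancers of 200–1000
bp at least 1 kb apart (placed by the uniform gap construction); 4
tracks × 1 dataset; per-track sensitivity 0.8; positional and width
jitter SD 50 bp; fold enrichments log-normal(μ=1.0, σ=0.5); one noise
peak per true peak per dataset, placed uniformly in intergenic space and
never overlapping a planted enhancer, independently across tracks; 150
promoter/exon/insulator intervals planted ≥2 kb from any enhancer so
annotation exclusion removes only noise. The genome size was chosen so
that true peaks dominate by signal sharing rather than by crowding: at
this density, independent noise from two tracks collides rarely enough
that the ≥50%-support rule — not any tuned threshold — is what separates
signal from noise. One master seed spawns child streams per
(track, dataset) via `numpy.random.SeedSequence`, so outputs are
byte-reproducible and per-track parameters can change without perturbing
other tracks' draws.

What the generator does *not* emulate: correlated artifacts between
assays (e.g. shared mappability blacklist regions), assay-specific peak
shapes, chromosome-scale covariates, or read-level noise. Passing the
recovery benchmark therefore shows that the weighting and support
machinery works as specified, not that any particular real tissue would
reach the same precision — real assay errors are partially correlated,
which can only lower the advantage of consensus over single tracks.

`score_against_truth` uses ≥1 bp overlap: recall is the fraction of
planted enhancers touched by a consensus peak, precision the fraction of
consensus peaks touching a planted enhancer. An empty truth set makes
recall undefined (NaN, with a warning).

## Numerical and degenerate-input choices

- Coordinates are validated at construction (`start ≥ 0`, `end > start`,
  summit inside the peak); malformed BED lines are rejected with their
  line number, but an empty file is a warning, not an error.
- Sorting is total and stable on `(chrom, start, end)`; ties keep input
  order.
- Normalization refuses empty and all-zero-signal datasets explicitly.
- BED scores are written with 6 significant digits, which makes a
  write→read→write cycle byte-stable.
- Problem sizes in tests and the acceptance script (300 planted
  enhancers, ≤500-peak oracle comparisons, 200 random matrices) keep the
  entire suite within seconds while exercising every code path at
  realistic density.

## Known limitations

- The within-track ASW merge weights every member dataset equally;
  datasets within a track are not themselves quality-weighted.
- Chromosome-length clipping only happens if the caller supplies sizes;
  merged peaks can in principle extend past a real chromosome end.
- The region-count Jaccard treats a sprawling multi-kb union region and
  a sharp 200 bp one as single events each; the bp mode inverts that
  trade-off. Neither is uniformly better.
- No enhancer–gene target assignment, super-enhancer calling or
  cross-species comparison is attempted.
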