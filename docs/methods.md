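# Methods

This note documents the models, conventions and numerical choices behind
`cherbp`, in the order the pipeline applies them.

## Coordinates and region model

All intervals are 0-based half-open internally. GTF input (1-based
inclusive) is converted on read and back on write; BED-family formats pass
through unchanged. A single internal convention prevents off-by-one drift
between the annotation, peak and event layers.

Each gene is modelled as a single transcript: an extent, a strand, ordered
non-overlapping exons, and introns derived as the exon gaps. Around the
strand-aware TSS and TES, fixed windows define the promoter and TTS
classes; a position at signed transcription-direction offset `d` from the
anchor belongs to the window when `-upstream <= d < downstream`.

| parameter | default | meaning |
|---|---|---|
| `promoter_upstream` / `promoter_downstream` | 1000 / 100 bp | promoter window around the TSS |
| `tts_upstream` / `tts_downstream` | 100 / 1000 bp | TTS window around the TES |
| `utr_proxy` | 200 bp | fixed-width UTR stand-ins at the transcript ends |

The defaults follow the common annotate-peaks convention of a promoter
window biased upstream and a TTS window biased downstream; all five are
configurable. Because the toy annotation carries no CDS/UTR features, the
5'/3' UTR classes are fixed-width proxies at the transcript ends
(disabled with `utr_proxy=0`).

Overlapping windows are resolved by a fixed priority —
promoter > tts > 5'UTR proxy > 3'UTR proxy > exon > intron > intergenic —
with ties between genes broken by lexicographically smaller `gene_id`.
Classification is therefore a pure function: every position gets exactly
one label, and the genome-wide per-base fractions of the seven classes sum
to 1 (verified to 1e-9 in the tests). Peaks are classified by their
midpoint, `floor((start+end)/2)`, rather than by any-overlap, so that each
peak contributes one label and region percentages sum to 100%.

"Nearest gene" distance is 0 when the peak midpoint lies in a gene body or
its promoter/TTS window (this single definition is also what "bound gene"
means throughout the integration; distal-enhancer linking is out of
scope); otherwise it is the signed midpoint-to-TSS offset, negative
upstream. Ties go to the smaller `gene_id`.

## Significance filters

All printed inequalities are implemented strictly, exactly as typeset;
boundary rows are excluded. Defaults:

* expression: keep when `pvalue < .05` and `|log2FC| > 0`. The raw
  p-value is used (padj is retained for reporting). Note the fold-change
  cut of `log2(1) = 0` keeps any non-zero fold change — effectively no
  fold-change filter; the threshold is configurable for stricter use.
* splicing: keep when `|ΔΨ| > .05`, `pvalue < .05` and `FDR < .1`. The ΔΨ
  sign convention is Ψ(condition) − Ψ(control); rMATS reports
  sample1 − sample2, so table producers must order samples accordingly.
* CLIP peaks: keep when `p < 10⁻³` (narrowPeak `pValue` column, i.e.
  −log10 p > 3) and fold enrichment (`signalValue`) > 4.

Rows with missing ("NA") statistics are excluded from filtering but
counted in the totals and logged. A Benjamini–Hochberg helper (wrapping
scipy's step-up implementation) is provided for dialects lacking an FDR
column.

## Enrichment against the genome background

For a peak set, per-region enrichment is the peak fraction divided by the
genome bp fraction of that region (exact per-base accounting, no
sampling). Significance uses a one-tailed (greater) Fisher's exact test,
`P(X ≥ k)` under the hypergeometric distribution of the 2×2 margins. The
background margin must be a count, so the genome is discretised into tiles
whose width is the median peak width (rounded up, minimum 1 bp): a
per-basepair background would make the test degenerate, and tying the tile
width to the peak width keeps the two margins in comparable units. The
tile construction is confined to one function so an alternative background
can be swapped in.

CLIP region summaries report, per region holding at least one surviving
peak: peak count, count fraction, and the arithmetic mean (and mean log2)
IP/input fold enrichment.

## Metagene profiles

Signal tracks are 4-column bedGraph expanded to per-base arrays; uncovered
positions are depth 0. Profiles average the per-base depth over all
anchors in 50-bp bins across ±3000 bp around each peak midpoint (the
narrowPeak summit can be used instead when present). Profiles are
peak-centric and strand-agnostic — no orientation flipping — and use the
per-bin mean, not sum, so profiles of differently sized anchor sets are
comparable. Tracks are assumed pre-normalised; no library-size scaling is
applied. Anchors near a chromosome end keep their window, with
off-chromosome positions contributing 0.

## Integration

Significant splicing events collapse to genes; the gene universe (all rows
of the knockdown expression table) is partitioned into DEG-only, AS-only,
Both and none. Both-genes with consistent directions map to subgroups
1–4 (expression down/up × inclusion up/down); a gene with significant
events of both ΔΨ signs is "mixed" and gets no subgroup.

* Transcriptional targets: significant DEGs ∩ bound genes (distance-0
  definition above, over all ChIP peaks).
* Splicing targets: events whose alternative segment shares ≥1 bp with a
  surviving CLIP peak (half-open arithmetic, so adjacency does not count;
  an optional symmetric window can extend the segment, default 0 — the
  most specific reading of "event located in a CLIP-enriched region").
* Differentiation overlap: gene mode intersects DEG gene sets and labels
  each shared gene concordant/discordant by log2FC sign agreement; event
  mode requires an exact (gene, type, segment interval) match.
* Co-regulated genes: the intersection of the differentiation-restricted
  transcriptional and splicing target sets, emitted with full evidence.

ChIP–CLIP peak distances are nearest same-chromosome edge-to-edge gaps,
binned into overlap / (0, 5 kb] / (5, 10] kb / > 10 kb. A 0-bp gap without
a shared base falls in the ≤5 kb bin; a ChIP peak with no same-chromosome
CLIP peak counts as >10 kb. Reported percentages include the ≤5 kb bin
explicitly so the four fractions always sum to 1.

## Synthetic study design

The generator emits the exact dialects the readers consume and a truth
manifest whose expected counts are derived from the planted flags by the
same set algebra the pipeline implements — the manifest is the oracle.
Defaults (the conditions all recovery tests run under): 2 chromosomes of
2 Mb, 500 non-overlapping single-transcript genes of 3–8 exons placed in
uniform slots with ≥5 kb spacing (so every peak midpoint resolves to one
gene), 40 transcriptional targets (promoter ChIP peak, |log2FC| = 2,
p ≤ 1e-4), 30 splicing targets (one significant event with |ΔΨ| = 0.3 and
a fold-change-8 CLIP peak inside its alternative segment), 10 co-regulated
genes drawn from both pools, and a 60% chance for any other target to
recur in the differentiation contrast (co-regulated genes always recur).
Decoys: 200 uniform ChIP peaks avoiding target promoters, 300 CLIP peaks
at fold change 2 (removed by the strict >4 filter), mostly centred in
internal introns, plus uniform-p null table rows with log2FC = 0 and
|ΔΨ| < .05 so every null row fails its filter at zero noise.

p-values are planted, not computed from simulated counts: the upstream
statistical engines (DESeq2, rMATS, Clipper) are out of scope, and the
generator emulates their output contract only. Coverage tracks are
analytic — flat background 1.0 plus Gaussian bumps (sd 150 bp, amplitude
10) at true ChIP peaks, quantised in 10-bp steps — not read-sampled.

With `noise_sd > 0`, planted effects are perturbed multiplicatively
(`effect × (1 + N(0, noise_sd))`), planted p-values degrade with the
attenuated effect (`10^(-u·|effect|/|nominal|)`, `u ~ U(4,8)`), null
log2FC/ΔΨ acquire proportional jitter, and CLIP fold changes are perturbed
likewise. Recovery (Jaccard between recovered and planted sets) is exactly
1 at zero noise and decreases monotonically in expectation with noise,
which the tests check over 10 seeds at noise 0 / 0.5 / 1.0 using a
scaled-down study (120 genes, 2 × 0.5 Mb, proportional target counts) so
the sweep stays fast.

What passing tests do and do not show: the generator exercises the
coordinate arithmetic, filter logic and set algebra end to end, but its
data are idealised — no overlapping or multi-isoform genes, no correlated
p-values, no read-level noise, no mappability structure, planted rather
than estimated statistics. Exact recovery on this toy therefore validates
the pipeline's logic, not the statistical power of any upstream caller on
real data.

## Determinism and degenerate inputs

One seed, one bundle: all randomness flows through a single NumPy
generator and files are written with fixed formatting, so repeated runs
are byte-identical, and the analysis report is a pure function of its
inputs (JSON serialised with sorted keys, no timestamps). Degenerate
inputs are defined rather than special-cased: empty annotation → all
intergenic; Jaccard of two empty sets → 0; empty ChIP set → the distance
profile is an error (undefined); absent CLIP or differentiation layers
mark their report sections "empty" and the run continues; unknown
chromosomes classify as intergenic with a logged warning.

## Known limitations

Single-transcript gene models (no isoform-aware region calls); no
distal-enhancer-to-gene linking; the Fisher background tiling is one
defensible choice among several; bigWig tracks must be converted to
bedGraph upstream; per-base track arrays assume chromosomes that fit
comfortably in memory (fine for the intended toy/regional scale).
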