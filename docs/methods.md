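# Methods

`orgate` quantifies the transcriptional architecture that keeps ant (and
other hymenopteran) olfactory sensory neurons functionally monogenic for
odorant receptors (ORs). Most ant ORs sit in tandem arrays — head-to-tail
clusters of dozens of paralogs — yet each neuron exports the mRNA of a
single *chosen* OR to its cytoplasm. Three observable signatures surround
the chosen promoter, and the package implements one quantification pipeline
per signature plus the imaging pipeline that grounds them in RNA-FISH:

1. **Downstream readthrough.** RNA polymerase II fails to terminate after
   the chosen gene, transcribing intergenic DNA and downstream array
   members whose transcripts stay nuclear. The signature is elevated
   coverage over intergenic intervals of OR gene pairs relative to matched
   non-OR pairs.
2. **Bidirectional promoters and antisense lncRNAs.** The chosen promoter
   initiates on both strands; the antisense product elongates upstream as a
   long non-coding RNA whose expression anti-correlates with the OR
   immediately upstream of the chosen one. Signatures: twin sense/antisense
   start-site peaks (antisense farther upstream), pervasive opposite-strand
   coverage at OR loci, and signed single-cell correlations.
3. **Nuclear sequestration.** Only chosen-OR transcripts reach the
   cytoplasm. The signature is the joint nuclear/cytoplasmic FISH signal of
   each segmented cell.

## Coordinate and annotation model

Internally all intervals are 0-based half-open; GFF3/GTF input (1-based
inclusive) is converted at the boundary. "OR" is not a standard biotype, so
membership is configured via an ID list or gene-name regex; lncRNAs come
from `gene_biotype` attributes or an analogous rule. Tandem arrays chain
ORs whose consecutive span gaps are ≤ `max_gap` (default 10 kb),
strand-agnostic so inverted members remain in their array; an array's
transcription direction is the modal member strand (ties resolve to the
first member, with a warning). Pseudogenes remain array members but are
excluded from overlap-fraction denominators.

Gene pairs for the readthrough/antisense comparisons pass four filters:
total CDS length of both members within 100 bp–10 kb, shared strand,
intergenic distance 50 bp–10 kb, and no other annotated gene overlapping
either member or the intergenic interval on either strand. OR pairs are
enumerated exhaustively; non-OR pairs are a seeded uniform sample of equal
size.

## Relative coverage

For each pair and orientation the per-feature mean depth (base-weighted
over exon unions, intron unions, or the whole intergenic span) is divided
by the sense-strand mean over the *upstream gene's exons*. This cancels
expression-level differences between loci: readthrough appears as
intergenic relative coverage near 1 instead of near 0, and pervasive
antisense transcription as antisense relative coverage near the sense
level. Pairs whose normalizer is zero are excluded (counted, not imputed).
Group differences use two-sided Wilcoxon rank-sum tests with
Benjamini–Hochberg correction across features.

## Promoter windows

Capped-small-RNA 5′ counts are assigned to the 1 kb window upstream of each
gene's anchor — the first CDS base for ORs (OR UTR annotations are
unreliable) and the annotated TSS otherwise. Both strands are searched over
the same genomic interval; a promoter is *bidirectional* when both strands
hold ≥ k reads (default k = 1, configurable — the choice of k is the main
sensitivity of the bidirectional fraction). Distances are measured from the
anchor toward upstream, so sense/antisense offset histograms and their
medians are directly comparable; windows truncated by the chromosome edge
are shortened and flagged, and a read may legitimately count toward two
overlapping promoters.

## Single-cell analysis

Counts are filtered to neurons (≥2 of 5 marker genes at UMI ≥2), scaled to
10,000 counts per cell and natural-log1p transformed (recorded in
`.uns['normalization']`; the per-cell identity Σ expm1(x) = 10,000 is a
tested invariant). The chosen OR is the per-cell argmax over OR columns;
ties break toward the lower genomic coordinate with an explicit flag, and
all-zero cells get none. Staircase matrices sort qualifying cells by the
genomic position of their chosen OR against the array's ORs in genomic
order.

lncRNA analyses pair each candidate chosen OR with the nearest antisense
lncRNA whose 3′ end lies within 10 kb upstream of the OR TSS (the distance
the bidirectional-promoter model cares about), bin by that distance
(≤2.5 / 2.5–5 / 5–10 kb), and correlate lncRNA expression with the chosen
OR and its immediate array neighbors across cells whose chosen OR
qualifies. Pooled (scatter-style) and per-lncRNA records are both
available; per-lncRNA summaries restrict to ≤5 kb partners and test the
mean r against zero with a one-sample t-test. Pearson r requires ≥3 cells
and non-constant vectors. The switch statistic is the fraction of cells in
the ≤2.5 kb bin detecting exactly one of {lncRNA, upstream OR}.

## RNA-FISH quantification

Stacks are (z, channel, y, x) with a designated DAPI channel. Depth
attenuation is corrected by scaling every non-DAPI slice by
max_z(mean DAPI) / mean DAPI(z); the correction is exact when DAPI content
per slice is comparable, and nuclear-density differences between slices
leak into it proportionally. Signal segmentation per slice: subtract a
sigma-100 Gaussian background, clip negatives, triangle-threshold the
residual, and drop 8-connected components under 12 px. Nuclear label masks
are injected (any trained segmentation backend); a Gaussian+Otsu+watershed
fallback ships for synthetic data and guarantees only the mask contract,
not biological fidelity. Cytoplasm is a 3 px ring (disk dilation minus
nucleus, ≈270 nm at 90 nm/px); pixels claimed by two rings or by any
nucleus are removed from all claimants, so rings are provably disjoint.

ROI means are taken over background-subtracted, signal-masked pixels with
non-signal pixels contributing zero to a full-ROI-area denominator
(`mask_mode: zeroed`, so blank ROIs score 0; `masked_only` and `unmasked`
are available because the best choice depends on probe density).
Normalization is robust quantile scaling per image and channel: the 0.001
and 0.999 quantiles of the *nuclear* means define the range for nuclear and
cytoplasmic values alike, values outside [0, 1] are kept, and thresholds
act on unclipped values. A cell is chosen-OR-expressing when normalized
nuclear > 0.75, normalized cytoplasmic > 0.2, nuclear area 400–900 px,
cytoplasmic area > 100 px and eccentricity < 0.8; transcript localization
is nuclear at > 0.1 and nuclear+cytoplasmic when the cytoplasmic threshold
is *also* met (cytoplasmic signal without nuclear signal is background).
ROIs are 2-D per slice with no z-linking, so replicate-level outputs are
proportions, never raw counts; replicate summaries report the mean with a
t-distribution 95% CI.

## Synthetic data: what it emulates and what it does not

Every generator is deterministic under a seed and returns ground truth.

- **Annotation**: head-to-tail two-exon OR arrays (gaps 1–6 kb, member
  inversion optional), nested antisense lncRNAs placed upstream-adjacent to
  an interior partner OR (3′ end 1.8 kb from the partner TSS by default),
  flanking non-OR genes on both strands, and isolated non-OR pairs passing
  the pair filters.
- **Coverage**: sense depth = promoter rate with exponential decay beyond
  the upstream gene's 3′ end, evaluated at each region's midpoint and
  deposited uniformly — this keeps the expected intergenic relative
  coverage in closed form, exp(−λ·L/2), at the cost of within-region decay
  realism. Antisense depth mirrors the sense profile scaled by a class
  fraction (0.5 at OR-like pairs, 0.005 at non-OR pairs, emulating the
  ~100-fold asymmetry). Per-base Poisson noise. The pair study uses 50
  OR-like and 50 non-OR pairs as independent two-gene transcription units;
  stacked readthrough across many-member arrays is deliberately not
  simulated here.
- **Start sites**: one sense peak per gene (Normal offset, default
  200±60 bp) and, for an exact-count subset of genes, an antisense peak
  farther upstream (500±60 bp); Poisson read counts unless disabled.
- **Counts**: cells pick an array and a promoter; chosen OR ~
  NB(100·s), downstream members decay as exp(−1.5·rank), with per-cell
  promoter strength s ~ Gamma(10, 1/10) shared by the chosen OR, downstream
  members and the partnered lncRNA (source of their positive coupling).
  Upstream leakage ~ NB(5·exp(−0.12·lncRNA count)), independent of s, so
  zero coupling decorrelates it. Five marker genes keep every cell through
  the neuron filter, and 60 housekeeping genes (Poisson 120) provide the
  stable library background without which per-cell normalization becomes
  compositional and correlation signs invert. `partner_bias` optionally
  conditions promoter choice on the lncRNA partner, emulating a
  correlation-study sample restricted to qualifying cells. Not emulated:
  ambient RNA, doublets, batch effects.
- **Stacks**: disk nuclei (radius 12–16 px, inside the 400–900 px gate)
  round-robin across slices and classes — *chosen* fills nucleus and ring,
  *nuclear-only* fills the nucleus at 40% intensity, *negative* has no
  probe signal — with multiplicative per-slice attenuation (0.9/slice),
  Gaussian PSF blur, Poisson sampling and optional additive noise. Not
  emulated: anisotropic optics, spot-level structure, segmentation errors
  (ground-truth masks are returned so imaging accuracy isolates the
  quantification, not the segmenter).

Because the generators realize exactly the structures the analyses assume,
passing tests demonstrate correct recovery of planted signal and correct
null behavior — not robustness to the annotation errors, mapping
artifacts, or segmentation failure modes of real data.

## Problem sizes and numerical choices

Default study sizes were chosen to give each statistic clear resolution at
desk scale: 50 pairs per class for coverage (rank-sum p ≪ 0.01 at the
default decay contrast), ~20–65 genes for start-site analyses, 1,000 cells
for chosen-OR recovery (≥99% at default dispersion 20), 20 lncRNAs × 500
cells for correlation signs, and 12-cell stacks at 256×256×6 for imaging
(≥95% class recovery across seeds). Monte-Carlo recovery tests compare
means across 20 seeds against closed forms at 3 standard errors. Degenerate
inputs fail loudly: zero-mean DAPI slices, zero quantile ranges, empty
interval unions and CDS-less first-CDS anchors raise errors; zero coverage
normalizers and empty rings are flagged and excluded rather than imputed.

## Known limitations

- The ≤10 kb chaining rule is applied uniformly; published array
  definitions derived by other means may differ near the threshold.
- The DAPI depth correction assumes comparable per-slice nuclear content.
- `bidirectional_fraction` at k = 1 is sensitive to sequencing depth; the
  threshold is exposed in config for sensitivity analyses.
- Correlation analyses use annotated lncRNAs only; unannotated antisense
  transcription is visible to the coverage module but not to the
  single-cell module.
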