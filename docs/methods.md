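# Methods

## Assay model

MSCC quantifies methylation at CCGG sites through differential restriction
digestion. HpaII cuts C^CGG only when the internal CpG is unmethylated; MspI
is methylation-insensitive. The HpaII library therefore samples unmethylated
molecules; the inverse library (HpaII ends deactivated, then MspI) samples
methylated — including hydroxymethylated — molecules. MmeI releases a
fixed-length genomic tag from each cut end; because CCGG is palindromic each
site yields two tags, one per side, and both begin `CGG`.

**Tag coordinates.** For a site whose first C sits at 0-based position *p*:
forward tag = `genome[p+1, p+19)`; reverse tag = reverse-complement of
`genome[p−15, p+3)`. The enzymes' real 18/20-bp cut heterogeneity is
collapsed to exactly 18 bp. These coordinates are a fixed internal
convention shared by the simulator and the mapper, so correctness is
internal consistency rather than base-exact chemistry. Tags running past a
chromosome end are omitted for that side; a tag occurring at more than one
(site, side) cannot identify its origin and is discarded entirely
(unique-mapping rule).

**Tag matching.** Reads are `index ⊕ tag`. Demultiplexing requires an exact
index match (mismatch-tolerant demultiplexing would trade sample
cross-contamination for yield). Tags are matched by exhaustive neighborhood
lookup in mismatch tiers 0..`max_mismatch`; the lowest non-empty tier wins
and must contain exactly one library entry, otherwise the read is rejected
as `ambiguous`. Uniqueness is judged *per tier*: a unique exact hit is
accepted even if 1-mismatch hits exist elsewhere (the alternative — global
uniqueness across tiers — would discard reads whose best interpretation is
unambiguous). `max_mismatch` defaults to 1 ("fewer than two" read
literally); 2 restores the inclusive reading. A non-ACGT base can never
match and so costs one mismatch at its position. At toy scale the hash
lookups are exact and fast; no genome-scale index is needed.

## Quantification

Per sample, each library gets a scale factor `f_L = K / spike(L)` from its
spike-in standard count (K = 10⁶ by default; it cancels). The methylation
level is `m·f_I / (m·f_I + u·f_H)`. This ratio-of-scaled-counts form is the
minimal estimator consistent with count normalization by standards; with
unbiased libraries it reduces to `m/(m+u)`, which given depth *d* is
`Binomial(d, p)/d` — unbiased with RMSE `sqrt(p(1−p)/d)`.

The depth filter (default ≥ 30 raw reads, boundary inclusive) is applied to
*raw* `u+m`, not normalized counts, because sampling noise is governed by
raw read numbers. No between-sample normalization beyond the per-library
spike-in scaling is applied.

Two error terms matter for the estimate:

* per-site binomial noise, `~0.05` at depth 100 for p = 0.5, vanishing with
  depth;
* a per-(sample, library) term from Poisson noise in the spike-in counts
  themselves (relative sd `sqrt(2/spike_in_mean)` on the scale-factor
  ratio, i.e. ~2.6% at the default 3000). This term is shared by all sites
  of a sample and does not average out within a run; it bounds how small a
  run-level mean bias one should expect (~0.007 sd at the defaults).

## Differential methylation

Units are 200-bp non-overlapping windows (trailing partial window kept) and
merged CGIs. A unit enters a comparison only with ≥ 4 member sites
quantified in **both** samples ("more than 3" sequenced CpGs); unit means
average only that shared site set, otherwise coverage differences would
masquerade as methylation differences. The pooled 2×2 table
`(m_a, u_a; m_b, u_b)` sums *raw* counts over the shared sites — the exact
test's sampling model is count-based, and scale factors are near-constant
within a comparison.

Fisher's two-sided exact test is computed from the conditional
hypergeometric definition: the p value is the probability mass of all
tables with the observed margins whose probability does not exceed the
observed table's, compared with relative tolerance 1e-7 to absorb
floating-point ties. Implementation notes: log-space binomial terms via
`gammaln`; the table is first put into a canonical row/column order (p is
invariant under these swaps) so that swapping the two samples returns the
bit-identical p; `fsum` makes the final summation exact-to-rounding; if
every table in the support is kept (the observed table is modal) p is
returned as exactly 1. A zero margin yields p = 1 by convention. The suite
checks the implementation against exact integer enumeration for all tables
with total ≤ 40 and against an independent library implementation.

A unit passes one comparison when |Δ| > 0.25 **and** BH-adjusted q < 0.05
(BH within each comparison across units). The assay's headline criterion is
the 25% cutoff alone; since no significance threshold accompanies it
explicitly, both readings are reported: `passes_delta`
(delta-only) and `passes` (delta + q), with the `delta_only` switch
selecting which feeds the DMR call. A unit is a *consistent* DMR only when
it passes in **all** treated-vs-baseline comparisons (all four timepoints
under the default five-sample design).

Site-level consistency uses the same all-comparisons rule on |Δ| > 0.25 per
site, over sites quantified in every sample. Same-sign change is *not*
required by default (the absolute-change reading); `strict_sign=True`
additionally demands one common direction.

## Genome-context analyses

* **Annotation.** Six gene-context classes with precedence
  `tss_region > exon > intron > upstream > downstream > intergenic` when a
  site touches several genes; TSS region = ±1 kb; up/downstream flanks =
  2 kb, strand-aware. CGI context: `cgi` inside a merged island, `shore`
  within 2 kb (the standard shore convention), else `open_sea`. All
  coordinates 0-based half-open; distances to an interval are counted to
  its nearest contained base, so boundaries are inclusive.
* **Metagene.** Each site maps to its *nearest* gene (assignment to all
  overlapping genes was the alternative; nearest-gene keeps each site's
  weight equal) and to a strand-aware relative coordinate: 0 at the TSS, 1
  at the TES, flanks of half a gene length per side (axis −0.5..1.5; 20
  flank bins per side, 40 body bins). Bin means are unweighted. The
  smoothed line is a centered moving average, default 11 bins, truncated at
  the series boundaries; a window wider than the series collapses to the
  whole-series mean.
* **Expression tertiles.** Genes are split into equal-count thirds by
  rank (stable sort by value then name, nearest-rank cuts). Rank splitting
  is deterministic and still yields near-equal groups under heavy ties —
  a value-threshold rule would put all tied genes in one group. The
  contrast table reports per-tertile mean levels in the TSS region (±1 kb)
  and in the latter gene body (relative position 0.5–1.0).
* **Peak overlap / short-RNA proximity.** Simple within/without (and
  within/near/without, flank 2 kb, boundary inclusive) stratified means per
  merged interval track; strata always partition the site set.

## The synthetic-data generator

The generator produces data with the statistical structure the analyses
assume, so every estimator has an exact recovery target. Defaults define
the study conditions used throughout the tests: five samples
(S0h, S4h, S12h, S24h, S96h; S0h is baseline), 3 chromosomes × 200 kb,
mean depth 50, unbiased libraries, spike-in mean 3000, sequencing error
1e-3.

* **Genome.** Background base composition 40% GC; CCGG motifs planted at
  mean spacing 50 bp (~4 per 200-bp window, so most windows clear the
  4-site rule); genes (2.5–6 kb, 2–5 exons, random strand) laid out with
  2–5 kb intergenic gaps; CGIs 1 kb wide, ~60% anchored at TSSs, CpG- and
  CCGG-enriched to ≥ 3× background CCGG density (≈ 4–5× at defaults);
  active-mark peaks (H3K9ac, H3K27ac, H3K4me3) over a random 70% of CGIs
  ±200 bp; repressive-mark peaks (H3K9me3, H3K27me3) and short-RNA loci in
  intergenic gaps. Expression is log-normal (so positive, heavy-tailed).
* **Methylome.** Background levels from the bimodal mixture
  `0.7·Beta(8,2) + 0.3·Beta(2,8)` (mammalian methylomes are bimodal);
  CGI sites `Beta(1,12)` (mean 0.077), shores `Beta(2,6)` (intermediate),
  sites under repressive peaks `Beta(8,2)`; a ×0.2 multiplicative dip
  within ±1 kb of any TSS; short-RNA neighborhoods hypomethylated (×0.25
  inside a locus, ×0.6 within 2 kb). Scenario `null` copies one draw to
  all samples; `expression_coupled` draws latter-gene-body levels from
  `Beta(4,4)` plus an expression-tertile offset (default +0.2 for the top
  tertile, +0.1 middle, 0 bottom) and deepens the TSS dip with expression
  (×0.1/0.3/0.6 for high/mid/low); `planted_dmr` starts from `null` and
  shifts treated samples in chosen regions.
* **DMR planting.** Planted regions are 200-bp-grid windows holding ≥ 4
  sites, chosen disjoint. Because a fixed signed shift on a bimodal
  background silently clips (a +0.4 shift on a site at 0.8 moves it only
  0.2, below the 25% cutoff), the shift direction per region defaults to
  the one with more dynamic range, ties broken toward the requested sign;
  the signed shift actually applied is recorded in the truth record.
* **Counts and reads.** The count model is exactly the assay model above;
  spike-in counts are `Poisson(spike_in_mean · e_L)` per library — the
  standards pass through the same chemistry, which is precisely why they
  can calibrate the efficiency scale. An optional gamma-mixed depth
  (`depth_dispersion`) models site-to-site coverage heterogeneity, shared
  between replicate sequencing runs of the same libraries; it is off by
  default and used for the depth-vs-accuracy curve, which needs sites
  spanning thresholds 10–100 in one run. Reads are `index ⊕ tag` with
  substitution errors on the tag portion only (indices are short and
  demultiplexing is exact-match; tags are fixed-length by the MmeI
  chemistry, so indels are out of scope). Standard tags carry prefixes
  `AAT`/`TTA`, guaranteeing ≥ 3 mismatches from every genomic tag (which
  begin `CGG`) and from the other library's standards.

**The standard DNA is a modeling assumption.** The assay description says
only that genomic DNA is "combined with standard DNA"; its sequence, amount
and methylation state are unspecified. One dedicated standard tag set per
library is the minimal model that makes per-library scaling identifiable,
and it is flagged as such.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PCR duplicates and amplification bias, quality
scores and base-call error structure, indels, repeat-driven multi-mapping
at genome scale (ambiguity here arises only from planted repeats), CNVs,
bisulfite chemistry, and 5mC/5hmC discrimination (the assay counts both as
methylated; so does the simulator).

## Problem sizes and numerical choices

The default 3×200 kb genome yields ~15,000 CCGG sites and ~2,500 eligible
200-bp windows — enough that "zero consistent DMRs" and "< 0.1% consistent
sites" are meaningful statements — while the whole test suite runs in well
under a minute of simulation time. Power analyses plant 50 DMRs of |Δ| =
0.4 at depth 50; estimator checks use 2,000–4,000 independent sites at
depths 100–200. Determinism: every random draw flows from a
`numpy` `Generator` seeded per stage from the configured seed; identical
config + seed reproduces byte-identical FASTA/BED/TSV/FASTQ outputs
(checksummed in the run manifest). Degenerate inputs: depth-0 sites are
kept in count tables and removed by the depth filter; `u = m = 0` never
yields a level; empty CGI or peak tracks produce empty-but-valid outputs;
an empty stratum reports a null mean with count 0 rather than an error.

## Known limitations

* The mapper is exhaustive-lookup, suitable for toy genomes (≤ a few Mb),
  not a replacement for a genome-scale aligner.
* Fisher p-values use double-precision log-space arithmetic; agreement with
  exact enumeration is ~1e-13 for small tables, far inside the 1e-7 tie
  tolerance, but not exact rational arithmetic.
* The pipeline's external-input mode expects the annotation directory
  layout the simulator writes (BED12 genes or refGene-style TSV, BED
  tracks, expression TSV).
* No replicate-aware dispersion modeling: the design pools dishes per
  timepoint, so the exact test sees only counting noise, as in the
  original analysis.
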