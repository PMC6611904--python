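# Methods

This note records the models, conventions, numerical choices and known
limitations behind `cismark`, in the order the pipeline runs.

## Coordinates

All intervals are 0-based half-open internally (BED convention). For a
`+` strand gene the TSS is `start` and the TES is `end − 1`; for a `−` strand
gene the TSS is `end − 1` and the TES is `start`. User-facing element
coordinates use the promoter literature's 1-based TSS-relative convention:
position +1 is the TSS base, the base immediately 5′ of it is −1, and there
is no position 0. Conversion happens only at the reporting boundary
(`ElementHit`); all arithmetic stays half-open.

Gene models are BED6 only. GFF3 is deliberately out of scope: the gene-level
analyses here need only id, coordinates and strand, and GFF3 attribute
dialects would add parsing ambiguity without adding information.

## Promoter scanning

Promoters are the `upstream` bp (default 2000) immediately 5′ of the TSS in
gene orientation; `−` strand promoters are reverse-complemented so patterns
are always searched in promoter orientation. Truncation at chromosome edges
is flagged and hits can only fall inside real sequence.

Patterns are exact IUPAC matchers compiled to regular expressions with a
lookahead so overlapping occurrences are all reported; gene-level inclusion
needs one hit. Ambiguity codes in the *pattern* match their base expansions;
ambiguity in the *subject* never matches (conservative: an N in the genome
is unknown, not a wildcard). By default both the pattern and its reverse
complement are searched (`both_strands=True`) because a double-stranded
binding site can face either way; the flag is recorded in the scan manifest
so either convention is reproducible.

## Island calling ("sicer-like")

Broad gene-body marks are called by the windowed-island scheme standard for
H3K36me3, with the classical parameter values as defaults: window W = 200 bp,
gap G = 200 bp, island FDR 10⁻³, ChIP/input fold ≥ 2. The background model
is deliberately simpler and fully deterministic compared with the original
random-reads island-score formulation:

1. reads per window from coverage mass / read length, discretised by
   cumulative rounding (so genome-wide counts conserve the library size
   exactly and the last partial window keeps its true length);
2. scale factor s = ChIP library / input library;
3. window eligibility: Poisson upper tail of the ChIP count at
   λ = s · max(input count, m̄) below `p_window` (default 0.1), where m̄ is
   the genome-wide mean input count per window — the floor prevents
   zero- or low-λ artifacts in input-sparse windows;
4. maximal eligible runs, bridging ineligible stretches totalling ≤ G bp;
5. island *p* = Poisson upper tail of the island ChIP count at
   λ = s · max(input count, windows × m̄, 1). Flooring at the island's
   expected input mass mirrors step 3; without it, a window whose *input*
   count fluctuates low while ChIP fluctuates high is handed a tiny λ and
   becomes spuriously significant — with depth-20 data that alone produces
   tens of false islands per megabase under a no-enrichment null, while the
   floored statistic leaves the null quiet (the suite checks < 1 significant
   island per Mb in ≥ 90 % of null runs);
6. Benjamini–Hochberg *q* across all candidate islands (q is floored at the
   raw p); significant ⇔ q < FDR and fold ≥ min_fold, with
   fold = (chip/chip_lib) / ((input+1)/input_lib) — the +1 pseudocount
   avoids division by zero and is recorded in the output.

The fold's input normalisation constant is the library-size ratio; that is a
choice (the classical tools do not pin it down) and is stated in the islands
manifest (`method: sicer-like`).

A gene is *enriched* when ≥ 1 significant island overlaps, by at least one
base, the genomic union of its 1-kb upstream region and gene body
(strand-aware).

## Metagene profiles

Each gene is a 900-bin vector: 300 fixed 10-bp bins over 3 kb upstream of
the TSS, 300 equal-fraction bins over the body, 300 fixed 10-bp bins over
3 kb downstream of the TES, ordered 5′→3′ in gene orientation (minus-strand
genes are flipped). Body bins come from a cumulative-rounding partition so
every base belongs to exactly one bin; bodies shorter than 300 bp produce
zero-width bins which are missing (NaN) and excluded from means, as are
flank bins truncated by chromosome edges. The upstream flank is anchored at
the TSS and the downstream flank at the TES — the natural reading of a
TSS→TES profile axis.

"Calibrated to the input" is implemented as a per-bin ratio
(RPKM_ChIP + c)/(RPKM_input + c) with pseudocount c = 1.0 (configurable;
log2 output available). A ratio keeps the no-enrichment null at exactly 1
and tolerates sparse bins; subtraction or ChIP-only RPKM are reasonable
alternatives and the pseudocount/log2 knobs leave the axis open rather than
pretending one choice is uniquely right.

The per-gene group statistic is the mean over the 300 body bins ("signal
downstream of the TSS"). Groups are compared with a two-sample
Kolmogorov–Smirnov test: D is the maximum ECDF gap evaluated at the pooled
sorted values (exact under ties), and the two-sided p comes from the
asymptotic Kolmogorov distribution at √(nm/(n+m))·D. At n = 15 + 15 this
asymptotic p tracks a 10⁴-replicate permutation p to within ~0.005 (checked
in the suite); for very small groups prefer the permutation route.

## DEG filter and integration

Down-regulated means strictly more than 1.5-fold down with adjusted
p strictly below 0.05: `log2fc < −log2(1.5)` and `q < 0.05`. Candidates are
element ∩ down; the observed statistic is the number of candidates carrying
the mark.

The null resamples B sets (default 1000) of |candidates| genes uniformly
without replacement from the element-free down-regulated pool, independently
across sets, and counts marked genes per set. Three summaries are reported
and never conflated:

- the raw empirical exceedance percentage 100·#{sets with count ≥ observed}/B
  (the headline convention in this literature; `tail="gt"` switches the
  inequality, and both tails are written to the report since ">" and "≥"
  are genuinely different conventions);
- the (b+1)/(B+1) estimator, which is a valid Monte-Carlo p-value;
- the analytic hypergeometric upper tail P(X ≥ observed) for
  X ~ Hypergeom(N = pool, K = marked in pool, k = set size), an asymptotic
  comparator computed via scipy's log-space routines.

**Validity regime.** The resampling test conditions on the realised mark
rate of the pool while the observed count is drawn from the candidates, so
it is exactly exchangeable only as pool/set-size → ∞. With a pool an order
of magnitude larger than the candidate set (the regime of the motivating
design, ~1700 vs ~130) the distortion is negligible; with pool ≲ 3× set the
test becomes noticeably anti-conservative. The type-I calibration test in
the suite therefore runs in the large-pool regime (pool ≈ 9× a ~13-gene
candidate set, 300 genes total, B = 500) and lands inside the binomial 95 %
CI of the nominal 5 % level across independent seed families; users applying
the test to small pools should rely on the hypergeometric tail instead.

Percentages (e.g. "75.8 %") are 100·num/den rounded half-up to one decimal.

## The synthetic-data generator

The generator defines the conditions everything is tested under; defaults
are the study-scale conditions used throughout the suite and the acceptance
script.

- **Annotation**: 500 genes, one 2-Mb chromosome, uniform gene lengths
  500–2400 bp, uniform intergenic gaps 2200–2600 bp, random strands. The
  geometry gives a gene density of one per ~4 kb (plant-like), fits 500
  genes in 2 Mb with a ~5σ margin, and keeps neighbouring genes' 1-kb
  extents out of reach of a planted island (island edges wander ≤ ~400 bp
  past the planted region through window snapping and gap bridging).
- **Sequences**: uniform random ACGT. With rejection enabled (default) every
  chance occurrence of the element in any promoter, either orientation, is
  resampled away before planting, so the element truth set is *exact* — the
  price is a background slightly depleted of the element 7-mer, which is why
  the flag can be disabled for realism studies. Planted copies sit at a
  uniform TSS-relative offset in [−2000, −8] and are additionally kept out
  of every *other* gene's promoter window (divergent gene pairs share
  promoter space at this spacing); a gene whose promoter cannot host the
  element is skipped with a warning.
- **Coverage**: per-200-bp-window Poisson counts; input mean d = 20
  reads/window, ChIP mean d·(1 + (f − 1)·overlap) with fold f = 8 inside the
  enriched region — [TSS, TSS + 1 kb) for the 5′-biased profile that
  broad gene-body marks show in plants, or [TES − 1 kb, TES) for the
  3′-biased profile seen in animals (`enrichment_profile="three_prime"`).
  Windows are emitted as bedGraph values such that mass/read-length recovers
  the counts exactly; read length is fixed at 50 bp for library bookkeeping
  (arbitrary but stated).
- **DEG table**: a gene is truly down-regulated with probability 0.35 if it
  carries the element and 0.15 otherwise (defaults chosen so the element-free
  down-regulated pool is several times the candidate set, the regime of the
  motivating design); true DEGs get log2fc = −log2(U), U ~ Uniform(1.5, 4)
  and q = 0.01, all others log2fc ~ N(0, 0.2) and q ~ Uniform(0.05, 1), so
  the standard filter recovers the truth set exactly.
- **Mark truth**: a gene is enriched with probability 0.75 given the element
  and 0.4 otherwise — the coupling whose detection the integration stage
  exists to test.

Everything is deterministic under (config, seed); per-stage generators are
derived from the master seed by hashing the stage name, so stages are
independently reproducible and the CLI's single `--seed` drives the whole
chain.

What the generator does **not** emulate: read-level artefacts (GC bias,
mappability, duplicates, fragment-length effects), overdispersion beyond
Poisson, correlated expression noise, introns/isoforms, and real promoter
base composition. Passing tests therefore demonstrate the *algorithms* are
correct and calibrated under their stated models, not that real libraries
satisfy those models; with real data the island caller in particular
inherits Poisson's tendency to overstate significance under overdispersion
(the fold ≥ 2 filter is the practical guard).

## Problem sizes

The suite runs at desk scale by design: 2-Mb/500-gene chromosomes for
recovery and the end-to-end run, 300 genes × 200 replicates × B = 500 for
type-I calibration, 20 replicates for power, 10⁴ permutations for the KS
oracle and 2 × 10⁴ draws for the tiny-pool resampling oracle. These sizes
give the quoted checks comfortable Monte-Carlo margins (3 SE bands) while
keeping the whole suite under a minute.

## Known limitations

- Midpoint counting stands in for fragment extension when converting raw
  read BED to coverage; with real single-end data the two differ at island
  edges by up to half a fragment length.
- The island caller's Poisson background has no local λ estimation beyond
  the per-island input count and the global floor; strong copy-number
  variation would need a local (sliding) background.
- The KS p-value is asymptotic; below ~10 values per group use a
  permutation test.
- The resampling test's empirical percentage is reported with one-decimal
  rounding for readability; inference should use `empirical_p_plus1` or the
  hypergeometric tail.
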