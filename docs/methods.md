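# Methods

## Scope and data model

The pipeline quantifies protein occupancy from binned genomic signal.
All coordinates are 0-based half-open; the base representation is a
`BinnedTrack` with one fixed-width value vector per chromosome (default
bin width 10 bp — fine enough to resolve meta-profile peak-offset
differences of a few tens of bp). Features carry a class label
(promoter, enhancer, PRE, origin, random, transcript) and an anchor:
the transcription start site for promoters (strand-aware: `start` on
"+", `end − 1` on "−") and the interval midpoint otherwise. Scoring
windows are centered on the anchor, not on the BED interval, so a
promoter's 500-bp window spans −250..+250 around its TSS.

bedGraph reading distributes each interval's value into bins as
`Σ value·overlap / capacity`, where a bin's capacity is its covered bp
within the chromosome (smaller for a trailing partial bin); this makes
write-then-read an exact round trip while agreeing with the
length-weighted-mean convention for partially covered bins. Zero runs
are written explicitly by default (lossless); a sparse mode suppresses
them.

## Enrichment and region calling

Enrichment is `log2(((ip+c)/S_ip) / ((input+c)/S_in))` with pseudocount
`c` (default 1 count per bin, a standard stabilizer; the original
normalization of such pipelines is rarely stated, so it is explicit and
configurable here). `S` are total counts (total-count normalization) or
1 ("none"). Simulated IP/input pairs are depth-matched by construction,
so the pipeline's synthetic mode uses `normalization="none"`, which
leaves background bins at exactly 0 expected log2 enrichment; for real
data total-count normalization is the default of the `enrich` command.

Region calling thresholds at a genome-wide percentile (default 95th)
computed by linear interpolation over all bins of all chromosomes.
Bins `≥` threshold count as enriched (ties kept, deterministic);
maximal runs of adjacent enriched bins are merged with no gap
tolerance, clipped to chromosome ends, and kept when ≥ 300 bp. On a
constant track the threshold equals the constant and each chromosome
becomes one region — a documented degenerate case. The caller is
verified bin-for-bin against an independent brute-force scan.

## Occupancy, proportionality and meta-profiles

Occupancy is the unweighted mean of track bins overlapping the window
(with 10-bp bins under 500-bp windows, edge-bin length weighting would
change values negligibly and the unweighted rule is exactly testable).
Subunit proportionality between factors a and b over a feature class is
summarized by the through-origin least-squares slope
`k = Σ a_i b_i / Σ a_i²` — the natural ratio estimate when the question
is stoichiometry — plus the Pearson correlation.

Meta-profiles average enrichment at oriented offsets around anchors.
The offset grid places profile-bin centers at
`−flank, …, −bin, 0, +bin, …, +flank`, so offset 0 and round peak
positions lie on the grid; each profile bin's per-feature value is the
unweighted mean of track bins overlapping its genomic interval (the
occupancy rule, so aligned windows conserve means across the two
modules). Reverse-strand windows are mirrored at bp resolution before
averaging. Features whose `[anchor−flank, anchor+flank]` window
intersects another input feature's window are removed (distortion
control; the exclusion is computed within the supplied feature set
only), and windows truncated by chromosome ends are dropped.
`peak_offset` returns the offset of the maximum mean; ties break toward
the smallest absolute offset, then upstream, so a flat profile reports
0. Defaults: flank 2000 bp and 10-bp profile bins for promoter-scale
classes; 25 kb flank and 1-kb bins for meta-origin profiles on the
default synthetic genome.

## Classification and replication proximity

A promoter is "high-SA" when its 500-bp window overlaps a called SA
region by ≥ 1 bp — the weakest faithful reading of "within a region",
and monotone in the region set. Early-replication proximity is plain
occupancy on the EdU log2-enrichment track. Extragenic enhancers are
those whose window keeps a gap of at least 500 bp (half-open edge
arithmetic; a gap of exactly 500 is retained, any overlap excludes)
from every transcribed region.

## Statistics

Condition shifts use the paired Wilcoxon signed-rank test — paired
because the same features are scored in mock and depleted conditions.
Zero differences are dropped (Wilcoxon's original treatment); with
n ≤ 25 and untied |d| the exact null distribution is used, otherwise
the normal approximation with continuity correction (scipy's exact path
assumes distinct ranks, so ties fall back to the approximation, which
uses average ranks). All-zero differences give P = 1 by convention.
P-values are reported raw per class, with Benjamini–Hochberg available
behind a flag. Viability crosses use Fisher's exact test (two-sided =
sum of tables with point probability ≤ observed) with
`percent recovered = 100·(males/females)/expected ratio`; bristle
counts use Welch's unequal-variance t-test with n−1 standard
deviations. Each statistic is cross-checked against an independent
oracle: full 2ⁿ sign enumeration, exact integer hypergeometric
enumeration over all 2×2 tables with margins ≤ 30, and a label
permutation test.

## The synthetic genome

The simulator emulates the statistical structure the analysis assumes,
at desk scale: two 2-Mb chromosomes, 10 origins (≥ 100 kb apart), 60
enhancers, 300 promoters, 20 PREs, 100 random intervals and 120
transcribed regions — a stand-in for the fly-cell census of 78 origins,
2353 enhancers, 7389 promoters, 195 PREs and 6892 random sequences on
~120 Mb, with distances scaled accordingly.

Layout rules: origins uniform with minimum separation; enhancers at
Gaussian offsets (sd 10 kb) from random origins; 15% of promoters
within 15 kb of an origin and the rest beyond 40 kb (the emulated
system's high-SA promoters are a similar minority); PREs beyond 40 kb;
transcripts ≥ 12 kb from origins (transcription pushes licensed
MCM2-7 helicases out of gene bodies, so early replication and the
enhancers nearest origins are extragenic); strands random for
promoters. Placement is by rejection sampling with an explicit failure
when a rule cannot be satisfied — no silent truncation.

Signal model per factor: expected log2 enrichment
`μ(b) = baseline + Σ_f A_class · m_depletion · exp(−d_f/λ) · s(class,d_f)
· exp(−(x_b − x_peak)²/2σ²)`, where `d_f` is the feature's distance to
the nearest origin center, `λ` the factor's origin-decay length, `s`
the promoter stoichiometry factor (applied only beyond the proximal
distance) and `x_peak` the oriented anchor plus the factor's peak
offset. Defaults: SA decays steeply (λ = 20 kb), is absent from distal
promoters (s = 0), peaks downstream (+100 bp) with a broad footprint
(σ = 400 bp) — producing the contiguous ≥ 300 bp domains the region
caller targets; Rad21/SMC1/Nipped-B decay gently (λ = 200 kb) with
sharp promoter footprints (σ = 60 bp) at −70/−35/−70 bp, and SMC1 is
subproportional at distal promoters (s = 0.5); Pol II (Rpb3) peaks at
+65 bp with no origin decay. The EdU track decays with per-bin origin
distance (λ_rep = 15 kb, amplitude 3). Depletion conditions rescale
class amplitudes per factor; promoters may be addressed as
`promoter_proximal`/`promoter_distal` because depletions in the
emulated system move occupancy in opposite directions at the two
groups.

Counts: IP bins are negative-binomial with mean `read_depth · 2^μ`
(default 50 expected reads per 10-bp bin) and dispersion 0.02
(variance m + 0.02 m²; dispersion 0 degenerates to Poisson); the input
is flat at `read_depth`. A noise-free mode returns exact expectations
(peaks truncated at 8.5 σ, below double precision of the summed
track). The truth table records each feature's class, anchor, strand,
brute-force origin distance and planted per-factor/condition amplitude
(class amplitude after depletion, decay and stoichiometry; baseline
excluded, overlap between neighboring features' footprints ignored).

What the simulator does **not** model: read-level effects (fragment
lengths, shifts, duplicates), mappability and GC bias, local background
structure, chromatin-state heterogeneity, or the upstream assays that
define real feature sets. Passing tests therefore demonstrate that the
pipeline's operations are correct and that its inferences recover
planted parameters under idealized noise — not that the defaults
reproduce any particular real dataset.

## Validation experiments and problem sizes

The `experiments` module runs each check end to end: 1000 random
tracks (≤ 500 bins, mixed constants/spikes/noise with exact ties) for
region-caller oracle equivalence; 100 default-scale replicates for peak
recovery (median |error| ≤ one 10-bp profile bin) and for the
replication-score orderings; one fixed-seed default run for the
stoichiometry slopes (0.5/1.0 ± 0.1 at distal/proximal promoters);
1000 mock-vs-mock trials for null calibration. The calibration layout
uses 60 *isolated* scoring windows (features thinned so no two windows
share track bins): clustered features with overlapping windows have
correlated occupancy noise, which violates the signed-rank test's
independence assumption and inflates its size — a caveat that applies
equally to real feature sets. These sizes keep the full validation run
in the low minutes on a single core while leaving each check's
statistical resolution well inside its tolerance.

## Known limitations

- Percentile thresholds are computed over bins, not base pairs; with a
  trailing partial bin the two weightings differ microscopically.
- The exact Wilcoxon path requires untied |differences|; heavily tied
  data silently use the (continuity-corrected) approximation.
- Through-origin slopes are attenuated by noise in the reference
  factor's occupancies (errors-in-variables); at the default noise the
  bias is ≪ the ±0.1 tolerance, but it grows at low coverage.
- Real-data mode starts from bedGraph coverage; BAM/bigWig ingestion is
  out of scope.
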